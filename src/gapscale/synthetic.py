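"""Synthetic embryo cohorts with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: four inbred lines forming two pairs with enlarged within-pair
length differences, exponential Bicoid gradients scaled either by amplitude
or by length constant, and per-embryo 50-bin expression profiles for six
gap genes whose 20 named half-maximum boundaries drift over the 10 time
classes and scale with embryo length according to configured true scaling
coefficients.

The central construction: for boundary b at time class t in an embryo of
length L from a pair with reference length <L>,

    xi_true = xi_mean(b, t) + S(b, t) * (L - <L>) / <L>
    xi_obs  = xi_true + N(0, positional_noise_sd)

so the pooled ordinary-least-squares slope of xi on L/<L> is exactly the
configured S.  Profiles are logistic-flank plateau domains whose
half-maximum crossings sit exactly at the drawn positions; only those
crossings matter downstream, the inter-flank shape is a modelling
convenience.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .config import (
    CohortConfig,
    ConfigurationError,
    LineSpec,
    PairConfig,
    default_config,
)
from .registry import (
    BOUNDARIES,
    GENE_DOMAINS,
    GENES,
    TIME_CLASSES,
    registry_violations,
)

_MAX_REDRAWS = 1000


def bin_centers(n_bins: int = 50) -> np.ndarray:
    """AP bin centers (k + 0.5) / n on [0, 1]."""
    return (np.arange(n_bins) + 0.5) / n_bins


# ---------------------------------------------------------------------------
# Bcd gradients

def bcd_profile(line: LineSpec, length_um: float, xi: np.ndarray) -> np.ndarray:
    """Noiseless Bcd concentration profile C(xi) = A exp(-xi L / lambda).

    Strictly decreasing in xi with C(0) = A.
    """
    if length_um <= 0:
        raise ValueError("length_um must be > 0")
    xi = np.asarray(xi, dtype=float)
    return line.bcd_amplitude * np.exp(
        -xi * length_um / line.bcd_length_constant_um
    )


def bcd_threshold_xi(line: LineSpec, length_um: float, threshold: float) -> float:
    """Closed-form crossing xi_T = (lambda / L) ln(A / T) of the noiseless
    gradient; the analytic oracle for the Monte-Carlo threshold model."""
    return (
        line.bcd_length_constant_um / length_um
        * np.log(line.bcd_amplitude / threshold)
    )


def bcd_mean_sd_profiles(
    line: LineSpec, xi: np.ndarray, length_um: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin mean and s.d. of a line's relative Bcd profile.

    The mean is the noiseless exponential at the line's mean length (or an
    explicit length); the s.d. is ``bcd_noise_cv`` times the mean.
    """
    L = line.mean_length_um if length_um is None else length_um
    mean = bcd_profile(line, L, xi)
    return mean, line.bcd_noise_cv * mean


# ---------------------------------------------------------------------------
# profile construction

def _sigma(t: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(t, -500, 500)))


def _logistic_domain(
    xi: np.ndarray, rise: float | None, fall: float | None, width: float
) -> np.ndarray:
    """Unit-peak domain whose half-peak crossings sit exactly at the flanks.

    Flanks are logistics with 10%-90% span ``width`` (C-infinity, so the
    50-bin cubic-spline sampling stays faithful).  When both flanks are
    present their tails overlap and would shift the half-of-local-peak
    crossings outward; the flank centres are therefore pulled inward by
    the closed-form compensation below, and the profile renormalised to
    unit peak, so the realised crossings are exact.
    """
    k = 2.0 * np.log(9.0) / width
    if rise is None and fall is None:
        return np.ones_like(xi)
    if rise is None:
        return _sigma(k * (fall - xi))
    if fall is None:
        return _sigma(k * (xi - rise))
    # want sigma(u+v) sigma(v-u) = 0.5 sigma(v)^2 at half-gap offset u;
    # with z = exp(-v) this is z^2 + (4 - 2 cosh u) z + 1 = 0 (small root)
    u = 0.5 * k * (fall - rise)
    c = 2.0 * np.cosh(u) - 4.0
    if c < 2.0:
        raise ConfigurationError(
            f"flanks at {rise:.3f}/{fall:.3f} too close for width {width:.3f}"
        )
    z = 0.5 * (c - np.sqrt(c * c - 4.0))
    v = -np.log(z)
    mid = 0.5 * (rise + fall)
    g = _sigma(k * (xi - (mid - v / k))) * _sigma(k * ((mid + v / k) - xi))
    return g / _sigma(v) ** 2


def profile_from_boundaries(
    domains: Sequence[tuple[float | None, float | None, float]],
    xi: np.ndarray | None = None,
    flank_width: float = 0.05,
    n_bins: int = 50,
) -> np.ndarray:
    """Build an expression profile realising half-maximum crossings.

    Parameters
    ----------
    domains
        Sequence of ``(rise_xi, fall_xi, amplitude)``.  ``None`` for a
        flank means the domain extends to the corresponding pole and that
        flank produces no crossing.
    xi
        Evaluation grid; defaults to the 50 standard bin centers.
    flank_width
        xi span of a smoothstep flank.  Narrow domains shrink their flanks
        so the two half-maximum crossings stay at the requested positions.

    Raises
    ------
    ConfigurationError
        If a domain's flanks are closer than two bin widths, or domains of
        one gene are out of order.
    """
    if xi is None:
        xi = bin_centers(n_bins)
    xi = np.asarray(xi, dtype=float)
    min_gap = 2.0 / n_bins
    prof = np.zeros_like(xi)
    last_right = -np.inf
    for rise, fall, amp in domains:
        if rise is not None and fall is not None:
            if fall - rise < min_gap:
                raise ConfigurationError(
                    f"domain flanks at {rise:.3f} and {fall:.3f} are closer "
                    f"than two bin widths ({min_gap:.3f})"
                )
        left = rise if rise is not None else 0.0
        if left < last_right:
            raise ConfigurationError("domains must be ordered and disjoint")
        last_right = fall if fall is not None else 1.0
        w = flank_width
        if rise is not None and fall is not None:
            w = min(w, 0.8 * (fall - rise))
        prof = prof + amp * _logistic_domain(xi, rise, fall, w)
    return prof


def gene_domains_at(
    pair: PairConfig,
    gene: str,
    time_class: str,
    positions: dict[str, float],
) -> list[tuple[float | None, float | None, float]]:
    """Resolve a gene's domain layout at a time class.

    Undetectable domains (e.g. the anterior *gt* domain before T5) get
    amplitude 0; a domain whose anterior flank alone is undetectable (the
    anterior *hb* domain at T3) extends to the anterior pole instead, so
    only its posterior boundary is seen.
    """
    out: list[tuple[float | None, float | None, float]] = []
    for left, right in GENE_DOMAINS[gene]:
        names = [n for n in (left, right) if n is not None]
        trs = {n: pair.trajectory(n) for n in names}
        detect = {n: trs[n].detectable(time_class) for n in names}
        if not any(detect.values()):
            continue  # whole domain invisible
        lxi = positions[left] if (left is not None and detect[left]) else None
        rxi = positions[right] if (right is not None and detect[right]) else None
        out.append((lxi, rxi, 1.0))
    return out


# ---------------------------------------------------------------------------
# cohort generation

@dataclass
class SyntheticGroundTruth:
    """Everything the generator knows that the analysis must recover.

    ``embryos``: one row per embryo (line, pair, time class, true length,
    staging features).  ``boundaries``: one row per embryo x detectable
    boundary with the pre-noise true position (``xi_true``) and the drawn
    observed position realised in the profile (``xi_drawn``).
    ``trajectories``: pair x boundary x time class mean positions and true
    S.  Fully determined by (config, seed).
    """

    embryos: pd.DataFrame
    boundaries: pd.DataFrame
    trajectories: pd.DataFrame
    seed: int


@dataclass
class Cohort:
    """A generated cohort: long-format profiles plus ground truth."""

    profiles: pd.DataFrame | None
    truth: SyntheticGroundTruth
    config: CohortConfig
    seed: int


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    # +-4 s.d. truncation; redraw is cheap at this tail mass
    if sd == 0:
        return mean
    for _ in range(_MAX_REDRAWS):
        x = rng.normal(mean, sd)
        if abs(x - mean) <= 4.0 * sd:
            return x
    raise RuntimeError("truncated normal sampling failed")


def _min_gene_gap(positions: dict[str, float], n_bins: int) -> bool:
    """True if within-gene flank pairs keep >= 2 bin widths separation."""
    min_gap = 2.0 / n_bins
    for gene, doms in GENE_DOMAINS.items():
        flanks = []
        for left, right in doms:
            for n in (left, right):
                if n is not None and n in positions:
                    flanks.append(positions[n])
        flanks.sort()
        if any(b - a < min_gap for a, b in zip(flanks, flanks[1:])):
            return False
    return True


def draw_boundary_positions(
    pair: PairConfig,
    time_class: str,
    delta: float,
    rng: np.random.Generator,
    n_bins: int = 50,
) -> tuple[dict[str, float], dict[str, float]]:
    """Draw one embryo's observed boundary positions.

    ``delta`` is the embryo's fractional length deviation (L - <L>) / <L>.
    Returns (true positions, drawn positions); draws are rejected until the
    registry order and within-gene minimum gaps hold, so every generated
    embryo obeys the registry.
    """
    true: dict[str, float] = {}
    for tr in pair.trajectories:
        if tr.detectable(time_class):
            true[tr.boundary_name] = tr.xi(time_class) + tr.S(time_class) * delta
    for _ in range(_MAX_REDRAWS):
        drawn = {
            n: true[n] + rng.normal(0.0, pair.trajectory(n).positional_noise_sd)
            for n in true
        }
        if not all(0.01 < x < 0.99 for x in drawn.values()):
            continue
        if registry_violations(drawn):
            continue
        if not _min_gene_gap(drawn, n_bins):
            continue
        return true, drawn
    raise ConfigurationError(
        f"{pair.name} at {time_class}: could not draw registry-consistent "
        "boundary positions; trajectory means are likely too close"
    )


def generate_cohort(
    config: CohortConfig | None = None,
    n_per_line_per_class: int = 5,
    seed: int = 0,
    with_profiles: bool = True,
    time_classes: Sequence[str] = TIME_CLASSES,
) -> Cohort:
    """Generate a full cohort across all configured pairs and time classes.

    Reproducible bit-identically from ``(config, seed)``.  With
    ``with_profiles=False`` only boundary observations and metadata are
    produced (fast path for analyses that skip profile detection).
    """
    if config is None:
        config = default_config()
    if n_per_line_per_class < 1:
        raise ValueError("n_per_line_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    n_bins = config.profile.n_bins
    xi_grid = bin_centers(n_bins)

    emb_rows, bnd_rows, prof_rows = [], [], []
    for pair in config.pairs:
        for line in pair.lines:
            for t in time_classes:
                for k in range(n_per_line_per_class):
                    eid = f"{pair.name}:{line.name}:{t}:{k:03d}"
                    L = _truncated_normal(rng, line.mean_length_um, line.length_sd_um)
                    delta = (L - pair.mean_length_um) / pair.mean_length_um
                    true, drawn = draw_boundary_positions(
                        pair, t, delta, rng, n_bins
                    )
                    stg = config.staging
                    if t == "nc13":
                        nl, ind = stg.nc13_nuclear_length, stg.nc13_internuclear
                    else:
                        nl = stg.nc14_nuclear_length[t]
                        ind = stg.nc14_internuclear
                    emb_rows.append(
                        dict(
                            embryo_id=eid, pair=pair.name, line=line.name,
                            time_class=t, length_um=L,
                            invagination_ratio=stg.invagination_by_class[t],
                            nuclear_length_um=nl, internuclear_um=ind,
                        )
                    )
                    for name in true:
                        bnd_rows.append(
                            dict(
                                embryo_id=eid, pair=pair.name, line=line.name,
                                time_class=t, boundary_name=name,
                                gene=BOUNDARIES[name].gene,
                                polarity=BOUNDARIES[name].polarity,
                                xi_true=true[name], xi_drawn=drawn[name],
                                length_um=L,
                            )
                        )
                    if with_profiles:
                        for gene in GENES:
                            doms = gene_domains_at(pair, gene, t, drawn)
                            y = profile_from_boundaries(
                                doms, xi_grid, config.profile.flank_width, n_bins
                            )
                            if config.profile.intensity_noise_sd > 0:
                                y = np.clip(
                                    y
                                    * (
                                        1.0
                                        + rng.normal(
                                            0.0,
                                            config.profile.intensity_noise_sd,
                                            size=y.shape,
                                        )
                                    ),
                                    0.0,
                                    None,
                                )
                            for b in range(n_bins):
                                prof_rows.append(
                                    dict(
                                        embryo_id=eid, line=line.name,
                                        time_class=t, length_um=L, gene=gene,
                                        bin_index=b, xi_center=xi_grid[b],
                                        intensity=y[b],
                                    )
                                )

    traj_rows = [
        dict(
            pair=pair.name, boundary_name=tr.boundary_name, time_class=t,
            xi_mean=tr.xi(t), true_S=tr.S(t),
            positional_noise_sd=tr.positional_noise_sd,
        )
        for pair in config.pairs
        for tr in pair.trajectories
        for t in time_classes
        if tr.detectable(t)
    ]
    truth = SyntheticGroundTruth(
        embryos=pd.DataFrame(emb_rows),
        boundaries=pd.DataFrame(bnd_rows),
        trajectories=pd.DataFrame(traj_rows),
        seed=seed,
    )
    profiles = pd.DataFrame(prof_rows) if with_profiles else None
    return Cohort(profiles=profiles, truth=truth, config=config, seed=seed)


def sample_boundary_observations(
    pair: PairConfig,
    boundary_name: str,
    time_classes: Sequence[str],
    n_per_line_per_class: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Fast path: observed (xi, L) for one boundary of one pair.

    Same drawing rules as :func:`generate_cohort` but restricted to a
    single trajectory, for estimator-recovery simulations.
    """
    rng = np.random.default_rng(seed)
    tr = pair.trajectory(boundary_name)
    rows = []
    for line in pair.lines:
        for t in time_classes:
            if not tr.detectable(t):
                continue
            for _ in range(n_per_line_per_class):
                L = _truncated_normal(rng, line.mean_length_um, line.length_sd_um)
                delta = (L - pair.mean_length_um) / pair.mean_length_um
                xi = (
                    tr.xi(t)
                    + tr.S(t) * delta
                    + rng.normal(0.0, tr.positional_noise_sd)
                )
                rows.append(
                    dict(
                        pair=pair.name, line=line.name, time_class=t,
                        boundary_name=boundary_name, length_um=L, xi=xi,
                    )
                )
    return pd.DataFrame(rows)


def true_scaling_slope(truth: SyntheticGroundTruth, pair: str, boundary: str,
                       time_class: str, mean_length_um: float) -> float:
    """Closed-form OLS slope of pre-noise true xi against L/<L>.

    By construction this equals the configured S exactly (oracle check).
    """
    df = truth.boundaries
    sel = df[
        (df.pair == pair)
        & (df.boundary_name == boundary)
        & (df.time_class == time_class)
    ]
    x = sel.length_um.to_numpy() / mean_length_um
    y = sel.xi_true.to_numpy()
    x = x - x.mean()
    return float((x * (y - y.mean())).sum() / (x * x).sum())


# ---------------------------------------------------------------------------
# ground-truth serialisation (profiles CSV lives in gapscale.io)

def ground_truth_to_json(truth: SyntheticGroundTruth, path) -> None:
    payload = {
        "seed": truth.seed,
        "embryos": truth.embryos.to_dict(orient="records"),
        "boundaries": truth.boundaries.to_dict(orient="records"),
        "trajectories": truth.trajectories.to_dict(orient="records"),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def ground_truth_from_json(path) -> SyntheticGroundTruth:
    with open(path) as fh:
        payload = json.load(fh)
    return SyntheticGroundTruth(
        embryos=pd.DataFrame(payload["embryos"]),
        boundaries=pd.DataFrame(payload["boundaries"]),
        trajectories=pd.DataFrame(payload["trajectories"]),
        seed=payload["seed"],
    )
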