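"""Configuration objects for cohorts, lines, trajectories and staging.

The default configuration emulates the study design: two pairs of inbred
lines selected for embryo-size extremes, with within-pair mean-length
differences of 24.5% (amplitude-scaled Bicoid pair, ``P_A``) and 23.6%
(length-constant-scaled pair, ``P_lambda``).  Each pair carries 20 named
gap-gene boundaries whose mean positions drift over the 10 time classes and
whose true scaling coefficients S follow a posterior-decreasing ("tilted")
profile at the final stage.

Units: lengths in micrometres, positions in fractional embryo length xi,
S dimensionless (d xi per fractional change in L).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import yaml

from .registry import (
    BOUNDARIES,
    REGISTRY_CHAIN,
    TIME_CLASSES,
    TIME_INDEX,
    StageDefinition,
    DEFAULT_STAGES,
    registry_violations,
)


class ConfigurationError(ValueError):
    """Raised when a cohort configuration violates a structural invariant."""


@dataclass(frozen=True)
class LineSpec:
    """One inbred line: embryo-length distribution and Bicoid gradient.

    The Bcd gradient is the exponential C(xi) = A * exp(-xi * L / lambda)
    with amplitude ``bcd_amplitude`` (A, arbitrary concentration units) and
    length constant ``bcd_length_constant_um`` (lambda, micrometres).
    ``bcd_noise_cv`` is the per-bin coefficient of variation used when the
    line's mean/sd profiles feed the Monte-Carlo threshold model.
    """

    name: str
    mean_length_um: float
    length_sd_um: float
    bcd_amplitude: float
    bcd_length_constant_um: float
    bcd_noise_cv: float = 0.15

    def __post_init__(self) -> None:
        if self.mean_length_um <= 0:
            raise ConfigurationError(f"{self.name}: mean_length_um must be > 0")
        if self.length_sd_um < 0:
            raise ConfigurationError(f"{self.name}: length_sd_um must be >= 0")
        if self.bcd_amplitude <= 0:
            raise ConfigurationError(f"{self.name}: bcd_amplitude must be > 0")
        if self.bcd_length_constant_um <= 0:
            raise ConfigurationError(
                f"{self.name}: bcd_length_constant_um must be > 0"
            )


@dataclass(frozen=True)
class BoundaryTrajectorySpec:
    """Ground-truth trajectory of one named boundary within one pair.

    ``xi_by_timeclass`` gives the pair-level mean position at each time
    class; ``true_S_by_timeclass`` the scaling coefficient imposed at each
    time class.  Per embryo, the true position is
    ``xi_mean(t) + S(t) * (L - <L>) / <L>`` with <L> the mean of the two
    lines' mean lengths, which makes the pooled-regression estimand exactly
    S.  ``positional_noise_sd`` is added on top, independently per embryo.
    """

    boundary_name: str
    gene: str
    polarity: str
    xi_by_timeclass: Mapping[str, float]
    true_S_by_timeclass: Mapping[str, float]
    positional_noise_sd: float = 0.01
    detectable_from: str = "nc13"
    undetectable_at: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.boundary_name not in BOUNDARIES:
            raise ConfigurationError(f"unknown boundary {self.boundary_name!r}")
        ref = BOUNDARIES[self.boundary_name]
        if (self.gene, self.polarity) != (ref.gene, ref.polarity):
            raise ConfigurationError(
                f"{self.boundary_name}: gene/polarity must be "
                f"({ref.gene}, {ref.polarity})"
            )
        for t, xi in self.xi_by_timeclass.items():
            if not 0.0 < xi < 1.0:
                raise ConfigurationError(
                    f"{self.boundary_name}: xi at {t} must lie in (0, 1)"
                )
        if self.positional_noise_sd < 0:
            raise ConfigurationError(
                f"{self.boundary_name}: positional_noise_sd must be >= 0"
            )

    def detectable(self, time_class: str) -> bool:
        return (
            TIME_INDEX[time_class] >= TIME_INDEX[self.detectable_from]
            and time_class not in self.undetectable_at
        )

    def xi(self, time_class: str) -> float:
        return float(self.xi_by_timeclass[time_class])

    def S(self, time_class: str) -> float:
        return float(self.true_S_by_timeclass[time_class])


@dataclass(frozen=True)
class PairConfig:
    """A large/small line pair with its 20 boundary trajectories."""

    name: str
    line_large: LineSpec
    line_small: LineSpec
    trajectories: tuple[BoundaryTrajectorySpec, ...]
    fractional_length_difference: float

    def __post_init__(self) -> None:
        ll, ls = self.line_large.mean_length_um, self.line_small.mean_length_um
        frac = abs(ll - ls) / ((ll + ls) / 2.0)
        if abs(frac - self.fractional_length_difference) > 1e-9:
            raise ConfigurationError(
                f"{self.name}: configured fractional length difference "
                f"{self.fractional_length_difference} does not match line "
                f"means (actual {frac:.6f})"
            )
        self.validate_trajectories()

    @property
    def mean_length_um(self) -> float:
        """<L>: mean of the two lines' mean lengths."""
        return 0.5 * (
            self.line_large.mean_length_um + self.line_small.mean_length_um
        )

    @property
    def lines(self) -> tuple[LineSpec, LineSpec]:
        return (self.line_large, self.line_small)

    def line(self, name: str) -> LineSpec:
        for ln in self.lines:
            if ln.name == name:
                return ln
        raise KeyError(name)

    def trajectory(self, boundary_name: str) -> BoundaryTrajectorySpec:
        for tr in self.trajectories:
            if tr.boundary_name == boundary_name:
                return tr
        raise KeyError(boundary_name)

    def validate_trajectories(self) -> None:
        """Mean positions must obey the registry order at every time class."""
        for t in TIME_CLASSES:
            positions = {
                tr.boundary_name: tr.xi(t)
                for tr in self.trajectories
                if t in tr.xi_by_timeclass and tr.detectable(t)
            }
            bad = registry_violations(positions, REGISTRY_CHAIN)
            if bad:
                a, p = bad[0]
                raise ConfigurationError(
                    f"{self.name}: registry pair {a} < {p} violated at {t}"
                )


@dataclass(frozen=True)
class StagingConfig:
    """Nuclear-morphology staging: rendering targets and classifier cuts.

    nc13 embryos have short nuclei and large internuclear distances; nc14
    nuclei elongate (T1 -> T3) and the dorsal membrane invaginates
    progressively (T3 -> T9).  The classifier first separates nc13 from
    nc14 on internuclear distance and nuclear length, splits T1/T2 on
    nuclear length while invagination is absent, then reads T3..T9 from a
    monotone partition of the invagination ratio (invagination depth over
    dorsal half-height).  The exact ratio cut points of the original
    protocol live in its antecedent work and are not published; the
    defaults below are placeholders forming a monotone partition of [0, 1)
    and are fully configurable.
    """

    # rendering targets, micrometres
    nc13_nuclear_length: float = 6.0
    nc13_internuclear: float = 12.0
    nc14_internuclear: float = 6.0
    nc14_nuclear_length: Mapping[str, float] = field(
        default_factory=lambda: {
            "T1": 9.0, "T2": 13.0, "T3": 16.0, "T4": 16.0, "T5": 16.0,
            "T6": 16.0, "T7": 16.0, "T8": 16.0, "T9": 16.0,
        }
    )
    #: invagination ratio drawn by the renderer per class
    invagination_by_class: Mapping[str, float] = field(
        default_factory=lambda: {
            "nc13": 0.0, "T1": 0.0, "T2": 0.0, "T3": 0.055, "T4": 0.115,
            "T5": 0.195, "T6": 0.295, "T7": 0.41, "T8": 0.54, "T9": 0.80,
        }
    )
    # classifier cut points
    nc13_internuclear_min: float = 9.0
    nc13_nuclear_length_max: float = 7.5
    t1_t2_nuclear_length_cut: float = 11.0
    invagination_onset: float = 0.03
    #: lower edges of the T3..T9 invagination-ratio bins
    invagination_bins: tuple[float, ...] = (0.03, 0.08, 0.15, 0.24, 0.35, 0.47, 0.61)

    def __post_init__(self) -> None:
        if list(self.invagination_bins) != sorted(self.invagination_bins):
            raise ConfigurationError("invagination_bins must be increasing")


@dataclass(frozen=True)
class RenderConfig:
    """Geometry and intensities of the schematic embryo renderer."""

    pixel_size_um: float = 1.0
    margin_px: int = 20
    half_height_frac: float = 0.2      # dorsoventral semi-axis as fraction of L
    anterior_exponent: float = 2.5     # superellipse exponent, blunter end
    posterior_exponent: float = 2.0
    nuclear_base: float = 0.15         # cytoplasmic background in DAPI channel
    fish_base: float = 0.0
    nuclear_blob_width_um: float = 4.0
    min_length_px: int = 100           # need >= 2 px per AP bin


@dataclass(frozen=True)
class ProfileConfig:
    """Shape parameters of generated 50-bin expression profiles."""

    n_bins: int = 50
    flank_width: float = 0.05          # xi span of a smoothstep flank
    intensity_noise_sd: float = 0.0    # multiplicative, per bin
    detectability_floor: float = 0.2   # domain peak relative to profile max


@dataclass(frozen=True)
class CohortConfig:
    """Everything the synthetic generator needs."""

    pairs: tuple[PairConfig, ...]
    staging: StagingConfig = StagingConfig()
    render: RenderConfig = RenderConfig()
    profile: ProfileConfig = ProfileConfig()
    stages: StageDefinition = DEFAULT_STAGES

    def pair(self, name: str) -> PairConfig:
        for p in self.pairs:
            if p.name == name:
                return p
        raise KeyError(name)

    def pair_of_line(self, line_name: str) -> PairConfig:
        for p in self.pairs:
            if line_name in (p.line_large.name, p.line_small.name):
                return p
        raise KeyError(line_name)


# ---------------------------------------------------------------------------
# default study emulation

#: per-boundary mean positions at T1 and T9 (nc13 tracks T1; linear drift
#: in between).  Anterior boundaries drift posterior, posterior boundaries
#: anterior, mid-embryo boundaries (hb2/Kr1) and the most anterior (kni1)
#: are static; otd1 and gt6 carry the largest spans (+0.09 / -0.08).
DEFAULT_TRACKS: dict[str, tuple[float, float]] = {
    "gt1": (0.060, 0.065),
    "gt2": (0.115, 0.125),
    "kni1": (0.100, 0.100),
    "otd1": (0.130, 0.220),
    "tll1": (0.175, 0.245),
    "hb1": (0.240, 0.290),
    "gt3": (0.245, 0.295),
    "tll2": (0.272, 0.322),
    "otd2": (0.295, 0.350),
    "gt4": (0.360, 0.400),
    "hb2": (0.470, 0.470),
    "Kr1": (0.475, 0.475),
    "Kr2": (0.605, 0.585),
    "kni2": (0.610, 0.590),
    "kni3": (0.700, 0.660),
    "gt5": (0.705, 0.665),
    "gt6": (0.830, 0.750),
    "hb3": (0.835, 0.785),
    "tll3": (0.890, 0.840),
    "hb4": (0.945, 0.925),
}

#: boundaries whose early-stage S carries the pair-specific Bcd signature
EARLY_BCD_SET = frozenset(
    {"gt1", "gt2", "kni1", "otd1", "tll1", "hb1", "gt3", "tll2", "otd2"}
)

#: final-stage tilt S_f(xi) = TILT_A + TILT_B * xi plus a deterministic
#: boundary-specific deviation; chosen so e.g. tll3 lands near S ~ -0.25.
#: Clipped so that even 4-s.d. embryo lengths keep every true boundary
#: position inside (0.01, 0.99).
TILT_A = 0.41
TILT_B = -0.83
TILT_DEV = 0.04
S_F_MIN = -0.28
S_F_MAX = 0.22

#: early-stage |S| in the anterior for the two pairs (over-scaled in the
#: amplitude pair, under-scaled in the lambda pair)
EARLY_ANTERIOR_S = 0.05

#: time class after which S ramps from its early to its final value
S_RAMP_FROM = "T3"


def linear_track(xi_t1: float, xi_t9: float) -> dict[str, float]:
    """Mean position per time class, linear from T1 to T9, nc13 = T1."""
    out = {"nc13": xi_t1}
    for t in TIME_CLASSES[1:]:
        f = (TIME_INDEX[t] - 1) / 8.0
        out[t] = xi_t1 + (xi_t9 - xi_t1) * f
    return out


def ramped_S(s_early: float, s_final: float, ramp_from: str = S_RAMP_FROM) -> dict[str, float]:
    """S per time class: hold ``s_early`` through ``ramp_from``, then ramp
    linearly to ``s_final`` at T9."""
    i0 = TIME_INDEX[ramp_from]
    span = TIME_INDEX["T9"] - i0
    out = {}
    for t in TIME_CLASSES:
        f = max(0, TIME_INDEX[t] - i0) / span
        out[t] = s_early + (s_final - s_early) * f
    return out


def default_trajectories(
    pair_kind: str,
    positional_noise_sd: float = 0.01,
) -> tuple[BoundaryTrajectorySpec, ...]:
    """Default 20-boundary trajectory set for ``'amplitude'`` or ``'lambda'``
    scaling pairs.

    Both pairs share mean-position tracks and final-stage S (their scaling
    characteristics converge); they differ in the early anterior S, which
    mirrors the sign of the pair's Bcd-encoded positional difference.
    """
    if pair_kind not in ("amplitude", "lambda"):
        raise ConfigurationError("pair_kind must be 'amplitude' or 'lambda'")
    sign = 1.0 if pair_kind == "amplitude" else -1.0
    # deterministic boundary-specific deviation from the pure tilt,
    # alternating along the AP order
    by_xi = sorted(DEFAULT_TRACKS, key=lambda n: DEFAULT_TRACKS[n][1])
    dev = {n: TILT_DEV * (1 if i % 2 == 0 else -1) for i, n in enumerate(by_xi)}
    specs = []
    for name, (xi1, xi9) in DEFAULT_TRACKS.items():
        b = BOUNDARIES[name]
        s_final = min(max(TILT_A + TILT_B * xi9 + dev[name], S_F_MIN), S_F_MAX)
        s_early = sign * EARLY_ANTERIOR_S if name in EARLY_BCD_SET else 0.0
        specs.append(
            BoundaryTrajectorySpec(
                boundary_name=name,
                gene=b.gene,
                polarity=b.polarity,
                xi_by_timeclass=linear_track(xi1, xi9),
                true_S_by_timeclass=ramped_S(s_early, s_final),
                positional_noise_sd=positional_noise_sd,
                detectable_from="T5" if name in ("gt1", "gt2") else "nc13",
                undetectable_at=frozenset({"T3"}) if name == "hb1" else frozenset(),
            )
        )
    return tuple(specs)


def default_pair_A(positional_noise_sd: float = 0.01) -> PairConfig:
    """Amplitude-scaled pair: common lambda, amplitudes tuned so relative
    Bcd-encoded positions coincide at mid-embryo (xi* = 0.5)."""
    lam = 100.0
    l_large, l_small = 561.25, 438.75      # 24.5% of the 500 um pair mean
    a_small = 1.0
    a_large = a_small * math.exp(0.5 * (l_large - l_small) / lam)
    return PairConfig(
        name="P_A",
        line_large=LineSpec("L_A", l_large, 12.0, a_large, lam),
        line_small=LineSpec("S_A", l_small, 12.0, a_small, lam),
        trajectories=default_trajectories("amplitude", positional_noise_sd),
        fractional_length_difference=0.245,
    )


def default_pair_lambda(positional_noise_sd: float = 0.01) -> PairConfig:
    """Length-constant-scaled pair: lambda grows slightly faster than L, so
    the large line's relative gradient is shallower but starts lower; the
    amplitudes are set so encoded positions coincide at xi* = 0.5, giving
    an under-scaled (negative Delta-xi^B) anterior."""
    l_large, l_small = 559.0, 441.0        # 23.6% of the 500 um pair mean
    c_small = 0.195                        # lambda / L for the small line
    c_large = 0.210
    a_small = 1.0
    a_large = a_small * math.exp(-0.5 * (c_large / c_small - 1.0) / c_large)
    return PairConfig(
        name="P_lambda",
        line_large=LineSpec("L_lambda", l_large, 12.0, a_large, c_large * l_large),
        line_small=LineSpec("S_lambda", l_small, 12.0, a_small, c_small * l_small),
        trajectories=default_trajectories("lambda", positional_noise_sd),
        fractional_length_difference=0.236,
    )


def span_ratio_pair(
    ratio: float,
    positional_noise_sd: float = 0.01,
    pair_kind: str = "amplitude",
) -> PairConfig:
    """A pair whose large-line moving spans are ``ratio`` x the small-line's.

    With the per-embryo construction xi = xi_mean(t) + S(t) * delta, a
    line's mean span over any interval is Delta-xi_mean + Delta-S * delta_line
    where delta_line = (L_line - <L>)/<L> = +-half the fractional length
    difference d.  Tying S to the drift as

        S(t) = k * (xi_mean(t) - xi_mean(T1)),  k = (ratio-1) / ((ratio+1) * d/2)

    makes span_large / span_small = ratio exactly, for every boundary and
    every interval.  Useful for span-regression recovery studies.
    """
    base = default_pair_A(positional_noise_sd) if pair_kind == "amplitude" \
        else default_pair_lambda(positional_noise_sd)
    d = base.fractional_length_difference
    k = (ratio - 1.0) / ((ratio + 1.0) * (d / 2.0))
    new_trs = []
    for tr in base.trajectories:
        xi0 = tr.xi("T1")
        S = {t: k * (tr.xi(t) - xi0) for t in TIME_CLASSES}
        new_trs.append(
            BoundaryTrajectorySpec(
                boundary_name=tr.boundary_name, gene=tr.gene,
                polarity=tr.polarity, xi_by_timeclass=tr.xi_by_timeclass,
                true_S_by_timeclass=S,
                positional_noise_sd=tr.positional_noise_sd,
                detectable_from=tr.detectable_from,
                undetectable_at=tr.undetectable_at,
            )
        )
    return PairConfig(
        name=f"span_ratio_{ratio}",
        line_large=base.line_large, line_small=base.line_small,
        trajectories=tuple(new_trs),
        fractional_length_difference=d,
    )


def default_config(positional_noise_sd: float = 0.01) -> CohortConfig:
    """The default two-pair study configuration."""
    return CohortConfig(
        pairs=(
            default_pair_A(positional_noise_sd),
            default_pair_lambda(positional_noise_sd),
        )
    )


# ---------------------------------------------------------------------------
# (de)serialisation

def config_to_dict(cfg: CohortConfig) -> dict:
    d = asdict(cfg)
    # frozensets and mappings to plain types for YAML
    for p in d["pairs"]:
        for tr in p["trajectories"]:
            tr["undetectable_at"] = sorted(tr["undetectable_at"])
            tr["xi_by_timeclass"] = dict(tr["xi_by_timeclass"])
            tr["true_S_by_timeclass"] = dict(tr["true_S_by_timeclass"])
    d["staging"]["nc14_nuclear_length"] = dict(d["staging"]["nc14_nuclear_length"])
    d["staging"]["invagination_by_class"] = dict(d["staging"]["invagination_by_class"])
    d["staging"]["invagination_bins"] = list(d["staging"]["invagination_bins"])
    d["stages"] = {
        "initial": sorted(cfg.stages.initial),
        "intermediate": sorted(cfg.stages.intermediate),
        "final": sorted(cfg.stages.final),
    }
    return d


def config_from_dict(d: dict) -> CohortConfig:
    pairs = []
    for p in d["pairs"]:
        trajectories = tuple(
            BoundaryTrajectorySpec(
                boundary_name=tr["boundary_name"],
                gene=tr["gene"],
                polarity=tr["polarity"],
                xi_by_timeclass=tr["xi_by_timeclass"],
                true_S_by_timeclass=tr["true_S_by_timeclass"],
                positional_noise_sd=tr["positional_noise_sd"],
                detectable_from=tr["detectable_from"],
                undetectable_at=frozenset(tr["undetectable_at"]),
            )
            for tr in p["trajectories"]
        )
        pairs.append(
            PairConfig(
                name=p["name"],
                line_large=LineSpec(**p["line_large"]),
                line_small=LineSpec(**p["line_small"]),
                trajectories=trajectories,
                fractional_length_difference=p["fractional_length_difference"],
            )
        )
    staging_kw = dict(d.get("staging", {}))
    if "invagination_bins" in staging_kw:
        staging_kw["invagination_bins"] = tuple(staging_kw["invagination_bins"])
    staging = StagingConfig(**staging_kw)
    render = RenderConfig(**d.get("render", {}))
    profile = ProfileConfig(**d.get("profile", {}))
    st = d.get("stages")
    stages = (
        StageDefinition(
            frozenset(st["initial"]),
            frozenset(st["intermediate"]),
            frozenset(st["final"]),
        )
        if st
        else DEFAULT_STAGES
    )
    return CohortConfig(
        pairs=tuple(pairs), staging=staging, render=render,
        profile=profile, stages=stages,
    )


def save_config(cfg: CohortConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)


def load_config(path) -> CohortConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))
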