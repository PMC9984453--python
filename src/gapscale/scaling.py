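"""Scaling coefficient S and its stage-wise / between-pair analyses.

S quantifies how a boundary adjusts its fractional position xi = x/L to
embryo-length differences: S = d xi / (dL/L), estimated as the ordinary
least-squares slope of xi against normalised length L/<L>, pooling the
large and small embryos of a pair.  S = 0 is perfect scaling (xi
independent of L); S > 0 over-scaling; S < 0 under-scaling.  A boundary
pinned at a fixed *absolute* position x has xi = x/L and hence S ~ -xi.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .registry import DEFAULT_STAGES, StageDefinition


@dataclass(frozen=True)
class ScalingEstimate:
    """S with 95% CI for one boundary at one time class or stage."""

    boundary_name: str
    pair: str
    label: str
    S: float
    ci95: tuple[float, float]
    p_value: float
    n: int
    xi_mean: float = math.nan

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not (lo <= self.S <= hi):
            raise ValueError("CI must bracket the estimate")


def scaling_coefficient(
    xi: np.ndarray,
    length_um: np.ndarray,
    line: np.ndarray,
    mean_length_um: float | None = None,
    boundary_name: str = "",
    pair: str = "",
    label: str = "",
    alpha: float = 0.05,
    bootstrap: bool = False,
    n_boot: int = 2000,
    seed: int = 0,
) -> ScalingEstimate:
    """Estimate S by pooled OLS of xi on L/<L>.

    Parameters
    ----------
    xi, length_um, line
        Per-embryo boundary position, embryo length and line label, pooled
        over the pair's large and small embryos.
    mean_length_um
        Reference <L>; defaults to the mean of the two lines' mean
        lengths computed from the data.
    bootstrap
        If true, the 95% CI is a percentile bootstrap over embryos instead
        of the t-based OLS interval (sensitivity option).

    Raises
    ------
    ValueError
        If fewer than 4 observations, only one line, fewer than 2 embryos
        in either line, or zero length variance.
    """
    xi = np.asarray(xi, float)
    L = np.asarray(length_um, float)
    line = np.asarray(line)
    if xi.size < 4:
        raise ValueError("need >= 4 pooled observations")
    labs, counts = np.unique(line, return_counts=True)
    if labs.size < 2:
        raise ValueError("both lines must contribute embryos")
    if counts.min() < 2:
        raise ValueError("each line must contribute >= 2 embryos")
    if np.ptp(L) == 0:
        raise ValueError("zero length variance")
    if mean_length_um is None:
        mean_length_um = float(np.mean([L[line == l].mean() for l in labs]))
    x = L / mean_length_um
    model = sm.OLS(xi, sm.add_constant(x)).fit()
    S = float(model.params[1])
    p = float(model.pvalues[1])
    if bootstrap:
        rng = np.random.default_rng(seed)
        idx = np.arange(xi.size)
        slopes = np.empty(n_boot)
        for b in range(n_boot):
            take = rng.choice(idx, size=idx.size, replace=True)
            xb = x[take] - x[take].mean()
            if np.ptp(xb) == 0:
                slopes[b] = np.nan
                continue
            yb = xi[take]
            slopes[b] = (xb * (yb - yb.mean())).sum() / (xb * xb).sum()
        lo, hi = np.nanpercentile(slopes, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    else:
        lo, hi = model.conf_int(alpha=alpha)[1]
    return ScalingEstimate(
        boundary_name, pair, label, S, (float(lo), float(hi)), p,
        int(xi.size), float(xi.mean()),
    )


def scaling_table(
    df: pd.DataFrame,
    pair_name: str,
    when: str,
    mean_length_um: float | None = None,
    stages: StageDefinition = DEFAULT_STAGES,
    min_per_line: int = 2,
) -> pd.DataFrame:
    """Per-boundary scaling estimates for one pair at one time/stage.

    ``df`` is the tidy boundary table; boundaries for which either line
    contributes fewer than ``min_per_line`` embryos yield NaN rows
    (defined-only-when-both-lines-contribute invariant).
    """
    if when in ("i", "m", "f", "initial", "intermediate", "final"):
        classes = stages.classes(when)
    else:
        classes = frozenset({when})
    sub = df[(df.pair == pair_name) & (df.time_class.isin(classes))]
    rows = []
    for b in sorted(sub.boundary_name.unique()):
        sel = sub[sub.boundary_name == b]
        counts = sel.groupby("line").size()
        if len(counts) < 2 or counts.min() < min_per_line:
            rows.append(
                dict(
                    boundary_name=b, pair=pair_name, label=when, S=np.nan,
                    ci_lo=np.nan, ci_hi=np.nan, p_value=np.nan,
                    n=len(sel), xi_mean=sel.xi.mean(),
                )
            )
            continue
        est = scaling_coefficient(
            sel.xi.to_numpy(), sel.length_um.to_numpy(), sel.line.to_numpy(),
            mean_length_um=mean_length_um, boundary_name=b, pair=pair_name,
            label=when,
        )
        rows.append(
            dict(
                boundary_name=b, pair=pair_name, label=when, S=est.S,
                ci_lo=est.ci95[0], ci_hi=est.ci95[1], p_value=est.p_value,
                n=est.n, xi_mean=est.xi_mean,
            )
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation plus OLS slope between two matched S sets."""

    r: float
    p_r: float
    slope: float
    slope_ci95: tuple[float, float]
    p_slope: float
    n: int


def correlate_estimates(
    s1: pd.DataFrame | np.ndarray,
    s2: pd.DataFrame | np.ndarray,
) -> CorrelationResult:
    """Correlate two matched sets of scaling estimates.

    Accepts two ``scaling_table`` frames (matched on ``boundary_name``) or
    two aligned arrays.  NaN pairs are excluded pairwise; fewer than 3
    finite pairs is an error.
    """
    if isinstance(s1, pd.DataFrame):
        merged = s1.merge(s2, on="boundary_name", suffixes=("_1", "_2"))
        x = merged.S_1.to_numpy()
        y = merged.S_2.to_numpy()
    else:
        x = np.asarray(s1, float)
        y = np.asarray(s2, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need >= 3 matched finite estimates")
    r, p_r = stats.pearsonr(x, y)
    if np.allclose(y, x):
        return CorrelationResult(1.0, float(p_r), 1.0, (1.0, 1.0), 0.0, x.size)
    model = sm.OLS(y, sm.add_constant(x)).fit()
    lo, hi = model.conf_int(alpha=0.05)[1]
    return CorrelationResult(
        float(r), float(p_r), float(model.params[1]),
        (float(lo), float(hi)), float(model.pvalues[1]), int(x.size),
    )


def tilt_correlation(
    S: np.ndarray, xi: np.ndarray
) -> tuple[float, float]:
    """Pearson correlation of S against AP position across boundaries.

    The global scaling tilt makes this negative at later stages: anterior
    boundaries over-scale, posterior ones under-scale.
    """
    S = np.asarray(S, float)
    xi = np.asarray(xi, float)
    ok = np.isfinite(S) & np.isfinite(xi)
    if ok.sum() < 3:
        raise ValueError("need >= 3 boundaries")
    r, p = stats.pearsonr(S[ok], xi[ok])
    return float(r), float(p)


def ols_slope_closed_form(x: np.ndarray, y: np.ndarray) -> float:
    """Explicit-summation OLS slope; independent oracle for the estimator."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x.mean(), y.mean()
    return float(((x - xm) * (y - ym)).sum() / ((x - xm) ** 2).sum())
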