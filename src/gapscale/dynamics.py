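"""Boundary-dynamics algebra: stage means, moving spans, Delta-xi^P.

All operations act on the tidy boundary table produced by
:func:`gapscale.boundaries.detect_cohort` (or equivalent real data):
columns ``embryo_id, pair, line, time_class, boundary_name, xi`` plus
``length_um`` where needed.

Conventions: a moving span Delta-xi(a -> b) is the mean position at the
later time minus the earlier one, within one line; a position difference
Delta-xi^P is the large-line mean minus the small-line mean at one time;
missing cells propagate as NaN records, never as zeros.  Uncertainty on a
difference of means is the propagated standard error
sqrt(sd_a^2/n_a + sd_b^2/n_b), which assumes independence between the two
groups (true for the cohort design); the s.d. spread *across boundaries*
of a set of spans is a different quantity and is left to the caller's
aggregation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .registry import ANTERIOR_BOUNDARIES, DEFAULT_STAGES, StageDefinition

EARLY_GROUP = ("nc13", "T1", "T2", "T3")


@dataclass(frozen=True)
class StageStats:
    """Mean boundary position over embryos pooled across stage classes."""

    boundary_name: str
    line: str
    label: str
    mean: float
    sd: float
    n: int

    @property
    def is_missing(self) -> bool:
        return self.n == 0


@dataclass(frozen=True)
class MovingSpan:
    """Positional change of one boundary between two times within a line."""

    boundary_name: str
    line: str
    label: str
    delta_xi: float
    delta_sd: float
    n_from: int
    n_to: int

    @property
    def is_missing(self) -> bool:
        return math.isnan(self.delta_xi)


@dataclass(frozen=True)
class PositionDifference:
    """Delta-xi^P: large-line minus small-line mean position."""

    boundary_name: str
    pair: str
    label: str
    delta_xi_p: float
    delta_sd: float
    n_large: int
    n_small: int


def _classes_of(when, stages: StageDefinition):
    if when is None:
        return None
    if when in ("i", "m", "f", "initial", "intermediate", "final"):
        return stages.classes(when)
    return frozenset({when})


def stage_mean(
    df: pd.DataFrame,
    boundary_name: str,
    line: str,
    when: str | None,
    stages: StageDefinition = DEFAULT_STAGES,
) -> StageStats:
    """Mean +- sd position of a boundary in a line at a time class or stage.

    ``when`` is a time-class name, a stage key (``'i'``/``'m'``/``'f'``),
    or ``None`` to pool every class present.  An empty cell returns a
    missing record (NaN mean, n = 0); a single observation returns its
    value with NaN sd.
    """
    classes = _classes_of(when, stages)
    sel = df[(df.boundary_name == boundary_name) & (df.line == line)]
    if classes is not None:
        sel = sel[sel.time_class.isin(classes)]
    n = len(sel)
    label = when if when is not None else "all"
    if n == 0:
        return StageStats(boundary_name, line, label, math.nan, math.nan, 0)
    xi = sel.xi.to_numpy()
    sd = float(np.std(xi, ddof=1)) if n > 1 else math.nan
    return StageStats(boundary_name, line, label, float(xi.mean()), sd, n)


def _diff_of_means(a: StageStats, b: StageStats) -> tuple[float, float]:
    """(b - a) with propagated standard error; NaN-safe."""
    if a.is_missing or b.is_missing:
        return math.nan, math.nan
    var = 0.0
    for s in (a, b):
        if s.n > 1 and not math.isnan(s.sd):
            var += s.sd**2 / s.n
        else:
            var = math.nan
            break
    return b.mean - a.mean, math.sqrt(var) if not math.isnan(var) else math.nan


def moving_span(
    df: pd.DataFrame,
    boundary_name: str,
    line: str,
    t_from: str,
    t_to: str,
    stages: StageDefinition = DEFAULT_STAGES,
) -> MovingSpan:
    """Moving span of one boundary between two times (classes or stages)."""
    a = stage_mean(df, boundary_name, line, t_from, stages)
    b = stage_mean(df, boundary_name, line, t_to, stages)
    d, sd = _diff_of_means(a, b)
    return MovingSpan(
        boundary_name, line, f"{t_to}/{t_from}", d, sd, a.n, b.n
    )


def spans_table(
    df: pd.DataFrame,
    line: str,
    t_from: str,
    t_to: str,
    stages: StageDefinition = DEFAULT_STAGES,
) -> pd.DataFrame:
    """Moving spans of every boundary of a line over one interval."""
    rows = []
    for b in sorted(df.boundary_name.unique()):
        s = moving_span(df, b, line, t_from, t_to, stages)
        rows.append(
            dict(
                boundary_name=b, line=line, label=s.label,
                delta_xi=s.delta_xi, delta_sd=s.delta_sd,
                n_from=s.n_from, n_to=s.n_to,
            )
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    ci95: tuple[float, float]
    p_value: float
    n: int


def regress_spans(
    spans_large: pd.DataFrame, spans_small: pd.DataFrame
) -> RegressionResult:
    """OLS of large-line spans on small-line spans across boundaries.

    Fits slope and intercept; the slope (with its t-based 95% CI and
    p-value) is the reported quantity.  Boundaries with a missing span in
    either line are excluded pairwise.
    """
    merged = spans_large.merge(
        spans_small, on="boundary_name", suffixes=("_L", "_S")
    ).dropna(subset=["delta_xi_L", "delta_xi_S"])
    if len(merged) < 3:
        raise ValueError("need >= 3 boundaries with spans in both lines")
    x = merged.delta_xi_S.to_numpy()
    y = merged.delta_xi_L.to_numpy()
    if np.ptp(x) == 0:
        raise ValueError("degenerate regressor: small-line spans are constant")
    if np.allclose(y, x):
        # identity input: slope exactly 1, zero-width CI
        return RegressionResult(1.0, 0.0, (1.0, 1.0), 0.0, len(merged))
    model = sm.OLS(y, sm.add_constant(x)).fit()
    lo, hi = model.conf_int(alpha=0.05)[1]
    return RegressionResult(
        float(model.params[1]), float(model.params[0]),
        (float(lo), float(hi)), float(model.pvalues[1]), len(merged),
    )


def position_difference(
    df: pd.DataFrame,
    boundary_name: str,
    pair_name: str,
    line_large: str,
    line_small: str,
    when: str,
    stages: StageDefinition = DEFAULT_STAGES,
) -> PositionDifference:
    """Delta-xi^P of one boundary at one time class or stage.

    Antisymmetric under swapping the large and small lines.
    """
    s = stage_mean(df, boundary_name, line_small, when, stages)
    l = stage_mean(df, boundary_name, line_large, when, stages)
    d, sd = _diff_of_means(s, l)
    return PositionDifference(boundary_name, pair_name, when, d, sd, l.n, s.n)


def delta_xi_p_table(
    df: pd.DataFrame,
    pair_name: str,
    line_large: str,
    line_small: str,
    when: str,
    stages: StageDefinition = DEFAULT_STAGES,
) -> pd.DataFrame:
    """Delta-xi^P for every boundary, with the mean position for tilt plots."""
    rows = []
    sub = df[df.pair == pair_name] if "pair" in df else df
    for b in sorted(sub.boundary_name.unique()):
        pd_ = position_difference(
            df, b, pair_name, line_large, line_small, when, stages
        )
        sm_ = stage_mean(df, b, line_small, when, stages)
        lm_ = stage_mean(df, b, line_large, when, stages)
        xi_mean = np.nanmean([sm_.mean, lm_.mean])
        rows.append(
            dict(
                boundary_name=b, pair=pair_name, label=when,
                xi_mean=xi_mean, delta_xi_p=pd_.delta_xi_p,
                delta_sd=pd_.delta_sd, n_large=pd_.n_large,
                n_small=pd_.n_small,
            )
        )
    return pd.DataFrame(rows)


def tilt_spearman(table: pd.DataFrame) -> tuple[float, float]:
    """Spearman correlation of Delta-xi^P against AP position.

    The developing "tilt" makes this negative: anterior boundaries
    over-shift (positive Delta-xi^P), posterior ones under-shift.
    """
    t = table.dropna(subset=["xi_mean", "delta_xi_p"])
    r, p = stats.spearmanr(t.xi_mean, t.delta_xi_p)
    return float(r), float(p)


def anterior_group_compare(
    df: pd.DataFrame,
    pair_a: tuple[str, str, str],
    pair_b: tuple[str, str, str],
    xi_cut: float = 0.3,
    boundaries: tuple[str, ...] = ANTERIOR_BOUNDARIES,
    early_classes: tuple[str, ...] = EARLY_GROUP,
) -> dict:
    """Compare anterior Delta-xi^P between two pairs, early vs late group.

    Embryos are split into an early group (nc13..T3) and the remaining
    later classes; for the anterior boundaries (xi < ``xi_cut``) the mean
    Delta-xi^P per pair per group is computed and the pairs compared by a
    paired t-test across boundaries.

    ``pair_a``/``pair_b`` are (pair_name, line_large, line_small).
    """
    late_classes = tuple(
        t for t in df.time_class.unique() if t not in early_classes
    )
    out: dict = {"boundaries": list(boundaries), "xi_cut": xi_cut}
    per_group_values: dict[str, dict[str, np.ndarray]] = {}
    for group, classes in (("early", early_classes), ("late", late_classes)):
        sub = df[df.time_class.isin(classes)]
        vals: dict[str, np.ndarray] = {}
        for name, large, small in (pair_a, pair_b):
            v = []
            for b in boundaries:
                s = stage_mean(sub, b, small, None)
                l = stage_mean(sub, b, large, None)
                v.append(
                    l.mean - s.mean
                    if not (l.is_missing or s.is_missing)
                    else math.nan
                )
            vals[name] = np.array(v)
            out[f"{group}_{name}_mean"] = float(np.nanmean(vals[name]))
            out[f"{group}_{name}_sd"] = float(np.nanstd(vals[name], ddof=1))
        per_group_values[group] = vals
        a = vals[pair_a[0]]
        b_ = vals[pair_b[0]]
        ok = ~(np.isnan(a) | np.isnan(b_))
        if ok.sum() < 2:
            raise ValueError("need >= 2 paired anterior boundaries")
        if np.allclose(a[ok], b_[ok]):
            out[f"{group}_t"] = 0.0
            out[f"{group}_p"] = 1.0
        else:
            t, p = stats.ttest_rel(a[ok], b_[ok])
            out[f"{group}_t"] = float(t)
            out[f"{group}_p"] = float(p)
    out["values"] = per_group_values
    return out
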