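"""Moving-span algebra, position differences and span regressions."""

import math

import numpy as np
import pandas as pd
import pytest

import gapscale as gs
from gapscale.config import CohortConfig, span_ratio_pair
from gapscale.dynamics import (
    anterior_group_compare,
    delta_xi_p_table,
    moving_span,
    position_difference,
    regress_spans,
    spans_table,
    stage_mean,
    tilt_spearman,
)


def toy_table(rows):
    return pd.DataFrame(
        rows, columns=["embryo_id", "pair", "line", "time_class",
                       "boundary_name", "xi", "length_um"]
    )


class TestStageMean:
    def test_single_observation(self):
        df = toy_table([("e1", "P", "L", "T4", "hb2", 0.47, 500.0)])
        s = stage_mean(df, "hb2", "L", "m")
        assert s.mean == 0.47 and s.n == 1 and math.isnan(s.sd)

    def test_empty_cell_is_missing_not_zero(self):
        df = toy_table([("e1", "P", "L", "T4", "hb2", 0.47, 500.0)])
        s = stage_mean(df, "hb2", "L", "f")
        assert s.is_missing and math.isnan(s.mean)

    def test_pools_across_stage_classes(self):
        df = toy_table(
            [
                ("e1", "P", "L", "T4", "hb2", 0.46, 500.0),
                ("e2", "P", "L", "T5", "hb2", 0.48, 500.0),
            ]
        )
        s = stage_mean(df, "hb2", "L", "m")
        assert s.mean == pytest.approx(0.47) and s.n == 2

    def test_hb1_missing_at_t3_propagates_na(self, fast_table):
        s = stage_mean(fast_table, "hb1", "L_A", "T3")
        assert s.is_missing

    def test_estimate_precision_on_synthetic_stage(self, fast_table):
        # noise sd 0.01, n = 2 classes x 15 embryos -> se ~ 0.0018
        cfg = gs.default_config()
        tr = cfg.pair("P_A").trajectory("Kr1")
        s = stage_mean(fast_table[fast_table.pair == "P_A"], "Kr1", "L_A", "m")
        true = np.mean([tr.xi("T4"), tr.xi("T5")])
        assert abs(s.mean - true) < 0.007


class TestMovingSpan:
    def test_identical_positions_zero_span(self):
        df = toy_table(
            [
                ("e1", "P", "L", "T1", "hb2", 0.47, 500.0),
                ("e2", "P", "L", "T9", "hb2", 0.47, 500.0),
            ]
        )
        s = moving_span(df, "hb2", "L", "T1", "T9")
        assert s.delta_xi == 0.0

    def test_missing_endpoint_gives_na_record(self):
        df = toy_table([("e1", "P", "L", "T1", "hb2", 0.47, 500.0)])
        s = moving_span(df, "hb2", "L", "T1", "T9")
        assert s.is_missing

    def test_propagated_sd_formula(self):
        rng = np.random.default_rng(0)
        rows = [
            (f"a{i}", "P", "L", "T1", "otd1", 0.13 + rng.normal(0, 0.01), 500.0)
            for i in range(20)
        ] + [
            (f"b{i}", "P", "L", "T9", "otd1", 0.22 + rng.normal(0, 0.01), 500.0)
            for i in range(30)
        ]
        df = toy_table(rows)
        s = moving_span(df, "otd1", "L", "T1", "T9")
        a = df[df.time_class == "T1"].xi
        b = df[df.time_class == "T9"].xi
        expect = math.sqrt(a.var(ddof=1) / 20 + b.var(ddof=1) / 30)
        assert s.delta_sd == pytest.approx(expect, rel=1e-12)
        assert s.delta_xi == pytest.approx(b.mean() - a.mean(), rel=1e-12)

    def test_additivity_of_mean_spans(self, fast_table):
        """Delta(a->b) + Delta(b->c) == Delta(a->c), exactly on means."""
        for b in ("otd1", "gt6", "Kr1"):
            ab = moving_span(fast_table, b, "L_A", "i", "m").delta_xi
            bc = moving_span(fast_table, b, "L_A", "m", "f").delta_xi
            ac = moving_span(fast_table, b, "L_A", "i", "f").delta_xi
            assert ab + bc == pytest.approx(ac, abs=1e-12)

    def test_configured_drift_recovered(self, fast_table, default_cfg):
        # a line's span is the mean drift plus the S change times the
        # line's fractional length offset
        pair = default_cfg.pair("P_A")
        tr = pair.trajectory("otd1")
        delta_line = (
            pair.line_small.mean_length_um - pair.mean_length_um
        ) / pair.mean_length_um
        true = (tr.xi("T9") - tr.xi("T1")) + (
            tr.S("T9") - tr.S("T1")
        ) * delta_line
        s = moving_span(fast_table, "otd1", "S_A", "T1", "T9")
        assert s.delta_xi == pytest.approx(true, abs=0.01)


class TestRegressSpans:
    def test_identity_input_slope_exactly_one(self, fast_table):
        t = spans_table(fast_table, "L_A", "i", "m")
        r = regress_spans(t, t.copy())
        assert r.slope == 1.0
        assert r.ci95 == (1.0, 1.0)

    def test_degenerate_regressor_raises(self):
        t = pd.DataFrame(
            dict(boundary_name=list("abc"), delta_xi=[0.1, 0.1, 0.1])
        )
        t2 = pd.DataFrame(
            dict(boundary_name=list("abc"), delta_xi=[0.1, 0.2, 0.3])
        )
        with pytest.raises(ValueError, match="degenerate"):
            regress_spans(t2, t)

    def test_needs_three_boundaries(self):
        t = pd.DataFrame(dict(boundary_name=["a"], delta_xi=[0.1]))
        with pytest.raises(ValueError):
            regress_spans(t, t)

    def test_ratio_construction_recovered(self):
        """Cohorts built with large spans = 1.5 x small spans yield a
        regression slope near 1.5."""
        pair = span_ratio_pair(1.5)
        cfg = CohortConfig(pairs=(pair,))
        c = gs.generate_cohort(cfg, 25, seed=9, with_profiles=False)
        df = c.truth.boundaries.rename(columns={"xi_drawn": "xi"})
        sl = spans_table(df, pair.line_large.name, "i", "m")
        ss = spans_table(df, pair.line_small.name, "i", "m")
        r = regress_spans(sl, ss)
        assert 1.4 <= r.slope <= 1.6


class TestPositionDifference:
    def test_equal_means_zero(self):
        df = toy_table(
            [
                ("e1", "P", "L", "T5", "hb2", 0.47, 560.0),
                ("e2", "P", "S", "T5", "hb2", 0.47, 440.0),
            ]
        )
        d = position_difference(df, "hb2", "P", "L", "S", "T5")
        assert d.delta_xi_p == 0.0

    def test_antisymmetry_under_line_swap(self, fast_table):
        for b in ("otd1", "tll3"):
            d1 = position_difference(fast_table, b, "P_A", "L_A", "S_A", "f")
            d2 = position_difference(fast_table, b, "P_A", "S_A", "L_A", "f")
            assert d1.delta_xi_p == pytest.approx(-d2.delta_xi_p, abs=1e-12)

    def test_sign_follows_true_S(self, fast_table, default_cfg):
        """Over-scaled boundaries have positive Delta-xi^P in expectation."""
        pair = default_cfg.pair("P_A")
        for b in ("otd1", "tll3"):
            d = position_difference(fast_table, b, "P_A", "L_A", "S_A", "f")
            s_true = np.mean([pair.trajectory(b).S(t) for t in ("T8", "T9")])
            assert np.sign(d.delta_xi_p) == np.sign(s_true)

    def test_missing_line_gives_na(self):
        df = toy_table([("e1", "P", "L", "T5", "hb2", 0.47, 560.0)])
        d = position_difference(df, "hb2", "P", "L", "S", "T5")
        assert math.isnan(d.delta_xi_p)


class TestTiltAndGroups:
    def test_final_stage_tilt_negative(self, fast_table):
        t = delta_xi_p_table(fast_table, "P_A", "L_A", "S_A", "f")
        r, p = tilt_spearman(t)
        assert r < -0.5

    def test_identical_pairs_p_one(self):
        rows = []
        for b in gs.ANTERIOR_BOUNDARIES:
            for pair, (ll, ls) in (("P1", ("L1", "S1")), ("P2", ("L2", "S2"))):
                for t in ("T1", "T5"):  # populate both groups
                    rows.append(("e", pair, ll, t, b, 0.2, 560.0))
                    rows.append(("e", pair, ls, t, b, 0.18, 440.0))
        df = toy_table(rows)
        res = anterior_group_compare(
            df, ("P1", "L1", "S1"), ("P2", "L2", "S2")
        )
        assert res["early_p"] == 1.0
        assert res["early_P1_mean"] == pytest.approx(res["early_P2_mean"])

    def test_early_sign_flip_between_pairs(self, fast_table):
        """The lambda pair's anterior under-scaling flips sign after T3."""
        res = anterior_group_compare(
            fast_table, ("P_A", "L_A", "S_A"),
            ("P_lambda", "L_lambda", "S_lambda"),
        )
        assert res["early_P_A_mean"] > 0
        assert res["early_P_lambda_mean"] < 0
        assert res["early_p"] < 0.05
        assert res["late_P_lambda_mean"] >= 0  # no longer negative

    def test_uses_the_six_anterior_boundaries(self):
        assert gs.ANTERIOR_BOUNDARIES == (
            "kni1", "otd1", "tll1", "gt3", "tll2", "otd2",
        )
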