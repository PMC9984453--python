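"""Generator contracts: counts, determinism, ground-truth consistency."""

import numpy as np
import pandas as pd
import pytest

import gapscale as gs
from gapscale.config import ConfigurationError, default_config
from gapscale.boundaries import detect_boundaries
from gapscale.synthetic import (
    bcd_profile,
    bcd_threshold_xi,
    bin_centers,
    generate_cohort,
    profile_from_boundaries,
    true_scaling_slope,
)


def test_cohort_counts_default_config():
    c = generate_cohort(n_per_line_per_class=5, seed=1, with_profiles=False)
    # 4 lines x 10 time classes x 5 embryos
    assert len(c.truth.embryos) == 200
    per_line = c.truth.embryos.groupby("line").size()
    assert (per_line == 50).all()


def test_profiles_shape_and_nonnegativity(small_cohort):
    prof = small_cohort.profiles
    counts = prof.groupby(["embryo_id", "gene"]).size()
    assert (counts == 50).all()
    assert prof.groupby("embryo_id").ngroups == len(small_cohort.truth.embryos)
    assert (prof.intensity >= 0).all()


def test_pair_fractional_length_differences(default_cfg):
    for pair, expected in zip(default_cfg.pairs, (0.245, 0.236)):
        ll = pair.line_large.mean_length_um
        ls = pair.line_small.mean_length_um
        assert abs((ll - ls) / ((ll + ls) / 2) - expected) < 1e-9


def test_bit_identical_reproduction(default_cfg):
    a = generate_cohort(default_cfg, 2, seed=123)
    b = generate_cohort(default_cfg, 2, seed=123)
    pd.testing.assert_frame_equal(a.profiles, b.profiles)
    pd.testing.assert_frame_equal(a.truth.embryos, b.truth.embryos)
    pd.testing.assert_frame_equal(a.truth.boundaries, b.truth.boundaries)
    c = generate_cohort(default_cfg, 2, seed=124)
    assert not a.truth.embryos.length_um.equals(c.truth.embryos.length_um)


def test_registry_order_holds_in_every_embryo(small_cohort):
    df = small_cohort.truth.boundaries
    for eid, g in df.groupby("embryo_id"):
        pos = dict(zip(g.boundary_name, g.xi_drawn))
        assert gs.registry_violations(pos) == [], eid


def test_detectability_schedule(small_cohort):
    df = small_cohort.truth.boundaries
    by_class = df.groupby("time_class").boundary_name.unique()
    for t in ("nc13", "T1", "T4"):
        assert "gt1" not in by_class[t] and "gt2" not in by_class[t]
    for t in ("T5", "T9"):
        assert "gt1" in by_class[t] and "gt2" in by_class[t]
    assert "hb1" not in by_class["T3"]
    assert "hb1" in by_class["T2"] and "hb1" in by_class["T4"]


def test_true_S_equals_analytic_slope_of_true_positions(fast_cohort):
    """The imposed construction makes the regression estimand exactly S."""
    cfg = fast_cohort.config
    for pair in cfg.pairs:
        for boundary, t in (("hb2", "T5"), ("tll3", "T9"), ("otd1", "T1")):
            slope = true_scaling_slope(
                fast_cohort.truth, pair.name, boundary, t, pair.mean_length_um
            )
            assert slope == pytest.approx(
                pair.trajectory(boundary).S(t), abs=1e-9
            )


def test_zero_noise_roundtrip_recovers_drawn_positions():
    cfg = default_config(positional_noise_sd=0.0)
    c = generate_cohort(cfg, 1, seed=2)
    xi = bin_centers()
    df = c.truth.boundaries
    prof = c.profiles
    worst = 0.0
    for (eid, gene), g in prof.groupby(["embryo_id", "gene"]):
        dets = detect_boundaries(xi, g.sort_values("bin_index").intensity.to_numpy())
        truth = df[(df.embryo_id == eid) & (df.gene == gene)].xi_drawn.sort_values()
        det_xi = sorted(d.xi for d in dets)
        assert len(det_xi) == len(truth)
        worst = max(worst, np.max(np.abs(np.asarray(det_xi) - truth.to_numpy())))
    assert worst < 1e-3


class TestBcdProfile:
    def test_closed_form_value(self):
        line = gs.LineSpec("x", 500.0, 0.0, 1.0, 100.0)
        assert bcd_profile(line, 500.0, np.array([0.4]))[0] == pytest.approx(
            np.exp(-2.0), rel=1e-12
        )
        assert bcd_profile(line, 500.0, np.array([0.0]))[0] == 1.0

    def test_strictly_decreasing(self):
        line = gs.LineSpec("x", 500.0, 0.0, 2.0, 80.0)
        prof = bcd_profile(line, 450.0, bin_centers())
        assert (np.diff(prof) < 0).all()

    def test_equal_relative_shape_gives_identical_profiles(self):
        # same A and same lambda/L ratio -> perfect scaling in xi
        a = gs.LineSpec("a", 560.0, 0.0, 1.5, 112.0)
        b = gs.LineSpec("b", 440.0, 0.0, 1.5, 88.0)
        xi = bin_centers()
        np.testing.assert_allclose(
            bcd_profile(a, 560.0, xi), bcd_profile(b, 440.0, xi), rtol=1e-12
        )

    def test_amplitude_scaled_pair_orders_and_crossing(self, default_cfg):
        pa = default_cfg.pair("P_A")
        xi = bin_centers()
        # in absolute position x (same lambda): concentration is higher in
        # the large line everywhere
        x_um = xi * pa.line_small.mean_length_um
        cl_abs = bcd_profile(
            pa.line_large, pa.line_large.mean_length_um,
            x_um / pa.line_large.mean_length_um,
        )
        cs_abs = bcd_profile(
            pa.line_small, pa.line_small.mean_length_um,
            x_um / pa.line_small.mean_length_um,
        )
        assert (cl_abs > cs_abs).all()  # higher amplitude, same lambda
        # encoded positions cross at the configured mid-embryo point
        for t_xi in (0.1, 0.3, 0.49):
            T = np.exp(
                -t_xi * pa.line_small.mean_length_um
                / pa.line_small.bcd_length_constant_um
            )
            d = bcd_threshold_xi(
                pa.line_large, pa.line_large.mean_length_um, T
            ) - bcd_threshold_xi(pa.line_small, pa.line_small.mean_length_um, T)
            assert d > 0  # anterior: over-scaled
        T_mid = np.exp(
            -0.5 * pa.line_small.mean_length_um
            / pa.line_small.bcd_length_constant_um
        )
        d_mid = bcd_threshold_xi(
            pa.line_large, pa.line_large.mean_length_um, T_mid
        ) - bcd_threshold_xi(pa.line_small, pa.line_small.mean_length_um, T_mid)
        assert abs(d_mid) < 1e-12


class TestProfileFromBoundaries:
    def test_single_domain_crossings(self):
        y = profile_from_boundaries([(0.30, 0.50, 1.0)])
        dets = detect_boundaries(bin_centers(), y)
        assert [d.polarity for d in dets] == ["rising", "falling"]
        assert dets[0].xi == pytest.approx(0.30, abs=1e-3)
        assert dets[1].xi == pytest.approx(0.50, abs=1e-3)

    def test_half_level_between_flanks(self):
        xi = bin_centers()
        y = profile_from_boundaries([(0.30, 0.50, 1.0)], xi)
        inside = (xi > 0.33) & (xi < 0.47)
        outside = (xi < 0.27) | (xi > 0.53)
        assert (y[inside] > 0.5 * y.max()).all()
        assert (y[outside] < 0.5 * y.max()).all()
        # unit peak up to 50-bin sampling of the continuous maximum
        assert y.max() == pytest.approx(1.0, abs=2e-3)

    def test_low_amplitude_domain_excluded_by_floor(self):
        y = profile_from_boundaries([(0.2, 0.4, 1.0), (0.6, 0.8, 0.1)])
        dets = detect_boundaries(bin_centers(), y)
        assert len(dets) == 2  # weak posterior domain under the 0.2 floor
        assert all(d.xi < 0.5 for d in dets)

    def test_too_close_flanks_rejected(self):
        with pytest.raises(ConfigurationError):
            profile_from_boundaries([(0.40, 0.43, 1.0)])

    def test_disordered_domains_rejected(self):
        with pytest.raises(ConfigurationError):
            profile_from_boundaries([(0.5, 0.7, 1.0), (0.2, 0.4, 1.0)])

    def test_random_two_domain_crossings_match_dense_grid(self):
        """Constructed crossings agree with brute-force evaluation."""
        rng = np.random.default_rng(0)
        grid = np.linspace(0.0, 1.0, 10_001)
        for _ in range(100):
            a1 = rng.uniform(0.1, 0.3)
            b1 = a1 + rng.uniform(0.08, 0.2)
            a2 = b1 + rng.uniform(0.1, 0.2)
            b2 = a2 + rng.uniform(0.08, 0.15)
            y = profile_from_boundaries(
                [(a1, b1, 1.0), (a2, b2, 1.0)], grid
            )
            for pos in (a1, b1, a2, b2):
                i = np.argmin(np.abs(grid - pos))
                assert abs(y[i] - 0.5) < 0.01  # half-peak sits on target


def test_generator_rejects_reordered_trajectories():
    cfg = default_config()
    pair = cfg.pairs[0]
    bad = []
    for tr in pair.trajectories:
        if tr.boundary_name == "otd1":
            moved = {t: 0.50 for t in gs.TIME_CLASSES}  # behind tll1/otd2
            bad.append(
                gs.BoundaryTrajectorySpec(
                    "otd1", "otd", "rising", moved, tr.true_S_by_timeclass,
                )
            )
        else:
            bad.append(tr)
    with pytest.raises(ConfigurationError, match="registry pair"):
        gs.PairConfig(
            pair.name, pair.line_large, pair.line_small, tuple(bad),
            pair.fractional_length_difference,
        )
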