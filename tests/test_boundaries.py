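"""Half-maximum detection, registry naming and positional errors."""

import numpy as np
import pytest

import gapscale as gs
from gapscale.boundaries import (
    assign_registry,
    detect_boundaries,
    positional_error,
    Detection,
)
from gapscale.synthetic import bin_centers, profile_from_boundaries


def trapezoid(xi, r0=0.40, r1=0.44, f0=0.56, f1=0.60):
    y = np.zeros_like(xi)
    y += np.clip((xi - r0) / (r1 - r0), 0, 1)
    y -= np.clip((xi - f0) / (f1 - f0), 0, 1)
    return y


class TestDetect:
    def test_trapezoid_linear_interpolation_exact(self):
        """Without smoothing the half-crossings of a linear flank are the
        flank midpoints, exactly."""
        xi = bin_centers()
        dets = detect_boundaries(xi, trapezoid(xi), smoothing=0)
        assert len(dets) == 2
        assert dets[0].xi == pytest.approx(0.42, abs=1e-12)
        assert dets[0].polarity == "rising"
        assert dets[1].xi == pytest.approx(0.58, abs=1e-12)
        assert dets[1].polarity == "falling"

    def test_trapezoid_default_spline_close(self):
        xi = bin_centers()
        dets = detect_boundaries(xi, trapezoid(xi))
        assert dets[0].xi == pytest.approx(0.42, abs=1e-3)
        assert dets[1].xi == pytest.approx(0.58, abs=1e-3)

    def test_all_zero_profile_empty(self):
        xi = bin_centers()
        assert detect_boundaries(xi, np.zeros(50)) == []

    def test_low_abundance_domain_skipped(self):
        xi = bin_centers()
        y = profile_from_boundaries([(0.2, 0.4, 1.0), (0.6, 0.8, 0.15)], xi)
        dets = detect_boundaries(xi, y)
        assert len(dets) == 2 and all(d.xi < 0.5 for d in dets)
        # raising the domain above the floor brings it back
        y2 = profile_from_boundaries([(0.2, 0.4, 1.0), (0.6, 0.8, 0.5)], xi)
        assert len(detect_boundaries(xi, y2)) == 4

    def test_intensity_scaling_invariance(self):
        xi = bin_centers()
        rng = np.random.default_rng(3)
        y = profile_from_boundaries([(0.25, 0.45, 1.0)], xi)
        y = np.clip(y + rng.normal(0, 0.02, 50), 0, None)
        a = detect_boundaries(xi, y)
        b = detect_boundaries(xi, 7.3 * y)
        assert len(a) == len(b)
        for da, db in zip(a, b):
            assert da.xi == pytest.approx(db.xi, abs=1e-9)

    def test_reflection_equivariance(self):
        """Reflecting the profile maps crossings xi -> 1-xi and swaps
        polarity."""
        xi = bin_centers()
        rng = np.random.default_rng(4)
        y = profile_from_boundaries([(0.22, 0.38, 1.0), (0.55, 0.72, 0.9)], xi)
        y = np.clip(y + rng.normal(0, 0.01, 50), 0, None)
        fwd = detect_boundaries(xi, y)
        rev = detect_boundaries(xi, y[::-1])
        assert len(fwd) == len(rev)
        flipped = sorted(
            (1.0 - d.xi, {"rising": "falling", "falling": "rising"}[d.polarity])
            for d in rev
        )
        for d, (x, pol) in zip(fwd, flipped):
            assert d.xi == pytest.approx(x, abs=1e-9)
            assert d.polarity == pol

    def test_random_profiles_match_dense_grid_oracle(self):
        """Root-found crossings agree with a 10^4-point grid search on the
        same smoothing spline."""
        from scipy.interpolate import make_smoothing_spline
        from gapscale.boundaries import DEFAULT_SMOOTHING

        xi = bin_centers()
        rng = np.random.default_rng(12)
        checked = 0
        for _ in range(100):
            if rng.random() < 0.5:
                a = rng.uniform(0.1, 0.35)
                doms = [(a, a + rng.uniform(0.1, 0.25), 1.0)]
            else:
                a1 = rng.uniform(0.05, 0.25)
                b1 = a1 + rng.uniform(0.08, 0.18)
                a2 = b1 + rng.uniform(0.08, 0.2)
                doms = [(a1, b1, 1.0), (a2, a2 + rng.uniform(0.08, 0.15), 0.8)]
            y = profile_from_boundaries(doms, xi)
            y = np.clip(y * (1 + rng.normal(0, 0.03, 50)), 0, None)
            dets = detect_boundaries(xi, y)
            spl = make_smoothing_spline(xi, y, lam=DEFAULT_SMOOTHING)
            grid = np.linspace(xi[0], xi[-1], 10_000)
            gy = np.clip(spl(grid), 0, None)
            for d in dets:
                half = 0.5 * d.domain_peak
                near = np.abs(grid - d.xi) < 0.01
                cross = np.abs(gy[near] - half)
                oracle_xi = grid[near][np.argmin(cross)]
                assert abs(d.xi - oracle_xi) < 0.002
                checked += 1
        assert checked >= 200

    def test_input_validation(self):
        xi = bin_centers()
        with pytest.raises(ValueError, match="50 bins"):
            detect_boundaries(xi[:20], np.ones(20))
        with pytest.raises(ValueError, match="nonnegative"):
            detect_boundaries(xi, np.linspace(-1, 1, 50))


class TestAssign:
    def test_cohort_assignment_fully_correct_at_default_noise(
        self, small_cohort, small_boundaries
    ):
        table, results = small_boundaries
        truth = small_cohort.truth.boundaries
        merged = table.merge(
            truth[["embryo_id", "boundary_name", "xi_drawn"]],
            on=["embryo_id", "boundary_name"],
            how="outer",
            indicator=True,
        )
        assert (merged._merge == "both").all()
        assert (merged.xi - merged.xi_drawn).abs().max() < 5e-3
        assert sum(len(r.missing) for r in results) == 0
        assert sum(len(r.unmatched) for r in results) == 0

    def test_empty_detections_report_all_expected_missing(self, default_cfg):
        pair = default_cfg.pairs[0]
        res = assign_registry({}, pair, "T8")
        assert res.observations == []
        assert set(res.missing) == set(gs.BOUNDARIES)  # all 20 expected at T8
        res_t1 = assign_registry({}, pair, "T1")
        assert set(res_t1.missing) == set(gs.BOUNDARIES) - {"gt1", "gt2"}

    def test_absent_hb1_at_t3_is_not_missing(self, default_cfg):
        pair = default_cfg.pairs[0]
        res = assign_registry({}, pair, "T3", genes=("hb",))
        assert "hb1" not in res.missing
        assert set(res.missing) == {"hb2", "hb3", "hb4"}

    def test_competing_detections_produce_ambiguity_record(self, default_cfg):
        pair = default_cfg.pairs[0]
        nominal = pair.trajectory("otd1").xi("T5")
        dets = {
            "otd": [
                Detection(nominal - 0.01, "rising", 1.0),
                Detection(nominal + 0.012, "rising", 1.0),
                Detection(pair.trajectory("otd2").xi("T5"), "falling", 1.0),
            ]
        }
        res = assign_registry(dets, pair, "T5", genes=("otd",))
        named = {o.boundary_name for o in res.observations}
        assert named == {"otd1", "otd2"}
        assert len(res.unmatched) == 1
        assert len(res.ambiguities) == 1
        amb = res.ambiguities[0]
        assert amb["boundary_name"] == "otd1"
        assert len(amb["candidates"]) == 2

    def test_named_order_obeys_registry(self, small_boundaries):
        table, _ = small_boundaries
        for eid, g in table.groupby("embryo_id"):
            pos = dict(zip(g.boundary_name, g.xi))
            assert gs.registry_violations(pos) == []


class TestPositionalError:
    def test_identical_positions_zero(self):
        assert positional_error(np.full(5, 0.4)) == 0.0

    def test_two_point_sd(self):
        assert positional_error(np.array([0.49, 0.51])) == pytest.approx(
            0.0141421356, abs=1e-9
        )

    def test_absolute_mode_normalises_by_reference_length(self):
        xi = np.array([0.5, 0.5, 0.5])
        L = np.array([450.0, 500.0, 550.0])
        # fixed relative position, varying absolute position
        got = positional_error(xi, L, 500.0, normalize_by="absolute")
        assert got == pytest.approx(np.std(xi * L / 500.0, ddof=1), rel=1e-12)
        assert positional_error(xi) == 0.0

    def test_sampling_distribution_at_known_noise(self, default_cfg):
        pair = default_cfg.pairs[0]
        df = gs.sample_boundary_observations(pair, "Kr1", ["T5"], 50, seed=8)
        one_line = df[df.line == pair.line_large.name]
        est = positional_error(one_line.xi.to_numpy())
        assert 0.008 <= est <= 0.012  # true noise sd 0.010, n = 50

    def test_requires_two_observations(self):
        with pytest.raises(ValueError):
            positional_error(np.array([0.4]))
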