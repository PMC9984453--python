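import pytest

import gapscale as gs
from gapscale.boundaries import detect_cohort


@pytest.fixture(scope="session")
def default_cfg():
    return gs.default_config()


@pytest.fixture(scope="session")
def small_cohort(default_cfg):
    """Small full cohort with profiles: 2 pairs x 2 lines x 10 classes x 2."""
    return gs.generate_cohort(default_cfg, n_per_line_per_class=2, seed=11)


@pytest.fixture(scope="session")
def small_boundaries(small_cohort):
    """Detected + named boundary table of the small cohort."""
    table, results = detect_cohort(small_cohort)
    return table, results


@pytest.fixture(scope="session")
def fast_cohort(default_cfg):
    """Larger observation-only cohort for dynamics/scaling statistics."""
    return gs.generate_cohort(
        default_cfg, n_per_line_per_class=15, seed=17, with_profiles=False
    )


@pytest.fixture(scope="session")
def fast_table(fast_cohort):
    """Boundary table built from ground-truth draws (no detection step)."""
    return fast_cohort.truth.boundaries.rename(columns={"xi_drawn": "xi"})
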