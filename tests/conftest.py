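import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import petdlbcl as p

settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cohort_2000():
    """Simulated cohort with the spec-example hazard structure (1, 1, 4.7, 10.1)."""
    spec = p.CohortSpec(n=2000, group_hr=(1.0, 1.0, 4.7, 10.1), seed=20)
    return spec, p.simulate_cohort_df(spec)


@pytest.fixture(scope="session")
def cohort_5000_pfs():
    """Cohort generated from the target per-group five-year PFS values."""
    spec = p.CohortSpec.from_five_year_pfs(n=5000, seed=50)
    return spec, p.simulate_cohort_df(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_suv_volume(rng, shape=(14, 15, 13), spacing=(2.0, 3.0, 2.5), with_mask=True):
    """A random non-negative SUV field with an optional random edit mask."""
    values = rng.gamma(shape=1.2, scale=1.6, size=shape)
    mask = rng.random(shape) < 0.1 if with_mask else None
    return p.SuvVolume(values, spacing, edit_mask=mask)
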