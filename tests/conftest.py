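import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vco2ree import CohortConfig, build_paired_dataset, generate_cohort

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_cohort():
    """12-patient default-parameter cohort, fixed seed."""
    return generate_cohort(CohortConfig(n_patients=12), seed=42)


@pytest.fixture(scope="session")
def small_paired(small_cohort):
    return build_paired_dataset(small_cohort.ic, small_cohort.traces)


@pytest.fixture(scope="session")
def noisefree_cohort():
    """Degenerate cohort: no RQ spread, no ventilator noise or bias, so the
    VCO2-only estimate at the cohort RQ must equal the reference exactly."""
    cfg = CohortConfig(
        n_patients=10, rq_sd=0.0, vent_noise_sd=0.0, vent_bias=1.0, seed=7
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def noisefree_paired(noisefree_cohort):
    return build_paired_dataset(noisefree_cohort.ic, noisefree_cohort.traces)


@pytest.fixture()
def rng():
    return np.random.default_rng(20251001)
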