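import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ntcpsim as ns

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def unit_params():
    """Predefined model on the normalized dose scale: D50 = 1, gamma = 1."""
    return ns.NTCPParams(d50=1.0, gamma=1.0)


@pytest.fixture
def small_cohort():
    """Normalized synthetic cohort of 120 patients, rank correlation 0.9."""
    spec = ns.SyntheticCohortSpec(n=120, rank_correlation=0.9, seed=42)
    return ns.normalize_cohort(ns.generate_cohort(spec))


@pytest.fixture
def full_cohort():
    """Normalized synthetic cohort at the reference study size (605)."""
    spec = ns.SyntheticCohortSpec(n=605, rank_correlation=0.9, seed=42)
    return ns.normalize_cohort(ns.generate_cohort(spec))
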