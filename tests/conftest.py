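import numpy as np
import pytest

from octamag import (
    DEFAULT_AL_MODEL,
    RTVUE_XR_AVANTI,
    BiometryRecord,
    CohortSpec,
    Eye,
    generate_cohort,
)


@pytest.fixture(scope="session")
def default_model():
    return DEFAULT_AL_MODEL


@pytest.fixture(scope="session")
def rtvue():
    return RTVUE_XR_AVANTI


@pytest.fixture(scope="session")
def small_cohort():
    """Seeded 60-eye cohort reused across read-only tests."""
    return generate_cohort(CohortSpec(n=60, seed=7))


@pytest.fixture(scope="session")
def cohort_650():
    """Training-cohort-sized generation, fixed seed, reused read-only."""
    return generate_cohort(CohortSpec(n=650, seed=1))


@pytest.fixture
def make_record():
    def _make(pid="P1", k=7.76, se=-0.15, **kw):
        kw.setdefault("eye", Eye.RIGHT)
        return BiometryRecord(participant_id=pid, k_mean=k, se=se, **kw)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
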