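import numpy as np
import pytest

from icureadmit.knowledge import load_knowledge_base
from icureadmit.synth import SynthConfig, generate_ehr


@pytest.fixture(scope="session")
def kb():
    return load_knowledge_base()


@pytest.fixture(scope="session")
def small_tables():
    """200-patient synthetic EHR shared across read-only tests."""
    return generate_ehr(SynthConfig(n_patients=200, seed=7))


@pytest.fixture(scope="session")
def small_cohort(small_tables, kb):
    from icureadmit.cohort import build_cohort
    cohort, report = build_cohort(small_tables, kb)
    return cohort, report


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
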