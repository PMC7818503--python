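import warnings

import pytest
from hypothesis import HealthCheck, settings

import sparsemeta as sm

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def mmn():
    """Multifocal motor neuropathy case study (3 trials, 1 double-zero)."""
    return sm.load_mmn()


@pytest.fixture(scope="session")
def gbs():
    """Guillain-Barre syndrome case study (4 trials, 1 double-zero)."""
    return sm.load_gbs()


@pytest.fixture(scope="session")
def single_trial():
    return sm.MetaAnalysisDataset((sm.TrialRecord("t1", 2, 10, 1, 10),))
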