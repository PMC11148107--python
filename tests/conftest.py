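import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lipscreen import run_screen, synthetic

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def seeded_screen():
    """The standard planted screen: 50 proteins, 7-dose design, 4 replicates,
    10% interactor proteins, noise sd 0.15 log2, 5% missing."""
    report, truth = synthetic.generate_screen(n_proteins=50, seed=1)
    return report, truth


@pytest.fixture(scope="session")
def screen_result(seeded_screen):
    report, _ = seeded_screen
    return run_screen(report)


@pytest.fixture(scope="session")
def null_screen_result():
    report, truth = synthetic.generate_null_screen(n_proteins=100, seed=7)
    assert not truth.responder_precursors
    return run_screen(report)
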