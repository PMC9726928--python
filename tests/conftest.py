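import numpy as np
import pytest

from sunkddm import SimConfig, run_experiment
from sunkddm.trials import SessionSet, TrialRecord


@pytest.fixture
def tiny_records():
    """One skip, one quit at 3 of 5, one earn at 7 of 7."""
    return [
        TrialRecord("s1", "sess1", "R1", 12, False, 0, "skip"),
        TrialRecord("s1", "sess1", "R1", 5, True, 3, "quit", w0=17.5),
        TrialRecord("s1", "sess1", "R2", 7, True, 7, "earn"),
    ]


@pytest.fixture
def tiny_session(tiny_records):
    return SessionSet.from_records(tiny_records, meta={"offer_support": [1, 30]})


@pytest.fixture(scope="session")
def baseline_session():
    """Baseline agent (sigma_W=5, sigma_N=3), threshold policy, 1e5 trials."""
    return run_experiment(SimConfig(n_trials=100_000, seed=11))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(7)
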