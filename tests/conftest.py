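import numpy as np
import pandas as pd
import pytest

from semload import BetaMatrix, SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One small simulated cohort shared across read-only tests."""
    cfg = SimulationConfig(n_samples=120, n_probes=800, seed=11, cohort_name="TESTA")
    return simulate_cohort(cfg)


@pytest.fixture()
def toy_beta():
    """3-probe x 4-sample matrix with easily hand-checked values."""
    values = pd.DataFrame(
        [[0.1, 0.2, 0.3, 0.4], [0.5, 0.5, 0.5, 0.5], [0.0, 1.0, 0.25, 0.75]],
        index=["cg1", "cg2", "cg3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return BetaMatrix(values)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
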