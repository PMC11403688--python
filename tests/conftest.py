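import numpy as np
import pandas as pd
import pytest

from gliomanet import simulate as sim
from gliomanet import survival as surv


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_survival_data(rng) -> surv.SurvivalData:
    """50 samples, 4 features, moderate effects, ~25% censoring."""
    n, p = 50, 4
    X = pd.DataFrame(
        rng.standard_normal((n, p)), columns=[f"g{i}" for i in range(p)]
    )
    beta = np.array([0.7, -0.5, 0.0, 0.0])
    t = rng.exponential(1.0 / np.exp(X.to_numpy() @ beta))
    e = (rng.random(n) > 0.25).astype(int)
    return surv.SurvivalData(t, e, X)


@pytest.fixture
def small_dataset() -> sim.SyntheticDataset:
    cfg = sim.SimulationConfig(
        n_per_type=60, p=24, block_sizes=[3] * 5, n_prognostic=3, seed=7
    )
    return sim.generate_dataset(cfg)
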