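import numpy as np
import pandas as pd
import pytest

from consmod import ExpressionStudy, SimulationConfig, simulate_pair


def make_study(values, name="test", groups=None):
    """ExpressionStudy from a 2-D array; first half cancer, rest normal."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    genes = [f"g{i+1}" for i in range(n_genes)]
    samples = [f"s{i+1}" for i in range(n_samples)]
    if groups is None:
        half = n_samples // 2
        groups = {s: ("cancer" if i < half else "normal") for i, s in enumerate(samples)}
    return ExpressionStudy(pd.DataFrame(values, index=genes, columns=samples), groups, name)


@pytest.fixture(scope="session")
def planted_pair():
    """Default-condition simulated pair: 8 modules of 40 among 400 genes."""
    cfg = SimulationConfig(seed=7)
    return simulate_pair(cfg) + (cfg,)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
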