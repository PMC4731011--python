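import numpy as np
import pandas as pd
import pytest

from pecapipe import SimulationConfig, simulate_qss
from pecapipe.containers import DEFAULT_TIME_GRID, ExpressionMatrix

GRID = list(DEFAULT_TIME_GRID)


@pytest.fixture(scope="session")
def grid():
    return np.asarray(GRID)


@pytest.fixture()
def small_matrix():
    """4 genes x 8 time points, natural scale."""
    rng = np.random.default_rng(42)
    vals = pd.DataFrame(
        np.exp(rng.normal(5, 1, (4, 8))),
        index=[f"G{i:06d}" for i in range(1, 5)],
        columns=GRID,
    )
    return ExpressionMatrix(vals, level="rna", scale="natural", replicate=1)


@pytest.fixture(scope="session")
def calibration_sim():
    """QSS study conditions: 1,000 genes, 10% regulated by a single permanent
    1.5 log-unit rate-ratio shift, noise SD 0.2."""
    cfg = SimulationConfig(
        n_genes=1000,
        seed=11,
        frac_regulated_rna=0.1,
        frac_regulated_protein=0.0,
        pattern_mix={"switch": 1.0},
        spike_rate=0.0,
        missing_rate=0.0,
    )
    rna, protein, truth = simulate_qss(cfg)
    return cfg, rna, protein, truth
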