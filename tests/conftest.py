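import numpy as np
import pandas as pd
import pytest

import prolifsig as ps


@pytest.fixture(scope="session")
def small_config():
    """Compact study: fast to simulate, still multi-panel and noisy."""
    return ps.SimulationConfig(
        n_genes=400,
        n_cell_lines=40,
        n_datasets_protein=2,
        n_datasets_transcript=2,
        fraction_planted=0.1,
        seed=123,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return ps.simulate_study(small_config)


@pytest.fixture
def toy_dataset():
    """Tiny hand-written protein matrix with one missing value."""
    values = pd.DataFrame(
        {
            "c1": [1.0, 2.0, 3.0, np.nan],
            "c2": [2.0, 1.0, 4.0, 0.5],
            "c3": [3.0, 4.0, 1.0, 0.2],
        },
        index=["PCNA", "MCM2", "G1", "G2"],
    )
    return ps.ExpressionDataset(dataset_id="toy", layer="protein", values=values)
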