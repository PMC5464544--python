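import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import polysometx as px

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """Default-shaped simulation at reduced size: 300 genes, 24 libraries."""
    cfg = px.SimConfig(n_genes=300, seed=17)
    return px.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_te_table(small_dataset):
    cm, designs, truth = small_dataset
    table = px.run_te_test(cm, designs)
    return cm, designs, truth, table


@pytest.fixture()
def toy_counts():
    """4 genes x 3 samples with one composition-biasing high-count gene."""
    return px.CountMatrix(
        pd.DataFrame(
            {
                "s1": [100, 200, 300, 5000],
                "s2": [110, 190, 310, 900],
                "s3": [90, 210, 290, 1100],
            },
            index=["g1", "g2", "g3", "g4"],
        )
    )


@pytest.fixture()
def te_profile_frame():
    """Helper to build a TEProfiles object from a plain array."""
    from polysometx.te_cluster import TEProfiles

    def build(values: np.ndarray, cell_lines=("a", "b", "c"), genes=None):
        cols = pd.MultiIndex.from_product(
            [list(cell_lines), ["control", "knockdown"]],
            names=["cell_line", "condition"],
        )
        genes = genes or [f"g{i}" for i in range(len(values))]
        return TEProfiles(
            values=pd.DataFrame(np.asarray(values, float), index=genes, columns=cols),
            excluded=[],
        )

    return build
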