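import numpy as np
import pandas as pd
import pytest

from evotiss import ExpressionDataset, SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_sim():
    """A modest synthetic study shared by read-only tests."""
    return simulate_dataset(
        SimConfig(n_genes=600, n_tissues=8, samples_per_tissue=30, seed=7)
    )


@pytest.fixture
def tiny_dataset():
    """3 genes x 4 samples over 2 tissues, values chosen by hand."""
    values = pd.DataFrame(
        [[1.0, 3.0, 0.0, 0.0], [5.0, 5.0, 5.0, 5.0], [2.0, 4.0, 8.0, 6.0]],
        index=pd.Index(["g1", "g2", "g3"], name="gene"),
        columns=["s1", "s2", "s3", "s4"],
    )
    tissue_of = pd.Series(
        ["liver", "liver", "cortex", "cortex"],
        index=pd.Index(values.columns, name="sample"),
    )
    return ExpressionDataset(values, tissue_of)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
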