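import numpy as np
import pandas as pd
import pytest

from girewire import FeatureTable, DegreeTable, CANONICAL_FEATURES
from girewire.simulate import SimulationConfig, simulate_species_pair


def make_feature_table(genes, species="species1", rng=None, **columns):
    """FeatureTable with given columns set and the rest filled with noise."""
    rng = rng or np.random.default_rng(0)
    n = len(genes)
    data = {}
    for feat in CANONICAL_FEATURES:
        if feat in columns:
            data[feat] = np.asarray(columns[feat], dtype=float)
        elif feat == "yeast_conservation":
            data[feat] = rng.integers(0, 24, size=n).astype(float)
        elif feat == "broad_conservation":
            data[feat] = rng.integers(0, 87, size=n).astype(float)
        elif feat == "expression_variation":
            data[feat] = rng.uniform(size=n)
        else:
            data[feat] = rng.normal(size=n)
    return FeatureTable(
        species=species, data=pd.DataFrame(data, index=pd.Index(genes, name="gene_id"))
    )


@pytest.fixture(scope="session")
def small_pair():
    """A modest two-species world shared by tests that just need valid inputs."""
    return simulate_species_pair(SimulationConfig(n_genes=300), seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
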