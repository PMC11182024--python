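import numpy as np
import pandas as pd
import pytest

from cryonet import synthetic


@pytest.fixture(scope="session")
def design96():
    return synthetic.generate_design(synthetic.DesignSpec())


@pytest.fixture(scope="session")
def small_params():
    return synthetic.CommunityParams(n_taxa=200, depth=5000, module_sizes=(20, 16, 12, 10))


@pytest.fixture(scope="session")
def small_dataset(design96, small_params):
    """A desk-scale synthetic microcosm: table, ground truth, design."""
    table, truth = synthetic.generate_community(design96, small_params, seed=11)
    return table, truth, design96


def toy_table(rows, sample_ids=None, taxon_ids=None):
    """Build a small samples x taxa count table from a list of row tuples."""
    rows = np.asarray(rows, dtype=np.int64)
    sample_ids = sample_ids or [f"s{i+1}" for i in range(rows.shape[0])]
    taxon_ids = taxon_ids or [f"t{j+1}" for j in range(rows.shape[1])]
    return pd.DataFrame(rows, index=sample_ids, columns=taxon_ids)
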