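import numpy as np
import pandas as pd
import pytest

from scmeta import corepipe
from scmeta.simdata import SimConfig, generate_collection


def truth_tables(matrices, table, truth):
    """Cell tables with the TRUE subpopulation filled in (bypasses clustering)."""
    out = []
    for cm in matrices:
        t = table[table["dataset_id"] == cm.dataset_id].reset_index(drop=True).copy()
        t["subpop"] = pd.array(truth.cell_subpop[cm.dataset_id], dtype="string")
        out.append(t)
    return out


@pytest.fixture(scope="session")
def small_collection():
    """3 datasets with planted markers (effect 4), no batch effects."""
    cfg = SimConfig(
        n_datasets=3,
        cells_per_dataset=(600, 500, 700),
        n_genes=600,
        marker_effect=4.0,
        seed=1,
    )
    matrices, table, truth = generate_collection(cfg)
    return cfg, matrices, table, truth


@pytest.fixture(scope="session")
def small_normalized(small_collection):
    _, matrices, table, truth = small_collection
    normed = [corepipe.lognormalize(cm) for cm in matrices]
    tables = truth_tables(matrices, table, truth)
    return normed, tables, truth


@pytest.fixture(scope="session")
def two_dataset_pair():
    """2 datasets, markers planted, mild uniform batch effect."""
    cfg = SimConfig(
        n_datasets=2,
        cells_per_dataset=(700, 700),
        n_genes=500,
        marker_effect=3.0,
        batch_sigma_uniform=0.2,
        seed=3,
    )
    matrices, table, truth = generate_collection(cfg)
    normed = [corepipe.lognormalize(cm) for cm in matrices]
    tables = truth_tables(matrices, table, truth)
    return normed, tables, truth
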