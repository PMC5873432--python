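import numpy as np
import pandas as pd
import pytest

from covnet import (CohortConfig, default_region_table, generate_cohort,
                    BinaryGraph)


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture(scope="session")
def full_regions():
    return default_region_table()


@pytest.fixture(scope="session")
def small_regions():
    """10 regions: 4 homologous pairs spanning four lobes + 2 midline."""
    rows = []
    for abbrev, name, lobe in [("PrG", "Precentral gyrus", "frontal"),
                               ("PCu", "Precuneus", "parietal"),
                               ("MTG", "Middle temporal gyrus", "temporal"),
                               ("AIns", "Anterior insula", "insula")]:
        rows.append((f"{abbrev}.L", f"{name} left", "L", lobe, f"{abbrev}.R"))
        rows.append((f"{abbrev}.R", f"{name} right", "R", lobe, f"{abbrev}.L"))
    rows.append(("CVL15", "Cerebellar Vermal Lobules I-V", "midline",
                 "subcortical", ""))
    rows.append(("CVL67", "Cerebellar Vermal Lobules VI-VII", "midline",
                 "subcortical", ""))
    frame = pd.DataFrame(rows, columns=["region_id", "name", "hemisphere",
                                        "lobe", "homologue_id"])
    from covnet.io import validate_regions
    return validate_regions(frame)


@pytest.fixture(scope="session")
def small_cohort(small_regions):
    config = CohortConfig(n_subjects=40, age_range=(20.0, 60.0),
                          region_table=small_regions, seed=11)
    return generate_cohort(config)


def make_graph(adj, sparsity=0.5, threshold=0.1, ids=None):
    adj = np.asarray(adj, dtype=bool)
    return BinaryGraph(adjacency=adj, sparsity=sparsity, threshold=threshold,
                       region_ids=tuple(ids) if ids else ())


@pytest.fixture
def triangle_graph():
    adj = np.zeros((3, 3), dtype=bool)
    for i, j in [(0, 1), (1, 2), (0, 2)]:
        adj[i, j] = adj[j, i] = True
    return make_graph(adj, ids=["a", "b", "c"])


@pytest.fixture
def path_graph():
    """a - b - c."""
    adj = np.zeros((3, 3), dtype=bool)
    for i, j in [(0, 1), (1, 2)]:
        adj[i, j] = adj[j, i] = True
    return make_graph(adj, ids=["a", "b", "c"])


def complete_graph(n):
    adj = ~np.eye(n, dtype=bool)
    return make_graph(adj, ids=[f"r{i}" for i in range(n)])


def random_corr_frame(n, rng, ids=None):
    """A symmetric zero-diagonal matrix of distinct off-diagonal values."""
    m = rng.normal(size=(n, 2 * n))
    corr = np.corrcoef(m)
    np.fill_diagonal(corr, 0.0)
    ids = ids or [f"r{i}" for i in range(n)]
    return pd.DataFrame(corr, index=ids, columns=ids)
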