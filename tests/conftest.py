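import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import hippocoupling as hc


@pytest.fixture(scope="session")
def small_sim():
    """A 3-group, 100-gene simulated dataset shared across tests."""
    cfg = hc.SimulationConfig(n_groups=3, cells_per_group=60, n_genes=100, seed=11)
    matrix, annotation = hc.simulate_counts(cfg)
    return cfg, matrix, annotation


@pytest.fixture(scope="session")
def small_norm(small_sim):
    _, matrix, annotation = small_sim
    filtered, _ = hc.qc_filter(matrix, min_cells=1, min_features=0)
    norm = hc.log_normalize(filtered)
    annotation = annotation[annotation["cell_id"].isin(set(filtered.cell_ids))]
    return norm, annotation.reset_index(drop=True)


@pytest.fixture(scope="session")
def small_profile(small_norm):
    norm, annotation = small_norm
    return hc.aggregate(norm, annotation)


def toy_counts(dense, gene_prefix="g", cell_prefix="c"):
    """Build a CountMatrix from a dense integer array."""
    dense = np.asarray(dense)
    return hc.CountMatrix(
        sp.csr_matrix(dense),
        np.array([f"{gene_prefix}{i}" for i in range(dense.shape[0])], dtype=object),
        np.array([f"{cell_prefix}{j}" for j in range(dense.shape[1])], dtype=object),
    )


def toy_annotation(groups, sexes=None, cell_prefix="c"):
    n = len(groups)
    return pd.DataFrame(
        {
            "cell_id": [f"{cell_prefix}{j}" for j in range(n)],
            "group": list(groups),
            "sex": list(sexes) if sexes is not None else ["F"] * n,
            "region": ["HIP"] * n,
            "subcluster": ["s0"] * n,
        }
    )
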