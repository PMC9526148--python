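import os
import sys

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

sys.path.insert(0, os.path.dirname(__file__))

from isletxmap import CellMatrix, GroupProfile, QCConfig, normalize_log, qc_filter
from isletxmap.synthetic_data import SimConfig, simulate_panel


def make_matrix(
    counts,
    lognorm=None,
    species="human",
    batches=None,
    cell_types=None,
    states=None,
    gene_ids=None,
):
    """Build a small CellMatrix from dense arrays."""
    counts = np.asarray(counts)
    n, g = counts.shape
    meta = pd.DataFrame(
        {
            "species": species,
            "batch": batches if batches is not None else ["b0"] * n,
            "cell_type": cell_types if cell_types is not None else ["t0"] * n,
        },
        index=pd.Index([f"c{i}" for i in range(n)], name="cell_id"),
    )
    if states is not None:
        meta["state"] = states
    gene_ids = gene_ids or [f"g{j}" for j in range(g)]
    gm = pd.DataFrame(index=pd.Index(gene_ids, name="native_id"))
    return CellMatrix(
        counts=sp.csr_matrix(counts),
        cell_meta=meta,
        gene_meta=gm,
        lognorm=None if lognorm is None else sp.csr_matrix(np.asarray(lognorm)),
    )


def make_profile(mean, frac, n_cells, groups=None, genes=None):
    groups = groups or [f"t{i}" for i in range(np.asarray(mean).shape[0])]
    genes = genes or [f"g{j}" for j in range(np.asarray(mean).shape[1])]
    return GroupProfile(
        mean_expr=pd.DataFrame(np.asarray(mean, dtype=float), index=groups, columns=genes),
        frac_expr=pd.DataFrame(np.asarray(frac, dtype=float), index=groups, columns=genes),
        n_cells=pd.Series(n_cells, index=groups),
    )


def preprocess_panel(panel, min_counts=100, min_genes=50, min_cells_per_gene=10):
    out = {}
    for s, m in panel.matrices.items():
        m = qc_filter(
            m,
            QCConfig(
                min_counts=min_counts,
                min_genes=min_genes,
                min_cells_per_gene=min_cells_per_gene,
            ),
        )
        out[s] = normalize_log(m)
    return out


@pytest.fixture(scope="session")
def small_panel():
    """Two-species panel with all planted structure at modest size."""
    cfg = SimConfig(
        species=("human", "pig"),
        cell_types={"alpha": 150, "beta": 150, "delta": 120, "pp": 120},
        states={"beta": {"mature": 0.6, "immature": 0.25, "stress": 0.15}},
        n_genes=1200,
        n_markers_per_type=40,
        modules=((50, 0.8), (40, 0.8)),
        seed=42,
    )
    return simulate_panel(cfg)


@pytest.fixture(scope="session")
def small_processed(small_panel):
    return preprocess_panel(small_panel)
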