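"""Data-driven gene sets: discovery, activation scoring, Welch DE ranking.

Gene modules are discovered without prior annotation by clustering the most
variable genes on their pairwise Pearson correlation pattern: each gene is
represented by its row of the gene-gene correlation matrix and rows are
grouped by Ward hierarchical clustering with Euclidean distance. Clusters
whose mean pairwise intra-set correlation falls below a floor (default
0.005) are treated as noise and dropped.

Per-cell activation of a gene set is its mean log-normalized expression
minus the mean over an expression-matched background: genes are binned by
overall mean expression and, for each set member, background genes are
drawn from the member's bin (set members excluded). When a bin's eligible
pool is not larger than the requested draw the whole pool is used, making
small fixtures exactly reproducible by hand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch

from .core_data import CellMatrix

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "select_variable_genes",
    "discover_gene_sets",
    "score_gene_sets",
    "rank_genes_welch",
]


@dataclass
class GeneSet:
    name: str
    genes: list[str]
    mean_intra_correlation: float = 0.0


@dataclass
class GeneSetCollection:
    sets: list[GeneSet]
    provenance: dict = field(default_factory=dict)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    def __len__(self) -> int:
        return len(self.sets)

    def membership(self) -> pd.Series:
        """gene -> set name over all retained sets."""
        return pd.Series(
            {g: s.name for s in self.sets for g in s.genes}, dtype=object
        )


def _gene_moments(matrix: CellMatrix):
    X = matrix.layer("lognorm")
    mean = np.asarray(X.mean(axis=0)).ravel()
    mean_sq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
    var = np.maximum(mean_sq - mean**2, 0.0)
    return mean, var


def select_variable_genes(
    matrix: CellMatrix, n: int = 3000, min_cells: int = 20, n_bins: int = 20
) -> list[str]:
    """Top variable genes by binned normalized dispersion.

    Genes expressed in at least ``min_cells`` cells are ranked by their
    dispersion (variance / mean of lognorm) z-scored within 20
    equal-frequency mean-expression bins, and the top ``n`` are returned in
    rank order (ties broken by gene id).
    """
    counts_layer = matrix.counts if matrix.counts.nnz else matrix.layer("lognorm")
    cells_per_gene = counts_layer.getnnz(axis=0)
    eligible = cells_per_gene >= min_cells
    n_eligible = int(eligible.sum())
    if n_eligible < n:
        raise ValueError(
            f"requested {n} variable genes but only {n_eligible} of "
            f"{matrix.n_genes} genes are expressed in >= {min_cells} cells"
        )
    mean, var = _gene_moments(matrix)
    ids = matrix.native_ids[eligible]
    mean, var = mean[eligible], var[eligible]
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), 0.0)

    df = pd.DataFrame({"gene": ids, "mean": mean, "disp": disp})
    df["bin"] = pd.qcut(df["mean"].rank(method="first"), min(n_bins, len(df)),
                        labels=False)
    z = df.groupby("bin")["disp"].transform(
        lambda x: (x - x.mean()) / x.std(ddof=1) if len(x) > 1 and x.std(ddof=1) > 0
        else x * 0.0
    )
    df["z"] = z
    df = df.sort_values(["z", "gene"], ascending=[False, True], kind="mergesort")
    return df["gene"].head(n).tolist()


def discover_gene_sets(
    matrix: CellMatrix,
    genes: list[str],
    n_clusters: int = 20,
    min_corr: float = 0.005,
) -> GeneSetCollection:
    """Ward-cluster genes on their correlation pattern into named sets.

    The gene-gene Pearson correlation matrix over cells is computed for the
    given genes; each gene's row is its feature vector; Ward linkage with
    Euclidean distance builds the tree, cut into ``n_clusters``. Sets with
    mean pairwise intra-set correlation below ``min_corr`` are dropped
    (singleton intra-correlation is defined as 0, so singletons always
    drop). Survivors are named G1..Gk in descending size.
    """
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    if n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    genes = list(genes)
    gi = matrix.native_ids.get_indexer(genes)
    if (gi < 0).any():
        missing = [g for g, i in zip(genes, gi) if i < 0]
        raise KeyError(f"genes not in matrix: {missing[:5]}")
    X = np.asarray(matrix.layer("lognorm")[:, gi].todense(), dtype=float)
    sd = X.std(axis=0)
    if (sd == 0).any():
        bad = genes[int(np.flatnonzero(sd == 0)[0])]
        raise ValueError(f"constant gene {bad!r}: correlation undefined")

    # order-invariant: cluster in sorted-gene order, report input order sets
    order = np.argsort(np.asarray(genes, dtype=object))
    genes_sorted = [genes[i] for i in order]
    C = np.corrcoef(X[:, order].T)
    link = sch.linkage(C, method="ward", metric="euclidean")
    labels = sch.fcluster(link, t=min(n_clusters, len(genes)), criterion="maxclust")

    sets = []
    for lab in np.unique(labels):
        members = [genes_sorted[i] for i in np.flatnonzero(labels == lab)]
        idx = np.flatnonzero(labels == lab)
        if len(idx) == 1:
            corr = 0.0
        else:
            sub = C[np.ix_(idx, idx)]
            corr = float((sub.sum() - len(idx)) / (len(idx) * (len(idx) - 1)))
        if corr >= min_corr and len(members) >= 2:
            sets.append((members, corr))
    sets.sort(key=lambda mc: (-len(mc[0]), mc[0][0]))
    collection = [
        GeneSet(name=f"G{i + 1}", genes=m, mean_intra_correlation=c)
        for i, (m, c) in enumerate(sets)
    ]
    return GeneSetCollection(
        sets=collection,
        provenance={
            "n_variable_genes": len(genes),
            "n_clusters_requested": n_clusters,
            "min_corr": min_corr,
        },
    )


def _expression_bins(mean: np.ndarray, ids: pd.Index, n_bins: int) -> np.ndarray:
    """Equal-frequency bin index per gene (ties broken by gene id)."""
    order = np.lexsort((np.asarray(ids, dtype=object), mean))
    ranks = np.empty(len(mean), dtype=int)
    ranks[order] = np.arange(len(mean))
    return (ranks * n_bins) // len(mean)


def score_gene_sets(
    matrix: CellMatrix,
    sets: GeneSetCollection,
    n_bins: int = 25,
    background_size: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Activation score per cell and gene set against matched background.

    Genes are binned by overall mean lognorm into ``n_bins`` equal-frequency
    bins. For each set, the background is the union over members of
    ``background_size`` genes sampled (seeded, without replacement) from the
    member's bin excluding all set members; a pool not larger than
    ``background_size`` is used whole (deterministically). The score is the
    member-mean minus the background-mean expression.
    """
    X = matrix.layer("lognorm")
    ids = matrix.native_ids
    mean, _ = _gene_moments(matrix)
    bins = _expression_bins(mean, ids, min(n_bins, matrix.n_genes))
    rng = np.random.default_rng(seed)

    id_pos = pd.Series(np.arange(len(ids)), index=ids)
    cols = {}
    for s in sets.sets:
        missing = [g for g in s.genes if g not in id_pos.index]
        if missing:
            raise KeyError(f"set {s.name!r} members not in matrix: {missing[:5]}")
        member_pos = id_pos[s.genes].to_numpy()
        member_set = set(member_pos)
        background: set = set()
        any_pool = False
        for p in member_pos:
            pool = np.flatnonzero(bins == bins[p])
            pool = np.array(sorted(set(pool) - member_set), dtype=int)
            if pool.size == 0:
                continue
            any_pool = True
            if pool.size <= background_size:
                background.update(pool.tolist())
            else:
                # draw against the id-sorted pool for order invariance
                pool_ids = sorted(ids[pool])
                sel = rng.choice(len(pool_ids), size=background_size, replace=False)
                background.update(id_pos[[pool_ids[i] for i in sel]].tolist())
        if not any_pool:
            raise ValueError(
                f"set {s.name!r}: empty background pool for every member"
            )
        bg = np.array(sorted(background), dtype=int)
        member_mean = np.asarray(X[:, member_pos].mean(axis=1)).ravel()
        bg_mean = np.asarray(X[:, bg].mean(axis=1)).ravel()
        cols[s.name] = member_mean - bg_mean

    out = pd.DataFrame(cols, index=matrix.cell_meta.index)
    out.attrs["score_config"] = {
        "n_bins": n_bins,
        "background_size": background_size,
        "seed": seed,
    }
    return out


def rank_genes_welch(
    matrix: CellMatrix,
    group_key: str,
    group_a: str,
    group_b: str,
    top_n: int = 50,
    var_floor: float = 1e-9,
) -> pd.DataFrame:
    """Welch t-statistic ranking of genes between two cell groups.

    Per-group variances are floored at ``var_floor`` so that genes constant
    within both groups but shifted between them still rank finitely and
    first. Returns the ``top_n`` genes by descending t (ties by gene id).
    """
    if group_key not in matrix.cell_meta.columns:
        raise KeyError(f"unknown group key {group_key!r}")
    labels = matrix.cell_meta[group_key]
    X = matrix.layer("lognorm")
    stats_ = {}
    for tag, name in ((group_a, "a"), (group_b, "b")):
        mask = (labels == tag).to_numpy()
        if mask.sum() < 2:
            raise ValueError(f"group {tag!r} has fewer than 2 cells")
        sub = X[mask]
        m = np.asarray(sub.mean(axis=0)).ravel()
        msq = np.asarray(sub.multiply(sub).mean(axis=0)).ravel()
        n = mask.sum()
        v = np.maximum((msq - m**2) * n / (n - 1), var_floor)
        stats_[name] = (m, v, n)
    (ma, va, na), (mb, vb, nb) = stats_["a"], stats_["b"]
    t = (ma - mb) / np.sqrt(va / na + vb / nb)
    df = pd.DataFrame({"gene": matrix.native_ids, "t": t})
    df = df.sort_values(["t", "gene"], ascending=[False, True], kind="mergesort")
    return df.head(top_n).reset_index(drop=True)
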