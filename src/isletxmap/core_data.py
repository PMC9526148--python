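"""Core data containers and preprocessing for cross-species islet scRNA-seq.

The central carrier is :class:`CellMatrix`: a cells x genes count matrix with
an optional log-normalized layer and per-cell / per-gene annotations. All
downstream statistics (markers, conservation calls, pattern correlations,
gene-set scores) consume only the log-normalized layer and the grouping tags
(species, batch, cell type, state) carried in ``cell_meta``.

Preprocessing follows the standard droplet-data recipe: cell-level QC on
mitochondrial fraction, total counts and detected genes; gene filtering on a
minimum number of expressing cells; total-count normalization that excludes
highly expressed genes from the size factor; log1p transform; and a
zero-preserving empirical-Bayes (ComBat) batch adjustment in which every
entry that was exactly zero before correction is reset to exactly zero, so
that sample-to-sample differences are never invented at undetected genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "CellMatrix",
    "QCConfig",
    "GroupProfile",
    "qc_filter",
    "normalize_log",
    "batch_correct_zero_preserving",
    "compute_group_profile",
]


def _as_csr(x) -> sp.csr_matrix:
    m = sp.csr_matrix(x)
    m.eliminate_zeros()
    return m


@dataclass
class CellMatrix:
    """Cells x genes expression matrix with annotations.

    Parameters
    ----------
    counts
        Raw UMI counts, cells x genes, non-negative integers (sparse).
    cell_meta
        One row per cell, indexed by cell id. Expected columns are
        ``species``, ``batch``, ``cell_type`` and optionally ``state``.
    gene_meta
        One row per gene, indexed by ``native_id`` (unique within the
        matrix). May carry a ``common_id`` column after ortholog mapping.
    lognorm
        Log-normalized layer, same shape as ``counts``; every zero count is
        a zero here as well.
    """

    counts: sp.csr_matrix
    cell_meta: pd.DataFrame
    gene_meta: pd.DataFrame
    lognorm: sp.csr_matrix | None = None

    def __post_init__(self) -> None:
        self.counts = _as_csr(self.counts)
        if self.lognorm is not None:
            self.lognorm = _as_csr(self.lognorm)
            if self.lognorm.shape != self.counts.shape:
                raise ValueError("counts and lognorm must share shape")
            if not np.all(np.isfinite(self.lognorm.data)):
                raise ValueError("lognorm layer contains non-finite values")
        n, g = self.counts.shape
        if len(self.cell_meta) != n:
            raise ValueError(f"cell_meta has {len(self.cell_meta)} rows for {n} cells")
        if len(self.gene_meta) != g:
            raise ValueError(f"gene_meta has {len(self.gene_meta)} rows for {g} genes")
        if self.gene_meta.index.has_duplicates:
            dup = self.gene_meta.index[self.gene_meta.index.duplicated()][0]
            raise ValueError(f"native_id not unique: {dup!r}")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def native_ids(self) -> pd.Index:
        return self.gene_meta.index

    @property
    def species(self) -> str:
        """Single species tag of this matrix (error if mixed)."""
        tags = self.cell_meta["species"].unique()
        if len(tags) != 1:
            raise ValueError(f"matrix holds multiple species: {list(tags)}")
        return str(tags[0])

    def layer(self, which: str = "lognorm") -> sp.csr_matrix:
        if which == "counts":
            return self.counts
        if which == "lognorm":
            if self.lognorm is None:
                raise ValueError("lognorm layer not computed; run normalize_log first")
            return self.lognorm
        raise KeyError(which)

    def subset(self, cells=None, genes=None) -> "CellMatrix":
        """Positional subset; order of the given indices is preserved."""
        ci = np.arange(self.n_cells) if cells is None else np.asarray(cells)
        gi = np.arange(self.n_genes) if genes is None else np.asarray(genes)
        if ci.dtype == bool:
            ci = np.flatnonzero(ci)
        if gi.dtype == bool:
            gi = np.flatnonzero(gi)
        return CellMatrix(
            counts=self.counts[ci][:, gi],
            cell_meta=self.cell_meta.iloc[ci].copy(),
            gene_meta=self.gene_meta.iloc[gi].copy(),
            lognorm=None if self.lognorm is None else self.lognorm[ci][:, gi],
        )

    def copy(self) -> "CellMatrix":
        return CellMatrix(
            counts=self.counts.copy(),
            cell_meta=self.cell_meta.copy(),
            gene_meta=self.gene_meta.copy(),
            lognorm=None if self.lognorm is None else self.lognorm.copy(),
        )

    def to_anndata(self):
        """Convert to an :class:`anndata.AnnData` (lognorm in X if present)."""
        import anndata as ad

        X = self.lognorm if self.lognorm is not None else self.counts
        adata = ad.AnnData(
            X=X.copy(), obs=self.cell_meta.copy(), var=self.gene_meta.copy()
        )
        adata.layers["counts"] = self.counts.copy()
        return adata


@dataclass
class QCConfig:
    """Cell- and gene-level quality-control thresholds.

    Defaults follow common droplet-data practice for islet samples: cells
    with >20% mitochondria-encoded counts are discarded, as are cells with
    fewer than 200 total counts or 200 detected genes; genes detected in
    fewer than 20 surviving cells are dropped before normalization.
    """

    max_mito_fraction: float = 0.20
    min_counts: int = 200
    min_genes: int = 200
    min_cells_per_gene: int = 20
    mito_gene_ids: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not (0.0 <= self.max_mito_fraction <= 1.0):
            raise ValueError("max_mito_fraction must be in [0, 1]")
        for name in ("min_counts", "min_genes", "min_cells_per_gene"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        self.mito_gene_ids = frozenset(self.mito_gene_ids)


@dataclass
class GroupProfile:
    """Per-group expression summary on the log-normalized layer.

    ``mean_expr`` and ``frac_expr`` are groups x genes frames sharing index
    (group tags) and columns (gene ids); ``n_cells`` is the per-group cell
    count. ``frac_expr`` is the fraction of cells with lognorm > 0.
    """

    mean_expr: pd.DataFrame
    frac_expr: pd.DataFrame
    n_cells: pd.Series

    def __post_init__(self) -> None:
        if not self.mean_expr.index.equals(self.frac_expr.index):
            raise ValueError("mean_expr / frac_expr group index mismatch")
        if not self.mean_expr.columns.equals(self.frac_expr.columns):
            raise ValueError("mean_expr / frac_expr gene columns mismatch")
        if (self.n_cells < 1).any():
            raise ValueError("groups must contain at least one cell")

    @property
    def groups(self) -> pd.Index:
        return self.mean_expr.index

    @property
    def genes(self) -> pd.Index:
        return self.mean_expr.columns

    def subset_genes(self, genes) -> "GroupProfile":
        genes = pd.Index(genes)
        missing = genes.difference(self.genes)
        if len(missing):
            raise KeyError(f"genes not in profile: {list(missing[:5])}")
        return GroupProfile(
            mean_expr=self.mean_expr[genes],
            frac_expr=self.frac_expr[genes],
            n_cells=self.n_cells,
        )

    def rename_genes(self, mapping: dict) -> "GroupProfile":
        return GroupProfile(
            mean_expr=self.mean_expr.rename(columns=mapping),
            frac_expr=self.frac_expr.rename(columns=mapping),
            n_cells=self.n_cells,
        )


def qc_filter(matrix: CellMatrix, cfg: QCConfig) -> CellMatrix:
    """Filter low-quality cells, then genes detected in too few cells.

    Cells are kept when their mitochondrial count fraction is at most
    ``max_mito_fraction``, their total counts reach ``min_counts`` and they
    express at least ``min_genes`` genes; all three are evaluated on the
    input gene space. Genes are then kept when expressed (count > 0) in at
    least ``min_cells_per_gene`` of the surviving cells. Ordering of
    survivors is preserved.
    """
    unknown = cfg.mito_gene_ids - set(matrix.native_ids)
    if unknown:
        raise KeyError(f"mito_gene_ids not in matrix: {sorted(unknown)[:5]}")

    counts = matrix.counts
    totals = np.asarray(counts.sum(axis=1)).ravel()
    mito_mask = matrix.native_ids.isin(cfg.mito_gene_ids)
    if mito_mask.any():
        mito_counts = np.asarray(counts[:, mito_mask].sum(axis=1)).ravel()
    else:
        mito_counts = np.zeros_like(totals)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)
    n_genes_per_cell = counts.getnnz(axis=1)

    crit = {
        "mito fraction": mito_frac <= cfg.max_mito_fraction,
        "total counts": totals >= cfg.min_counts,
        "detected genes": n_genes_per_cell >= cfg.min_genes,
    }
    keep_cells = np.logical_and.reduce(list(crit.values()))
    if not keep_cells.any():
        for name, mask in crit.items():
            if not mask.any():
                raise ValueError(f"no cells survive: {name} threshold excludes every cell")
        raise ValueError("no cells survive: combined QC thresholds exclude every cell")

    surv = counts[keep_cells]
    cells_per_gene = surv.getnnz(axis=0)
    keep_genes = cells_per_gene >= cfg.min_cells_per_gene
    if not keep_genes.any():
        raise ValueError(
            "no genes survive: min_cells_per_gene threshold excludes every gene"
        )
    return matrix.subset(cells=keep_cells, genes=keep_genes)


def normalize_log(
    matrix: CellMatrix,
    max_fraction: float = 0.05,
    target: float | None = None,
) -> CellMatrix:
    """Total-count normalization excluding highly expressed genes, then log1p.

    A gene is flagged *highly expressed* if in any single cell its count
    strictly exceeds ``max_fraction`` of that cell's total counts. Flagged
    genes are excluded only from the per-cell size-factor computation: the
    size factor is the sum of counts over non-flagged genes divided by
    ``target`` (the median of those filtered sums when ``target`` is None).
    The log-normalized layer is ``log(1 + count / size_factor)`` over *all*
    genes, so zeros map to zeros.
    """
    counts = matrix.counts
    totals = np.asarray(counts.sum(axis=1)).ravel()
    if (totals <= 0).any():
        bad = matrix.cell_meta.index[totals <= 0]
        raise ValueError(f"cells with zero total counts: {list(bad[:5])}")

    # per-gene max of count / cell-total, via row scaling
    frac = sp.diags(1.0 / totals) @ counts
    gene_max_frac = np.zeros(matrix.n_genes)
    frac_csc = frac.tocsc()
    for j in range(matrix.n_genes):
        col = frac_csc.data[frac_csc.indptr[j] : frac_csc.indptr[j + 1]]
        if col.size:
            gene_max_frac[j] = col.max()
    flagged = gene_max_frac > max_fraction

    filtered_sums = totals - np.asarray(counts[:, flagged].sum(axis=1)).ravel()
    if (filtered_sums <= 0).any():
        bad = matrix.cell_meta.index[filtered_sums <= 0]
        raise ValueError(
            "cells with zero counts outside highly-expressed genes: "
            f"{list(bad[:5])}"
        )
    tgt = float(np.median(filtered_sums)) if target is None else float(target)
    if tgt <= 0:
        raise ValueError("normalization target must be positive")
    size_factors = filtered_sums / tgt

    lognorm = sp.diags(1.0 / size_factors) @ counts.astype(float)
    lognorm.data = np.log1p(lognorm.data)
    out = matrix.copy()
    out.lognorm = _as_csr(lognorm)
    out.cell_meta = out.cell_meta.copy()
    out.cell_meta["size_factor"] = size_factors
    out.gene_meta = out.gene_meta.copy()
    out.gene_meta["highly_expressed"] = flagged
    return out


def batch_correct_zero_preserving(
    matrix: CellMatrix, batch_key: str = "batch"
) -> CellMatrix:
    """ComBat location/scale batch adjustment that keeps zeros at zero.

    Runs the parametric empirical-Bayes ComBat adjustment (batch-only model,
    no covariates) on the log-normalized layer, then resets every entry that
    was exactly zero before correction back to exactly zero. Non-zero
    entries are not clipped and may become negative. Genes whose residual
    variance within batches is zero carry no batch information and are
    passed through unchanged. A single batch is a no-op.
    """
    if matrix.lognorm is None:
        raise ValueError("lognorm layer required; run normalize_log first")
    if batch_key not in matrix.cell_meta.columns:
        raise KeyError(f"unknown batch key {batch_key!r}")
    batches = matrix.cell_meta[batch_key]
    if batches.isna().any():
        bad = matrix.cell_meta.index[batches.isna()]
        raise ValueError(f"missing batch labels for cells: {list(bad[:5])}")
    sizes = batches.value_counts()
    if len(sizes) == 1:
        return matrix.copy()
    if (sizes < 2).any():
        small = sizes.index[sizes < 2][0]
        raise ValueError(f"batch {small!r} has fewer than 2 cells")

    X = np.asarray(matrix.lognorm.todense(), dtype=float)
    zero_mask = X == 0.0

    # genes with zero within-batch residual variance are uninformative for the
    # EB fit (ComBat would divide by zero); adjust only the rest
    codes = batches.astype("category").cat.codes.to_numpy()
    resid = X - np.stack(
        [X[codes == b].mean(axis=0) for b in range(codes.max() + 1)]
    )[codes]
    adjustable = resid.var(axis=0) > 0.0

    if adjustable.any():
        import anndata as ad
        import scanpy as sc

        adata = ad.AnnData(
            X=X[:, adjustable].copy(),
            obs=pd.DataFrame({batch_key: batches.astype(str).to_numpy()},
                             index=matrix.cell_meta.index.astype(str)),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sc.pp.combat(adata, key=batch_key)
        X[:, adjustable] = adata.X

    X[zero_mask] = 0.0
    out = matrix.copy()
    out.lognorm = _as_csr(X)
    return out


def compute_group_profile(
    matrix: CellMatrix, group_key: str, genes=None
) -> GroupProfile:
    """Mean expression and expressing fraction per group on the lognorm layer."""
    if matrix.lognorm is None:
        raise ValueError("lognorm layer required; run normalize_log first")
    if group_key not in matrix.cell_meta.columns:
        raise KeyError(f"unknown group key {group_key!r}")
    labels = matrix.cell_meta[group_key]
    if labels.isna().any():
        bad = matrix.cell_meta.index[labels.isna()]
        raise ValueError(f"cells without a {group_key!r} label: {list(bad[:5])}")

    X = matrix.lognorm
    gene_index = matrix.native_ids
    if genes is not None:
        genes = pd.Index(genes)
        missing = genes.difference(gene_index)
        if len(missing):
            raise KeyError(f"requested genes not in matrix: {list(missing[:5])}")
        gi = gene_index.get_indexer(genes)
        X = X[:, gi]
        gene_index = genes

    groups = pd.Index(sorted(labels.unique()))
    means = np.empty((len(groups), X.shape[1]))
    fracs = np.empty_like(means)
    counts = np.empty(len(groups), dtype=int)
    for i, g in enumerate(groups):
        rows = X[(labels == g).to_numpy()]
        counts[i] = rows.shape[0]
        means[i] = np.asarray(rows.mean(axis=0)).ravel()
        fracs[i] = rows.getnnz(axis=0) / rows.shape[0]
    return GroupProfile(
        mean_expr=pd.DataFrame(means, index=groups, columns=gene_index),
        frac_expr=pd.DataFrame(fracs, index=groups, columns=gene_index),
        n_cells=pd.Series(counts, index=groups, name="n_cells"),
    )
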