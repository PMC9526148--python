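"""Pattern-correlation statistics for cross-species profile comparison.

Two flavours of similarity between expression patterns across cell types:

* **harmonic mode** — each (group, gene) entry is the harmonic mean
  ``h = 2 m f' / (m + f')`` of the group mean expression ``m`` and the
  normalized expressing fraction ``f' = f / mean_gene(f)`` (normalized to
  the per-group mean fraction over the compared gene subset, which cancels
  group- and species-level detection-rate differences). Pearson correlation
  of the flattened group x gene grids then leverages both the magnitude and
  the penetrance of expression.
* **mean mode** — plain Pearson correlation of group-mean expression grids.

A third statistic places cell-type centroids of several species into a
joint PCA space (after per-species gene scaling) and correlates them after
discarding the top variance components, which are typically dominated by
the cross-species axis rather than by cell identity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
from scipy import stats

from .core_data import CellMatrix, GroupProfile

__all__ = [
    "HarmonicProfile",
    "harmonic_profile",
    "pattern_correlation",
    "pca_group_correlation",
]


@dataclass
class HarmonicProfile:
    """Groups x genes grid of harmonic mean-expression/fraction averages."""

    values: pd.DataFrame

    @property
    def groups(self) -> pd.Index:
        return self.values.index

    @property
    def genes(self) -> pd.Index:
        return self.values.columns


def harmonic_profile(profile: GroupProfile, genes=None) -> HarmonicProfile:
    """Harmonic average of mean expression and normalized fraction.

    The fraction of expressing cells is first divided by its per-group mean
    over the requested gene subset (so the statistic is invariant to a
    group-wide rescaling of detection rates); ``h`` is zero whenever the
    mean or the fraction is zero.
    """
    genes = profile.genes if genes is None else pd.Index(genes)
    if len(genes) == 0:
        raise ValueError("empty gene subset")
    prof = profile.subset_genes(genes)
    M = prof.mean_expr.to_numpy(dtype=float)
    F = prof.frac_expr.to_numpy(dtype=float)
    mean_f = F.mean(axis=1)
    dead = mean_f <= 0
    if dead.any():
        raise ValueError(
            f"group {prof.groups[dead][0]!r} has all-zero fractions over the subset"
        )
    Fp = F / mean_f[:, None]
    denom = M + Fp
    with np.errstate(invalid="ignore", divide="ignore"):
        H = np.where(denom > 0, 2.0 * M * Fp / np.where(denom > 0, denom, 1.0), 0.0)
    return HarmonicProfile(values=pd.DataFrame(H, index=prof.groups, columns=genes))


def _as_grid(obj) -> pd.DataFrame:
    if isinstance(obj, HarmonicProfile):
        return obj.values
    if isinstance(obj, GroupProfile):
        return obj.mean_expr
    if isinstance(obj, pd.DataFrame):
        return obj
    raise TypeError(f"cannot correlate a {type(obj).__name__}")


def pattern_correlation(a, b, genes=None, groups=None) -> float:
    """Pearson correlation of two group x gene pattern grids.

    Both sides are reduced to the same grid (intersection of groups and
    genes, optionally restricted), flattened in identical order, and
    correlated. Pass :class:`HarmonicProfile` objects for harmonic mode or
    :class:`GroupProfile` / plain frames for group-mean mode.
    """
    A, B = _as_grid(a), _as_grid(b)
    g_rows = A.index.intersection(B.index)
    g_cols = A.columns.intersection(B.columns)
    if groups is not None:
        g_rows = g_rows.intersection(pd.Index(groups))
    if genes is not None:
        g_cols = g_cols.intersection(pd.Index(genes))
    x = A.loc[g_rows, g_cols].to_numpy(dtype=float).ravel()
    y = B.loc[g_rows, g_cols].to_numpy(dtype=float).ravel()
    if x.size < 3:
        raise ValueError(f"need at least 3 grid points, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant pattern vector: correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


def _subsample_positions(
    cell_ids: pd.Index, labels: pd.Series, cap: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-group subsample drawn against the sorted cell-id list.

    Drawing against sorted ids (not raw positions) makes the selection
    invariant to cell order at a fixed seed.
    """
    keep_ids: list = []
    for g in sorted(labels.unique()):
        ids = sorted(cell_ids[(labels == g).to_numpy()])
        if len(ids) < 3:
            warnings.warn(f"group {g!r} has <3 cells; excluded")
            continue
        if len(ids) > cap:
            sel = rng.choice(len(ids), size=cap, replace=False)
            ids = [ids[i] for i in sorted(sel)]
        keep_ids.extend(ids)
    return cell_ids.get_indexer(keep_ids)


def pca_group_correlation(
    matrices: dict[str, CellMatrix],
    group_key: str = "cell_type",
    n_pcs: int = 50,
    drop_top: int = 2,
    subsample_cap: int = 2000,
    seed: int = 0,
):
    """Cross-species cell-type correlation in a joint PCA space.

    Cells of every (species, group) are subsampled to ``subsample_cap`` to
    balance representation, genes are z-scored within species, cells are
    concatenated and reduced to ``n_pcs`` principal components. The first
    ``drop_top`` components — typically carrying the species axis — are
    discarded; remaining coordinates are averaged per (species, group) and
    correlated pairwise. Returns ``(corr, order)`` where ``corr`` is a
    symmetric frame over (species, group) labels and ``order`` the leaf
    order of average-linkage clustering on correlation distance.
    """
    from sklearn.decomposition import PCA

    if n_pcs <= drop_top:
        raise ValueError("n_pcs must exceed drop_top")
    rng = np.random.default_rng(seed)

    common = None
    for m in matrices.values():
        ids = (
            pd.Index(m.gene_meta["common_id"])
            if "common_id" in m.gene_meta.columns
            else m.native_ids
        )
        common = ids if common is None else common.intersection(ids)
    if common is None or len(common) == 0:
        raise ValueError("no common genes across matrices")
    common = pd.Index(sorted(common))

    blocks, entities = [], []
    for species in sorted(matrices):
        m = matrices[species]
        ids = (
            pd.Index(m.gene_meta["common_id"])
            if "common_id" in m.gene_meta.columns
            else m.native_ids
        )
        gi = ids.get_indexer(common)
        labels = m.cell_meta[group_key]
        pos = _subsample_positions(m.cell_meta.index, labels, subsample_cap, rng)
        X = np.asarray(m.layer("lognorm")[pos][:, gi].todense(), dtype=float)
        mu, sd = X.mean(axis=0), X.std(axis=0)
        sd[sd == 0] = 1.0
        blocks.append((X - mu) / sd)
        entities.append(
            pd.DataFrame(
                {
                    "species": species,
                    "group": labels.iloc[pos].to_numpy(),
                }
            )
        )
    X = np.vstack(blocks)
    ent = pd.concat(entities, ignore_index=True)

    n_comp = min(n_pcs, X.shape[0] - 1, X.shape[1])
    if n_comp <= drop_top:
        raise ValueError("not enough data for the requested component count")
    pca = PCA(n_components=n_comp, random_state=seed)
    coords = pca.fit_transform(X)[:, drop_top:]

    keys = ent["species"].str.cat(ent["group"].astype(str), sep="|")
    centroids = (
        pd.DataFrame(coords, index=keys.to_numpy())
        .groupby(level=0)
        .mean()
        .sort_index()
    )
    corr = centroids.T.corr(method="pearson")

    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    link = sch.linkage(ssd.squareform(dist, checks=False), method="average")
    order = [corr.index[i] for i in sch.leaves_list(link)]
    return corr, order
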