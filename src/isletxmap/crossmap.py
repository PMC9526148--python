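"""Reference mapping in gene-set space with kNN label transfer.

The reference model represents every cell by its gene-set activation
scores, z-scales each set with parameters fitted on the reference, and
stores a PCA basis of that scaled space together with the reference
coordinates and labels. Query cells (another species, another study) are
scored on the same gene sets (members intersected with the query gene
space), scaled with the *reference* parameters, projected with the
reference loadings and labelled by majority vote among their k nearest
reference cells. Scaling with reference parameters — never refitted on the
query — is what makes the projection a mapping onto the reference state
map rather than a fresh embedding.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import CellMatrix
from .genesets import GeneSet, GeneSetCollection, score_gene_sets

__all__ = [
    "ReferenceModel",
    "fit_reference",
    "project_and_classify",
    "knn_classify",
    "composition_summary",
]


@dataclass
class ReferenceModel:
    gene_sets: GeneSetCollection
    set_names: list[str]
    scaling_mean: np.ndarray
    scaling_sd: np.ndarray
    loadings: np.ndarray  # n_components x n_sets
    reference_coords: np.ndarray  # n_cells x n_components
    reference_labels: np.ndarray
    k: int = 15
    n_components: int = 2
    score_config: dict = field(default_factory=dict)

    def save(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        cfg = {
            "set_names": self.set_names,
            "scaling_mean": self.scaling_mean.tolist(),
            "scaling_sd": self.scaling_sd.tolist(),
            "k": self.k,
            "n_components": self.n_components,
            "score_config": self.score_config,
            "gene_sets": [
                {
                    "name": s.name,
                    "genes": s.genes,
                    "mean_intra_correlation": s.mean_intra_correlation,
                }
                for s in self.gene_sets.sets
            ],
        }
        with open(os.path.join(outdir, "model.json"), "w") as fh:
            json.dump(cfg, fh, indent=1)
        pd.DataFrame(self.loadings, columns=self.set_names).to_csv(
            os.path.join(outdir, "loadings.tsv"), sep="\t", index=False
        )
        coords = pd.DataFrame(
            self.reference_coords,
            columns=[f"pc_{i + 1}" for i in range(self.n_components)],
        )
        coords["label"] = self.reference_labels
        coords.to_csv(
            os.path.join(outdir, "reference_coords.tsv"), sep="\t", index=False
        )

    @classmethod
    def load(cls, indir: str) -> "ReferenceModel":
        with open(os.path.join(indir, "model.json")) as fh:
            cfg = json.load(fh)
        loadings = pd.read_csv(
            os.path.join(indir, "loadings.tsv"), sep="\t"
        ).to_numpy()
        coords = pd.read_csv(os.path.join(indir, "reference_coords.tsv"), sep="\t")
        labels = coords.pop("label").to_numpy()
        sets = GeneSetCollection(
            sets=[
                GeneSet(
                    name=s["name"],
                    genes=s["genes"],
                    mean_intra_correlation=s["mean_intra_correlation"],
                )
                for s in cfg["gene_sets"]
            ]
        )
        return cls(
            gene_sets=sets,
            set_names=cfg["set_names"],
            scaling_mean=np.asarray(cfg["scaling_mean"], dtype=float),
            scaling_sd=np.asarray(cfg["scaling_sd"], dtype=float),
            loadings=loadings,
            reference_coords=coords.to_numpy(dtype=float),
            reference_labels=labels,
            k=int(cfg["k"]),
            n_components=int(cfg["n_components"]),
            score_config=cfg.get("score_config", {}),
        )


def fit_reference(
    scores: pd.DataFrame,
    labels,
    n_components: int,
    k: int = 15,
    gene_sets: GeneSetCollection | None = None,
) -> ReferenceModel:
    """Fit scaling + PCA + kNN reference on a cells x sets score matrix."""
    from sklearn.decomposition import PCA

    labels = np.asarray(labels)
    if len(labels) != len(scores):
        raise ValueError("labels must match score rows")
    if len(scores) < k + 1:
        raise ValueError(f"need at least k+1={k + 1} cells")
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 distinct labels")

    sd = scores.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all gene sets have zero score variance")
    if not keep.all():
        warnings.warn(
            f"dropping zero-variance sets: {list(scores.columns[~keep])}"
        )
    scores = scores.loc[:, keep]
    if n_components > scores.shape[1]:
        raise ValueError(
            f"n_components={n_components} exceeds {scores.shape[1]} usable sets"
        )
    mean = scores.mean(axis=0).to_numpy()
    sdv = scores.std(axis=0, ddof=0).to_numpy()
    Z = (scores.to_numpy() - mean) / sdv
    pca = PCA(n_components=n_components, random_state=0)
    coords = pca.fit_transform(Z)

    if gene_sets is None:
        gene_sets = GeneSetCollection(
            sets=[GeneSet(name=c, genes=[]) for c in scores.columns]
        )
    else:
        gene_sets = GeneSetCollection(
            sets=[s for s in gene_sets.sets if s.name in set(scores.columns)],
            provenance=gene_sets.provenance,
        )
    return ReferenceModel(
        gene_sets=gene_sets,
        set_names=list(scores.columns),
        scaling_mean=mean,
        scaling_sd=sdv,
        loadings=pca.components_,
        reference_coords=coords,
        reference_labels=labels,
        k=k,
        n_components=n_components,
        score_config={},
    )


def knn_classify(
    model: ReferenceModel,
    coords: np.ndarray,
    k: int | None = None,
    exclude_self: bool = False,
) -> pd.DataFrame:
    """Majority-vote label transfer from the reference cells.

    Ties are broken by the lexicographically smallest label. With
    ``exclude_self`` the single nearest zero-distance neighbor is skipped
    (for self-mapping checks on the reference itself).
    """
    from sklearn.neighbors import NearestNeighbors

    k = model.k if k is None else int(k)
    n_query = k + (1 if exclude_self else 0)
    nn = NearestNeighbors(n_neighbors=min(n_query, len(model.reference_coords)))
    nn.fit(model.reference_coords)
    dist, idx = nn.kneighbors(coords)
    if exclude_self:
        dist, idx = dist[:, 1:], idx[:, 1:]
    labels = np.asarray(model.reference_labels)
    out_labels, out_dist = [], []
    for d_row, i_row in zip(dist, idx):
        neigh = labels[i_row]
        vals, counts = np.unique(neigh, return_counts=True)
        winners = vals[counts == counts.max()]
        out_labels.append(sorted(map(str, winners))[0])
        out_dist.append(float(d_row.mean()))
    return pd.DataFrame({"label": out_labels, "mean_neighbor_dist": out_dist})


def _intersect_sets(
    sets: GeneSetCollection, query_ids: pd.Index
) -> tuple[GeneSetCollection, list[str]]:
    kept, lost = [], []
    available = set(query_ids)
    for s in sets.sets:
        members = [g for g in s.genes if g in available]
        if members:
            kept.append(GeneSet(s.name, members, s.mean_intra_correlation))
        else:
            lost.append(s.name)
    return GeneSetCollection(sets=kept, provenance=sets.provenance), lost


def project_and_classify(
    model: ReferenceModel,
    query: CellMatrix,
    gene_subset_mode: str = "shared",
    n_bins: int = 25,
    background_size: int = 50,
    seed: int = 0,
    k: int | None = None,
) -> pd.DataFrame:
    """Score, scale, project and label query cells against the reference.

    Set members are intersected with the query gene space (``common_id``
    when mapped into the reference namespace, else ``native_id``); sets
    losing every member are kept at the reference mean (scaled score 0) and
    reported with a warning. Expression bins for the background are
    computed on the query itself.
    """
    if gene_subset_mode not in ("shared", "mappable"):
        raise ValueError("gene_subset_mode must be 'shared' or 'mappable'")
    if gene_subset_mode == "mappable" and "common_id" not in query.gene_meta.columns:
        raise ValueError("query has no common_id; run apply_mapping first")
    ids = (
        pd.Index(query.gene_meta["common_id"])
        if "common_id" in query.gene_meta.columns
        else query.native_ids
    )

    sets, lost = _intersect_sets(model.gene_sets, ids)
    if lost:
        warnings.warn(f"sets with no members in query: {lost}")
    if len(sets) == 0:
        raise ValueError("every gene set lost all members in the query")

    q = query
    if not ids.equals(query.native_ids):
        q = query.copy()
        q.gene_meta = q.gene_meta.set_index(pd.Index(ids, name="native_id"))

    scores = score_gene_sets(
        q, sets, n_bins=n_bins, background_size=background_size, seed=seed
    )
    Z = np.zeros((len(scores), len(model.set_names)))
    for j, name in enumerate(model.set_names):
        if name in scores.columns:
            Z[:, j] = (scores[name].to_numpy() - model.scaling_mean[j]) / (
                model.scaling_sd[j]
            )
    coords = Z @ model.loadings.T
    res = knn_classify(model, coords, k=k)
    res.index = query.cell_meta.index
    for i in range(model.n_components):
        res[f"pc_{i + 1}"] = coords[:, i]
    return res


def composition_summary(labels, stratify_by=None) -> pd.DataFrame:
    """Counts and fractions of labels, optionally per stratum."""
    labels = pd.Series(labels, name="label")
    if len(labels) == 0:
        raise ValueError("no cells")
    if stratify_by is None:
        strata = pd.Series(["all"] * len(labels), index=labels.index, name="stratum")
    else:
        strata = pd.Series(stratify_by, index=labels.index, name="stratum")
    df = pd.DataFrame({"stratum": strata.to_numpy(), "label": labels.to_numpy()})
    counts = (
        df.groupby(["stratum", "label"], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )
    totals = counts.groupby("stratum")["count"].transform("sum")
    counts["fraction"] = counts["count"] / totals
    return counts
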