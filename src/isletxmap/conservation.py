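"""Enriched-marker detection and cross-species conservation classification.

A gene is an *enriched marker* of a cell type when it is expressed in a
minimum fraction of that type's cells and its mean log-normalized
expression exceeds the cell-count-weighted mean over all other cells by a
log2 fold-change threshold (defaults: fraction >= 0.05, log2FC > 0.5, i.e.
at least 1.4-fold).

Conservation of a reference species' expression in a target species is
classified per (gene, cell type):

* expression level — ``conserved`` (expressed in the matched type in both),
  ``loss`` (reference-expressed but in the target only some other type
  passes), ``absent`` (no target type passes), ``gain`` (target-expressed
  in the matched type while the reference is not);
* marker level — for each reference-enriched (gene, type): ``conserved``
  (enriched for the same type in the target), ``switch`` (enriched for a
  different type), ``loss`` (expressed somewhere but enriched nowhere),
  ``absent`` otherwise. A same-type match takes precedence over switches.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .core_data import GroupProfile

__all__ = [
    "MarkerTable",
    "find_enriched_markers",
    "classify_expression_conservation",
    "classify_marker_conservation",
    "marker_overlap",
]

CATEGORIES = ("conserved", "loss", "switch", "absent", "gain")


@dataclass
class MarkerTable:
    """Long table of per (cell_type, gene) marker statistics.

    Columns: ``cell_type``, ``gene``, ``log2fc``, ``frac_in_type``,
    ``is_enriched``.
    """

    table: pd.DataFrame
    frac_threshold: float = 0.05
    fc_threshold: float = 0.5

    @property
    def cell_types(self) -> list:
        return sorted(self.table["cell_type"].unique())

    def enriched(self, cell_type=None) -> pd.DataFrame:
        t = self.table[self.table["is_enriched"]]
        if cell_type is not None:
            t = t[t["cell_type"] == cell_type]
        return t

    def enriched_genes(self, cell_type) -> set:
        return set(self.enriched(cell_type)["gene"])

    def _enriched_grid(self) -> pd.DataFrame:
        """cell_type x gene boolean enrichment grid."""
        return self.table.pivot(
            index="cell_type", columns="gene", values="is_enriched"
        ).fillna(False)


def find_enriched_markers(
    profile: GroupProfile,
    frac_threshold: float = 0.05,
    fc_threshold: float = 0.5,
    epsilon: float = 1e-9,
    frac_strict: bool = False,
) -> MarkerTable:
    """Detect cell-type-enriched genes from a group profile.

    ``log2fc = log2((E_c + eps) / (E_rest + eps))`` where ``E_rest`` is the
    cell-count-weighted mean over all other groups. The fraction gate is
    ``>=`` by default (``frac_strict=True`` switches to ``>``).
    """
    if len(profile.groups) < 2:
        raise ValueError("marker detection needs at least 2 groups")
    M = profile.mean_expr.to_numpy()
    F = profile.frac_expr.to_numpy()
    n = profile.n_cells.to_numpy().astype(float)[:, None]
    total = (M * n).sum(axis=0)
    rest_mean = (total - M * n) / (n.sum() - n)
    log2fc = np.log2((M + epsilon) / (rest_mean + epsilon))
    gate = F > frac_threshold if frac_strict else F >= frac_threshold
    enriched = gate & (log2fc > fc_threshold)

    rows = pd.DataFrame(
        {
            "cell_type": np.repeat(profile.groups, len(profile.genes)),
            "gene": np.tile(profile.genes, len(profile.groups)),
            "log2fc": log2fc.ravel(),
            "frac_in_type": F.ravel(),
            "is_enriched": enriched.ravel(),
        }
    )
    return MarkerTable(
        table=rows, frac_threshold=frac_threshold, fc_threshold=fc_threshold
    )


def _shared_grids(ref: GroupProfile, target: GroupProfile):
    genes = ref.genes.intersection(target.genes)
    if len(genes) == 0:
        raise ValueError("no shared genes between reference and target")
    types = ref.groups.intersection(target.groups)
    if len(types) == 0:
        raise ValueError("no shared cell types between reference and target")
    return genes, types


def classify_expression_conservation(
    ref: GroupProfile,
    target: GroupProfile,
    expressed_threshold: float = 0.05,
) -> pd.DataFrame:
    """Expression-level conservation calls per (gene, cell type).

    "Expressed" means the fraction of expressing cells strictly exceeds
    ``expressed_threshold``. Rows are emitted for every (gene, type) where
    the reference passes (conserved / loss / absent) or only the target
    passes (gain); exactly one category per emitted pair.
    """
    genes, types = _shared_grids(ref, target)
    R = ref.frac_expr.loc[types, genes].to_numpy() > expressed_threshold
    T = target.frac_expr.loc[types, genes].to_numpy() > expressed_threshold
    # passes counted over *all* target types, including ones outside the
    # shared vocabulary, so "another cell type" means any other target type
    pass_count_full = (
        target.frac_expr[genes].to_numpy() > expressed_threshold
    ).sum(axis=0)[None, :]
    any_other = (pass_count_full - T.astype(int)) > 0

    conserved = R & T
    loss = R & ~T & any_other
    absent = R & ~T & ~any_other
    gain = ~R & T

    frames = []
    for cat, mask in (
        ("conserved", conserved),
        ("loss", loss),
        ("absent", absent),
        ("gain", gain),
    ):
        ti, gi = np.nonzero(mask)
        frames.append(
            pd.DataFrame(
                {
                    "gene": genes[gi],
                    "cell_type": types[ti],
                    "category": cat,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["cell_type", "gene"]).reset_index(drop=True)


def classify_marker_conservation(
    ref_markers: MarkerTable,
    tgt_markers: MarkerTable,
    tgt_profile: GroupProfile,
    expressed_threshold: float = 0.05,
) -> pd.DataFrame:
    """Marker-level conservation calls for every reference-enriched pair."""
    ref_enr = ref_markers.enriched()
    if ref_enr.empty:
        return pd.DataFrame(columns=["gene", "cell_type", "category"])

    tgt_grid = tgt_markers._enriched_grid()
    tgt_genes = set(tgt_profile.genes)

    expressed_any = (tgt_profile.frac_expr > expressed_threshold).any(axis=0)

    records = []
    for cell_type, gene in ref_enr[["cell_type", "gene"]].itertuples(index=False):
        enriched_same = (
            cell_type in tgt_grid.index
            and gene in tgt_grid.columns
            and bool(tgt_grid.at[cell_type, gene])
        )
        enriched_elsewhere = (
            gene in tgt_grid.columns
            and bool(tgt_grid[gene].drop(index=cell_type, errors="ignore").any())
        )
        if enriched_same:
            cat = "conserved"
        elif enriched_elsewhere:
            cat = "switch"
        elif gene in tgt_genes and bool(expressed_any.get(gene, False)):
            cat = "loss"
        else:
            cat = "absent"
        records.append((gene, cell_type, cat))
    out = pd.DataFrame(records, columns=["gene", "cell_type", "category"])
    return out.sort_values(["cell_type", "gene"]).reset_index(drop=True)


def marker_overlap(markers_by_species: dict[str, MarkerTable]) -> pd.DataFrame:
    """Per-cell-type Venn region counts of enriched marker genes.

    Regions are exclusive: a gene is counted once, in the region named by
    exactly the set of species in which it is enriched for that cell type.
    """
    if len(markers_by_species) < 2:
        raise ValueError("marker overlap needs at least 2 species")
    species = sorted(markers_by_species)
    cell_types = sorted(
        set().union(*(m.cell_types for m in markers_by_species.values()))
    )
    rows = []
    for ct in cell_types:
        sets = {s: markers_by_species[s].enriched_genes(ct) for s in species}
        all_genes = set().union(*sets.values())
        for gene in all_genes:
            member_of = frozenset(s for s in species if gene in sets[s])
            rows.append((ct, "&".join(sorted(member_of)), gene))
    df = pd.DataFrame(rows, columns=["cell_type", "region", "gene"])
    counts = (
        df.groupby(["cell_type", "region"])["gene"].count().rename("count")
    ).reset_index()
    # include empty regions so every intersection is reported
    regions = [
        "&".join(sorted(c))
        for r in range(1, len(species) + 1)
        for c in combinations(species, r)
    ]
    full = pd.MultiIndex.from_product(
        [cell_types, regions], names=["cell_type", "region"]
    )
    out = (
        counts.set_index(["cell_type", "region"])
        .reindex(full, fill_value=0)
        .reset_index()
    )
    return out
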