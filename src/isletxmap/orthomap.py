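"""Ortholog resolution to a one-to-one cross-species gene space.

An ortholog table holds one record per candidate gene tuple (one id column
per species). Annotation releases produce one-to-many records; resolution
keeps, for every ambiguity group, the record whose candidate partner shows
the highest overall mean log-normalized expression in the partner's species
(ties broken by lexicographically smallest id), after dropping records with
any id undetected in its species. Matrices are then renamed into a chosen
namespace, and the variance retained by the mappable subset summarizes how
much signal the cross-species gene space preserves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import CellMatrix, GroupProfile

__all__ = [
    "OrthologTable",
    "resolve_orthologs",
    "apply_mapping",
    "explained_variance_fraction",
    "read_ortholog_table",
    "write_ortholog_table",
]

_META_COLS = ("cardinality", "kept")


@dataclass
class OrthologTable:
    """Cross-species gene records; one id column per species.

    After :func:`resolve_orthologs` the frame carries ``cardinality``
    (``one_to_one`` / ``ambiguous``) and ``kept`` columns and ``resolved``
    is True; :attr:`mapping` is then the surviving one-to-one table.
    """

    records: pd.DataFrame
    resolved: bool = False

    def __post_init__(self) -> None:
        if self.records.shape[1] < 2 and not set(_META_COLS) & set(
            self.records.columns
        ):
            raise ValueError("ortholog table needs at least two species columns")

    @property
    def species(self) -> list[str]:
        return [c for c in self.records.columns if c not in _META_COLS]

    @property
    def mapping(self) -> pd.DataFrame:
        if not self.resolved:
            raise ValueError("table not resolved; run resolve_orthologs first")
        kept = self.records[self.records["kept"]]
        return kept[self.species].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)


def _overall_mean_expression(obj) -> pd.Series:
    """Mean lognorm per gene across all cells of one species."""
    if isinstance(obj, CellMatrix):
        if obj.lognorm is None:
            raise ValueError("lognorm layer required for ortholog resolution")
        vals = np.asarray(obj.lognorm.mean(axis=0)).ravel()
        return pd.Series(vals, index=obj.native_ids)
    if isinstance(obj, GroupProfile):
        w = obj.n_cells.to_numpy()[:, None]
        vals = (obj.mean_expr.to_numpy() * w).sum(axis=0) / w.sum()
        return pd.Series(vals, index=obj.genes)
    if isinstance(obj, pd.Series):
        return obj
    raise TypeError(f"cannot derive expression from {type(obj).__name__}")


def _resolve_pair(
    records: pd.DataFrame, col_a: str, col_b: str, expr: dict[str, pd.Series]
) -> pd.DataFrame:
    """Keep, per duplicated id in one column, the max-expressed partner."""
    for own, partner in ((col_a, col_b), (col_b, col_a)):
        dup_ids = records[own][records[own].duplicated(keep=False)].unique()
        keep = np.ones(len(records), dtype=bool)
        for gid in dup_ids:
            rows = records.index[records[own] == gid]
            partners = records.loc[rows, partner]
            missing = [p for p in partners if p not in expr[partner].index]
            if missing:
                raise KeyError(
                    f"expression missing for ambiguous candidate {missing[0]!r} "
                    f"in species {partner!r}"
                )
            vals = expr[partner].loc[partners]
            best = vals.max()
            tied = sorted(partners[(vals == best).to_numpy()])
            winner = tied[0]
            keep[records.index.get_indexer(rows)] &= (
                records.loc[rows, partner] == winner
            ).to_numpy()
        records = records[keep].reset_index(drop=True)
    return records


def resolve_orthologs(table: OrthologTable, expr_by_species: dict) -> OrthologTable:
    """Resolve ambiguous records by maximal overall mean expression.

    ``expr_by_species`` maps each species tag to a :class:`CellMatrix`,
    :class:`GroupProfile` or per-gene expression series; an id counts as
    *detected* when present there. Records with any undetected id are
    dropped; in each ambiguity group only the candidate partner with the
    highest overall mean expression survives (ties: smallest id). With
    three species, pairs are resolved anchored on the middle column
    (e.g. pig<->human then pig<->mouse). Output is deterministic and
    independent of input record order.
    """
    species = table.species
    missing_sp = [s for s in species if s not in expr_by_species]
    if missing_sp:
        raise KeyError(f"no expression data for species {missing_sp[0]!r}")
    expr = {s: _overall_mean_expression(expr_by_species[s]) for s in species}

    recs = table.records[species].dropna().astype(str)
    recs = recs.sort_values(by=species).reset_index(drop=True)

    detected = np.ones(len(recs), dtype=bool)
    for s in species:
        detected &= recs[s].isin(expr[s].index).to_numpy()
    surv = recs[detected].reset_index(drop=True)

    ambiguous_ids = {
        s: set(surv[s][surv[s].duplicated(keep=False)]) for s in species
    }

    anchor = "pig" if "pig" in species else species[min(1, len(species) - 1)]
    others = [s for s in species if s != anchor]
    for other in others:
        surv = _resolve_pair(surv, anchor, other, expr)

    kept_keys = set(map(tuple, surv[species].to_numpy()))
    out = recs.copy()
    out["cardinality"] = [
        "ambiguous"
        if any(out.at[i, s] in ambiguous_ids[s] for s in species)
        else "one_to_one"
        for i in out.index
    ]
    out["kept"] = [tuple(row) in kept_keys for row in out[species].to_numpy()]
    return OrthologTable(records=out, resolved=True)


def apply_mapping(
    matrix: CellMatrix, table: OrthologTable, namespace: str
) -> CellMatrix:
    """Subset a matrix to mapped genes and rename into ``namespace`` ids.

    Genes come out in table order with ``common_id`` set to the chosen
    namespace's id; the matrix's own species column of the table is matched
    against its ``native_id`` index.
    """
    if not table.resolved:
        raise ValueError("ortholog table not resolved")
    if namespace not in table.species:
        raise KeyError(f"namespace {namespace!r} not a species column")
    own = matrix.species
    if own not in table.species:
        raise KeyError(f"matrix species {own!r} not a species column")
    mapping = table.mapping
    present = mapping[own].isin(matrix.native_ids)
    mapping = mapping[present]
    if mapping.empty:
        raise ValueError("no mappable genes between matrix and ortholog table")
    gi = matrix.native_ids.get_indexer(mapping[own])
    out = matrix.subset(genes=gi)
    out.gene_meta = out.gene_meta.copy()
    out.gene_meta["common_id"] = mapping[namespace].to_numpy()
    return out


def explained_variance_fraction(matrix: CellMatrix, gene_subset) -> float:
    """Fraction of summed per-gene lognorm variance carried by a gene subset."""
    if matrix.lognorm is None:
        raise ValueError("lognorm layer required")
    subset = pd.Index(pd.unique(pd.Series(list(gene_subset), dtype=object)))
    in_native = matrix.native_ids.isin(subset)
    if not in_native.any() and "common_id" in matrix.gene_meta.columns:
        in_native = matrix.gene_meta["common_id"].isin(subset).to_numpy()
    unknown = len(subset) > 0 and in_native.sum() == 0
    if unknown:
        raise KeyError("gene_subset has no overlap with matrix genes")

    X = matrix.lognorm
    mean = np.asarray(X.mean(axis=0)).ravel()
    mean_sq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
    var = mean_sq - mean**2
    total = var.sum()
    if total <= 0:
        raise ValueError("total variance is zero")
    return float(var[in_native].sum() / total)


def read_ortholog_table(path: str) -> OrthologTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    resolved = "kept" in df.columns
    if resolved:
        df["kept"] = df["kept"].map({"True": True, "False": False}).astype(bool)
    return OrthologTable(records=df, resolved=resolved)


def write_ortholog_table(table: OrthologTable, path: str) -> None:
    table.records.to_csv(path, sep="\t", index=False)
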