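"""Plain-text I/O: Matrix Market matrices, TSV annotations, GMT gene sets.

A :class:`~isletxmap.core_data.CellMatrix` is stored as a directory holding
``matrix.mtx`` (counts, cells as rows), ``genes.tsv`` (native_id and
optional common_id), ``barcodes.tsv`` (cell ids), ``cell_meta.tsv`` and,
when present, ``lognorm.mtx``. Group profiles travel as long-format TSV and
gene-set collections as GMT (set name, description, members).
"""

from __future__ import annotations

import os

import pandas as pd
import scipy.io
import scipy.sparse as sp

from .core_data import CellMatrix, GroupProfile
from .genesets import GeneSet, GeneSetCollection

__all__ = [
    "read_cell_matrix",
    "write_cell_matrix",
    "read_profile",
    "write_profile",
    "read_gmt",
    "write_gmt",
]


def write_cell_matrix(matrix: CellMatrix, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    scipy.io.mmwrite(os.path.join(outdir, "matrix.mtx"), matrix.counts)
    genes = matrix.gene_meta.copy()
    genes.index.name = "native_id"
    genes.reset_index().to_csv(
        os.path.join(outdir, "genes.tsv"), sep="\t", index=False
    )
    with open(os.path.join(outdir, "barcodes.tsv"), "w") as fh:
        fh.write("\n".join(map(str, matrix.cell_meta.index)) + "\n")
    meta = matrix.cell_meta.copy()
    meta.index.name = "cell_id"
    meta.reset_index().to_csv(
        os.path.join(outdir, "cell_meta.tsv"), sep="\t", index=False
    )
    if matrix.lognorm is not None:
        scipy.io.mmwrite(os.path.join(outdir, "lognorm.mtx"), matrix.lognorm)


def read_cell_matrix(indir: str) -> CellMatrix:
    counts = sp.csr_matrix(scipy.io.mmread(os.path.join(indir, "matrix.mtx")))
    genes = pd.read_csv(os.path.join(indir, "genes.tsv"), sep="\t").set_index(
        "native_id"
    )
    meta = pd.read_csv(os.path.join(indir, "cell_meta.tsv"), sep="\t").set_index(
        "cell_id"
    )
    lognorm_path = os.path.join(indir, "lognorm.mtx")
    lognorm = (
        sp.csr_matrix(scipy.io.mmread(lognorm_path))
        if os.path.exists(lognorm_path)
        else None
    )
    return CellMatrix(counts=counts, cell_meta=meta, gene_meta=genes, lognorm=lognorm)


def write_profile(profile: GroupProfile, path: str) -> None:
    long = (
        profile.mean_expr.stack()
        .rename("mean_expr")
        .to_frame()
        .join(profile.frac_expr.stack().rename("frac_expr"))
        .reset_index()
    )
    long.columns = ["group", "gene", "mean_expr", "frac_expr"]
    long["n_cells"] = profile.n_cells.reindex(long["group"]).to_numpy()
    long.to_csv(path, sep="\t", index=False)


def read_profile(path: str) -> GroupProfile:
    long = pd.read_csv(path, sep="\t")
    mean = long.pivot(index="group", columns="gene", values="mean_expr")
    frac = long.pivot(index="group", columns="gene", values="frac_expr")
    n = long.groupby("group")["n_cells"].first().astype(int)
    return GroupProfile(mean_expr=mean, frac_expr=frac, n_cells=n.loc[mean.index])


def write_gmt(collection: GeneSetCollection, path: str) -> None:
    with open(path, "w") as fh:
        for s in collection.sets:
            desc = f"mean_intra_correlation={s.mean_intra_correlation:.6g}"
            fh.write("\t".join([s.name, desc, *s.genes]) + "\n")


def read_gmt(path: str) -> GeneSetCollection:
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name, desc, genes = parts[0], parts[1], parts[2:]
            corr = 0.0
            if "mean_intra_correlation=" in desc:
                corr = float(desc.split("=", 1)[1])
            sets.append(GeneSet(name=name, genes=list(genes), mean_intra_correlation=corr))
    return GeneSetCollection(sets=sets, provenance={"source": os.path.basename(path)})
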