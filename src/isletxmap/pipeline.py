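"""Staged pipeline orchestration with a single JSON configuration.

Stages run in declared order, each reading the previous stage's on-disk
outputs from the run directory, so any suffix of the pipeline can be rerun
from intermediate files. Every output file is recorded with a SHA-256
checksum in the run report; all randomness flows from the single global
seed via per-stage derived seeds.

Stage chain: ``simulate`` (synthetic panel) -> ``preprocess`` (QC,
normalization, zero-preserving batch correction, ortholog resolution and
renaming into the reference namespace) -> ``markers`` -> ``conserve`` ->
``corr`` -> ``genesets`` -> ``score`` -> ``map`` -> ``report``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import sys
import time
import warnings

import pandas as pd

from . import conservation as cons
from . import core_data, crossmap, genesets, orthomap
from . import io as iomod
from . import synthetic_data as synth
from .pattern_correlation import (
    harmonic_profile,
    pattern_correlation,
    pca_group_correlation,
)

__all__ = ["PipelineConfig", "run_pipeline", "default_config", "STAGES"]

STAGES = (
    "simulate",
    "preprocess",
    "markers",
    "conserve",
    "corr",
    "genesets",
    "score",
    "map",
    "report",
)

_STAGE_DEFAULTS: dict[str, dict] = {
    "simulate": {},  # SimConfig fields
    "preprocess": {
        "max_mito_fraction": 0.20,
        "min_counts": 200,
        "min_genes": 200,
        "min_cells_per_gene": 20,
        "mito_gene_ids": [],
        "max_fraction": 0.05,
        "batch_correct": True,
    },
    "markers": {"frac_threshold": 0.05, "fc_threshold": 0.5},
    "conserve": {"expressed_threshold": 0.05},
    "corr": {"n_pcs": 50, "drop_top": 2, "subsample_cap": 2000},
    "genesets": {
        "cell_type": "beta",
        "n_variable_genes": 3000,
        "min_cells": 20,
        "n_clusters": 20,
        "min_corr": 0.005,
    },
    "score": {"n_bins": 25, "background_size": 50},
    "map": {"n_components": 10, "k": 15, "label_key": "state"},
    "report": {},
}

_TOP_KEYS = {"stages", "seed", "outdir", "reference"} | set(STAGES)


class PipelineConfig:
    """Validated pipeline configuration.

    A plain dict mirroring :data:`_STAGE_DEFAULTS`: a ``stages`` list, a
    global ``seed``, the run ``outdir``, the ``reference`` species and one
    optional parameter block per stage. Unknown keys are rejected.
    """

    def __init__(self, raw: dict):
        unknown = set(raw) - _TOP_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        self.stages = list(raw.get("stages", STAGES[:-1]))
        for st in self.stages:
            if st not in STAGES:
                raise ValueError(f"unknown stage {st!r}")
        self.seed = int(raw.get("seed", 0))
        self.outdir = raw.get("outdir", "isletxmap_run")
        self.reference = raw.get("reference", "human")
        self.params: dict[str, dict] = {}
        sim_fields = {f.name for f in dataclasses.fields(synth.SimConfig)}
        for st in STAGES:
            block = dict(_STAGE_DEFAULTS[st])
            given = raw.get(st, {})
            allowed = sim_fields if st == "simulate" else set(block)
            bad = set(given) - allowed
            if bad:
                raise ValueError(f"unknown keys in stage {st!r}: {sorted(bad)}")
            block.update(given)
            self.params[st] = block

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _species_dirs(outdir: str, sub: str) -> dict[str, str]:
    base = os.path.join(outdir, sub)
    if not os.path.isdir(base):
        return {}
    return {
        d: os.path.join(base, d)
        for d in sorted(os.listdir(base))
        if os.path.isdir(os.path.join(base, d))
    }


def _load_matrices(outdir: str, sub: str) -> dict[str, core_data.CellMatrix]:
    return {
        s: iomod.read_cell_matrix(p) for s, p in _species_dirs(outdir, sub).items()
    }


def _stage_simulate(cfg: PipelineConfig, out: str) -> list[str]:
    block = dict(cfg.params["simulate"])
    block.setdefault("seed", cfg.stage_seed("simulate"))
    sim = synth.simulate_panel(synth.SimConfig(**block))
    written = []
    for s, m in sim.matrices.items():
        d = os.path.join(out, "raw", s)
        iomod.write_cell_matrix(m, d)
        written += [os.path.join(d, f) for f in os.listdir(d)]
    if sim.ortholog is not None:
        p = os.path.join(out, "orthologs.tsv")
        orthomap.write_ortholog_table(sim.ortholog, p)
        written.append(p)
    tdir = os.path.join(out, "truth")
    synth.write_ground_truth(sim.truth, tdir)
    written += [os.path.join(tdir, f) for f in os.listdir(tdir)]
    with open(os.path.join(out, "sim_config.json"), "w") as fh:
        json.dump(synth.config_to_json(sim.config), fh, indent=1, default=list)
    written.append(os.path.join(out, "sim_config.json"))
    return written


def _stage_preprocess(cfg: PipelineConfig, out: str) -> list[str]:
    p = cfg.params["preprocess"]
    qc = core_data.QCConfig(
        max_mito_fraction=p["max_mito_fraction"],
        min_counts=p["min_counts"],
        min_genes=p["min_genes"],
        min_cells_per_gene=p["min_cells_per_gene"],
        mito_gene_ids=frozenset(p["mito_gene_ids"]),
    )
    raw = _load_matrices(out, "raw")
    if not raw:
        raise FileNotFoundError("no raw matrices found; run simulate or stage inputs")
    processed = {}
    for s, m in raw.items():
        m = core_data.qc_filter(m, qc)
        m = core_data.normalize_log(m, max_fraction=p["max_fraction"])
        if p["batch_correct"] and m.cell_meta["batch"].nunique() > 1:
            m = core_data.batch_correct_zero_preserving(m, "batch")
        processed[s] = m

    written = []
    ortho_path = os.path.join(out, "orthologs.tsv")
    if len(processed) > 1 and os.path.exists(ortho_path):
        table = orthomap.read_ortholog_table(ortho_path)
        resolved = orthomap.resolve_orthologs(table, processed)
        rpath = os.path.join(out, "orthologs_resolved.tsv")
        orthomap.write_ortholog_table(resolved, rpath)
        written.append(rpath)
        ev = {}
        for s in processed:
            mapped = orthomap.apply_mapping(processed[s], resolved, cfg.reference)
            ev[s] = orthomap.explained_variance_fraction(
                processed[s], set(mapped.gene_meta.index)
            )
            processed[s] = mapped
        with open(os.path.join(out, "explained_variance.json"), "w") as fh:
            json.dump(ev, fh, indent=1)
        written.append(os.path.join(out, "explained_variance.json"))
    for s, m in processed.items():
        d = os.path.join(out, "processed", s)
        iomod.write_cell_matrix(m, d)
        written += [os.path.join(d, f) for f in os.listdir(d)]
    return written


def _common_profiles(cfg, out, group_key="cell_type"):
    mats = _load_matrices(out, "processed")
    profiles = {}
    for s, m in mats.items():
        prof = core_data.compute_group_profile(m, group_key)
        if "common_id" in m.gene_meta.columns:
            prof = prof.rename_genes(
                dict(zip(m.gene_meta.index, m.gene_meta["common_id"]))
            )
        profiles[s] = prof
    return mats, profiles


def _stage_markers(cfg: PipelineConfig, out: str) -> list[str]:
    p = cfg.params["markers"]
    _, profiles = _common_profiles(cfg, out)
    written = []
    for s, prof in profiles.items():
        mt = cons.find_enriched_markers(
            prof, frac_threshold=p["frac_threshold"], fc_threshold=p["fc_threshold"]
        )
        path = os.path.join(out, f"markers_{s}.tsv")
        mt.table.to_csv(path, sep="\t", index=False)
        ppath = os.path.join(out, f"profile_{s}.tsv")
        iomod.write_profile(prof, ppath)
        written += [path, ppath]
    return written


def _read_markers(out: str, species: str) -> cons.MarkerTable:
    t = pd.read_csv(os.path.join(out, f"markers_{species}.tsv"), sep="\t")
    return cons.MarkerTable(table=t)


def _stage_conserve(cfg: PipelineConfig, out: str) -> list[str]:
    p = cfg.params["conserve"]
    _, profiles = _common_profiles(cfg, out)
    ref = cfg.reference
    if ref not in profiles:
        raise ValueError(f"reference species {ref!r} not among processed matrices")
    ref_markers = _read_markers(out, ref)
    written = []
    calls = []
    for s, prof in profiles.items():
        if s == ref:
            continue
        expr = cons.classify_expression_conservation(
            profiles[ref], prof, expressed_threshold=p["expressed_threshold"]
        )
        expr["species"] = s
        expr["level"] = "expression"
        mark = cons.classify_marker_conservation(
            ref_markers,
            _read_markers(out, s),
            prof,
            expressed_threshold=p["expressed_threshold"],
        )
        mark["species"] = s
        mark["level"] = "marker"
        calls += [expr, mark]
    path = os.path.join(out, "conservation_calls.tsv")
    pd.concat(calls, ignore_index=True).to_csv(path, sep="\t", index=False)
    written.append(path)

    venn = cons.marker_overlap(
        {s: _read_markers(out, s) for s in profiles}
    )
    vpath = os.path.join(out, "marker_overlap.tsv")
    venn.to_csv(vpath, sep="\t", index=False)
    written.append(vpath)
    return written


def _stage_corr(cfg: PipelineConfig, out: str) -> list[str]:
    p = cfg.params["corr"]
    mats, profiles = _common_profiles(cfg, out)
    written = []
    species = sorted(profiles)
    shared = None
    for prof in profiles.values():
        shared = prof.genes if shared is None else shared.intersection(prof.genes)
    rows = []
    for i, a in enumerate(species):
        for b in species[i + 1 :]:
            ha = harmonic_profile(profiles[a], shared)
            hb = harmonic_profile(profiles[b], shared)
            rows.append(
                {
                    "species_a": a,
                    "species_b": b,
                    "harmonic_r": pattern_correlation(ha, hb),
                    "mean_r": pattern_correlation(profiles[a], profiles[b]),
                }
            )
    path = os.path.join(out, "pattern_correlations.tsv")
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    written.append(path)

    if len(mats) > 0:
        n_pcs = min(p["n_pcs"], min(m.n_cells for m in mats.values()) - 1)
        corr, order = pca_group_correlation(
            mats,
            n_pcs=n_pcs,
            drop_top=p["drop_top"],
            subsample_cap=p["subsample_cap"],
            seed=cfg.stage_seed("corr"),
        )
        cpath = os.path.join(out, "pca_group_correlation.tsv")
        corr.loc[order, order].to_csv(cpath, sep="\t")
        written.append(cpath)
    return written


def _reference_subset(cfg, out, cell_type):
    mats = _load_matrices(out, "processed")
    ref = mats[cfg.reference]
    mask = (ref.cell_meta["cell_type"] == cell_type).to_numpy()
    if mask.sum() == 0:
        raise ValueError(f"no {cell_type!r} cells in reference species")
    return mats, ref.subset(cells=mask)


def _stage_genesets(cfg: PipelineConfig, out: str) -> list[str]:
    p = cfg.params["genesets"]
    _, sub = _reference_subset(cfg, out, p["cell_type"])
    n_var = min(p["n_variable_genes"], sub.n_genes)
    genes = genesets.select_variable_genes(
        sub, n=n_var, min_cells=p["min_cells"]
    )
    coll = genesets.discover_gene_sets(
        sub, genes, n_clusters=p["n_clusters"], min_corr=p["min_corr"]
    )
    path = os.path.join(out, "gene_sets.gmt")
    iomod.write_gmt(coll, path)
    return [path]


def _stage_score(cfg: PipelineConfig, out: str) -> list[str]:
    p = cfg.params["score"]
    gp = cfg.params["genesets"]
    _, sub = _reference_subset(cfg, out, gp["cell_type"])
    coll = iomod.read_gmt(os.path.join(out, "gene_sets.gmt"))
    sub2 = sub.copy()
    if "common_id" in sub.gene_meta.columns:
        sub2.gene_meta = sub.gene_meta.set_index(
            pd.Index(sub.gene_meta["common_id"], name="native_id")
        )
    scores = genesets.score_gene_sets(
        sub2,
        coll,
        n_bins=p["n_bins"],
        background_size=p["background_size"],
        seed=cfg.stage_seed("score"),
    )
    path = os.path.join(out, "gene_set_scores.tsv")
    scores.rename_axis("cell_id").to_csv(path, sep="\t")
    return [path]


def _stage_map(cfg: PipelineConfig, out: str) -> list[str]:
    p = cfg.params["map"]
    gp = cfg.params["genesets"]
    mats, sub = _reference_subset(cfg, out, gp["cell_type"])
    coll = iomod.read_gmt(os.path.join(out, "gene_sets.gmt"))
    scores = pd.read_csv(
        os.path.join(out, "gene_set_scores.tsv"), sep="\t"
    ).set_index("cell_id")
    label_key = p["label_key"]
    if label_key not in sub.cell_meta.columns or sub.cell_meta[label_key].isna().all():
        label_key = "cell_type"
    labels = sub.cell_meta[label_key].astype(str).to_numpy()
    n_comp = min(p["n_components"], scores.shape[1])
    model = crossmap.fit_reference(
        scores, labels, n_components=n_comp, k=p["k"], gene_sets=coll
    )
    mdir = os.path.join(out, "reference_model")
    model.save(mdir)
    written = [os.path.join(mdir, f) for f in os.listdir(mdir)]

    results = []
    for s, m in mats.items():
        if s == cfg.reference:
            continue
        mask = (m.cell_meta["cell_type"] == gp["cell_type"]).to_numpy()
        if mask.sum() == 0:
            continue
        query = m.subset(cells=mask)
        res = crossmap.project_and_classify(
            model, query, seed=cfg.stage_seed("map")
        )
        res["species"] = s
        results.append(res.rename_axis("cell_id").reset_index())
    if results:
        allres = pd.concat(results, ignore_index=True)
        path = os.path.join(out, "mapped_cells.tsv")
        allres.to_csv(path, sep="\t", index=False)
        written.append(path)
        comp = crossmap.composition_summary(
            allres["label"], stratify_by=allres["species"]
        )
        cpath = os.path.join(out, "mapped_composition.tsv")
        comp.to_csv(cpath, sep="\t", index=False)
        written.append(cpath)
    return written


def _stage_report(cfg: PipelineConfig, out: str) -> list[str]:
    return []


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "markers": _stage_markers,
    "conserve": _stage_conserve,
    "corr": _stage_corr,
    "genesets": _stage_genesets,
    "score": _stage_score,
    "map": _stage_map,
    "report": _stage_report,
}


def run_pipeline(config: dict | PipelineConfig, outdir: str | None = None) -> dict:
    """Execute the configured stages in order and write a run report.

    Returns the report dict: per-stage status and timing, every output file
    with its SHA-256 checksum, and collected warnings. On stage failure the
    report names the failing stage, partial outputs are retained, and the
    exception propagates after the report is written.
    """
    cfg = config if isinstance(config, PipelineConfig) else PipelineConfig(config)
    out = outdir or cfg.outdir
    os.makedirs(out, exist_ok=True)
    report: dict = {"stages": [], "outputs": {}, "warnings": [], "seed": cfg.seed}
    failing = None
    try:
        for stage in cfg.stages:
            t0 = time.time()
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                files = _STAGE_FNS[stage](cfg, out)
            for w in caught:
                report["warnings"].append(f"{stage}: {w.message}")
            for f in sorted(files):
                rel = os.path.relpath(f, out)
                report["outputs"][rel] = _sha256(f)
            report["stages"].append(
                {"stage": stage, "seconds": round(time.time() - t0, 3), "ok": True}
            )
            print(f"[isletxmap] {stage}: ok ({time.time() - t0:.1f}s)", file=sys.stderr)
    except Exception as exc:  # noqa: BLE001 - report then re-raise
        failing = cfg.stages[len(report["stages"])]
        report["stages"].append({"stage": failing, "ok": False, "error": str(exc)})
        with open(os.path.join(out, "report.json"), "w") as fh:
            json.dump(report, fh, indent=1)
        raise
    with open(os.path.join(out, "report.json"), "w") as fh:
        json.dump(report, fh, indent=1)
    return report


def default_config(**overrides) -> dict:
    """A complete config dict with all stage defaults filled in."""
    cfg = {
        "stages": list(STAGES[:-1]),
        "seed": 0,
        "outdir": "isletxmap_run",
        "reference": "human",
    }
    cfg.update(overrides)
    return cfg
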