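"""Multi-species single-cell count simulator with planted ground truth.

The generator emulates the statistical structure a cross-species islet
pipeline consumes, so every stage can be validated against known truth:

* cell types with planted marker genes (a log2 fold-change effect on the
  type's cells), optionally sub-divided into states (e.g. mature /
  immature / stressed beta cells) with their own state-marker blocks;
* per-target-species conservation edits of each marker gene — ``conserved``
  keeps the effect in the matched type, ``loss`` removes the enrichment but
  keeps base expression, ``switch`` moves the effect to another type,
  ``absent`` reduces the gene to a trace level in that species (detected,
  but below the expressed-fraction threshold, mimicking the detection-limit
  behaviour of real cross-species data), and dedicated ``gain`` genes are
  at trace level in the reference but expressed and enriched in the target;
* rank-one correlated gene modules driven by one latent Gaussian factor
  per block, shared by all species;
* per-batch log-normal depth/composition shifts;
* negative-binomial counts at a 10x-like depth, optionally thinned by a
  logistic detection (dropout) model in the gene mean;
* an ortholog table with a planted fraction of ambiguous records whose
  correct resolution (the higher-expressed partner) is recorded.

All randomness flows from ``SimConfig.seed``; the same config yields
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core_data import CellMatrix
from .orthomap import OrthologTable

__all__ = ["SimConfig", "GroundTruth", "SimPanel", "simulate_panel"]

_CONS_CATEGORIES = ("conserved", "loss", "switch", "absent")


@dataclass
class SimConfig:
    """Study conditions for the synthetic multi-species islet panel.

    Defaults describe a three-species panel (human reference) with the four
    endocrine cell types, beta-like cell states dominated by a mature state
    (~60%), strong planted markers (log2FC = 2), expression-conservation
    proportions in the 50-60% conserved range with ~5% gains, two
    rank-one gene modules, two donors/batches per species and 10x-like
    sequencing depth. ``dropout_slope``/``dropout_midpoint`` parametrize a
    logistic detection probability in log1p(mean); the default is mild
    because at this depth most zeros already come from NB sampling.
    """

    species: tuple = ("human", "pig", "mouse")
    reference: str = "human"
    cell_types: dict = field(
        default_factory=lambda: {"alpha": 200, "beta": 200, "delta": 200, "pp": 200}
    )
    states: dict = field(
        default_factory=lambda: {
            "beta": {"mature": 0.6, "immature": 0.25, "stress": 0.15}
        }
    )
    n_genes: int = 2000
    n_markers_per_type: int = 50
    marker_log2fc: float = 2.0
    conservation_props: dict = field(
        default_factory=lambda: {
            "conserved": 0.55,
            "loss": 0.20,
            "switch": 0.10,
            "absent": 0.10,
            "gain": 0.05,
        }
    )
    n_state_markers: int = 30
    state_log2fc: float = 2.0
    modules: tuple = ((60, 0.8), (40, 0.8))
    nb_dispersion: float = 0.1
    dropout_slope: float = 2.0
    dropout_midpoint: float = -2.0
    batches_per_species: int = 2
    batch_lsd: float = 0.15
    depth: float = 5000.0
    ambiguous_fraction: float = 0.05
    base_log_mean: float = 0.0
    base_log_sd: float = 0.8
    residual_fraction: float = 0.01
    module_mean_scale: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reference not in self.species:
            raise ValueError("reference must be one of species")
        props = self.conservation_props
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise ValueError("conservation proportions must sum to 1")
        for st in self.states.values():
            if abs(sum(st.values()) - 1.0) > 1e-9:
                raise ValueError("state proportions must sum to 1")
        n_types = len(self.cell_types)
        n_state_blocks = sum(len(v) for v in self.states.values())
        n_gain = len(self.species[1:]) * n_types * self._n_gain_per_type()
        needed = (
            n_types * self.n_markers_per_type
            + n_state_blocks * self.n_state_markers
            + sum(m[0] for m in self.modules)
            + n_gain
        )
        if needed > self.n_genes:
            raise ValueError(
                f"infeasible spec: {needed} structured genes > n_genes={self.n_genes}"
            )
        if min(self.cell_types.values()) <= 0:
            raise ValueError("cell counts must be positive")

    def _n_gain_per_type(self) -> int:
        p = self.conservation_props.get("gain", 0.0)
        return int(round(p / max(1.0 - p, 1e-12) * self.n_markers_per_type))


@dataclass
class GroundTruth:
    """Planted structure: per-gene roles, per-cell labels, ortholog answers.

    ``genes`` is indexed by the species-neutral gene key and carries
    ``marker_of``, ``module``, ``state_marker_of`` plus one
    ``category_<species>`` column per non-reference species. ``cells``
    holds (cell_id, species, batch, cell_type, state). ``ortholog_kept``
    marks, per ortholog record, whether resolution should keep it.
    """

    genes: pd.DataFrame
    cells: pd.DataFrame
    ortholog_kept: pd.Series

    def markers_of(self, cell_type: str) -> list[str]:
        return list(self.genes.index[self.genes["marker_of"] == cell_type])

    def module_members(self, module_id: int) -> list[str]:
        return list(self.genes.index[self.genes["module"] == module_id])


@dataclass
class SimPanel:
    matrices: dict
    ortholog: OrthologTable | None
    truth: GroundTruth
    config: SimConfig

    def native_id(self, species: str, gene_key: str) -> str:
        return f"{species[:3].upper()}_{gene_key}"


def _gene_key(i: int) -> str:
    return f"G{i:05d}"


def _native(species: str, key: str) -> str:
    return f"{species[:3].upper()}_{key}"


def simulate_panel(cfg: SimConfig) -> SimPanel:
    """Draw a multi-species count panel with planted structure.

    Returns per-species :class:`CellMatrix` (counts only; run the
    preprocessing chain to obtain the lognorm layer), the ortholog table
    with planted ambiguities, and the ground truth.
    """
    rng = np.random.default_rng(cfg.seed)
    types = list(cfg.cell_types)
    species = list(cfg.species)
    targets = [s for s in species if s != cfg.reference]
    n_genes = cfg.n_genes
    keys = [_gene_key(i) for i in range(n_genes)]

    # ---- gene role allocation -------------------------------------------
    genes = pd.DataFrame(
        index=pd.Index(keys, name="gene"),
        data={
            "marker_of": pd.Series([None] * n_genes, index=keys, dtype=object),
            "state_marker_of": pd.Series([None] * n_genes, index=keys, dtype=object),
            "module": np.full(n_genes, -1, dtype=int),
        },
    )
    cursor = 0

    def take(n: int) -> list[int]:
        nonlocal cursor
        if cursor + n > n_genes:
            raise ValueError("infeasible spec: ran out of genes")
        out = list(range(cursor, cursor + n))
        cursor += n
        return out

    marker_idx = {ct: take(cfg.n_markers_per_type) for ct in types}
    for ct, idx in marker_idx.items():
        genes.iloc[idx, genes.columns.get_loc("marker_of")] = ct

    n_gain = cfg._n_gain_per_type()
    gain_idx = {
        (s, ct): take(n_gain) for s in targets for ct in types if n_gain > 0
    }

    state_idx = {}
    for ct, st_props in cfg.states.items():
        for st in st_props:
            idx = take(cfg.n_state_markers)
            state_idx[(ct, st)] = idx
            genes.iloc[idx, genes.columns.get_loc("state_marker_of")] = f"{ct}:{st}"

    for m, (size, _lsd) in enumerate(cfg.modules):
        idx = take(size)
        genes.iloc[idx, genes.columns.get_loc("module")] = m

    # ---- base means; structured genes drawn from a detectable range ------
    base = np.exp(rng.normal(cfg.base_log_mean, cfg.base_log_sd, size=n_genes))
    structured = np.zeros(n_genes, dtype=bool)
    for idx in marker_idx.values():
        structured[idx] = True
    for idx in gain_idx.values():
        structured[idx] = True
    for idx in state_idx.values():
        structured[idx] = True
    base[structured] = np.exp(
        rng.normal(np.log(2.0), 0.3, size=int(structured.sum()))
    )
    # module genes sit in a moderate-expression stratum so their shared
    # factor stays a small share of total counts (keeps the compositional
    # correlation induced by size-factor normalization negligible)
    in_module = (genes["module"] >= 0).to_numpy()
    base[in_module] *= cfg.module_mean_scale

    # ---- conservation category per marker gene and target species --------
    nong = {k: v for k, v in cfg.conservation_props.items() if k != "gain"}
    cat_names = list(nong)
    cat_p = np.array([nong[c] for c in cat_names])
    cat_p = cat_p / cat_p.sum()
    for s in targets:
        col = np.array([None] * n_genes, dtype=object)
        for ct, idx in marker_idx.items():
            draws = rng.choice(len(cat_names), size=len(idx), p=cat_p)
            col[idx] = [cat_names[d] for d in draws]
        for (gs, ct), idx in gain_idx.items():
            if gs == s:
                col[idx] = "gain"
        genes[f"category_{s}"] = col

    # ---- per (species, type) linear mean profiles ------------------------
    fc = 2.0**cfg.marker_log2fc
    sfc = 2.0**cfg.state_log2fc

    def type_after(ct: str) -> str:
        return types[(types.index(ct) + 1) % len(types)]

    profiles = {}  # (species, cell_type) -> mean vector (pre-state, pre-batch)
    for s in species:
        for ct in types:
            mu = base.copy()
            for mct, idx in marker_idx.items():
                idx = np.asarray(idx, dtype=int)
                if s == cfg.reference:
                    if mct == ct:
                        mu[idx] *= fc
                else:
                    cats = genes[f"category_{s}"].to_numpy()[idx]
                    is_cons = cats == "conserved"
                    is_switch = cats == "switch"
                    is_absent = cats == "absent"
                    if mct == ct:
                        mu[idx[is_cons]] *= fc
                    if mct != ct and type_after(mct) == ct:
                        mu[idx[is_switch]] *= fc
                    # trace level: detected overall, below the expressed gate
                    mu[idx[is_absent]] = base[idx[is_absent]] * cfg.residual_fraction
            for (gs, gct), idx in gain_idx.items():
                idx = np.asarray(idx, dtype=int)
                if s == cfg.reference or gs != s:
                    mu[idx] = base[idx] * cfg.residual_fraction
                elif gct == ct:
                    mu[idx] *= fc
            profiles[(s, ct)] = mu

    # ---- cells, states, batches ------------------------------------------
    module_lsd = [m[1] for m in cfg.modules]
    module_genes = [
        np.flatnonzero((genes["module"] == m).to_numpy())
        for m in range(len(cfg.modules))
    ]

    matrices = {}
    cell_rows = []
    mean_expr_by_species = {}
    for s in species:
        batch_shift = np.exp(
            rng.normal(0.0, cfg.batch_lsd, size=(cfg.batches_per_species, n_genes))
        )
        rows_mu = []
        meta = []
        for ct in types:
            n_cells = cfg.cell_types[ct]
            st_props = cfg.states.get(ct)
            if st_props:
                st_names = list(st_props)
                st_draw = rng.choice(
                    len(st_names), size=n_cells, p=np.array(list(st_props.values()))
                )
                states = [st_names[d] for d in st_draw]
            else:
                states = [""] * n_cells
            batches = rng.integers(0, cfg.batches_per_species, size=n_cells)
            mu_ct = np.tile(profiles[(s, ct)], (n_cells, 1))
            for (sct, st), idx in state_idx.items():
                if sct != ct:
                    continue
                in_state = np.asarray([x == st for x in states])
                mu_ct[np.ix_(in_state, np.asarray(idx, dtype=int))] *= sfc
            # rank-one module factors, shared loading within block
            for m_id, idx in enumerate(module_genes):
                z = rng.normal(0.0, 1.0, size=n_cells)
                lsd = module_lsd[m_id]
                mu_ct[:, idx] *= np.exp(lsd * z - 0.5 * lsd**2)[:, None]
            mu_ct *= batch_shift[batches]
            rows_mu.append(mu_ct)
            meta.append(
                pd.DataFrame(
                    {
                        "species": s,
                        "batch": [f"{s}_b{b}" for b in batches],
                        "cell_type": ct,
                        "state": states,
                    }
                )
            )
        MU = np.vstack(rows_mu)
        meta = pd.concat(meta, ignore_index=True)
        meta.index = pd.Index(
            [f"{s}_c{i:05d}" for i in range(len(meta))], name="cell_id"
        )

        # scale to expected depth, NB draw, logistic detection thinning
        row_sums = MU.sum(axis=1, keepdims=True)
        expected = MU / row_sums * cfg.depth
        r = 1.0 / cfg.nb_dispersion
        p = r / (r + expected)
        counts = rng.negative_binomial(r, np.clip(p, 1e-12, 1.0))
        with np.errstate(over="ignore"):
            detect = 1.0 / (
                1.0
                + np.exp(
                    -cfg.dropout_slope * (np.log1p(expected) - cfg.dropout_midpoint)
                )
            )
        counts = counts * (rng.random(counts.shape) < detect)

        # species-specific duplicate (paralog-like) genes are appended later
        gene_meta = pd.DataFrame(
            index=pd.Index([_native(s, k) for k in keys], name="native_id")
        )
        gene_meta["gene_key"] = keys
        matrices[s] = CellMatrix(
            counts=sp.csr_matrix(counts),
            cell_meta=meta,
            gene_meta=gene_meta,
        )
        cell_rows.append(meta.reset_index())
        mean_expr_by_species[s] = expected.mean(axis=0)

    # ---- ortholog table with planted ambiguities --------------------------
    if len(species) < 2:
        truth = GroundTruth(
            genes=genes,
            cells=pd.concat(cell_rows, ignore_index=True),
            ortholog_kept=pd.Series(dtype=bool),
        )
        return SimPanel(matrices=matrices, ortholog=None, truth=truth, config=cfg)

    records = pd.DataFrame(
        {s: [_native(s, k) for k in keys] for s in species}
    )
    n_amb = int(round(cfg.ambiguous_fraction * n_genes))
    amb_pos = sorted(
        rng.choice(n_genes, size=min(n_amb, n_genes), replace=False).tolist()
    )
    anchor = "pig" if "pig" in species else species[1]
    dup_targets = [s for s in species if s != anchor]
    extra_records = []
    dup_genes = {s: [] for s in species}
    for j, gi in enumerate(amb_pos):
        dup_sp = dup_targets[j % len(dup_targets)]
        key = keys[gi]
        dup_id = _native(dup_sp, key) + "D"
        dup_genes[dup_sp].append((dup_id, gi))
        rec = {s: _native(s, key) for s in species}
        rec[dup_sp] = dup_id
        extra_records.append(rec)
    records["_kept_truth"] = True
    extra = pd.DataFrame(extra_records)
    extra["_kept_truth"] = False
    records = pd.concat([records, extra], ignore_index=True)

    # append low-expressed duplicate genes to their species' matrices so the
    # planted argmax (the original gene) is the higher-expressed partner
    for s, dups in dup_genes.items():
        if not dups:
            continue
        m = matrices[s]
        dup_cols = []
        for dup_id, gi in dups:
            expected = np.maximum(mean_expr_by_species[s][gi] * 0.1, 1e-3)
            r = 1.0 / cfg.nb_dispersion
            p = r / (r + expected)
            dup_cols.append(rng.negative_binomial(r, p, size=m.n_cells))
        dup_block = sp.csr_matrix(np.column_stack(dup_cols))
        new_meta = pd.DataFrame(
            index=pd.Index([d for d, _ in dups], name="native_id")
        )
        new_meta["gene_key"] = [keys[gi] + "D" for _, gi in dups]
        matrices[s] = CellMatrix(
            counts=sp.hstack([m.counts, dup_block], format="csr"),
            cell_meta=m.cell_meta,
            gene_meta=pd.concat([m.gene_meta, new_meta]),
        )

    kept_truth = records.pop("_kept_truth")
    ortho = OrthologTable(records=records, resolved=False)

    truth = GroundTruth(
        genes=genes,
        cells=pd.concat(cell_rows, ignore_index=True),
        ortholog_kept=kept_truth,
    )
    return SimPanel(matrices=matrices, ortholog=ortho, truth=truth, config=cfg)


def write_ground_truth(truth: GroundTruth, outdir: str) -> None:
    import os

    os.makedirs(outdir, exist_ok=True)
    truth.genes.to_csv(os.path.join(outdir, "truth_genes.tsv"), sep="\t")
    truth.cells.to_csv(
        os.path.join(outdir, "truth_cells.tsv"), sep="\t", index=False
    )
    truth.ortholog_kept.to_frame("kept_truth").to_csv(
        os.path.join(outdir, "truth_ortholog.tsv"), sep="\t", index=False
    )


def config_to_json(cfg: SimConfig) -> dict:
    return asdict(cfg)
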