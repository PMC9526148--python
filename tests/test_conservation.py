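"""Marker detection, conservation rule tables, Venn overlaps."""

import numpy as np
import pandas as pd
import pytest

import oracles
from conftest import make_profile
from isletxmap import (
    classify_expression_conservation,
    classify_marker_conservation,
    find_enriched_markers,
    marker_overlap,
)


class TestFindEnrichedMarkers:
    def test_hand_computed_fold_change(self):
        prof = make_profile(
            mean=[[3.0], [0.5]], frac=[[0.6], [0.5]], n_cells=[10, 10]
        )
        mt = find_enriched_markers(prof)
        row = mt.table.set_index("cell_type").loc["t0"]
        assert row["log2fc"] == pytest.approx(np.log2(3.0 / 0.5), abs=1e-6)
        assert bool(row["is_enriched"])

    def test_weighted_rest_mean(self):
        # rest mean must weight groups by cell count, not average them
        prof = make_profile(
            mean=[[2.0], [1.0], [0.0]],
            frac=[[0.9], [0.9], [0.0]],
            n_cells=[10, 30, 10],
        )
        mt = find_enriched_markers(prof)
        row = mt.table.set_index("cell_type").loc["t0"]
        rest = (1.0 * 30 + 0.0 * 10) / 40
        assert row["log2fc"] == pytest.approx(np.log2(2.0 / rest), abs=1e-6)

    def test_identical_means_not_enriched(self):
        prof = make_profile(
            mean=[[1.0], [1.0]], frac=[[0.9], [0.9]], n_cells=[5, 5]
        )
        mt = find_enriched_markers(prof)
        assert not mt.table["is_enriched"].any()
        assert np.allclose(mt.table["log2fc"], 0.0)

    def test_fraction_gate_blocks_low_penetrance(self):
        prof = make_profile(
            mean=[[5.0], [0.01]], frac=[[0.04], [0.5]], n_cells=[100, 100]
        )
        mt = find_enriched_markers(prof)
        assert not mt.table.set_index("cell_type").loc["t0", "is_enriched"]

    def test_single_group_errors(self):
        prof = make_profile(mean=[[1.0]], frac=[[0.5]], n_cells=[5])
        with pytest.raises(ValueError, match="2 groups"):
            find_enriched_markers(prof)


class TestExpressionConservation:
    def _call(self, ref_frac, tgt_frac):
        types = sorted(ref_frac)
        genes = sorted(next(iter(ref_frac.values())))
        ref = make_profile(
            mean=[[1.0] * len(genes)] * len(types),
            frac=[[ref_frac[t][g] for g in genes] for t in types],
            n_cells=[10] * len(types),
            groups=types,
            genes=genes,
        )
        tgt = make_profile(
            mean=[[1.0] * len(genes)] * len(types),
            frac=[[tgt_frac[t][g] for g in genes] for t in types],
            n_cells=[10] * len(types),
            groups=types,
            genes=genes,
        )
        return classify_expression_conservation(ref, tgt)

    def test_rule_table_cases(self):
        ref = {"alpha": {"x": 0.0}, "beta": {"x": 0.5}}
        for tgt, expected in [
            ({"alpha": {"x": 0.0}, "beta": {"x": 0.3}}, "conserved"),
            ({"alpha": {"x": 0.4}, "beta": {"x": 0.01}}, "loss"),
            ({"alpha": {"x": 0.0}, "beta": {"x": 0.0}}, "absent"),
        ]:
            out = self._call(ref, tgt).set_index(["gene", "cell_type"])
            assert out.loc[("x", "beta"), "category"] == expected

    def test_gain_definition(self):
        ref = {"alpha": {"x": 0.0}, "beta": {"x": 0.0}}
        tgt = {"alpha": {"x": 0.0}, "beta": {"x": 0.4}}
        out = self._call(ref, tgt).set_index(["gene", "cell_type"])
        assert out.loc[("x", "beta"), "category"] == "gain"
        assert ("x", "alpha") not in out.index

    def test_no_shared_genes_errors(self):
        ref = make_profile([[1.0]], [[0.5]], [5], genes=["a"])
        tgt = make_profile([[1.0]], [[0.5]], [5], genes=["b"])
        with pytest.raises(ValueError, match="no shared genes"):
            classify_expression_conservation(ref, tgt)


class TestMarkerConservation:
    def _toy(self):
        # one gene per outcome: conserved / switch / loss / absent
        genes = ["gc", "gs", "gl", "ga"]
        ref = make_profile(
            mean=[[3.0, 3.0, 3.0, 3.0], [0.1, 0.1, 0.1, 0.1]],
            frac=[[0.9, 0.9, 0.9, 0.9], [0.1, 0.1, 0.1, 0.1]],
            n_cells=[10, 10],
            groups=["beta", "alpha"],
            genes=genes,
        )
        tgt = make_profile(
            mean=[[3.0, 0.1, 1.0, 0.0], [0.1, 3.0, 1.0, 0.0]],
            frac=[[0.9, 0.02, 0.5, 0.0], [0.1, 0.9, 0.5, 0.0]],
            n_cells=[10, 10],
            groups=["beta", "alpha"],
            genes=genes,
        )
        return ref, tgt

    def test_four_outcome_toy(self):
        ref, tgt = self._toy()
        ref_mk = find_enriched_markers(ref)
        tgt_mk = find_enriched_markers(tgt)
        calls = classify_marker_conservation(ref_mk, tgt_mk, tgt).set_index("gene")
        beta_calls = calls[calls["cell_type"] == "beta"]["category"]
        assert beta_calls.loc["gc"] == "conserved"
        assert beta_calls.loc["gs"] == "switch"
        assert beta_calls.loc["gl"] == "loss"
        assert beta_calls.loc["ga"] == "absent"

    def test_empty_reference_markers(self):
        ref = make_profile(
            [[1.0], [1.0]], [[0.5], [0.5]], [5, 5], groups=["a", "b"]
        )
        mk = find_enriched_markers(ref)
        out = classify_marker_conservation(mk, mk, ref)
        assert out.empty

    def test_same_type_match_takes_precedence(self):
        ref, tgt = self._toy()
        ref_mk = find_enriched_markers(ref)
        # enrich gc for both target types; same-type match must win
        t = find_enriched_markers(tgt).table
        t.loc[(t["gene"] == "gc"), "is_enriched"] = True
        from isletxmap import MarkerTable

        calls = classify_marker_conservation(ref_mk, MarkerTable(table=t), tgt)
        got = calls.set_index(["gene", "cell_type"]).loc[("gc", "beta"), "category"]
        assert got == "conserved"

    def test_matches_enumeration_oracle(self, small_panel, small_processed):
        from isletxmap import compute_group_profile

        profs = {
            s: compute_group_profile(m, "cell_type")
            for s, m in small_processed.items()
        }
        # move to a shared namespace via the gene_key annotation
        profs = {
            s: p.rename_genes(
                dict(
                    zip(
                        small_processed[s].gene_meta.index,
                        small_processed[s].gene_meta["gene_key"],
                    )
                )
            )
            for s, p in profs.items()
        }
        shared = profs["human"].genes.intersection(profs["pig"].genes)
        profs = {s: p.subset_genes(shared) for s, p in profs.items()}
        mk = {s: find_enriched_markers(p) for s, p in profs.items()}

        calls = classify_marker_conservation(
            mk["human"], mk["pig"], profs["pig"]
        )
        ref_enr = {
            ct: mk["human"].enriched_genes(ct) for ct in mk["human"].cell_types
        }
        tgt_enr = {
            ct: mk["pig"].enriched_genes(ct) for ct in mk["pig"].cell_types
        }
        tgt_frac = {
            ct: profs["pig"].frac_expr.loc[ct].to_dict()
            for ct in profs["pig"].groups
        }
        expect = oracles.marker_conservation(ref_enr, tgt_enr, tgt_frac)
        got = {
            (r.gene, r.cell_type): r.category for r in calls.itertuples()
        }
        assert got == expect


class TestMarkerOverlap:
    def _tables(self, sets_by_species):
        from isletxmap import MarkerTable

        out = {}
        for sp, genes in sets_by_species.items():
            rows = pd.DataFrame(
                {
                    "cell_type": "beta",
                    "gene": sorted(genes),
                    "log2fc": 1.0,
                    "frac_in_type": 0.5,
                    "is_enriched": True,
                }
            )
            out[sp] = MarkerTable(table=rows)
        return out

    def test_set_algebra_example(self):
        tables = self._tables(
            {"human": {"a", "b", "c"}, "pig": {"b", "c"}, "mouse": {"c"}}
        )
        out = marker_overlap(tables).set_index("region")["count"]
        assert out.loc["human&mouse&pig"] == 1  # c
        assert out.loc["human&pig"] == 1  # b
        assert out.loc["human"] == 1  # a
        assert out.loc["mouse"] == 0

    def test_identical_sets_all_in_triple_intersection(self):
        tables = self._tables(
            {"human": {"a", "b"}, "pig": {"a", "b"}, "mouse": {"a", "b"}}
        )
        out = marker_overlap(tables).set_index("region")["count"]
        assert out.loc["human&mouse&pig"] == 2
        assert out.drop("human&mouse&pig").sum() == 0

    def test_disjoint_sets_only_exclusive_regions(self):
        tables = self._tables({"human": {"a"}, "pig": {"b"}})
        out = marker_overlap(tables).set_index("region")["count"]
        assert out.loc["human"] == 1 and out.loc["pig"] == 1
        assert out.loc["human&pig"] == 0

    def test_regions_partition_each_species_set(self):
        tables = self._tables(
            {"human": {"a", "b", "c", "d"}, "pig": {"c", "d"}, "mouse": {"d", "e"}}
        )
        out = marker_overlap(tables).set_index("region")["count"]
        human_total = sum(
            out.loc[r] for r in out.index if "human" in r.split("&")
        )
        assert human_total == 4
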