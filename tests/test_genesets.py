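"""Variable genes, correlation-based set discovery, scoring, Welch ranking."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_matrix
from isletxmap import (
    GeneSet,
    GeneSetCollection,
    discover_gene_sets,
    rank_genes_welch,
    score_gene_sets,
    select_variable_genes,
)


class TestSelectVariableGenes:
    def test_requesting_all_eligible_returns_all(self):
        rng = np.random.default_rng(0)
        X = rng.poisson(2.0, size=(30, 10)).astype(float)
        X[:, 0] += 1  # ensure every gene expressed everywhere
        m = make_matrix(X.astype(int), lognorm=X)
        got = select_variable_genes(m, n=10, min_cells=1)
        assert sorted(got) == [f"g{j}" for j in range(10)]

    def test_high_dispersion_gene_ranks_first(self):
        rng = np.random.default_rng(1)
        n = 200
        X = np.abs(rng.normal(2.0, 0.3, size=(n, 12)))
        X[:, 5] = np.abs(rng.normal(2.0, 3.0, size=n))  # 10x the variance
        m = make_matrix(np.ceil(X).astype(int), lognorm=X)
        got = select_variable_genes(m, n=3, min_cells=1, n_bins=1)
        assert got[0] == "g5"

    def test_constant_gene_never_selected(self):
        rng = np.random.default_rng(2)
        X = np.abs(rng.normal(2.0, 1.0, size=(50, 6)))
        X[:, 2] = 2.0
        m = make_matrix(np.ceil(X).astype(int), lognorm=X)
        got = select_variable_genes(m, n=5, min_cells=1, n_bins=1)
        assert "g2" not in got

    def test_too_few_eligible_errors_with_counts(self):
        X = np.ones((5, 4))
        m = make_matrix(X.astype(int), lognorm=X)
        with pytest.raises(ValueError, match="4 of 4"):
            select_variable_genes(m, n=10, min_cells=1)

    def test_planted_structure_dominates_top_list(self, small_panel, small_processed):
        m = small_processed["human"]
        got = select_variable_genes(m, n=150, min_cells=20)
        truth = small_panel.truth.genes
        structured = {
            "HUM_" + g
            for g in truth.index[
                truth["marker_of"].notna()
                | truth["state_marker_of"].notna()
                | (truth["module"] >= 0)
            ]
        }
        frac = len(set(got) & structured) / len(got)
        assert frac >= 0.6


class TestDiscoverGeneSets:
    def _block_matrix(self, seed=0, n=400):
        rng = np.random.default_rng(seed)
        z1, z2 = rng.normal(size=n), rng.normal(size=n)
        cols = {}
        for j in range(6):
            cols[f"a{j}"] = 2 + z1 + rng.normal(scale=0.4, size=n)
        for j in range(5):
            cols[f"b{j}"] = 2 + z2 + rng.normal(scale=0.4, size=n)
        for j in range(8):
            cols[f"n{j}"] = 2 + rng.normal(size=n)
        X = np.abs(np.column_stack(list(cols.values())))
        return make_matrix(np.ceil(X).astype(int), lognorm=X,
                           gene_ids=list(cols)), list(cols)

    def test_planted_blocks_recovered_and_noise_dropped(self):
        m, genes = self._block_matrix()
        coll = discover_gene_sets(m, genes, n_clusters=3, min_corr=0.05)
        members = {s.name: set(s.genes) for s in coll.sets}
        sets = sorted(members.values(), key=lambda s: sorted(s)[0])
        assert sets[0] == {f"a{j}" for j in range(6)}
        assert sets[1] == {f"b{j}" for j in range(5)}

    def test_singletons_dropped_by_convention(self):
        m, genes = self._block_matrix(n=50)
        coll = discover_gene_sets(m, genes, n_clusters=len(genes), min_corr=0.005)
        assert len(coll) == 0

    def test_duplicate_columns_co_cluster(self):
        rng = np.random.default_rng(3)
        base = np.abs(rng.normal(2, 1, size=(100, 4)))
        X = np.column_stack([base, base[:, 0]])
        ids = ["g0", "g1", "g2", "g3", "g0dup"]
        m = make_matrix(np.ceil(X).astype(int), lognorm=X, gene_ids=ids)
        coll = discover_gene_sets(m, ids, n_clusters=4, min_corr=-1.0)
        member = coll.membership()
        assert member["g0"] == member["g0dup"]

    def test_constant_gene_errors(self):
        X = np.abs(np.random.default_rng(4).normal(2, 1, size=(30, 3)))
        X[:, 1] = 1.0
        m = make_matrix(np.ceil(X).astype(int), lognorm=X)
        with pytest.raises(ValueError, match="constant gene"):
            discover_gene_sets(m, ["g0", "g1", "g2"], n_clusters=2)

    def test_gene_order_invariance(self):
        m, genes = self._block_matrix(seed=5)
        a = discover_gene_sets(m, genes, n_clusters=3, min_corr=0.05)
        b = discover_gene_sets(m, genes[::-1], n_clusters=3, min_corr=0.05)
        assert {frozenset(s.genes) for s in a.sets} == {
            frozenset(s.genes) for s in b.sets
        }


class TestScoreGeneSets:
    def test_whole_pool_fallback_matches_hand_arithmetic(self):
        # one cell: target gene at 2.0, other three genes mean 0.5
        X = np.array([[2.0, 0.5, 0.5, 0.5]])
        m = make_matrix(np.ceil(X).astype(int), lognorm=X)
        coll = GeneSetCollection(sets=[GeneSet("S", ["g0"])])
        s = score_gene_sets(m, coll, n_bins=1, background_size=50, seed=0)
        assert s.loc["c0", "S"] == pytest.approx(2.0 - 0.5, abs=1e-12)

    def test_all_zero_set_and_pool_scores_zero(self):
        X = np.zeros((3, 4))
        X[:, 3] = 1.0  # keep the matrix non-degenerate
        m = make_matrix(X.astype(int), lognorm=X)
        coll = GeneSetCollection(sets=[GeneSet("S", ["g0"])])
        s = score_gene_sets(m, coll, n_bins=2, background_size=2, seed=0)
        assert np.allclose(s["S"], 0.0)

    def test_bit_reproducible_given_seed(self, small_processed):
        m = small_processed["human"]
        genes = list(m.gene_meta.index[:40])
        coll = GeneSetCollection(sets=[GeneSet("S", genes[:8])])
        s1 = score_gene_sets(m, coll, seed=11)
        s2 = score_gene_sets(m, coll, seed=11)
        assert (s1.to_numpy() == s2.to_numpy()).all()

    def test_constant_shift_cancels(self, small_processed):
        m = small_processed["human"].subset(cells=np.arange(100))
        genes = list(m.gene_meta.index)
        coll = GeneSetCollection(sets=[GeneSet("S", genes[:10])])
        s1 = score_gene_sets(m, coll, seed=5)
        shifted = m.copy()
        dense = shifted.lognorm.toarray() + 1.7
        import scipy.sparse as sp

        shifted.lognorm = sp.csr_matrix(dense)
        s2 = score_gene_sets(shifted, coll, seed=5)
        assert np.allclose(s1.to_numpy(), s2.to_numpy(), atol=1e-9)

    def test_null_set_from_own_pool_scores_near_zero(self):
        rng = np.random.default_rng(7)
        n, g = 400, 300
        X = np.abs(2.0 + rng.normal(0, 0.5, size=(n, g)))
        m = make_matrix(np.ceil(X).astype(int), lognorm=X)
        ids = list(m.gene_meta.index)
        members = sorted(rng.choice(ids, size=50, replace=False))
        coll = GeneSetCollection(sets=[GeneSet("null", members)])
        s = score_gene_sets(m, coll, n_bins=1, background_size=250, seed=13)
        assert abs(s["null"].mean()) <= 0.05

    def test_missing_member_errors(self):
        X = np.ones((2, 2))
        m = make_matrix(X.astype(int), lognorm=X)
        coll = GeneSetCollection(sets=[GeneSet("S", ["nope"])])
        with pytest.raises(KeyError, match="nope"):
            score_gene_sets(m, coll)


class TestRankGenesWelch:
    def _two_groups(self, X_a, X_b, gene_ids=None):
        X = np.vstack([X_a, X_b])
        return make_matrix(
            np.ceil(X).astype(int),
            lognorm=X,
            cell_types=["A"] * len(X_a) + ["B"] * len(X_b),
            gene_ids=gene_ids,
        )

    def test_identical_groups_all_zero_lexicographic(self):
        block = np.tile([[1.0, 2.0, 3.0]], (4, 1))
        m = self._two_groups(block, block)
        out = rank_genes_welch(m, "cell_type", "A", "B", top_n=3)
        assert np.allclose(out["t"], 0.0)
        assert list(out["gene"]) == ["g0", "g1", "g2"]

    def test_variance_floor_engages_on_constant_shift(self):
        a = np.column_stack([np.full(4, 2.0), np.random.default_rng(0).uniform(1, 2, 4)])
        b = np.column_stack([np.zeros(4), np.random.default_rng(1).uniform(1, 2, 4)])
        m = self._two_groups(a, b)
        out = rank_genes_welch(m, "cell_type", "A", "B", top_n=2)
        assert out.iloc[0]["gene"] == "g0"
        assert out.iloc[0]["t"] > 1e3

    def test_planted_shift_genes_reach_top_50(self):
        rng = np.random.default_rng(21)
        n, g = 50, 200
        base_a = np.abs(rng.normal(2, 1, size=(n, g)))
        base_b = np.abs(rng.normal(2, 1, size=(n, g)))
        shift = [f"g{j}" for j in range(5)]
        base_a[:, :5] += 2.0
        m = self._two_groups(base_a, base_b)
        out = rank_genes_welch(m, "cell_type", "A", "B", top_n=50)
        assert set(shift) <= set(out["gene"])

    def test_antisymmetric_in_group_order(self):
        rng = np.random.default_rng(22)
        m = self._two_groups(
            np.abs(rng.normal(2, 1, size=(10, 6))),
            np.abs(rng.normal(2, 1, size=(10, 6))),
        )
        ab = rank_genes_welch(m, "cell_type", "A", "B", top_n=6).set_index("gene")
        ba = rank_genes_welch(m, "cell_type", "B", "A", top_n=6).set_index("gene")
        assert np.allclose(ab["t"], -ba.loc[ab.index, "t"])

    def test_small_group_errors(self):
        m = self._two_groups(np.ones((1, 3)), np.ones((4, 3)))
        with pytest.raises(ValueError, match="fewer than 2"):
            rank_genes_welch(m, "cell_type", "A", "B")
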