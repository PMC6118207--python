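"""Sequence simulation: topologies, substitution process, missing data."""

import dendropy
import numpy as np
import pytest

from tigerpart.simulate import (
    CONDITION_IDS,
    BlockModel,
    build_tree,
    get_condition,
    gtr_rate_matrix,
    inject_missing,
    simulate_block,
    simulate_condition,
)


class TestBuildTree:
    @pytest.mark.parametrize("shape", ["asymmetric", "symmetric"])
    def test_seventeen_leaves_fourteen_internal_edges(self, shape):
        tree = build_tree(shape, internal_bl=0.01)
        leaves = [lf for lf in tree.leaf_node_iter()]
        assert len(leaves) == 17
        labels = {lf.taxon.label for lf in leaves}
        assert labels == {"outgroup"} | set("ABCDEFGHIJKLMNOP")
        internal = [
            e for e in tree.preorder_edge_iter()
            if e.tail_node is not None and not e.head_node.is_leaf()
        ]
        assert len(internal) == 14
        assert all(e.length == 0.01 for e in internal)
        terminal = [
            e for e in tree.preorder_edge_iter()
            if e.tail_node is not None and e.head_node.is_leaf()
        ]
        assert all(e.length == 0.1 for e in terminal)

    def test_newick_round_trip(self):
        tree = build_tree("symmetric", internal_bl=0.005, terminal_bl=0.1)
        back = dendropy.Tree.get(
            data=tree.as_string(schema="newick"), schema="newick"
        )
        from tigerpart.treecompare import robinson_foulds

        assert robinson_foulds(tree.as_string(schema="newick"),
                               back.as_string(schema="newick")).raw == 0

    def test_unknown_shape(self):
        with pytest.raises(ValueError):
            build_tree("ladder", internal_bl=0.01)


class TestConditionTable:
    def test_all_fourteen_conditions_build(self):
        assert len(CONDITION_IDS) == 14
        for cid in CONDITION_IDS:
            cond = get_condition(cid, "asymmetric")
            assert len(cond.blocks) == 4
            assert cond.terminal_branch_length == 0.1

    def test_odd_conditions_have_no_invariant_sites(self):
        for cid in ("S1", "S5", "S9"):
            cond = get_condition(cid, "symmetric")
            assert all(b.p_inv == 0.0 for b in cond.blocks)

    def test_even_conditions_have_graded_p_inv(self):
        cond = get_condition("S2", "asymmetric")
        assert [b.p_inv for b in cond.blocks] == [0.80, 0.60, 0.40, 0.20]

    def test_s9_block1_gtr_rates(self):
        cond = get_condition("S9", "asymmetric")
        assert cond.blocks[0].exchangeabilities == (0.01, 0.01, 0.001, 0.01,
                                                    0.001)
        assert cond.blocks[0].internal_branch_length == 0.005

    def test_s13_varies_internal_length_per_block(self):
        cond = get_condition("S13", "asymmetric")
        assert [b.internal_branch_length for b in cond.blocks] == [
            0.005, 0.01, 0.015, 0.02,
        ]


class TestRateMatrix:
    def test_stationarity_and_normalisation(self):
        pi = np.array([0.4, 0.1, 0.4, 0.1])
        q = gtr_rate_matrix(pi, (0.8, 0.5, 0.5, 0.2, 0.2))
        assert np.allclose(q.sum(axis=1), 0.0)
        assert np.allclose(pi @ q, 0.0)  # stationary
        assert np.isclose(-(pi @ np.diag(q)), 1.0)  # mean rate 1
        # detailed balance (reversibility)
        flux = pi[:, None] * q
        assert np.allclose(flux, flux.T)

    def test_expected_substitutions_match_f81_closed_form(self):
        # on a branch of length t, P(different) = (1-sum pi^2)(1-e^(-t/(1-sum pi^2)))
        pi = np.array([0.3, 0.2, 0.3, 0.2])
        tree = dendropy.Tree.get(data="(a:0.25,b:0.0);", schema="newick")
        model = BlockModel(base_freqs=tuple(pi), alpha=None)
        aln = simulate_block(tree, model, n_sites=40000, seed=5)
        a = np.array(list(aln.sequence("a")))
        b = np.array(list(aln.sequence("b")))
        p_diff = (a != b).mean()
        beta = 1.0 - float(pi @ pi)
        expected = beta * (1.0 - np.exp(-0.25 / beta))
        se = np.sqrt(expected * (1 - expected) / 40000)
        assert abs(p_diff - expected) < 3.5 * se


class TestSimulateBlock:
    def test_zero_length_tree_copies_root_state(self):
        tree = build_tree("asymmetric", internal_bl=0.0, terminal_bl=0.0)
        model = BlockModel(base_freqs=(0.25, 0.25, 0.25, 0.25), alpha=0.5)
        aln = simulate_block(tree, model, n_sites=50, seed=1)
        seqs = {aln.sequence(t) for t in aln.taxa}
        assert len(seqs) == 1

    def test_deterministic_given_seed(self):
        tree = build_tree("symmetric", internal_bl=0.01)
        model = BlockModel(base_freqs=(0.4, 0.1, 0.4, 0.1), alpha=0.5)
        a1 = simulate_block(tree, model, n_sites=100, seed=9)
        a2 = simulate_block(tree, model, n_sites=100, seed=9)
        assert np.array_equal(a1.matrix, a2.matrix)

    def test_p_inv_one_like_all_invariant(self):
        tree = build_tree("asymmetric", internal_bl=0.05)
        model = BlockModel(base_freqs=(0.25,) * 4, p_inv=0.999999, alpha=0.5)
        aln = simulate_block(tree, model, n_sites=200, seed=3)
        assert all(
            len(set(aln.matrix[:, s])) == 1 for s in range(aln.n_sites)
        )

    def test_long_branch_reaches_stationary_frequencies(self):
        pi = np.array([0.4, 0.1, 0.4, 0.1])
        tree = dendropy.Tree.get(data="(a:10.0,b:0.0);", schema="newick")
        model = BlockModel(base_freqs=tuple(pi), alpha=None)
        aln = simulate_block(tree, model, n_sites=10000, seed=11)
        seq = aln.sequence("a")
        for state, p in zip("TCAG", pi):
            obs = seq.count(state) / len(seq)
            se = np.sqrt(p * (1 - p) / 10000)
            assert abs(obs - p) < 4 * se

    def test_invalid_model_rejected(self):
        with pytest.raises(ValueError):
            BlockModel(base_freqs=(0.5, 0.5, 0.1, 0.1))
        with pytest.raises(ValueError):
            BlockModel(base_freqs=(0.25,) * 4, alpha=-1.0)


class TestSimulateCondition:
    def test_dimensions_and_boundaries(self):
        sim = simulate_condition(get_condition("S1", "asymmetric"), seed=0)
        assert sim.alignment.n_taxa == 17
        assert sim.alignment.n_sites == 4000
        assert sim.block_boundaries == (
            (1, 1000), (1001, 2000), (2001, 3000), (3001, 4000)
        )

    def test_reproducible(self):
        c = get_condition("S3", "symmetric")
        a = simulate_condition(c, seed=4).alignment
        b = simulate_condition(c, seed=4).alignment
        assert np.array_equal(a.matrix, b.matrix)


@pytest.fixture(scope="module")
def sim():
    return simulate_condition(get_condition("S1", "asymmetric"), seed=2)


class TestInjectMissing:

    def test_exactly_three_thousand_missing_cells(self, sim):
        out = inject_missing(sim.alignment, sim.block_boundaries, seed=0)
        assert int((out.matrix == "?").sum()) == 3000
        # outgroup untouched
        assert "?" not in out.sequence("outgroup")

    def test_seeded_choice_is_stable(self, sim):
        a = inject_missing(sim.alignment, sim.block_boundaries, seed=5)
        b = inject_missing(sim.alignment, sim.block_boundaries, seed=5)
        assert np.array_equal(a.matrix, b.matrix)

    def test_zero_taxa_is_identity(self, sim):
        out = inject_missing(sim.alignment, sim.block_boundaries, n_taxa=0,
                             seed=1)
        assert out is sim.alignment

    def test_shared_block_mode_blanks_one_block_only(self, sim):
        out = inject_missing(sim.alignment, sim.block_boundaries, seed=3,
                             independent_blocks=False)
        missing_cols = np.unique(np.nonzero(out.matrix == "?")[1])
        blocks_hit = {(c // 1000) for c in missing_cols}
        assert len(blocks_hit) == 1

    def test_too_many_taxa_rejected(self, sim):
        with pytest.raises(ValueError):
            inject_missing(sim.alignment, sim.block_boundaries, n_taxa=17)
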