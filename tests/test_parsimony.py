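"""Fitch counting, exhaustive enumeration and heuristic search."""

import itertools

import numpy as np
import pytest

from middenid.parsimony import (
    CharacterMatrix,
    encode_states,
    exhaustive_search,
    fitch_length,
    heuristic_search,
    random_addition_tree,
)
from middenid.trees import Tree, all_topologies

from conftest import random_tree

STATES = list("ACGT-")


def aln(rows):
    return encode_states(list(rows.items()))


def brute_force_length(tree: Tree, m: CharacterMatrix) -> int:
    """Minimum changes over all internal-node state assignments (5 states)."""
    internal = tree.internal()
    edges = tree.edges()
    rows = {t: m.states[i] for i, t in enumerate(m.taxa)}
    bits = [1, 2, 4, 8, 16]
    total = 0
    for site in range(m.n_sites):
        best = np.inf
        for assign in itertools.product(bits, repeat=len(internal)):
            state = dict(zip(internal, assign))
            for lf in tree.leaves():
                state[lf] = int(rows[lf][site])
            cost = sum(
                1 for u, v in edges if state[u] & state[v] == 0
            )
            best = min(best, cost)
        total += int(best * m.weights[site])
    return total


class TestEncodeStates:
    def test_state_sets(self):
        m = aln({"a": "A", "b": "-", "c": "N", "d": "R"})
        assert m.states[:, 0].tolist() == [1, 16, 15, 5]

    def test_n_is_not_gap(self):
        # N encodes an unread base; the gap bit is reserved for '-'
        m = aln({"a": "N", "b": "N", "c": "N", "d": "N"})
        assert (m.states == 15).all()

    def test_illegal_symbol_rejected(self):
        with pytest.raises(ValueError):
            aln({"a": "A!", "b": "AC", "c": "AC", "d": "AC"})

    def test_unequal_rows_rejected(self):
        with pytest.raises(ValueError):
            aln({"a": "AC", "b": "A", "c": "AC", "d": "AC"})


class TestFitchLength:
    def test_constant_matrix_scores_zero(self, rng):
        m = aln({f"t{i}": "AAAA" for i in range(6)})
        assert fitch_length(random_tree(m.taxa, rng), m) == 0

    def test_four_taxon_single_column(self):
        m = aln({"t1": "A", "t2": "A", "t3": "C", "t4": "C"})
        assert fitch_length(Tree.from_newick("((t1,t2),(t3,t4));"), m) == 1
        assert fitch_length(Tree.from_newick("((t1,t3),(t2,t4));"), m) == 2

    def test_gap_is_a_real_fifth_state(self):
        m = aln({"t1": "-", "t2": "-", "t3": "A", "t4": "A"})
        assert fitch_length(Tree.from_newick("((t1,t2),(t3,t4));"), m) == 1

    def test_lower_bound_per_column(self, rng):
        # each column needs at least (#distinct singleton states - 1) steps
        for _ in range(10):
            seqs = {f"t{i}": "".join(rng.choice(STATES, 4)) for i in range(6)}
            m = aln(seqs)
            t = random_tree(m.taxa, rng)
            total = fitch_length(t, m)
            bound = sum(
                len({s[k] for s in seqs.values()}) - 1 for k in range(4)
            )
            assert total >= bound

    def test_matches_brute_force_assignment_minimum(self, rng):
        for _ in range(5):
            seqs = {f"t{i}": "".join(rng.choice(STATES, 3)) for i in range(6)}
            m = aln(seqs)
            t = random_tree(m.taxa, rng)
            assert fitch_length(t, m) == brute_force_length(t, m)

    def test_invariant_to_rooting(self, rng):
        seqs = {f"t{i}": "".join(rng.choice(STATES, 8)) for i in range(7)}
        m = aln(seqs)
        t = random_tree(m.taxa, rng)
        base = fitch_length(t, m)
        for lf in m.taxa:
            assert fitch_length(t.root_with_outgroup(lf), m) == base

    def test_duplicated_column_doubles_contribution(self, rng):
        seqs = {f"t{i}": "".join(rng.choice(STATES, 5)) for i in range(6)}
        m1 = aln(seqs)
        m_dup = aln({k: v + v for k, v in seqs.items()})
        m_const = aln({k: v + "A" for k, v in seqs.items()})
        t = random_tree(m1.taxa, rng)
        assert fitch_length(t, m_dup) == 2 * fitch_length(t, m1)
        assert fitch_length(t, m_const) == fitch_length(t, m1)

    def test_leaf_mismatch_rejected(self):
        m = aln({"t1": "A", "t2": "A", "t3": "C", "t4": "C"})
        with pytest.raises(ValueError):
            fitch_length(Tree.from_newick("((t1,t2),(t3,t5));"), m)


class TestExhaustive:
    def test_four_taxon_unique_optimum(self):
        m = aln({"t1": "A", "t2": "A", "t3": "C", "t4": "C"})
        res = exhaustive_search(m)
        assert res.best_score == 1
        assert len(res.optimal_trees) == 1
        expected = Tree.from_newick("((t1,t2),(t3,t4));")
        assert res.optimal_trees[0].topology_key() == expected.topology_key()

    def test_constant_matrix_all_trees_optimal(self):
        m = aln({f"t{i}": "AAAA" for i in range(6)})
        res = exhaustive_search(m)
        assert res.best_score == 0
        assert len(res.optimal_trees) == 105

    def test_too_many_taxa_rejected(self):
        m = aln({f"t{i:02d}": "A" * 4 for i in range(10)})
        with pytest.raises(ValueError):
            exhaustive_search(m)


class TestSearch:
    def test_three_taxon_addition_unique(self):
        m = aln({"t1": "AC", "t2": "AG", "t3": "CC", "t4": "CG"})
        for order in itertools.permutations(m.taxa):
            t = random_addition_tree(m, list(order))
            assert set(t.leaves()) == set(m.taxa)

    def test_addition_never_beats_exhaustive(self, rng):
        seqs = {f"t{i}": "".join(rng.choice(STATES, 12)) for i in range(6)}
        m = aln(seqs)
        best = exhaustive_search(m).best_score
        for _ in range(5):
            order = [m.taxa[i] for i in rng.permutation(6)]
            t = random_addition_tree(m, order)
            assert fitch_length(t, m) >= best

    def test_clean_signal_recovered_from_most_addition_orders(self):
        from middenid.simulate import PanelSpec, simulate_panel

        spec = PanelSpec(tree=(("A", "B"), (("C", "D"), ("E", "F"))),
                         length=60, subs_per_branch=5)
        res = simulate_panel(spec, seed=2)
        m = encode_states(res.alignment)
        true_key = res.true_tree.topology_key()
        hits = 0
        orders = list(itertools.permutations(m.taxa))[:120]
        for order in orders:
            t = random_addition_tree(m, list(order))
            hits += t.topology_key() == true_key
        assert hits / len(orders) >= 0.9

    def test_determinism_same_seed_same_result(self, rng):
        seqs = {f"t{i}": "".join(rng.choice(STATES, 20)) for i in range(7)}
        m = aln(seqs)
        r1 = heuristic_search(m, n_starts=10, seed=42)
        r2 = heuristic_search(m, n_starts=10, seed=42)
        assert r1.best_score == r2.best_score
        assert [t.topology_key() for t in r1.optimal_trees] == \
               [t.topology_key() for t in r2.optimal_trees]
        assert r1.consensus.newick(with_support=True) == \
               r2.consensus.newick(with_support=True)

    def test_heuristic_matches_exhaustive_on_unique_optimum(self, rng):
        found = 0
        for trial in range(10):
            seqs = {f"t{i}": "".join(rng.choice(STATES, 25)) for i in range(7)}
            m = aln(seqs)
            ex = exhaustive_search(m)
            if len(ex.optimal_trees) != 1:
                continue
            he = heuristic_search(m, n_starts=10, seed=trial)
            assert he.best_score == ex.best_score
            assert he.optimal_trees[0].topology_key() == \
                ex.optimal_trees[0].topology_key()
            found += 1
        assert found >= 3  # unique optima are common at 25 random columns

    def test_nni_swap_also_finds_optimum(self, rng):
        seqs = {f"t{i}": "".join(rng.choice(STATES, 20)) for i in range(6)}
        m = aln(seqs)
        ex = exhaustive_search(m)
        he = heuristic_search(m, n_starts=20, swap="NNI", seed=1)
        assert he.best_score == ex.best_score

    def test_topology_recovery_on_simulated_panels(self):
        """Planted 12-taxon topologies are recovered from strong signal."""
        from middenid.simulate import PanelSpec, simulate_panel

        tree = ((("a", "b"), ("c", "d")),
                ((("e", "f"), ("g", "h")), (("i", "j"), ("k", "l"))))
        hits = 0
        n_seeds = 5
        for seed in range(n_seeds):
            res = simulate_panel(
                PanelSpec(tree=tree, length=60, subs_per_branch=4), seed
            )
            m = encode_states(res.alignment)
            he = heuristic_search(m, n_starts=20, seed=seed)
            hits += any(
                t.topology_key() == res.true_tree.topology_key()
                for t in he.optimal_trees
            )
        assert hits >= n_seeds - 1
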