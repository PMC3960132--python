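"""Global alignment, difference counting and exact haplotype matching."""


import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from middenid import (
    ReferenceHaplotype,
    count_differences,
    difference_matrix,
    match_exact,
    pairwise_align,
    star_align,
)

SEQ = st.text(alphabet="ACGT", min_size=1, max_size=25)


def brute_force_best_score(a, b, match=1, mismatch=-1, gap=-2):
    """Exhaustive global alignment score by enumerating gap placements."""
    best = [-1e9]

    def rec(i, j, score):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            rec(i + 1, j + 1, score + s)
        if i < len(a):
            rec(i + 1, j, score + gap)
        if j < len(b):
            rec(i, j + 1, score + gap)

    rec(0, 0, 0)
    return best[0]


class TestPairwiseAlign:
    def test_identical_sequences(self):
        assert pairwise_align("ACGT", "ACGT") == ("ACGT", "ACGT", 4.0)

    def test_single_deletion(self):
        # exhaustive check over alignments of these strings gives score 1
        a, b, score = pairwise_align("ACGT", "AGT")
        assert (a, b) == ("ACGT", "A-GT")
        assert score == 1.0
        assert score == brute_force_best_score("ACGT", "AGT")

    @given(a=SEQ, b=SEQ)
    @settings(max_examples=100, derandomize=True)
    def test_score_is_symmetric(self, a, b):
        _, _, s_ab = pairwise_align(a, b)
        _, _, s_ba = pairwise_align(b, a)
        assert s_ab == s_ba

    @given(a=st.text(alphabet="ACGT", min_size=1, max_size=7),
           b=st.text(alphabet="ACGT", min_size=1, max_size=7))
    @settings(max_examples=50, derandomize=True)
    def test_optimal_against_exhaustive_enumeration(self, a, b):
        _, _, score = pairwise_align(a, b)
        assert score == brute_force_best_score(a, b)

    def test_n_matches_everything(self):
        a, b, score = pairwise_align("ANGT", "ACGT")
        assert score == 4.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pairwise_align("", "ACGT")


class TestCountDifferences:
    @pytest.mark.parametrize(
        "a,b,subs,gaps,skipped",
        [
            ("ACGT", "ACGT", 0, 0, 0),
            ("ACGT", "ACTT", 1, 0, 0),
            ("AC-T", "ACGT", 0, 1, 0),
            ("ANGT", "AAGT", 0, 0, 1),
            ("RCGT", "ACGT", 0, 0, 0),   # ambiguity covering the base
            ("RCGT", "TCGT", 0, 0, 1),   # disjoint ambiguity: unresolvable
        ],
    )
    def test_column_rules(self, a, b, subs, gaps, skipped):
        rep = count_differences(a, b)
        assert rep.substitutions == subs
        assert rep.gap_columns == gaps
        assert rep.skipped_sites == skipped
        assert rep.total_differences == subs + gaps

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            count_differences("ACG", "ACGT")

    @given(a=SEQ)
    @settings(max_examples=50, derandomize=True)
    def test_self_comparison_is_zero(self, a):
        assert count_differences(a, a).total_differences == 0

    @given(ab=st.tuples(
        st.text(alphabet="ACGT", min_size=5, max_size=5),
        st.text(alphabet="ACGT", min_size=5, max_size=5)))
    @settings(max_examples=100, derandomize=True)
    def test_hamming_equivalence_and_symmetry_on_gapless(self, ab):
        a, b = ab
        rep = count_differences(a, b)
        hamming = sum(x != y for x, y in zip(a, b))
        assert rep.total_differences == hamming
        assert rep.gap_columns == 0
        rev = count_differences(b, a)
        assert rev.total_differences == rep.total_differences

    @given(a=SEQ, b=SEQ)
    @settings(max_examples=50, derandomize=True)
    def test_column_partition_invariant(self, a, b):
        aa, bb, _ = pairwise_align(a, b)
        rep = count_differences(aa, bb)
        assert (rep.compared_sites + rep.gap_columns + rep.skipped_sites
                == rep.aligned_length)
        assert rep.total_differences <= rep.aligned_length


class TestMatchExact:
    def panel(self):
        return [
            ReferenceHaplotype("R1", bases="ACGTACGTAC"),
            ReferenceHaplotype("R2", bases="ACGTACGTTT"),
            ReferenceHaplotype("R3", bases="TTTTACGTAC"),
        ]

    def test_identical_member_matches(self):
        assert match_exact("ACGTACGTAC", self.panel()) == ["R1"]

    def test_no_match_is_empty(self):
        assert match_exact("GGGGGGGGGG", self.panel()) == []

    def test_fragment_matches_references_identical_over_span(self):
        # two references identical over the query's span, differing outside
        panel = [
            ReferenceHaplotype("HapB", bases="AAAACGTACGTAAAA"),
            ReferenceHaplotype("HapV", bases="GGGACGTACGTGGGG"),
            ReferenceHaplotype("Far", bases="AAAACTTTCGTAAAA"),
        ]
        assert match_exact("CGTACGT", panel) == ["HapB", "HapV"]


class TestDifferenceMatrix:
    def test_single_identical_reference(self):
        reps = difference_matrix("ACGTAC", [ReferenceHaplotype("R", bases="ACGTAC")])
        assert len(reps) == 1 and reps[0].total_differences == 0

    def test_planted_substitution_counts_reproduced(self):
        from middenid.simulate import make_planted_panel
        import numpy as np

        base = "".join(np.random.default_rng(5).choice(list("ACGT"), 60))
        edits = {"k0": 0, "k3": 3, "k8": 8, "k6": 6, "k7": 7, "k4": 4}
        panel = make_planted_panel(base, edits, seed=5)
        reps = difference_matrix(base, panel)
        assert {r.ref_id: r.total_differences for r in reps} == edits

    def test_panel_permutation_permutes_rows(self):
        panel = [ReferenceHaplotype(f"R{i}", bases="ACGTAC") for i in range(3)]
        fwd = difference_matrix("ACGTTC", panel)
        rev = difference_matrix("ACGTTC", panel[::-1])
        assert [r.ref_id for r in rev] == [r.ref_id for r in fwd][::-1]

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            difference_matrix("ACGT", [])


class TestStarAlign:
    def test_equal_length_rows(self):
        rows = star_align([("a", "ACGTACG"), ("b", "ACGACG"), ("c", "ACGTACG")])
        lengths = {len(s) for _, s in rows}
        assert len(lengths) == 1

    def test_short_sequence_ends_become_unknown(self):
        rows = dict(star_align([("long", "AAACGTACGTTT"), ("short", "CGTACG")]))
        assert rows["short"].startswith("NNN")
        assert rows["short"].endswith("NNN")
        assert "CGTACG" in rows["short"]
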