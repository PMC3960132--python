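"""Synthetic generators: determinism, planted truths, stream independence."""

import numpy as np
import pytest

from middenid import PelletClass, classify_pellet
from middenid.parsimony import encode_states, fitch_length
from middenid.simulate import (
    PanelSpec,
    ReplicateSpec,
    make_bundle,
    make_linear_curve,
    make_planted_panel,
    simulate_dates,
    simulate_panel,
    simulate_pellets,
    simulate_replicates,
)


class TestPanel:
    def test_zero_edits_gives_constant_alignment(self):
        spec = PanelSpec(tree=(("A", "B"), ("C", "D")), subs_per_branch=0,
                         length=30)
        res = simulate_panel(spec, seed=0)
        seqs = {s for _, s in res.alignment}
        assert len(seqs) == 1

    def test_planted_edit_counts_bound_pairwise_distance(self):
        spec = PanelSpec(tree=(("A", "B"), ("C", "D")), subs_per_branch=5,
                         length=60)
        res = simulate_panel(spec, seed=1)
        a = res.haplotypes["A"]
        b = res.haplotypes["B"]
        diff = sum(x != y for x, y in zip(a, b))
        assert 0 < diff <= 10  # at most the planted 5+5, minus collisions

    def test_deterministic_per_seed(self):
        spec = PanelSpec()
        assert simulate_panel(spec, 3).alignment == simulate_panel(spec, 3).alignment
        assert (simulate_panel(spec, 3).alignment
                != simulate_panel(spec, 4).alignment)

    def test_deletions_appear_as_gaps(self):
        spec = PanelSpec(tree=(("A", "B"), ("C", "D")), subs_per_branch=1,
                         indel_rate=2.0, length=40)
        res = simulate_panel(spec, seed=5)
        assert any("-" in s for _, s in res.alignment)
        # gapless haplotypes drop exactly the deleted sites
        for lf, aligned in res.alignment:
            assert res.haplotypes[lf] == aligned.replace("-", "")

    def test_true_tree_is_fitch_optimal_for_clean_signal(self):
        spec = PanelSpec(tree=(("A", "B"), (("C", "D"), ("E", "F"))),
                         subs_per_branch=5, length=60)
        res = simulate_panel(spec, seed=7)
        m = encode_states(res.alignment)
        from middenid.parsimony import exhaustive_search

        ex = exhaustive_search(m)
        keys = {t.topology_key() for t in ex.optimal_trees}
        assert res.true_tree.topology_key() in keys

    def test_too_many_substitutions_rejected(self):
        with pytest.raises(ValueError):
            simulate_panel(PanelSpec(length=20, subs_per_branch=21), seed=0)


class TestPlantedPanel:
    def test_exact_edit_counts(self):
        base = "ACGTACGTACGTACGTACGT"
        panel = make_planted_panel(base, {"a": 0, "b": 2, "c": 5}, seed=1)
        by_acc = {r.accession: r.bases for r in panel}
        assert by_acc["a"] == base
        assert sum(x != y for x, y in zip(base, by_acc["b"])) == 2
        assert sum(x != y for x, y in zip(base, by_acc["c"])) == 5


class TestReplicates:
    def test_noise_free_replicates_equal_truth(self):
        spec = ReplicateSpec(miscall_rate=0, n_rate=0, slippage_rate=0)
        reads = simulate_replicates("ACGTAACGT", spec, seed=0)
        assert len(reads) == 12
        from middenid import Direction, reverse_complement

        for r in reads:
            if r.direction is Direction.FORWARD:
                assert r.bases == "ACGTAACGT"
            else:
                assert reverse_complement(r.bases) == "ACGTAACGT"

    def test_certain_miscall_changes_single_base(self):
        spec = ReplicateSpec(n_forward=1, n_reverse=0, miscall_rate=1.0,
                             n_rate=0, slippage_rate=0)
        (read,) = simulate_replicates("A", spec, seed=0)
        assert read.bases != "A"

    def test_rates_validated(self):
        with pytest.raises(ValueError):
            ReplicateSpec(miscall_rate=1.5)


class TestPellets:
    def test_degenerate_spec_reproduces_means(self):
        from middenid.simulate import PelletClassSpec

        spec = {PelletClass.OVIS_LIKE: PelletClassSpec(
            15.5, 0.0, 10.1, 0.0, 0.2, 0.0)}
        pellets, labels = simulate_pellets(
            {PelletClass.OVIS_LIKE: 3}, seed=0, specs=spec
        )
        for p in pellets:
            assert (p.length_mm, p.width_mm, p.weight_g) == (15.5, 10.1, 0.2)
            assert classify_pellet(p).label is PelletClass.OVIS_LIKE
        assert labels == [PelletClass.OVIS_LIKE] * 3

    def test_true_labels_allow_confusion_matrix(self):
        pellets, labels = simulate_pellets(
            {PelletClass.OVIS_LIKE: 20, PelletClass.LARGE_UNGULATE: 20}, seed=1
        )
        assert len(pellets) == len(labels) == 40
        predicted = [classify_pellet(p).label for p in pellets]
        agree = sum(p == t for p, t in zip(predicted, labels))
        assert agree >= 30  # deliberate overlap, but mostly recoverable

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            simulate_pellets({PelletClass.OVIS_LIKE: 0}, seed=0)


class TestCurveAndDates:
    def test_sigma_zero_dates_recover_truth_through_identity_curve(self):
        from middenid.calibration import calibrate

        curve = make_linear_curve(0.0, 1.0, (1000, 2000))
        dates = simulate_dates([1500.0], curve, sigma=1e-9, seed=0)
        # measurement noise ~0: calibrated median lands on the true age
        cal = calibrate(
            type(dates[0])(dates[0].lab_id, dates[0].c14_age, 1.0), curve
        )
        assert cal.median == pytest.approx(1500, abs=1)

    def test_zero_slope_rejected(self):
        with pytest.raises(ValueError):
            make_linear_curve(0.0, 0.0, (0, 10))


class TestStreamIndependence:
    def test_pellet_count_does_not_perturb_sequences(self):
        a = make_bundle(seed=5, n_pellets=10)
        b = make_bundle(seed=5, n_pellets=50)
        assert a.true_haplotype == b.true_haplotype
        assert [r.bases for r in a.reads["frag1"]] == \
               [r.bases for r in b.reads["frag1"]]
        assert [d.c14_age for d in a.dates] == [d.c14_age for d in b.dates]

    def test_bundle_deterministic(self):
        a = make_bundle(seed=8)
        b = make_bundle(seed=8)
        assert a.true_haplotype == b.true_haplotype
        assert [p.length_mm for p in a.pellets] == [p.length_mm for p in b.pellets]
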