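"""Generators: birth--death trees, fossil-style calibrations, alignments."""

import math

import numpy as np
import pytest

from chronocal import (
    generate_calibrations,
    make_crossval_study,
    make_study,
    simulate_alignment,
    simulate_bd_tree,
    turtle_fixture,
    turtle_table,
    validate_order,
)


class TestBirthDeathTrees:
    def test_two_tip_root_age_is_exponential(self):
        """At n=2 the present sits at the end of the two-lineage sojourn,
        so the root age is Exp(2 lambda): mean 1/(2 lambda)."""
        ages = [
            simulate_bd_tree(2, 1.0, seed=s).ages[-1] for s in range(500)
        ]
        mean, se = np.mean(ages), np.std(ages) / math.sqrt(500)
        assert abs(mean - 0.5) < 3 * se + 0.01

    def test_structure_and_order(self):
        for seed in range(5):
            t = simulate_bd_tree(8, 1.0, death=0.4, seed=seed)
            assert t.n_tips == 8
            assert len(t.internal_nodes) == 7
            assert validate_order(t) == []

    def test_yule_root_age_matches_closed_form(self):
        """Forward pure-birth: root age = sum of Exp(k lambda) sojourns for
        k = 2..n, so E = (1/lambda) * sum 1/k."""
        n, lam, reps = 8, 1.0, 500
        expect = sum(1.0 / k for k in range(2, n + 1)) / lam
        ages = [simulate_bd_tree(n, lam, seed=s).ages[-1] for s in range(reps)]
        mean, se = np.mean(ages), np.std(ages) / math.sqrt(reps)
        assert abs(mean - expect) < 3 * se

    def test_reproducible(self):
        a = simulate_bd_tree(6, 0.5, death=0.2, seed=3)
        b = simulate_bd_tree(6, 0.5, death=0.2, seed=3)
        assert a.to_newick() == b.to_newick()

    def test_invalid_rates(self):
        with pytest.raises(ValueError):
            simulate_bd_tree(4, 1.0, death=1.5)


class TestGeneratedCalibrations:
    def test_minima_postdate_and_maxima_predate_truth(self):
        for seed in range(5):
            tree = simulate_bd_tree(8, 0.05, seed=seed)
            tree, cals = generate_calibrations(tree, seed=seed)
            for c in cals:
                age = tree.ages[tree.node_by_label(c.node_label)]
                assert 0 < c.t_L < age
                assert c.t_U is None or c.t_U > age

    def test_tight_minima_in_high_gap_rate_limit(self):
        tree = simulate_bd_tree(8, 0.05, seed=1)
        tree, cals = generate_calibrations(tree, gap_rate=1e4, seed=1)
        for c in cals:
            age = tree.ages[tree.node_by_label(c.node_label)]
            assert age - c.t_L < 0.01

    def test_root_always_bounded(self):
        tree = simulate_bd_tree(8, 0.05, seed=2)
        tree, cals = generate_calibrations(tree, style="min-only", seed=2)
        root_label = tree.node_name(tree.root)
        root_cal = next(c for c in cals if c.node_label == root_label)
        assert root_cal.t_U is not None

    def test_linked_maxima_are_fixed_multiple_of_minima(self):
        tree = simulate_bd_tree(8, 0.05, seed=3)
        tree, cals = generate_calibrations(tree, style="min-max-linked", seed=3)
        root_label = tree.node_name(tree.root)
        for c in cals:
            if c.node_label != root_label:
                assert c.t_U == pytest.approx(1.221 * c.t_L)

    def test_misleading_minimum_predates_nothing(self):
        tree = simulate_bd_tree(8, 0.05, seed=4)
        _, cals = generate_calibrations(tree, seed=4)
        victim = cals[-1].node_label  # a non-root calibrated node
        tree2, cals2 = generate_calibrations(tree, seed=4, misleading_node=victim)
        bad = next(c for c in cals2 if c.node_label == victim)
        assert bad.t_L > tree2.ages[tree2.node_by_label(victim)]
        assert bad.t_U > bad.t_L

    def test_bit_reproducible(self):
        tree = simulate_bd_tree(8, 0.05, seed=5)
        _, a = generate_calibrations(tree, seed=5)
        _, b = generate_calibrations(tree, seed=5)
        assert a == b


class TestAlignments:
    def test_zero_rate_means_identical_sequences(self):
        tree = simulate_bd_tree(5, 0.05, seed=1)
        aln = simulate_alignment(tree, 0.0, 50, seed=1)
        assert len(set(aln.sequences)) == 1

    def test_pairwise_divergence_matches_jc_expectation(self):
        from chronocal import parse_newick

        T, r, n = 50.0, 0.004, 10_000
        tree = parse_newick(f"(A:{T},B:{T});")
        aln = simulate_alignment(tree, r, n, seed=7)
        diff = sum(a != b for a, b in zip(*aln.sequences))
        p = 0.75 * (1.0 - math.exp(-8.0 * r * T / 3.0))
        se = math.sqrt(p * (1 - p) * n)
        assert abs(diff - p * n) < 3 * se

    def test_reproducible(self):
        tree = simulate_bd_tree(4, 0.05, seed=2)
        assert simulate_alignment(tree, 0.01, 100, seed=9) == simulate_alignment(
            tree, 0.01, 100, seed=9
        )


class TestTurtleFixture:
    def test_priori_root_bounds(self):
        _, cals = turtle_fixture("priori")
        root = next(c for c in cals if c.node_label == "Testudines")
        assert (root.t_L, root.t_U) == (155.6, 251.4)

    def test_posteriori_pelomedusidae(self):
        _, cals = turtle_fixture("posteriori")
        pel = next(c for c in cals if c.node_label == "Pelomedusidae")
        assert (pel.t_L, pel.t_U) == (18.0, 22.0)

    def test_all_windows_ordered(self):
        for era in ("priori", "posteriori"):
            _, cals = turtle_fixture(era)
            assert all(c.t_L < c.t_U for c in cals)

    def test_table_carries_unattached_row_and_verdicts(self):
        df = turtle_table()
        lind = df[df["node_label"] == "Lindholmemydidae"]
        assert not bool(lind["attached"].iloc[0])
        assert "near" in df.columns and "dornburg" in df.columns


def test_studies_are_reproducible_and_valid():
    for maker in (lambda s: make_study(seed=s), lambda s: make_crossval_study(seed=s)):
        a, b = maker(3), maker(3)
        assert a.tree.to_newick() == b.tree.to_newick()
        assert a.calibrations == b.calibrations
        assert a.alignment == b.alignment
        assert validate_order(a.tree) == []
        for c in a.calibrations:
            age = a.tree.ages[a.tree.node_by_label(c.node_label)]
            assert c.t_L < age < c.t_U
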