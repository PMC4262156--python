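"""Cross-validation statistics against an independent brute-force oracle."""

import numpy as np
import pandas as pd
import pytest

from chronocal import (
    Calibration,
    MCMCSettings,
    XValRound,
    dbar_min,
    dbar_minmax,
    discrepancy_minmax,
    max_abs_revision,
    pooled_s,
    revision_percentages,
    rounds_from_stub,
    run_round,
    sequential_removal,
    ss_min,
    ss_minmax,
    turtle_fixture,
    turtle_table,
)
from chronocal.joint_prior import ConfigurationError


# -- independent oracle (plain loops, no shared code paths) -----------------

def oracle_stats(rows, variant):
    """rows: list of (focal, {target: (ma, mn, mx)}).  Returns per-focal
    (dbar, ss) plus pooled s, via the most literal possible arithmetic."""
    out = {}
    for focal, targets in rows:
        diffs = []
        for ma, mn, mx in targets.values():
            if variant == "min":
                diffs.append(ma - mn)
            else:
                if ma > mx:
                    diffs.append(ma - mx)
                elif ma < mn:
                    diffs.append(ma - mn)
                else:
                    diffs.append(0.0)
        dbar = sum(diffs) / len(diffs)
        ss = sum(d * d for d in diffs)
        out[focal] = (dbar, ss)
    n = len(rows)
    s = sum(v[1] for v in out.values()) / (n * (n - 1))
    return out, s


def round_from(focal, targets):
    return XValRound(
        focal,
        {k: v[0] for k, v in targets.items()},
        {k: v[1] for k, v in targets.items()},
        {k: v[2] for k, v in targets.items()},
    )


STUB = [
    ("a", {"b": (60.0, 50.0, 70.0), "c": (30.0, 25.0, 28.0), "d": (90.0, 95.0, 120.0)}),
    ("b", {"a": (110.0, 100.0, 130.0), "c": (26.0, 25.0, 28.0), "d": (100.0, 95.0, 120.0)}),
    ("c", {"a": (140.0, 100.0, 130.0), "b": (75.0, 50.0, 70.0), "d": (118.0, 95.0, 120.0)}),
    ("d", {"a": (95.0, 100.0, 130.0), "b": (40.0, 50.0, 70.0), "c": (20.0, 25.0, 28.0)}),
]


class TestStatistics:
    def test_dbar_min_worked_example(self):
        assert dbar_min({"x": 60.0, "y": 30.0}, {"x": 50.0, "y": 25.0}) == 7.5
        assert dbar_min({"x": 50.0}, {"x": 50.0}) == 0.0
        assert dbar_min({"x": 40.0}, {"x": 50.0}) == -10.0

    def test_ss_min_worked_example(self):
        assert ss_min({"x": 60.0, "y": 30.0}, {"x": 50.0, "y": 25.0}) == 125.0
        assert ss_min({"x": 50.0}, {"x": 50.0}) == 0.0
        assert ss_min({"x": 40.0}, {"x": 50.0}) == 100.0

    def test_discrepancy_sign_convention(self):
        assert discrepancy_minmax(60.0, 50.0, 70.0) == 0.0
        assert discrepancy_minmax(80.0, 50.0, 70.0) == 10.0
        assert discrepancy_minmax(45.0, 50.0, 70.0) == -5.0
        with pytest.raises(ValueError, match="below"):
            discrepancy_minmax(60.0, 70.0, 50.0)

    def test_pooled_s_and_removal_mechanism(self):
        """The published arithmetic: s = 250/6 = 41.667, and removing the
        largest SS shrinks the numerator by 50% but the denominator by
        66.7%, so s *rises* to 62.5."""
        assert pooled_s([125.0, 80.0, 45.0], 3) == pytest.approx(41.667, abs=1e-3)
        assert pooled_s([80.0, 45.0], 2) == pytest.approx(62.5)
        assert pooled_s([0.0, 0.0, 0.0], 3) == 0.0
        with pytest.raises(ValueError):
            pooled_s([1.0], 1)

    @pytest.mark.parametrize("variant", ["min", "minmax"])
    def test_matches_brute_force_oracle(self, variant):
        expected, s_exp = oracle_stats(STUB, variant)
        rounds = [round_from(f, t) for f, t in STUB]
        for r in rounds:
            dbar_exp, ss_exp = expected[r.focal]
            assert abs(r.dbar(variant) - dbar_exp) < 1e-12
            assert abs(r.ss(variant) - ss_exp) < 1e-12
        got_s = pooled_s([r.ss(variant) for r in rounds], len(rounds))
        assert abs(got_s - s_exp) < 1e-12

    def test_minmax_never_exceeds_min_when_estimates_predate_minima(self, rng):
        """Allowing a window can only shrink or zero each discrepancy."""
        for _ in range(50):
            mn = rng.uniform(10, 100, 5)
            mx = mn * rng.uniform(1.1, 2.0, 5)
            ma = mn + rng.uniform(0, 60, 5)  # estimates at/above minima
            est = {f"n{i}": ma[i] for i in range(5)}
            assert ss_minmax(
                est, {f"n{i}": mn[i] for i in range(5)},
                {f"n{i}": mx[i] for i in range(5)},
            ) <= ss_min(est, {f"n{i}": mn[i] for i in range(5)}) + 1e-12


class TestSequentialRemoval:
    def test_brute_force_trace(self):
        """Every step of the trace equals a from-scratch recomputation on
        the surviving set, and the planted worst calibration goes first."""
        rows = STUB
        rounds = [round_from(f, t) for f, t in rows]
        trace = sequential_removal(rounds, variant="min", n_boot=0)
        surviving = sorted(r.focal for r in rounds)
        by_focal = {f: dict(t) for f, t in rows}
        for step in range(len(trace.s)):
            sub = [
                (f, {k: v for k, v in by_focal[f].items() if k in surviving})
                for f in surviving
            ]
            expected, s_exp = oracle_stats(sub, "min")
            assert abs(trace.s[step] - s_exp) < 1e-12
            assert trace.n[step] == len(surviving)
            assert trace.denominator[step] == len(surviving) * (len(surviving) - 1)
            if step < len(trace.s) - 1:
                worst = max(sorted(expected), key=lambda f: expected[f][1])
                assert trace.removed[step + 1] == worst
                surviving.remove(worst)
        # focal 'c' has the wildly old estimates -> largest SS -> removed first
        assert trace.removed[1] == "c"

    def test_consistent_set_keeps_s_near_zero(self):
        rows = [
            (f, {g: (50.0 + i, 50.0 + i, 60.0 + i) for i, g in enumerate("abcd") if g != f})
            for f in "abcd"
        ]
        trace = sequential_removal([round_from(f, t) for f, t in rows],
                                   variant="minmax", n_boot=0)
        assert max(trace.s) == 0.0

    def test_removal_order_deterministic_with_label_tiebreak(self):
        rows = [
            (f, {g: (60.0, 50.0, 70.0) for g in "abc" if g != f}) for f in "abc"
        ]
        t1 = sequential_removal([round_from(f, t) for f, t in rows], n_boot=0)
        t2 = sequential_removal([round_from(f, t) for f, t in rows], n_boot=0)
        assert t1.removed == t2.removed == ["", "a"]  # ties break by label

    def test_bootstrap_interval_brackets_s(self):
        rounds = [round_from(f, t) for f, t in STUB]
        trace = sequential_removal(rounds, variant="min", n_boot=2000, seed=1)
        lo, hi = trace.s_ci[0]
        assert lo <= trace.s[0] * 1.5 and hi >= trace.s[0] * 0.5


class TestRounds:
    def test_focal_excluded_and_estimates_cover_others(self):
        tree, cals = turtle_fixture("priori")
        sub = cals[:6]
        r = run_round(
            tree, sub, focal="Pelomedusoides",
            mcmc=MCMCSettings(n_iter=4000, burn_in=0.25, thin=4), seed=1,
        )
        assert "Pelomedusoides" not in r.estimates
        assert set(r.estimates) == {c.node_label for c in sub} - {"Pelomedusoides"}

    def test_round_statistics_match_hand_computation(self):
        stub = pd.DataFrame(
            {
                "focal_node": ["a", "a", "b", "b"],
                "target_node": ["b", "c", "a", "c"],
                "mean_age": [60.0, 30.0, 110.0, 26.0],
            }
        )
        cals = [
            Calibration("a", "uniform", 100.0, 130.0),
            Calibration("b", "uniform", 50.0, 70.0),
            Calibration("c", "uniform", 25.0, 28.0),
        ]
        rounds = rounds_from_stub(stub, cals)
        ra = next(r for r in rounds if r.focal == "a")
        assert ra.dbar("min") == pytest.approx(((60 - 50) + (30 - 25)) / 2)
        assert ra.ss("min") == pytest.approx(100 + 25)
        assert ra.ss("minmax") == pytest.approx(4.0)  # only c: 30 > 28

    def test_posteriori_round_uses_root_soft_max(self):
        tree, cals = turtle_fixture("posteriori")
        pel = next(c for c in cals if c.node_label == "Pelomedusidae")
        assert (pel.t_L, pel.t_U) == (18.0, 22.0)
        root = next(c for c in cals if c.node_label == "Testudines")
        assert root.t_U == 251.4
        r = run_round(
            tree, cals, focal="Pelomedusidae",
            mcmc=MCMCSettings(n_iter=3000, burn_in=0.25, thin=4), seed=0,
        )
        assert len(r.estimates) == len(cals) - 1

    def test_root_focal_without_maximum_errors(self, two_tip_tree):
        cals = [Calibration("R", "cauchy", 10.0, p=0.1, c=0.5)]
        with pytest.raises(ConfigurationError):
            run_round(two_tip_tree, cals, focal="R")


class TestRevision:
    def test_table1_percentages(self):
        df = revision_percentages(turtle_table())
        by = df.set_index("node_label")["revision_pct"]
        # revised younger by 89.4%: the largest revision in the set
        assert by["Heosemys_Mauremys"] == pytest.approx(100 * (50 - 5.3) / 50, abs=1e-9)
        assert by["Pleurodira"] == pytest.approx(100 * (110 - 111) / 110, abs=1e-9)
        assert max_abs_revision(turtle_table()) == pytest.approx(89.4, abs=0.05)

    def test_identical_minima_give_zero(self):
        df = revision_percentages(
            pd.DataFrame({"node_label": ["x"], "min_post": [50.0], "min_priori": [50.0]})
        )
        assert df["revision_pct"].iloc[0] == 0.0

    def test_zero_reference_minimum_rejected(self):
        with pytest.raises(ValueError, match="zero minimum"):
            revision_percentages(
                pd.DataFrame({"node_label": ["x"], "min_post": [0.0], "min_priori": [1.0]})
            )
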