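"""Calibration cross-validation: leave-one-calibration-in consistency scoring.

Each calibration x in a set of n is used *alone* (plus the root soft
maximum) to date the tree; the resulting mean age estimates MA_i at the
other calibrated nodes are scored against those nodes' fossil constraints
FA_i:

    D-bar_x = (1 / (n - 1)) * sum_{i != x} (MA_i - FA_i)
    SS_x    = sum_{i != x} (MA_i - FA_i)^2
    s       = sum_x SS_x / (n * (n - 1))

The ``min`` variant takes FA_i to be the fossil minima; the ``minmax``
variant replaces the difference with a discrepancy that is zero whenever
the estimate falls inside [minimum, maximum], positive (MA - max) above
the maximum and negative (MA - min) below the minimum.

Sequential removal drops the highest-SS calibration at each step and
recomputes everything on the survivors; because the denominator n(n-1)
shrinks faster than the numerator sum(SS) when the surviving rounds stay
similar, s can *rise* as "inconsistent" calibrations are removed — the
mechanism that makes the pooled statistic hard to interpret.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibrations import Calibration
from .joint_prior import (
    ConfigurationError,
    MCMCSettings,
    TreePriorParams,
    sample_prior,
)
from .timetree import TimeTree

__all__ = [
    "XValRound",
    "RemovalTrace",
    "dbar_min",
    "ss_min",
    "discrepancy_minmax",
    "dbar_minmax",
    "ss_minmax",
    "pooled_s",
    "run_round",
    "run_all_rounds",
    "rounds_from_stub",
    "sequential_removal",
    "revision_percentages",
]


# ---------------------------------------------------------------------------
# statistics


def dbar_min(estimates: dict, minima: dict) -> float:
    """Mean of (molecular estimate - fossil minimum) over non-focal nodes.

    Positive values mean the estimates predate the minima, as they should
    if minima postdate the true divergences.
    """
    if not estimates:
        raise ValueError("no non-focal estimates")
    return float(np.mean([estimates[k] - minima[k] for k in estimates]))


def ss_min(estimates: dict, minima: dict) -> float:
    """Sum of squared (estimate - minimum) differences."""
    if not estimates:
        raise ValueError("no non-focal estimates")
    return float(sum((estimates[k] - minima[k]) ** 2 for k in estimates))


def discrepancy_minmax(ma: float, fa_min: float, fa_max: float) -> float:
    """Signed discrepancy against a [minimum, maximum] interval.

    Zero inside the interval; ``ma - fa_max`` (positive, too old) above it;
    ``ma - fa_min`` (negative, too young) below it.
    """
    if not fa_min < fa_max:
        raise ValueError("minimum must lie below maximum")
    if ma > fa_max:
        return ma - fa_max
    if ma < fa_min:
        return ma - fa_min
    return 0.0


def _minmax_discrepancies(estimates: dict, minima: dict, maxima: dict) -> list:
    return [
        discrepancy_minmax(estimates[k], minima[k], maxima[k]) for k in estimates
    ]


def dbar_minmax(estimates: dict, minima: dict, maxima: dict) -> float:
    if not estimates:
        raise ValueError("no non-focal estimates")
    return float(np.mean(_minmax_discrepancies(estimates, minima, maxima)))


def ss_minmax(estimates: dict, minima: dict, maxima: dict) -> float:
    if not estimates:
        raise ValueError("no non-focal estimates")
    return float(sum(d * d for d in _minmax_discrepancies(estimates, minima, maxima)))


def pooled_s(ss_values, n: int) -> float:
    """Pooled average squared deviation ``s = sum(SS) / (n (n - 1))``."""
    ss_values = list(ss_values)
    if n < 2:
        raise ValueError("pooled s needs at least two calibrations")
    if len(ss_values) != n:
        raise ValueError("need one SS value per calibration")
    return float(sum(ss_values) / (n * (n - 1)))


# ---------------------------------------------------------------------------
# rounds


@dataclass
class XValRound:
    """Output of one leave-one-calibration-in round."""

    focal: str
    estimates: dict            # node label -> posterior mean age (Ma)
    minima: dict               # node label -> fossil minimum (all non-focal)
    maxima: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.focal in self.estimates:
            raise ValueError("estimates must exclude the focal node")

    def restricted(self, labels) -> "XValRound":
        keep = [k for k in self.estimates if k in labels]
        return XValRound(
            self.focal,
            {k: self.estimates[k] for k in keep},
            {k: self.minima[k] for k in keep},
            {k: self.maxima[k] for k in keep if k in self.maxima},
        )

    def dbar(self, variant: str = "min") -> float:
        if variant == "min":
            return dbar_min(self.estimates, self.minima)
        return dbar_minmax(self.estimates, self.minima, self.maxima)

    def ss(self, variant: str = "min") -> float:
        if variant == "min":
            return ss_min(self.estimates, self.minima)
        return ss_minmax(self.estimates, self.minima, self.maxima)


def run_round(
    tree: TimeTree,
    calibrations: list[Calibration],
    focal: str,
    root_label: str | None = None,
    engine: str = "prior",
    alignment=None,
    clock=None,
    params: TreePriorParams | None = None,
    mcmc: MCMCSettings | None = None,
    seed: int = 0,
    use_median: bool = False,
    focal_fixed: bool = False,
) -> XValRound:
    """Date the tree with only the focal calibration (plus the root soft
    maximum) and record mean ages at every other calibrated node.

    Per the cross-validation protocol, the root carries only its soft
    *maximum* during a round (the root minimum is dropped, so the focal
    calibration alone sets the timescale) unless the root itself is focal.
    With ``focal_fixed=True`` the focal node is pinned at its minimum age
    (a 0.1%-wide window) — the original protocol's fixed-age calibration
    style — instead of spanning its full [minimum, maximum] window.
    """
    by_label = {c.node_label: c for c in calibrations}
    if focal not in by_label:
        raise ConfigurationError(f"focal calibration {focal!r} not in the set")
    if focal_fixed:
        fc = by_label[focal]
        by_label[focal] = Calibration(
            focal, "uniform", t_L=fc.t_L * 0.999, t_U=fc.t_L * 1.001
        )
    root_label = root_label or tree.node_name(tree.root)
    root_cal = by_label.get(root_label)
    if focal == root_label:
        active = [by_label[focal]]
        if not by_label[focal].has_upper_bound:
            raise ConfigurationError(
                "focal calibration is the root but carries no maximum"
            )
    else:
        if root_cal is None or not root_cal.has_upper_bound:
            raise ConfigurationError(
                "cross-validation requires a root soft maximum calibration"
            )
        root_max_only = Calibration(
            root_cal.node_label,
            "uniform",
            t_L=min(1e-3 * root_cal.t_U, root_cal.t_L),
            t_U=root_cal.t_U,
            tail_R=root_cal.tail_R,
        )
        active = [by_label[focal], root_max_only]

    mcmc = mcmc or MCMCSettings(n_iter=40_000, burn_in=0.25, thin=10)
    if engine == "prior":
        samples = sample_prior(tree, active, params=params, mcmc=mcmc, seed=seed)
    elif engine == "posterior":
        from .clock import sample_posterior

        if alignment is None or clock is None:
            raise ConfigurationError("posterior engine needs alignment + clock")
        samples = sample_posterior(
            tree, active, alignment, clock, params=params, mcmc=mcmc, seed=seed
        )
    else:
        raise ConfigurationError(f"unknown engine {engine!r}")

    estimates = {}
    for cal in calibrations:
        if cal.node_label == focal:
            continue
        x = samples.column(cal.node_label)
        estimates[cal.node_label] = float(np.median(x) if use_median else x.mean())
    minima = {c.node_label: c.t_L for c in calibrations if c.node_label != focal}
    maxima = {
        c.node_label: c.t_U
        for c in calibrations
        if c.node_label != focal and c.t_U is not None
    }
    return XValRound(focal, estimates, minima, maxima)


def run_all_rounds(tree, calibrations, seed: int = 0, **kw) -> list[XValRound]:
    """One round per calibration, with per-round derived seeds."""
    return [
        run_round(tree, calibrations, c.node_label, seed=seed + 7919 * i, **kw)
        for i, c in enumerate(calibrations)
    ]


def rounds_from_stub(
    stub: pd.DataFrame, calibrations: list[Calibration]
) -> list[XValRound]:
    """Build rounds from a frozen estimate table.

    ``stub`` columns: ``focal_node``, ``target_node``, ``mean_age``.  This
    decouples statistic correctness from sampler stochasticity and lets
    users bring externally computed posterior summaries.
    """
    by_label = {c.node_label: c for c in calibrations}
    rounds = []
    for focal, grp in stub.groupby("focal_node", sort=True):
        est = dict(zip(grp["target_node"], grp["mean_age"].astype(float)))
        minima = {k: by_label[k].t_L for k in est}
        maxima = {
            k: by_label[k].t_U for k in est if by_label[k].t_U is not None
        }
        rounds.append(XValRound(str(focal), est, minima, maxima))
    return rounds


# ---------------------------------------------------------------------------
# sequential removal


@dataclass
class RemovalTrace:
    """Per-step record of the sequential-removal diagnostic."""

    removed: list                 # calibration removed at each step ('' first)
    n: list
    sum_ss: list
    denominator: list             # n (n - 1)
    s: list
    pct_change_sum_ss: list
    pct_change_denominator: list
    pct_change_s: list
    s_ci: list                    # optional bootstrap (lo, hi) per step

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "removed": self.removed,
                "n": self.n,
                "sum_ss": self.sum_ss,
                "n(n-1)": self.denominator,
                "s": self.s,
                "pct_change_sum_ss": self.pct_change_sum_ss,
                "pct_change_n(n-1)": self.pct_change_denominator,
                "pct_change_s": self.pct_change_s,
                "s_ci_lo": [c[0] if c else math.nan for c in self.s_ci],
                "s_ci_hi": [c[1] if c else math.nan for c in self.s_ci],
            }
        )


def _step_stats(rounds: list[XValRound], variant: str):
    ss = [r.ss(variant) for r in rounds]
    n = len(rounds)
    return ss, sum(ss), n * (n - 1), pooled_s(ss, n)


def _bootstrap_ci(rounds, variant, n_boot, rng, level=0.95):
    # resample rounds (the SS contributions) with replacement
    ss = np.array([r.ss(variant) for r in rounds])
    n = len(ss)
    idx = rng.integers(0, n, size=(n_boot, n))
    s_boot = ss[idx].sum(axis=1) / (n * (n - 1))
    a = (1 - level) / 2
    return tuple(np.quantile(s_boot, [a, 1 - a]))


def sequential_removal(
    rounds: list[XValRound],
    variant: str = "min",
    n_boot: int = 10_000,
    seed: int = 0,
) -> RemovalTrace:
    """Iteratively remove the highest-SS calibration, re-scoring survivors.

    All rounds are restricted to the surviving calibration set at every
    step (both as focal rounds and as scoring targets).  Ties in SS break
    by node-label order.  When ``n_boot > 0`` a nonparametric bootstrap
    over the rounds' SS contributions attaches an interval to each s.
    """
    if len(rounds) < 3:
        raise ValueError("sequential removal needs at least three calibrations")
    rng = np.random.default_rng(seed)
    surviving = sorted(r.focal for r in rounds)
    current = {r.focal: r for r in rounds}
    trace = RemovalTrace([], [], [], [], [], [], [], [], [])

    def record(removed_label):
        active = [current[f].restricted(surviving) for f in surviving]
        ss, tot, denom, s = _step_stats(active, variant)
        trace.removed.append(removed_label)
        trace.n.append(len(active))
        trace.sum_ss.append(tot)
        trace.denominator.append(denom)
        trace.s.append(s)
        if len(trace.s) == 1:
            for col in (trace.pct_change_sum_ss, trace.pct_change_denominator,
                        trace.pct_change_s):
                col.append(math.nan)
        else:
            for col, cur, prev in (
                (trace.pct_change_sum_ss, tot, trace.sum_ss[-2]),
                (trace.pct_change_denominator, denom, trace.denominator[-2]),
                (trace.pct_change_s, s, trace.s[-2]),
            ):
                col.append(
                    100.0 * (cur - prev) / prev if prev != 0 else math.nan
                )
        trace.s_ci.append(
            _bootstrap_ci(active, variant, n_boot, rng) if n_boot > 0 else None
        )
        return {f: r.ss(variant) for f, r in zip(surviving, active)}

    ss_now = record("")
    while len(surviving) > 2:
        worst = max(sorted(ss_now), key=lambda f: ss_now[f])
        surviving.remove(worst)
        ss_now = record(worst)
    return trace


# ---------------------------------------------------------------------------
# constraint-revision arithmetic


def revision_percentages(table: pd.DataFrame) -> pd.DataFrame:
    """Per-node percent revision of minima between two constraint eras.

    Expects columns ``node_label``, ``min_post`` (the consistency-era
    minimum) and ``min_priori`` (the revised fossil-based minimum); emits
    the signed percentage ``100 * (min_post - min_priori) / min_post``
    (positive = the revision moved the minimum younger).  Rows lacking
    either minimum are dropped.
    """
    df = table.dropna(subset=["min_post", "min_priori"]).copy()
    if (df["min_post"] == 0).any():
        raise ValueError("zero minimum in the reference era")
    df["revision_pct"] = (
        100.0 * (df["min_post"] - df["min_priori"]) / df["min_post"]
    )
    return df[["node_label", "min_post", "min_priori", "revision_pct"]]


def max_abs_revision(table: pd.DataFrame) -> float:
    """Largest absolute percent revision across nodes."""
    return float(revision_percentages(table)["revision_pct"].abs().max())
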