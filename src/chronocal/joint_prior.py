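"""Joint priors on node ages and prior-only MCMC sampling.

The user writes down one calibration density per calibrated clade, but no
Bayesian dating program samples those densities as written: the joint prior
on the full node-age vector is *truncated* to the region where every
ancestor is older than its descendants, and combined with a tree-prior
kernel for the remaining nodes.  Two constructions are implemented:

``conditional``
    Product of the specified calibration densities over calibrated nodes,
    times a tree-prior kernel for the *uncalibrated* node ages conditional
    on the calibrated ones, truncated to the order-valid region.  The root
    must carry an upper-bounded calibration.

``multiplicative``
    Product of the specified calibration densities times the tree-prior
    kernel over *all* non-root internal node ages, truncated likewise.
    Calibrated nodes are thus doubly weighted by calibration and tree
    prior, which is what makes effective priors deviate from specified ones
    even with a single calibration under this construction.

Sampling the joint prior without sequence data ("prior-only" runs) exposes
the *effective* marginal priors, which are what the diagnostics modules
compare against the specified densities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .calibrations import Calibration
from .timetree import TimeTree

__all__ = [
    "TreePriorParams",
    "JointPrior",
    "PriorSampleSet",
    "MCMCSettings",
    "log_joint_prior",
    "bd_kernel_logpdf",
    "sample_prior",
    "effective_marginal",
    "InfeasibleCalibrationError",
    "ConfigurationError",
]


class ConfigurationError(ValueError):
    """Calibration/construction combinations that cannot define a prior."""


class InfeasibleCalibrationError(ConfigurationError):
    """A calibration pair with zero-volume joint support."""


@dataclass(frozen=True)
class TreePriorParams:
    """Tree-prior kernel for node ages given the root age.

    ``kernel='uniform'`` spreads each non-root internal node age uniformly
    on ``(0, t_root)`` (order statistics of i.i.d. uniforms, once truncated).
    ``kernel='birth-death'`` uses the standard birth--death node-age density
    conditional on the root age with per-lineage birth rate ``birth`` (per
    Ma), death rate ``death`` and extant-species sampling fraction ``rho``.
    """

    birth: float = 1.0
    death: float = 1.0
    rho: float = 0.1
    kernel: str = "uniform"

    def __post_init__(self):
        if self.kernel not in ("uniform", "birth-death"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if not self.birth > 0 or self.death < 0 or not (0 <= self.rho <= 1):
            raise ValueError("require birth > 0, death >= 0, 0 <= rho <= 1")


def _bd_p0(t, lam, mu, rho):
    if abs(lam - mu) < 1e-12:
        return rho / (1.0 + rho * lam * t)
    return (
        rho
        * (lam - mu)
        / (rho * lam + (lam * (1 - rho) - mu) * np.exp(-(lam - mu) * t))
    )


def bd_kernel_logpdf(age, t_root, params: TreePriorParams):
    """Log density of one non-root node age given the root age.

    Under the uniform kernel this is ``-log(t_root)`` on ``(0, t_root)``.
    Under the birth--death kernel it is the classical conditional node-age
    density, which integrates to 1 on ``(0, t_root)`` and collapses to the
    uniform kernel in the critical, vanishing-sampling limit
    (``birth == death``, ``rho -> 0``).
    """
    age = np.asarray(age, dtype=float)
    inside = (age > 0) & (age < t_root)
    if params.kernel == "uniform":
        out = np.full_like(age, -math.log(t_root))
        return np.where(inside, out, -np.inf)
    lam, mu, rho = params.birth, params.death, params.rho
    p0 = _bd_p0(age, lam, mu, rho)
    p0_root = float(_bd_p0(np.asarray(t_root), lam, mu, rho))
    v = 1.0 - p0_root * math.exp((mu - lam) * t_root) / rho
    with np.errstate(divide="ignore", invalid="ignore"):
        logg = (
            math.log(lam)
            + 2.0 * np.log(p0)
            + (mu - lam) * age
            - math.log(rho)
            - math.log(v)
        )
    return np.where(inside, logg, -np.inf)


# ---------------------------------------------------------------------------
# fast scalar calibration evaluators for the sampler hot path


class _ScalarCal:
    """Scalar logpdf/cdf/quantile for one calibration (hard minimum only)."""

    __slots__ = (
        "kind", "tL", "tU", "logh", "h", "lamU", "tailR", "coretop",
        "A", "s", "mass", "locdf", "logC",
    )

    def __init__(self, cal: Calibration):
        self.tL = cal.t_L
        if cal.family == "uniform":
            if cal.tail_L != 0:
                raise NotImplementedError(
                    "sampler fast path requires a hard minimum (tail_L = 0)"
                )
            self.kind = 1
            self.tU = cal.t_U
            self.h = (1.0 - cal.tail_R) / (cal.t_U - cal.t_L)
            self.logh = math.log(self.h)
            self.tailR = cal.tail_R
            self.lamU = self.h / cal.tail_R if cal.tail_R > 0 else math.inf
            self.coretop = 1.0 - cal.tail_R
        else:
            self.kind = 2
            self.A = cal.t_L * (1.0 + cal.p)
            self.s = cal.c * cal.t_L
            self.mass = 0.5 + math.atan(cal.p / cal.c) / math.pi
            self.locdf = 0.5 + math.atan((cal.t_L - self.A) / self.s) / math.pi
            self.logC = math.log(self.s / (math.pi * self.mass))

    def logpdf(self, t: float) -> float:
        if t < self.tL:
            return -math.inf
        if self.kind == 1:
            if t <= self.tU:
                return self.logh
            if self.lamU == math.inf:
                return -math.inf
            return self.logh - self.lamU * (t - self.tU)
        d = t - self.A
        return self.logC - math.log(d * d + self.s * self.s)

    def cdf(self, t: float) -> float:
        if t <= self.tL:
            return 0.0
        if self.kind == 1:
            if t <= self.tU:
                return self.h * (t - self.tL)
            if self.lamU == math.inf:
                return 1.0
            return self.coretop + self.tailR * (
                1.0 - math.exp(-self.lamU * (t - self.tU))
            )
        return (0.5 + math.atan((t - self.A) / self.s) / math.pi - self.locdf) / self.mass

    def quantile(self, q: float) -> float:
        if self.kind == 1:
            if q <= self.coretop:
                return self.tL + q / self.h
            frac = min((q - self.coretop) / self.tailR, 1.0 - 1e-16)
            return self.tU - math.log1p(-frac) / self.lamU
        x = q * self.mass + self.locdf - 0.5
        return max(self.A + self.s * math.tan(math.pi * x), self.tL)


# ---------------------------------------------------------------------------


class JointPrior:
    """The joint prior density over internal node ages of a fixed tree."""

    def __init__(
        self,
        tree: TimeTree,
        calibrations: list[Calibration],
        params: TreePriorParams | None = None,
        construction: str = "conditional",
    ):
        if construction not in ("conditional", "multiplicative"):
            raise ConfigurationError(f"unknown construction {construction!r}")
        self.tree = tree
        self.params = params or TreePriorParams()
        self.construction = construction
        self.cal_by_node: dict[int, Calibration] = {}
        for cal in calibrations:
            try:
                node = tree.node_by_label(cal.node_label)
            except KeyError:
                raise ConfigurationError(
                    f"calibration references unknown clade {cal.node_label!r}"
                ) from None
            if tree.is_tip(node):
                raise ConfigurationError(
                    f"calibration {cal.node_label!r} attaches to a tip"
                )
            if node in self.cal_by_node:
                raise ConfigurationError(
                    f"two calibrations attach to node {cal.node_label!r}"
                )
            self.cal_by_node[node] = cal

        root_cal = self.cal_by_node.get(tree.root)
        if root_cal is None:
            raise ConfigurationError(
                "the root must carry a calibration: the conditional "
                "construction requires an upper-bounded root, and the "
                "multiplicative construction refuses a silent default"
            )
        if construction == "conditional" and not root_cal.has_upper_bound:
            raise ConfigurationError(
                "conditional construction requires an upper-bounded "
                "(uniform soft-maximum) calibration at the root"
            )

        self._check_feasibility()

        internal = set(tree.internal_nodes)
        if construction == "conditional":
            self.kernel_nodes = sorted(
                internal - set(self.cal_by_node) - {tree.root}
            )
        else:
            self.kernel_nodes = sorted(internal - {tree.root})
        self._kernel_arr = np.array(self.kernel_nodes, dtype=np.int64)

    def _check_feasibility(self):
        tree = self.tree
        for node, cal in self.cal_by_node.items():
            v = int(tree.parent[node])
            while v != -1:
                anc = self.cal_by_node.get(v)
                if (
                    anc is not None
                    and anc.has_upper_bound
                    and anc.tail_R == 0
                    and cal.t_L >= anc.t_U
                ):
                    raise InfeasibleCalibrationError(
                        f"calibration {cal.node_label!r} (minimum {cal.t_L} Ma) "
                        f"cannot fit below the hard maximum {anc.t_U} Ma of "
                        f"ancestor {anc.node_label!r}"
                    )
                v = int(tree.parent[v])

    def log_density(self, ages: np.ndarray) -> float:
        """Log joint prior density; ``-inf`` outside the order-valid region."""
        tree = self.tree
        ages = np.asarray(ages, dtype=float)
        par = tree.parent
        nonroot = par >= 0
        if np.any(ages[nonroot] >= ages[par[nonroot]]):
            return -math.inf
        if np.any(ages[: tree.n_tips] != 0.0):
            return -math.inf
        total = 0.0
        for node, cal in self.cal_by_node.items():
            lp = float(cal.logpdf(ages[node]))
            if not np.isfinite(lp):
                return -math.inf
            total += lp
        if self._kernel_arr.size:
            k = bd_kernel_logpdf(
                ages[self._kernel_arr], float(ages[tree.root]), self.params
            )
            if not np.all(np.isfinite(k)):
                return -math.inf
            total += float(k.sum())
        return total


def log_joint_prior(
    ages,
    tree: TimeTree,
    calibrations: list[Calibration],
    params: TreePriorParams | None = None,
    construction: str = "conditional",
) -> float:
    """Convenience wrapper: evaluate the joint prior at one age vector."""
    return JointPrior(tree, calibrations, params, construction).log_density(ages)


# ---------------------------------------------------------------------------
# sampling


@dataclass(frozen=True)
class MCMCSettings:
    """Metropolis-within-Gibbs settings.

    One iteration is a full sweep updating every internal node once (plus,
    in posterior runs, one clock-rate move).  ``burn_in`` is a fraction of
    ``n_iter``; step widths are tuned during burn-in only.
    """

    n_iter: int = 200_000
    burn_in: float = 0.25
    thin: int = 20

    def __post_init__(self):
        if self.n_iter < 10 or not (0 <= self.burn_in < 1) or self.thin < 1:
            raise ValueError("invalid MCMC settings")


@dataclass
class PriorSampleSet:
    """Stored MCMC draws of the internal node-age vector."""

    draws: np.ndarray                 # (n_draws, n_internal)
    node_ids: list[int]
    node_names: list[str]
    tree: TimeTree
    seed: int
    n_iter: int
    burn_in: int
    thin: int
    acceptance: dict = field(default_factory=dict)
    rate_draws: np.ndarray | None = None
    _ess: dict | None = field(default=None, repr=False)

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    def _col(self, node) -> int:
        if isinstance(node, str):
            node = self.tree.node_by_label(node)
        return self.node_ids.index(int(node))

    def column(self, node) -> np.ndarray:
        """Draws for one node (by internal index or clade label)."""
        return self.draws[:, self._col(node)]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.draws, columns=self.node_names)

    @property
    def ess(self) -> dict:
        """Per-node effective sample size (autocorrelation-adjusted)."""
        if self._ess is None:
            import arviz as az

            self._ess = {
                name: float(az.ess(np.asarray(self.draws[:, j])))
                for j, name in enumerate(self.node_names)
            }
        return self._ess

    def low_ess(self, threshold: float = 200.0) -> list[str]:
        return [k for k, v in self.ess.items() if v < threshold]

    def order_valid_fraction(self) -> float:
        """Fraction of stored draws satisfying ancestor > descendant."""
        tree = self.tree
        ages = np.zeros((self.n_draws, tree.n_nodes))
        ages[:, self.node_ids] = self.draws
        ok = np.ones(self.n_draws, dtype=bool)
        for v in range(tree.n_nodes):
            p = int(tree.parent[v])
            if p != -1:
                ok &= ages[:, p] > ages[:, v]
        return float(ok.mean())


def _subtree_minima(jp: JointPrior) -> np.ndarray:
    """Per-node max of calibration minima over the node's subtree."""
    tree = jp.tree
    m = np.zeros(tree.n_nodes)
    for v in range(tree.n_nodes):  # tips first, then internal postorder
        if not tree.is_tip(v):
            m[v] = max(m[c] for c in tree.children[v])
        cal = jp.cal_by_node.get(v)
        if cal is not None:
            m[v] = max(m[v], cal.t_L)
    return m


def _initial_ages(jp: JointPrior) -> np.ndarray:
    tree = jp.tree
    m = _subtree_minima(jp)
    ages = np.zeros(tree.n_nodes)
    root_cal = jp.cal_by_node[tree.root]
    root0 = float(root_cal.quantile(0.5))
    root0 = max(root0, m[tree.root] * 1.05 + 1.0)
    ages[tree.root] = root0
    for v in tree.preorder_internal():
        if v == tree.root:
            continue
        hi = ages[int(tree.parent[v])]
        lo = m[v]
        if lo >= hi:
            raise InfeasibleCalibrationError(
                f"cannot initialise node {tree.node_name(v)!r}: subtree "
                f"minimum {lo:.6g} Ma meets or exceeds parent age {hi:.6g} Ma"
            )
        ages[v] = lo + 0.5 * (hi - lo)
    return ages


class _Sampler:
    """Metropolis-within-Gibbs over internal node ages (optionally + rate).

    Non-root calibrated nodes are updated by exact inverse-cdf draws from
    their specified calibration truncated to the current (oldest child,
    parent) interval -- a valid independence proposal whose Hastings ratio
    reduces to the tree-kernel and likelihood terms, and to certain
    acceptance under the conditional/uniform-kernel prior.  Uncalibrated
    nodes slide uniformly within their interval.  The root mixes the
    truncated-calibration draw with a tuned multiplier move.
    """

    def __init__(self, jp: JointPrior, rng: np.random.Generator,
                 likelihood=None, clock=None, rate0: float | None = None):
        self.jp = jp
        self.rng = rng
        self.likelihood = likelihood
        self.clock = clock
        tree = jp.tree
        self.tree = tree
        self.ages = _initial_ages(jp)
        self.order = tree.preorder_internal()
        self.scal = {
            v: _ScalarCal(cal) for v, cal in jp.cal_by_node.items()
            if cal.tail_L == 0
        }
        self.generic = {
            v: cal for v, cal in jp.cal_by_node.items() if cal.tail_L != 0
        }
        self.kernel_set = set(jp.kernel_nodes)
        self.uniform_kernel = jp.params.kernel == "uniform"
        self.root_step = 0.5
        self.rate = rate0
        self.acc = {"node": 0, "node_prop": 0, "root": 0, "root_prop": 0,
                    "rootm": 0, "rootm_prop": 0, "rate": 0, "rate_prop": 0}
        self.rate_step = 0.4
        if likelihood is not None:
            likelihood.full_update(self.ages, self.rate)

    # kernel log terms -----------------------------------------------------

    def _kernel_term(self, v: int, t: float, t_root: float) -> float:
        if v not in self.kernel_set:
            return 0.0
        if self.uniform_kernel:
            return -math.log(t_root)
        return float(bd_kernel_logpdf(t, t_root, self.jp.params))

    def _kernel_sum(self, t_root: float) -> float:
        arr = self.jp._kernel_arr
        if arr.size == 0:
            return 0.0
        if self.uniform_kernel:
            return -arr.size * math.log(t_root)
        return float(
            bd_kernel_logpdf(self.ages[arr], t_root, self.jp.params).sum()
        )

    def _cal_logpdf(self, v: int, t: float) -> float:
        sc = self.scal.get(v)
        if sc is not None:
            return sc.logpdf(t)
        cal = self.generic.get(v)
        if cal is not None:
            return float(cal.logpdf(t))
        return 0.0

    # moves ----------------------------------------------------------------

    def _lik_delta(self, v: int, t_new: float) -> float:
        if self.likelihood is None:
            return 0.0
        return self.likelihood.propose_age(v, t_new)

    def _commit(self, v: int, t_new: float, accept: bool):
        if self.likelihood is not None:
            if accept:
                self.likelihood.accept()
            else:
                self.likelihood.reject()
        if accept:
            self.ages[v] = t_new

    def _update_nonroot(self, v: int):
        tree = self.tree
        ages = self.ages
        low = max(ages[c] for c in tree.children[v])
        high = ages[int(tree.parent[v])]
        if high - low <= 0:
            return
        t_old = ages[v]
        t_root = ages[tree.root]
        sc = self.scal.get(v)
        self.acc["node_prop"] += 1
        if sc is not None:
            # truncated inverse-cdf independence proposal from the
            # specified calibration; its density cancels in the ratio
            c0, c1 = sc.cdf(low), sc.cdf(high)
            if c1 - c0 < 1e-12:
                t_new = low + self.rng.random() * (high - low)
                dlog = self._cal_logpdf(v, t_new) - self._cal_logpdf(v, t_old)
            else:
                t_new = sc.quantile(c0 + self.rng.random() * (c1 - c0))
                if not (low < t_new < high):
                    return
                dlog = 0.0
        else:
            t_new = low + self.rng.random() * (high - low)
            dlog = self._cal_logpdf(v, t_new) - self._cal_logpdf(v, t_old)
        dlog += self._kernel_term(v, t_new, t_root) - self._kernel_term(
            v, t_old, t_root
        )
        if math.isnan(dlog):  # -inf minus -inf: both states outside support
            dlog = 0.0
        if dlog == -math.inf:
            return
        dlog += self._lik_delta(v, t_new)
        ok = dlog >= 0 or self.rng.random() < math.exp(dlog)
        self._commit(v, t_new, ok)
        if ok:
            self.acc["node"] += 1

    def _update_root(self):
        tree = self.tree
        ages = self.ages
        root = tree.root
        low = max(ages[c] for c in tree.children[root])
        t_old = ages[root]
        sc = self.scal.get(root)
        self.acc["root_prop"] += 1
        use_gibbs = sc is not None and self.rng.random() < 0.5
        if use_gibbs:
            c0 = sc.cdf(low)
            if 1.0 - c0 < 1e-12:
                return
            t_new = sc.quantile(c0 + self.rng.random() * (1.0 - c0))
            if t_new <= low:
                return
            dlog = 0.0  # calibration density cancels against the proposal
        else:
            self.acc["rootm_prop"] += 1
            e = math.exp(self.root_step * (self.rng.random() - 0.5))
            t_new = t_old * e
            if t_new <= low:
                return
            dlog = self._cal_logpdf(root, t_new) - self._cal_logpdf(root, t_old)
            dlog += math.log(e)  # multiplier Jacobian
        dlog += self._kernel_sum(t_new) - self._kernel_sum(t_old)
        if dlog == -math.inf:
            return
        dlog += self._lik_delta(root, t_new)
        ok = dlog >= 0 or self.rng.random() < math.exp(dlog)
        self._commit(root, t_new, ok)
        if ok:
            self.acc["root"] += 1
            if not use_gibbs:
                self.acc["rootm"] += 1

    def _update_rate(self):
        e = math.exp(self.rate_step * (self.rng.random() - 0.5))
        r_new = self.rate * e
        dlog = self.clock.log_rate_prior(r_new) - self.clock.log_rate_prior(
            self.rate
        )
        dlog += math.log(e)
        dlog += self.likelihood.propose_rate(r_new)
        self.acc["rate_prop"] += 1
        if dlog >= 0 or self.rng.random() < math.exp(dlog):
            self.likelihood.accept()
            self.rate = r_new
            self.acc["rate"] += 1
        else:
            self.likelihood.reject()

    def sweep(self):
        for v in self.order:
            if v == self.tree.root:
                self._update_root()
            else:
                self._update_nonroot(v)
        if self.likelihood is not None and self.clock is not None:
            self._update_rate()

    def tune(self):
        # keep multiplier acceptance inside the 0.2--0.5 band
        if self.acc["rootm_prop"] >= 100:
            r = self.acc["rootm"] / self.acc["rootm_prop"]
            if r > 0.5:
                self.root_step = min(self.root_step * 1.4, 5.0)
            elif r < 0.2:
                self.root_step = max(self.root_step / 1.4, 1e-3)
            self.acc["rootm"] = self.acc["rootm_prop"] = 0
        if self.acc["rate_prop"] >= 200:
            r = self.acc["rate"] / self.acc["rate_prop"]
            if r > 0.5:
                self.rate_step *= 1.4
            elif r < 0.2:
                self.rate_step /= 1.4
            self.acc["rate"] = self.acc["rate_prop"] = 0


def _run_chain(jp, mcmc: MCMCSettings, seed: int,
               likelihood=None, clock=None, rate0=None):
    rng = np.random.default_rng(seed)
    smp = _Sampler(jp, rng, likelihood=likelihood, clock=clock, rate0=rate0)
    tree = jp.tree
    internal = tree.internal_nodes
    n_burn = int(mcmc.n_iter * mcmc.burn_in)
    n_keep = (mcmc.n_iter - n_burn) // mcmc.thin
    draws = np.empty((n_keep, len(internal)))
    rates = np.empty(n_keep) if likelihood is not None and clock is not None else None
    for it in range(n_burn):
        smp.sweep()
        if it % 200 == 199:
            smp.tune()
    k = 0
    for it in range(mcmc.n_iter - n_burn):
        smp.sweep()
        if (it + 1) % mcmc.thin == 0 and k < n_keep:
            draws[k] = smp.ages[internal]
            if rates is not None:
                rates[k] = smp.rate
            k += 1
    acc = dict(smp.acc)
    return draws[:k], (rates[:k] if rates is not None else None), acc, smp


def sample_prior(
    tree: TimeTree,
    calibrations: list[Calibration],
    params: TreePriorParams | None = None,
    construction: str = "conditional",
    mcmc: MCMCSettings | None = None,
    seed: int = 0,
) -> PriorSampleSet:
    """Prior-only MCMC: sample the joint time prior with no sequence data.

    This is the package's analogue of running a dating program with an
    empty alignment, which is how effective priors are exposed for
    comparison against the specified calibration densities.
    """
    mcmc = mcmc or MCMCSettings()
    jp = JointPrior(tree, calibrations, params, construction)
    draws, _, acc, _ = _run_chain(jp, mcmc, seed)
    internal = tree.internal_nodes
    n_burn = int(mcmc.n_iter * mcmc.burn_in)
    return PriorSampleSet(
        draws=draws,
        node_ids=internal,
        node_names=[tree.node_name(v) for v in internal],
        tree=tree,
        seed=seed,
        n_iter=mcmc.n_iter,
        burn_in=n_burn,
        thin=mcmc.thin,
        acceptance=acc,
    )


def effective_marginal(samples: PriorSampleSet, node) -> dict:
    """Summary of one node's effective marginal prior.

    Empirical mean and (2.5, 50, 97.5)% quantiles (linear interpolation),
    plus a Freedman--Diaconis histogram, with sample provenance attached.
    """
    x = samples.column(node)
    if x.size == 0:
        raise RuntimeError("empty sample set")
    q = np.quantile(x, [0.025, 0.5, 0.975])
    if np.ptp(x) == 0:
        edges = np.array([x[0] - 0.5, x[0] + 0.5])
    else:
        edges = np.histogram_bin_edges(x, bins="fd")
    hist, edges = np.histogram(x, bins=edges, density=True)
    return {
        "mean": float(x.mean()),
        "q2.5": float(q[0]),
        "q50": float(q[1]),
        "q97.5": float(q[2]),
        "hist": hist,
        "bin_edges": edges,
        "n": int(x.size),
        "seed": samples.seed,
    }
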