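"""Joint-prior construction, truncation, kernels and prior-only sampling."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from chronocal import (
    Calibration,
    ConfigurationError,
    InfeasibleCalibrationError,
    MCMCSettings,
    TreePriorParams,
    bd_kernel_logpdf,
    effective_marginal,
    log_joint_prior,
    parse_newick,
    sample_prior,
)

FAST = MCMCSettings(n_iter=30_000, burn_in=0.2, thin=2)


def inner_marginal_quadrature(cal_root, cal_inner, grid):
    """Truncated joint f(t1, t2) ∝ fR(t1) fI(t2) 1{t1 > t2}: the inner
    node's marginal by outer integration, normalised on the grid."""
    upper = np.array(
        [integrate.quad(cal_root.pdf, t, np.inf, limit=200)[0] for t in grid]
    )
    m = cal_inner.pdf(grid) * upper
    return m / np.trapezoid(m, grid)


class TestLogJointPrior:
    def test_single_node_reduces_to_calibration_density(self, two_tip_tree):
        cal = Calibration("R", "uniform", 10, 20)
        ages = np.array([0.0, 0.0, 15.0])
        got = log_joint_prior(ages, two_tip_tree, [cal])
        assert got == pytest.approx(float(cal.logpdf(15.0)))

    def test_order_violation_is_minus_inf(self, three_tip_tree, nested_cals):
        ages = np.array([0.0, 0.0, 0.0, 14.0, 12.0])  # inner older than root
        assert log_joint_prior(ages, three_tip_tree, nested_cals) == -math.inf

    def test_conditional_marginal_deviates_from_specified(
        self, three_tip_tree, nested_cals
    ):
        """Truncation reshapes the inner node's marginal: total variation
        against its specified uniform density exceeds 0.01 (quadrature)."""
        grid = np.linspace(0.01, 60, 2001)
        m = inner_marginal_quadrature(nested_cals[0], nested_cals[1], grid)
        spec = nested_cals[1].pdf(grid)
        spec = spec / np.trapezoid(spec, grid)
        tv = 0.5 * np.trapezoid(np.abs(m - spec), grid)
        assert tv > 0.01

    def test_conditional_requires_bounded_root(self, three_tip_tree):
        cals = [
            Calibration("R", "cauchy", 10.0, p=0.1, c=0.5),
            Calibration("I", "uniform", 5, 15),
        ]
        with pytest.raises(ConfigurationError, match="root"):
            log_joint_prior(np.zeros(5), three_tip_tree, cals)

    def test_duplicate_calibration_rejected(self, two_tip_tree):
        cals = [
            Calibration("R", "uniform", 10, 20),
            Calibration("R", "uniform", 12, 22),
        ]
        with pytest.raises(ConfigurationError, match="two calibrations"):
            log_joint_prior(np.zeros(3), two_tip_tree, cals)

    def test_infeasible_pair_is_loud(self, three_tip_tree):
        cals = [
            Calibration("R", "uniform", 10, 20, tail_R=0.0),  # hard max 20
            Calibration("I", "uniform", 25, 40),              # min above it
        ]
        with pytest.raises(InfeasibleCalibrationError, match="cannot fit"):
            log_joint_prior(np.zeros(5), three_tip_tree, cals)


class TestBirthDeathKernel:
    @pytest.mark.parametrize("lam,mu,rho", [(1, 1, 0.1), (2, 1, 0.5), (1, 0.5, 0.9)])
    def test_normalizes_on_zero_to_root(self, lam, mu, rho):
        params = TreePriorParams(lam, mu, rho, kernel="birth-death")
        mass, _ = integrate.quad(
            lambda a: np.exp(bd_kernel_logpdf(a, 10.0, params)), 0, 10, limit=200
        )
        assert mass == pytest.approx(1.0, abs=1e-6)

    def test_uniform_kernel_value(self):
        params = TreePriorParams(kernel="uniform")
        assert bd_kernel_logpdf(50.0, 200.0, params) == pytest.approx(
            math.log(1 / 200)
        )
        assert bd_kernel_logpdf(250.0, 200.0, params) == -math.inf

    def test_critical_low_sampling_limit_is_uniform(self):
        params = TreePriorParams(1.0, 1.0, 1e-8, kernel="birth-death")
        ages = np.linspace(0.5, 9.5, 19)
        got = bd_kernel_logpdf(ages, 10.0, params)
        assert np.max(np.abs(got - (-math.log(10.0)))) < 1e-4


class TestSamplePrior:
    def test_single_calibration_fidelity(self, two_tip_tree, testudines_root_cal):
        """With one root calibration and the conditional construction, the
        effective prior equals the specified density (nothing to truncate)."""
        s = sample_prior(
            two_tip_tree,
            [testudines_root_cal],
            mcmc=MCMCSettings(n_iter=110_000, burn_in=0.1, thin=1),
            seed=3,
        )
        ks = stats.kstest(s.column("R"), testudines_root_cal.cdf).statistic
        assert ks < 0.02
        assert s.order_valid_fraction() == 1.0

    def test_sampled_marginal_matches_quadrature(self, three_tip_tree, nested_cals):
        s = sample_prior(
            three_tip_tree,
            nested_cals,
            mcmc=MCMCSettings(n_iter=150_000, burn_in=0.2, thin=2),
            seed=5,
        )
        edges = np.linspace(0, 40, 81)
        h, _ = np.histogram(s.column("I"), bins=edges, density=True)
        centers = 0.5 * (edges[1:] + edges[:-1])
        grid = np.linspace(0.01, 40, 2001)
        m = inner_marginal_quadrature(nested_cals[0], nested_cals[1], grid)
        m_bin = np.interp(centers, grid, m)
        m_bin /= m_bin.sum() * (edges[1] - edges[0])
        tv = 0.5 * np.sum(np.abs(h - m_bin)) * (edges[1] - edges[0])
        assert tv < 0.02

    def test_constructions_differ_at_root(self, three_tip_tree, nested_cals):
        """Conditional and multiplicative joint priors put measurably
        different marginals on the root (TV > 0.01)."""
        sc = sample_prior(
            three_tip_tree, nested_cals, construction="conditional", mcmc=FAST, seed=5
        )
        sm = sample_prior(
            three_tip_tree, nested_cals, construction="multiplicative",
            mcmc=FAST, seed=5,
        )
        edges = np.linspace(0, 60, 121)
        hc, _ = np.histogram(sc.column("R"), bins=edges)
        hm, _ = np.histogram(sm.column("R"), bins=edges)
        tv = 0.5 * np.abs(hc / hc.sum() - hm / hm.sum()).sum()
        assert tv > 0.01

    def test_all_draws_order_valid_and_deterministic(
        self, three_tip_tree, nested_cals
    ):
        a = sample_prior(three_tip_tree, nested_cals, mcmc=FAST, seed=11)
        b = sample_prior(three_tip_tree, nested_cals, mcmc=FAST, seed=11)
        assert a.order_valid_fraction() == 1.0
        assert np.array_equal(a.draws, b.draws)

    def test_bd_kernel_sampling_runs_and_keeps_order(self):
        tree = parse_newick("(((A:2,B:2)X:3,C:5)Y:5,D:10)R;")
        cals = [Calibration("R", "uniform", 8, 15)]
        params = TreePriorParams(1.0, 1.0, 0.1, kernel="birth-death")
        s = sample_prior(tree, cals, params=params, mcmc=FAST, seed=2)
        assert s.order_valid_fraction() == 1.0
        # uncalibrated internal ages stay inside (0, root age)
        assert (s.column("X") < s.column("R")).all()


class TestEffectiveMarginal:
    def test_quantiles_match_specified_for_single_calibration(
        self, two_tip_tree, testudines_root_cal
    ):
        s = sample_prior(
            two_tip_tree,
            [testudines_root_cal],
            mcmc=MCMCSettings(n_iter=110_000, burn_in=0.1, thin=1),
            seed=3,
        )
        em = effective_marginal(s, "R")
        expect = float(testudines_root_cal.quantile(0.025))
        assert em["q2.5"] == pytest.approx(expect, abs=2.0)
        assert em["n"] == s.n_draws and em["seed"] == 3

    def test_degenerate_constant_chain(self, two_tip_tree, testudines_root_cal):
        s = sample_prior(two_tip_tree, [testudines_root_cal], mcmc=FAST, seed=0)
        s.draws = np.full_like(s.draws, 42.0)
        em = effective_marginal(s, "R")
        assert em["q2.5"] == em["q50"] == em["q97.5"] == 42.0
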