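# Methods

## Time trees

Chronograms are stored as node-age vectors (Ma before present) over a
fixed, rooted, strictly bifurcating topology with extant tips at age 0;
branch lengths are derived on output as `age(parent) − age(child)`.  Ages
are the primary objects because every prior in the package is a prior on
node ages.  Parsing (via dendropy) rejects polytomies, unifurcations,
non-contemporaneous tips (tolerance 1e-6 Ma, covering round-trip float
noise) and tied parent/child ages (tolerance 1e-9 Ma): zero-length internal
branches would break density evaluation downstream.  Clades are addressed
by internal-node label or by MRCA of a tip set.

## Calibration densities

Both families are anchored on a hard minimum t_L (zero mass below, unless
a lower tail mass is explicitly configured).

**Uniform soft-bound.** Constant density on [t_L, t_U] carrying mass
1 − tail_L − tail_R, exponential upper tail of total mass tail_R (default
0.025).  The published sources state the tail mass but not the tail's
functional form; we take the minimal contract — fixed mass plus density
continuity at t_U — which fixes the decay rate at
λ = (1 − tail_R)/(tail_R (t_U − t_L)).  A configurable lower tail
(truncated at age 0, with exact renormalisation) exists but defaults to
hard (tail_L = 0).

**Truncated Cauchy.** Cauchy with location A = t_L(1 + p) and scale
s = c·t_L renormalised on [t_L, ∞).  p and c are dimensionless; the mode
sits at t_L(1 + p) and the 97.5% quantile is strictly increasing in c, so
the (p, c) grid spans "minimum is nearly the age" to "the divergence may
long predate the fossil".  cdf and quantile are closed-form (arctangent),
and sampling is by inverse cdf.

## Joint prior constructions and truncation

Given calibrations and a tree-prior kernel, the log joint prior is

- conditional: Σ log f_cal(t_i) over calibrated nodes + Σ log g(t_j | t_root)
  over uncalibrated internal nodes, −∞ outside the ancestor-older-than-
  descendant region.  The root must carry an upper-bounded calibration.
- multiplicative: the same calibration sum plus the kernel over *all*
  non-root internal nodes.  Calibrated nodes are doubly weighted, which is
  why this construction distorts even single-calibration priors; the extra
  (1/t_root) factors per calibrated node also pull the root marginal
  younger than under the conditional construction — the two constructions'
  characteristic root-skew contrast.

Both constructions require an explicit root calibration; there is no
silent default for the root's upper limit.  Calibration pairs whose
supports cannot nest (descendant minimum at or above an ancestral hard
maximum) raise an error at construction rather than being silently
truncated — silent truncation is precisely the failure mode the
diagnostics exist to expose.

The kernel g is either uniform-order-statistics, g = 1/t_root on
(0, t_root) (default: the truncation phenomena under study do not depend
on the kernel choice), or the standard birth–death node-age density
conditional on the root age with parameters (λ, μ, ρ), default (1, 1, 0.1).
The birth–death form integrates to 1 on (0, t_root) and collapses to the
uniform kernel as λ → μ, ρ → 0 (both verified by quadrature in the tests).

## MCMC

A Metropolis-within-Gibbs sampler over internal node ages (plus, in
posterior runs, the clock rate).  One iteration sweeps all internal nodes.
Moves:

- non-root nodes: an inverse-cdf draw from the node's own specified
  calibration truncated to the current (oldest child, parent) interval.
  This is an independence proposal whose density cancels the calibration
  term in the Hastings ratio, leaving only kernel/likelihood terms — under
  the conditional construction with the uniform kernel it is an exact
  Gibbs update.  Uncalibrated nodes slide uniformly in their interval.
- root: a 50/50 mixture of the truncated-calibration draw and a multiplier
  proposal (Jacobian included) whose step is tuned during burn-in only to
  an acceptance rate of 0.2–0.5 (soft bounds leave the root support
  unbounded above, so a scale move is the safe default).
- clock rate: a tuned multiplier against the gamma rate prior.

Defaults: 200,000 sweeps, 25% burn-in, thinning 20.  (Published MCMC
iteration counts of order 10^6 refer to comparable total single-parameter
update counts; one sweep here updates every node.)  Per-node effective
sample sizes are computed through arviz and chains flag any node below
ESS 200.  Every stored draw satisfies the age-order constraint by
construction; the test suite asserts this, plus exact determinism given a
seed, sampling fidelity against the specified density when only a root
calibration exists (KS < 0.02 at 1e5 draws), and agreement with direct
2-D quadrature of the truncated joint on three-tip fixtures (TV < 0.02).

## Dating engine

Strict clock, JC69, Felsenstein pruning over unique site patterns with
cached per-node partials: an age update recomputes only the focal-to-root
path (restored on rejection); a rate update recomputes everything.  This
is deliberately the simplest engine that exhibits prior-driven effects —
relaxed clocks, richer substitution models and approximate likelihoods are
out of scope.  The rate prior is gamma (default shape 2) with a mean that
can be set crudely from the data (mean pairwise JC distance over twice a
root-age guess).  Core laws tested: pruning equals brute-force state
enumeration on small trees; with a zero-length alignment the posterior
equals the prior (the field's standard prior-exposure diagnostic); on 50
synthetic 8-tip, 2000-site studies, 95% posterior intervals cover ≥ 90% of
true node ages and the posterior rate is within 10% of truth on average.

## Cross-validation statistics

Leave-one-calibration-in rounds: the tree is dated with the focal
calibration plus the root's soft maximum only (the root *minimum* is
dropped during a round, so the focal alone sets the timescale; an option
instead pins the focal at its minimum age — the original protocol's
fixed-age style).  Per round, D̄ and SS aggregate (estimate − minimum)
differences, or signed min–max window discrepancies (zero inside the
window, estimate − maximum above, estimate − minimum below; this sign
convention is stated explicitly because published prose is ambiguous about
the sign of "slightly negative" values).  The pooled statistic is
s = ΣSS/(n(n−1)).  Sequential removal deletes the largest-SS calibration
per step (label-order tie-break), restricting every surviving round to the
surviving target set, and reports s, ΣSS, n(n−1) and their percent
changes: because the denominator shrinks quadratically, s can *rise* as
"inconsistent" calibrations are removed — the removal trace makes that
mechanism explicit, and a worked example (SS = {125, 80, 45}: s rises
41.67 → 62.5 after removing the worst) is frozen in the tests.  No named
significance test accompanies removal steps in the source material, so an
assumption-light nonparametric bootstrap over the rounds' SS contributions
(default 10^4 resamples) attaches an interval to each step's s; it is
clearly this package's choice.  Rounds may be fed from a frozen stub table
instead of live MCMC, decoupling statistic correctness from sampler noise;
all statistics are checked against an independently written brute-force
implementation to 1e-12.

## Diagnostics

Specified-vs-effective comparisons summarise effective marginals by
histogram and empirical quantiles, not KDE: hard minima create genuine
density discontinuities that kernel smoothing would smear.  The "95% prior
interval" is equal-tail (2.5%, 97.5%), matching the excess definitions
(lower_excess = effective 2.5% quantile − specified t_L; note that even a
perfectly faithful sampler has a positive lower excess, since the
specified density's own 2.5% quantile sits above a hard minimum).
Total-variation distances are computed on a 512-bin grid spanning the
union of supports; construction contrasts report histogram modes, skew
signs, TV, and an older/younger-favoring verdict relative to the specified
window midpoint.

## Synthetic data

The generators define the study conditions:

- **Birth–death trees**: forward simulation from one lineage; the present
  is placed at the end of the first sojourn at n lineages, so the root age
  of a two-tip Yule tree is Exp(2λ) and the n-tip Yule expectation is
  (1/λ) Σ_{k=2..n} 1/k (both used as closed-form oracles).  Extinct side
  branches are pruned; extinct runs restart.
- **Calibrations**: minima are true ages minus exponential gaps (rate γ,
  truncated so minima stay positive); maxima, where used, are true ages
  plus exponential excesses — minima postdate and maxima predate every
  divergence by construction.  Options: gaps as uniform *fractions* of the
  true age (clade-age-proportional incompleteness); maxima linked to
  minima as t_U = 1.221·t_L (the construction behind the classic turtle
  consistency analyses, which inherits any error in the minimum); a
  deliberately misleading minimum planted *above* one node's true age.
- **Alignments**: JC69 simulated along the chronogram at a strict rate.
- **Default study**: 8 tips, birth 0.02/lineage/Ma (root ages of order
  10² Ma), mean gap and maximum excess 10 Ma, rate 0.002 subs/site/Ma,
  2000 sites — a vertebrate-scale problem with informative but not
  saturated sequences.

The cross-validation demonstration study uses 10 tips, every internal node
calibrated, age-proportional gaps of 15–65% of each node's history
(deepest clades missing the most), conservative maxima 10–40% above the
truth, 800 sites (600 in the test suite), and fixed-age focal rounds.
Under these conditions the round whose calibration scores most consistent
under minimum-only scoring is typically a young-scaling one whose
estimates dip below the tight shallow minima, while the overestimates of
accurate rounds are absorbed by the windows — so the same calibration
lands among the least consistent under min–max scoring.  What passing this
shows is the internal incoherence of consistency ranking, not anything
about real fossil records: the generator has no taphonomy, no rate
variation, and a correct clock model.

The turtle fixture ships as a Newick chronogram (ages assigned by
top-down recursive midpoints of the revised constraint windows, which by
construction satisfy the age ordering) plus a TSV carrying both constraint
eras, the published per-method consistency verdicts as annotation columns,
and one unattached row (a clade absent from the packaged topology).  One
source sentence quotes the root maximum as 251.5 Ma where the table prints
251.4; the fixture uses 251.4.

## Numerical choices and limitations

Quantile summaries use linear (type-7) interpolation; histogram bin widths
follow Freedman–Diaconis.  Normalisation of every density is verified by
piecewise adaptive quadrature to 1e-6.  Seeds propagate explicitly;
regeneration from (parameters, seed) is bit-identical everywhere.  The
package does not infer topology, relaxed clocks, birth–death parameters,
or stratigraphic-occurrence priors, and deliberately offers no automated
"calibration quality verdicts": the diagnostics quantify prior distortion,
they do not certify accuracy.
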