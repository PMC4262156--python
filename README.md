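# chronocal

Fossil-calibration priors for Bayesian divergence-time estimation: what you
specify is not what you get, and this package quantifies the difference.

## The problem

Node dating calibrates a molecular phylogeny with probabilistic age
constraints derived from fossils: a *hard minimum* t<sub>L</sub> (no prior
mass younger than the oldest fossil of the clade) and, sometimes, a *soft
maximum* t<sub>U</sub> that a small tail mass (2.5% by convention) may
exceed.  Two density families cover common practice:

- **uniform soft-bound**: f(t) = (1 − tail)/(t<sub>U</sub> − t<sub>L</sub>)
  on [t<sub>L</sub>, t<sub>U</sub>], with an exponential upper tail of mass
  0.025 matched for continuity at t<sub>U</sub>;
- **truncated Cauchy**: a heavy-tailed density above t<sub>L</sub> with
  location t<sub>L</sub>(1 + p) and scale c·t<sub>L</sub>, expressing how
  far a divergence may predate its oldest fossil.

No dating program samples these densities as written.  The joint prior on
the node-age vector **t** is truncated to the region where every ancestor
is older than its descendants and combined with a tree-prior kernel.  Two
constructions are in use:

- **conditional** (MCMCTree-style): ∏ calibration densities × tree-prior
  kernel of the *uncalibrated* ages given the calibrated ones;
- **multiplicative** (BEAST-style): ∏ calibration densities × tree prior
  over *all* ages.

Either way, the *effective* marginal prior a node experiences can differ
sharply from the *specified* density — which also undermines calibration
cross-validation, the a-posteriori procedure that scores each calibration
x by how well it alone predicts the other nodes' fossil constraints:

D̄<sub>x</sub> = (1/(n−1)) Σ<sub>i≠x</sub> (MA<sub>i</sub> − FA<sub>i</sub>),
SS<sub>x</sub> = Σ<sub>i≠x</sub> (MA<sub>i</sub> − FA<sub>i</sub>)²,
s = Σ SS / (n(n−1)),

where MA<sub>i</sub> are posterior mean ages and FA<sub>i</sub> fossil
minima (or signed min–max window discrepancies).  The package implements
the densities, both joint-prior constructions, prior-only and strict-clock
JC69 posterior MCMC over node ages, the cross-validation statistics with
sequential-removal traces, specified-vs-effective diagnostics, synthetic
study generators, and the classic turtle (Testudines) calibration fixture
(both constraint eras of its 22 named clades; root 155.6–251.4 Ma).

## Worked example

```python
from chronocal import (turtle_fixture, sample_prior, MCMCSettings,
                       effective_marginal, compare_specified_effective)

tree, cals = turtle_fixture("priori")       # 23-tip chronogram + 22 windows
s = sample_prior(tree, cals,                # prior-only MCMC, no sequences
                 mcmc=MCMCSettings(n_iter=100_000, burn_in=0.25, thin=10),
                 seed=1)
em = effective_marginal(s, "Testudines")
print(f"root effective prior: mean {em['mean']:.1f} Ma, "
      f"95% interval ({em['q2.5']:.1f}, {em['q97.5']:.1f}) Ma")
rep = compare_specified_effective(s, cals)
row = rep.node("Pelomedusidae")
print(f"Pelomedusidae: specified window (5.3, 149.5) Ma, effective 95% "
      f"interval ({row['q2.5']:.1f}, {row['q97.5']:.1f}) Ma, "
      f"TV distance {row['tv']:.2f}")
```

prints

```
root effective prior: mean 214.3 Ma, 95% interval (167.1, 251.7) Ma
Pelomedusidae: specified window (5.3, 149.5) Ma, effective 95% interval (8.3, 129.6) Ma, TV distance 0.21
```

Every calibration here was *specified* as a flat window, yet the sampled
(effective) root prior is non-uniform: its lower 95% bound sits 11.5 Myr
above the specified 155.6 Ma minimum, pushed there by the 21 overlapping
descendant constraints, and the Pelomedusidae marginal is visibly
reshaped (total-variation distance 0.21 from its specified density).

A CLI wraps the experiment runners:

```sh
chronocal prior-grid --out runs/grid          # Cauchy (p, c) grid vs uniform
chronocal diagnostics --out runs/diag         # specified vs effective priors
chronocal xval --engine prior --out runs/xval # cross-validation + removal trace
chronocal synth --n-tips 8 --seed 1 --out study/
```

(omitting `--tree/--calibrations` uses the packaged turtle fixture).

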