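# Methods

## The balance statistic

For N treatment groups and a categorical covariate with M levels, the input
is the M × N contingency table of subject counts. Each group column k is
normalized by its own total to the group covariate distribution pₖ(C); the
common distribution p̃(C) is the **unweighted** mean (1/N) Σₖ pₖ(C) —
group sample sizes never weight the mixture, which is what makes the
statistic a pure function of proportions and hence insensitive to sample
size. The balance statistic is

    JSD = (1/N) Σₖ D(pₖ ‖ p̃) = (1/N) Σₖ Σᵢ pₖ(cᵢ) log₂( pₖ(cᵢ) / p̃(cᵢ) ),

in bits, bounded by 0 ≤ JSD ≤ log₂ N. The kernel also accepts arbitrary
positive weights summing to one, but weighted JSD is an extension and is
never used in reports.

### Decomposition

The double sum is reported term by term: cell (i, k) contributes
(1/N)·pₖ(cᵢ)·log₂(pₖ(cᵢ)/p̃(cᵢ)). Column sums are group contributions
(each equal to (1/N)·D(pₖ‖p̃), hence non-negative); row sums are
covariate-level contributions (non-negative by the log-sum inequality,
since p̃ is the mean of the pₖ). Individual cells may be negative: a
negative cell marks a group under-represented at that level relative to
the mixture. A unit test verifies the three resummations agree with the
overall statistic to 1e-12 on randomized tables, and independently checks
the identity JSD = H(p̃) − (1/N) Σₖ H(pₖ) computed purely from entropies.

### Conventions and degenerate inputs

- 0·log₂ 0 = 0 throughout; a level unobserved in one group contributes
  exactly zero to that group's sum.
- A covariate level unobserved in *every* group is dropped with a logged
  warning before computation (its mixture probability would be 0/0).
- A group column with zero total is a validation error naming the group.
- Relative entropy D(g‖f) raises a `DomainError` naming the offending
  label when g has mass where f has none, rather than returning an
  infinity sentinel; the JSD never hits this case because the mixture's
  support covers every component's support.
- Distributions constructed from counts normalize by exact division;
  pre-normalized probability inputs are accepted within 1e-9 of unit sum.
- Logarithms are base 2 (bits) in every reported quantity; kernel
  functions take an optional `base` argument for nats or hartleys.
- Rendered tables display 4 decimals, with marginal totals computed from
  unrounded cells and then rounded — so displayed cells need not sum to
  displayed totals, and every report carries a caveat line saying so.
- No "acceptable imbalance" threshold is implemented or defaulted. The
  `normalized` ratio (overall / log₂ N) is a labeled convenience
  extension, not a calibrated score.

## Continuous covariates

Continuous covariates enter via histogram binning: bin edges are computed
once from the pooled sample (all groups concatenated) so every group is
tabulated against the same partition, then occupancies form a contingency
table. Defaults: 10 equal-width bins over the pooled min–max range,
intervals left-closed/right-open with the last interval closed so the
maximum is included. A quantile strategy is available; duplicate quantile
edges from heavily tied data are collapsed with a logged warning. Binning
is coarsening, so refining a nested equal-width partition can only reveal
divergence — binned JSD is non-decreasing in the number of bins — and any
finite binning understates the continuous-density JSD. Kernel or
parametric density estimation is deliberately out of scope.

The standardized difference score is implemented in both forms:

- sample: (x̄₁ − x̄₂) / √((s₁² + s₂²)/2) with (n−1) sample variances —
  "combined standard deviation" is not standardized in the literature, and
  this root-mean-square convention is the common choice;
- population (for Gaussian specifications): (μ₁ − μ₂) / √((σ₁² + σ₂²)/2).

## Gaussian JSD by quadrature

For two normal distributions the JSD
(1/2)[∫f₁ log₂(f₁/m) + ∫f₂ log₂(f₂/m)], m = (f₁+f₂)/2, is evaluated by the
trapezoid rule on a fixed grid of 20,001 equally spaced points spanning
[min μ − 8·max σ, max μ + 8·max σ]. The integrand is smooth and decays
with the Gaussian tails, so truncation plus discretization error is well
below 1e-6; tests confirm agreement with an independent 400,001-point
midpoint-rule oracle to 1e-5, symmetry to 1e-9, and affine invariance to
1e-6. Results are clamped to [0, 1] (two distributions can diverge by at
most one bit).

The divergence-vs-standardized-difference curve fixes group 1 at N(0, 1)
and gives group 2 standard deviation σ₂; for each target standardized
difference d the second mean is solved as μ₂ = −d·√((1+σ₂²)/2). Which
parameter is swept is a free choice; this one reproduces the expected
behavior at both ends — the curve starts at zero iff σ₂ = 1 (with unequal
SDs it starts strictly positive at d = 0, the shape sensitivity the
standardized difference lacks) and every curve asymptotes at one bit.

## Synthetic data generator

`jsdbalance.fixtures` draws reproducible datasets through numpy's
`default_rng` (PCG64; the algorithm name is recorded in fixture metadata).
Two modes:

- **multinomial** — per-group categorical counts with stated level
  probabilities; `generate_counts` draws the contingency table directly so
  large-n recovery checks need not materialize per-subject rows. With the
  worked example's three-group profile at 10⁶ subjects per group, the
  sampled JSD lands within 0.001 bits of the population value, which the
  acceptance-style test asserts at a fixed seed.
- **gaussian_mixture** — per-group continuous samples from normal
  mixtures. Four named two-group presets cover the canonical scenarios:
  `location-shift` (N(0,1) vs N(1,1)); `scale-difference` (N(0,1) vs
  N(0,3)); `skew-mirror` (mirrored two-component mixtures, both mean 0);
  `bimodal-vs-unimodal` (a symmetric two-mode mixture vs a single normal
  with matched mean and near-matched variance). All but the first have
  matched group means, so their sample standardized difference converges
  to zero while the binned JSD stays bounded away from it.

What the generator does *not* emulate: missing-data mechanisms (reader-side
exclusion is complete-case), covariate measurement error, correlated
multivariate covariates, or outcome models — passing tests demonstrate the
statistic's arithmetic and sampling behavior, not robustness to those
real-data features.

## Problem sizes in tests

Property suites run 100 randomized instances per invariant with tables up
to 6 × 4; Monte-Carlo checks use 10⁴–10⁵ samples per group (10⁶ for the
multinomial recovery test, drawn as counts); quadrature cross-checks use a
400,001-point oracle grid. The full suite completes in a few seconds.

## Known limitations

- Binned JSD depends on the binning spec; there is no default correction
  for the downward discretization bias.
- Group-wise covariate distributions are plug-in (empirical) estimates;
  no small-sample bias correction is applied, and the JSD of small samples
  is noisy upward (an imbalance of a few thousandths of a bit is not
  distinguishable from sampling noise at modest n).
- Only a single (possibly pre-crossed) categorical covariate per table;
  joint multivariate balance requires the caller to construct the
  cross-classification.
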