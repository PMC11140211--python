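# Methods

## Model

Phenotypes are modeled by the standard bivariate linear mixed model for a
cohort of `n` individuals with kinship matrix `K`.  After residualizing on
covariates and rescaling, each trait has total variance 1, so the genetic
variance equals the narrow-sense heritability `h²` and

    var(y)       = h²·K + (1 − h²)·I
    cov(y1, y2)  = h1·h2·ρk·K + √(1−h1²)·√(1−h2²)·ρe·I

with genetic correlation `ρk ∈ [−1, 1]` and residual correlation
`ρe ∈ [−1, 1]`.  All estimation uses the closed-form Haseman-Elston (HE)
moment estimators with `W = K` with zeroed diagonal:

    ĥ²  = yᵀWy / tr(WW)
    ρ̂k = y1ᵀWy2 / √(y1ᵀWy1 · y2ᵀWy2)

`ĥ²` is unbounded (negative values and values above 1 are legitimate
moment-estimator outputs and are never clipped); `ρ̂k` is undefined whenever
either denominator quadratic form is nonpositive, which is propagated as an
explicit invalid state so the bootstrap can count such replicates.

**Centering.**  The quadratic forms are applied to data as given; they do
not re-center internally.  Real data must pass through `residualize`
(covariates → least-squares residuals; no covariates → mean-centering),
mirroring the usual pipeline of rank-normalizing, residualizing, then
estimating.  Simulated bootstrap draws are mean-zero by construction, and on
mean-zero data the HE heritability estimator is exactly unbiased:
`E[yᵀWy] = h²·tr(WW)` because `diag(W) = 0`.  Re-projecting out the sample
mean inside the estimator would instead introduce a finite-sample bias of
order `1ᵀW1/n²` (≈ −0.013 at `h² = 0.5` on the default synthetic cohort),
which is why centering is an explicit preprocessing step rather than an
implicit one.

## Parametric bootstrap

Because `(ĥ1², ĥ2², ρ̂k)` has an awkward joint distribution near the
parameter boundaries, intervals are built by simulation.  For every
combination of a candidate-parameter grid — default
`h̃² ∈ {0.05, 0.15, …, 0.95}` per trait and
`ρ̃k ∈ {−0.95, −0.85, …, 0.95}`, i.e. 10 × 10 × 20 = 2,000 combinations, all
at bin midpoints — `n_reps` phenotype pairs are drawn from the model,
estimated, and the estimate triplets binned into 10 heritability bins of
width 0.1 on [0, 1] and 20 correlation bins of width 0.1 on [−1, 1] (all
half-open, last bin closed, out-of-support estimates clamped to the extreme
bins).  Only the integer count tensor is persisted (HDF5), indexed by
(true-parameter bins × estimate bins); stores with disjoint seeds add.

The residual correlation is held at a single value for the whole grid.  The
package default in its own experiments is `ρe = 0.2`, a deliberately
conservative nonzero choice; coverage is empirically insensitive to it, and
the parameter is required (not defaulted) in the API so the choice is always
explicit.

Given an observed triplet, the conditional PMF of the true-correlation bin
follows from Bayes' theorem with a uniform prior over the grid:

    Pr(ρ̃ ∈ A_r | obs) = Σ_{h̃1,h̃2} p̂(obs | h̃1, h̃2, ρ̃_r)
                         / Σ_{r'} Σ_{h̃1,h̃2} p̂(obs | h̃1, h̃2, ρ̃_{r'})

where `p̂(obs | combo)` is that combination's count in the observed estimate
bins divided by its number of *valid* replicates (replicates with undefined
`ρ̂` are excluded from both numerator and denominator so they do not distort
conditional probabilities).  If the observed bins were never realized
anywhere in the store the PMF is reported as an explicit "unsupported
estimate region" error — no silent smoothing; an optional additive
(Laplace) smoothing count exists for exploratory use and is off by default.

## Confidence intervals

**PMF percentiles.**  Mass is treated as uniform within each bin, giving a
piecewise-linear CDF; bounds are placed by linear interpolation.  With
`cpl = CDF(ρ̂)` (the estimate clamped into [−1, 1]), three cases:

* `cpl < α/2` — too little mass below the estimate for an equal lower tail:
  the interval starts at the support's lower edge and extends to the
  smallest `x` carrying `1−α` mass;
* `1 − cpl < α/2` — mirror image at the upper end;
* otherwise the usual equal-tail interval `[CDF⁻¹(α/2), CDF⁻¹(1−α/2)]`.

Evaluating `cpl` on the interpolated CDF (rather than whole-bin sums) makes
the trichotomy continuous in `ρ̂`.  Quantile inversion takes the largest `x`
with `CDF(x) ≤ q` for lower bounds and the smallest `x` with `CDF(x) ≥ q`
for upper bounds, so flat (zero-mass) stretches are excluded from the
interval and the mass guarantee `CDF(upper) − CDF(lower) ≥ 1−α` holds
exactly in every case.

**Beta approximation.**  The discrete PMF cannot resolve tail probabilities
below its granularity, so for small `α` (and small p-values) the PMF is
approximated by a beta distribution: bin midpoints are mapped from [−1, 1]
to [0, 1] by `m → (m+1)/2`, the PMF mean `μ` and variance `v` computed on
that scale, and shapes fit by moment matching,
`a = μ(μ(1−μ)/v − 1)`, `b = (1−μ)(μ(1−μ)/v − 1)`.  (Moment matching was
chosen over maximum likelihood: it is closed-form, exact for the first two
moments, and the fit is only ever used for its quantiles.)  Equal-tail beta
quantiles are back-transformed by `x → 2x−1`.  A PMF concentrated in a
single bin cannot be fit and is reported as an error directing the caller
to the PMF method.

**Fisher comparator.**  `z = arctanh(ρ̂)` treated as normal with
`σ = 1/√(Neff − 3)`, `Neff = tr(WW)`; equal-tail normal interval
back-transformed by `tanh`.  This is the classical Pearson-correlation
recipe transplanted to genetic correlations and is included as the baseline
that the bootstrap is designed to beat near boundaries.

**p-values.**  `p` is the smallest `α` at which the level-(1−α) interval
excludes 0, found by bisection on `α` over `(sensitivity, 1)` — equal-tail
intervals shrink monotonically in `α`, so the crossing is unique.  Default
sensitivity 1e-6 (≤ 60 iterations); values below the floor are reported as
the floor and should be read as `p ≤ sensitivity`.  The beta method is the
default because its continuous quantiles resolve arbitrarily small
p-values.  Multiple testing uses Benjamini-Hochberg step-up adjustment
(via statsmodels).

## Simulation engine

The 2n×2n joint covariance decomposes by kinship block; each 2b×2b block
covariance is factorized by eigendecomposition with negative eigenvalues
clipped at 0 (tolerance 1e-8), so boundary parameters (`h² = 1`, `|ρ| = 1`)
that make the covariance singular still sample; a block whose kinship is
materially non-PSD (eigenvalue < −1e-8) is an error naming the block.
Sampling uses one PCG64 stream per (seed, block index, replicate chunk)
with chunks of 1,000 replicates, so results are bitwise reproducible
regardless of how combinations are distributed over workers; the grid runs
its 2,000 combinations as independent jobs seeded from (grid seed, flat
combination index).  A consequence of positional per-block seeding is that
reordering the blocks of `K` reassigns streams: draws are equal in
distribution, not bitwise, under block permutation.

## Synthetic data and what it does (not) show

The generator produces block-diagonal kinships of equicorrelated families
(diagonal 1, constant within-family coefficient) plus singletons, and the
package's own experiments use 50 families of 10 with coefficient 0.5
(n = 500, `Neff = 1125`), optionally block-replicated 4× (n = 2,000,
`Neff = 4500`); bootstrap stores use `n_reps = 500` per combination and
experiments 500 evaluation replicates — sizes chosen so a complete
evaluation runs in minutes on one CPU while leaving Monte-Carlo error well
below the effects being measured.  This emulates the family structure that
drives HE estimation but not features of real cohorts: kinship coefficients
are not constant within real families, realistic matrices have many small
nonzero off-block entries (sparsified here to exact zeros), phenotypes are
not exactly Gaussian, and covariate effects are absent (simulation is
covariate-free; covariates enter only through residualization of real
data).  Passing coverage on these conditions therefore demonstrates the
*procedure* is correct and calibrated under its own model, not that any
particular real dataset satisfies that model.

## Known limitations

* **Bin-width conservatism.**  The inversion p-value conditions on the
  *binned* estimate triplet.  When the sampling SD of `ρ̂` becomes
  comparable to or smaller than the 0.1 bin width (large `Neff`; e.g. the
  4× replicated cohort, `Neff = 4500`, null SD ≈ 0.08), within-bin
  information is discarded, the conditional PMF over-disperses relative to
  the sampling distribution, and the test becomes conservative: measured
  type-1 error ≈ 0.01–0.02 at nominal 0.05 there, versus ≈ 0.05–0.06 on the
  base cohort (`Neff = 1125`, null SD ≈ 0.17).  Coverage errs on the side
  of over-coverage in the same regime.  A finer grid/bin scheme (supported,
  at proportional cost) is the remedy when `Neff` is large.
* The store is dataset-dependent: it must be rebuilt for a new kinship
  matrix (the cost amortizes over many trait pairs on the same cohort).
* Only a single relatedness matrix is modeled; multi-component covariance
  structures (several variance components beyond kinship + noise) are out
  of scope.
* Grid values must sit at bin midpoints; continuous-parameter interpolation
  across grid combinations is not attempted.
* The heritability filter of the network layer uses the closed interval
  [0.3, 0.9] (boundaries inclusive); self-pairs are excluded from
  estimation and the network, and pair-count utilities expose the
  with-self-pairs convention only for bookkeeping against panel sizes.
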