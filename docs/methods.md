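# Methods

## Data preparation

One record is a (context, study, species, trait, generation) measurement
carrying a mean, an SD and a sample size. Generations of urbanization are
time since colonization divided by age at maturity, unrounded.

Filters run in a fixed order, each dropped record logged with a reason:
records from lines selected *for* high fear/aggression; dog records in
the domestication context (between-breed variability from repeated
selective breeding); then any (study, trait) group left with fewer than
2 values — a single value cannot inform a trajectory.

Harmonization multiplies latency-type means (direction −1) by −1 so that
larger always means a stronger antipredator response; SDs are untouched.
Each trait group whose minimum is negative is shifted up by |minimum| so
its baseline is exactly 0; groups already non-negative are left alone —
unconditionally adding the minimum would displace naturally positive
traits for no benefit, and the conditional shift preserves all pairwise
differences either way. Standardization computes (value − group mean) /
group SD within (context, study, trait), with the sample SD (n−1):
groups are small and the n−1 convention keeps the unit honest.
Zero-SD or singleton groups get z = 0 with a warning rather than being
dropped, so their records remain available for the CV analysis.

The |CV| is computed from the oriented but unstandardized mean and SD —
after standardization the group mean is 0 and a CV would be undefined.
Per-record weights default to the sample size (precision ∝ n); a
`weighting` switch (`n`, `inverse_n`, `none`) exposes the alternative
readings, since "weighted by the inverse of the sample size" admits both.

## Trajectory curves

Mean: `f(x) = y_ini + k·aˣ` with `a ∈ (0,1)`. Its derivative
`k·ln(a)·aˣ` is the per-generation rate of change; the
generations-to-asymptote summary solves `|f(x) − y_ini| = c·|k|` in
closed form, `x = ln(c)/ln(a)`, with `c = 0.05` by default ("asymptote
reached" = 95% of the change completed; the 5% cut is a convention, and
the function takes any fraction).

CV: `g(x) = y_ini + a·(k/λ)·u^(k−1)·exp(−u^k)`, `u = (x − t_min)/λ` —
baseline plus a scaled Weibull *density* bump. The printed form of such
equations is ambiguous about grouping; the density interpretation is the
standard Weibull shape consistent with a rise-then-decline of variance,
and with `a = 1` the bump integrates to exactly 1 (a test asserts this).
For `x < t_min` the curve is defined as the baseline `y_ini`, avoiding
fractional powers of negative numbers; for `k > 1` this is also the
continuous limit from the right.

## Curve fitting

Both curves are fitted by minimizing the weighted mean absolute error
`Σ wᵢ|yᵢ − f(xᵢ)| / Σ wᵢ`. MAE is used uniformly for both stages to keep
them consistent, and is robust to the heavy-tailed residuals typical of
meta-analytic data. The optimizer is an in-package (μ/μ_w, λ)-CMA-ES
with the standard recursions: population `4 + ⌊3 ln d⌋`, weighted
recombination of the best half, cumulation paths for step size and
rank-one covariance update, rank-μ update. Box constraints are handled
by smooth reparameterisations — logistic for `a ∈ (0,1)`, log for
`k, λ > 0`, `exp(·) − 1` clamped at 0 for `t_min` — rather than
rejection, which keeps the covariance adaptation well behaved. Fits are
best-of-5 restarts (the first from a data-driven start, the rest
jittered), 5,000–8,000 evaluations each, objective tolerance 1e−10, all
deterministic given the seed.

Loess (tricube kernel over span-nearest neighbours, local degree 0–2,
default span 0.75 and degree 2, no robustness iterations) provides the
assumption-free first look; span selection minimizes in-sample MAE over
a candidate list, ties to the smallest span. The smoother is written
in-package because no installed library provides degree-2 loess with the
span/kernel conventions needed here.

## Bayesian meta-regression

The analysis model is `y = Xβ + Σ_l Z_l u_l + e` with random levels
study, species, phylogeny and trait type (behavioral vs physiological).
The curve's nonlinear shape is frozen at the CMA-ES estimate and enters
X as a single basis covariate — `aˣ` for the mean model, the unit-scale
Weibull bump for the CV model — so the Bayesian stage estimates an
intercept (asymptote/baseline) and a slope (the curve's amplitude); the
slope's 95% credible interval excluding zero is the significance test of
the fit. Interaction models code the first life-history factor full-rank
one-hot (one intercept and one slope per level, no global intercept) and
any further factor in reference coding; genuinely aliased columns (e.g.
a sociality level constant within foraging guilds in a small species
pool) are dropped with a warning, as standard model fitters do.
Maximum longevity enters as a centred log10 covariate.

The phylogenetic level has covariance `σ²_phylo·A`, where A is the
Brownian-motion correlation matrix of an ultrametric tree: entry (i, j)
is the root-to-MRCA depth over tree height — the standard construction
for phylogenetic mixed models. Residuals are heteroscedastic,
`Var(eᵢ) = σ²_e/wᵢ`.

Inference is a blocked Gibbs sampler: flat prior on β; each scalar
variance has an inverse-gamma(ν/2, νV/2) prior — the univariate
inverse-Wishart — with V = 1, ν = 0.02. Per sweep: β from its Gaussian
conditional; each `u_l` from its conditional (diagonal precision for
spherical levels, a q×q Cholesky solve for the phylogenetic level); then
all variances from inverse-gamma conditionals. Chains are exactly
reproducible from the seed. Reference settings are 10⁶ iterations,
burn-in 30,000, thinning 100, 5 chains; the test suite and the
acceptance script use scaled-down chains (2,500–30,000 iterations,
proportional burn-in/thinning) — chosen as the package's working sizes,
at which every calibration property below is already stable.

`pMCMC` is twice the smaller tail fraction relative to zero, floored at
1/(number of draws) so finite chains never report zero. Effective sample
size uses the initial-positive-sequence autocorrelation estimator.

DIC uses the *marginal* Gaussian likelihood — random effects integrated
out at the sampled variances, `V = σ²_e W⁻¹ + Σ_l σ²_l Z_l A_l Z_lᵀ` —
with `DIC = 2·mean(D) − D(posterior means)` and `pD = mean(D) − D(θ̄)`.
Model weights are `exp(−ΔDIC/2)`, normalized. A caveat verified
empirically: marginal DIC penalizes a spurious *random* level with few
groups only weakly (it can absorb chance imbalance at little pD cost),
so the model-selection consistency property is demonstrated with
fixed-effect over-specification, where pD grows by ~1 per spurious
covariate and the generating model wins essentially always.

## Heterogeneity

`I²_l = 100·σ²_l / (Σ σ² + v̄)` for study, species and phylogeny, with
the residual share absorbing `σ²_residual + v̄` so shares sum to exactly
100. The typical sampling variance v̄ is taken as the model's own
per-record residual variance averaged over records, `σ²_e·mean(1/wᵢ)`;
because the heteroscedastic residual *is* the sampling variance in this
model, the pipeline passes it through the residual slot (as a
`residual_scale = mean(1/w)` factor) and sets the separate v̄ argument
to 0 — passing both would double-count. `H² = σ²_phylo/(σ²_phylo +
σ²_species)`, the phylogenetic share of species-linked variance
(Pagel's-λ analogue); it is undefined (flagged None) when both
components are zero. Posterior partitions are computed per retained draw
and summarized with equal-tailed 95% CIs.

## Synthetic data

The generator emulates the statistical structure the analysis assumes:
a pure-birth (Yule) tree with height normalized to 1; per-record latent
response = inverse curve + species + phylogenetic (jointly `N(0, σ²A)`)
+ study + trait-type effects + `N(0, σ²_e/nᵢ)` noise; raw means embed
the latent response through a per-(study, trait) affine map (default
offset 5, scale 1, keeping means positive) so the standardization stage
is genuinely exercised; raw SDs are set so each record's |CV| equals the
Weibull curve times multiplicative lognormal noise — multiplicative so
SDs stay positive, since nothing in the source analysis prescribes a
generative model for the CV.

Default conditions encode the study's reported dynamics: decay factors
`a = 0.05^(1/30) ≈ 0.905` (domestication) and `0.05^(1/90) ≈ 0.967`
(urbanization) so the mean reaches its 5% asymptote at ~30 and ~90
generations respectively, captivity intermediate with the weakest
signal; CV baselines equal across contexts at generation 0; the
domestication CV bump peaks near generation 18 and declines past 50.
Random-effect SDs 0.2–0.4 and residual SD 0.3 on the z-score scale,
sample sizes 5–30, 12–20 studies × 2 traits × 8 generations per context,
30 species.

What the generator does *not* emulate: the taxonomic skew of real data
(bird-dominated urbanization samples), unbalanced generation coverage
across studies, missing SDs, and publication bias. Passing tests
therefore demonstrate correctness of the machinery under the assumed
model, not robustness to these real-data features.

A deliberate consequence of within-group standardization: an affine map
per (study, trait) group changes `y_ini` and `k` (they are recovered on
the standardized scale) but leaves the decay factor `a` — the quantity
the timescale conclusions rest on — exactly invariant, and the noiseless
round-trip test recovers it to 1e−6.

## Numerical choices and edge cases

- Ultrametricity is checked at relative tolerance 1e−6;
  `force_height_normalize` stretches terminal branches instead of
  rejecting.
- A is jittered by 1e−10 on the diagonal before inversion/Cholesky.
- CMA-ES treats non-finite objective values as very bad candidates and
  guards against divergence (σ·√λ_max > 1e8 aborts the restart).
- Zero group SDs, zero means (CV undefined), empty filter input, single
  leaf trees and degenerate posteriors are all handled without raising,
  with logs or flags; genuinely invalid configuration (non-positive
  maturity age, negative SDs, burn-in ≥ iterations, singular designs)
  raises.
- Tie-breaks: span selection prefers the smaller span; model ranking is
  a stable sort on ΔDIC.

## Known limitations

- The Gibbs sampler covers Gaussian responses only, one variance per
  level (no parameter expansion); heavy posterior correlation between
  species and phylogeny variances is expected when the tree carries
  little signal — their sum, and H², remain well identified.
- DIC's weak penalty on small spurious random levels (above) means
  random-structure comparisons should be read with the pD column.
- The CV stage inherits whatever bias the |CV| transform introduces for
  means near zero; records with exactly zero mean are excluded and
  logged.
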