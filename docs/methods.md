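# Methods

## Model

`pgordinal` fits cumulative-link ordinal regression by Markov chain Monte
Carlo, in the threshold (latent-liability) formulation used in genomic
prediction.  Observation *j* of line *i* has ordinal score
y<sub>ij</sub> ∈ {1..C} determined by a latent liability

    l_ij = x_ij'β + b_i + ε_ij,      y_ij = c  ⇔  γ_{c−1} < l_ij < γ_c,

with γ₀ = −∞ < γ₁ < … < γ_{C−1} < γ_C = +∞.  The residual is standard
logistic (logit link) or standard normal (probit link).  Priors:
β | σ_β² ~ N(β₀, Σ₀σ_β²) (optionally improper flat), b | σ_b² ~ N(0, G σ_b²)
for a genomic relationship matrix G, scaled inverse chi-square priors
χ⁻²(ν, S) on both variances, and the thresholds are order statistics of
U(γmin, γmax).  No intercept is allowed in X — the thresholds absorb it —
and the dataset validator rejects constant non-zero columns, categories
that never occur (their threshold conditionals would be unbounded), and
incomplete design matrices (no imputation is attempted here).

### Pólya-Gamma augmentation

The logistic density of each residual is mixed through a Pólya-Gamma
variable ω_ij ~ PG(2, ·): conditional on ω the liability is Gaussian with
variance 1/ω_ij, and every full conditional becomes a standard family.
One Gibbs sweep updates, in order:

1. liabilities — N(x'β + b, 1/ω) truncated to the category interval;
2. ω_ij ~ PG(2, −l_ij + x_ij'β + b_i) (the PG density is symmetric in its
   tilt, so the sign convention is immaterial; we keep this one);
3. β ~ N(Σ̃₀(Σ₀⁻¹σ_β⁻²β₀ − X'DωZb + X'Dωl), Σ̃₀),
   Σ̃₀ = (Σ₀⁻¹σ_β⁻² + X'DωX)⁻¹, Dω = diag(ω);
4. b ~ N(F(Z'Dωl − Z'DωXβ), F), F = (σ_b⁻²G⁻¹ + Z'DωZ)⁻¹;
5. σ_b² ~ χ⁻²(ν_b + I, (b'G⁻¹b + ν_b S_b)/(ν_b + I));
6. each γ_c uniform on (max{max(l|y=c), γ_{c−1}, γmin},
   min{min(l|y=c+1), γ_{c+1}, γmax}), swept in increasing c with fresh
   neighbours, which preserves ordering by construction;
7. σ_β² ~ χ⁻²(ν_β + p, [(β−β₀)'Σ₀⁻¹(β−β₀) + ν_β S_β]/(ν_β + p)).

Setting every ω ≡ 1 and skipping step 2 gives exactly the classic probit
threshold sampler (Albert–Chib style): the probit model is a special case
of the same loop, and a testing hook (`pin_omega`) verifies the reduction
draw for draw.  Steps 4–5 are skipped entirely without polygenic effects.
The printed normalizing constant of the liability conditional is treated
as the correctly normalized truncated normal N(x'β + b, 1/ω); anything
else would not leave the augmented joint invariant.

### Exact samplers

The PG(1, z) sampler is Devroye's alternating-series rejection method (an
inverse-Gaussian body and exponential tail proposal for the Jacobi-theta
density, with the partial-sum acceptance test); PG(2, z) is the sum of two
independent PG(1, z) draws, PG being infinitely divisible in its shape.
Only integer shapes are supported — the sweep needs PG(2, ·) only, and
approximate (moment-matched) PG samplers are deliberately out of scope
because exact sampling is the point of the augmented logit chain.
Truncated normals combine plain rejection in the bulk, uniform rejection
on narrow slivers, and Robert's translated-exponential rejection for
one-sided regions, switching strategies from the erfc-computable region
masses; draws are exact and finite arbitrarily far into the tails (the
tests exercise an interval eight standard deviations out).  Both kernels
are numba-compiled; each call is seeded from an explicit `RNGStream`
(PCG64 with SeedSequence-derived sub-streams per replicate/fold), so runs
are bit-reproducible from a single master seed and replicate results do
not depend on execution order.

### p ≫ n (threshold Bayesian ridge regression)

With all markers in X and prior β ~ N(0, I σ_β²), step 3's posterior mean
is the ridge estimator (X'DωX + I σ_β⁻²)⁻¹X'Dωl with the liabilities as
pseudo-response.  Whole-genome panels make the p×p solve infeasible, so
when p > 2n (and Σ₀ is scalar) β is drawn by the auxiliary-variable
identity of Bhattacharya, Chakraborty & Mallick (2016): draw
u ~ N(0, λI_p), δ ~ N(0, I_n), solve the n×n system
(λX̃X̃' + I)w = ỹ − X̃u − δ with X̃ = Dω^{1/2}X, and set
β = u + λX̃'w.  The output distribution is identical to the direct
formula; a shared-moment test checks the two routes against each other up
to Monte-Carlo error.  X̃X̃' is assembled from a cached XX' (computed once
per dataset), so the per-iteration cost is O(n² + np).  Marker columns are
mean-centered in ridge mode (`fit --ridge`); the shift is absorbed by the
thresholds and centering improves the conditioning of XX'.

### Initialization and numerical choices

γ starts at the standard-normal quantiles of the empirical cumulative
category frequencies, clipped strictly inside (γmin, γmax); β = 0, b = 0,
σ_b² = S_b, σ_β² = 1, ω = 1, and liabilities start at the midpoint of
their category interval (±0.5 past the boundary threshold in the open end
categories).  Chains are stored unthinned (subsampling MCMC output only
loses precision for posterior means and quantiles).  Default
hyperparameters are the weakly-informative ν_β = 3, S_β = 0.001,
β₀ = 0, Σ₀ = 10000·I; the same weakly-informative (ν, S) pair is the
default for σ_b².  Threshold bounds are ±1000 in the real-data
profile and ±4 in the simulation profile.  The observed-category
probability inside the deviance is floored at 1e−12 with a logged warning.

## Simulation designs

The built-in generator reproduces the two study designs: I = 40
genotypes with covariates x_i ~ U[−0.1, 0.1]³ (redrawn per replicate by
default, so across-replicate SDs reflect full sampling variability; a
`shared_x` flag instead freezes one covariate design across replicates), β = (−6, −5, 7), and thresholds at
the standard-normal quintile cutpoints (−0.8416, −0.2533, 0.2533, 0.8416)
cutting liabilities into C = 5 categories.  Design one draws residuals
from the standard logistic with n_i ∈ {5, 10, 20, 40} replicates per
genotype; design two fixes n_i = 40 and replaces an exact
round(PO%·1600), uniformly-placed subset of residuals with unscaled
Student-t₄ draws (PO ∈ {5, 10, 20, 30}), probing robustness to
heavy-tailed outliers.  The replication harness fits BLOR (logit chain),
BPOR (probit chain), BLOR* / MLLOR* (probit estimates rescaled by
k = 1.75; k is a parameter, 1.702 etc. are accepted) and MLLOR (logit
MLE), with the simulation prior β ~ N(0, 10000·I₃), σ_β² fixed at 1, and
γ bounds ±4.  Bayesian point estimates are posterior means.  Failed
replicate fits are excluded with a logged count.

What the generator does **not** emulate: marker genotypes, linkage
disequilibrium and relatedness structure (the simulated designs have
three dense covariates and no polygenic term), environments, or missing
data.  Passing the simulation checks therefore demonstrates correctness
of the sampler and estimators under the model, not performance on real
genomic panels; the ridge/polygenic code paths are exercised separately
on synthetic marker data of realistic shape.

## MLE baseline

The cumulative-link MLE maximizes Σ log[F(γ_y − x'β) − F(γ_{y−1} − x'β)]
by damped Newton iteration: analytic gradient, central finite-difference
Hessian of that gradient with a Levenberg-style ridge when not positive
definite, step halving on the objective, and convergence at gradient
sup-norm < 1e−8 (cap 200 iterations).  Thresholds are parameterized as
(γ₁, log-increments), so monotonicity holds at every iterate.
Non-convergence is reported through a flag, never silently.  Tests verify
it against scipy's derivative-free Powell optimizer and against R's
MASS::polr on a shared fixture.

## Evaluation metrics

Category probabilities are π_c(η) = F(γ_c − η) − F(γ_{c−1} − η).
Posterior point/interval estimates are computed per stored draw with
equal-tailed quantile bounds (default 95%, configurable — the interval
level is a convention, not prescribed).  The Brier score is halved to lie
in [0, 1].  DIC uses the classic plug-in at the joint posterior mean of
(β, b, γ): DIC = 2·D̄ − D(θ̄).  Cross-validation makes 10 independent
uniform 90/10 splits (unstratified, observation-level) and predicts
held-out categories from posterior-mean parameters — not
posterior-predictive averaging — so the k-rescaled approximations are
scored identically; per-category probability tables average over
observations.

## Problem sizes and reproduction

`scripts/acceptance.py` reruns the replication experiments: 50 replicates
throughout, with the full 20,000/10,000 chains at n_i = 5 (n = 200) and
shortened chains at n = 1600 (4,000/2,000 for design one, 3,000/1,500 for
design two).  At n = 1600 the conjugate sweeps converge within a few
hundred iterations and posterior means from the shortened chains agree
with 60,000-iteration reference runs to well under the across-replicate
noise, so the shorter chains are the package's default desk-scale choice.

## Known limitations

* Threshold updates are uniform draws between adjacent liability order
  statistics, so their mixing slows as n grows (step size ~ 1/n); for n in
  the tens of thousands, expect to lengthen chains substantially or
  initialize thresholds near link-appropriate quantiles.  All study-scale
  problems here (n ≤ 1600) converge within a few hundred sweeps.
* Only integer PG shapes are implemented (the sampler needs b = 2 only).
* No genotype×environment terms, multi-trait models, variable-selection
  priors, convergence diagnostics beyond the stored draws, or marker
  imputation.
* The MLE baseline requires p < n and no polygenic term; it exists to
  benchmark the simulation designs, not for genomic panels.
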