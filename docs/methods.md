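# Methods

## The model

`jointirt` fits a two-component joint model for the item responses of a
computer-administered test.  For person *i* = 1..N and item *k* = 1..K:

**Accuracy (RA).**  A normal-ogive (probit) IRT model,

    P(Y_ik = 1 | theta_i, a_k, b_k) = Phi(a_k * theta_i - b_k),

optionally with a guessing mixture (3PL),
`P = c_k + (1 - c_k) * Phi(a_k*theta_i - b_k)`.  A bracketed convention
`Phi(a_k*(theta_i - b_k))` puts difficulties on the ability scale; the two
are related by `b = a * b~`.

**Response time (RT).**  Log-RTs are normal,

    RT_ik = lambda_k - phi_k * zeta_i + eps_ik,   eps_ik ~ N(0, sigma2_k),

where `lambda_k` is the time intensity (average log-time demand), `phi_k`
the time discrimination (item-specific sensitivity of log-RT to working
speed `zeta_i`), and `sigma2_k` an item-specific residual variance.  Two
alternative conventions are supported: the bracketed
`phi_k * (lambda~_k - zeta_i)` form, and the reciprocal-error-SD form
(`wl`), in which the mean is `lambda_k - zeta_i` and the reported time
discrimination is `1/sigma_k`.

**Population structure.**  Persons are exchangeable draws from a bivariate
normal, `(theta_i, zeta_i) ~ N2(mu_P, Sigma_P)`; the off-diagonal of
`Sigma_P` carries the speed–accuracy relationship.  Item parameter vectors
`(a_k, b_k, phi_k, lambda_k)` are 4-variate normal with positivity
restrictions on `a_k` and `phi_k`.  Hyperpriors are inverse-Wishart for the
covariances (`nu_P = 3, V_P = I`; `nu_I = 5, V_I = I`), a kappa-weighted
normal for the item mean (`kappa = 1` prior measurement,
`mu_0 = (1, 0, 1, 3.7)`), inverse-gamma(1, 0.1) for `sigma2_k`, and
Beta(20, 80) for guessing (prior proportion 1/5, SD 0.04).  Person and
item means can be regressed on dummy-coded predictors (ability, speed,
difficulty, time intensity only; the discriminations vary too little for
predictors to be useful, so none are supported there).

## Estimation

Everything is estimated by blocked Gibbs sampling with data augmentation:
each observed binary response is backed by a latent propensity
`Z_ik ~ N(a_k*theta_i - b_k, 1)` truncated by the response, which turns all
full conditionals into (truncated) normal linear-model or standard
conjugate updates.  The update order within an iteration is fixed:
augmentation → persons → items → residual variances → guessing →
hyperparameters → identification → imputation.  Any valid order leaves the
stationary distribution unchanged; a fixed order makes runs exactly
reproducible given a seed.

Details worth recording:

* **Item block.**  The 4-variate item conditional is sampled by a fixed
  coordinate scan (a, b, phi, lambda), each coordinate from its univariate
  normal conditional given the others (prior cross-covariances included);
  `a_k` and `phi_k` are drawn from positive-truncated conditionals.
  Truncated normals use an inverse-CDF sampler in log space
  (`log_ndtr`/`ndtri_exp`), stable for truncation points tens of SDs out.
* **Under the 3PL**, a correct response is attributed to a random guess
  with posterior odds `c_k : (1 - c_k) * Phi(a_k*theta_i - b_k)`; guessed
  cells are excluded from the IRT likelihood, and `c_k` has a conjugate
  Beta update over guessed/non-guessed counts.
* **Identification.**  The latent scales are fixed by `prod(a_k) = 1` and
  `prod(phi_k) = 1` (rescaling compensated on theta/zeta, so the
  likelihood is invariant).  Rule 1 additionally enforces
  `sum(b_k) = 0` and `sum(lambda_k) = 0`; a plain mean-subtraction is not
  likelihood-invariant when discriminations vary, so the shift is
  `b <- b + a*t`, `theta <- theta + t` with `t = -sum(b)/sum(a)` (idem for
  the RT side), which satisfies the sum constraint exactly and leaves
  every success probability unchanged to machine precision.  Rule 2
  (default) instead fixes the population means of ability and speed at
  zero.  Constraints are applied per iteration; stored draws satisfy them
  to 1e-8.  With `wl` or `td=False` the time-discrimination product
  constraint is moot (the speed scale is identified by the RT units
  directly).
* **Conventions as metadata.**  The sampler always works on the
  non-bracketed scale (which also mixes better); `par1` and the bracketed
  RT convention are reporting reparameterizations (`b~ = b/a`,
  `lambda~ = lambda/phi`), so difficulties on different scales are never
  mixed.  The practical consequence is that the hierarchical item prior is
  always placed on the non-bracketed parameters.
* **Missing data.**  Missing-by-design cells are excluded from every
  likelihood term and never imputed.  Missing-at-random cells are refreshed
  each iteration from their predictive distributions (Bernoulli for Y,
  normal for log-RT).  A fully missing record is rejected unless covered by
  the design masks (constant-speed model) or the run is a
  differential-speed fit, where such records legitimately receive
  population-average draws.
* **Starting values** are random (seed-controlled) around moment-based
  guesses: probit-transformed proportions correct for difficulties, column
  means/variances of the log-RTs for time intensities and residual
  variances.
* **Degenerate items** (all correct / all wrong) are allowed; the
  hierarchical prior regularizes them and a warning is logged.

## Fit and residual diagnostics

All fit statistics are accumulated inside the run (after `n_resid_start`
iterations), evaluating each statistic at the current draw and averaging
extreme/not-extreme indicators over draws, i.e. posterior probabilities of
aberrance.  One open design point is whether such statistics should
integrate over the prior or the posterior; this implementation accumulates
over posterior draws, which is what an MCMC run can deliver and matches the
"posterior probability of an extreme pattern" reading.

* RA person fit is the negative log-likelihood of the response pattern,
  standardized by its conditional mean and SD (the l_z construction:
  mean `sum[-p ln p - (1-p) ln(1-p)]`, variance
  `sum[p(1-p) ln^2(p/(1-p))]`), compared against the standard-normal 0.95
  quantile 1.645.  Guessed responses are excluded under the 3PL.
* RT person fit is `sum_k (rt_ik - (lambda_k - phi_k*zeta_i))^2 / sigma2_k`,
  chi-square with one degree of freedom per observed cell (missing cells
  reduce the df; for a 170-item test the 5% critical value is 201.4).
* The joint flag is the draw-wise conjunction of the two indicators.
* Item fit applies the same two constructions down an item's column.
* Latent RA residuals are Rao-Blackwellized truncated-normal means.  The
  self-consistent truncated-normal forms are used for both the mean and
  the two-sided exceedance probability (for a correct response the
  denominator is `Phi(a*theta - b)`, for an incorrect one
  `Phi(b - a*theta)`); a one-sided variant with a mismatched denominator
  can exceed 1 and is not used.  Verified against direct Monte-Carlo
  simulation of the truncated latent variable in the test suite.
* RT residual exceedance is `Phi(-C - e/s) + 1 - Phi(C - e/s)` with C = 2
  (standardized scale) by default.
* Normality of each item's standardized RT residuals is checked per draw
  with a Kolmogorov–Smirnov statistic (asymptotic Kolmogorov p-value);
  the reported quantity is the posterior rejection rate at the 5% level.
  The latent-RA analogue (and the latent-residual person test) are
  computed for completeness but have essentially no power, because
  Rao-Blackwellized residuals are bounded and far from normal even under
  the model.

## Differential working speed

Speed may change during the test: with `X_ik = (position - 1)/K` the
equidistant time scale (first item solved at 0),

    RT_ik = lambda_k - phi_k * (zeta0_i + zeta1_i*X_ik + zeta2_i*X_ik^2) + eps_ik,

and `(theta_i, zeta0_i, zeta1_i, zeta2_i)` is 4-variate normal with mean
`(mu_theta, 0, 0, 0)`.  By default the covariances among the speed
components are restricted to zero — their covariance is carried by the time
discriminations — while the ability–speed covariances stay free.  This is
parameterized as independent `zeta_j ~ N(0, sigma2_j)` plus a conjugate
normal regression `theta = mu_theta + gamma'zeta + e`, which encodes
exactly that restriction and is positive definite by construction; the
implied covariance matrix is reported.  With all `phi_k` fixed at one the
full covariance can instead be drawn from an inverse-Wishart
(`full_covariance=True`).

Identification: `prod(a) = 1`, `prod(phi) = 1`, each speed component
centered at zero per iteration with the compensating shift applied to the
time intensities through the (common) time-scale row, and — under the
default rule — `sum(b) = 0` with the mean ability left free.  The wording
"difficulty and discrimination restricted to zero and one" in this model
family is ambiguous between fixing every item and fixing the scale; this
implementation fixes the scale through the product/sum constraints,
consistent with the constant-speed rules, and treats that as its reading.
`components` selects intercept-only (the constant-speed model), linear, or
quadratic growth; guessing is not supported in this sampler.

## Synthetic data

The generator draws persons and items from the hierarchical model itself,
so recovery tests are exact self-consistency checks.  Defaults are chosen
once to look like operational licensure-exam data: mean discrimination
1.19, mean time discrimination 1.03, mean time intensity 3.96 log-seconds
(≈ 52 s), item variances (0.32, 0.27, 0.05, 0.11) with item correlations
(a,b) = −0.43, (a,phi) = 0.49, (b,lambda) = 0.46, (phi,lambda) = −0.40,
ability–speed correlation 0.4, and inverse-gamma residual variances with
mean 0.26.  Mean difficulty 0 and person variances (1, 0.25) are not
pinned down by any published magnitude on the identified scale; they were
chosen as a balanced test with speed varying about half as much as ability
(in SD terms), which is typical of joint-model applications.  Positivity
of the simulated discriminations is enforced by redrawing the full item
vector (rejection is rare at these settings, ≈2%).

What the generator does *not* emulate: raw-time censoring or rounding,
within-person strategy shifts other than the smooth growth model, local
item dependence, and not-reached missingness that correlates with speed.
Passing recovery/calibration tests therefore demonstrates correctness of
the estimator under the model, not robustness to these violations.

## Problem sizes and numerical choices

The validation suite uses sizes chosen to make Monte-Carlo error small
relative to the tolerances while keeping runs short: the recovery study is
20 replicates of N = 500 persons by K = 20 items with 3000 iterations
(10% burn-in); null calibration uses one N = 500 by K = 50 run with the
residual machinery on (2000 accumulation draws); the oracle comparison is
N = 5, K = 3 with all item parameters and the person covariance anchored,
20000 iterations against 2-D grid integration (241-point grid on
[-6, 6]^2); the nesting check compares the two samplers on the same
N = 300 by K = 15 dataset under the ident=2 convention, where both fix the
person means and leave the item locations free.

Numerical details: probit tails via `log_ndtr`; truncated-normal draws
clipped at 38 SD; a 2x2 closed-form Cholesky for the vectorized person
update; batched 4x4 Cholesky factorizations for the growth person block;
inverse-gamma draws as scale over gamma variates.  ESS uses Geyer's
initial-positive-sequence truncation of the FFT autocorrelation; MCSE is
SD/sqrt(ESS), so 400 effective draws put the Monte-Carlo error at 5% of
the posterior uncertainty.  A Geweke-style first-10%/last-50% mean
comparison is the built-in single-chain convergence check; multi-chain
diagnostics are obtained by re-running with different seeds.

## Known limitations

Binary accuracy only (no ordinal/polytomous link); two hierarchy levels;
no hidden-Markov or moderated-discrimination dynamics; no predictors for
the discriminations; the guessing mixture is not available in the
differential-speed sampler; with per-person item orders that differ, the
trend/quadratic centering compensation is approximate (exact for a shared
order).  The latent-residual normality diagnostics (`EAPKSA`, `lZPA`) are
reported but have no power by construction.
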