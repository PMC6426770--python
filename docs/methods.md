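# Methods

## Models

One trait, two methods, I parcel indicators per method (default I = 3).
The measurement model is congeneric with strong factorial invariance:
Y_im = alpha_i + lambda_i T_m + eps_im, with the first parcel as scaling
indicator (lambda = 1, alpha = 0) in both methods, fixing the scale and
origin of each trait factor. Residual covariances between identical
parcels across methods can be freed to absorb parcel-specific variance
shared by raters; the bundled application model frees all three.

Three equivalent linear structures are exposed:

* TMU: latent moments of (T1, T2) free.
* LD: latents (T_ref, M) with M = T_other − T_ref; the non-reference
  indicators load on both. The method-on-trait covariance is
  parameterized as the regression M = b0 + b1 T_ref + zeta.
* LM: latents (T, M*) with T = (T1+T2)/2, M* = (T2−T1)/2; method-factor
  loadings are −1 (method 1) and +1 (method 2), and
  M* = b0* + b1* T + zeta*. Only K = 2 methods are supported: the
  deviation algebra generalizes, but the two-method case is the one the
  package specifies and tests.

These are bijective reparameterizations, so chi-square and
log-likelihood agree across the three fits (the suite asserts 1e-6).
Useful identities: Var(M*) = Var(M)/4, E(M*) = E(M)/2, M1* = −M2*.

## Linear estimation

Models are fit to ML (divisor-N) sample moments by minimizing the
normal-theory discrepancy
F = ln|Sigma| − ln|S| + tr(S Sigma⁻¹) − p + (m − mu)' Sigma⁻¹ (m − mu)
with an analytic gradient, L-BFGS-B, and Newton polishing from a
finite-difference Hessian of the gradient (relative step 1e-6). The
polish matters: reparameterization-equivalence tests compare chi-squares
near machine precision. Convergence demands a gradient infinity-norm
below 1e-4 (typically 1e-11 is reached); rank-deficiency of the Hessian
(smallest eigenvalue < 1e-10 of the largest) raises an
under-identification error naming the null-space parameters.

* chi_square = N · F_min (multiplier N, not N−1; at the bundled
  application's N = 752 the difference is ~0.13%).
* Standard errors: inverse observed information (N/2 times the F
  Hessian); delta method for standardized and derived quantities.
* RMSEA = sqrt(max(0, (chi2 − df)/(df (N−1)))); CFI against the
  independence baseline with free means and variances (the conventional
  baseline; closed form chi2_b = N(sum ln S_ii − ln|S|)). AIC/BIC are
  reported from the ML log-likelihood.
* Starting values: loadings 1, intercepts 0, latent means at the grand
  indicator mean, latent variances at half the mean observed variance,
  error variances at half the observed variances.
* Variances are left unconstrained (no log transform) with non-PD
  detection during line search; Heywood cases surface as estimation
  errors rather than being silently truncated.

## Quadratic estimation

With M = b0 + b1 t + b2 t² + zeta (t is T_ref for LD, T for LM), the
indicators are no longer jointly normal and moment fitting is
insufficient: raw data are required. Conditional on t the model is
linear-Gaussian with mean mu(t) = m0 + m1 t + m2 t² and constant
covariance Sigma_c = Var(zeta) (Lu)(Lu)' + Theta, where Lu stacks the
method-factor loadings through the measurement model. The marginal
likelihood integrates t out with Gauss–Hermite quadrature (default 32
nodes, configurable).

Nodes are placed adaptively per subject at the Gaussian posterior of the
linearized model (mean and variance in closed form). Two consequences:

* at b2 = 0 the integrand is exactly proportional to the quadrature
  kernel, so the quadratic likelihood equals the closed-form linear
  likelihood at any node count — the LR test's nesting is exact, not
  approximate;
* for b2 ≠ 0 the integrand is a mild perturbation of the kernel and 32
  nodes agree with adaptive 1-D integration to ~1e-12 (asserted at 1e-6).

The marginal likelihood is maximized directly by L-BFGS-B with an
analytic score (Fisher's identity: posterior-weighted expectations of
the complete-data score; node positions treated as fixed, which is
exact up to quadrature error). Variances are log-parameterized inside
the optimizer; estimates are reported on the natural scale. Warm starts
come from the linear fit with b2 = 0, which also guarantees LR ≥ 0
because the optimizer is monotone. The same marginal likelihood with an
EM loop is the classical LMS formulation; direct quasi-Newton
maximization of the identical estimand is simpler and was chosen
deliberately. Statistical significance of b2 uses the df-1 chi-square LR
test (no boundary corrections); Wald SEs (central-difference Jacobian of
the analytic score) are reported for interval construction.
Solutions with any error variance below 1e-6 or collapsed latent
variances are flagged as Heywood-like; `converged` records optimizer
status.

## Curve analytics

For f(t) = b0 + b1 t + b2 t²: roots by the quadratic formula (duplicate
collapsed when |discriminant| < 1e-12), inflection −b1/(2 b2), extremum
f at the inflection, labelled u-shaped (b2 > 0) or inverted-u (b2 < 0).
|b2| ≤ 1e-10 is treated as effectively linear — below that threshold the
vertex location is numerically meaningless on these scales — and the
operations instead raise (or return the linear root). Summaries carry
in-range flags against the observed trait span rather than dropping
out-of-range values, since roots and inflections are substantively
interpretable only inside the data.

## Synthetic data and Monte Carlo

The generator draws t ~ N(mean, var), zeta ~ N(0, Var(zeta)), forms
M = b0 + b1 t + b2 t² + zeta, maps to (T1, T2) by the LD or LM
structure, and emits indicators through the invariant measurement model.
Error variances are set so each indicator's reliability (squared
completely standardized loading) hits the design target, using exact
normal moments of (t, t²) for Var(T_m). Default populations are the
bundled application estimates: loadings (1, 1.23, 1.09), intercepts
(0, 0.03, 0.09); LD predictor N(0.95, 0.69) with (0.18, −0.16),
Var(zeta) = 0.23 linear and (0.24, −0.33, 0.06) quadratic; LM predictor
N(0.93, 0.64) with Var(zeta*) = 0.06 and (−0.034, 0.11, −0.036)
quadratic. Null (Type-I) cells use the linear population with b2 = 0;
power cells keep the quadratic population's intercept/slope and set b2
from Cohen's f² ∈ {0.02, 0.15, 0.35} via f² = 2 b2² sigma⁴ / Var(zeta)
(the squared term residualized on the linear term has variance 2 sigma⁴
for a normal predictor, so b2 scales as 1/sigma²). Simulation
populations carry no cross-method error covariances, and Monte Carlo
fits correspondingly omit them.

Seeding is hierarchical: `default_rng([master_seed, replication])`, so
every cell is bit-reproducible and replications are independent streams.
Rejection rates are computed over converged replications (non-converged
ones are counted and flagged when they exceed 20%); the binomial 95% CI
accompanies each rate.

The implemented study grid is a desk-scale reduction: 200 replications
per cell over N ∈ {100, 250, 500}, reliability ∈ {0.6, 0.8}, effect ∈
{null, small, medium, large}; the recovery check uses N = 5000 with 100
replications, and in-suite calibration checks use 100–150 replications.
The generator emulates the Gaussian population models of the
application; it does not emulate the skew and kurtosis of real rating
scales, floor effects of bounded scales, missing data, or non-invariant
measurement — passing tests therefore certify the estimator under
correctly specified Gaussian populations, not robustness to violations.

## Data conventions and degenerate inputs

Indicator files are CSV with `P<i>_M<m>` columns (configurable layout);
rows with any missing cell are listwise-deleted and counted. Moment
summaries serialize to YAML/JSON as means + covariance (or
correlations + SDs). Covariances are divisor-N throughout; published
tables usually print divisor-(N−1) SDs, a difference far below the
2-decimal rounding of such tables at these sample sizes. Parcels built
from rating scales are treated as continuous; no floor/ceiling
correction is applied. Degenerate cases are defined rather than left to
chance: identical methods give a zero-variance method factor, chi2 = df
gives RMSEA 0, df = 0 flags RMSEA as undefined, and a correlation-bound
violation or asymmetric input fails fast at construction.

## Known limitations

* One trait only; LD/LM regression fits support exactly two methods.
* No FIML for missing data (listwise deletion only), no categorical or
  robust estimation, no multi-group models.
* The LR test for b2 uses the plain chi-square(1) reference.
* Published summary tables rounded to two decimals propagate visibly
  into chi-square-scale quantities refit from them; covariance-side
  parameters are far less sensitive than mean-side ones.
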