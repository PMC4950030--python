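# Methods

## The model

`hetvar` works with aggregate meta-analytic data: `k` independent studies,
each contributing an effect estimate `y_i` (log odds ratio, log hazard
ratio, mean difference, ...) and its within-study sampling variance `v_i`,
treated as known.  The random-effects (RE) model assumes

    y_i = theta_i + e_i,    e_i ~ N(0, v_i)
    theta_i = mu + d_i,     d_i ~ N(0, tau^2)

so that marginally `y_i ~ N(mu, v_i + tau^2)`.  The between-study variance
`tau^2` is the quantity of interest throughout; `mu` is pooled by inverse
variance with weights `w_i = 1/(v_i + tau^2)` (fixed-effect weights `1/v_i`
at `tau^2 = 0`).  All distributional statements are exact only when the
`v_i` are known; with estimated variances they are large-sample
approximations, which the binary-outcome generator (below) makes visible.

## Point estimators

Seventeen estimators are implemented, organised by principle:

**Generalised method of moments.**  For any positive weights `a_i` the
generalised Cochran statistic `Q_a = sum a_i (y_i - mu_a)^2` has a linear
expectation in `tau^2`; solving gives

    tau^2 = max(0, [Q_a - (sum a v - sum a^2 v / sum a)]
                    / [sum a - sum a^2 / sum a]).

DerSimonian–Laird (DL) is the special case `a_i = 1/v_i`, Hedges–Olkin (HO)
the case of constant weights, and the two-step variants DL2/HO2 re-weight
with `a_i = 1/(v_i + tau^2_step1)`.  Paule–Mandel (PM) carries the idea to
its fixed point: it solves `Q_gen(tau^2) = k - 1`, where `Q_gen` uses RE
weights and re-profiles the pooled mean at every candidate value.  `Q_gen`
is strictly decreasing, so the root is unique; it is bracketed by doubling
from `max(v_i)` and located with Brent's method (tolerance `tol`, default
1e-10).  When `Q_gen(0) <= k - 1` the PM estimate is zero by definition.
Hartung–Makambi (HM) damps the DL quadratic form by `Q/(2(k-1)+Q)` and so
never needs truncation; at `Q = 0` the formula itself vanishes, so the
package returns exactly 0 there — a boundary convention worth noting
because HM is otherwise strictly positive.  Hunter–Schmidt (HS) is
`max(0, (Q-k)/S1)` and is deliberately kept despite its negative bias.
DLp returns DL when positive and otherwise a fixed constant `c`
(default 0.01, in effect-variance units).

**Likelihood.**  ML iterates the score fixed point of the marginal normal
likelihood; REML adds the `-1/2 ln sum w` restriction term that corrects
the downward ML bias, and AREML replaces that correction with the direct
degrees-of-freedom factor `k/(k-1)`.  Iterations start at the DL estimate,
truncate at zero each step, and stop when `|Delta| <= tol (1 + tau^2)` —
a mixed relative/absolute rule chosen so the criterion behaves sensibly
near zero.  If the fixed point oscillates, the driver falls back to bounded
scalar maximisation of the (restricted) profile likelihood and accepts the
result only if the defining equation is satisfied to 1e-6; otherwise a
convergence error carrying the iteration trace is raised.  The REML inner
weighted mean is self-consistent by default (`reml_mu='self_consistent'`),
which is the stationarity condition of the restricted likelihood as
implemented and is verified against a grid-search maximiser in the tests;
an `'ml'` switch freezes the mean at ML weights for users who want the
textbook display read literally.

**Model error variance (Sidik–Jonkman).**  One weighted-least-squares step
from a crude initial variance `tau0^2` (the raw spread `sum (y-ybar)^2/k`,
or in the improved variant the HO estimate with 0.01 substituted when HO is
zero).  Because the SJ weights are RE weights up to the constant `tau0^2`,
the update is `tau^2 <- tau0^2 Q_gen(tau0^2)/(k-1)`; iterating it converges
to the PM root, a connection the tests verify exactly.  SJ is strictly
positive on any dataset whose effects are not all identical; with exactly
identical effects the weighted sum of squares is structurally zero and the
improved variant returns 0 (the original variant refuses the degenerate
initial variance).

**Bayes family.**  The Rukhin Bayes estimator shrinks the raw spread of
effects using total sample sizes `n_i` and a prior mean for `tau^2`:

    tau^2_RB = max(0, Syy/(k+1)
                      + [2k(N-k) tau2_prior - (k-1) sum v] / [(N+k)(k+1)]),

`Syy = sum (y-ybar)^2`, `N = sum n_i`.  RB0 sets the prior mean to zero;
RBp uses `(k-1) sum(v)/(2k)`, for which the `2k` factors cancel and the
estimator is strictly positive whenever `N >= k+2` (guaranteed by
`n_i >= 2`).  The grouping of this expression was fixed from the structural
requirements (prior term vanishing at zero prior mean, strict positivity of
RBp) because published renderings are typographically ambiguous; the
adopted algebra is stated in the code next to the formula.

The Bayes modal (BM) estimator maximises the profile log-likelihood in
`tau` plus the log prior of a Gamma(shape 2, rate 1e-4) on `tau`, i.e. a
`+ln tau` penalty that sends the objective to `-inf` at zero: the mode is
always interior, hence strictly positive, and always dominates ML.  The
package optimises this objective numerically (bounded Brent); the familiar
closed form `tau_BM = [tau_ML + sqrt(tau_ML^2 + 4 Var(tau_ML))]/2` is
provided as a cross-check only, because it relies on a normal Taylor
approximation and on the delta-method bridge `Var(tau) =
Var(tau^2)/(4 tau^2)` between the Fisher variance of `tau^2` and the
standard-deviation scale — a bridge that degenerates at `tau_ML = 0`.

The fully Bayesian (FB) estimate uses the hierarchical model with a flat
prior on `mu` (integrated analytically) and, by default, a half-normal
prior `tau ~ N(0, 10^4)` on `tau >= 0`.  The one-dimensional marginal
posterior of `tau` is tabulated on a deterministic 2048-node grid rather
than sampled by MCMC: results are then exactly reproducible and need no
convergence diagnostics.  The grid is built in two stages because the
marginal decays only polynomially in `tau` until the prior takes over, so
for small `k` the posterior is heavy-tailed: a coarse uniform pass extends
the grid until a local-exponential bound puts less than 1e-6 of the mass
beyond the end, then 75% of the nodes are re-laid linearly over the central
99.5% of the mass with a geometric tail.  The point summary is the
posterior median of `tau^2` (a deliberate choice — the mean is dominated by
the heavy tail at small `k`; the median is also equivariant under the
`tau -> tau^2` transform).  A long-run Metropolis sampler serves as an
independent oracle in the tests, never as the engine.

**Bootstrap (DLb).**  The mean of `B` (default 1000) re-estimates of a base
estimator (DL by default) over study-level resamples with replacement, all
drawn from one generator seeded by `opts.seed`, so results are bit-for-bit
reproducible.

Every estimator records its pre-truncation value, a truncation flag, and
iteration/convergence metadata; truncation is applied once, at the end,
with a strict `< 0` test and no tolerance.

## Confidence intervals

* **Q-profile (QP)** inverts the pivot `Q_gen(tau^2) ~ chi^2_{k-1}`:
  the bounds solve `Q_gen = chi^2_{k-1, 1-a/2}` and `chi^2_{k-1, a/2}`.
  Exact under the model with known `v_i`.  When even `Q_gen(0)` falls
  below the lower quantile the interval is the null set, reported as
  `[0, 0]` with `degenerate=True` (read: the data appear highly
  homogeneous).
* **Biggerstaff–Jackson (BJ)** and **Jackson** invert the exact cdf of `Q`
  (respectively the generalised `Q_a`, default weights `1/sqrt(v_i)`) in
  `tau^2`.  The distribution of these quadratic forms is a positive linear
  combination of chi-squared(1) variables whose coefficients are the `k-1`
  positive eigenvalues of `Sigma^{1/2} A Sigma^{1/2}`,
  `A = diag(a) - a a'/sum a`, `Sigma = diag(v_i + tau^2)`.  The BJ variant
  can equivalently be driven by the HM functional of `Q`; since that
  functional is monotone the resulting interval coincides with the
  Q-based one, which the tests use as a consistency check.
* **Biggerstaff–Tweedie (BT)** replaces the exact distribution of `Q` with
  a gamma distribution matched to its first two moments
  (`E(Q) = (S1 - S2/S1) tau^2 + k - 1`, with the corresponding quartic
  variance expression) and solves the two tail equations in `tau^2`.
* **Profile likelihood (PL)** collects the `tau^2` whose profile
  log-likelihood is within `chi^2_{1, level}/2` of the maximum.  The exact
  quantile is used rather than the rounded 3.84.  At `tau^2 = 0` the
  likelihood-ratio statistic is really a mixture of `chi^2_1` and a point
  mass, which makes the interval conservative near the boundary; the
  standard cutoff is kept deliberately.
* **Wald (Wt)** is `tau^2_hat ± z sqrt(Var)` with the inverse-Fisher
  variances `Var(tau^2_ML) = 2/sum w^2` and
  `Var(tau^2_REML) = 2/[sum w^2 - 2 sum w^3/sum w + (sum w^2/sum w)^2]`,
  lower bound truncated at zero.  Adequate only for large `k`.
* **SJ** scales the (always positive) SJ estimate by `chi^2_{k-1}`
  quantiles; its bounds are strictly positive, so at `tau^2 = 0` it covers
  with probability zero — a structural property, tested as such.
* **Bootstrap** percentile intervals, parametric (`y_i* ~
  N(mu_hat, tau^2_hat + v_i)`) or nonparametric (pair resampling), for any
  base estimator, deterministic given the seed.
* **Credible**: equal-tailed posterior quantiles of `tau^2` from the FB
  grid.

All root searches in `tau^2` exploit monotonicity of the inverted function,
expand the bracket by doubling from `max(v_i)`, and treat hitting the cap
(`10^4 max(v_i)`) as an explicit error rather than silently truncating.
Every returned bound satisfies its defining equation to root-finder
tolerance, and the test suite re-verifies the residuals.  A warning is
emitted if an interval excludes the point estimate it is paired with; the
QP/PM pairing avoids this by construction.  A compatibility matrix
classifies every (estimator, interval) pair as naturally paired, usable in
principle, or incompatible; the CLI refuses incompatible pairs unless
`--force` is given (the adjustment such forced pairings might need is an
open question in the literature, so they are merely warned about).

## The chi-squared mixture engine

The cdf of `sum lambda_j chi^2_1` is computed by Ruben's expansion into a
mixture of central chi-squares: with `beta = min lambda`, the cdf is
`sum_n a_n F_{chi2, m+2n}(x/beta)` where the non-negative `a_n` follow a
one-term recursion and sum to one, so the truncation error after `N` terms
is bounded by `1 - sum a_n` — a rigorous, cheap accuracy control (default
1e-10).  This was preferred over characteristic-function inversion
(Imhof-type integrals), whose oscillatory semi-infinite integrand defeats
adaptive quadrature error estimates precisely in the small-`k` cases a
meta-analysis tool cares about.  Convergence of the series slows as the
spread `max lambda / min lambda` grows (terms decay like
`(1 - min/max)^n`); for inverse-variance-type weights that ratio is the
spread of the `v_i`, and a hard cap of 1e5 terms raises an explicit error
with the achieved bound rather than returning a silent approximation.
Exact special cases (single coefficient, equal coefficients) short-circuit
to scaled chi-squared cdfs.  Eigenvalues below `1e-12 max lambda` are
dropped as the structural zero of the centering constraint.

## Synthetic data generator

`simulate_normal_meta` draws, per replicate, `theta_i ~ N(mu, tau^2)` and
`y_i ~ N(theta_i, v_i)` with `v_i` fixed and known — the default
within-variance rule draws the `v_i` once, uniformly from a stated range
(default `[0.05, 0.3]`, a typical spread for log odds/hazard ratios from
moderately sized trials), and holds them fixed across replicates to mimic
the known-variances assumption; an option redraws them each replicate.
The default evaluation scenario uses `k = 10` studies and `tau^2 = 0.1`,
i.e. a moderately heterogeneous meta-analysis of typical size.  Each
replicate owns an RNG stream keyed by `(seed, rep_index)` through numpy's
`SeedSequence`, so any subset of replicates can be recomputed in any order
with identical results.

`simulate_binary_meta` generates 2x2 tables (binomial arms, per-study
control risk, true log odds ratios `theta_i ~ N(mu, tau^2)`) and computes
empirical log odds ratios with the Woolf variance, adding the 0.5
continuity correction to all four cells of a table only when it contains a
zero cell; double-zero/double-full tables are redrawn.  Its `v_i` are
therefore *estimated*, which is exactly the regime in which the
known-variance optimality claims degrade.

What the generator does **not** emulate: correlation between `y_i` and
`v_i` (present in real log-OR data), non-normal random effects,
small-study/publication bias, and outcome-measure-specific variance
estimation error.  Passing coverage and unbiasedness tests therefore
demonstrate correctness of the implementations under the stated model, not
robustness of the methods on arbitrary real data.

## Evaluation harness and problem sizes

`run_estimator_study` reports per-method mean, bias (also of the
untruncated values, for the unbiasedness theory), MSE, proportion of zero
estimates and Monte-Carlo standard errors; `run_interval_study` reports
coverage, per-tail miss rates, degenerate proportion and mean width with
binomial standard errors.  Per-replicate estimator failures are excluded
and counted.  The shipped calibration runs (tests and
`scripts/acceptance.py`) use 5000 replicates for interval coverage and
10000 for estimator bias, sizes at which three binomial/Monte-Carlo
standard errors resolve the quantities of interest to a few parts per
thousand while a full run stays in the minutes range on one core.

## Known limitations

* Arm-level data ingestion (2x2 tables, means and SDs) is out of scope:
  inputs are precomputed `(y_i, v_i)`.
* The rare-event refinements of PM (continuity-corrected variance
  borrowing strength across studies) and the Mantel–Haenszel/Peto line of
  methods need count-level data and are not implemented.
* Confidence intervals for the pooled effect `mu` (Hartung–Knapp etc.) are
  not provided; the package is about `tau^2`.
* The modified Q-profile lower-bound variant and generalised-inference
  intervals are not implemented.
* Informative empirical priors for `tau^2` (evidence-based libraries of
  priors) are not bundled; the FB module accepts only half-normal and
  uniform priors on `tau`.
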