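# Methods

## The generating model

`hierbias` studies a two-group experiment with a two-level normal
hierarchy.  For group `g = 1, 2`, participant `i = 1..N`, and trial
`j = 1..K`:

    x_gij ~ Normal(theta_gi, sigma2_gi)        (trial level)
    theta_gi ~ Normal(mu_g, tau^2)             (participant level)
    mu_2 = mu_1 + delta * tau                  (standardized effect delta)

with a half-normal(scale `lam`) distribution supplying each participant's
trial-level noise scale.  The fixed generating constants are `mu1 = 6.52`,
`tau = 0.16`, `lam = 0.29`; they describe a realistic response-time-like
measurement on the seconds scale and are used unchanged in every simulation.
The design grid crosses `K in {2, 5, 15, 30}`, `N in {2, 5, 15, 30}` and
`delta in {0, 0.1, 0.5, 1}` — 64 cells, 200 replicate datasets each in the
full study.

**Half-normal convention.**  `GeneratingConfig.sigma_mode` selects whether
the half-normal draw is the trial *standard deviation* (`"sd"`, default,
`E[sigma^2] = lam^2`) or the trial *variance* itself (`"variance"`,
`E[sigma^2] = lam * sqrt(2/pi)`).  The SD reading is the default because it
reproduces the reported magnitudes of the shortcut biases (two-step type I
error around six times the nominal level, group-estimate inflation around
four times at N = 30, K = 2); the variance reading makes the sampling
variance roughly three times larger relative to `tau^2` and roughly doubles
those inflation factors.  The fitted hierarchical model always mirrors the
generator's convention, so the Bayesian analyses remain well specified
under either switch.

**Seeding.**  All randomness derives from one root seed through
`numpy.random.SeedSequence(root, spawn_key=(cell_index, replicate))`, so any
single replicate of any cell can be regenerated bit-identically and
parallel execution cannot change results.  Draws of exactly zero for the
half-normal (a measure-zero event) are redrawn.

## The two Bayesian models and their samplers

The *hierarchical* model is the generating model with priors
`mu1 ~ Normal(6, 1/3)` truncated to positive values, `tau ~ Uniform(0, 15)`,
`lam ~ Uniform(0, 10)` and `delta ~ Normal(0, 1)`.  The *non-hierarchical*
model applies the same group level directly to the participant sample means,
`xbar_gi ~ Normal(mu_g, tau^2)`, discarding the trial level — precisely the
"ignoring the hierarchy" shortcut.

Both posteriors are sampled with a hand-written Gibbs scheme:

* exact conjugate updates for `theta_gi` (normal), `mu1` (truncated normal)
  and `delta` (normal);
* slice sampling (shrinkage procedure on the bounded prior support) for
  `tau` and `lam`;
* a random-walk Metropolis step on `log sigma2_gi`, vectorised across
  participants, with per-coordinate step sizes adapted during burn-in
  towards 44% acceptance;
* an interweaving (ancillarity–sufficiency) update for `tau`: after the
  centered updates, `theta` is re-expressed as `mu_g + tau * eta` and `tau`
  is drawn from its conjugate truncated-normal conditional given `eta`.
  Without this step the centered Gibbs sampler mixes extremely slowly in
  the funnel that opens at small `K` (little information about each
  `theta_gi`, hence strong `tau`–`theta` coupling); with it, split R-hat
  drops below 1.03 within 2,000 iterations even at N = 30, K = 2.
  The same interweaving trick is why this sampler out-mixes an
  off-the-shelf centered Gibbs implementation of the identical model.

Reference chain settings follow the study design: hierarchical fits use 3
chains of 20,000 iterations, 2,000 burn-in, thinning 1-in-4 (4,500 retained
per chain); non-hierarchical fits use 3 chains of 5,000 iterations, 500
burn-in, no thinning (4,500 per chain).  The desk profile (3 x 2,000,
burn-in 500) is used for replicated simulation runs; it retains 4,500
pooled draws, comfortably above the 1,000-draw minimum the density
estimator requires.

**Validation.**  The sampler, not the model, is the artifact most likely to
be wrong, so it is validated two independent ways in the test suite:
simulation-based calibration (parameters drawn from the priors, data
simulated, posterior rank of the truth uniform over 200 replicates, checked
by chi-square at level .01 for every group-level parameter, for both
samplers), and agreement of the non-hierarchical posterior mean/SD of
`delta` with dense 3-D grid integration over `(mu1, delta, tau)` to within
0.02 on a fixed toy dataset.

**Convergence policy.**  Split-chain R-hat is computed for every parameter
(participant-level parameters report their worst entry); a fit converges
when all values are at or below 1.05.  A failing fit is retried once with
doubled iteration and burn-in counts; if it still fails, the replicate is
counted as failed and excluded from summaries — counts are carried in every
`CellSummary` and the run manifest, never silently dropped.

## The five analysis strategies

Frequentist strategies are equal-n pooled two-sample t tests,
`t = (mu2_hat - mu1_hat) / sqrt((tau2_1 + tau2_2) / N)`, two-sided at
`alpha = .05`.  Degrees of freedom are `2N - 2` for all four variants (the
equal-n pooled convention implied by the pooled standard error), and the
per-group variance estimates use the unbiased `N - 1` denominator.

* **TR** feeds in the true participant means `theta_gi` (available only in
  simulation; the reference against which the others are judged).
* **NF** feeds in the sample means `xbar_gi`; their variance is
  `tau^2 + sigma^2/K`, so the group-level variance is overestimated and
  t values shrink toward 0.
* **TF** feeds in the participant-level posterior medians from the
  hierarchical fit; shrinkage deflates their spread below `tau^2`, so t
  values inflate.
* **HF** uses the posterior medians of `mu_1`, `mu_2` and the single
  group-level SD `tau`, with standard error `sqrt(2 tau_hat^2 / N)`.  The
  model has one `tau`, hence one pooled estimate rather than per-group
  values.

Bayesian strategies compute the Savage–Dickey ratio
`BF10 = p(delta = 0 | H1) / p(delta = 0 | data, H1)` — prior over posterior
density at the point null, so `BF10 > 1` favours the alternative — for the
hierarchical and non-hierarchical models.

**Density at the null.**  The posterior density of `delta` at 0 is
estimated from at least 1,000 pooled draws by a log-spline-type fit: counts
in 300 equal bins are Poisson-regressed on a cubic B-spline basis (12
interior knots) and the fitted log-density is normalised numerically.  A
Gaussian-kernel estimate computed on the log scale is the fallback, and is
also used whenever 0 lies outside the sampled range (the spline has no data
there).  Both estimators reproduce closed-form normal densities to well
under the 2%/5% tolerances asserted in the tests.  When the posterior puts
essentially no mass at 0 the estimate is floored at 1e-300 and flagged:
such Bayes factors are "very large", not infinite, and their exact
magnitude should not be interpreted.

## Aggregation

Per design cell the harness records each strategy's rejection indicator,
t, df and p per replicate; per-model log Bayes factors paired replicate by
replicate; and the posterior SD of `delta` per model (the overconfidence
diagnostic).  Quantile-averaged posteriors (for Fig.-style summaries of the
typical posterior across replications) average matched sample quantiles on
an evenly spaced 99-point probability grid — the interpolation-free choice,
since the exact averaging rule is not otherwise pinned down.  The
difference of absolute log Bayes factors, `|log BF_H| - |log BF_NH|`, is
reported per replicate with the convention that negative values mean the
non-hierarchical model claims more evidence than the hierarchical one.

## Problem sizes used in the shipped checks

The full 64 x 200 x two-MCMC-model grid is hours of compute; the package's
own checks use the cells where theory says the biases peak, at sizes chosen
so the whole suite runs on one CPU in well under half an hour:

* frequentist-only nominal-level checks run all 16 null (N, K) cells at
  10,000 replicates;
* MCMC-dependent checks (two-step inflation, group-estimate bias,
  Bayes-factor bias, overconfidence) run the N = 30, K = 2 cell at 150
  replicates with desk-profile chains, and the N = 2 cell at 100
  replicates;
* simulation-based calibration uses 200 replicates at N = 5, K = 5 with
  two chains of 1,500 iterations.

At these sizes the Monte Carlo standard error of a rejection proportion
near .3 is about .037, which is why magnitude checks use bands of roughly
plus/minus three such errors around the expected multiples of alpha.

## What the generator does and does not emulate

The generator reproduces the stated two-level normal world exactly:
balanced groups, equal `tau` across groups, independent trials, and
participant noise scales drawn from one half-normal.  Real experimental
data violate several of these (unequal and correlated parameters across
participants, non-normal trial distributions, missingness, unequal group
sizes), and cognitive-model parameters are typically estimated, not
observed.  Passing tests therefore demonstrate the *mechanisms* of the
biases — variance inflation from ignoring the hierarchy, variance deflation
from shrinkage — not their magnitudes in any particular empirical setting;
in more complex models the same mechanisms can be stronger.

## Known limitations

* Bayes factors with the posterior far from the null are floored, so their
  magnitudes (not directions) are unreliable in high-power cells.
* `tau` is weakly identified at K = 2; its posterior concentrates well
  below the generating value, which is intrinsic to the model, not a
  sampler artifact (verified against an independent long-run Gibbs
  implementation of the same model).
* The frequentist mixed-model analysis (the recommended practice) is out of
  scope; TR plays the role of the unbiased reference instead.
* Only balanced two-group designs with a common `K` are supported.
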