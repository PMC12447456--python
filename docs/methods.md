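# Methods

## Model

Each participant's year of daily observations is modeled with a
first-order dynamic Bayesian network over four endogenous variables —
perceived busyness B, perceived restedness R, app page views PV, and
Fitbit steps per wear-time minute FS — conditioned on three exogenous
ones: messages received MS, temperature T, and the weekend indicator W.
Every endogenous node follows a linear conditional Gaussian given its
parents; the joint density factorizes node-by-node and day-by-day, as in
any Bayesian network unrolled over time slices. Day 0 is an initial
condition: it is conditioned on, never assigned a transition density.

The default parent sets follow the full dynamic hypothesis set: B and R
are pure AR(1); PV depends on its own lag plus same-day B, R, W, MS, and T;
FS depends on its own lag plus same-day PV, B, W, MS, T *and* the previous
day's PV. Two structure flags (`include_temp_on_pv`,
`include_lagged_pv_on_fs`) remove the T→PV and PV(k−1)→FS edges, which
reproduces the shorter textbook form of the difference equations. The
default keeps both because the lagged page-views→steps effect (`t_pvfs`)
is one of the reported quantities and only exists in the larger structure.

All continuous variables are standardized per participant over *observed*
entries (sample SD, ddof = 1) before modeling; W stays binary. Likert
items are treated as continuous Gaussians — the linear-Gaussian family is
the model, the 1–5 discreteness is measurement. Reported weights are
therefore standardized coefficients, and natural-unit effects are obtained
per posterior draw as weight × SD(outcome)/SD(predictor) (binary
predictors: × SD(outcome), i.e. per 0→1 switch).

Priors: Normal(0, 1) on every weight and bias, Exponential(1) on every
noise SD, on the standardized scale. These are weakly informative — a
standardized regression weight of magnitude above ~2 is implausible — and
both hyperparameters are configurable per parameter.

## Inference

The posterior over parameters and missing values jointly is sampled with a
blocked Gibbs scheme (`idiodbn.inference`):

1. **Weights + bias per node** — exact multivariate-Gaussian conjugate
   update given the node's noise SD and the current imputations.
2. **Noise SD per node** — univariate slice sampling on log σ; the
   Exponential prior enters on the natural scale with the log-scale
   Jacobian. Slice sampling needs no step-size tuning and leaves the
   target invariant exactly.
3. **Missing entries per variable** — one exact joint Gaussian draw of all
   of a variable's missing days. Conditional on everything else, the
   precision matrix over a variable's full series couples only
   day-adjacent entries (the lag-1 chain), so the missing block is
   tridiagonal after conditioning on observed days and is sampled with a
   banded Cholesky in O(n).

Defaults are 1000 kept draws after 1000 discarded warmup sweeps, one
chain. Initialization is prior-typical: weights and biases 0, noise SDs 1,
missing standardized values 0. All randomness flows through one
`numpy.random.Generator`, so a seed fixes the entire draw matrix.

Missing values are part of the state vector (data augmentation) rather
than integrated out analytically: estimation and multiple imputation
happen simultaneously, uncertainty from missingness widens the parameter
posteriors, and the approach generalizes beyond conjugate special cases.
Missingness is assumed MAR given the always-observed covariates.

One propriety detail: a missing value on day 0 enters the joint only as a
lag-1 predictor, so when the corresponding weight is near zero its
conditional would be nearly flat. Day-0 imputations therefore carry a
standard-normal prior on the standardized scale (a stationary-ish initial
distribution). The same term appears in `log_joint`, the grid oracle, and
the sampler, so all three remain mutually consistent.

### Validation oracles

Two independent routes check the sampler rather than re-deriving it:

* `conjugate_posterior_oracle` — the closed-form Gaussian posterior for a
  node's coefficients when the noise SD is fixed. With SDs pinned the
  coefficient block update *is* an exact draw from this posterior, so
  sampler means/SDs must match within Monte-Carlo error (they do, within
  3 MCSE on a 100-day fixture).
* `grid_posterior_oracle` — brute-force evaluation of `log_joint` on a
  parameter grid with missing entries marginalized by quadrature. On a
  20-day, one-free-weight, one-missing-value fixture the sampler marginal
  matches within total-variation distance 0.02 at 20,000 draws.

Monte-Carlo standard errors use bulk effective sample sizes (arviz).

## The synthetic cohort generator

`idiodbn.cohort` emulates the structure of a year-long micro-randomized
trial's daily logs. Standardized latent series evolve by the difference
equations with Gaussian innovations; exogenous processes are a calendar
weekend indicator, a seasonal temperature sinusoid (amplitude 8, noise SD
2 around a mean of 20) and truncated-Poisson messages (rate 3/day, cap
12 — a stand-in for trial randomization, which is out of scope). Latents
are de-standardized through a natural-scale registry (B, R: 3 ± 1 Likert;
PV: 40 ± 15 views; FS: 8 ± 3 steps/wear-min) and discretized the way real
measurements are: Likert values rounded and clipped to [1, 5], counts
rounded to nonnegative integers, FS clipped at zero. Discretization makes
the fitted continuous-Gaussian model an *approximation* of the generative
process, exactly as with real Likert data; the resulting attenuation is
accepted and reflected in the recovery tolerances below.

Missingness is imposed by an explicit logistic MAR mechanism on
always-observed covariates only (default: intercept −1.4 plus 0.4 on
weekends, ≈ 21% missing in B, R, and FS); mechanisms referencing maskable
variables are rejected as MNAR. Pre-mask truths ride along on the series
for evaluation only.

The default cohort is two groups of five participants, 365 days each,
mirroring the two-group study design: group A draws the page-views→steps
weight from U(0.15, 0.30) and its lag-1 version from U(0.05, 0.15); group
B draws both near zero; the temperature→steps weight is idiographic,
U(−0.2, 0.2), in both. Shared weights (e.g. messages→page-views 0.45,
busyness→page-views −0.2) sit in the 0.1–0.6 magnitude range typical of
standardized daily-dynamics coefficients. What the generator does *not*
emulate: real weather, intraday structure, nonstationarity, habituation,
or MNAR dropout — so passing tests demonstrate correct inference under the
model's assumptions, not robustness to their violation.

## Eligibility screening

Participants qualify for modeling when every maskable variable (B, R, FS)
has strictly less than 40% missingness and every modeled variable shows at
least 3 distinct observed values. The variability rule operationalizes
"sufficient within-person variability" — no published cutoff exists, so
the threshold is the weakest one under which standardization and slope
estimation are defined, and it is configurable.

## Reporting

Effects are summarized as posterior mean, SD, and the 95% equal-tailed
interval with linear-interpolation quantiles (stated so results are
bit-reproducible); highest-density intervals were not used because
reported intervals in this literature are percentile-style and symmetric
in practice. The credible flag is the exclusion rule: lower bound above
zero or upper bound below it. Group-level aggregation is idiographic-first
counting: the proportion of participants per group whose flag fires with a
given sign. Forest tables sort edges by |posterior mean| within
participant. No multiplicity adjustment is applied across edges — the
flags are a screening summary, not hypothesis tests.

The baseline-covariate table pools the two groups' published (mean, SD,
n = 5) rows exactly and runs pooled-variance two-sample t-tests from the
summary statistics (Welch available as an option); the pooled variant is
the default because it reproduces the published group comparisons.

## Study sizes and numerical choices

The simulation studies run at the study's own scale: recovery uses 20
participants × 365 days × 1000 kept draws (~40 s single-core); the
missing-data study uses 10 seeds × 3 missingness arms at 400 kept draws
each. Measured at these sizes: weight coverage ≈ 93–95% (target band
85–100%), credible-sign agreement ≈ 90–92% for |true weight| ≥ 0.2,
imputation-interval coverage ≈ 94–95%, and mean wB interval widths
increasing ≈ 0.19 → 0.22 → 0.28 across 0/20/40% busyness missingness.
The 40%-missingness arm sits on the eligibility boundary by construction,
so those fits bypass the screen deliberately.

Degenerate inputs are errors, not warnings: zero-variance variables cannot
be standardized, non-positive noise SDs have no density, MNAR mechanisms
are rejected, and a missing page-view cell is invalid input since page
views are defined to be fully observed (a gap-filled calendar day gets
zero page views — no log *is* zero views — with temperature interpolated
and EMA/steps missing).

## Known limitations

* Imputation point-accuracy is information-bounded: a missing restedness
  day is informed only by its neighbors through wR and a weak child edge,
  capping the imputation-truth correlation near 0.42 for R under the
  default dynamics (B reaches ≈ 0.55). Intervals remain calibrated — the
  posterior is honestly wide — but pooled correlation sits near 0.45.
* Likert discretization attenuates weights involving B and R by a few
  percent of an SD; at 365 days this stays well inside one posterior SD
  but would bias longer series.
* Local stationarity: one set of weights per participant per year. Trends,
  habituation, and regime shifts are future structure, not captured here.
* MAR is assumed, not tested; MNAR sensitivity analysis is out of scope.
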