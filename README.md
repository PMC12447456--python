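# idiodbn

Idiographic (n-of-1) dynamic Bayesian networks for daily mobile-health time
series: per-participant models of how app engagement, walking behavior,
intervention messages, context, and psychological state drive one another
from day to day, fit by joint MCMC with Bayesian imputation of missing
values and summarized as 95% credible-interval effects.

## The problem and the model

Digital behavior-change interventions deliver activity prompts through an
app while a wrist-worn tracker records walking. Whether they work depends
on *engagement* — and engagement is dynamic: it responds to yesterday's
behavior, today's busyness, the weekend, the weather. Group-level snapshots
miss this, so each participant gets their own model of a year of daily
data.

Each day *k* carries seven variables: perceived busyness **B** and
restedness **R** (EMA Likert 1–5, may be missing), app page views **PV**
(count, always observed), Fitbit steps per wear-time minute **FS** (may be
missing on non-wear days), messages/prompts received **MS**, temperature
**T**, and a weekend indicator **W**. A first-order dynamic Bayesian
network ties them together with linear conditional Gaussian nodes:

    B(k)  = wB·B(k−1) + bB + ε_B
    R(k)  = wR·R(k−1) + bR + ε_R
    PV(k) = wPV·PV(k−1) + wPVBU·B(k) + wPVR·R(k) + wPVW·W(k)
            + wPVMS·MS(k) + wPVT·T(k) + bPV + ε_PV
    FS(k) = wFS·FS(k−1) + wFSPV·PV(k) + wFSPV1·PV(k−1) + wFSBU·B(k)
            + wFSW·W(k) + wFSMS·MS(k) + wFST·T(k) + bFS + ε_FS

with ε ~ Normal(0, σ_node); MS, T, and W are exogenous. Weights and biases
carry Normal(0, 1) priors, noise SDs Exponential(1) priors, all on the
per-participant standardized scale. Inference is a blocked Gibbs sampler
over parameters *and* the missing entries jointly (data augmentation under
MAR), so imputation uncertainty propagates into every posterior. An edge is
flagged *credible* when its 95% equal-tailed Bayesian credible interval
excludes zero, and standardized weights are translated into natural units
(e.g. page views per message) via weight × SD(outcome)/SD(predictor).

Because real daily logs of this kind cannot be shared, the package ships a
generative twin: `idiodbn.cohort` simulates year-long cohorts from the same
equations with known ground truth, Likert discretization, and an explicit
MAR missingness mechanism — which is what makes coverage and recovery
claims testable.

## Worked example

```sh
idiodbn simulate --seed 11 --out results/cohort     # 10 participants × 365 days
idiodbn summarize results/cohort/group_a_1.csv --seed 21
```

or in Python:

```python
from idiodbn import McmcConfig, fit_participant, read_daily_csv, summarize_draws

series = read_daily_csv("results/cohort/group_a_1.csv")
post = fit_participant(series, cfg=McmcConfig(n_draws=1000, n_warmup=1000, seed=21))
for eff in summarize_draws(post):
    if eff.alias in ("t_m", "t_fsaa", "t_baa"):
        print(eff.label, eff.mean, eff.bci95, eff.credible, eff.natural_mean)
```

For this participant the run prints (rounded):

```
 alias      mean       sd  bci_lower  bci_upper  credible  natural_mean
   t_m  0.459404 0.042089   0.376154   0.542484      True      4.097150
t_fsaa  0.315836 0.060170   0.199821   0.437184      True      0.058414
 t_baa -0.233076 0.047932  -0.325376  -0.140099      True     -3.830230
```

Read: each message received predicts ~0.46 SD more page views that day —
about 4.1 extra page views per message in natural units, with a 95% BCI of
(3.35, 4.84) that clearly excludes zero; each page view predicts ~0.06 more
steps per wear-minute; and a one-point-busier day predicts ~3.8 fewer page
views. The `analysis/` scripts chain the full workflow: simulate → fit →
group-level credible-effect counts → baseline table → missing-data and
recovery studies, writing tables under `results/`.

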