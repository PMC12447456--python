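#!/usr/bin/env python
"""Fit one idiographic DBN per participant and save draws and effects.

Reads the daily logs written by 01_simulate_cohort.py, screens each
participant for eligibility, runs the joint MCMC (1000 kept draws after
1000 warmup sweeps), and writes per-participant draw tables and per-edge
effect summaries (posterior mean, SD, 95% BCI, credible flag, natural-unit
effect).
"""

from pathlib import Path

from idiodbn.daily_data import check_eligibility, read_daily_csv, summarize_missingness
from idiodbn.inference import McmcConfig, fit_participant
from idiodbn.summaries import forest_report, summarize_draws

SEED = 21
IN_DIR = Path("results/cohort")
OUT = Path("results/fits")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    participants = {}
    for i, path in enumerate(sorted(IN_DIR.glob("group_*.csv"))):
        series = read_daily_csv(path)
        elig = check_eligibility(summarize_missingness(series))
        if not elig.eligible:
            print(f"{series.participant_id}: skipped ({'; '.join(elig.reasons)})")
            continue
        post = fit_participant(
            series, cfg=McmcConfig(n_draws=1000, n_warmup=1000, seed=SEED + i)
        )
        post.to_frame().to_csv(
            OUT / f"{series.participant_id}_draws.csv", index=False, float_format="%.6g"
        )
        effects = summarize_draws(post)
        participants[series.participant_id] = effects
        credible = [e.label for e in effects if e.credible]
        print(f"{series.participant_id}: credible edges -> {', '.join(credible)}")
    report = forest_report(participants)
    report.to_csv(OUT / "effects.csv", index=False, float_format="%.6g")
    print(f"wrote draws and {len(report)} effect rows to {OUT}/")


if __name__ == "__main__":
    main()
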