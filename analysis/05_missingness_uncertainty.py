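#!/usr/bin/env python
"""Posterior uncertainty and imputation quality as missingness grows.

Masks the busyness series at 0%, 20%, and 40% (MAR) across 10 simulated
participants, refits each arm, and reports the average width of the wB
(busyness autoregression) 95% interval, the coverage of imputed-value
intervals against held-out truth, and the imputation-truth correlation.
"""

import json
from pathlib import Path

from idiodbn.experiments import missingness_study

SEED = 31
OUT = Path("results")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    res = missingness_study(rates=(0.0, 0.2, 0.4), n_seeds=10, seed=SEED)
    print("mean 95% interval width of wB by missingness rate:")
    for rate, width in zip(res.rates, res.mean_widths):
        print(f"  {int(100 * rate):>3d}% missing -> width {width:.4f}")
    print(f"widths non-decreasing: {res.monotone}")
    print(
        f"imputation: 95% intervals cover truth {100 * res.imputation_coverage:.1f}% "
        f"of {res.imputation_n} held-out entries; correlation with truth "
        f"{res.imputation_correlation:.3f}"
    )
    (OUT / "missingness_uncertainty.json").write_text(
        json.dumps(
            {
                "rates": list(res.rates),
                "mean_widths": res.mean_widths,
                "monotone": res.monotone,
                "imputation_coverage": res.imputation_coverage,
                "imputation_correlation": res.imputation_correlation,
                "n_entries": res.imputation_n,
            },
            indent=1,
        )
    )


if __name__ == "__main__":
    main()
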