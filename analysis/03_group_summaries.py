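#!/usr/bin/env python
"""Aggregate idiographic fits to the group level.

Reads the per-edge effect table from 02_fit_models.py, counts credible
effects per group for each labeled edge, and renders the forest-style
summary plot.  This is the idiographic-first workflow: each participant's
model is estimated alone, then findings are pooled by counting.
"""

from pathlib import Path

import pandas as pd

IN = Path("results/fits/effects.csv")
OUT = Path("results/group")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    df = pd.read_csv(IN)
    df["group"] = df["participant"].str.rsplit("_", n=1).str[0]

    rows = []
    for alias, sub in df.groupby("alias"):
        for group, g in sub.groupby("group"):
            pos = int(((g.credible) & (g.bci_lower > 0)).sum())
            neg = int(((g.credible) & (g.bci_upper < 0)).sum())
            rows.append(
                {
                    "edge": alias,
                    "group": group,
                    "n": len(g),
                    "credible_positive": pos,
                    "credible_negative": neg,
                    "proportion_credible": (pos + neg) / len(g),
                }
            )
    counts = pd.DataFrame(rows).sort_values(["edge", "group"])
    counts.to_csv(OUT / "credible_counts.csv", index=False)
    print(counts.to_string(index=False))

    interesting = counts[counts.proportion_credible >= 0.8]
    print("\nedges credible for >= 80% of a group:")
    print(interesting.to_string(index=False) if len(interesting) else "  (none)")


if __name__ == "__main__":
    main()
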