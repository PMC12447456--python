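"""Cohort descriptive statistics, group comparisons, and missingness exports.

Covers the sample-description side of the analysis: per-group and overall
summary statistics for baseline covariates, exact pooling of per-group
(mean, SD, n) rows into combined-sample statistics, two-sample t-tests run
from summary statistics, and the long-format missing-data table behind
participant × day heatmaps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .daily_data import DailySeries


class StatsError(ValueError):
    pass


#: Baseline characteristics of the ten-adult sample the cohort presets
#: emulate: per-group (mean, SD) with n = 5 in each group.
BASELINE_GROUPS: dict[str, dict] = {
    "hispanic_latino": {
        "n": 5,
        "age": (42.4, 7.44),
        "bmi": (34.84, 4.91),
        "baseline_steps": (4361.63, 643.81),
    },
    "nh_white": {
        "n": 5,
        "age": (50.2, 5.31),
        "bmi": (28.24, 2.91),
        "baseline_steps": (8116.69, 3843.84),
    },
}


@dataclass
class GroupStats:
    label: str
    n: int
    mean: float
    sd: float
    median: float
    iqr: float
    degenerate: bool = False  # single observation: SD 0 by convention

    def __post_init__(self) -> None:
        if self.n < 1 or self.sd < 0 or self.iqr < 0:
            raise StatsError("invalid group statistics")


def _stats_for(label: str, values: np.ndarray) -> GroupStats:
    values = np.asarray(values, dtype=float)
    n = len(values)
    q25, q75 = np.quantile(values, [0.25, 0.75], method="linear")
    return GroupStats(
        label=label,
        n=n,
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)) if n > 1 else 0.0,
        median=float(np.median(values)),
        iqr=float(q75 - q25),
        degenerate=n == 1,
    )


def describe_cohort(
    records: pd.DataFrame, covariates: Sequence[str] | None = None
) -> dict[str, dict[str, GroupStats]]:
    """Per-group and overall mean/SD/median/IQR for each covariate.

    ``records`` has one row per participant with a ``group`` column; SD uses
    ddof=1, IQR is the 75th − 25th percentile with linear interpolation.
    """
    if len(records) < 1:
        raise StatsError("need at least one participant")
    covariates = covariates or [c for c in records.columns if c != "group"]
    out: dict[str, dict[str, GroupStats]] = {}
    for cov in covariates:
        per: dict[str, GroupStats] = {
            "overall": _stats_for("overall", records[cov].to_numpy())
        }
        for group, sub in records.groupby("group"):
            per[str(group)] = _stats_for(str(group), sub[cov].to_numpy())
        out[cov] = per
    return out


def pool_group_stats(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> tuple[float, float]:
    """Combine two groups' (mean, SD, n) into exact combined-sample stats.

    Combined variance = [(n1−1)s1² + (n2−1)s2² + n1(m1−M)² + n2(m2−M)²]
    / (n1 + n2 − 1), with M the weighted mean.
    """
    if n1 < 1 or n2 < 1:
        raise StatsError("both groups need n >= 1")
    if s1 < 0 or s2 < 0:
        raise StatsError("SDs must be nonnegative")
    n = n1 + n2
    mean = (n1 * m1 + n2 * m2) / n
    var = (
        (n1 - 1) * s1**2
        + (n2 - 1) * s2**2
        + n1 * (m1 - mean) ** 2
        + n2 * (m2 - mean) ** 2
    ) / (n - 1)
    return mean, math.sqrt(var)


def two_sample_ttest(
    m1: float,
    s1: float,
    n1: int,
    m2: float,
    s2: float,
    n2: int,
    variant: str = "pooled",
) -> tuple[float, float, float]:
    """Two-sided two-sample t-test from summary statistics.

    ``variant`` is ``pooled`` (equal-variance, the default) or ``welch``.
    Returns (t, df, p).  Zero pooled variance: equal means give t=0, p=1 by
    convention; unequal means are an error.
    """
    if n1 < 2 or n2 < 2:
        raise StatsError("both groups need n >= 2")
    if variant not in ("pooled", "welch"):
        raise StatsError("variant must be pooled|welch")
    if s1 == 0.0 and s2 == 0.0:
        if m1 == m2:
            return 0.0, float(n1 + n2 - 2), 1.0
        raise StatsError("zero pooled variance with unequal means")
    res = stats.ttest_ind_from_stats(
        m1, s1, n1, m2, s2, n2, equal_var=(variant == "pooled")
    )
    if variant == "pooled":
        df = float(n1 + n2 - 2)
    else:
        a, b = s1**2 / n1, s2**2 / n2
        df = (a + b) ** 2 / (a**2 / (n1 - 1) + b**2 / (n2 - 1))
    return float(res.statistic), df, float(res.pvalue)


def baseline_table(groups: dict[str, dict] | None = None) -> pd.DataFrame:
    """Pooled overall row plus t-tests for each baseline covariate."""
    groups = groups or BASELINE_GROUPS
    (g1, d1), (g2, d2) = list(groups.items())
    rows = []
    for cov in ("age", "bmi", "baseline_steps"):
        m1, s1 = d1[cov]
        m2, s2 = d2[cov]
        mean, sd = pool_group_stats(m1, s1, d1["n"], m2, s2, d2["n"])
        t, df, p = two_sample_ttest(m1, s1, d1["n"], m2, s2, d2["n"])
        rows.append(
            {
                "covariate": cov,
                f"{g1}_mean": m1, f"{g1}_sd": s1,
                f"{g2}_mean": m2, f"{g2}_sd": s2,
                "overall_mean": mean, "overall_sd": sd,
                "t": t, "df": df, "p": p,
            }
        )
    return pd.DataFrame(rows)


def missingness_heatmap_export(cohort: Iterable[DailySeries]) -> pd.DataFrame:
    """Long-format missingness table: participant × day × variable → category.

    EMA variables (busyness, restedness) are ``observed`` or ``missing``;
    daily steps are ``zero`` / ``nonzero`` / ``missing`` so that zero-step
    days (often non-wear) are distinguishable in a heatmap.
    """
    rows = []
    for series in cohort:
        for var, name in (("B", "busyness"), ("R", "restedness"), ("FS", "steps")):
            arr = series[var]
            for day in range(series.n_days):
                val = arr[day]
                if np.isnan(val):
                    cat = "missing"
                elif var == "FS":
                    cat = "zero" if val == 0.0 else "nonzero"
                else:
                    cat = "observed"
                rows.append(
                    {
                        "participant": series.participant_id,
                        "day": day,
                        "variable": name,
                        "category": cat,
                    }
                )
    return pd.DataFrame(rows, columns=["participant", "day", "variable", "category"])
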