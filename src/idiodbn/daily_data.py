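"""Daily-log domain types, file I/O, standardization, and eligibility screening.

One participant's record is a :class:`DailySeries`: a consecutive run of
calendar days carrying seven daily variables from a wearable + app study —

====  =============================  =========================================
key   CSV column                     meaning
====  =============================  =========================================
B     busyness                       perceived busyness, EMA Likert 1–5
R     restedness                     perceived restedness, EMA Likert 1–5
PV    page_views                     daily app page views (fully observed)
FS    steps_per_wear_min             Fitbit steps per minute of wear time
MS    messages                       messages/prompts received that day
T     temperature                    daily temperature (units arbitrary)
W     weekend                        1 on Saturday/Sunday, else 0
====  =============================  =========================================

B, R and FS may be missing (EMA non-response, tracker non-wear); PV, MS, T
and W are always observed.  Missing cells are NaN internally and empty cells
in CSV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: canonical variable order
VARIABLES = ("B", "R", "PV", "FS", "MS", "T", "W")

#: variables that may contain missing entries
MASKABLE = ("B", "R", "FS")

#: continuous variables that standardization applies to (never W)
STANDARDIZABLE = ("B", "R", "PV", "FS", "MS", "T")

#: variables entering the dynamic model (screened for variability)
MODELED = ("B", "R", "PV", "FS")

CSV_COLUMNS = {
    "B": "busyness",
    "R": "restedness",
    "PV": "page_views",
    "FS": "steps_per_wear_min",
    "MS": "messages",
    "T": "temperature",
    "W": "weekend",
}
_CSV_TO_KEY = {v: k for k, v in CSV_COLUMNS.items()}


class DataError(ValueError):
    """A daily-log record violates a structural invariant."""


@dataclass
class DailySeries:
    """One participant's day-indexed multivariate daily record.

    ``values`` maps each variable key to a float array of length ``n_days``;
    missing entries are NaN.  ``masked_truth`` (set by the synthetic-data
    masking step, for evaluation only) holds the pre-mask values of entries
    that were hidden: NaN everywhere except at masked positions.
    """

    participant_id: str
    group: str
    dates: pd.DatetimeIndex
    values: dict[str, np.ndarray]
    masked_truth: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.values = {k: np.asarray(v, dtype=float) for k, v in self.values.items()}
        self.validate()

    @property
    def n_days(self) -> int:
        return len(self.dates)

    def __getitem__(self, key: str) -> np.ndarray:
        return self.values[key]

    def missing_mask(self, key: str) -> np.ndarray:
        return np.isnan(self.values[key])

    def validate(self) -> None:
        n = len(self.dates)
        if n < 1:
            raise DataError("empty series")
        deltas = np.diff(self.dates.values).astype("timedelta64[D]").astype(int)
        if n > 1 and not np.all(deltas == 1):
            raise DataError("calendar days must be consecutive")
        for key in VARIABLES:
            if key not in self.values:
                raise DataError(f"variable {key} absent")
            if len(self.values[key]) != n:
                raise DataError(f"variable {key} has wrong length")
        for key in ("PV", "MS", "T", "W"):
            if np.isnan(self.values[key]).any():
                if key == "PV":
                    raise DataError("PV must be fully observed")
                raise DataError(f"{key} must be fully observed")
        for key in ("B", "R"):
            obs = self.values[key][~np.isnan(self.values[key])]
            if obs.size and (obs.min() < 1 or obs.max() > 5):
                raise DataError(f"Likert out of range in {key}")
        for key in ("PV", "FS", "MS"):
            obs = self.values[key][~np.isnan(self.values[key])]
            if obs.size and obs.min() < 0:
                raise DataError(f"{key} must be nonnegative")
        w = self.values["W"]
        expected_w = (self.dates.dayofweek >= 5).astype(float)
        if not np.array_equal(w, expected_w):
            raise DataError("weekend indicator inconsistent with calendar")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"participant_id": self.participant_id, "date": self.dates.strftime("%Y-%m-%d")})
        for key in VARIABLES:
            df[CSV_COLUMNS[key]] = self.values[key]
        return df


@dataclass
class StandardizedSeries:
    """Per-variable z-scored series with the scales needed to invert.

    Continuous variables are z-scored over *observed* entries only (sample
    SD, ddof=1); W passes through on its 0/1 scale.  ``scales`` maps each
    standardized variable to its (mean, SD).
    """

    values: dict[str, np.ndarray]
    scales: dict[str, tuple[float, float]]
    n_days: int

    def inverse(self) -> dict[str, np.ndarray]:
        """Map back to natural units (observed and imputed entries alike)."""
        out = {}
        for key, arr in self.values.items():
            if key in self.scales:
                mu, sd = self.scales[key]
                out[key] = mu + sd * arr
            else:
                out[key] = arr.copy()
        return out


@dataclass
class MissingnessSummary:
    fraction: dict[str, float]
    unique_observed: dict[str, int]
    n_days: int


@dataclass
class Eligibility:
    eligible: bool
    reasons: list[str] = field(default_factory=list)


def weekend_indicator(dates: pd.DatetimeIndex) -> np.ndarray:
    return (dates.dayofweek >= 5).astype(float)


def read_daily_csv(path, *, sentinel: str = "", fill_gaps: bool = False) -> DailySeries:
    """Read one participant's daily log.

    Rows are sorted by date; non-consecutive calendars raise unless
    ``fill_gaps`` inserts rows (page views and messages 0 on inserted days —
    a day with no logged views is zero views — temperature interpolated,
    B/R/FS missing).  The missing-cell sentinel defaults to the empty cell.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"participant_id", "date"} | {CSV_COLUMNS[k] for k in VARIABLES if k != "W"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise DataError(f"missing columns: {sorted(missing_cols)}")
    try:
        dates = pd.DatetimeIndex(pd.to_datetime(df["date"], format="%Y-%m-%d"))
    except (ValueError, TypeError) as exc:
        raise DataError(f"malformed date: {exc}") from exc
    order = np.argsort(dates.values, kind="stable")
    df = df.iloc[order].reset_index(drop=True)
    dates = dates[order]

    def col(key: str) -> np.ndarray:
        raw = df[CSV_COLUMNS[key]].to_numpy()
        out = np.empty(len(raw))
        for i, cell in enumerate(raw):
            cell = cell.strip()
            if cell == sentinel:
                out[i] = np.nan
            else:
                try:
                    out[i] = float(cell)
                except ValueError as exc:
                    raise DataError(f"bad value {cell!r} in {CSV_COLUMNS[key]}") from exc
        return out

    values = {k: col(k) for k in VARIABLES if k != "W"}
    if "weekend" in df.columns:
        values["W"] = col("W")
    else:
        values["W"] = weekend_indicator(dates)

    if np.isnan(values["PV"]).any():
        raise DataError("PV must be fully observed")

    gaps = np.diff(dates.values).astype("timedelta64[D]").astype(int) if len(dates) > 1 else np.array([])
    if gaps.size and (gaps != 1).any():
        if (gaps < 1).any():
            raise DataError("duplicate dates")
        if not fill_gaps:
            raise DataError("non-consecutive calendar (pass fill_gaps=True to insert missing rows)")
        full = pd.date_range(dates[0], dates[-1], freq="D")
        frame = pd.DataFrame(values, index=dates).reindex(full)
        frame["PV"] = frame["PV"].fillna(0.0)
        frame["MS"] = frame["MS"].fillna(0.0)
        frame["T"] = frame["T"].interpolate(limit_direction="both")
        dates = pd.DatetimeIndex(full)
        values = {k: frame[k].to_numpy() for k in VARIABLES if k != "W"}
        values["W"] = weekend_indicator(dates)

    pid = str(df["participant_id"].iloc[0]) if len(df) else "unknown"
    group = str(df["group"].iloc[0]) if "group" in df.columns else "unknown"
    return DailySeries(participant_id=pid, group=group, dates=dates, values=values)


def write_daily_csv(series: DailySeries, path, *, sentinel: str = "") -> None:
    """Write the daily-log CSV dialect; inverse of :func:`read_daily_csv`."""
    df = series.to_frame()
    df.insert(1, "group", series.group)
    for key in ("PV", "MS", "W"):
        df[CSV_COLUMNS[key]] = df[CSV_COLUMNS[key]].astype(int)
    df.to_csv(path, index=False, na_rep=sentinel)


def summarize_missingness(series: DailySeries) -> MissingnessSummary:
    """Per-variable missing fraction and distinct-observed-value counts."""
    frac, uniq = {}, {}
    n = series.n_days
    for key in ("B", "R", "PV", "FS", "MS", "T"):
        arr = series.values[key]
        obs = arr[~np.isnan(arr)]
        frac[key] = float(np.isnan(arr).sum()) / n
        uniq[key] = int(np.unique(obs).size)
    return MissingnessSummary(fraction=frac, unique_observed=uniq, n_days=n)


def check_eligibility(
    summary: MissingnessSummary,
    max_missing: float = 0.40,
    min_unique: int = 3,
    screened: Sequence[str] = MASKABLE,
    modeled: Sequence[str] = MODELED,
) -> Eligibility:
    """Data-sufficiency screen for dynamic modeling.

    A participant is eligible iff every screened variable has missing
    fraction strictly below ``max_missing`` and every modeled variable shows
    at least ``min_unique`` distinct observed values (enough within-person
    variability to estimate dynamics).
    """
    reasons = []
    for key in screened:
        if summary.fraction[key] >= max_missing:
            reasons.append(
                f"{key}: missing fraction {summary.fraction[key]:.3f} >= {max_missing:g}"
            )
    for key in modeled:
        if summary.unique_observed[key] < min_unique:
            reasons.append(
                f"{key}: insufficient variability "
                f"({summary.unique_observed[key]} unique observed values < {min_unique})"
            )
    return Eligibility(eligible=not reasons, reasons=reasons)


def standardize(series: DailySeries, variables: Sequence[str] = STANDARDIZABLE) -> StandardizedSeries:
    """Z-score the named continuous variables over observed entries.

    Uses observed-data sample moments (SD with ddof=1).  Missing entries
    stay NaN.  W is never standardized and passes through as 0/1.
    """
    values: dict[str, np.ndarray] = {}
    scales: dict[str, tuple[float, float]] = {}
    for key in variables:
        if key == "W":
            raise DataError("W is binary and is never standardized")
        arr = series.values[key]
        obs = arr[~np.isnan(arr)]
        if np.unique(obs).size < 2:
            raise DataError(f"zero variance: {key} has < 2 distinct observed values")
        mu = float(obs.mean())
        sd = float(obs.std(ddof=1))
        values[key] = (arr - mu) / sd
        scales[key] = (mu, sd)
    values["W"] = series.values["W"].copy()
    return StandardizedSeries(values=values, scales=scales, n_days=series.n_days)
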