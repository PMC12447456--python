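"""Synthetic daily-cohort generator with known ground truth.

The study data these models were designed for are not shareable, so this
module generates cohorts of daily series from the DBN generative model
itself: standardized latent dynamics evolved by the difference equations
with Gaussian innovations, de-standardized through a natural-scale registry
and discretized the way the real measurements are (Likert rounding/clipping
for the EMA items, integer counts for page views and messages, nonnegative
steps-per-wear-minute).  Missingness is then imposed by an explicitly
missing-at-random mechanism that depends only on always-observed covariates,
with the pre-mask truth kept alongside for evaluation.

Two cohort presets mirror the study design: two groups of five participants
followed for a year, with the page-views→steps coupling drawn positive in
one group and near zero in the other, and idiographic (per-participant)
temperature effects in both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .daily_data import DailySeries, MASKABLE, weekend_indicator
from .dbn import DBNStructure, ModelError, default_structure, zero_params

#: natural-scale (mean, SD) registry used to de-standardize the latent series
DEFAULT_SCALES: dict[str, tuple[float, float]] = {
    "B": (3.0, 1.0),        # Likert 1–5
    "R": (3.0, 1.0),
    "PV": (40.0, 15.0),     # app page views / day
    "FS": (8.0, 3.0),       # steps per wear-time minute
    "MS": (3.0, math.sqrt(3.0)),  # Poisson(3) messages / day
    "T": (20.0, 6.0),       # °C; sinusoid amplitude 8 + noise ≈ SD 6
}

#: standardized-scale weights shared by both presets (idiographic entries
#: and the group-contrast entries are drawn per participant by the presets)
DEFAULT_PARAMS: dict[str, float] = {
    "wB": 0.4, "bB": 0.0, "sigma_B": 0.9,
    "wR": 0.3, "bR": 0.0, "sigma_R": 0.95,
    "wPV": 0.3, "wPVBU": -0.2, "wPVR": 0.1, "wPVW": 0.2, "wPVMS": 0.45,
    "wPVT": 0.05, "bPV": 0.0, "sigma_PV": 0.8,
    "wFS": 0.3, "wFSPV": 0.2, "wFSBU": -0.15, "wFSW": 0.1, "wFSMS": -0.12,
    "wFST": 0.1, "wFSPV1": 0.1, "bFS": 0.0, "sigma_FS": 0.8,
}


class SimulationError(ValueError):
    """Invalid ground truth or missingness mechanism."""


@dataclass
class GroundTruth:
    """Standardized-scale parameters plus the natural-scale registry."""

    params: dict[str, float]
    scales: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SCALES)
    )
    message_rate: float = 3.0
    message_cap: int = 12
    temp_amplitude: float = 8.0
    temp_noise_sd: float = 2.0
    temp_phase_days: float = -80.0
    start_date: str = "2019-01-01"

    def __post_init__(self) -> None:
        for name, val in self.params.items():
            if name.startswith("sigma") and val < 0:
                raise SimulationError(f"negative noise SD {name}")
        for key, (_, sd) in self.scales.items():
            if sd <= 0:
                raise SimulationError(f"non-positive natural SD for {key}")
        if self.message_rate < 0 or self.temp_noise_sd < 0:
            raise SimulationError("rates and noise SDs must be nonnegative")


@dataclass
class MarMechanism:
    """Logistic missingness on always-observed covariates (hence MAR).

    ``coeffs`` maps covariate names to logistic coefficients; allowed keys
    are ``intercept``, ``W``, ``MS``, ``T``, and ``day_frac`` (day index
    scaled to [0, 1]).  Referencing a maskable variable would make the
    mechanism missing-not-at-random and is rejected.
    """

    coeffs: dict[str, float] = field(default_factory=lambda: {"intercept": -1.4})
    variables: tuple[str, ...] = MASKABLE

    _ALLOWED = ("intercept", "W", "MS", "T", "day_frac")

    def __post_init__(self) -> None:
        bad = [k for k in self.coeffs if k not in self._ALLOWED]
        if bad:
            raise SimulationError(
                f"MAR mechanism may only reference always-observed covariates; got {bad}"
            )
        bad_vars = [v for v in self.variables if v not in MASKABLE]
        if bad_vars:
            raise SimulationError(f"cannot mask always-observed variables {bad_vars}")

    def probabilities(self, series: DailySeries) -> np.ndarray:
        n = series.n_days
        eta = np.full(n, self.coeffs.get("intercept", 0.0))
        if "W" in self.coeffs:
            eta = eta + self.coeffs["W"] * series["W"]
        if "MS" in self.coeffs:
            eta = eta + self.coeffs["MS"] * series["MS"]
        if "T" in self.coeffs:
            eta = eta + self.coeffs["T"] * series["T"]
        if "day_frac" in self.coeffs:
            eta = eta + self.coeffs["day_frac"] * (np.arange(n) / max(n - 1, 1))
        return expit(eta)


@dataclass
class CohortPreset:
    """A group recipe: shared weights, per-participant draws, missingness."""

    group: str
    n_participants: int = 5
    n_days: int = 365
    base_params: dict[str, float] = field(default_factory=dict)
    random_weights: dict[str, tuple[float, float]] = field(default_factory=dict)
    mechanism: MarMechanism | None = field(
        default_factory=lambda: MarMechanism({"intercept": -1.4, "W": 0.4})
    )
    scales: dict[str, tuple[float, float]] | None = None


def default_presets() -> list[CohortPreset]:
    """Two five-participant groups for one study year.

    Group A draws a clearly positive page-views→steps coupling (and a
    positive lag-1 version of it); group B draws both near zero.  The
    temperature→steps weight is idiographic in both groups.  The default
    missingness mechanism leaves roughly a fifth of EMA and steps entries
    missing — comfortably inside the sub-40% eligibility band.
    """
    mech = MarMechanism({"intercept": -1.4, "W": 0.4})
    return [
        CohortPreset(
            group="group_a",
            random_weights={
                "wFSPV": (0.15, 0.30),
                "wFSPV1": (0.05, 0.15),
                "wFST": (-0.2, 0.2),
            },
            mechanism=mech,
        ),
        CohortPreset(
            group="group_b",
            random_weights={
                "wFSPV": (-0.05, 0.05),
                "wFSPV1": (-0.05, 0.05),
                "wFST": (-0.2, 0.2),
            },
            mechanism=mech,
        ),
    ]


def simulate_participant(
    truth: GroundTruth,
    n_days: int = 365,
    seed: int = 0,
    participant_id: str = "p1",
    group: str = "group_a",
    structure: DBNStructure | None = None,
) -> DailySeries:
    """Generate one participant's fully observed daily series.

    Exogenous processes: W from the calendar, T a seasonal sinusoid plus
    Gaussian noise, MS truncated Poisson.  Endogenous standardized series
    start at bias + innovation on day 0 and evolve by the difference
    equations; observed values are de-standardized and discretized.
    """
    if n_days < 2:
        raise SimulationError("n_days must be >= 2")
    structure = structure or default_structure()
    params = dict(zero_params(structure))
    params.update(truth.params)
    rng = np.random.default_rng(seed)

    dates = pd.date_range(truth.start_date, periods=n_days, freq="D")
    w = weekend_indicator(dates)
    day = np.arange(n_days)
    t_mean, _ = truth.scales["T"]
    t_nat = (
        t_mean
        + truth.temp_amplitude * np.sin(2 * np.pi * (day - truth.temp_phase_days) / 365.25)
        + rng.normal(0.0, truth.temp_noise_sd, n_days)
    )
    ms_nat = np.minimum(rng.poisson(truth.message_rate, n_days), truth.message_cap).astype(float)

    std: dict[str, np.ndarray] = {"W": w}
    for key, nat in (("MS", ms_nat), ("T", t_nat)):
        mu, sd = truth.scales[key]
        std[key] = (nat - mu) / sd
    for name in structure.nodes:
        std[name] = np.zeros(n_days)

    order = list(structure.nodes)  # B, R, PV, FS is topological at lag 0
    for name in order:
        spec = structure.node(name)
        std[name][0] = params[spec.bias_name] + rng.normal(0.0, params[spec.noise_sd_name])
    for k in range(1, n_days):
        for name in order:
            spec = structure.node(name)
            mean = params[spec.bias_name]
            for (p, lag), wname in zip(spec.parents, spec.weight_names):
                mean += params[wname] * std[p][k - lag]
            std[name][k] = mean + rng.normal(0.0, params[spec.noise_sd_name])

    def destd(key: str) -> np.ndarray:
        mu, sd = truth.scales[key]
        return mu + sd * std[key]

    values = {
        "B": np.clip(np.round(destd("B")), 1, 5),
        "R": np.clip(np.round(destd("R")), 1, 5),
        "PV": np.maximum(np.round(destd("PV")), 0),
        "FS": np.maximum(destd("FS"), 0.0),
        "MS": ms_nat,
        "T": t_nat,
        "W": w,
    }
    return DailySeries(participant_id=participant_id, group=group, dates=dates, values=values)


def impose_mar_missingness(
    series: DailySeries, mechanism: MarMechanism, seed: int = 0
) -> DailySeries:
    """Mask B, R, FS entries independently with the mechanism's logistic
    probabilities; PV, MS, T, W are never masked.  The pre-mask values are
    kept on ``masked_truth`` for evaluation only."""
    rng = np.random.default_rng(seed)
    probs = mechanism.probabilities(series)
    values = {k: v.copy() for k, v in series.values.items()}
    truth: dict[str, np.ndarray] = {}
    for var in mechanism.variables:
        mask = rng.random(series.n_days) < probs
        hidden = np.full(series.n_days, np.nan)
        hidden[mask] = values[var][mask]
        values[var][mask] = np.nan
        truth[var] = hidden
    return DailySeries(
        participant_id=series.participant_id,
        group=series.group,
        dates=series.dates,
        values=values,
        masked_truth=truth,
    )


def simulate_cohort(
    presets: Sequence[CohortPreset] | None = None,
    seed: int = 0,
    structure: DBNStructure | None = None,
) -> list[tuple[DailySeries, GroundTruth]]:
    """Generate a cohort: independent participants, deterministic per seed."""
    presets = list(presets) if presets is not None else default_presets()
    structure = structure or default_structure()
    total = sum(p.n_participants for p in presets)
    children = np.random.SeedSequence(seed).spawn(total + 1)
    draw_rng = np.random.default_rng(children[0])
    out: list[tuple[DailySeries, GroundTruth]] = []
    idx = 0
    for preset in presets:
        for i in range(preset.n_participants):
            params = dict(DEFAULT_PARAMS)
            params.update(preset.base_params)
            for wname, (lo, hi) in sorted(preset.random_weights.items()):
                params[wname] = float(draw_rng.uniform(lo, hi))
            truth = GroundTruth(
                params=params,
                scales=dict(preset.scales) if preset.scales else dict(DEFAULT_SCALES),
            )
            sim_seed = int(children[idx + 1].generate_state(1)[0] & 0x7FFFFFFF)
            series = simulate_participant(
                truth,
                n_days=preset.n_days,
                seed=sim_seed,
                participant_id=f"{preset.group}_{i + 1}",
                group=preset.group,
                structure=structure,
            )
            if preset.mechanism is not None:
                series = impose_mar_missingness(series, preset.mechanism, seed=sim_seed + 1)
            out.append((series, truth))
            idx += 1
    return out
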