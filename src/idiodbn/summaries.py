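"""Posterior draws → reported effects: 95% BCIs, credible flags, natural units.

An edge effect is *credible* when its 95% equal-tailed Bayesian credible
interval excludes zero.  Standardized weights are translated to natural
units per draw via weight × SD(outcome) / SD(predictor) (binary predictors:
per 0→1 switch, i.e. × SD(outcome)), so the natural-unit interval is itself
a posterior interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dbn import DBNStructure
from .inference import PosteriorDraws


class SummaryError(ValueError):
    pass


@dataclass
class EffectSummary:
    """Posterior summary for one edge (weight) of one participant's DBN."""

    edge: str                      # weight symbol, e.g. "wPVMS"
    alias: str | None              # reporting label, e.g. "t_m"
    node: str                      # outcome variable
    parent: str                    # predictor variable
    lag: int
    mean: float
    sd: float
    bci95: tuple[float, float]
    credible: bool
    natural_mean: float
    natural_bci95: tuple[float, float]
    sd_outcome: float
    sd_predictor: float

    @property
    def label(self) -> str:
        return self.alias or self.edge


def equal_tailed_interval(draws: np.ndarray, alpha: float = 0.05) -> tuple[float, float]:
    """Equal-tailed interval at quantiles α/2 and 1−α/2 (linear interpolation)."""
    if not 0.0 < alpha < 1.0:
        raise SummaryError("alpha must be in (0, 1)")
    lo, hi = np.quantile(draws, [alpha / 2.0, 1.0 - alpha / 2.0], method="linear")
    return float(lo), float(hi)


def is_credible(interval: tuple[float, float]) -> bool:
    """The screening rule: the interval neither crosses nor contains zero."""
    lo, hi = interval
    return lo > 0.0 or hi < 0.0


def back_transform(weight: float, sd_outcome: float, sd_predictor: float) -> float:
    """Standardized weight → per-raw-unit effect: weight × SD_out / SD_pred."""
    if sd_outcome <= 0 or sd_predictor <= 0:
        raise SummaryError("scale SDs must be positive")
    return weight * sd_outcome / sd_predictor


def summarize_draws(
    post: PosteriorDraws,
    scales: Mapping[str, tuple[float, float]] | None = None,
    alpha: float = 0.05,
) -> list[EffectSummary]:
    """One :class:`EffectSummary` per edge of the fitted structure."""
    if not 0.0 < alpha < 1.0:
        raise SummaryError("alpha must be in (0, 1)")
    if post.n_draws < 2:
        raise SummaryError("need at least 2 draws")
    scales = scales if scales is not None else post.scales
    structure = post.structure
    out: list[EffectSummary] = []
    for node_name, spec in structure.nodes.items():
        sd_out = scales[node_name][1]
        for (parent, lag), wname in zip(spec.parents, spec.weight_names):
            draws = post.col(wname)
            sd_pred = 1.0 if parent == "W" else scales[parent][1]
            natural = draws * (sd_out / sd_pred)
            interval = equal_tailed_interval(draws, alpha)
            out.append(
                EffectSummary(
                    edge=wname,
                    alias=structure.alias_for(node_name, parent, lag),
                    node=node_name,
                    parent=parent,
                    lag=lag,
                    mean=float(draws.mean()),
                    sd=float(draws.std(ddof=1)),
                    bci95=interval,
                    credible=is_credible(interval),
                    natural_mean=float(natural.mean()),
                    natural_bci95=equal_tailed_interval(natural, alpha),
                    sd_outcome=float(sd_out),
                    sd_predictor=float(sd_pred),
                )
            )
    return out


def _find_effect(effects: Sequence[EffectSummary], edge: str) -> EffectSummary:
    for eff in effects:
        if eff.edge == edge or eff.alias == edge:
            return eff
    raise SummaryError(f"no summary for edge {edge!r}")


def credible_effect_counts(
    participants: Iterable[tuple[str, Sequence[EffectSummary]]],
    edge: str,
    sign: str = "either",
) -> dict[str, tuple[int, int, float]]:
    """Per-group (count, group size, proportion) of credible effects.

    ``participants`` yields (group label, effect summaries); ``edge`` is a
    weight symbol or alias; ``sign`` restricts to credible-positive or
    credible-negative effects.
    """
    if sign not in ("positive", "negative", "either"):
        raise SummaryError("sign must be positive|negative|either")
    tallies: dict[str, list[int]] = {}
    for group, effects in participants:
        eff = _find_effect(effects, edge)
        hit = eff.credible and (
            sign == "either"
            or (sign == "positive" and eff.bci95[0] > 0)
            or (sign == "negative" and eff.bci95[1] < 0)
        )
        tallies.setdefault(group, [0, 0])
        tallies[group][0] += int(hit)
        tallies[group][1] += 1
    return {g: (c, n, c / n) for g, (c, n) in tallies.items()}


def forest_report(
    participants: Mapping[str, Sequence[EffectSummary]],
    edges: Sequence[str] | None = None,
    plot_path=None,
) -> pd.DataFrame:
    """Tabular forest summary: one row per participant × edge, sorted by
    effect size (|posterior mean|, descending) within each participant."""
    rows = []
    for pid, effects in participants.items():
        selected = (
            effects if edges is None else [_find_effect(effects, e) for e in edges]
        )
        for eff in selected:
            rows.append(
                {
                    "participant": pid,
                    "edge": eff.edge,
                    "alias": eff.label,
                    "mean": eff.mean,
                    "sd": eff.sd,
                    "bci_lower": eff.bci95[0],
                    "bci_upper": eff.bci95[1],
                    "credible": eff.credible,
                    "natural_mean": eff.natural_mean,
                    "natural_lower": eff.natural_bci95[0],
                    "natural_upper": eff.natural_bci95[1],
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "participant", "edge", "alias", "mean", "sd", "bci_lower", "bci_upper",
            "credible", "natural_mean", "natural_lower", "natural_upper",
        ],
    )
    if len(df):
        df["_size"] = df["mean"].abs()
        df = (
            df.sort_values(["participant", "_size"], ascending=[True, False], kind="stable")
            .drop(columns="_size")
            .reset_index(drop=True)
        )
    if plot_path is not None and len(df):
        _forest_plot(df, plot_path)
    return df


def _forest_plot(df: pd.DataFrame, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pids = list(dict.fromkeys(df["participant"]))
    fig, axes = plt.subplots(
        len(pids), 1, figsize=(7, 2 + 1.6 * len(pids)), squeeze=False, sharex=True
    )
    for ax, pid in zip(axes[:, 0], pids):
        sub = df[df["participant"] == pid]
        ypos = np.arange(len(sub))[::-1]
        colors = ["crimson" if c else "black" for c in sub["credible"]]
        for y, (_, row), c in zip(ypos, sub.iterrows(), colors):
            ax.plot([row.bci_lower, row.bci_upper], [y, y], color=c, lw=1.5)
            ax.plot(row["mean"], y, "o", color="steelblue", ms=4)
        ax.axvline(0.0, color="red", ls="--", lw=0.8)
        ax.set_yticks(ypos)
        ax.set_yticklabels(sub["alias"])
        ax.set_title(pid, fontsize=9)
    axes[-1, 0].set_xlabel("standardized effect (posterior mean, 95% BCI)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
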