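"""End-to-end orchestration: simulate/ingest → screen → fit → summarize → report.

A run is driven by a :class:`RunConfig` and produces a manifest listing
every artifact with its SHA-256 hash, the seeds used, and a config echo;
rerunning the same config reproduces all non-plot artifacts byte-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import cohort as cohort_mod
from .cohort import CohortPreset, default_presets, simulate_cohort
from .cohort_stats import describe_cohort, missingness_heatmap_export
from .daily_data import (
    DailySeries,
    check_eligibility,
    read_daily_csv,
    summarize_missingness,
    write_daily_csv,
)
from .dbn import PriorConfig, default_structure
from .inference import InferenceError, McmcConfig, fit_participant
from .summaries import credible_effect_counts, forest_report, summarize_draws

import pandas as pd


@dataclass
class RunConfig:
    out_dir: str = "run_out"
    input_dir: str | None = None  # ingest daily CSVs instead of simulating
    seed: int = 0
    n_draws: int = 1000
    n_warmup: int = 1000
    include_temp_on_pv: bool = True
    include_lagged_pv_on_fs: bool = True
    alpha: float = 0.05
    make_plots: bool = False
    priors: PriorConfig = field(default_factory=PriorConfig)
    presets: list[CohortPreset] | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["priors"] = self.priors.to_dict()
        d["presets"] = None if self.presets is None else "custom"
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        priors = PriorConfig.from_dict(raw.pop("priors", {}))
        raw.pop("presets", None)
        return cls(priors=priors, **raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_end_to_end(cfg: RunConfig) -> dict:
    """Execute the full pipeline and return (and write) the run manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    structure = default_structure(cfg.include_temp_on_pv, cfg.include_lagged_pv_on_fs)
    manifest: dict = {
        "config": cfg.to_dict(),
        "participants": {},
        "artifacts": {},
        "skipped": {},
    }

    # --- data stage -------------------------------------------------------
    cohort: list[DailySeries] = []
    if cfg.input_dir is None:
        presets = cfg.presets if cfg.presets is not None else default_presets()
        sampled = simulate_cohort(presets, seed=cfg.seed, structure=structure)
        for series, truth in sampled:
            path = out / f"{series.participant_id}.csv"
            write_daily_csv(series, path)
            manifest["artifacts"][path.name] = _sha256(path)
            cohort.append(series)
        truth_path = out / "ground_truth.json"
        truth_path.write_text(
            json.dumps(
                {s.participant_id: t.params for s, t in sampled}, indent=1, sort_keys=True
            )
        )
        manifest["artifacts"][truth_path.name] = _sha256(truth_path)
    else:
        for path in sorted(Path(cfg.input_dir).glob("*.csv")):
            cohort.append(read_daily_csv(path))

    # --- eligibility + fit + summarize ------------------------------------
    participants: dict[str, list] = {}
    groups: list[tuple[str, list]] = []
    for series in cohort:
        elig = check_eligibility(summarize_missingness(series))
        if not elig.eligible:
            manifest["skipped"][series.participant_id] = elig.reasons
            continue
        pid_hash = int.from_bytes(
            hashlib.sha256(series.participant_id.encode()).digest()[:4], "little"
        )
        mcfg = McmcConfig(
            n_draws=cfg.n_draws,
            n_warmup=cfg.n_warmup,
            seed=(cfg.seed + pid_hash) % (2**31),
        )
        try:
            post = fit_participant(series, structure, cfg.priors, mcfg)
        except InferenceError as exc:
            raise InferenceError(f"{series.participant_id}: fit stage: {exc}") from exc
        draws_path = out / f"{series.participant_id}_draws.csv"
        post.to_frame().to_csv(draws_path, index=False, float_format="%.6g")
        manifest["artifacts"][draws_path.name] = _sha256(draws_path)
        effects = summarize_draws(post, alpha=cfg.alpha)
        participants[series.participant_id] = effects
        groups.append((series.group, effects))
        manifest["participants"][series.participant_id] = {
            "group": series.group,
            "n_days": series.n_days,
            "seed": mcfg.seed,
            "n_missing": {k: int(len(v)) for k, v in post.missing_index.items()},
        }

    # --- cohort report ----------------------------------------------------
    if participants:
        report = forest_report(
            participants,
            plot_path=(out / "forest.png") if cfg.make_plots else None,
        )
        report_path = out / "effects.csv"
        report.to_csv(report_path, index=False, float_format="%.6g")
        manifest["artifacts"][report_path.name] = _sha256(report_path)

        counts = {}
        for alias in structure.alias_map:
            counts[alias] = {
                g: {"count": c, "n": n, "proportion": p}
                for g, (c, n, p) in credible_effect_counts(groups, alias).items()
            }
        counts_path = out / "credible_counts.json"
        counts_path.write_text(json.dumps(counts, indent=1, sort_keys=True))
        manifest["artifacts"][counts_path.name] = _sha256(counts_path)

    heat = missingness_heatmap_export(cohort)
    heat_path = out / "missingness.csv"
    heat.to_csv(heat_path, index=False)
    manifest["artifacts"][heat_path.name] = _sha256(heat_path)

    daily_desc = describe_cohort(
        pd.DataFrame(
            {
                "group": [s.group for s in cohort],
                "mean_page_views": [float(np.mean(s["PV"])) for s in cohort],
                "mean_steps_per_wear_min": [
                    float(np.nanmean(s["FS"])) for s in cohort
                ],
            }
        )
    )
    desc_path = out / "cohort_description.json"
    desc_path.write_text(
        json.dumps(
            {
                cov: {g: vars(st) for g, st in per.items()}
                for cov, per in daily_desc.items()
            },
            indent=1,
            sort_keys=True,
        )
    )
    manifest["artifacts"][desc_path.name] = _sha256(desc_path)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
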