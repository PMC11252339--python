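"""End-to-end orchestration: simulate -> maps -> analyses -> report.

A :class:`RunConfig` bundles the simulation parameters with the analysis
settings; :func:`run_pipeline` executes the stages in dependency order,
writes each stage's tables (CSV/JSON) under the run directory, and stamps
every output with a hash of the configuration so a rerun with the same
config and seed is bit-identical.  Disabling a stage makes downstream
stages that consume it fail fast with a dependency error.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import behavior, decoders, population, rate_remapping, rotation
from .context import SIMILARITY_THRESHOLD
from .errors import ConfigurationError
from .session import (SessionTables, classify_cells, compute_session_tables,
                      session_bmr_records, trial_pairs)
from .synthetic import SessionBundle, SimConfig, generate_study

ALL_STAGES = ("simulate", "maps", "behavior", "bmr", "context_sim",
              "context_predict", "decode", "rate_remap", "report")

_DEPS = {
    "maps": ("simulate",),
    "behavior": ("simulate",),
    "bmr": ("maps",),
    "context_sim": ("maps",),
    "context_predict": ("maps", "context_sim"),
    "decode": ("maps",),
    "rate_remap": ("maps",),
    "report": (),
}


@dataclass
class RunConfig:
    """Everything a pipeline run needs, serializable to YAML."""

    sim: SimConfig = field(default_factory=SimConfig)
    out_dir: str = "run"
    stages: tuple[str, ...] = ALL_STAGES
    similarity_threshold: float = SIMILARITY_THRESHOLD
    rate_mode: str = "mean"

    def to_dict(self) -> dict[str, Any]:
        return {"sim": dataclasses.asdict(self.sim), "out_dir": self.out_dir,
                "stages": list(self.stages),
                "similarity_threshold": self.similarity_threshold,
                "rate_mode": self.rate_mode}

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        sim = d.get("sim", {})
        # YAML round-trip turns tuples into lists; restore the nested ones
        for k in ("coherence_by_day", "rate_gain_by_day"):
            if k in sim:
                sim[k] = tuple(sim[k])
        if "dig_probs_by_day" in sim:
            sim["dig_probs_by_day"] = tuple(tuple(r) for r in sim["dig_probs_by_day"])
        return cls(sim=SimConfig(**sim), out_dir=d.get("out_dir", "run"),
                   stages=tuple(d.get("stages", ALL_STAGES)),
                   similarity_threshold=d.get("similarity_threshold",
                                              SIMILARITY_THRESHOLD),
                   rate_mode=d.get("rate_mode", "mean"))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _check_deps(stages: tuple[str, ...]) -> None:
    done = set()
    for s in stages:
        missing = [d for d in _DEPS.get(s, ()) if d not in done]
        if missing:
            raise ConfigurationError(
                f"stage {s!r} requires disabled stage(s) {missing}")
        done.add(s)


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the configured stages and write outputs under ``out_dir``.

    Returns the in-memory stage products (bundles, tables, summary frames).
    """
    _check_deps(config.stages)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    manifest = {"config": config.to_dict(), "config_hash": chash,
                "stages": list(config.stages)}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)

    products: dict[str, Any] = {"manifest": manifest}
    bundles: list[SessionBundle] = []
    tables: list[SessionTables] = []
    classes: dict[tuple[int, int], pd.DataFrame] = {}

    if "simulate" in config.stages:
        bundles = generate_study(config.sim)
        products["bundles"] = bundles
        behavior.trials_to_frame(
            [t for b in bundles for t in b.trials]
        ).to_csv(out / "trials.csv", index=False)

    if "maps" in config.stages:
        tables = [compute_session_tables(b) for b in bundles]
        products["tables"] = tables

    if "behavior" in config.stages:
        all_trials = behavior.trials_to_frame(
            [t for b in bundles for t in b.trials])
        props = behavior.dig_proportions(all_trials, group_by=("day",))
        props.to_csv(out / "dig_proportions.csv", index=False)
        bf_out = {}
        ecdf_frames = []
        for model in ("cg", "c"):
            per_day = {}
            for day, grp in all_trials.groupby("day"):
                res = behavior.bayes_factor_by_animal(grp, model)
                per_day[int(day)] = {
                    "log_bf_per_animal": res.log_bf_per_animal,
                    "log_bf_group": res.log_bf_group,
                    "group_decision": res.group_decision,
                }
                ecdf = res.ecdf()
                ecdf["model"], ecdf["day"] = model, int(day)
                ecdf_frames.append(ecdf)
            bf_out[model] = per_day
        with open(out / "bayes_factors.json", "w") as fh:
            json.dump(bf_out, fh, indent=1)
        pd.concat(ecdf_frames).to_csv(out / "bf_ecdf.csv", index=False)
        products["behavior"] = {"proportions": props, "bf": bf_out}

    if "bmr" in config.stages:
        per_animal_rows = []
        coher_frames = []
        for tb in tables:
            recs = session_bmr_records(tb)
            per_cell, per_animal = rotation.bmr_proportions(
                recs, animal_of_cell={c: tb.animal for c in tb.cell_ids})
            if not per_animal.empty:
                per_animal["day"] = tb.day
                per_animal_rows.append(per_animal)
            rows = [rotation.coherency_per_trial_pair(
                        recs, p, tb.included_cells_for_pair(p),
                        comparison=tb.pair_comparison(p))
                    for p in trial_pairs(tb)]
            ct = rotation.coherency_table(rows)
            if not ct.empty:
                ct["animal"], ct["day"] = tb.animal, tb.day
                coher_frames.append(ct)
        bmr_df = pd.concat(per_animal_rows) if per_animal_rows else pd.DataFrame()
        coher_df = pd.concat(coher_frames) if coher_frames else pd.DataFrame()
        bmr_df.to_csv(out / "bmr_proportions.csv", index=False)
        coher_df.to_csv(out / "coherency.csv", index=False)
        products["bmr"] = {"proportions": bmr_df, "coherency": coher_df}

    if "context_sim" in config.stages:
        frames = []
        for tb in tables:
            df = classify_cells(tb, threshold=config.similarity_threshold)
            df["animal"], df["day"] = tb.animal, tb.day
            classes[(tb.animal, tb.day)] = df
            frames.append(df)
        sim_df = pd.concat(frames)
        sim_df.to_csv(out / "context_similarity.csv", index=False)
        products["context_sim"] = sim_df

    if "context_predict" in config.stages:
        rows = []
        for tb in tables:
            df = classes[(tb.animal, tb.day)]
            for cls in ("FI", "FS"):
                cells = df.loc[df["cell_class"] == cls, "cell_id"].tolist()
                if not cells:
                    continue
                try:
                    acc, _ = population.predict_context_by_location(
                        tb.square_maps, tb.contexts, cells,
                        rng=np.random.default_rng(config.sim.seed + tb.animal))
                except Exception:
                    continue
                rows.append({"animal": tb.animal, "day": tb.day,
                             "cell_class": cls, "accuracy": acc})
        ctx_df = pd.DataFrame(rows)
        ctx_df.to_csv(out / "context_prediction.csv", index=False)
        products["context_predict"] = ctx_df

    if "decode" in config.stages:
        rows = []
        for tb in tables:
            rec = {"animal": tb.animal, "day": tb.day}
            try:
                rec["heading_alignment"] = decoders.predict_heading_from_alignment(
                    tb.angles, tb.dig1)
            except Exception:
                rec["heading_alignment"] = np.nan
            for target in ("context", "heading"):
                try:
                    rec[f"{target}_rate"] = decoders.predict_from_rates(
                        tb.mean_rates, tb.contexts, tb.dig1, target,
                        field_presence=tb.field_presence)
                except Exception:
                    rec[f"{target}_rate"] = np.nan
            rows.append(rec)
        dec_df = pd.DataFrame(rows)
        dec_df.to_csv(out / "decoding_accuracy.csv", index=False)
        products["decode"] = dec_df

    if "rate_remap" in config.stages:
        frames = []
        for tb in tables:
            df = rate_remapping.summary_table(tb.mean_rates, tb.contexts)
            df["animal"], df["day"] = tb.animal, tb.day
            frames.append(df)
        rr_df = pd.concat(frames)
        rr_df.to_csv(out / "rate_remapping.csv", index=False)
        products["rate_remap"] = rr_df

    if "report" in config.stages:
        report: dict[str, Any] = {"config_hash": chash}
        if "decode" in config.stages and not products["decode"].empty:
            report["decoding_means_by_day"] = (
                products["decode"].groupby("day").mean(numeric_only=True)
                .drop(columns=["animal"], errors="ignore")
                .round(4).to_dict())
        if "context_sim" in config.stages:
            cs = products["context_sim"]
            report["cell_class_counts"] = (
                cs["cell_class"].value_counts().to_dict())
            report["mean_similarity_by_class"] = (
                cs.groupby("cell_class")["similarity"].mean()
                .round(4).dropna().to_dict())
        if "rate_remap" in config.stages:
            rr = products["rate_remap"]
            report["rate_gap_by_day"] = (
                rr.groupby("day")["gap"].mean().round(4).to_dict())
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, default=float)
        products["report"] = report

    return products
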