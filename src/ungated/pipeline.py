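"""End-to-end orchestration: config, seeds, stages, artifacts, manifest.

A single structured config (YAML or dict) drives every stage; unknown keys
are rejected rather than ignored.  All randomness derives from one base
seed with fixed documented offsets:

====================  =================
stage                 seed
====================  =================
cohort generation     base
preprocess sampling   base + 1000
calibration split     base + 2000
continuous training   base + 3000 + r
gated training        base + 4000 + r
====================  =================

Stages are deterministic given the config, so any stage can be recomputed
from the config alone; artifact digests are recorded in a run manifest and
reruns with equal inputs produce equal digests.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation, gating, models, preprocessing, synthetic
from .io import EventTable, OutcomeTable, write_events_csv, write_outcomes
from .panel import default_panel

_SCHEMA: dict[str, set[str]] = {
    "": {"seed", "profile", "cohort", "preprocess", "gating", "model", "evaluation"},
    "cohort": {"n_individuals", "n_events_per_individual", "debris_fraction",
               "doublet_fraction", "dead_fraction", "outlier_rate",
               "drift_amplitude", "scenario", "write_events"},
    "preprocess": {"trim_fraction", "sample_size", "outlier_threshold",
                   "n_interior_sections", "lower_percentile", "upper_percentile"},
    "gating": {"n_leaves"},
    "model": {"standardize_inputs", "continuous_epochs", "gated_epochs",
              "batch_size", "learning_rate"},
    "evaluation": {"outcomes", "n_replicates", "n_calibration",
                   "include_control_in_sign_test"},
}

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "profile": "desk",          # desk | full (epoch profile)
    "cohort": {
        "n_individuals": 567,
        "n_events_per_individual": 20_000,
        "debris_fraction": 0.05,
        "doublet_fraction": 0.03,
        "dead_fraction": 0.05,
        "outlier_rate": 0.001,
        "drift_amplitude": 0.05,
        "scenario": "default",  # default | intensity_shift
        "write_events": False,
    },
    "preprocess": {
        "trim_fraction": 0.10,
        "sample_size": 5000,
        "outlier_threshold": -50_000.0,
        "n_interior_sections": 100,
        "lower_percentile": 2.5,
        "upper_percentile": 97.5,
    },
    "gating": {"n_leaves": 64},
    "model": {
        "standardize_inputs": False,
        "continuous_epochs": None,   # None -> profile default
        "gated_epochs": None,
        "batch_size": 100,
        "learning_rate": 1e-3,
    },
    "evaluation": {
        "outcomes": None,            # None -> every generated outcome
        "n_replicates": 5,
        "n_calibration": 300,
        "include_control_in_sign_test": True,
    },
}


class ConfigError(ValueError):
    pass


def _check_keys(block: dict, name: str) -> None:
    allowed = _SCHEMA[name]
    unknown = sorted(set(block) - allowed)
    if unknown:
        where = name or "top level"
        raise ConfigError(f"unknown config key(s) in {where}: {unknown}")


def merge_config(overrides: dict | None = None) -> dict:
    """defaults < file/dict < CLI overrides, with unknown keys rejected."""
    cfg = {k: (dict(v) if isinstance(v, dict) else v)
           for k, v in DEFAULT_CONFIG.items()}
    if overrides:
        _check_keys(overrides, "")
        for key, value in overrides.items():
            if isinstance(value, dict):
                _check_keys(value, key)
                cfg[key].update(value)
            else:
                cfg[key] = value
    return cfg


def load_config(path: str | Path | None, overrides: dict | None = None) -> dict:
    file_cfg: dict = {}
    if path is not None:
        with open(path) as fh:
            file_cfg = yaml.safe_load(fh) or {}
    merged = merge_config(file_cfg)
    if overrides:
        merged = _apply_overrides(merged, overrides)
    return merged


def _apply_overrides(cfg: dict, overrides: dict) -> dict:
    _check_keys(overrides, "")
    for key, value in overrides.items():
        if isinstance(value, dict):
            _check_keys(value, key)
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------

def cohort_config_from(cfg: dict) -> synthetic.CohortConfig:
    block = cfg["cohort"]
    panel = default_panel()
    scenario = block.get("scenario", "default")
    if scenario == "default":
        channel_models = None
    elif scenario == "intensity_shift":
        channel_models = synthetic.intensity_shift_channel_models(panel)
    else:
        raise ConfigError(f"unknown cohort scenario {scenario!r}")
    return synthetic.CohortConfig(
        n_individuals=block["n_individuals"],
        n_events_per_individual=block["n_events_per_individual"],
        panel=panel,
        seed=cfg["seed"],
        debris_fraction=block["debris_fraction"],
        doublet_fraction=block["doublet_fraction"],
        dead_fraction=block["dead_fraction"],
        outlier_rate=block["outlier_rate"],
        drift_amplitude=block["drift_amplitude"],
        channel_models=channel_models,
    )


def preprocess_config_from(cfg: dict) -> preprocessing.PreprocessConfig:
    block = cfg["preprocess"]
    return preprocessing.PreprocessConfig(seed=cfg["seed"] + 1000, **block)


def stage_simulate(cfg: dict):
    """Generate the synthetic cohort (events, outcomes, ground truth)."""
    return synthetic.generate_cohort(cohort_config_from(cfg))


def stage_preprocess(tables: list[EventTable], cfg: dict) -> pd.DataFrame:
    """Primary gating + cleaning + binning; returns the wide feature matrix."""
    panel = default_panel()
    gated = [gating.primary_gate(ev, panel) for ev in tables]
    empty = [ev.individual_id for ev in gated if ev.n_events == 0]
    if empty:
        raise ValueError(f"primary gating removed every event for: {empty}")
    binned = preprocessing.preprocess_cohort(gated, panel, preprocess_config_from(cfg))
    return preprocessing.bins_to_wide(binned)


def stage_gate(tables: list[EventTable], cfg: dict) -> tuple[pd.DataFrame, gating.GateNode]:
    """Primary gating + synthetic threshold tree; returns counts and tree."""
    panel = default_panel()
    gated = [gating.primary_gate(ev, panel) for ev in tables]
    tree = gating.default_synthetic_tree(panel, gated, n_leaves=cfg["gating"]["n_leaves"])
    counts = gating.counts_to_frame([gating.apply_gating_tree(ev, tree) for ev in gated])
    return counts, tree


def _effective_calibration(n_complete: int, requested: int) -> int:
    """Scale the 300/267 plan down proportionally when the cohort is smaller."""
    if requested < n_complete:
        return requested
    return max(1, round(n_complete * 300 / 567))


def model_specs_from(cfg: dict, n_channels: int, n_sections: int,
                     n_leaves: int) -> tuple[models.NetworkSpec, models.NetworkSpec]:
    block = cfg["model"]
    cont = models.continuous_spec(
        n_branches=n_channels, branch_input_size=n_sections,
        batch_size=block["batch_size"], learning_rate=block["learning_rate"],
        standardize_inputs=block["standardize_inputs"])
    gate = models.gated_spec(
        input_size=n_leaves, layer_sizes=models.scaled_gated_layers(n_leaves),
        batch_size=block["batch_size"], learning_rate=block["learning_rate"],
        standardize_inputs=block["standardize_inputs"])
    if cfg["profile"] == "desk":
        cont, gate = models.desk_profile(cont), models.desk_profile(gate)
    elif cfg["profile"] != "full":
        raise ConfigError(f"unknown profile {cfg['profile']!r}")
    from dataclasses import replace
    if block["continuous_epochs"] is not None:
        cont = replace(cont, epochs=block["continuous_epochs"])
    if block["gated_epochs"] is not None:
        gate = replace(gate, epochs=block["gated_epochs"])
    return cont, gate


@dataclass
class ExperimentResult:
    """Everything the train/evaluate stages produce, in memory."""

    summaries: list[evaluation.EvaluationSummary]
    summary_frame: pd.DataFrame
    sign: evaluation.SignTestResult | None
    replicates: dict[tuple[str, str], list[models.TrainedReplicate]]
    split: models.SplitPlan
    contributions: dict[str, pd.DataFrame] = field(default_factory=dict)


def run_experiment(features: pd.DataFrame, counts: pd.DataFrame,
                   outcomes: OutcomeTable, cfg: dict,
                   control_outcomes: tuple[str, ...] = ("Religion",)) -> ExperimentResult:
    """Train both arms on every requested outcome and evaluate them.

    Individuals with any missing declared outcome are removed before the
    split (so every outcome's models see the same people); the split is
    fixed across replicates and shared by both arms.
    """
    ev_cfg = cfg["evaluation"]
    complete = outcomes.complete_cases()
    ids = [i for i in complete.ids if i in features.index and i in counts.index]
    n_cal = _effective_calibration(len(ids), ev_cfg["n_calibration"])
    split = models.make_split(ids, n_calibration=n_cal, seed=cfg["seed"] + 2000)

    panel = default_panel()
    n_channels = panel.n_fluorescence
    n_sections = features.shape[1] // n_channels
    cont_spec, gate_spec = model_specs_from(cfg, n_channels, n_sections,
                                            counts.shape[1])

    Xc_cal = features.loc[list(split.calibration_ids)].to_numpy(float)
    Xc_val = features.loc[list(split.validation_ids)].to_numpy(float)
    Xg_cal = counts.loc[list(split.calibration_ids)].to_numpy(float)
    Xg_val = counts.loc[list(split.validation_ids)].to_numpy(float)

    wanted = ev_cfg["outcomes"] or list(complete.outcome_names)
    missing = [o for o in wanted if o not in complete.outcome_names]
    if missing:
        raise ConfigError(f"unknown outcome(s) requested: {missing}")

    replicate_rmses: dict[tuple[str, str], list[float]] = {}
    replicates: dict[tuple[str, str], list[models.TrainedReplicate]] = {}
    outcome_means: dict[str, float] = {}
    contributions: dict[str, pd.DataFrame] = {}

    for outcome in wanted:
        y_cal = complete.data.loc[list(split.calibration_ids), outcome].to_numpy(float)
        y_val = complete.data.loc[list(split.validation_ids), outcome].to_numpy(float)
        outcome_means[outcome] = float(complete.data[outcome].mean())
        for kind, spec, X_cal, X_val, offset in (
                ("continuous", cont_spec, Xc_cal, Xc_val, 3000),
                ("gated", gate_spec, Xg_cal, Xg_val, 4000)):
            reps = models.run_replicates(
                X_cal, y_cal, X_val, y_val, spec,
                n_replicates=ev_cfg["n_replicates"],
                base_seed=cfg["seed"] + offset)
            replicates[(outcome, kind)] = reps
            replicate_rmses[(outcome, kind)] = [r.rmse_val for r in reps]
        contributions[outcome] = models.contribution_summary(
            replicates[(outcome, "continuous")], panel.fluorescence_channels)

    summaries = evaluation.summarize_replicates(replicate_rmses, outcome_means)
    frame = evaluation.summaries_to_frame(summaries)

    sign = None
    if len(wanted) >= 1:
        test_outcomes = list(wanted)
        if not ev_cfg["include_control_in_sign_test"]:
            test_outcomes = [o for o in test_outcomes if o not in control_outcomes]
        if len(test_outcomes) >= 1:
            cont = {o: frame.loc[o, "continuous_rmse"] for o in test_outcomes}
            gate = {o: frame.loc[o, "gated_rmse"] for o in test_outcomes}
            diffs = {o: cont[o] - gate[o] for o in test_outcomes}
            if any(d != 0 for d in diffs.values()):
                sign = evaluation.sign_test(cont, gate)

    return ExperimentResult(summaries=summaries, summary_frame=frame, sign=sign,
                            replicates=replicates, split=split,
                            contributions=contributions)


# ---------------------------------------------------------------------------
# Manifest and on-disk runs
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict
    seeds: dict[str, int]
    artifacts: dict[str, str] = field(default_factory=dict)

    def record(self, path: Path) -> None:
        self.artifacts[str(path)] = _sha256(path)

    def write(self, path: Path) -> Path:
        path.write_text(json.dumps(
            {"config": self.config, "seeds": self.seeds,
             "artifacts": self.artifacts}, indent=2, default=str))
        return path


def _seed_map(base: int) -> dict[str, int]:
    return {"base": base, "cohort": base, "preprocess": base + 1000,
            "split": base + 2000, "continuous_training": base + 3000,
            "gated_training": base + 4000}


def run_stage(stage: str, cfg: dict, outdir: str | Path) -> RunManifest:
    """Run one pipeline stage (or ``all``) and write its artifacts + manifest.

    Stages recompute their upstream inputs deterministically from the config
    rather than reading them back from disk; a rerun with an equal config
    yields byte-identical artifacts.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg, seeds=_seed_map(cfg["seed"]))

    known = {"simulate", "preprocess", "gate", "train", "evaluate", "all"}
    if stage not in known:
        raise ConfigError(f"unknown stage {stage!r}; expected one of {sorted(known)}")

    tables, outcomes, truth = stage_simulate(cfg)

    if stage in ("simulate", "all"):
        p = write_outcomes(outcomes, outdir / "outcomes.csv")
        manifest.record(p)
        p = outdir / "ground_truth.csv"
        truth.to_frame().to_csv(p)
        manifest.record(p)
        if cfg["cohort"]["write_events"]:
            events_dir = outdir / "events"
            events_dir.mkdir(exist_ok=True)
            for ev in tables:
                manifest.record(write_events_csv(ev, events_dir / f"{ev.individual_id}.csv"))

    features = counts = tree = None
    if stage in ("preprocess", "all"):
        features = stage_preprocess(tables, cfg)
        p = outdir / "features_wide.csv"
        features.to_csv(p)
        manifest.record(p)
    if stage in ("gate", "all"):
        counts, tree = stage_gate(tables, cfg)
        p = outdir / "gated_counts.csv"
        counts.to_csv(p)
        manifest.record(p)
        p = outdir / "gating_tree.yaml"
        p.write_text(yaml.safe_dump(tree.to_dict(), sort_keys=False))
        manifest.record(p)

    if stage in ("train", "evaluate", "all"):
        if features is None:
            features = stage_preprocess(tables, cfg)
        if counts is None:
            counts, tree = stage_gate(tables, cfg)
        result = run_experiment(features, counts, outcomes, cfg)
        p = outdir / "evaluation_summary.csv"
        result.summary_frame.to_csv(p)
        manifest.record(p)
        if result.sign is not None:
            p = outdir / "sign_test.json"
            p.write_text(json.dumps({
                "n_outcomes": result.sign.n_outcomes,
                "k_lower": result.sign.k_lower,
                "p_value": result.sign.p_value,
                "ties_dropped": result.sign.ties_dropped}, indent=2))
            manifest.record(p)
        for outcome, contrib in result.contributions.items():
            p = outdir / f"contributions_{outcome.replace(' ', '_')}.csv"
            contrib.to_csv(p, index=False)
            manifest.record(p)
        errors = evaluation.export_error_distributions(
            result.replicates, validation_ids=list(result.split.validation_ids))
        p = outdir / "error_distributions.csv"
        errors.to_csv(p, index=False)
        manifest.record(p)

    mpath = manifest.write(outdir / "manifest.json")
    return manifest
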