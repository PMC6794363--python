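"""End-to-end pipeline orchestration: simulate → score → infer → report.

All interchange is plain tab-separated text with header rows.  Every run
writes a manifest recording the configuration, seed, per-stage row counts
and SHA-256 checksums of the output tables, which suffices to re-execute
and reproduce the run byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from dietchoice import inference, task, tfeq
from dietchoice.simulate import SimulationConfig, generate_cohort

logger = logging.getLogger(__name__)

SEP = "\t"

TABLES = ("demographics", "tfeq_items", "ratings", "trials")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    mode: str = "full"  # simulate | analyze | full
    output_dir: str = "dietchoice_run"
    seed: int = 0
    input_dir: str | None = None  # required for mode=analyze
    simulation: SimulationConfig | None = None
    collapse_ht: bool = True
    rt_trim_unit: str = "participant"
    rt_trim_k: float = 2.2
    cluster_robust: bool = False
    referent_metric: str = "euclidean"

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "analyze", "full"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "analyze" and self.input_dir is None:
            raise ValueError("mode=analyze requires input_dir")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        sim = cfg.pop("simulation", None)
        rc = cls(**cfg)
        if sim is not None:
            rc.simulation = SimulationConfig(**sim)
        return rc


def _write_table(df: pd.DataFrame, path: Path) -> dict:
    df.to_csv(path, sep=SEP, index=False)
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    return {"path": path.name, "rows": len(df), "sha256": digest}


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=SEP)


def _load_inputs(input_dir: Path) -> dict[str, pd.DataFrame]:
    tables = {}
    for name in TABLES:
        p = input_dir / f"{name}.tsv"
        if not p.exists():
            raise FileNotFoundError(f"required input table missing: {p}")
        tables[name] = read_table(p)
    return tables


def _validate_schema(tables: dict[str, pd.DataFrame]) -> None:
    required = {
        "demographics": {"participant_id", "height_m", "weight_kg"},
        "tfeq_items": {"participant_id"},
        "ratings": {"participant_id", "item_id", "taste", "health"},
        "trials": {"participant_id", "target_item_id", "referent_item_id",
                   "preference", "rt_ms"},
    }
    for name, cols in required.items():
        missing = cols - set(tables[name].columns)
        if missing:
            raise ValueError(
                f"table {name!r}: missing required columns {sorted(missing)}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the run manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "mode": config.mode,
        "seed": config.seed,
        "config": {
            k: v for k, v in dataclasses.asdict(config).items()
            if k != "simulation"
        },
        "outputs": {},
        "stages": {},
    }

    if config.mode in ("simulate", "full"):
        sim_cfg = config.simulation or SimulationConfig(seed=config.seed)
        manifest["config"]["simulation"] = dataclasses.asdict(sim_cfg)
        demo, items, ratings, trials, truth = generate_cohort(sim_cfg)
        tables = {"demographics": demo, "tfeq_items": items,
                  "ratings": ratings, "trials": trials}
        for name, df in tables.items():
            manifest["outputs"][name] = _write_table(df, out / f"{name}.tsv")
        # ground truth is written for auditing but never read back by scoring
        manifest["outputs"]["ground_truth"] = _write_table(
            truth, out / "ground_truth.tsv")
        manifest["stages"]["simulate"] = {"n_participants": len(demo)}
    else:
        tables = _load_inputs(Path(config.input_dir))

    if config.mode in ("analyze", "full"):
        _validate_schema(tables)
        demo, items, ratings, trials = (
            tables["demographics"], tables["tfeq_items"],
            tables["ratings"], tables["trials"])

        cleaned, exclusions = inference.clean_participants(demo, trials, ratings)
        manifest["outputs"]["exclusions"] = _write_table(
            exclusions, out / "exclusions.tsv")
        keep = cleaned["participant_id"]
        items = items[items["participant_id"].isin(keep)]
        ratings = ratings[ratings["participant_id"].isin(keep)]
        trials = trials[trials["participant_id"].isin(keep)]
        manifest["stages"]["clean"] = {
            "n_retained": len(cleaned), "n_excluded": len(exclusions)}

        scores = tfeq.score_tfeq(items)
        manifest["outputs"]["tfeq_scores"] = _write_table(
            scores, out / "tfeq_scores.tsv")

        outcomes = task.score_task(trials, ratings)
        derived = task.derive_trials(trials, ratings)
        trimmed, trim_report = task.filter_rt_outliers(
            derived, k=config.rt_trim_k, unit=config.rt_trim_unit)
        manifest["outputs"]["task_outcomes"] = _write_table(
            outcomes, out / "task_outcomes.tsv")
        manifest["outputs"]["derived_trials"] = _write_table(
            derived, out / "derived_trials.tsv")
        manifest["stages"]["rt_trim"] = {
            "n_input": trim_report.n_input, "n_removed": trim_report.n_removed}

        participant = (cleaned.merge(scores, on="participant_id")
                       .merge(outcomes, on="participant_id"))
        mean_rt = (trimmed.groupby("participant_id")["rt_ms"].mean()
                   .rename("mean_rt_ms").reset_index())
        participant = participant.merge(mean_rt, on="participant_id")

        outcome_cols = ["participant_id", "taste_sensitivity",
                        "health_sensitivity", "prop_healthy", "prop_tasty",
                        "cr", "ue", "ee", "mean_rt_ms"]
        covariates = inference.screen_covariates(
            cleaned, participant[outcome_cols])
        manifest["stages"]["screening"] = {"covariates": covariates}

        models = inference.fit_outcome_models(participant, covariates)
        rt_models = inference.fit_rt_models(
            trimmed, scores, cleaned, covariates,
            cluster_robust=config.cluster_robust)
        diff_kind = "health_minus_taste" if config.collapse_ht else "health"
        moderations = {}
        for mod in ("cr", "disinhibited"):
            for kind in ("health", "taste", "health_minus_taste"):
                for form in ("median-split", "continuous"):
                    key = f"{mod}:{kind}:{form}"
                    moderations[key] = inference.moderation_analysis(
                        trimmed, scores, moderator=mod, difference_kind=kind,
                        demographics=cleaned, covariates=covariates, form=form)

        descriptives = inference.describe_by_weight_status(cleaned, scores)
        manifest["outputs"]["descriptives"] = _write_table(
            descriptives, out / "descriptives_by_weight_status.tsv")

        model_rows = []
        for name, res in {**models, **rt_models}.items():
            t = res.table.copy()
            t.insert(0, "model", name)
            t["n_obs"] = res.n_obs
            t["covariates"] = ",".join(res.covariates)
            t["standardized"] = res.standardized
            model_rows.append(t)
        manifest["outputs"]["model_results"] = _write_table(
            pd.concat(model_rows, ignore_index=True), out / "model_results.tsv")

        mod_rows = []
        for key, m in moderations.items():
            row = {"model": key, "moderator": m.moderator, "form": m.form,
                   "difference_kind": m.difference_kind,
                   "interaction_estimate": m.interaction_estimate,
                   "interaction_se": m.interaction_se,
                   "interaction_p": m.interaction_p,
                   "significant_p<0.10": m.significant}
            for label, sres in m.strata.items():
                row[f"slope_{label}"] = sres.coef("difference")
                row[f"p_{label}"] = sres.pvalue("difference")
            mod_rows.append(row)
        manifest["outputs"]["moderation_results"] = _write_table(
            pd.DataFrame(mod_rows), out / "moderation_results.tsv")
        manifest["stages"]["analyze"] = {
            "n_models": len(models) + len(rt_models),
            "n_moderations": len(moderations),
            "ht_difference_kind": diff_kind,
        }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    logger.info("pipeline run complete: %s", out / "manifest.json")
    return manifest
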