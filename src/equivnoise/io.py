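"""Formats, configuration and cohort summaries.

All tabular interchange is UTF-8 CSV with header rows; angles are stored in
linear degrees and coherences as proportions in [0, 1] (log10 staircase
units never leak into files).  Task and cohort configuration travels as YAML
mirroring the dataclass fields, and every pipeline run is described by a
JSON run manifest recording seeds, versions and output paths.
"""

from __future__ import annotations

import dataclasses
import json
import platform
import sys
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .en_model import fit_participant
from .errors import IncompleteInputError, SchemaError
from .observer_sim import CohortSpec, StaircaseAxis
from .psychometric import PsychometricParams, quest_init, quest_threshold_estimate, quest_update
from .tasks import TASK_NAMES, TaskConfig, default_configs

__all__ = [
    "TRIAL_LOG_COLUMNS",
    "THRESHOLD_COLUMNS",
    "EN_COLUMNS",
    "RunManifest",
    "CohortSummary",
    "compute_composite",
    "summarize_cohort",
    "read_csv_checked",
    "write_trial_log",
    "read_trial_log",
    "write_thresholds",
    "read_thresholds",
    "write_en_results",
    "read_en_results",
    "task_configs_to_yaml",
    "task_configs_from_yaml",
    "cohort_spec_to_yaml",
    "cohort_spec_from_yaml",
    "fit_thresholds_from_log",
    "en_results_from_thresholds",
    "en_results_from_cohort",
]

TRIAL_LOG_COLUMNS = [
    "participant_id", "task", "trial_index", "condition", "side",
    "stimulus_value", "response", "correct", "staircase_id", "block",
]
THRESHOLD_COLUMNS = ["participant_id", "task", "condition", "threshold"]
EN_COLUMNS = [
    "participant_id", "modality", "no_noise_threshold_deg", "mtn_deg",
    "coherence_threshold", "n_samp", "sigma_int_deg",
]

_TASK_MODALITY = {
    "motion_avg": "motion", "motion_coh": "motion",
    "ori_avg": "orientation", "ori_coh": "orientation",
}


def compute_composite(spelling_score: float, pde_score: float) -> float:
    """Reading-and-spelling composite: the mean of the spelling and non-word
    reading standard scores, rounded to 2 decimals for reporting.  Composites
    of 89 or below meet the reading-difficulty inclusion cut-off."""
    if spelling_score <= 0 or pde_score <= 0:
        raise SchemaError("standard scores must be positive")
    return round((spelling_score + pde_score) / 2.0, 2)


def read_csv_checked(path, required_columns: list[str], label: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{label} file {path} is missing column(s): {', '.join(missing)}")
    return df


def write_trial_log(df: pd.DataFrame, path) -> None:
    missing = [c for c in TRIAL_LOG_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trial log is missing column(s): {', '.join(missing)}")
    df.to_csv(path, index=False)


def read_trial_log(path) -> pd.DataFrame:
    return read_csv_checked(path, TRIAL_LOG_COLUMNS, "trial log")


def write_thresholds(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_thresholds(path) -> pd.DataFrame:
    return read_csv_checked(path, THRESHOLD_COLUMNS, "thresholds")


def write_en_results(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_en_results(path) -> pd.DataFrame:
    return read_csv_checked(path, EN_COLUMNS, "equivalent-noise results")


# ---------------------------------------------------------------------------
# YAML configuration


def task_configs_to_yaml(configs: dict[str, TaskConfig]) -> str:
    doc = {name: dataclasses.asdict(cfg) for name, cfg in configs.items()}
    return yaml.safe_dump(doc, sort_keys=True)


def task_configs_from_yaml(text: str) -> dict[str, TaskConfig]:
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise SchemaError("task config YAML must map task names to fields")
    out = {}
    valid = {f.name for f in dataclasses.fields(TaskConfig)}
    for name, fields in doc.items():
        unknown = set(fields) - valid
        if unknown:
            raise SchemaError(f"task {name!r}: unknown field(s) {sorted(unknown)}")
        out[name] = TaskConfig(**fields)
    return out


def cohort_spec_to_yaml(spec: CohortSpec) -> str:
    doc = dataclasses.asdict(spec)
    doc["age_range"] = list(doc["age_range"])
    doc["lapse_range"] = list(doc["lapse_range"])
    doc["n_samp_bounds"] = list(doc["n_samp_bounds"])
    return yaml.safe_dump(doc, sort_keys=True)


def cohort_spec_from_yaml(text: str) -> CohortSpec:
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise SchemaError("cohort spec YAML must be a mapping")
    valid = {f.name for f in dataclasses.fields(CohortSpec)}
    unknown = set(doc) - valid
    if unknown:
        raise SchemaError(f"cohort spec: unknown field(s) {sorted(unknown)}")
    for key in ("age_range", "lapse_range", "n_samp_bounds"):
        if key in doc:
            doc[key] = tuple(doc[key])
    return CohortSpec(**doc)


# ---------------------------------------------------------------------------
# Run manifest


@dataclass
class RunManifest:
    """Provenance of one pipeline stage: enough to reproduce it exactly."""

    command: str
    seed: Optional[int]
    config: dict = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    versions: dict = field(default_factory=dict)
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.versions:
            self.versions = {
                "python": platform.python_version(),
                "numpy": np.__version__,
                "pandas": pd.__version__,
                "equivnoise": _package_version(),
            }
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()

    def write(self, path) -> None:
        for out in self.outputs:
            if not Path(out).exists():
                raise IncompleteInputError(f"manifest names missing output {out}")
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def read(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def _package_version() -> str:
    mod = sys.modules.get("equivnoise")
    return getattr(mod, "__version__", "unknown")


# ---------------------------------------------------------------------------
# Cohort summaries


@dataclass
class CohortSummary:
    """Demographics block plus per-task catch-trial error summaries."""

    demographics: pd.DataFrame  # group x (n, age mean/sd/min/max)
    catch_errors: pd.DataFrame  # (task, group) x (mean, sd, min, max) of error proportion


def summarize_cohort(cohort: pd.DataFrame, trial_logs: pd.DataFrame) -> CohortSummary:
    """Group-level mean/SD/range of age and of catch-error proportions.

    The catch-error proportion per child and task is errors / number of catch
    trials, computed from the trial logs; participant ids in the logs must
    exist in the cohort table.
    """
    unknown = set(trial_logs["participant_id"]) - set(cohort["participant_id"])
    if unknown:
        raise IncompleteInputError(
            f"trial log references unknown participant(s): {sorted(unknown)[:5]}"
        )
    demo = (
        cohort.groupby("group")["age_years"]
        .agg(n="count", mean="mean", sd="std", min="min", max="max")
        .reset_index()
    )
    catch = trial_logs[trial_logs["condition"] == "catch"]
    per_child = (
        catch.groupby(["participant_id", "task"])["correct"]
        .agg(lambda c: 1.0 - np.mean(c))
        .rename("error_proportion")
        .reset_index()
        .merge(cohort[["participant_id", "group"]], on="participant_id")
    )
    catch_summary = (
        per_child.groupby(["task", "group"])["error_proportion"]
        .agg(mean="mean", sd="std", min="min", max="max")
        .reset_index()
    )
    return CohortSummary(demographics=demo, catch_errors=catch_summary)


# ---------------------------------------------------------------------------
# Threshold re-fitting from trial logs


def fit_thresholds_from_log(
    trial_logs: pd.DataFrame,
    configs: Optional[dict[str, TaskConfig]] = None,
) -> pd.DataFrame:
    """Replay logged staircase trials through QUEST to recover thresholds.

    Each (participant, task, staircase) history is replayed in trial order
    from the staircase's standard prior; the result equals the thresholds
    produced live, because the posterior depends only on the (intensity,
    outcome) sequence.
    """
    configs = configs or default_configs()
    rows = []
    stair = trial_logs[trial_logs["condition"] != "catch"]
    for (pid, task, cond), sub in stair.groupby(["participant_id", "task", "staircase_id"]):
        cfg = configs[task]
        axis = StaircaseAxis(cond, cfg)
        params = PsychometricParams(
            beta=cfg.weibull_beta, lapse=cfg.assumed_lapse,
            target_accuracy=cfg.target_accuracy,
        )
        state = quest_init(axis.start_internal(), cfg.prior_sd_log, params)
        for _, row in sub.sort_values("trial_index").iterrows():
            state = quest_update(state, axis.to_internal(row["stimulus_value"]), bool(row["correct"]))
        est = quest_threshold_estimate(state)
        rows.append(
            {
                "participant_id": pid,
                "task": task,
                "condition": cond,
                "threshold": axis.from_internal(est.value_log),
            }
        )
    return pd.DataFrame(rows, columns=THRESHOLD_COLUMNS)


def en_results_from_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Equivalent-noise decomposition straight from a wide cohort table.

    Produces the tidy EN results layout (one row per participant and
    modality) with group and age carried along, honouring the ``retained_for``
    exclusion outcome: excluded participants contribute no rows, and
    motion-only participants contribute no orientation row.
    """
    rows = []
    for _, r in cohort.iterrows():
        retained = r.get("retained_for", "both")
        if retained == "neither":
            continue
        blocks = [("motion", "no_noise_motion_deg", "mtn_motion_deg", "coherence_motion")]
        if retained in ("both", "orientation"):
            blocks.append(("orientation", "no_noise_ori_deg", "mtn_ori_deg", "coherence_ori"))
        for modality, nn_col, mtn_col, coh_col in blocks:
            est = fit_participant(
                r[nn_col], r[mtn_col], modality, coherence_threshold=r[coh_col]
            )
            rows.append(
                {
                    "participant_id": r["participant_id"],
                    "modality": modality,
                    "no_noise_threshold_deg": est.no_noise_threshold,
                    "mtn_deg": est.mtn,
                    "coherence_threshold": est.coherence_threshold,
                    "n_samp": est.n_samp,
                    "sigma_int_deg": est.sigma_int,
                    "group": r.get("group"),
                    "age_years": r.get("age_years"),
                }
            )
    return pd.DataFrame(rows, columns=EN_COLUMNS + ["group", "age_years"])


def en_results_from_thresholds(thresholds: pd.DataFrame) -> pd.DataFrame:
    """Equivalent-noise decomposition for every participant and modality."""
    rows = []
    for pid, sub in thresholds.groupby("participant_id"):
        lookup = {(r["task"], r["condition"]): r["threshold"] for _, r in sub.iterrows()}
        for avg_task, coh_task in (("motion_avg", "motion_coh"), ("ori_avg", "ori_coh")):
            no_noise = lookup.get((avg_task, "no_noise"))
            mtn = lookup.get((avg_task, "high_noise"))
            coherence = lookup.get((coh_task, "coherence"))
            if no_noise is None or mtn is None:
                continue
            est = fit_participant(
                no_noise, mtn, _TASK_MODALITY[avg_task], coherence_threshold=coherence
            )
            rows.append(
                {
                    "participant_id": pid,
                    "modality": est.modality,
                    "no_noise_threshold_deg": est.no_noise_threshold,
                    "mtn_deg": est.mtn,
                    "coherence_threshold": est.coherence_threshold,
                    "n_samp": est.n_samp,
                    "sigma_int_deg": est.sigma_int,
                }
            )
    return pd.DataFrame(rows, columns=EN_COLUMNS)
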