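"""Generative equivalent-noise observers and synthetic cohorts.

An observer is defined by exactly the two-parameter observation model the
analysis estimates: on each trial it pools ``round(n_samp)`` randomly chosen
elements, perturbs each by independent Gaussian internal noise of SD
``sigma_int`` degrees, averages them on the circular (motion) or axial
(orientation) domain, and answers with the side of the pooled mean — plus a
small stimulus-independent lapse rate.  In the small-angle regime this gives
the closed-form accuracy

    P(correct) = Phi( offset / sqrt((sigma_int**2 + sigma_ext**2) / n_samp) )

which the test-suite uses as an oracle.  No late/decision noise and no
noise-exclusion failure are modelled.

Cohorts draw per-child parameters from log-normal distributions with
configurable group multipliers and age trends, run the full four-task session
for each child through the QUEST engine, and apply the screening rules, so
every downstream analysis stage can be exercised without any external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ._circular import circular_mean_offset
from .psychometric import (
    PsychometricParams,
    QuestState,
    quest_init,
    quest_propose,
    quest_threshold_estimate,
    quest_update,
)
from .tasks import (
    TASK_NAMES,
    ElementSet,
    TaskConfig,
    TaskOutcome,
    TrialSpec,
    apply_exclusions,
    build_session,
    default_configs,
    run_criterion_phase,
    sample_stimulus,
)

__all__ = [
    "ObserverParams",
    "CohortSpec",
    "ParticipantResult",
    "simulate_response",
    "averaging_accuracy",
    "run_participant",
    "generate_cohort",
    "StaircaseAxis",
]


@dataclass(frozen=True)
class ObserverParams:
    """Ground-truth generative parameters for one modality.

    sigma_int: SD (degrees) of the per-element estimation noise.
    n_samp: effective number of pooled elements (>= 1; rounded for draws).
    lapse: probability of a random response regardless of the stimulus.
    """

    sigma_int: float
    n_samp: float
    lapse: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_int < 0:
            raise ValueError("sigma_int must be >= 0")
        if self.n_samp < 1:
            raise ValueError("n_samp must be >= 1")
        if not (0.0 <= self.lapse <= 0.2):
            raise ValueError("lapse must be in [0, 0.2]")


def simulate_response(obs: ObserverParams, elements: ElementSet, rng) -> int:
    """One 2AFC response (+1 right / -1 left) to an element set."""
    if rng.random() < obs.lapse:
        return 1 if rng.random() < 0.5 else -1
    m = min(max(int(round(obs.n_samp)), 1), len(elements.values))
    idx = rng.choice(len(elements.values), size=m, replace=False)
    noisy = elements.values[idx] + rng.normal(0.0, obs.sigma_int, m)
    offset = float(circular_mean_offset(noisy, elements.period))
    if offset == 0.0:
        return 1 if rng.random() < 0.5 else -1
    return 1 if offset > 0 else -1


def averaging_accuracy(
    sigma_int: float,
    n_samp: int,
    mean_offset_deg: float,
    external_sd: float,
    period: float,
    n_trials: int,
    rng,
) -> float:
    """Monte-Carlo accuracy of the averaging observer (vectorized, lapse-free).

    Elements are drawn fresh per trial from a Gaussian around the (positive)
    mean offset with SD ``external_sd``, perturbed by internal noise, wrapped,
    and pooled by the circular mean; accuracy is the fraction of trials whose
    pooled mean falls on the correct side.
    """
    m = max(int(round(n_samp)), 1)
    draws = rng.normal(mean_offset_deg, external_sd, size=(n_trials, m))
    draws += rng.normal(0.0, sigma_int, size=(n_trials, m))
    offsets = circular_mean_offset(draws, period, axis=1)
    return float(np.mean(offsets > 0) + 0.5 * np.mean(offsets == 0))


class StaircaseAxis:
    """Map between physical stimulus values and the QUEST intensity axis.

    QUEST assumes performance non-decreasing in intensity, so conditions in
    which a larger physical value is harder (the external-noise SD staircase)
    use a negated log axis internally.  Proposals are clamped to physically
    presentable values; the staircase is updated at the clamped value shown.
    """

    def __init__(self, condition: str, config: TaskConfig):
        self.condition = condition
        self.config = config

    def to_internal(self, physical: float) -> float:
        x = math.log10(physical)
        return -x if self.condition == "high_noise" else x

    def from_internal(self, x: float) -> float:
        return 10.0 ** (-x) if self.condition == "high_noise" else 10.0**x

    def clamp_physical(self, value: float) -> float:
        if self.condition == "no_noise":
            return min(value, self.config.max_offset_deg)
        if self.condition == "coherence":
            return min(value, 1.0)
        return value  # SD: 10**x is already positive, no upper bound

    def start_internal(self) -> float:
        cfg = self.config
        start = {
            "no_noise": cfg.start_no_noise_deg,
            "high_noise": cfg.start_high_noise_sd_deg,
            "coherence": cfg.start_coherence,
        }[self.condition]
        return self.to_internal(start)


@dataclass
class ParticipantResult:
    """Everything one simulated child produces across the four tasks."""

    participant_id: str
    trial_rows: list[dict] = field(default_factory=list)
    thresholds: dict[str, dict[str, float]] = field(default_factory=dict)
    posterior_sd: dict[str, dict[str, float]] = field(default_factory=dict)
    criterion: dict[str, tuple[bool, int]] = field(default_factory=dict)
    catch_errors: dict[str, int] = field(default_factory=dict)

    def trial_log(self) -> pd.DataFrame:
        return pd.DataFrame(self.trial_rows)

    def task_outcomes(self) -> dict[str, TaskOutcome]:
        out = {}
        for task in TASK_NAMES:
            coh = self.thresholds.get(task, {}).get("coherence")
            out[task] = TaskOutcome(
                passed_criterion=self.criterion[task][0],
                catch_errors=self.catch_errors[task],
                completed=True,
                coherence_threshold=coh,
            )
        return out


def run_participant(
    params_by_modality: dict[str, ObserverParams],
    configs: Optional[dict[str, TaskConfig]] = None,
    seed: int = 0,
    participant_id: str = "p000",
) -> ParticipantResult:
    """Simulate the full procedure for one child.

    For each task: criterion phase, then the randomly interleaved staircase
    and catch trials, with QUEST proposing each staircase intensity and
    updating on the response.  Thresholds are posterior means, mapped back to
    linear stimulus units (the SD staircase's negated axis is inverted here).
    """
    configs = configs or default_configs()
    result = ParticipantResult(participant_id=participant_id)
    seq = np.random.SeedSequence(seed)
    task_seeds = {name: s for name, s in zip(TASK_NAMES, seq.spawn(len(TASK_NAMES)))}
    for task in TASK_NAMES:
        cfg = configs[task]
        obs = params_by_modality[cfg.modality]
        child_seqs = task_seeds[task].spawn(3)
        rng = np.random.default_rng(child_seqs[0])
        session_seed = int(np.random.default_rng(child_seqs[1]).integers(2**31))

        def respond(elements: ElementSet, r) -> int:
            return simulate_response(obs, elements, r)

        passed, n_used = run_criterion_phase(respond, cfg, rng)
        result.criterion[task] = (passed, n_used)

        pparams = PsychometricParams(
            beta=cfg.weibull_beta,
            lapse=cfg.assumed_lapse,
            target_accuracy=cfg.target_accuracy,
        )
        axes = {c: StaircaseAxis(c, cfg) for c in cfg.staircase_conditions}
        states: dict[str, QuestState] = {
            c: quest_init(axes[c].start_internal(), cfg.prior_sd_log, pparams)
            for c in cfg.staircase_conditions
        }
        catch_errors = 0
        for trial in build_session(cfg, session_seed):
            if trial.condition == "catch":
                elements = sample_stimulus(trial, cfg, rng)
                response = simulate_response(obs, elements, rng)
                correct = response == trial.side
                catch_errors += 0 if correct else 1
                shown = trial.stimulus_value
            else:
                axis = axes[trial.condition]
                state = states[trial.condition]
                proposal = axis.from_internal(quest_propose(state))
                shown = axis.clamp_physical(proposal)
                live = TrialSpec(
                    trial_index=trial.trial_index,
                    condition=trial.condition,
                    side=trial.side,
                    stimulus_value=shown,
                    source_staircase=trial.source_staircase,
                    block=trial.block,
                )
                elements = sample_stimulus(live, cfg, rng)
                response = simulate_response(obs, elements, rng)
                correct = response == trial.side
                states[trial.condition] = quest_update(
                    state, axis.to_internal(shown), correct
                )
            result.trial_rows.append(
                {
                    "participant_id": participant_id,
                    "task": task,
                    "trial_index": trial.trial_index,
                    "condition": trial.condition,
                    "side": "right" if trial.side > 0 else "left",
                    "stimulus_value": shown,
                    "response": "right" if response > 0 else "left",
                    "correct": bool(correct),
                    "staircase_id": trial.source_staircase or "none",
                    "block": trial.block,
                }
            )
        result.catch_errors[task] = catch_errors
        result.thresholds[task] = {}
        result.posterior_sd[task] = {}
        for cond, state in states.items():
            est = quest_threshold_estimate(state)
            result.thresholds[task][cond] = axes[cond].from_internal(est.value_log)
            result.posterior_sd[task][cond] = est.posterior_sd_log
    return result


@dataclass
class CohortSpec:
    """Distributions the synthetic cohort is drawn from.

    Defaults emulate the study conditions: 48 children per group aged 8-15,
    log-normal parameter spreads with median internal noise of 6 deg (motion)
    and 4 deg (orientation), median sampling 2.5, small lapse rates, a mild
    improvement of both parameters with age, and a motion internal-noise
    multiplier of 1.3 in the dyslexic group (the direction of the reported
    group difference).
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"typical": 48, "dyslexic": 48}
    )
    median_sigma_int: dict[str, float] = field(
        default_factory=lambda: {"motion": 6.0, "orientation": 4.0}
    )
    median_n_samp: dict[str, float] = field(
        default_factory=lambda: {"motion": 2.5, "orientation": 2.5}
    )
    sigma_log_sigma_int: float = 0.40
    sigma_log_n_samp: float = 0.45
    sigma_int_multiplier: dict[str, float] = field(
        default_factory=lambda: {"motion": 1.3, "orientation": 1.0}
    )
    n_samp_multiplier: dict[str, float] = field(
        default_factory=lambda: {"motion": 1.0, "orientation": 1.0}
    )
    reference_group: str = "typical"
    age_range: tuple[float, float] = (8.0, 15.0)
    age_center: float = 11.5
    sigma_int_age_slope: float = -0.04  # log-units per year
    n_samp_age_slope: float = 0.03
    lapse_range: tuple[float, float] = (0.0, 0.04)
    n_samp_bounds: tuple[float, float] = (1.0, 20.0)

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be positive")
        for d in (self.median_sigma_int, self.median_n_samp):
            if any(v <= 0 for v in d.values()):
                raise ValueError("parameter medians must be positive")


def _draw_observer(spec: CohortSpec, group: str, modality: str, age: float, rng) -> ObserverParams:
    mult_s = 1.0 if group == spec.reference_group else spec.sigma_int_multiplier[modality]
    mult_n = 1.0 if group == spec.reference_group else spec.n_samp_multiplier[modality]
    da = age - spec.age_center
    sigma = math.exp(
        math.log(spec.median_sigma_int[modality] * mult_s)
        + spec.sigma_int_age_slope * da
        + rng.normal(0.0, spec.sigma_log_sigma_int)
    )
    n_samp = math.exp(
        math.log(spec.median_n_samp[modality] * mult_n)
        + spec.n_samp_age_slope * da
        + rng.normal(0.0, spec.sigma_log_n_samp)
    )
    n_samp = float(np.clip(n_samp, *spec.n_samp_bounds))
    lapse = float(rng.uniform(*spec.lapse_range))
    return ObserverParams(sigma_int=sigma, n_samp=n_samp, lapse=lapse)


def generate_cohort(
    spec: CohortSpec,
    seed: int,
    configs: Optional[dict[str, TaskConfig]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a cohort, run every child through the four tasks, apply exclusions.

    Returns ``(cohort_table, trial_logs)``.  The cohort table is tidy: one row
    per child with group, age, sex, ground-truth parameters, the six threshold
    estimates, catch-error counts and the exclusion outcome.
    """
    configs = configs or default_configs()
    seq = np.random.SeedSequence(seed)
    top_rng = np.random.default_rng(seq)
    rows = []
    logs = []
    pid = 0
    for group, size in spec.group_sizes.items():
        for _ in range(size):
            pid += 1
            participant_id = f"p{pid:03d}"
            age = float(top_rng.uniform(*spec.age_range))
            sex = "f" if top_rng.random() < 0.5 else "m"
            params = {
                mod: _draw_observer(spec, group, mod, age, top_rng)
                for mod in ("motion", "orientation")
            }
            child_seed = int(top_rng.integers(2**31))
            result = run_participant(
                params, configs=configs, seed=child_seed, participant_id=participant_id
            )
            report = apply_exclusions(participant_id, result.task_outcomes())
            row = {
                "participant_id": participant_id,
                "group": group,
                "age_years": round(age, 3),
                "sex": sex,
                "no_noise_motion_deg": result.thresholds["motion_avg"]["no_noise"],
                "mtn_motion_deg": result.thresholds["motion_avg"]["high_noise"],
                "coherence_motion": result.thresholds["motion_coh"]["coherence"],
                "no_noise_ori_deg": result.thresholds["ori_avg"]["no_noise"],
                "mtn_ori_deg": result.thresholds["ori_avg"]["high_noise"],
                "coherence_ori": result.thresholds["ori_coh"]["coherence"],
                "true_sigma_int_motion": params["motion"].sigma_int,
                "true_n_samp_motion": params["motion"].n_samp,
                "true_lapse_motion": params["motion"].lapse,
                "true_sigma_int_ori": params["orientation"].sigma_int,
                "true_n_samp_ori": params["orientation"].n_samp,
                "true_lapse_ori": params["orientation"].lapse,
                "retained_for": report.retained_for,
                "seed": child_seed,
            }
            for task in TASK_NAMES:
                row[f"catch_errors_{task}"] = result.catch_errors[task]
                row[f"passed_criterion_{task}"] = result.criterion[task][0]
            rows.append(row)
            logs.append(result.trial_log())
    cohort = pd.DataFrame(rows)
    trial_logs = pd.concat(logs, ignore_index=True)
    return cohort, trial_logs
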