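"""The four task sessions: motion/orientation x averaging/coherence.

An averaging task interleaves two 75-trial QUEST staircases (no-noise: mean
offset varied at SD 0; high-noise: SD varied at a fixed mean offset) with 15
very easy catch trials, giving 165 trials.  A coherence task is a single
75-trial staircase plus 15 catch trials (90 trials).  Catch trials reuse the
criterion-phase stimulus for the task and screen for inattention; four or
more errors out of 15 is grounds for exclusion.

Stimulus element sets are generated here as bare angle lists (no rendering):
directions on a 360-degree circle, orientations on a 180-degree axial
domain, with the left/right answer carried by the sign of the offset from
the vertical reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Optional

import numpy as np

from ._circular import MOTION_PERIOD, ORIENTATION_PERIOD, wrap
from .errors import ConfigurationError, IncompleteInputError, ParameterDomainError

__all__ = [
    "TaskConfig",
    "TrialSpec",
    "ElementSet",
    "TaskOutcome",
    "ExclusionReport",
    "default_configs",
    "build_session",
    "sample_stimulus",
    "run_criterion_phase",
    "apply_exclusions",
    "TASK_NAMES",
    "CATCH_ERROR_CUTOFF",
]

Modality = Literal["motion", "orientation"]
Paradigm = Literal["averaging", "coherence"]
Condition = Literal["no_noise", "high_noise", "coherence", "catch"]

TASK_NAMES = ("motion_avg", "motion_coh", "ori_avg", "ori_coh")
MOTION_TASKS = ("motion_avg", "motion_coh")
ORIENTATION_TASKS = ("ori_avg", "ori_coh")

#: responding incorrectly to this many (or more) of the 15 catch trials
#: indicates chance-level attention and triggers exclusion
CATCH_ERROR_CUTOFF = 4


@dataclass(frozen=True)
class TaskConfig:
    """Structure of one task session.

    Defaults follow the study design: 100 elements, 75-trial staircases, 15
    catch trials, 4 blocks; high-noise fixed offsets of +/-45 deg (motion) and
    +/-22.5 deg (orientation); coherence signal offsets of +/-90 deg (motion)
    and +/-45 deg (orientation); staircase starting points of 2.5 deg mean
    offset, 0.001 deg SD and 50% coherence; QUEST prior SD 2 log10 units,
    Weibull slope 3.5, lapse 0.01.
    """

    modality: Modality
    paradigm: Paradigm
    n_elements: int = 100
    staircase_len: int = 75
    n_catch: int = 15
    n_blocks: int = 4
    fixed_offset_deg: float = 45.0  # averaging high-noise mean offset
    signal_offset_deg: float = 90.0  # coherence signal direction/orientation
    start_no_noise_deg: float = 2.5
    start_high_noise_sd_deg: float = 0.001
    start_coherence: float = 0.5
    prior_sd_log: float = 2.0
    weibull_beta: float = 3.5
    assumed_lapse: float = 0.01
    target_accuracy: float = 0.84
    criterion_max_trials: int = 20
    criterion_run_length: int = 4

    def __post_init__(self) -> None:
        if self.n_elements <= 0 or self.staircase_len <= 0:
            raise ConfigurationError("n_elements and staircase_len must be positive")
        if self.n_catch < 0:
            raise ConfigurationError("n_catch must be non-negative")
        for name in ("fixed_offset_deg", "signal_offset_deg"):
            v = getattr(self, name)
            if not (0.0 < v <= 90.0):
                raise ConfigurationError(f"{name} must be in (0, 90], got {v}")

    @property
    def period(self) -> float:
        return MOTION_PERIOD if self.modality == "motion" else ORIENTATION_PERIOD

    @property
    def max_offset_deg(self) -> float:
        """Largest presentable mean offset (quarter period: unambiguous side)."""
        return self.period / 4.0

    @property
    def staircase_conditions(self) -> tuple[str, ...]:
        if self.paradigm == "averaging":
            return ("no_noise", "high_noise")
        return ("coherence",)

    @property
    def n_trials(self) -> int:
        return self.staircase_len * len(self.staircase_conditions) + self.n_catch

    @property
    def task_name(self) -> str:
        stem = "motion" if self.modality == "motion" else "ori"
        return f"{stem}_{'avg' if self.paradigm == 'averaging' else 'coh'}"


def default_configs() -> dict[str, TaskConfig]:
    """The four study tasks, keyed by task name."""
    return {
        "motion_avg": TaskConfig("motion", "averaging", fixed_offset_deg=45.0),
        "motion_coh": TaskConfig("motion", "coherence", signal_offset_deg=90.0),
        "ori_avg": TaskConfig("orientation", "averaging", fixed_offset_deg=22.5),
        "ori_coh": TaskConfig("orientation", "coherence", signal_offset_deg=45.0),
    }


@dataclass
class TrialSpec:
    """One 2AFC trial slot.

    ``side`` is +1 (right of vertical) or -1 (left).  ``stimulus_value`` is a
    mean offset in degrees (no-noise), an SD in degrees (high-noise), a signal
    proportion (coherence), or fixed by the criterion stimulus (catch); it is
    None for staircase slots until the staircase proposes a value at run time.
    """

    trial_index: int
    condition: Condition
    side: int
    stimulus_value: Optional[float] = None
    source_staircase: Optional[str] = None
    block: int = 0


@dataclass
class ElementSet:
    """Per-element angles for one stimulus (degrees, wrapped to the domain)."""

    values: np.ndarray
    modality: Modality
    signal_mask: Optional[np.ndarray] = None

    @property
    def period(self) -> float:
        return MOTION_PERIOD if self.modality == "motion" else ORIENTATION_PERIOD


def build_session(config: TaskConfig, seed: int) -> list[TrialSpec]:
    """Randomly interleave staircase slots and catch trials.

    Deterministic given ``seed``: same seed, same trial order and sides.
    Sides are drawn independently 50/50 per trial.  Blocks are annotations
    only (four near-equal contiguous chunks).
    """
    rng = np.random.default_rng(seed)
    slots: list[tuple[str, Optional[str]]] = []
    for cond in config.staircase_conditions:
        slots += [(cond, cond)] * config.staircase_len
    slots += [("catch", None)] * config.n_catch
    order = rng.permutation(len(slots))
    block_edges = np.array_split(np.arange(len(slots)), config.n_blocks)
    block_of = np.empty(len(slots), dtype=int)
    for b, idx in enumerate(block_edges):
        block_of[idx] = b
    trials = []
    for pos, slot_i in enumerate(order):
        cond, stair = slots[slot_i]
        side = 1 if rng.random() < 0.5 else -1
        value = _catch_value(config) if cond == "catch" else None
        trials.append(
            TrialSpec(
                trial_index=pos + 1,
                condition=cond,  # type: ignore[arg-type]
                side=side,
                stimulus_value=value,
                source_staircase=stair,
                block=int(block_of[pos]),
            )
        )
    return trials


def _catch_value(config: TaskConfig) -> float:
    # criterion-trial stimulus: SD 0 at the fixed offset, or 100% coherence
    return 1.0 if config.paradigm == "coherence" else config.fixed_offset_deg


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def sample_stimulus(trial: TrialSpec, config: TaskConfig, rng) -> ElementSet:
    """Generate the element angles for one trial.

    no_noise: all elements at the signed mean offset.  high_noise: independent
    Gaussian draws around the signed fixed offset with the staircase SD,
    wrapped onto the domain (the nominal pre-wrap SD is the external noise the
    staircase and MTN refer to).  coherence: round(c*n) signal elements at the
    signed signal offset, the rest uniform random.  catch: the criterion
    stimulus.
    """
    period = config.period
    n = config.n_elements
    v = trial.stimulus_value
    mask = None
    if trial.condition == "no_noise":
        if v is None or not (0.0 <= v <= config.max_offset_deg):
            raise ParameterDomainError(f"no-noise offset out of range: {v}")
        values = np.full(n, trial.side * v)
    elif trial.condition == "high_noise":
        if v is None or v < 0.0:
            raise ParameterDomainError(f"external-noise SD out of range: {v}")
        values = rng.normal(trial.side * config.fixed_offset_deg, v, n)
    elif trial.condition == "coherence":
        if v is None or not (0.0 <= v <= 1.0):
            raise ParameterDomainError(f"coherence out of range: {v}")
        k = _round_half_up(v * n)
        values = np.empty(n)
        values[:k] = trial.side * config.signal_offset_deg
        values[k:] = rng.uniform(0.0, period, n - k)
        mask = np.zeros(n, dtype=bool)
        mask[:k] = True
    elif trial.condition == "catch":
        if config.paradigm == "coherence":
            values = np.full(n, trial.side * config.signal_offset_deg)
            mask = np.ones(n, dtype=bool)
        else:
            values = np.full(n, trial.side * config.fixed_offset_deg)
    else:  # pragma: no cover
        raise ParameterDomainError(f"unknown condition {trial.condition!r}")
    return ElementSet(values=wrap(values, period), modality=config.modality, signal_mask=mask)


def run_criterion_phase(
    observer: Callable[[ElementSet, np.random.Generator], int],
    config: TaskConfig,
    rng,
) -> tuple[bool, int]:
    """Easy practice trials until four consecutive correct responses.

    Up to 20 trials are presented; the stimuli are the criterion stimuli (SD 0
    at the fixed mean offset for averaging; 100% coherence for coherence).
    Returns (passed, number of trials used).
    """
    streak = 0
    for t in range(1, config.criterion_max_trials + 1):
        side = 1 if rng.random() < 0.5 else -1
        trial = TrialSpec(trial_index=t, condition="catch", side=side,
                          stimulus_value=_catch_value(config))
        elements = sample_stimulus(trial, config, rng)
        response = observer(elements, rng)
        streak = streak + 1 if response == side else 0
        if streak >= config.criterion_run_length:
            return True, t
    return False, config.criterion_max_trials


@dataclass
class TaskOutcome:
    """Per-task quantities the exclusion rules consume."""

    passed_criterion: bool
    catch_errors: int
    completed: bool
    coherence_threshold: Optional[float] = None  # proportion; averaging: None


@dataclass
class ExclusionReport:
    """Outcome of the participant-level screening rules.

    Failures on either motion task remove the participant from the dataset
    entirely; failures confined to the orientation tasks retain the
    participant for motion analyses only.
    """

    participant_id: str
    flags: dict[str, dict[str, bool]] = field(default_factory=dict)
    retained_for: Literal["both", "motion", "orientation", "neither"] = "both"


def _task_flags(outcome: TaskOutcome) -> dict[str, bool]:
    return {
        "failed_criterion": not outcome.passed_criterion,
        "failed_catch": outcome.catch_errors >= CATCH_ERROR_CUTOFF,
        "incomplete": not outcome.completed,
        "threshold_at_ceiling": (
            outcome.coherence_threshold is not None and outcome.coherence_threshold >= 1.0
        ),
    }


def apply_exclusions(participant_id: str, outcomes: dict[str, TaskOutcome]) -> ExclusionReport:
    """Apply the screening rules to one participant's four task outcomes."""
    missing = [t for t in TASK_NAMES if t not in outcomes]
    if missing:
        raise IncompleteInputError(f"missing task outcomes for {participant_id}: {missing}")
    flags = {task: _task_flags(outcomes[task]) for task in TASK_NAMES}
    motion_fail = any(any(flags[t].values()) for t in MOTION_TASKS)
    ori_fail = any(any(flags[t].values()) for t in ORIENTATION_TASKS)
    if motion_fail:
        retained = "neither"
    elif ori_fail:
        retained = "motion"
    else:
        retained = "both"
    return ExclusionReport(participant_id=participant_id, flags=flags, retained_for=retained)
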