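"""Weibull psychometric function and the QUEST Bayesian adaptive staircase.

The staircase maintains a discretized posterior over log10 threshold.  The
Weibull is the Watson–Pelli log-intensity form

    p(x) = delta*gamma + (1 - delta) * [1 - (1 - gamma) * exp(-10**(beta*(x - T + eps)))]

with guess rate ``gamma``, lapse rate ``delta`` and slope ``beta``.  The
internal offset ``eps`` is solved analytically once per parameter set so that
``p(T)`` equals the target accuracy exactly (84% correct for the 2AFC tasks
here): the threshold a staircase estimates is then the target-accuracy point
by construction, whatever the Weibull internals.

All intensities are log10 stimulus units.  Conditions in which a *larger*
physical value is harder (the external-noise SD staircase) are handled by the
caller negating the axis before it reaches this module; QUEST itself always
assumes performance non-decreasing in intensity.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError, NumericalDegeneracyError, ParameterDomainError

__all__ = [
    "PsychometricParams",
    "QuestState",
    "ThresholdEstimate",
    "weibull_p_correct",
    "quest_init",
    "quest_propose",
    "quest_update",
    "quest_threshold_estimate",
    "run_staircase",
    "weibull_responder",
    "quest_state_to_json",
    "quest_state_from_json",
]

#: default grid half-width (log10 units); covers a prior SD of 2 three times over
DEFAULT_GRID_RANGE = 6.0
#: default grid step (log10 units); far below any reported effect size
DEFAULT_GRID_STEP = 0.02


@dataclass(frozen=True)
class PsychometricParams:
    """Weibull parameters anchored at a target-accuracy threshold.

    threshold_log
        log10 stimulus value at the target-accuracy point.
    beta
        Weibull slope (dimensionless, > 0).
    gamma
        guess rate; 0.5 for 2AFC.
    lapse
        stimulus-independent error probability, in [0, 0.5).
    target_accuracy
        accuracy defining the threshold, in (gamma, 1 - lapse*(1-gamma)).
    """

    threshold_log: float = 0.0
    beta: float = 3.5
    gamma: float = 0.5
    lapse: float = 0.01
    target_accuracy: float = 0.84
    epsilon: float = field(init=False, repr=False, default=0.0)

    def __post_init__(self) -> None:
        if not (self.beta > 0):
            raise ParameterDomainError(f"beta must be > 0, got {self.beta}")
        if not (0.0 <= self.gamma < 1.0):
            raise ParameterDomainError(f"gamma must be in [0, 1), got {self.gamma}")
        if not (0.0 <= self.lapse < 0.5):
            raise ParameterDomainError(f"lapse must be in [0, 0.5), got {self.lapse}")
        ceiling = 1.0 - self.lapse * (1.0 - self.gamma)
        if not (self.gamma < self.target_accuracy < ceiling):
            raise ParameterDomainError(
                "target_accuracy must lie strictly between the guess rate "
                f"({self.gamma}) and the lapse ceiling ({ceiling:.4f}); "
                f"got {self.target_accuracy}"
            )
        # Solve p(threshold_log) == target_accuracy for the offset eps.
        q = (1.0 - (self.target_accuracy - self.lapse * self.gamma) / (1.0 - self.lapse)) / (
            1.0 - self.gamma
        )
        object.__setattr__(self, "epsilon", math.log10(-math.log(q)) / self.beta)

    @property
    def ceiling(self) -> float:
        return 1.0 - self.lapse * (1.0 - self.gamma)

    @property
    def floor(self) -> float:
        return self.lapse * self.gamma + (1.0 - self.lapse) * self.gamma


def _p_correct_from_delta(delta_log, params: PsychometricParams):
    """Probability correct as a function of x_log - threshold_log."""
    d = np.asarray(delta_log, dtype=float)
    expo = np.power(10.0, np.clip(params.beta * (d + params.epsilon), -300, 300))
    core = 1.0 - (1.0 - params.gamma) * np.exp(-expo)
    return params.lapse * params.gamma + (1.0 - params.lapse) * core


def weibull_p_correct(x_log, params: PsychometricParams):
    """Probability of a correct response at log10 intensity ``x_log``.

    Monotone non-decreasing in ``x_log``; equals ``params.target_accuracy``
    at ``params.threshold_log`` exactly.
    """
    return _p_correct_from_delta(np.asarray(x_log, dtype=float) - params.threshold_log, params)


@dataclass
class QuestState:
    """Posterior over log10 threshold plus trial history for one staircase."""

    grid: np.ndarray
    posterior: np.ndarray
    params: PsychometricParams
    history: list[tuple[float, bool]] = field(default_factory=list)

    def copy(self) -> "QuestState":
        return QuestState(self.grid, self.posterior.copy(), self.params, list(self.history))


@dataclass(frozen=True)
class ThresholdEstimate:
    """Posterior-mean threshold on both the log10 and linear scales."""

    value_log: float
    value_linear: float
    posterior_sd_log: float
    n_trials: int


def quest_init(
    start_log: float,
    prior_sd_log: float,
    params: PsychometricParams,
    grid_range: float = DEFAULT_GRID_RANGE,
    grid_step: float = DEFAULT_GRID_STEP,
) -> QuestState:
    """Fresh staircase: discretized Gaussian prior centred on ``start_log``.

    The grid spans ``start_log +/- grid_range`` and must cover at least three
    prior standard deviations on each side.
    """
    if prior_sd_log <= 0:
        raise ParameterDomainError("prior_sd_log must be positive")
    if grid_range < 3.0 * prior_sd_log:
        raise ConfigurationError(
            f"grid half-range {grid_range} does not cover 3 prior SDs ({3 * prior_sd_log})"
        )
    n = int(round(2.0 * grid_range / grid_step)) + 1
    grid = start_log + np.linspace(-grid_range, grid_range, n)
    prior = np.exp(-0.5 * ((grid - start_log) / prior_sd_log) ** 2)
    prior /= prior.sum()
    return QuestState(grid=grid, posterior=prior, params=params)


def quest_propose(state: QuestState) -> float:
    """Next test intensity: the posterior mean (QuestMean placement rule)."""
    mean = float(np.dot(state.grid, state.posterior))
    return float(np.clip(mean, state.grid[0], state.grid[-1]))


def quest_update(state: QuestState, x_log: float, correct: bool) -> QuestState:
    """Bayesian update after observing one trial at ``x_log``.

    Each candidate threshold t is weighted by the Weibull likelihood of the
    observed outcome at ``x_log`` given threshold t, then renormalized.
    Returns a new state; the input is not mutated.
    """
    if not math.isfinite(x_log):
        raise ParameterDomainError(f"x_log must be finite, got {x_log}")
    p = _p_correct_from_delta(x_log - state.grid, state.params)
    lik = p if correct else 1.0 - p
    post = state.posterior * lik
    total = post.sum()
    if not np.isfinite(total) or total <= 0.0:
        # recover in log space before declaring degeneracy
        with np.errstate(divide="ignore"):
            log_post = np.log(state.posterior) + np.log(np.maximum(lik, 0.0))
        if not np.any(np.isfinite(log_post)):
            raise NumericalDegeneracyError("posterior mass vanished after update")
        log_post -= np.nanmax(log_post[np.isfinite(log_post)])
        post = np.exp(log_post)
        total = post.sum()
        if not np.isfinite(total) or total <= 0.0:
            raise NumericalDegeneracyError("posterior mass vanished after update")
    post = post / total
    return QuestState(
        grid=state.grid,
        posterior=post,
        params=state.params,
        history=state.history + [(float(x_log), bool(correct))],
    )


def quest_threshold_estimate(state: QuestState) -> ThresholdEstimate:
    """Threshold as the mean of the posterior probability density."""
    mean = float(np.dot(state.grid, state.posterior))
    second = float(np.dot(state.grid**2, state.posterior))
    var = max(second - mean**2, 0.0)
    return ThresholdEstimate(
        value_log=mean,
        value_linear=10.0**mean,
        posterior_sd_log=math.sqrt(var),
        n_trials=len(state.history),
    )


def weibull_responder(true_threshold_log: float, params: PsychometricParams, rng):
    """A simulated observer whose true psychometric function is this Weibull.

    Returns a callable ``f(x_log) -> bool`` (correct/incorrect).
    """
    truth = replace(params, threshold_log=true_threshold_log)

    def respond(x_log: float) -> bool:
        return bool(rng.random() < weibull_p_correct(x_log, truth))

    return respond


def run_staircase(responder, state: QuestState, n_trials: int) -> QuestState:
    """Drive a staircase for ``n_trials``: propose, query, update."""
    for _ in range(n_trials):
        x = quest_propose(state)
        state = quest_update(state, x, responder(x))
    return state


def quest_state_to_json(state: QuestState) -> str:
    """Serialize grid bounds/step, posterior and history to a JSON document."""
    doc = {
        "grid": {
            "lo": float(state.grid[0]),
            "hi": float(state.grid[-1]),
            "n": int(len(state.grid)),
        },
        "posterior": state.posterior.tolist(),
        "params": {
            "threshold_log": state.params.threshold_log,
            "beta": state.params.beta,
            "gamma": state.params.gamma,
            "lapse": state.params.lapse,
            "target_accuracy": state.params.target_accuracy,
        },
        "history": [[x, bool(c)] for x, c in state.history],
    }
    return json.dumps(doc)


def quest_state_from_json(doc: str) -> QuestState:
    d = json.loads(doc)
    grid = np.linspace(d["grid"]["lo"], d["grid"]["hi"], d["grid"]["n"])
    return QuestState(
        grid=grid,
        posterior=np.asarray(d["posterior"], dtype=float),
        params=PsychometricParams(**d["params"]),
        history=[(float(x), bool(c)) for x, c in d["history"]],
    )
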