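"""Candidate reinforcement-learning models for the volatile bandit task.

The family spans the dimensions the design varies: learning
(Rescorla–Wagner delta rule with one learning rate, or separate rates for
the stable and volatile phases), exploration (a softmax temperature),
starting bias (complementary initial values b and 1-b), and whether
displayed coin magnitudes enter the utility. Two chance-level null models
and two win-stay/lose-shift heuristics complete the 12-member family.

The designated winning model is the four-parameter Rescorla–Wagner
variant: starting bias b, temperature tau, and phase-specific learning
rates alpha_stable and alpha_volatile.

Choice rule (softmax with temperature tau):

    P(A) = exp(u_A / tau) / (exp(u_A / tau) + exp(u_B / tau))

where u is the estimated reward probability v, or v * magnitude / 100 for
magnitude-sensitive models. Lower tau means more deterministic (less
exploratory) choice.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .task import TaskSchedule

__all__ = [
    "ModelSpec",
    "AgentParams",
    "ValueState",
    "TrialSeries",
    "WINNING_MODEL_ID",
    "default_family",
    "get_spec",
    "initial_state",
    "rw_update",
    "choice_prob",
    "log_likelihood",
    "pointwise_loglik",
    "derive_trial_series",
    "family_to_json",
]

WINNING_MODEL_ID = "M06"


@dataclass(frozen=True)
class ModelSpec:
    """Structure of one candidate model."""

    model_id: str
    rule: Literal["random", "rescorla_wagner", "win_stay_lose_shift"]
    is_null: bool = False
    has_bias: bool = False
    dual_learning_rate: bool = False
    uses_magnitude: bool = False
    is_winner: bool = False

    def __post_init__(self) -> None:
        if self.is_null and (self.rule != "random" or self.n_free_params not in (0, 1)):
            raise ValueError(f"{self.model_id}: null models must be random with <=1 parameter")

    @property
    def param_names(self) -> tuple[str, ...]:
        if self.rule == "random":
            return ("bias",) if self.has_bias else ()
        if self.rule == "win_stay_lose_shift":
            return ("stay", "bias") if self.has_bias else ("stay",)
        names: list[str] = []
        if self.has_bias:
            names.append("bias")
        names.append("tau")
        names.append("alpha_stable")
        if self.dual_learning_rate:
            names.append("alpha_volatile")
        return tuple(names)

    @property
    def n_free_params(self) -> int:
        return len(self.param_names)


@dataclass(frozen=True)
class AgentParams:
    """Participant-level parameters; fields unused by a spec are ignored.

    bias: initial value of option A, in (0, 1); 0.5 = no preference.
    tau: softmax temperature, > 0; higher = more exploratory.
    alpha_stable / alpha_volatile: learning rates in (0, 1). Single-rate
    models use alpha_stable on every trial.
    stay: win-stay probability for the heuristic models, in (0, 1).
    """

    bias: float = 0.5
    tau: float = 1.0
    alpha_stable: float = 0.3
    alpha_volatile: float = 0.3
    stay: float = 0.7

    def __post_init__(self) -> None:
        for name in ("bias", "alpha_stable", "alpha_volatile", "stay"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie strictly in (0, 1), got {v}")
        if not self.tau > 0.0:
            raise ValueError(f"tau must be > 0, got {self.tau}")

    def as_dict(self) -> dict[str, float]:
        return {
            "bias": self.bias,
            "tau": self.tau,
            "alpha_stable": self.alpha_stable,
            "alpha_volatile": self.alpha_volatile,
            "stay": self.stay,
        }


@dataclass
class ValueState:
    """Estimated reward probabilities of the two options."""

    v_A: float
    v_B: float


@dataclass(frozen=True)
class TrialSeries:
    """Trialwise model-derived series used as parametric regressors."""

    ev_chosen: np.ndarray
    pe: np.ndarray
    phase: tuple[str, ...]


def default_family() -> tuple[ModelSpec, ...]:
    """The 12-model candidate family.

    M01/M02: null (chance / constant-bias choice). M03-M06: Rescorla-Wagner
    on probability estimates, crossing single vs dual learning rates with
    bias off/on; M06 (bias + tau + two rates, 4 parameters) is the
    designated winner. M07-M10: same lattice with magnitude-weighted
    utilities. M11/M12: win-stay/lose-shift without and with a starting
    bias.
    """
    specs = [
        ModelSpec("M01", "random", is_null=True),
        ModelSpec("M02", "random", is_null=True, has_bias=True),
        ModelSpec("M03", "rescorla_wagner"),
        ModelSpec("M04", "rescorla_wagner", dual_learning_rate=True),
        ModelSpec("M05", "rescorla_wagner", has_bias=True),
        ModelSpec("M06", "rescorla_wagner", has_bias=True, dual_learning_rate=True, is_winner=True),
        ModelSpec("M07", "rescorla_wagner", uses_magnitude=True),
        ModelSpec("M08", "rescorla_wagner", dual_learning_rate=True, uses_magnitude=True),
        ModelSpec("M09", "rescorla_wagner", has_bias=True, uses_magnitude=True),
        ModelSpec(
            "M10",
            "rescorla_wagner",
            has_bias=True,
            dual_learning_rate=True,
            uses_magnitude=True,
        ),
        ModelSpec("M11", "win_stay_lose_shift"),
        ModelSpec("M12", "win_stay_lose_shift", has_bias=True),
    ]
    return tuple(specs)


def get_spec(model_id: str) -> ModelSpec:
    for spec in default_family():
        if spec.model_id == model_id:
            return spec
    raise KeyError(f"unknown model id {model_id!r}")


def family_to_json(path) -> None:
    """Persist the model registry as JSON."""
    entries = [
        {
            "model_id": s.model_id,
            "rule": s.rule,
            "is_null": s.is_null,
            "has_bias": s.has_bias,
            "dual_learning_rate": s.dual_learning_rate,
            "uses_magnitude": s.uses_magnitude,
            "is_winner": s.is_winner,
            "n_free_params": s.n_free_params,
            "param_names": list(s.param_names),
        }
        for s in default_family()
    ]
    with open(path, "w") as fh:
        json.dump(entries, fh, indent=2)


def initial_state(spec: ModelSpec, params: AgentParams) -> ValueState:
    """Starting value estimates: (b, 1-b) when the spec has a bias, else (0.5, 0.5)."""
    if spec.has_bias:
        return ValueState(v_A=params.bias, v_B=1.0 - params.bias)
    return ValueState(v_A=0.5, v_B=0.5)


def rw_update(state: ValueState, chosen: str, r: int, alpha: float) -> ValueState:
    """Delta-rule update of the chosen option only: v += alpha * (r - v)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if chosen == "A":
        return ValueState(v_A=state.v_A + alpha * (r - state.v_A), v_B=state.v_B)
    return ValueState(v_A=state.v_A, v_B=state.v_B + alpha * (r - state.v_B))


def _utilities(state: ValueState, trial, spec: ModelSpec) -> tuple[float, float]:
    if spec.uses_magnitude:
        if trial.magnitude_A <= 0 or trial.magnitude_B <= 0:
            raise ValueError(
                f"{spec.model_id} requires magnitudes but trial {trial.trial_index} has none; "
                "generate the schedule with magnitude_rule='complementary_uniform'"
            )
        return state.v_A * trial.magnitude_A / 100.0, state.v_B * trial.magnitude_B / 100.0
    return state.v_A, state.v_B


def choice_prob(state: ValueState, trial, spec: ModelSpec, tau: float) -> float:
    """Softmax probability of choosing option A."""
    if not tau > 0.0:
        raise ValueError(f"tau must be > 0, got {tau}")
    u_a, u_b = _utilities(state, trial, spec)
    # logistic form of the two-option softmax; numerically safe for |du| large
    du = (u_a - u_b) / tau
    if du >= 0:
        return 1.0 / (1.0 + math.exp(-du))
    e = math.exp(du)
    return e / (1.0 + e)


def _p_choose_a_sequence(
    spec: ModelSpec, params: AgentParams, choices: Sequence, schedule: TaskSchedule
) -> tuple[list[float], list[float]]:
    """Sequential choice probabilities P(A) and pre-outcome EV of the chosen option.

    ``choices`` holds records with ``chosen`` ("A"/"B") and ``outcome``
    (0/1) attributes, aligned 1:1 with the schedule's trials.
    """
    trials = schedule.trials
    if len(choices) != len(trials):
        raise ValueError(
            f"choice sequence length {len(choices)} does not match schedule length {len(trials)}"
        )
    p_a: list[float] = []
    ev: list[float] = []

    if spec.rule == "random":
        p = params.bias if spec.has_bias else 0.5
        for c in choices:
            p_a.append(p)
            ev.append(p if c.chosen == "A" else 1.0 - p)
        return p_a, ev

    if spec.rule == "win_stay_lose_shift":
        p_first = params.bias if spec.has_bias else 0.5
        prev_choice: str | None = None
        prev_outcome = 0
        for c in choices:
            if prev_choice is None:
                p = p_first
            else:
                p_stay = params.stay if prev_outcome == 1 else 1.0 - params.stay
                p = p_stay if prev_choice == "A" else 1.0 - p_stay
            p_a.append(p)
            ev.append(p if c.chosen == "A" else 1.0 - p)
            prev_choice, prev_outcome = c.chosen, c.outcome
        return p_a, ev

    state = initial_state(spec, params)
    for c, t in zip(choices, trials):
        p_a.append(choice_prob(state, t, spec, params.tau))
        ev.append(state.v_A if c.chosen == "A" else state.v_B)
        alpha = (
            params.alpha_volatile
            if (spec.dual_learning_rate and t.phase == "volatile")
            else params.alpha_stable
        )
        state = rw_update(state, c.chosen, c.outcome, alpha)
    return p_a, ev


def pointwise_loglik(
    spec: ModelSpec, params: AgentParams, choices: Sequence, schedule: TaskSchedule
) -> np.ndarray:
    """Per-trial log probability of the observed choices."""
    p_a, _ = _p_choose_a_sequence(spec, params, choices, schedule)
    out = np.empty(len(p_a))
    for i, (p, c) in enumerate(zip(p_a, choices)):
        pc = p if c.chosen == "A" else 1.0 - p
        out[i] = math.log(max(pc, 1e-300))
    return out


def log_likelihood(
    spec: ModelSpec, params: AgentParams, choices: Sequence, schedule: TaskSchedule
) -> tuple[float, np.ndarray]:
    """Total and per-trial log-likelihood of a choice sequence."""
    pw = pointwise_loglik(spec, params, choices, schedule)
    return float(pw.sum()), pw


def derive_trial_series(
    spec: ModelSpec, params: AgentParams, choices: Sequence, schedule: TaskSchedule
) -> TrialSeries:
    """Expected value of the chosen option (pre-outcome) and prediction error per trial."""
    _, ev = _p_choose_a_sequence(spec, params, choices, schedule)
    ev_arr = np.asarray(ev)
    r = np.asarray([c.outcome for c in choices], dtype=float)
    return TrialSeries(
        ev_chosen=ev_arr,
        pe=r - ev_arr,
        phase=tuple(t.phase for t in schedule.trials),
    )
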