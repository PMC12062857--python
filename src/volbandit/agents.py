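"""Synthetic behaviour and cohorts for the volatile bandit study design.

Two layers:

* ``simulate_agent`` draws trialwise choices from any model in the family,
  playing against a task schedule.
* ``generate_cohort`` builds a full synthetic study cohort — two matched
  groups (maltreated MT, non-maltreated NMT), covariates drawn i.i.d. from
  shared distributions, a standardized group difference in softmax
  temperature, a configurable fraction of random responders (participants
  whose choices come from the chance-level null model), counterbalanced
  phase order, and longitudinal symptom scores with a group-by-temperature
  interaction plus per-group retention.

Default cohort parameters follow the study structure they emulate:
n = 37 vs 32, temperature difference d = 0.70 (NMT above MT), 35% random
responders, learning-rate distributions centred on 0.35 (stable) and 0.41
(volatile), retention probabilities 27/37 and 29/32.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import expit

from .models import WINNING_MODEL_ID, AgentParams, ModelSpec, get_spec
from .task import TaskConfig, TaskSchedule, generate_schedule

__all__ = [
    "ChoiceRecord",
    "BehaviouralDataset",
    "CohortConfig",
    "simulate_agent",
    "generate_cohort",
    "generate_followup_symptoms",
    "cohort_to_csv",
    "cohort_from_csv",
]

COHORT_COLUMNS = [
    "participant_id",
    "group",
    "sex",
    "age",
    "iq",
    "pubertal",
    "ses",
    "order",
    "responder_type",
    "true_bias",
    "true_tau",
    "true_alpha_stable",
    "true_alpha_volatile",
    "sdq_emotional_baseline",
    "sdq_total_baseline",
    "retained",
    "sdq_emotional_followup",
    "sdq_total_followup",
]


@dataclass(frozen=True)
class ChoiceRecord:
    participant_id: str
    trial_index: int
    chosen: str  # "A" or "B"
    outcome: int  # 1 if the chosen option was the rewarded one
    coins_won: int


class BehaviouralDataset:
    """Trialwise choices grouped by participant, each tied to a schedule."""

    def __init__(self) -> None:
        self._schedules: dict[str, TaskSchedule] = {}
        self._choices: dict[str, list[ChoiceRecord]] = {}

    def add(self, participant_id: str, schedule: TaskSchedule, choices: Sequence[ChoiceRecord]) -> None:
        if participant_id in self._choices:
            raise ValueError(f"duplicate participant id {participant_id!r}")
        if len(choices) != len(schedule):
            raise ValueError(
                f"participant {participant_id!r}: {len(choices)} choice records "
                f"for a {len(schedule)}-trial schedule"
            )
        self._schedules[participant_id] = schedule
        self._choices[participant_id] = list(choices)

    @property
    def participant_ids(self) -> list[str]:
        return list(self._choices)

    def __len__(self) -> int:
        return len(self._choices)

    def __contains__(self, pid: str) -> bool:
        return pid in self._choices

    def schedule(self, pid: str) -> TaskSchedule:
        return self._schedules[pid]

    def choices(self, pid: str) -> list[ChoiceRecord]:
        return self._choices[pid]

    def subset(self, pids: Iterable[str]) -> "BehaviouralDataset":
        out = BehaviouralDataset()
        for pid in pids:
            out.add(pid, self._schedules[pid], self._choices[pid])
        return out

    def to_frame(self) -> pd.DataFrame:
        """Tidy trials table: one row per participant x trial, with schedule columns."""
        rows = []
        for pid, recs in self._choices.items():
            sched = self._schedules[pid]
            for rec, trial in zip(recs, sched.trials):
                rows.append(
                    {
                        "participant_id": pid,
                        "trial_index": rec.trial_index,
                        "phase": trial.phase,
                        "block_id": trial.block_id,
                        "high_prob_option": trial.high_prob_option,
                        "rewarded_option": trial.rewarded_option,
                        "magnitude_A": trial.magnitude_A,
                        "magnitude_B": trial.magnitude_B,
                        "chosen": rec.chosen,
                        "outcome": rec.outcome,
                        "coins_won": rec.coins_won,
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "BehaviouralDataset":
        from .task import TrialRecord, _infer_config

        out = cls()
        required = {"participant_id", "trial_index", "chosen", "outcome", "rewarded_option"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"trials table missing columns: {sorted(missing)}")
        for pid, grp in frame.groupby("participant_id", sort=False):
            grp = grp.sort_values("trial_index")
            trials = tuple(
                TrialRecord(
                    int(r.trial_index),
                    str(r.phase),
                    int(r.block_id),
                    str(r.high_prob_option),
                    str(r.rewarded_option),
                    int(r.magnitude_A),
                    int(r.magnitude_B),
                )
                for r in grp.itertuples()
            )
            schedule = TaskSchedule(config=_infer_config(trials), trials=trials)
            recs = [
                ChoiceRecord(str(pid), int(r.trial_index), str(r.chosen), int(r.outcome), int(r.coins_won))
                for r in grp.itertuples()
            ]
            out.add(str(pid), schedule, recs)
        return out

    @classmethod
    def from_csv(cls, path) -> "BehaviouralDataset":
        return cls.from_frame(pd.read_csv(path))


def simulate_agent(
    params: AgentParams,
    spec: ModelSpec,
    schedule: TaskSchedule,
    seed: int,
    participant_id: str = "agent",
) -> list[ChoiceRecord]:
    """Play the schedule with choices drawn from the model's own probabilities.

    Value updates see the simulated choice and the realised outcome, exactly
    as the likelihood does, so simulated data are in-model by construction.
    """
    if spec.uses_magnitude and schedule.config.magnitude_rule == "none":
        raise ValueError(
            f"{spec.model_id} uses magnitudes but the schedule was generated without them"
        )
    from .models import choice_prob, initial_state, rw_update

    rng = np.random.default_rng(seed)
    records: list[ChoiceRecord] = []
    state = initial_state(spec, params)
    prev_choice: str | None = None
    prev_outcome = 0
    for trial in schedule.trials:
        if spec.rule == "random":
            p_a = params.bias if spec.has_bias else 0.5
        elif spec.rule == "win_stay_lose_shift":
            if prev_choice is None:
                p_a = params.bias if spec.has_bias else 0.5
            else:
                p_stay = params.stay if prev_outcome == 1 else 1.0 - params.stay
                p_a = p_stay if prev_choice == "A" else 1.0 - p_stay
        else:
            p_a = choice_prob(state, trial, spec, params.tau)
        chosen = "A" if rng.random() < p_a else "B"
        outcome = int(chosen == trial.rewarded_option)
        if spec.rule == "rescorla_wagner":
            alpha = (
                params.alpha_volatile
                if (spec.dual_learning_rate and trial.phase == "volatile")
                else params.alpha_stable
            )
            state = rw_update(state, chosen, outcome, alpha)
        prev_choice, prev_outcome = chosen, outcome
        mag = trial.magnitude_A if chosen == "A" else trial.magnitude_B
        records.append(
            ChoiceRecord(
                participant_id=participant_id,
                trial_index=trial.trial_index,
                chosen=chosen,
                outcome=outcome,
                coins_won=outcome * mag,
            )
        )
    return records


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


@dataclass(frozen=True)
class CohortConfig:
    """Generating conditions for a synthetic cohort.

    Group sizes, the temperature effect size, the random-responder fraction,
    symptom-model coefficients and retention probabilities default to the
    study structure the generator emulates. Symptom-model coefficients are
    standardized regression weights on an outcome constructed with total
    variance near 1, with group effect-coded MT = -1, NMT = +1.
    """

    n_mt: int = 37
    n_nmt: int = 32
    temperature_effect_d: float = 0.70  # NMT minus MT, in pooled-SD units
    random_responder_fraction: float = 0.35
    # covariates (shared across groups -> matched in expectation)
    sex_p_female: float = 0.535
    age_mean: float = 13.6
    age_sd: float = 2.1
    iq_mean: float = 101.0
    iq_sd: float = 10.5
    pubertal_mean: float = 2.45
    pubertal_sd: float = 0.85
    ses_mean: float = 3.25
    ses_sd: float = 0.9
    # agent parameter distributions (truncated normals on the natural scale)
    tau_mean_nmt: float = 0.45
    tau_pooled_sd: float = 0.20
    alpha_stable_mean: float = 0.35
    alpha_stable_sd: float = 0.07
    alpha_volatile_mean: float = 0.41
    alpha_volatile_sd: float = 0.17
    bias_logit_sd: float = 1.0
    # baseline symptoms: (mean, sd) per group
    sdq_emotional_baseline_mt: tuple[float, float] = (2.8, 2.3)
    sdq_emotional_baseline_nmt: tuple[float, float] = (1.5, 1.5)
    sdq_total_baseline_mt: tuple[float, float] = (11.2, 6.8)
    sdq_total_baseline_nmt: tuple[float, float] = (6.6, 4.3)
    # longitudinal symptom model (standardized scale)
    beta_interaction: float = -0.80
    beta_baseline: float = 0.30
    beta_group: float = -0.40
    beta_temperature: float = -0.15
    symptom_noise_sd: float = 0.30
    followup_loc: float = 2.8  # affine map of the standardized outcome back to
    followup_scale: float = 2.2  # an SDQ-like score range
    # retention
    retention_p_mt: float = 27 / 37
    retention_p_nmt: float = 29 / 32
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.random_responder_fraction <= 1.0):
            raise ValueError("random_responder_fraction must lie in [0, 1]")
        for name in ("retention_p_mt", "retention_p_nmt", "sex_p_female"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_mt < 2 or self.n_nmt < 2:
            raise ValueError("group sizes must be >= 2")
        for name in (
            "age_sd", "iq_sd", "pubertal_sd", "ses_sd", "tau_pooled_sd",
            "alpha_stable_sd", "alpha_volatile_sd", "bias_logit_sd",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def generate_cohort(
    config: CohortConfig,
    task_config: TaskConfig | None = None,
    simulate_behaviour: bool = True,
) -> tuple[pd.DataFrame, BehaviouralDataset]:
    """Draw a cohort table and (optionally) its trialwise behaviour.

    Covariates are i.i.d. from shared distributions, so the groups are
    matched in expectation. Temperature in the MT group is shifted down by
    ``temperature_effect_d`` pooled-SD units. A fixed, rounded fraction of
    each group is designated random responders and simulated from the null
    model; all others play the winning four-parameter model with their true
    parameters. Phase order alternates deterministically within each group
    (counterbalancing). Follow-up symptoms and retention are appended via
    :func:`generate_followup_symptoms`.
    """
    rng = np.random.default_rng(config.seed)
    n_total = config.n_mt + config.n_nmt
    if config.n_mt % 2 == 1 or config.n_nmt % 2 == 1:
        warnings.warn(
            "odd group size: phase-order counterbalancing is off by one participant",
            stacklevel=2,
        )
    groups = ["MT"] * config.n_mt + ["NMT"] * config.n_nmt
    tau_mean_mt = config.tau_mean_nmt - config.temperature_effect_d * config.tau_pooled_sd

    rows = []
    for i, group in enumerate(groups):
        tau_mean = tau_mean_mt if group == "MT" else config.tau_mean_nmt
        tau = float(_truncnorm(rng, tau_mean, config.tau_pooled_sd, 0.02, np.inf, None))
        rows.append(
            {
                "participant_id": f"{group}{i:03d}",
                "group": group,
                "sex": "F" if rng.random() < config.sex_p_female else "M",
                "age": float(_truncnorm(rng, config.age_mean, config.age_sd, 10.0, 16.99, None)),
                "iq": float(rng.normal(config.iq_mean, config.iq_sd)),
                "pubertal": float(_truncnorm(rng, config.pubertal_mean, config.pubertal_sd, 1.0, 5.0, None)),
                "ses": float(_truncnorm(rng, config.ses_mean, config.ses_sd, 1.0, 5.0, None)),
                "true_bias": float(expit(rng.normal(0.0, config.bias_logit_sd))),
                "true_tau": tau,
                "true_alpha_stable": float(
                    _truncnorm(rng, config.alpha_stable_mean, config.alpha_stable_sd, 0.02, 0.98, None)
                ),
                "true_alpha_volatile": float(
                    _truncnorm(rng, config.alpha_volatile_mean, config.alpha_volatile_sd, 0.02, 0.98, None)
                ),
            }
        )
    cohort = pd.DataFrame(rows)

    # random responders: fixed rounded count per group, random membership
    cohort["responder_type"] = "model"
    for group, n_g in (("MT", config.n_mt), ("NMT", config.n_nmt)):
        n_rand = int(round(config.random_responder_fraction * n_g))
        idx = cohort.index[cohort["group"] == group]
        chosen = rng.choice(idx, size=n_rand, replace=False)
        cohort.loc[chosen, "responder_type"] = "random"

    # deterministic alternating counterbalancing within group
    orders = []
    counters = {"MT": 0, "NMT": 0}
    for group in cohort["group"]:
        orders.append("stable_first" if counters[group] % 2 == 0 else "volatile_first")
        counters[group] += 1
    cohort["order"] = orders

    # baseline symptoms
    for col, mt_ms, nmt_ms in (
        ("sdq_emotional_baseline", config.sdq_emotional_baseline_mt, config.sdq_emotional_baseline_nmt),
        ("sdq_total_baseline", config.sdq_total_baseline_mt, config.sdq_total_baseline_nmt),
    ):
        vals = np.empty(n_total)
        for group, (m, s) in (("MT", mt_ms), ("NMT", nmt_ms)):
            mask = (cohort["group"] == group).to_numpy()
            vals[mask] = _truncnorm(rng, m, s, 0.0, np.inf, int(mask.sum()))
        cohort[col] = vals

    dataset = BehaviouralDataset()
    if simulate_behaviour:
        base_task = task_config or TaskConfig()
        winner = get_spec(WINNING_MODEL_ID)
        null = get_spec("M01")
        for row in cohort.itertuples():
            sched_cfg = replace(
                base_task, order=row.order, seed=int(rng.integers(2**31 - 1))
            )
            schedule = generate_schedule(sched_cfg)
            params = AgentParams(
                bias=row.true_bias,
                tau=row.true_tau,
                alpha_stable=row.true_alpha_stable,
                alpha_volatile=row.true_alpha_volatile,
            )
            spec = null if row.responder_type == "random" else winner
            recs = simulate_agent(
                params, spec, schedule, seed=int(rng.integers(2**31 - 1)),
                participant_id=row.participant_id,
            )
            dataset.add(row.participant_id, schedule, recs)

    cohort = generate_followup_symptoms(cohort, config, seed=int(rng.integers(2**31 - 1)))
    return cohort[COHORT_COLUMNS], dataset


def generate_followup_symptoms(cohort: pd.DataFrame, config: CohortConfig, seed: int) -> pd.DataFrame:
    """Append follow-up symptoms and retention flags.

    Follow-up emotional symptoms are a linear combination of the z-scored
    baseline score, effect-coded group (MT = -1, NMT = +1), z-scored true
    temperature, and the group-by-temperature product weighted by
    ``beta_interaction``, plus Gaussian noise, mapped affinely onto an
    SDQ-like scale. Coefficients are standardized weights chosen so the
    outcome variance is near 1; the standardized interaction coefficient a
    moderation regression recovers is therefore commensurate with
    ``beta_interaction``. Follow-up values are present only for retained
    participants (drawn per-group Bernoulli).
    """
    rng = np.random.default_rng(seed)
    cohort = cohort.copy()

    def z(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        sd = x.std(ddof=1)
        return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)

    g = np.where(cohort["group"] == "MT", -1.0, 1.0)
    z_base = z(cohort["sdq_emotional_baseline"])
    z_tau = z(cohort["true_tau"])
    noise = rng.normal(0.0, config.symptom_noise_sd, size=len(cohort))
    y = (
        config.beta_baseline * z_base
        + config.beta_group * g
        + config.beta_temperature * z_tau
        + config.beta_interaction * g * z_tau
        + noise
    )
    followup_emo = config.followup_loc + config.followup_scale * y

    z_total = z(cohort["sdq_total_baseline"])
    noise_t = rng.normal(0.0, config.symptom_noise_sd, size=len(cohort))
    y_total = 0.6 * z_total + config.beta_group * g + noise_t
    followup_total = 9.8 + 5.8 * y_total

    p_ret = np.where(cohort["group"] == "MT", config.retention_p_mt, config.retention_p_nmt)
    retained = rng.random(len(cohort)) < p_ret
    cohort["retained"] = retained
    cohort["sdq_emotional_followup"] = np.where(retained, followup_emo, np.nan)
    cohort["sdq_total_followup"] = np.where(retained, followup_total, np.nan)
    return cohort


def cohort_to_csv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False, na_rep="")


def cohort_from_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    return frame
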