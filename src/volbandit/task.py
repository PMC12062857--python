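"""Reward schedules for the stable/volatile two-option bandit task.

The task presents two options ("pirates") A and B for 120 trials. In the
stable phase (60 trials) one option pays off on exactly 75% of trials; in
the volatile phase (three blocks of 20 trials) the better option pays off
on exactly 80% of trials within each block and the identity of the better
option reverses at every block boundary. Phase order is counterbalanced
across participants.

Schedules use an exact-ratio construction: the number of trials on which
the high-probability option is rewarded is fixed (45/60 stable, 16/20 per
volatile block) and only the positions of those trials are randomised.
This guarantees the nominal contingencies in every realisation.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterator, Literal, Sequence

import numpy as np

__all__ = [
    "TaskConfig",
    "TrialRecord",
    "TaskSchedule",
    "TaskConfigError",
    "ScheduleParseError",
    "generate_schedule",
    "assign_magnitudes",
    "write_schedule_csv",
    "read_schedule_csv",
]

SCHEDULE_CSV_HEADER = [
    "trial_index",
    "phase",
    "block_id",
    "high_prob_option",
    "rewarded_option",
    "magnitude_A",
    "magnitude_B",
]


class TaskConfigError(ValueError):
    """Raised when a task configuration violates its invariants."""


class ScheduleParseError(ValueError):
    """Raised when a schedule file cannot be parsed; carries the line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class TaskConfig:
    """Structural parameters of the bandit task.

    Defaults reproduce the 120-trial design: 60 stable trials at a 75/25
    contingency and three 20-trial volatile blocks at 80/20.
    """

    n_stable_trials: int = 60
    stable_p: float = 0.75
    n_volatile_blocks: int = 3
    volatile_block_len: int = 20
    volatile_p: float = 0.80
    order: Literal["stable_first", "volatile_first"] = "stable_first"
    magnitude_rule: Literal["none", "complementary_uniform"] = "complementary_uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_stable_trials", "n_volatile_blocks", "volatile_block_len"):
            if getattr(self, name) < 1:
                raise TaskConfigError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in ("stable_p", "volatile_p"):
            p = getattr(self, name)
            if not 0.5 < p < 1.0:
                raise TaskConfigError(f"{name} must lie in (0.5, 1), got {p}")
        if self.order not in ("stable_first", "volatile_first"):
            raise TaskConfigError(f"order must be stable_first/volatile_first, got {self.order!r}")
        if self.magnitude_rule not in ("none", "complementary_uniform"):
            raise TaskConfigError(f"unknown magnitude_rule {self.magnitude_rule!r}")
        # Exact-ratio construction needs integer reward counts.
        n_hi = self.stable_p * self.n_stable_trials
        if abs(n_hi - round(n_hi)) > 1e-9:
            raise TaskConfigError(
                f"stable_p * n_stable_trials = {n_hi} is not an integer; "
                "exact-ratio schedules require integer reward counts (field: stable_p)"
            )
        n_hi_v = self.volatile_p * self.volatile_block_len
        if abs(n_hi_v - round(n_hi_v)) > 1e-9:
            raise TaskConfigError(
                f"volatile_p * volatile_block_len = {n_hi_v} is not an integer; "
                "exact-ratio schedules require integer reward counts (field: volatile_p)"
            )

    @property
    def n_trials(self) -> int:
        return self.n_stable_trials + self.n_volatile_blocks * self.volatile_block_len


@dataclass(frozen=True)
class TrialRecord:
    trial_index: int  # 1-based
    phase: Literal["stable", "volatile"]
    block_id: int
    high_prob_option: Literal["A", "B"]
    rewarded_option: Literal["A", "B"]
    magnitude_A: int = 0
    magnitude_B: int = 0


@dataclass(frozen=True)
class TaskSchedule:
    config: TaskConfig
    trials: tuple[TrialRecord, ...]

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self) -> Iterator[TrialRecord]:
        return iter(self.trials)

    def validate(self) -> None:
        """Check structural invariants; raise AssertionError on violation."""
        cfg = self.config
        assert len(self.trials) == cfg.n_trials
        stable = [t for t in self.trials if t.phase == "stable"]
        n_hi = sum(t.rewarded_option == t.high_prob_option for t in stable)
        assert n_hi == round(cfg.stable_p * cfg.n_stable_trials)
        vol_blocks: dict[int, list[TrialRecord]] = {}
        for t in self.trials:
            if t.phase == "volatile":
                vol_blocks.setdefault(t.block_id, []).append(t)
        for trials in vol_blocks.values():
            assert len(trials) == cfg.volatile_block_len
            n_hi_v = sum(t.rewarded_option == t.high_prob_option for t in trials)
            assert n_hi_v == round(cfg.volatile_p * cfg.volatile_block_len)
            assert len({t.high_prob_option for t in trials}) == 1


def _reward_sequence(n: int, n_high: int, high: str, rng: np.random.Generator) -> list[str]:
    """Rewarded option per trial: exactly ``n_high`` of ``n`` go to ``high``."""
    other = "B" if high == "A" else "A"
    seq = [high] * n_high + [other] * (n - n_high)
    return list(rng.permutation(seq))


def generate_schedule(config: TaskConfig) -> TaskSchedule:
    """Build a schedule satisfying the exact-ratio contingency invariants.

    Rewarded trials are positioned by a seeded permutation within the
    stable phase and within each volatile block. The high-probability
    option is A in the stable phase and alternates A, B, A, ... across
    volatile blocks (a contingency reversal at every block boundary).
    """
    rng = np.random.default_rng(config.seed)
    stable_high = "A"
    n_hi_stable = round(config.stable_p * config.n_stable_trials)
    n_hi_block = round(config.volatile_p * config.volatile_block_len)

    stable_part: list[tuple[str, int, str, str]] = [
        ("stable", 0, stable_high, rewarded)
        for rewarded in _reward_sequence(config.n_stable_trials, n_hi_stable, stable_high, rng)
    ]
    volatile_part: list[tuple[str, int, str, str]] = []
    for b in range(config.n_volatile_blocks):
        high = "A" if b % 2 == 0 else "B"
        for rewarded in _reward_sequence(config.volatile_block_len, n_hi_block, high, rng):
            volatile_part.append(("volatile", b + 1, high, rewarded))

    ordered = (
        stable_part + volatile_part
        if config.order == "stable_first"
        else volatile_part + stable_part
    )
    trials = tuple(
        TrialRecord(
            trial_index=i + 1,
            phase=phase,  # type: ignore[arg-type]
            block_id=block,
            high_prob_option=high,  # type: ignore[arg-type]
            rewarded_option=rewarded,  # type: ignore[arg-type]
        )
        for i, (phase, block, high, rewarded) in enumerate(ordered)
    )
    schedule = TaskSchedule(config=config, trials=trials)
    if config.magnitude_rule == "complementary_uniform":
        schedule = assign_magnitudes(schedule, seed=config.seed + 1)
    schedule.validate()
    return schedule


def assign_magnitudes(schedule: TaskSchedule, seed: int) -> TaskSchedule:
    """Draw complementary coin magnitudes: A ~ Uniform{10..90}, B = 100 - A."""
    if schedule.config.magnitude_rule == "none":
        warnings.warn("magnitude_rule is 'none'; assign_magnitudes is a no-op", stacklevel=2)
        return schedule
    rng = np.random.default_rng(seed)
    mags = rng.integers(10, 91, size=len(schedule.trials))
    trials = tuple(
        replace(t, magnitude_A=int(m), magnitude_B=int(100 - m))
        for t, m in zip(schedule.trials, mags)
    )
    return TaskSchedule(config=schedule.config, trials=trials)


def write_schedule_csv(schedule: TaskSchedule, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(SCHEDULE_CSV_HEADER)
        for t in schedule.trials:
            writer.writerow(
                [
                    t.trial_index,
                    t.phase,
                    t.block_id,
                    t.high_prob_option,
                    t.rewarded_option,
                    t.magnitude_A,
                    t.magnitude_B,
                ]
            )


def read_schedule_csv(path, config: TaskConfig | None = None) -> TaskSchedule:
    """Read a schedule written by :func:`write_schedule_csv`.

    The dialect is strict: the exact header, lower-case phase labels, and
    in-range values are required. ``config`` defaults to a TaskConfig
    inferred from the trial rows (counts and phase structure), which is
    sufficient for round-tripping default schedules.
    """
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ScheduleParseError("empty file, expected header", line=1) from None
        if header != SCHEDULE_CSV_HEADER:
            raise ScheduleParseError(
                f"bad header {header!r}, expected {SCHEDULE_CSV_HEADER!r}", line=1
            )
        trials: list[TrialRecord] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(SCHEDULE_CSV_HEADER):
                raise ScheduleParseError(f"expected {len(SCHEDULE_CSV_HEADER)} fields", line=lineno)
            try:
                idx = int(row[0])
                block = int(row[2])
                mag_a = int(row[5])
                mag_b = int(row[6])
            except ValueError as exc:
                raise ScheduleParseError(str(exc), line=lineno) from None
            phase, high, rewarded = row[1], row[3], row[4]
            if phase not in ("stable", "volatile"):
                raise ScheduleParseError(f"bad phase {phase!r}", line=lineno)
            if high not in ("A", "B") or rewarded not in ("A", "B"):
                raise ScheduleParseError(f"bad option label in {row!r}", line=lineno)
            if mag_a < 0 or mag_b < 0:
                raise ScheduleParseError("negative magnitude", line=lineno)
            trials.append(
                TrialRecord(idx, phase, block, high, rewarded, mag_a, mag_b)  # type: ignore[arg-type]
            )
    if not trials:
        raise ScheduleParseError("no trial rows", line=2)
    if config is None:
        config = _infer_config(trials)
    return TaskSchedule(config=config, trials=tuple(trials))


def _infer_config(trials: Sequence[TrialRecord]) -> TaskConfig:
    stable = [t for t in trials if t.phase == "stable"]
    vol = [t for t in trials if t.phase == "volatile"]
    blocks = sorted({t.block_id for t in vol})
    block_len = len(vol) // len(blocks) if blocks else 1
    n_hi = sum(t.rewarded_option == t.high_prob_option for t in stable)
    first_block = [t for t in vol if t.block_id == blocks[0]] if blocks else []
    n_hi_v = sum(t.rewarded_option == t.high_prob_option for t in first_block)
    any_mag = any(t.magnitude_A > 0 for t in trials)
    return TaskConfig(
        n_stable_trials=len(stable),
        stable_p=n_hi / len(stable),
        n_volatile_blocks=len(blocks),
        volatile_block_len=block_len,
        volatile_p=n_hi_v / block_len,
        order="stable_first" if trials[0].phase == "stable" else "volatile_first",
        magnitude_rule="complementary_uniform" if any_mag else "none",
    )
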