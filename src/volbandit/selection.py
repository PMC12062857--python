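"""Model scoring and comparison: WAIC, K-fold CV, null-model exclusion.

The participant-level comparison mirrors the analysis pipeline this
package reproduces: every candidate model is scored per participant with
a complexity-penalised predictive criterion (WAIC from the Laplace
approximation around the participant's MAP fit), each non-null model is
compared against the chance-level null model, and participants whose best
model is the null are flagged as random responders and excluded before
the group-level analysis. Group model comparison is an equal-weighted sum
of participant model evidence; a WAIC over pooled hierarchical draws is
also provided.

WAIC here follows the standard pointwise definition: for trial i,
``lppd_i = log mean_s exp(loglik_is)`` and ``p_i = var_s loglik_is``;
``elpd_waic = sum_i (lppd_i - p_i)`` with a standard error from the
spread of the pointwise contributions. ``waic = -2 * elpd_waic``.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from ._likelihood import participant_arrays, pointwise_vec
from .inference import LOG_HALF, ParticipantFit, PriorSpec, fit_participant
from .models import ModelSpec

__all__ = [
    "WaicResult",
    "KfoldResult",
    "ExclusionReport",
    "compute_waic",
    "participant_evidence",
    "participant_null_comparison",
    "kfold_cv",
    "compare_models_group",
    "compare_models_by_participant_evidence",
]


@dataclass(frozen=True)
class WaicResult:
    elpd_waic: float
    p_waic: float
    waic: float
    se: float
    n_points: int
    per_participant_elpd: np.ndarray | None = None

    def as_dict(self) -> dict:
        return {
            "elpd_waic": self.elpd_waic,
            "p_waic": self.p_waic,
            "waic": self.waic,
            "se": self.se,
            "n_points": self.n_points,
        }


def compute_waic(pointwise_loglik: np.ndarray) -> WaicResult:
    """WAIC from a draws-by-points (or draws-by-participants-by-trials) matrix."""
    pw = np.asarray(pointwise_loglik, dtype=float)
    if pw.ndim not in (2, 3):
        raise ValueError("pointwise_loglik must be 2-D (S, n) or 3-D (S, P, T)")
    S = pw.shape[0]
    if S < 2:
        raise ValueError("WAIC needs >= 2 draws (the variance penalty is undefined)")
    if not np.all(np.isfinite(pw)):
        raise ValueError("pointwise log-likelihood contains non-finite values")
    per_participant = None
    if pw.ndim == 3:
        P, T = pw.shape[1], pw.shape[2]
        lppd_pt = logsumexp(pw, axis=0) - math.log(S)        # (P, T)
        p_pt = pw.var(axis=0, ddof=1)                        # (P, T)
        per_participant = (lppd_pt - p_pt).sum(axis=1)       # (P,)
        pw = pw.reshape(S, P * T)
    lppd_i = logsumexp(pw, axis=0) - math.log(S)
    p_i = pw.var(axis=0, ddof=1)
    elpd_i = lppd_i - p_i
    n = elpd_i.size
    elpd = float(elpd_i.sum())
    se = float(math.sqrt(n * elpd_i.var(ddof=1))) if n > 1 else 0.0
    return WaicResult(
        elpd_waic=elpd,
        p_waic=float(p_i.sum()),
        waic=-2.0 * elpd,
        se=se,
        n_points=n,
        per_participant_elpd=per_participant,
    )


def participant_evidence(
    spec: ModelSpec,
    choices,
    schedule,
    priors: PriorSpec | None = None,
    n_draws: int = 200,
    seed: int = 0,
) -> tuple[float, ParticipantFit | None]:
    """Complexity-penalised model evidence (WAIC elpd) for one participant.

    Parameter-free models have the closed form ``n * log(0.5)``; all others
    use WAIC over Laplace-approximation draws around the MAP fit.
    """
    n = len(choices)
    if spec.n_free_params == 0:
        return n * LOG_HALF, None
    fit = fit_participant(spec, choices, schedule, priors=priors, seed=seed)
    arr = participant_arrays(choices, schedule)
    theta = fit.laplace_draws(n_draws, seed=seed + 1)
    pw = pointwise_vec(spec, {k: v for k, v in theta.items()}, arr)  # (S, T)
    return compute_waic(pw).elpd_waic, fit


@dataclass(frozen=True)
class ExclusionReport:
    """Outcome of the participant-level null-model comparison."""

    table: pd.DataFrame  # per participant: best_model, elpd per model, excluded
    excluded_fraction: float

    @property
    def excluded_ids(self) -> list[str]:
        return list(self.table.index[self.table["excluded"]])

    @property
    def included_ids(self) -> list[str]:
        return list(self.table.index[~self.table["excluded"]])


def participant_null_comparison(
    dataset,
    family,
    priors: PriorSpec | None = None,
    n_draws: int = 200,
    seed: int = 0,
) -> ExclusionReport:
    """Score every model per participant; flag those best fit by a null model.

    A participant is excluded when no non-null model achieves higher
    penalised evidence than the best null model — the signature of random
    decision making. Fit failures are carried as flags (``any_fit_failed``),
    never silently dropped. The result is invariant to participant order.
    """
    family = list(family)
    null_specs = [s for s in family if s.is_null]
    if not null_specs:
        raise ValueError("family contains no null model")
    rows = []
    for pid in dataset.participant_ids:
        choices = dataset.choices(pid)
        schedule = dataset.schedule(pid)
        evidences: dict[str, float] = {}
        any_failed = False
        for spec in family:
            elpd, fit = participant_evidence(
                spec, choices, schedule, priors=priors, n_draws=n_draws,
                seed=seed + (zlib.crc32(pid.encode()) % 100_000),
            )
            evidences[spec.model_id] = elpd
            if fit is not None and not fit.converged:
                any_failed = True
        best_null = max(evidences[s.model_id] for s in null_specs)
        non_null = {s.model_id: evidences[s.model_id] for s in family if not s.is_null}
        best_alt_id = max(non_null, key=non_null.get)
        excluded = non_null[best_alt_id] <= best_null
        best_model = (
            max((s.model_id for s in null_specs), key=evidences.get) if excluded else best_alt_id
        )
        rows.append(
            {
                "participant_id": pid,
                **{f"elpd_{m}": v for m, v in evidences.items()},
                "best_model": best_model,
                "evidence_vs_null": non_null[best_alt_id] - best_null,
                "excluded": excluded,
                "any_fit_failed": any_failed,
            }
        )
    table = pd.DataFrame(rows).set_index("participant_id")
    frac = float(table["excluded"].mean()) if len(table) else float("nan")
    return ExclusionReport(table=table, excluded_fraction=frac)


@dataclass(frozen=True)
class KfoldResult:
    K: int
    seed: int
    fold_scores: np.ndarray   # held-out log score per fold
    elpd_kfold: float

    def as_dict(self) -> dict:
        return {
            "K": self.K,
            "seed": self.seed,
            "fold_scores": self.fold_scores.tolist(),
            "elpd_kfold": self.elpd_kfold,
        }


def _fold_assignment(schedule, K: int, rng: np.random.Generator) -> np.ndarray:
    """Phase-stratified fold labels for one participant's trials."""
    phases = np.array([t.phase for t in schedule.trials])
    folds = np.empty(len(phases), dtype=int)
    offset = 0
    for ph in ("stable", "volatile"):
        idx = np.flatnonzero(phases == ph)
        if idx.size == 0:
            continue
        perm = rng.permutation(idx)
        # continue the round-robin across phases so K = n gives singleton folds
        folds[perm] = (np.arange(idx.size) + offset) % K
        offset += idx.size
    return folds


def kfold_cv(
    spec: ModelSpec,
    dataset,
    priors: PriorSpec | None = None,
    K: int = 10,
    seed: int = 0,
) -> KfoldResult:
    """K-fold cross-validated predictive score, stratified by phase.

    Trials are partitioned within participant. For each fold the model is
    refit by MAP on the training trials' likelihood terms (value updates
    still traverse every trial, since the learner saw all feedback) and
    held-out trials are scored at the training MAP. ``K = n_trials``
    reduces to leave-one-trial-out.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    rng = np.random.default_rng(seed)
    assignments: dict[str, np.ndarray] = {}
    for pid in dataset.participant_ids:
        schedule = dataset.schedule(pid)
        if len(schedule) < K:
            raise ValueError(
                f"participant {pid!r} has {len(schedule)} trials, fewer than K={K}; "
                "stratified partitioning impossible"
            )
        assignments[pid] = _fold_assignment(schedule, K, rng)

    fold_scores = np.zeros(K)
    for pid in dataset.participant_ids:
        choices = dataset.choices(pid)
        schedule = dataset.schedule(pid)
        folds = assignments[pid]
        for k in range(K):
            heldout = folds == k
            if not heldout.any():
                continue
            train_w = (~heldout).astype(float)
            fit = fit_participant(
                spec, choices, schedule, priors=priors, seed=seed + k, weights=train_w
            )
            if spec.n_free_params == 0:
                score = heldout.sum() * LOG_HALF
            else:
                arr = participant_arrays(choices, schedule)
                pw = pointwise_vec(
                    spec,
                    {n: np.asarray(v) for n, v in fit.estimates.items()},
                    arr,
                )
                score = float(pw[heldout].sum())
            fold_scores[k] += score
    return KfoldResult(K=K, seed=seed, fold_scores=fold_scores, elpd_kfold=float(fold_scores.sum()))


def _rank_table(rows: list[dict]) -> pd.DataFrame:
    table = pd.DataFrame(rows).set_index("model_id")
    # lowest WAIC wins; ties broken toward fewer free parameters
    table = table.sort_values(["waic", "n_free_params"], kind="mergesort")
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def compare_models_group(fits: dict, included_ids: list[str] | None = None) -> pd.DataFrame:
    """Rank hierarchical fits by WAIC over the included participants.

    ``fits`` maps model_id to a PosteriorFit. All fits must cover the same
    participant set; ``included_ids`` restricts the comparison (e.g. after
    exclusion). Returns a table sorted by WAIC with the winner first.
    """
    if not fits:
        raise ValueError("no fits to compare")
    id_sets = {tuple(f.participant_ids) for f in fits.values()}
    if len(id_sets) > 1:
        raise ValueError("fits cover different participant sets")
    all_ids = list(next(iter(fits.values())).participant_ids)
    if included_ids is None:
        included_ids = all_ids
    missing = set(included_ids) - set(all_ids)
    if missing:
        raise ValueError(f"included participants absent from fits: {sorted(missing)}")
    keep = np.array([pid in set(included_ids) for pid in all_ids])
    rows = []
    for model_id, fit in fits.items():
        waic = compute_waic(fit.pointwise_loglik[:, keep, :])
        rows.append(
            {
                "model_id": model_id,
                "elpd": waic.elpd_waic,
                "p_waic": waic.p_waic,
                "waic": waic.waic,
                "se": waic.se,
                "n_free_params": fit.spec.n_free_params,
            }
        )
    return _rank_table(rows)


def compare_models_by_participant_evidence(
    dataset,
    family,
    included_ids: list[str] | None = None,
    priors: PriorSpec | None = None,
    n_draws: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Rank models by the equal-weighted sum of participant-level evidence."""
    family = list(family)
    ids = included_ids if included_ids is not None else dataset.participant_ids
    rows = []
    for spec in family:
        total = 0.0
        for pid in ids:
            elpd, _ = participant_evidence(
                spec, dataset.choices(pid), dataset.schedule(pid),
                priors=priors, n_draws=n_draws, seed=seed + (zlib.crc32(pid.encode()) % 100_000),
            )
            total += elpd
        rows.append(
            {
                "model_id": spec.model_id,
                "elpd": total,
                "waic": -2.0 * total,
                "n_free_params": spec.n_free_params,
            }
        )
    return _rank_table(rows)
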