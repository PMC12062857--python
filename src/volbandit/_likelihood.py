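"""Fast likelihood kernels over array-packed choice data.

Two evaluation paths serve the fitting code:

* a scalar pure-Python loop (``loglik_scalar``) used inside per-participant
  optimisation, where call overhead dominates;
* a broadcast NumPy path (``pointwise_vec``) that evaluates many parameter
  vectors and/or many participants at once, used by the hierarchical
  sampler and by posterior-draw pointwise log-likelihoods.

Both reproduce :func:`volbandit.models.log_likelihood` exactly; a test
pins the scalar/vector/reference paths against each other.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .models import ModelSpec
from .task import TaskSchedule

TINY = 1e-300


def participant_arrays(choices: Sequence, schedule: TaskSchedule) -> dict[str, np.ndarray]:
    """Pack one participant's trials into flat arrays (shape (T,))."""
    if len(choices) != len(schedule):
        raise ValueError("choices and schedule lengths differ")
    chosen_a = np.array([1.0 if c.chosen == "A" else 0.0 for c in choices])
    r = np.array([float(c.outcome) for c in choices])
    vol = np.array([t.phase == "volatile" for t in schedule.trials])
    if schedule.config.magnitude_rule == "none":
        s_a = np.ones(len(choices))
        s_b = np.ones(len(choices))
        has_mag = False
    else:
        s_a = np.array([t.magnitude_A / 100.0 for t in schedule.trials])
        s_b = np.array([t.magnitude_B / 100.0 for t in schedule.trials])
        has_mag = True
    return {"chosen_a": chosen_a, "r": r, "vol": vol, "s_a": s_a, "s_b": s_b,
            "has_mag": has_mag}


def dataset_arrays(dataset, pids: Sequence[str] | None = None) -> dict[str, np.ndarray]:
    """Stack participants into (P, T) arrays; all must share one trial count."""
    pids = list(pids) if pids is not None else dataset.participant_ids
    per = [participant_arrays(dataset.choices(p), dataset.schedule(p)) for p in pids]
    lengths = {a["r"].shape[0] for a in per}
    if len(lengths) > 1:
        raise ValueError(f"participants have unequal trial counts: {sorted(lengths)}")
    out = {k: np.stack([a[k] for a in per]) for k in ("chosen_a", "r", "vol", "s_a", "s_b")}
    out["has_mag"] = all(a["has_mag"] for a in per)
    out["participant_ids"] = pids
    return out


def _check_magnitudes(spec: ModelSpec, arr: dict) -> None:
    if spec.uses_magnitude and not arr["has_mag"]:
        raise ValueError(f"{spec.model_id} requires magnitudes but the schedule has none")


def loglik_scalar(spec: ModelSpec, theta: dict[str, float], arr: dict,
                  weights: np.ndarray | None = None) -> float:
    """Total (optionally trial-weighted) log-likelihood; pure-Python loop."""
    _check_magnitudes(spec, arr)
    chosen_a = arr["chosen_a"].tolist()
    r = arr["r"].tolist()
    w = weights.tolist() if weights is not None else None
    total = 0.0
    log = math.log
    exp = math.exp

    if spec.rule == "random":
        p_a = theta.get("bias", 0.5) if spec.has_bias else 0.5
        for i, ca in enumerate(chosen_a):
            p = p_a if ca else 1.0 - p_a
            term = log(p if p > TINY else TINY)
            total += term * w[i] if w is not None else term
        return total

    if spec.rule == "win_stay_lose_shift":
        stay = theta["stay"]
        p_first = theta.get("bias", 0.5) if spec.has_bias else 0.5
        prev_a, prev_r = None, 0.0
        for i, ca in enumerate(chosen_a):
            if prev_a is None:
                p_a = p_first
            else:
                p_stay = stay if prev_r == 1.0 else 1.0 - stay
                p_a = p_stay if prev_a else 1.0 - p_stay
            p = p_a if ca else 1.0 - p_a
            term = log(p if p > TINY else TINY)
            total += term * w[i] if w is not None else term
            prev_a, prev_r = ca, r[i]
        return total

    # Rescorla-Wagner
    tau = theta["tau"]
    a_s = theta["alpha_stable"]
    a_v = theta.get("alpha_volatile", a_s) if spec.dual_learning_rate else a_s
    b = theta.get("bias", 0.5) if spec.has_bias else 0.5
    v_a, v_b = b, 1.0 - b
    vol = arr["vol"].tolist()
    s_a = arr["s_a"].tolist()
    s_b = arr["s_b"].tolist()
    use_mag = spec.uses_magnitude
    for i, ca in enumerate(chosen_a):
        if use_mag:
            du = (v_a * s_a[i] - v_b * s_b[i]) / tau
        else:
            du = (v_a - v_b) / tau
        # log P(chosen) via the stable log-sigmoid form
        if ca:
            term = -math.log1p(exp(-du)) if du > -30 else du
        else:
            term = -math.log1p(exp(du)) if du < 30 else -du
        total += term * w[i] if w is not None else term
        alpha = a_v if vol[i] else a_s
        if ca:
            v_a += alpha * (r[i] - v_a)
        else:
            v_b += alpha * (r[i] - v_b)
    return total


def pointwise_vec(spec: ModelSpec, theta: dict[str, np.ndarray], arr: dict) -> np.ndarray:
    """Pointwise log-likelihood, broadcasting parameter arrays against data.

    Data arrays have shape ``(..., T)`` and parameter arrays any shape
    broadcastable against the data's leading dimensions; the result has
    the broadcast shape plus a trailing T axis. Typical uses:
    ``(P, T)`` data with ``(P,)`` parameters, or ``(T,)`` data with
    ``(S, 1)``-shaped parameters for posterior draws.
    """
    _check_magnitudes(spec, arr)
    chosen_a = arr["chosen_a"]
    r = arr["r"]
    T = chosen_a.shape[-1]
    lead = np.broadcast_shapes(
        chosen_a.shape[:-1], *(np.shape(v) for v in theta.values())
    )
    out = np.empty(lead + (T,))

    if spec.rule == "random":
        b = theta.get("bias", 0.5) if spec.has_bias else 0.5
        p_a = np.broadcast_to(np.asarray(b, dtype=float), lead)
        for t in range(T):
            p = np.where(chosen_a[..., t] == 1.0, p_a, 1.0 - p_a)
            out[..., t] = np.log(np.maximum(p, TINY))
        return out

    if spec.rule == "win_stay_lose_shift":
        stay = np.asarray(theta["stay"], dtype=float)
        p_first = np.asarray(theta.get("bias", 0.5) if spec.has_bias else 0.5, dtype=float)
        for t in range(T):
            if t == 0:
                p_a = np.broadcast_to(p_first, lead)
            else:
                p_stay = np.where(r[..., t - 1] == 1.0, stay, 1.0 - stay)
                p_a = np.where(chosen_a[..., t - 1] == 1.0, p_stay, 1.0 - p_stay)
            p = np.where(chosen_a[..., t] == 1.0, p_a, 1.0 - p_a)
            out[..., t] = np.log(np.maximum(p, TINY))
        return out

    tau = np.asarray(theta["tau"], dtype=float)
    a_s = np.asarray(theta["alpha_stable"], dtype=float)
    if spec.dual_learning_rate:
        a_v = np.asarray(theta.get("alpha_volatile", a_s), dtype=float)
    else:
        a_v = a_s
    if spec.has_bias:
        b = np.asarray(theta.get("bias", 0.5), dtype=float)
    else:
        b = np.asarray(0.5)
    v_a = np.broadcast_to(b, lead).astype(float).copy()
    v_b = 1.0 - v_a
    vol = arr["vol"]
    s_a, s_b = arr["s_a"], arr["s_b"]
    use_mag = spec.uses_magnitude
    for t in range(T):
        if use_mag:
            du = (v_a * s_a[..., t] - v_b * s_b[..., t]) / tau
        else:
            du = (v_a - v_b) / tau
        ca = chosen_a[..., t] == 1.0
        signed = np.where(ca, du, -du)
        # log sigmoid(signed), numerically stable
        out[..., t] = np.where(
            signed > -30.0, -np.log1p(np.exp(-np.clip(signed, -30.0, 700.0))), signed
        )
        alpha = np.where(vol[..., t], a_v, a_s)
        rt = r[..., t]
        v_a = np.where(ca, v_a + alpha * (rt - v_a), v_a)
        v_b = np.where(~ca, v_b + alpha * (rt - v_b), v_b)
    return out
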