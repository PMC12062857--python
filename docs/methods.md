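# Methods

This note documents the modelling and numerical choices in `volbandit`: the
task, the candidate model family, the inference machinery, the model
selection and exclusion rules, the synthetic-cohort generator and its
defaults, the group-level statistics, and known limitations.

## Task

A session is 120 two-option (A/B) trials: a 60-trial **stable** phase with a
75/25 reward contingency and a 60-trial **volatile** phase of three 20-trial
blocks with an 80/20 contingency that reverses at every block boundary.
Ratios are exact, not expected: the stable phase contains exactly 45 trials
rewarding the high-probability option, and each volatile block exactly 16.
The rewarded-trial positions are shuffled within phase/block from a seeded
generator. Phase order (stable-first / volatile-first) is a configuration
flag counterbalanced across a cohort. Reward magnitudes are complementary:
`magnitude_A ~ U{10..90}` per trial and `magnitude_B = 100 - magnitude_A`,
so magnitude information is orthogonal to probability information. The
schedule validator rejects configurations whose trial counts and rates do
not produce integer reward counts.

## Candidate model family

Twelve models, spanning null baselines, Rescorla–Wagner (RW) learners and
win-stay/lose-shift (WSLS) heuristics:

| ID  | Kind | Free parameters | k |
|-----|------|-----------------|---|
| M01 | random (null) | — | 0 |
| M02 | biased random (null) | bias | 1 |
| M03 | RW | tau, alpha | 2 |
| M04 | RW dual-rate | tau, alpha_stable, alpha_volatile | 3 |
| M05 | RW + bias | bias, tau, alpha | 3 |
| M06 | RW dual-rate + bias (**winner**) | bias, tau, alpha_stable, alpha_volatile | 4 |
| M07 | RW, magnitude-weighted | tau, alpha | 2 |
| M08 | RW dual-rate, magnitude-weighted | tau, alpha_stable, alpha_volatile | 3 |
| M09 | RW + bias, magnitude-weighted | bias, tau, alpha | 3 |
| M10 | RW dual-rate + bias, magnitude-weighted | bias, tau, alpha_stable, alpha_volatile | 4 |
| M11 | WSLS | stay | 1 |
| M12 | WSLS + bias | bias, stay | 2 |

RW models update only the chosen option's expected value by the delta rule
`V <- V + alpha * (r - V)` with `r` in {0, 1}; dual-rate variants use
`alpha_stable` in the stable phase and `alpha_volatile` in volatile blocks.
Magnitude-weighted variants act on utilities `u = V * magnitude / 100`.
Choice is softmax on the (utility) difference,
`P(A) = 1 / (1 + exp(-(u_A - u_B) / tau))`; smaller temperature `tau` means
more deterministic choice. The bias parameter sets initial values to
`(b, 1 - b)`; with typical learning rates its influence washes out within
roughly ten trials, so it is primarily identified by early-session choices.
WSLS repeats a rewarded choice and switches after a loss with probability
`stay`, with an optional biased first trial.

Each model exposes three likelihood paths — a plain reference
implementation, a fast scalar loop, and a vectorised pointwise evaluator —
which are tested to agree to 1e-9 across the full family.

## Parameter transforms and priors

Inference operates on unconstrained coordinates: logit for unit-interval
parameters (`bias`, learning rates, `stay`) and log for `tau`. Priors are
Normal(0, 1.5) on logit-scale parameters and Normal(-1, 1) on `log tau`,
weakly informative on the natural scales. Group-level standard deviations
get half-Normal(1) priors.

## Per-participant inference

`fit_participant` maximises the log posterior with multi-start L-BFGS-B on
the unconstrained scale and reports a Laplace approximation from the
numerical Hessian at the mode. `laplace_draws` samples from that Gaussian
and maps draws back to the natural scale. Per-participant evidence for
model selection is the WAIC computed over 200 Laplace draws; for the
zero-parameter null the evidence is the closed form `n * log(0.5)`.

## Hierarchical inference

`fit_hierarchical` implements a non-centred hierarchical model: participant
parameters on the unconstrained scale are `theta_p = mu + sigma * eta_p`
with standard-normal `eta_p`, Normal hyperpriors on `mu` and half-Normal(1)
on `sigma`. Sampling is Metropolis-within-Gibbs:

- vectorised random-walk Metropolis on each participant's unconstrained
  parameters, with Robbins–Monro step-size adaptation and a Welford
  estimate of the per-parameter proposal scale during warmup;
- conjugate Gibbs updates for `mu` given the participant draws;
- Metropolis on `log sigma`;
- an **interweaved non-centred sweep**: once per iteration, for each
  parameter dimension in random order, a joint proposal shifts the group
  mean by `delta ~ Normal(0, 0.2 / sqrt(P))` and rescales the group SD and
  every participant's deviation from the mean by a common factor
  `c = exp(0.35 * Normal(0, 1))`. The acceptance ratio includes the
  `log c` Jacobian of the rescaling and the hyperprior terms. This move is
  what breaks the funnel coupling between `sigma` and the participant
  deviations: when `sigma` is small, centred participant updates freeze and
  `sigma` cannot move conditionally on them, but the joint rescaling
  traverses the funnel directly. The translation scale is
  state-independent so the proposal stays symmetric.

Diagnostics use ArviZ: split-R-hat and effective sample size per dimension,
reported as `max_rhat` / `min_ess` plus per-dimension acceptance rates for
the interweaved move. Runs are accepted when `max_rhat <= 1.05`. The
random-walk sampler has no divergence concept; the `divergences` field
counts non-finite log-density proposals and should be zero.

Determinism: all randomness flows from `numpy` `SeedSequence` objects —
chains spawn with `spawn_key=(chain,)`, and per-participant seeds derive
from `zlib.crc32` of the participant ID, so results are independent of
participant ordering and stable across runs and platforms.

## Model selection and exclusion

- **WAIC**: `elpd_waic = sum_i (lppd_i - var_i)` over pointwise
  log-likelihood draws; `waic = -2 * elpd_waic`. Ties in model ranking are
  broken toward fewer parameters using a stable sort.
- **K-fold cross-validation**: folds are stratified by phase so every fold
  holds out proportionally from stable and volatile trials; `K = n`
  reduces exactly to leave-one-trial-out.
- **Exclusion rule**: a participant is excluded when no non-null model
  achieves higher penalised evidence than the best null (random) model —
  the signature of stimulus-independent responding. Fit failures are
  flagged, never silently dropped, and the report is invariant to
  participant order.
- **Group comparison**: models are ranked by the equal-weighted sum of
  participant-level evidence across included participants.

## Synthetic cohort generator

The generator produces an MT group (default n = 37) and an NMT group
(default n = 32) with:

- winning-model behavioural parameters: `tau` truncated-Normal with NMT
  mean 0.45 and pooled SD 0.20, with the MT mean shifted by a standardised
  effect of 0.70 (MT more deterministic/less exploratory);
  `alpha_stable ~ TN(0.35, 0.07)` and `alpha_volatile ~ TN(0.41, 0.17)`,
  reflecting faster, more variable updating under volatility; bias
  logit-Normal(0, 1).
- a configurable fraction (default 35%) of **random responders** whose
  choices are coin flips, with exact rounded counts per group;
- matched covariates (age, IQ, pubertal stage, SES, sex) drawn from shared
  distributions;
- Bernoulli retention with expected retained counts 27/37 (MT) and 29/32
  (NMT); follow-up symptom scores exist only for retained participants;
- longitudinal emotional-symptom scores built from standardized baseline,
  group (effect-coded MT = -1, NMT = +1), temperature and a group-by-
  temperature interaction with default standardized weight -0.80, plus
  configurable Gaussian noise.

These defaults were fixed a priori from the design targets above and are
not tuned to downstream test outcomes.

## Group-level statistics

- Two-sample pooled-variance t-tests (df = n1 + n2 - 2) and paired
  t-tests, with Cohen's d.
- Pearson chi-square on 2x2 tables without continuity correction (e.g.
  retention 27/37 vs 29/32 gives chi-square 3.50, p ~= .061).
- Mann–Whitney U: exact enumeration of all C(n, n1) group assignments with
  midranks for combined n <= 12, normal approximation without continuity
  correction otherwise.
- Power analysis via the noncentral t distribution; the sensitivity effect
  size inverts power with Brent's method. A guard maps numerical NaN
  underflow at extreme noncentrality to power 1.0.
- Moderated regression: OLS on z-scored continuous predictors with
  effect-coded group, listwise deletion, and part (semipartial)
  correlations `r_part = t * sqrt(1 - R^2) / sqrt(df_resid)`; simple
  effects are estimated per group; Holm correction is available for
  families of tests.

Standard numerics are delegated to SciPy, statsmodels and ArviZ; the
bespoke components are the task/agent/likelihood code, the hierarchical
sampler and the exact Mann–Whitney enumeration (kept in-package so exact
small-sample behaviour is fully specified and testable).

## Limitations

- Individual differences in the stable-phase learning rate are small
  relative to single-session estimation noise (60 stable trials), so
  recovery of `alpha_stable` is substantially weaker than for `tau` or
  `alpha_volatile`; this is an information limit of the design at default
  generator settings, not an estimator artifact (unpooled estimates recover
  it worse than the hierarchical fit).
- The model family contains several nested RW variants whose predictions
  differ mainly in early trials; with per-parameter complexity penalties,
  single-cohort model identification between adjacent variants (e.g.
  dual-rate with vs without bias) is not guaranteed.
- About a third of pure coin-flip responders produce 120-trial sequences
  that mildly favour some structured model, so the null-model exclusion
  rule under-detects random responding at the default 35% contamination.
- The random-walk hierarchical sampler needs a few thousand iterations for
  R-hat <= 1.05 on ~70-participant cohorts (minutes of CPU time); it trades
  speed for having no gradient requirement.
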