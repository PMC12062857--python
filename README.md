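# volbandit

Simulation, model fitting and group-level analysis for a two-option
probabilistic reward-learning task with stable and volatile phases, aimed at
studying how youth exposed to maltreatment (MT) differ from non-maltreated
(NMT) peers in adapting choice behaviour to environmental volatility, and
whether those differences moderate later emotional symptoms.

## Scientific problem

Participants repeatedly choose between two options, A and B, each paired with
a visible reward magnitude; only one option pays out on each trial. The
session has 120 trials:

- a **stable phase** (60 trials) in which one option is rewarded on exactly
  75% of trials, and
- a **volatile phase** (3 blocks of 20 trials) in which the better option is
  rewarded on exactly 80% of trials within each block and the contingency
  reverses at every block boundary.

Phase order is counterbalanced across participants. Adaptive behaviour in
this design is well described by reinforcement-learning models whose
parameters — choice temperature and phase-specific learning rates — index how
deterministically a participant exploits value estimates and how quickly they
update after surprising outcomes. The package provides:

1. exact-ratio task schedule generation (`volbandit.task`),
2. synthetic agents and a two-group cohort generator with covariates,
   retention and longitudinal symptom scores (`volbandit.agents`),
3. a 12-model candidate family (`volbandit.models`) with fast likelihood
   evaluation (`volbandit._likelihood`),
4. per-participant MAP + Laplace fits and a hierarchical Bayesian sampler
   (`volbandit.inference`),
5. WAIC model selection, K-fold cross-validation and a null-model exclusion
   rule (`volbandit.selection`),
6. the cohort-level statistics: t-tests, chi-square, exact Mann–Whitney,
   noncentral-t power analysis and moderated regression (`volbandit.stats`),
7. a staged, seeded, resumable analysis pipeline with a CLI
   (`volbandit.pipeline`, `volbandit.cli`).

## The winning model

The designated model (`M06`) is a Rescorla–Wagner learner with dual learning
rates, an initial bias and a softmax temperature. Expected values update only
for the chosen option:

```
V_c(t+1) = V_c(t) + alpha_phase * (r(t) - V_c(t))
```

with `alpha_phase` equal to `alpha_stable` or `alpha_volatile` according to
the current phase, and `r(t)` in {0, 1}. Choice follows a softmax on the
value difference:

```
P(choose A) = 1 / (1 + exp(-(V_A - V_B) / tau))
```

The bias parameter `b` sets the initial values to `(b, 1 - b)`. The family
also contains null (random) baselines, single-learning-rate and magnitude-
weighted variants, and win-stay/lose-shift heuristics; see
`docs/methods.md` for the full table.

## Run the tests

```bash
python -m pytest -q tests/
```

The suite includes end-to-end acceptance tests in
`tests/test_acceptance.py`; the hierarchical-sampler and model-recovery
tests run for several minutes each.

## Worked example

Generate a schedule, simulate an agent from the winning model, and fit it
back by MAP:

```python
import numpy as np
from volbandit.task import TaskConfig, generate_schedule
from volbandit.models import AgentParams, get_spec
from volbandit.agents import simulate_agent
from volbandit.inference import fit_participant

schedule = generate_schedule(TaskConfig(seed=42))
len(schedule)                      # 120
stable = [t for t in schedule if t.phase == "stable"]
sum(t.rewarded_option == t.high_prob_option for t in stable) / len(stable)
                                   # 0.75 (exact by construction)

spec = get_spec("M06")
truth = AgentParams(tau=0.30, alpha_stable=0.35, alpha_volatile=0.45, bias=0.5)
records = simulate_agent(truth, spec, schedule, seed=7)
np.mean([r.chosen == t.high_prob_option
         for r, t in zip(records, schedule.trials)])
                                   # 0.683 — the agent learns the task

fit = fit_participant(spec, records, schedule, seed=0)
fit.estimates
# {'bias': 0.384, 'tau': 0.273, 'alpha_stable': 0.236, 'alpha_volatile': 0.273}
fit.log_posterior                  # -62.14
```

Single-session point estimates are noisy (one 120-trial session carries
limited information per parameter); group-level analyses in this package use
the hierarchical sampler, whose partial pooling substantially improves
per-participant estimates.

## Documentation

`docs/methods.md` describes the model family, priors and transforms, the
hierarchical sampler design, the synthetic-cohort generator defaults and
their rationale, and known limitations.
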