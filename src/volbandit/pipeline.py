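"""Staged analysis pipeline: simulate -> fit -> select -> stats -> report.

Each stage reads the previous stage's artifacts from the output directory,
derives its own seed deterministically from the global seed and the stage
name, and writes a sidecar JSON recording the configuration hash, the
stage seed and the artifact paths. Re-running a stage with unchanged
inputs is idempotent; a configuration-hash mismatch between stages is
refused unless forced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import time
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .agents import (
    BehaviouralDataset,
    CohortConfig,
    cohort_from_csv,
    cohort_to_csv,
    generate_cohort,
)
from .inference import PosteriorFit, PriorSpec, SamplerConfig, fit_hierarchical
from .models import WINNING_MODEL_ID, default_family, family_to_json, get_spec
from .selection import (
    compare_models_by_participant_evidence,
    participant_null_comparison,
)
from .stats import (
    chi_square_2x2,
    hierarchical_regression,
    holm_correction,
    paired_ttest,
    power_two_sample_t,
    sensitivity_d,
    simple_effects,
    two_sample_ttest,
)
from .task import TaskConfig

__all__ = ["RunConfig", "PipelineError", "run_stage", "reproduce", "STAGES"]

STAGES = ("simulate", "fit", "select", "stats", "report")


class PipelineError(RuntimeError):
    pass


@dataclass(frozen=True)
class RunConfig:
    task: TaskConfig = field(default_factory=TaskConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    priors: PriorSpec = field(default_factory=PriorSpec)
    sampler: SamplerConfig = field(default_factory=lambda: SamplerConfig(chains=2, warmup=400, draws=400))
    k_folds: int = 10
    alpha: float = 0.05
    holm: bool = False
    evidence_draws: int = 200
    seed: int = 0

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)

    def to_dict(self) -> dict:
        return {
            "task": dataclasses.asdict(self.task),
            "cohort": dataclasses.asdict(self.cohort),
            "priors": dataclasses.asdict(self.priors),
            "sampler": dataclasses.asdict(self.sampler),
            "k_folds": self.k_folds,
            "alpha": self.alpha,
            "holm": self.holm,
            "evidence_draws": self.evidence_draws,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        def build(klass, sub):
            if sub is None:
                return klass()
            fields = {f.name for f in dataclasses.fields(klass)}
            unknown = set(sub) - fields
            if unknown:
                raise PipelineError(f"unknown {klass.__name__} fields: {sorted(unknown)}")
            sub = {
                k: tuple(v) if isinstance(v, list) else v for k, v in sub.items()
            }
            return klass(**sub)

        return cls(
            task=build(TaskConfig, d.get("task")),
            cohort=build(CohortConfig, d.get("cohort")),
            priors=build(PriorSpec, d.get("priors")),
            sampler=build(SamplerConfig, d.get("sampler")),
            k_folds=d.get("k_folds", 10),
            alpha=d.get("alpha", 0.05),
            holm=d.get("holm", False),
            evidence_draws=d.get("evidence_draws", 200),
            seed=d.get("seed", 0),
        )

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            text = fh.read()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.from_dict(data or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _sidecar_path(outdir, stage):
    return os.path.join(outdir, f"{stage}.meta.json")


def _write_sidecar(outdir, stage, config: RunConfig, artifacts: list[str], t0: float) -> None:
    meta = {
        "stage": stage,
        "config_hash": config.config_hash(),
        "seed": config.stage_seed(stage),
        "artifacts": artifacts,
        "wall_time_s": round(time.time() - t0, 3),
    }
    with open(_sidecar_path(outdir, stage), "w") as fh:
        json.dump(meta, fh, indent=2)


def _require_upstream(outdir, stage, upstream, config: RunConfig, force: bool) -> None:
    path = _sidecar_path(outdir, upstream)
    if not os.path.exists(path):
        raise PipelineError(
            f"stage {stage!r} needs artifacts from stage {upstream!r}; "
            f"run `volbandit {upstream}` first"
        )
    with open(path) as fh:
        meta = json.load(fh)
    if meta.get("config_hash") != config.config_hash() and not force:
        raise PipelineError(
            f"config hash mismatch between {upstream!r} artifacts and the current "
            "config; re-run upstream stages or pass --force"
        )


def stage_simulate(config: RunConfig, outdir: str) -> dict:
    t0 = time.time()
    os.makedirs(outdir, exist_ok=True)
    cohort_cfg = dataclasses.replace(config.cohort, seed=config.stage_seed("simulate"))
    cohort, dataset = generate_cohort(cohort_cfg, task_config=config.task)
    cohort_path = os.path.join(outdir, "cohort.csv")
    trials_path = os.path.join(outdir, "trials.csv")
    family_path = os.path.join(outdir, "model_family.json")
    cohort_to_csv(cohort, cohort_path)
    dataset.to_csv(trials_path)
    family_to_json(family_path)
    _write_sidecar(outdir, "simulate", config, [cohort_path, trials_path, family_path], t0)
    return {"cohort": cohort_path, "trials": trials_path, "n_participants": len(cohort)}


def _load_dataset(outdir) -> BehaviouralDataset:
    trials_path = os.path.join(outdir, "trials.csv")
    try:
        return BehaviouralDataset.from_csv(trials_path)
    except Exception as exc:  # surface file + reason for corrupted inputs
        raise PipelineError(f"cannot read trials table {trials_path!r}: {exc}") from exc


def stage_fit(config: RunConfig, outdir: str, force: bool = False) -> dict:
    t0 = time.time()
    _require_upstream(outdir, "fit", "simulate", config, force)
    dataset = _load_dataset(outdir)
    seed = config.stage_seed("fit")

    exclusion = participant_null_comparison(
        dataset, default_family(), priors=config.priors,
        n_draws=config.evidence_draws, seed=seed,
    )
    evidence_path = os.path.join(outdir, "participant_evidence.csv")
    exclusion.table.to_csv(evidence_path)

    included = exclusion.included_ids
    fit_dir = os.path.join(outdir, f"posterior_{WINNING_MODEL_ID}")
    sampler = dataclasses.replace(config.sampler, seed=seed + 1)
    fit = fit_hierarchical(
        get_spec(WINNING_MODEL_ID), dataset.subset(included),
        priors=config.priors, sampler_config=sampler,
    )
    fit.save(fit_dir)
    _write_sidecar(outdir, "fit", config, [evidence_path, fit_dir], t0)
    return {"excluded_fraction": exclusion.excluded_fraction, "posterior_dir": fit_dir}


def stage_select(config: RunConfig, outdir: str, force: bool = False) -> dict:
    t0 = time.time()
    _require_upstream(outdir, "select", "fit", config, force)
    dataset = _load_dataset(outdir)
    seed = config.stage_seed("select")
    table = pd.read_csv(os.path.join(outdir, "participant_evidence.csv"), index_col=0)
    included = list(table.index[~table["excluded"]])

    comparison = compare_models_by_participant_evidence(
        dataset, default_family(), included_ids=included,
        priors=config.priors, n_draws=config.evidence_draws, seed=seed,
    )
    comparison_path = os.path.join(outdir, "model_comparison.csv")
    comparison.to_csv(comparison_path)
    summary = {
        "winner": comparison.index[0],
        "excluded_fraction": float(table["excluded"].mean()),
        "config_hash": config.config_hash(),
    }
    with open(os.path.join(outdir, "selection.json"), "w") as fh:
        json.dump(summary, fh, indent=2)
    _write_sidecar(outdir, "select", config, [comparison_path], t0)
    return summary


def stage_stats(config: RunConfig, outdir: str, force: bool = False) -> dict:
    t0 = time.time()
    _require_upstream(outdir, "stats", "fit", config, force)
    cohort = cohort_from_csv(os.path.join(outdir, "cohort.csv"))
    table = pd.read_csv(os.path.join(outdir, "participant_evidence.csv"), index_col=0)
    fit = PosteriorFit.load(os.path.join(outdir, f"posterior_{WINNING_MODEL_ID}"))

    params = fit.posterior_mean_params()
    merged = cohort.set_index("participant_id").join(params, how="left")
    included = merged.loc[~table["excluded"].reindex(merged.index, fill_value=True)]

    results: dict = {}
    mt_tau = included.loc[included["group"] == "MT", "tau"].dropna()
    nmt_tau = included.loc[included["group"] == "NMT", "tau"].dropna()
    results["temperature_ttest"] = two_sample_ttest(nmt_tau, mt_tau).as_dict()
    lr = included[["alpha_stable", "alpha_volatile"]].dropna()
    results["learning_rate_paired_ttest"] = paired_ttest(
        lr["alpha_stable"], lr["alpha_volatile"]
    ).as_dict()

    retained = cohort.groupby("group")["retained"].agg(["sum", "count"])
    obs = [
        [int(retained.loc["MT", "sum"]), int(retained.loc["MT", "count"] - retained.loc["MT", "sum"])],
        [int(retained.loc["NMT", "sum"]), int(retained.loc["NMT", "count"] - retained.loc["NMT", "sum"])],
    ]
    results["retention_chi_square"] = chi_square_2x2(obs).as_dict()
    results["followup_completeness"] = float(cohort["retained"].mean())

    results["power_at_d_0.70"] = power_two_sample_t(
        int((cohort["group"] == "MT").sum()), int((cohort["group"] == "NMT").sum()),
        d=0.70, alpha=config.alpha,
    ).as_dict()
    results["sensitivity_d"] = sensitivity_d(
        int((cohort["group"] == "MT").sum()), int((cohort["group"] == "NMT").sum()),
        alpha=config.alpha, power=0.80,
    ).as_dict()

    reg_frame = included.reset_index()
    predictors = ["sdq_emotional_baseline", "sex", "age", "iq", "pubertal", "tau", "group"]
    reg = hierarchical_regression(
        reg_frame, "sdq_emotional_followup", predictors, interactions=[("group", "tau")]
    )
    results["longitudinal_regression"] = reg.as_dict()
    simple = simple_effects(
        reg_frame, "sdq_emotional_followup",
        ["sdq_emotional_baseline", "sex", "age", "iq", "pubertal", "tau"],
    )
    results["simple_effects"] = {g: r.as_dict() for g, r in simple.items()}
    if config.holm:
        pvals = {
            "temperature": results["temperature_ttest"]["p"],
            "learning_rates": results["learning_rate_paired_ttest"]["p"],
            "interaction": reg.terms.loc["group:tau", "p"],
        }
        results["holm_adjusted_p"] = holm_correction(pvals)

    stats_path = os.path.join(outdir, "stats.json")
    with open(stats_path, "w") as fh:
        json.dump(results, fh, indent=2)
    _write_sidecar(outdir, "stats", config, [stats_path], t0)
    return results


def stage_report(config: RunConfig, outdir: str, force: bool = False) -> str:
    t0 = time.time()
    for upstream in ("simulate", "fit", "select", "stats"):
        _require_upstream(outdir, "report", upstream, config, force)
    with open(os.path.join(outdir, "stats.json")) as fh:
        stats = json.load(fh)
    with open(os.path.join(outdir, "selection.json")) as fh:
        selection = json.load(fh)
    comparison = pd.read_csv(os.path.join(outdir, "model_comparison.csv"), index_col=0)
    cohort = cohort_from_csv(os.path.join(outdir, "cohort.csv"))
    n_trials = config.task.n_trials

    lines = [
        "# Volatile bandit analysis report",
        "",
        f"Config hash: `{config.config_hash()}` | global seed: {config.seed}",
        "",
        "## Task and cohort",
        f"- Trials per participant: {n_trials} "
        f"({config.task.n_stable_trials} stable at {config.task.stable_p:.0%}, "
        f"{config.task.n_volatile_blocks} x {config.task.volatile_block_len} volatile at "
        f"{config.task.volatile_p:.0%})",
        f"- Participants: {len(cohort)} (MT {int((cohort['group'] == 'MT').sum())}, "
        f"NMT {int((cohort['group'] == 'NMT').sum())})",
        "",
        "## Model selection",
        f"- Candidate models: {len(comparison)}",
        f"- Winning model: {selection['winner']} "
        f"({get_spec(selection['winner']).n_free_params} free parameters)",
        f"- Excluded (null-best) fraction: {selection['excluded_fraction']:.2f}",
        "",
        "## Group statistics",
        f"- Temperature t-test (NMT vs MT): t({stats['temperature_ttest']['df']}) = "
        f"{stats['temperature_ttest']['t']:.2f}, p = {stats['temperature_ttest']['p']:.3f}",
        f"- Learning rates stable vs volatile: t({stats['learning_rate_paired_ttest']['df']}) = "
        f"{stats['learning_rate_paired_ttest']['t']:.2f}, "
        f"p = {stats['learning_rate_paired_ttest']['p']:.3f}",
        f"- Retention chi-square: X2(1) = {stats['retention_chi_square']['chi2']:.2f}, "
        f"p = {stats['retention_chi_square']['p']:.3f}",
        f"- Follow-up completeness: {stats['followup_completeness']:.0%}",
        f"- Power at d = 0.70: {stats['power_at_d_0.70']['power']:.3f}; "
        f"sensitivity d at 80% power: {stats['sensitivity_d']['d']:.3f}",
        "",
        "## Longitudinal moderation",
        f"- Group x temperature interaction beta = "
        f"{stats['longitudinal_regression']['terms']['group:tau']['beta']:.2f}, "
        f"p = {stats['longitudinal_regression']['terms']['group:tau']['p']:.3g}",
        "",
    ]
    report_path = os.path.join(outdir, "report.md")
    with open(report_path, "w") as fh:
        fh.write("\n".join(lines))
    _write_sidecar(outdir, "report", config, [report_path], t0)
    return report_path


def run_stage(stage: str, config: RunConfig, outdir: str, force: bool = False):
    if stage == "simulate":
        return stage_simulate(config, outdir)
    if stage == "fit":
        return stage_fit(config, outdir, force)
    if stage == "select":
        return stage_select(config, outdir, force)
    if stage == "stats":
        return stage_stats(config, outdir, force)
    if stage == "report":
        return stage_report(config, outdir, force)
    raise PipelineError(f"unknown stage {stage!r}; choose from {STAGES}")


def reproduce(config: RunConfig, outdir: str, force: bool = False) -> str:
    """Run every stage in order and return the report path."""
    for stage in STAGES:
        run_stage(stage, config, outdir, force=force)
    return os.path.join(outdir, "report.md")
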