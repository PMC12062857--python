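import numpy as np
import pandas as pd
import pytest

from volbandit.agents import (
    BehaviouralDataset,
    ChoiceRecord,
    CohortConfig,
    cohort_from_csv,
    cohort_to_csv,
    generate_cohort,
    generate_followup_symptoms,
    simulate_agent,
)
from volbandit.models import AgentParams, get_spec
from volbandit.stats import hierarchical_regression, two_sample_ttest
from volbandit.task import TaskConfig, TaskSchedule, TrialRecord, generate_schedule


class TestSimulateAgent:
    def test_outcomes_consistent_with_schedule(self, default_schedule, winner_spec):
        recs = simulate_agent(AgentParams(tau=0.4), winner_spec, default_schedule, seed=1)
        for rec, trial in zip(recs, default_schedule.trials):
            assert rec.outcome == int(rec.chosen == trial.rewarded_option)
            mag = trial.magnitude_A if rec.chosen == "A" else trial.magnitude_B
            assert rec.coins_won == rec.outcome * mag

    def test_same_seed_reproducible(self, default_schedule, winner_spec):
        a = simulate_agent(AgentParams(), winner_spec, default_schedule, seed=9)
        b = simulate_agent(AgentParams(), winner_spec, default_schedule, seed=9)
        assert a == b

    def test_magnitude_model_on_plain_schedule_rejected(self, plain_schedule):
        with pytest.raises(ValueError, match="magnitude"):
            simulate_agent(AgentParams(), get_spec("M07"), plain_schedule, seed=0)

    def test_choice_frequencies_match_analytic_probabilities(self):
        """On a 2-trial schedule the trial-1 choice frequency must converge to
        the analytic P(A); hand-computed for a biased null model."""
        sched = TaskSchedule(
            config=TaskConfig(magnitude_rule="none"),
            trials=(
                TrialRecord(1, "stable", 0, "A", "A"),
                TrialRecord(2, "stable", 0, "A", "A"),
            ),
        )
        spec = get_spec("M02")
        params = AgentParams(bias=0.7)
        n = 4000
        first_a = sum(
            simulate_agent(params, spec, sched, seed=s)[0].chosen == "A"
            for s in range(n)
        )
        # binomial SE at p=0.7, n=4000 is ~0.0072; allow 4 SE
        assert abs(first_a / n - 0.7) < 4 * np.sqrt(0.7 * 0.3 / n)

    def test_rw_agent_learns_the_better_option(self, default_schedule, winner_spec):
        """A deterministic-ish learner should pick the stable high option
        on well over half of late stable trials."""
        params = AgentParams(tau=0.1, alpha_stable=0.35, alpha_volatile=0.41)
        recs = simulate_agent(params, winner_spec, default_schedule, seed=2)
        stable_late = [
            rec for rec, t in zip(recs, default_schedule.trials)
            if t.phase == "stable" and t.trial_index > 20
        ]
        frac_high = np.mean([r.chosen == "A" for r in stable_late])
        assert frac_high > 0.7


class TestBehaviouralDataset:
    def test_round_trip_frame(self, small_cohort):
        _, dataset = small_cohort
        frame = dataset.to_frame()
        back = BehaviouralDataset.from_frame(frame)
        assert back.participant_ids == dataset.participant_ids
        pid = dataset.participant_ids[0]
        assert back.choices(pid) == dataset.choices(pid)
        assert back.schedule(pid).trials == dataset.schedule(pid).trials

    def test_duplicate_participant_rejected(self, default_schedule, winner_spec):
        ds = BehaviouralDataset()
        recs = simulate_agent(AgentParams(), winner_spec, default_schedule, seed=0)
        ds.add("p1", default_schedule, recs)
        with pytest.raises(ValueError, match="duplicate"):
            ds.add("p1", default_schedule, recs)

    def test_length_mismatch_rejected(self, default_schedule, winner_spec):
        ds = BehaviouralDataset()
        recs = simulate_agent(AgentParams(), winner_spec, default_schedule, seed=0)
        with pytest.raises(ValueError, match="choice records"):
            ds.add("p1", default_schedule, recs[:-1])

    def test_subset(self, small_cohort):
        _, dataset = small_cohort
        keep = dataset.participant_ids[:3]
        sub = dataset.subset(keep)
        assert sub.participant_ids == keep


class TestCohortGeneration:
    def test_group_sizes_and_ids(self):
        cohort, dataset = generate_cohort(CohortConfig(seed=4))
        assert len(cohort) == 69
        assert (cohort["group"] == "MT").sum() == 37
        assert (cohort["group"] == "NMT").sum() == 32
        assert len(dataset) == 69
        assert cohort["participant_id"].is_unique

    def test_random_responder_counts_exact(self):
        cohort, _ = generate_cohort(CohortConfig(seed=4), simulate_behaviour=False)
        by_group = cohort.groupby("group")["responder_type"].apply(
            lambda s: (s == "random").sum()
        )
        assert by_group["MT"] == round(0.35 * 37)
        assert by_group["NMT"] == round(0.35 * 32)

    def test_counterbalancing_alternates_within_group(self):
        cohort, _ = generate_cohort(CohortConfig(seed=4), simulate_behaviour=False)
        for group, sub in cohort.groupby("group"):
            orders = sub["order"].tolist()
            assert orders[0] == "stable_first"
            assert all(a != b for a, b in zip(orders, orders[1:]))

    def test_temperature_shift_between_groups(self):
        cfg = CohortConfig(n_mt=200, n_nmt=200, seed=8)
        cohort, _ = generate_cohort(cfg, simulate_behaviour=False)
        mt = cohort.loc[cohort["group"] == "MT", "true_tau"]
        nmt = cohort.loc[cohort["group"] == "NMT", "true_tau"]
        shift = nmt.mean() - mt.mean()
        assert shift == pytest.approx(0.70 * cfg.tau_pooled_sd, abs=0.05)

    def test_covariates_matched_between_groups(self):
        """Covariates come from shared distributions: at large n the group
        difference must be within sampling error."""
        cohort, _ = generate_cohort(
            CohortConfig(n_mt=300, n_nmt=300, seed=12), simulate_behaviour=False
        )
        for col in ("age", "iq", "pubertal", "ses"):
            mt = cohort.loc[cohort["group"] == "MT", col]
            nmt = cohort.loc[cohort["group"] == "NMT", col]
            res = two_sample_ttest(mt, nmt)
            assert abs(res.cohen_d) < 0.30

    def test_followup_missing_iff_not_retained(self):
        cohort, _ = generate_cohort(CohortConfig(seed=4), simulate_behaviour=False)
        assert cohort.loc[~cohort["retained"], "sdq_emotional_followup"].isna().all()
        assert cohort.loc[cohort["retained"], "sdq_emotional_followup"].notna().all()

    def test_retained_counts_near_expectation(self):
        """Expected retention is 27/37 (MT) and 29/32 (NMT)."""
        sums = np.zeros(2)
        reps = 40
        for seed in range(reps):
            cohort, _ = generate_cohort(CohortConfig(seed=300 + seed), simulate_behaviour=False)
            by = cohort.groupby("group")["retained"].sum()
            sums += [by["MT"], by["NMT"]]
        means = sums / reps
        assert means[0] == pytest.approx(27.0, abs=1.5)
        assert means[1] == pytest.approx(29.0, abs=1.0)

    def test_random_responders_choose_at_chance(self):
        cohort, dataset = generate_cohort(CohortConfig(seed=4))
        rand_ids = cohort.loc[cohort["responder_type"] == "random", "participant_id"]
        fracs = [
            np.mean([c.chosen == "A" for c in dataset.choices(pid)]) for pid in rand_ids
        ]
        # each is Binomial(120, 0.5)/120; the pooled mean should be very close to 0.5
        assert abs(np.mean(fracs) - 0.5) < 0.05

    def test_odd_group_size_warns(self):
        with pytest.warns(UserWarning, match="counterbalancing"):
            generate_cohort(CohortConfig(n_mt=5, n_nmt=4, seed=0), simulate_behaviour=False)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(random_responder_fraction=1.2)
        with pytest.raises(ValueError):
            CohortConfig(tau_pooled_sd=0.0)

    def test_cohort_csv_round_trip(self, tmp_path):
        cohort, _ = generate_cohort(CohortConfig(seed=4), simulate_behaviour=False)
        path = tmp_path / "cohort.csv"
        cohort_to_csv(cohort, path)
        back = cohort_from_csv(path)
        assert list(back.columns) == list(cohort.columns)
        pd.testing.assert_frame_equal(
            back, cohort.reset_index(drop=True), check_exact=False, rtol=1e-12
        )

    def test_cohort_csv_missing_column_rejected(self, tmp_path):
        cohort, _ = generate_cohort(CohortConfig(seed=4), simulate_behaviour=False)
        path = tmp_path / "cohort.csv"
        cohort_to_csv(cohort.drop(columns=["true_tau"]), path)
        with pytest.raises(ValueError, match="true_tau"):
            cohort_from_csv(path)


class TestFollowupGenerator:
    def test_noiseless_regression_recovers_coefficients(self):
        """With noise SD ~ 0 the moderation regression must recover the
        generating standardized coefficients almost exactly."""
        cfg = CohortConfig(
            n_mt=150, n_nmt=150, symptom_noise_sd=1e-8,
            retention_p_mt=1.0, retention_p_nmt=1.0, seed=31,
        )
        cohort, _ = generate_cohort(cfg, simulate_behaviour=False)
        frame = cohort.rename(columns={"true_tau": "tau"})
        res = hierarchical_regression(
            frame, "sdq_emotional_followup",
            ["sdq_emotional_baseline", "tau", "group"],
            interactions=[("group", "tau")],
        )
        # the generator scales the outcome to near-unit variance, so the
        # recovered standardized interaction is commensurate with the weight
        assert res.beta("group:tau") == pytest.approx(cfg.beta_interaction, abs=0.1)
        assert np.sign(res.beta("group")) == np.sign(cfg.beta_group)

    def test_zero_interaction_case(self):
        cfg = CohortConfig(
            n_mt=150, n_nmt=150, beta_interaction=0.0,
            retention_p_mt=1.0, retention_p_nmt=1.0, seed=32,
        )
        cohort, _ = generate_cohort(cfg, simulate_behaviour=False)
        frame = cohort.rename(columns={"true_tau": "tau"})
        res = hierarchical_regression(
            frame, "sdq_emotional_followup",
            ["sdq_emotional_baseline", "tau", "group"],
            interactions=[("group", "tau")],
        )
        assert abs(res.beta("group:tau")) < 0.15
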