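import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from volbandit.stats import (
    chi_square_2x2,
    hierarchical_regression,
    holm_correction,
    mann_whitney_u,
    paired_ttest,
    power_two_sample_t,
    sensitivity_d,
    simple_effects,
    two_sample_ttest,
)


class TestTTests:
    def test_matches_scipy_pooled(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(0, 1, 24), rng.normal(0.5, 1, 22)
        res = two_sample_ttest(x, y)
        ref = sps.ttest_ind(x, y, equal_var=True)
        assert res.t == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-12)
        assert res.df == 44  # 24 + 22 - 2

    def test_hand_computed_toy(self):
        # (1,2,3) vs (2,3,4): pooled sd = 1, diff = -1, t = -1 / sqrt(2/3)
        res = two_sample_ttest([1, 2, 3], [2, 3, 4])
        assert res.t == pytest.approx(-1 / math.sqrt(2 / 3), abs=1e-12)
        assert res.cohen_d == pytest.approx(-1.0, abs=1e-12)

    def test_identical_samples_zero_t(self):
        res = two_sample_ttest([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.t == 0
        assert res.p == pytest.approx(1.0, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            two_sample_ttest([1, 1, 1], [1, 1, 1])

    def test_paired_matches_one_sample_on_differences(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(0, 1, 46), rng.normal(0.2, 1, 46)
        res = paired_ttest(x, y)
        ref = sps.ttest_1samp(x - y, 0.0)
        assert res.t == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-12)
        assert res.df == 45

    def test_paired_validation(self):
        with pytest.raises(ValueError):
            paired_ttest([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            paired_ttest([1, 2, 3], [1, 2, 3])  # zero-variance differences


class TestChiSquare:
    def test_matches_explicit_formula_fuzz(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            obs = rng.integers(1, 60, size=(2, 2)).astype(float)
            res = chi_square_2x2(obs)
            row = obs.sum(axis=1, keepdims=True)
            col = obs.sum(axis=0, keepdims=True)
            exp = row @ col / obs.sum()
            chi2 = ((obs - exp) ** 2 / exp).sum()
            assert res.chi2 == pytest.approx(chi2, abs=1e-10)
            assert res.df == 1

    def test_input_validation(self):
        with pytest.raises(ValueError):
            chi_square_2x2([[1, 2, 3], [4, 5, 6]])
        with pytest.raises(ValueError):
            chi_square_2x2([[0, 0], [3, 4]])
        with pytest.raises(ValueError):
            chi_square_2x2([[-1, 2], [3, 4]])


class TestMannWhitney:
    def test_exact_4v4_matches_full_enumeration(self):
        """Independent brute force: enumerate all C(8,4) subset assignments of
        the observed ranks and count deviations at least as extreme."""
        x = [1.2, 3.4, 2.2, 5.0]
        y = [0.5, 2.9, 2.2, 4.1]  # includes a tie across groups
        res = mann_whitney_u(x, y)
        assert res.method == "exact"

        ranks = sps.rankdata(np.concatenate([x, y]))
        n1 = 4
        mu = 4 * 4 / 2
        u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
        dev = abs(u_obs - mu)
        count = sum(
            abs(ranks[list(sub)].sum() - n1 * (n1 + 1) / 2 - mu) >= dev - 1e-12
            for sub in combinations(range(8), 4)
        )
        assert res.u == pytest.approx(u_obs, abs=1e-12)
        assert res.p == pytest.approx(count / math.comb(8, 4), abs=1e-12)

    def test_exact_no_ties_matches_scipy_exact(self):
        x = [3.1, 7.2, 1.4, 9.9, 5.5]
        y = [2.2, 6.1, 8.8, 0.7]
        res = mann_whitney_u(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert res.u == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_large_samples_use_asymptotic(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, 20), rng.normal(0.4, 1, 18)
        res = mann_whitney_u(x, y)
        assert res.method == "asymptotic"
        ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic", use_continuity=False)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestPower:
    def test_monotone_in_d_and_n(self):
        ds = [0.2, 0.4, 0.6, 0.8, 1.0]
        powers = [power_two_sample_t(37, 32, d).power for d in ds]
        assert all(a < b for a, b in zip(powers, powers[1:]))
        ns = [10, 20, 40, 80]
        powers_n = [power_two_sample_t(n, n, 0.5).power for n in ns]
        assert all(a < b for a, b in zip(powers_n, powers_n[1:]))

    def test_sensitivity_round_trips(self):
        sens = sensitivity_d(37, 32, alpha=0.05, power=0.80)
        back = power_two_sample_t(37, 32, sens.d, alpha=0.05)
        assert back.power == pytest.approx(0.80, abs=1e-4)

    def test_power_at_zero_effect_equals_alpha(self):
        res = power_two_sample_t(30, 30, 0.0, alpha=0.05)
        assert res.power == pytest.approx(0.05, abs=1e-9)

    def test_monte_carlo_cross_check(self):
        """Vectorised simulation of 40k two-sample t-tests at d = 0.7."""
        n1, n2, d, alpha = 37, 32, 0.7, 0.05
        rng = np.random.default_rng(6)
        reps = 40_000
        x = rng.normal(d, 1.0, size=(reps, n1))
        y = rng.normal(0.0, 1.0, size=(reps, n2))
        sp2 = ((n1 - 1) * x.var(axis=1, ddof=1) + (n2 - 1) * y.var(axis=1, ddof=1)) / (n1 + n2 - 2)
        t = (x.mean(axis=1) - y.mean(axis=1)) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        crit = sps.t.ppf(1 - alpha / 2, n1 + n2 - 2)
        mc_power = float((np.abs(t) > crit).mean())
        assert power_two_sample_t(n1, n2, d, alpha).power == pytest.approx(mc_power, abs=0.01)

    def test_validation(self):
        with pytest.raises(ValueError):
            power_two_sample_t(1, 30, 0.5)
        with pytest.raises(ValueError):
            power_two_sample_t(30, 30, -0.1)
        with pytest.raises(ValueError):
            sensitivity_d(30, 30, power=0.04, alpha=0.05)


def _synthetic_regression_frame(n=400, beta_int=-0.5, noise=0.2, seed=0):
    rng = np.random.default_rng(seed)
    group = np.where(rng.random(n) < 0.5, "MT", "NMT")
    g = np.where(group == "MT", -1.0, 1.0)
    tau = rng.normal(0, 1, n)
    base = rng.normal(0, 1, n)
    y = 0.3 * base + 0.2 * g - 0.1 * tau + beta_int * g * tau + rng.normal(0, noise, n)
    return pd.DataFrame({"group": group, "tau": tau, "baseline": base, "y": y})


class TestRegression:
    def test_recovers_standardized_interaction(self):
        frame = _synthetic_regression_frame(beta_int=-0.5, noise=0.05, seed=4)
        res = hierarchical_regression(frame, "y", ["baseline", "tau", "group"],
                                      interactions=[("group", "tau")])
        sd_y = frame["y"].std(ddof=1)
        assert res.beta("group:tau") == pytest.approx(-0.5 / sd_y, abs=0.03)

    def test_effect_coding_is_mt_minus_one(self):
        """Flipping which rows are MT must flip the sign of the group beta."""
        frame = _synthetic_regression_frame(beta_int=0.0, noise=0.05, seed=5)
        res = hierarchical_regression(frame, "y", ["group"])
        flipped = frame.assign(group=np.where(frame["group"] == "MT", "NMT", "MT"))
        res_f = hierarchical_regression(flipped, "y", ["group"])
        assert res.beta("group") == pytest.approx(-res_f.beta("group"), abs=1e-10)

    def test_part_r_identity(self):
        frame = _synthetic_regression_frame(seed=6)
        res = hierarchical_regression(frame, "y", ["baseline", "tau", "group"],
                                      interactions=[("group", "tau")])
        for term in res.terms.index:
            expected = res.terms.loc[term, "t"] * math.sqrt(1 - res.r_squared) / math.sqrt(res.df_resid)
            assert res.terms.loc[term, "part_r"] == pytest.approx(expected, abs=1e-12)

    def test_listwise_deletion(self):
        frame = _synthetic_regression_frame(seed=7)
        frame.loc[:9, "y"] = np.nan
        res = hierarchical_regression(frame, "y", ["baseline", "tau"])
        assert res.n == len(frame) - 10

    def test_rank_deficiency_reported(self):
        frame = _synthetic_regression_frame(seed=8)
        frame["tau_copy"] = frame["tau"]
        with pytest.raises(ValueError, match="rank deficient"):
            hierarchical_regression(frame, "y", ["tau", "tau_copy"])

    def test_constant_column_rejected(self):
        frame = _synthetic_regression_frame(seed=9)
        frame["flat"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            hierarchical_regression(frame, "y", ["flat"])

    def test_too_few_cases_rejected(self):
        frame = _synthetic_regression_frame(seed=10).head(3)
        with pytest.raises(ValueError, match="complete cases"):
            hierarchical_regression(frame, "y", ["baseline", "tau", "group"])

    def test_simple_effects_recover_group_slopes(self):
        """Generated slopes: MT slope = -0.1 - beta_int, NMT = -0.1 + beta_int."""
        frame = _synthetic_regression_frame(n=2000, beta_int=-0.4, noise=0.05, seed=11)
        effects = simple_effects(frame, "y", ["baseline", "tau"])
        assert set(effects) == {"MT", "NMT"}
        # within-group standardized slope signs follow the generated slopes
        assert effects["MT"].beta("tau") > 0   # -0.1 + 0.4 = +0.3
        assert effects["NMT"].beta("tau") < 0  # -0.1 - 0.4 = -0.5

    def test_simple_effects_homogeneous_case(self):
        frame = _synthetic_regression_frame(n=3000, beta_int=0.0, noise=0.05, seed=12)
        effects = simple_effects(frame, "y", ["baseline", "tau"])
        assert effects["MT"].beta("tau") == pytest.approx(effects["NMT"].beta("tau"), abs=0.05)


class TestHolm:
    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        pvals = {"a": 0.01, "b": 0.04, "c": 0.03, "d": 0.20}
        adj = holm_correction(pvals)
        names = list(pvals)
        _, ref, _, _ = multipletests([pvals[n] for n in names], method="holm")
        for n, r in zip(names, ref):
            assert adj[n] == pytest.approx(r, abs=1e-12)

    def test_monotone_and_capped(self):
        adj = holm_correction({"a": 0.5, "b": 0.9})
        assert max(adj.values()) <= 1.0
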