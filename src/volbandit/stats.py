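"""Group-difference, retention, power and longitudinal moderation statistics.

Conventions match the reporting style of the study design this package
reproduces: pooled-variance Student t-tests (the printed degrees of
freedom follow the pooled form), Pearson chi-square without continuity
correction, noncentral-t power calculations, and OLS moderation
regressions on standardized predictors with effect-coded group
(MT = -1, NMT = +1), reporting standardized betas and part (semipartial)
correlations signed by the coefficient:

    sr_j = t_j * sqrt(1 - R^2) / sqrt(df_resid)
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, sqrt

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "TTestResult",
    "ChiSquareResult",
    "MannWhitneyResult",
    "PowerResult",
    "RegressionResult",
    "two_sample_ttest",
    "paired_ttest",
    "chi_square_2x2",
    "mann_whitney_u",
    "power_two_sample_t",
    "sensitivity_d",
    "hierarchical_regression",
    "simple_effects",
    "holm_correction",
]


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    mean_difference: float
    cohen_d: float

    def as_dict(self) -> dict:
        return {"t": self.t, "df": self.df, "p": self.p,
                "mean_difference": self.mean_difference, "cohen_d": self.cohen_d}


def two_sample_ttest(x, y) -> TTestResult:
    """Pooled-variance Student t-test (two-tailed) with Cohen's d."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("both samples need n >= 2")
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0:
        raise ValueError("zero pooled variance; t statistic undefined")
    diff = x.mean() - y.mean()
    t = diff / sqrt(sp2 * (1 / n1 + 1 / n2))
    df = n1 + n2 - 2
    p = 2 * sps.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=df, p=float(p),
                       mean_difference=float(diff), cohen_d=float(diff / sqrt(sp2)))


def paired_ttest(x, y) -> TTestResult:
    """Paired t-test on the differences x - y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired samples must have equal length")
    if len(x) < 2:
        raise ValueError("need >= 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance of differences; t statistic undefined")
    t = d.mean() / (sd / sqrt(len(d)))
    df = len(d) - 1
    p = 2 * sps.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=df, p=float(p),
                       mean_difference=float(d.mean()), cohen_d=float(d.mean() / sd))


@dataclass(frozen=True)
class ChiSquareResult:
    chi2: float
    df: int
    p: float
    observed: np.ndarray
    expected: np.ndarray

    def as_dict(self) -> dict:
        return {"chi2": self.chi2, "df": self.df, "p": self.p,
                "observed": self.observed.tolist(), "expected": self.expected.tolist()}


def chi_square_2x2(table) -> ChiSquareResult:
    """Pearson chi-square on a 2x2 table, no continuity correction."""
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (obs < 0).any():
        raise ValueError("negative cell count")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("zero margin; chi-square undefined")
    chi2, p, df, expected = sps.chi2_contingency(obs, correction=False)
    return ChiSquareResult(chi2=float(chi2), df=int(df), p=float(p),
                           observed=obs, expected=expected)


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    p: float
    method: str  # "exact" or "asymptotic"

    def as_dict(self) -> dict:
        return {"u": self.u, "p": self.p, "method": self.method}


def mann_whitney_u(x, y) -> MannWhitneyResult:
    """Mann-Whitney U (U for the first sample), two-tailed.

    Combined n <= 12 uses exact enumeration over all rank assignments
    (midranks under ties); larger samples use the tie-corrected normal
    approximation without continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)

    if n1 + n2 <= 12:
        mu = n1 * n2 / 2
        dev_obs = abs(u_obs - mu)
        count = 0
        total = comb(n1 + n2, n1)
        for subset in combinations(range(n1 + n2), n1):
            u = ranks[list(subset)].sum() - n1 * (n1 + 1) / 2
            if abs(u - mu) >= dev_obs - 1e-12:
                count += 1
        return MannWhitneyResult(u=u_obs, p=count / total, method="exact")

    res = sps.mannwhitneyu(x, y, alternative="two-sided",
                           method="asymptotic", use_continuity=False)
    return MannWhitneyResult(u=float(res.statistic), p=float(res.pvalue), method="asymptotic")


@dataclass(frozen=True)
class PowerResult:
    n1: int
    n2: int
    alpha: float
    d: float
    power: float
    mode: str  # "power_at_d" or "sensitivity_d"

    def as_dict(self) -> dict:
        return {"n1": self.n1, "n2": self.n2, "alpha": self.alpha,
                "d": self.d, "power": self.power, "mode": self.mode}


def _power(n1: int, n2: int, d: float, alpha: float) -> float:
    df = n1 + n2 - 2
    ncp = d * sqrt(n1 * n2 / (n1 + n2))
    tcrit = sps.t.ppf(1 - alpha / 2, df)
    power = float(sps.nct.sf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp))
    if np.isnan(power):
        # scipy's noncentral t underflows at extreme noncentrality, where the
        # rejection probability is 1 to double precision
        return 1.0
    return power


def power_two_sample_t(n1: int, n2: int, d: float, alpha: float = 0.05) -> PowerResult:
    """Power of a two-tailed two-sample t-test at standardized effect d."""
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be >= 2")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if d < 0:
        raise ValueError("d must be >= 0")
    return PowerResult(n1=n1, n2=n2, alpha=alpha, d=d,
                       power=_power(n1, n2, d, alpha), mode="power_at_d")


def sensitivity_d(n1: int, n2: int, alpha: float = 0.05, power: float = 0.80) -> PowerResult:
    """Smallest detectable standardized effect at the requested power."""
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must lie in (0, 1)")
    if power <= alpha:
        raise ValueError("requested power must exceed alpha")
    from scipy.optimize import brentq

    hi = 10.0
    if _power(n1, n2, hi, alpha) < power:
        raise ValueError("requested power unattainable at these sample sizes")
    d = brentq(lambda dd: _power(n1, n2, dd, alpha) - power, 0.0, hi, xtol=1e-6)
    return PowerResult(n1=n1, n2=n2, alpha=alpha, d=float(d),
                       power=power, mode="sensitivity_d")


@dataclass(frozen=True)
class RegressionResult:
    """OLS moderation model: standardized betas, part correlations, fit stats."""

    terms: pd.DataFrame   # index: term; columns: beta, t, p, part_r
    df_resid: int
    r_squared: float
    f_stat: float
    f_df: tuple[int, int]
    f_p: float
    n: int

    def beta(self, term: str) -> float:
        return float(self.terms.loc[term, "beta"])

    def as_dict(self) -> dict:
        return {
            "terms": self.terms.to_dict(orient="index"),
            "df_resid": self.df_resid, "r_squared": self.r_squared,
            "f_stat": self.f_stat, "f_df": list(self.f_df), "f_p": self.f_p,
            "n": self.n,
        }


def _code_column(frame: pd.DataFrame, col: str) -> np.ndarray:
    """Standardize a numeric column or effect-code a two-level one.

    Group labels MT/NMT get the fixed coding MT = -1, NMT = +1; other
    two-level columns are coded ±1 by sorted level order; numeric columns
    are z-scored.
    """
    s = frame[col]
    if s.dtype == object or s.dtype.name in ("category", "bool"):
        levels = sorted(s.unique())
        if levels == ["MT", "NMT"]:
            return np.where(s == "MT", -1.0, 1.0)
        if len(levels) != 2:
            raise ValueError(f"column {col!r} has {len(levels)} levels; expected 2")
        return np.where(s == levels[0], -1.0, 1.0)
    x = s.to_numpy(dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError(f"column {col!r} is constant")
    return (x - x.mean()) / sd


def hierarchical_regression(
    cohort: pd.DataFrame,
    outcome: str,
    predictors: list[str],
    interactions: list[tuple[str, str]] | None = None,
) -> RegressionResult:
    """OLS on standardized predictors with effect-coded categoricals.

    ``interactions`` lists (a, b) pairs whose coded product enters as
    ``a:b``. Complete cases only (listwise deletion). The outcome is
    z-scored, so the reported coefficients are standardized betas. Part
    correlations carry the coefficient's sign.
    """
    interactions = interactions or []
    used = [outcome, *predictors, *{c for pair in interactions for c in pair}]
    data = cohort[list(dict.fromkeys(used))].dropna()
    n = len(data)
    n_terms = len(predictors) + len(interactions)
    if n < n_terms + 2:
        raise ValueError(f"only {n} complete cases for {n_terms} terms")

    cols: dict[str, np.ndarray] = {}
    for col in predictors:
        cols[col] = _code_column(data, col)
    for a, b in interactions:
        xa = cols.get(a)
        xa = xa if xa is not None else _code_column(data, a)
        xb = cols.get(b)
        xb = xb if xb is not None else _code_column(data, b)
        cols[f"{a}:{b}"] = xa * xb
    y = _code_column(data, outcome)

    X = pd.DataFrame(cols, index=data.index)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = corr.stack().idxmax()
        raise ValueError(f"design matrix is rank deficient; near-collinear terms: {worst}")

    model = sm.OLS(y, sm.add_constant(X)).fit()
    r2 = float(model.rsquared)
    df_resid = int(model.df_resid)
    terms = pd.DataFrame(
        {
            "beta": model.params.drop("const"),
            "t": model.tvalues.drop("const"),
            "p": model.pvalues.drop("const"),
        }
    )
    terms["part_r"] = terms["t"] * sqrt(max(1.0 - r2, 0.0)) / sqrt(df_resid)
    return RegressionResult(
        terms=terms,
        df_resid=df_resid,
        r_squared=r2,
        f_stat=float(model.fvalue),
        f_df=(int(model.df_model), df_resid),
        f_p=float(model.f_pvalue),
        n=n,
    )


def simple_effects(
    cohort: pd.DataFrame,
    outcome: str,
    predictors: list[str],
    group_col: str = "group",
) -> dict[str, RegressionResult]:
    """Within-group regressions with the shared covariates minus group terms."""
    out: dict[str, RegressionResult] = {}
    for level, sub in cohort.groupby(group_col):
        if len(sub) == 0:
            raise ValueError(f"group {level!r} is empty")
        out[str(level)] = hierarchical_regression(sub, outcome, predictors)
    return out


def holm_correction(pvalues: dict[str, float]) -> dict[str, float]:
    """Holm step-down adjusted p-values (off by default in the pipeline)."""
    items = sorted(pvalues.items(), key=lambda kv: kv[1])
    m = len(items)
    adjusted: dict[str, float] = {}
    running = 0.0
    for i, (name, p) in enumerate(items):
        running = max(running, (m - i) * p)
        adjusted[name] = min(1.0, running)
    return adjusted
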