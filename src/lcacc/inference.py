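"""Nonparametric test and resampling layer shared by all analyses.

Thin, uniformly shaped wrappers around scipy.stats (Wilcoxon signed-rank,
Mann-Whitney/rank-sum, two-sample Kolmogorov-Smirnov, one-way ANOVA) and
statsmodels (two-factor ANOVA), plus a seeded percentile bootstrap for
median confidence intervals.  Small-sample tests are exact; larger samples
use the usual normal approximations with tie correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "BootCi",
    "TestResult",
    "anova_oneway",
    "anova_twofactor",
    "bootstrap_median_ci",
    "ks_test",
    "ranksum_test",
    "signrank_test",
]

EXACT_N_MAX = 25


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n: tuple[int, ...]
    method: str
    two_sided: bool = True


@dataclass
class BootCi:
    estimate: float
    lower: float
    upper: float
    n_boot: int
    alpha: float
    seed: int | None

    def covers(self, value: float) -> bool:
        return self.lower <= value <= self.upper


def bootstrap_median_ci(
    values: np.ndarray,
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> BootCi:
    """Percentile bootstrap CI for the median (resampling with replacement)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("need at least 2 finite values")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, v.size, size=(n_boot, v.size))
    medians = np.median(v[idx], axis=1)
    lower, upper = np.percentile(medians, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return BootCi(
        estimate=float(np.median(v)),
        lower=float(lower),
        upper=float(upper),
        n_boot=n_boot,
        alpha=alpha,
        seed=None if isinstance(seed, np.random.Generator) else int(seed),
    )


def signrank_test(differences: np.ndarray) -> TestResult:
    """Two-sided Wilcoxon signed-rank test for median difference = 0.

    Exact for n <= 25 without ties/zeros, normal approximation otherwise.
    """
    d = np.asarray(differences, dtype=float)
    d = d[np.isfinite(d)]
    nonzero = d[d != 0]
    if nonzero.size == 0:
        raise ValueError("all differences are zero")
    ranks_tied = np.unique(np.abs(nonzero)).size < nonzero.size
    exact = nonzero.size <= EXACT_N_MAX and nonzero.size == d.size and not ranks_tied
    stat, p = sps.wilcoxon(d, method="exact" if exact else "approx")
    return TestResult(
        statistic=float(stat),
        p_value=float(p),
        n=(int(d.size),),
        method="wilcoxon-signrank-" + ("exact" if exact else "approx"),
    )


def ranksum_test(a: np.ndarray, b: np.ndarray) -> TestResult:
    """Two-sided Mann-Whitney U / Wilcoxon rank-sum test.

    Exact for small tie-free samples, tie-corrected normal approximation
    otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    exact = max(a.size, b.size) <= EXACT_N_MAX and not has_ties
    stat, p = sps.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return TestResult(
        statistic=float(stat),
        p_value=float(p),
        n=(int(a.size), int(b.size)),
        method="mann-whitney-" + ("exact" if exact else "asymptotic"),
    )


def ks_test(a: np.ndarray, b: np.ndarray) -> TestResult:
    """Two-sample, two-sided Kolmogorov-Smirnov test."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")
    stat, p = sps.ks_2samp(a, b)
    return TestResult(
        statistic=float(stat),
        p_value=float(p),
        n=(int(a.size), int(b.size)),
        method="ks-2samp",
    )


def anova_oneway(*groups: np.ndarray) -> TestResult:
    """One-way fixed-effects ANOVA (F test)."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    clean = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size < 2 for g in clean):
        raise ValueError("each group needs at least 2 values")
    stat, p = sps.f_oneway(*clean)
    return TestResult(
        statistic=float(stat),
        p_value=float(p),
        n=tuple(int(g.size) for g in clean),
        method="anova-oneway",
    )


def anova_twofactor(
    values: np.ndarray,
    factor_a: np.ndarray,
    factor_b: np.ndarray,
) -> dict[str, TestResult]:
    """Two-factor fixed-effects ANOVA with interaction.

    Returns results keyed ``"a"``, ``"b"``, ``"a:b"``.  Used for designs
    with a trial-group factor and a pupil-measure (or bin-size) factor.
    """
    import pandas as pd
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = pd.DataFrame(
        {
            "y": np.asarray(values, dtype=float),
            "fa": np.asarray(factor_a).astype(str),
            "fb": np.asarray(factor_b).astype(str),
        }
    ).dropna()
    model = ols("y ~ C(fa) * C(fb)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    out = {}
    for key, row_name in (("a", "C(fa)"), ("b", "C(fb)"), ("a:b", "C(fa):C(fb)")):
        out[key] = TestResult(
            statistic=float(table.loc[row_name, "F"]),
            p_value=float(table.loc[row_name, "PR(>F)"]),
            n=(int(len(df)),),
            method="anova-twofactor",
        )
    return out
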