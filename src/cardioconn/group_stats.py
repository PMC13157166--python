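"""Cohort-table statistics: group comparisons, categorical tests, Spearman
matrices, BH-FDR, IQR outlier screening, and the within-mask post-hoc
group comparison.

Conventions (all configurable):

* continuous metrics: Shapiro-Wilk normality per group at alpha = 0.05
  decides between an independent-samples t-test and a Mann-Whitney U;
* categorical 2x2 tables: Pearson chi-square (df 1, no continuity
  correction) or Fisher's exact test.  The Fisher default is the
  one-sided upper hypergeometric tail P(X >= observed); the
  probability-ordering two-sided convention is also exposed;
* multiple testing: Benjamini-Hochberg step-up across the declared
  family, values capped at 1 and monotone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "iqr_filter",
    "compare_continuous",
    "compare_categorical",
    "bh_fdr",
    "spearman_matrix",
    "posthoc_group_in_mask",
]


@dataclass
class TestResult:
    test: str
    statistic: float
    p: float
    p_adjusted: float | None = None
    n_a: int | None = None
    n_b: int | None = None

    def __post_init__(self) -> None:
        if np.isfinite(self.p) and not (0.0 <= self.p <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def iqr_filter(values: np.ndarray, k: float = 1.5) -> np.ndarray:
    """Boolean keep-mask under the Tukey fence rule.

    A value is kept iff it lies within [Q1 - k*IQR, Q3 + k*IQR], with
    quartiles by linear interpolation.  NaNs are dropped (kept=False).
    """
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    if finite.sum() < 4:
        raise ValueError("need at least 4 finite values for IQR screening")
    q1, q3 = np.percentile(v[finite], [25, 75])
    iqr = q3 - q1
    keep = (v >= q1 - k * iqr) & (v <= q3 + k * iqr)
    return keep & finite


def compare_continuous(
    values_a: np.ndarray,
    values_b: np.ndarray,
    normality_alpha: float = 0.05,
) -> TestResult:
    """Two-sample comparison with normality-dependent test choice.

    Shapiro-Wilk is run per group; the t-test is used only if both
    groups pass at ``normality_alpha``, otherwise Mann-Whitney U
    (two-sided in either case).  Degenerate constant samples fall back
    to Mann-Whitney with a warning.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 observations per group")
    degenerate = np.ptp(a) == 0 or np.ptp(b) == 0
    if degenerate:
        warnings.warn("constant sample: using Mann-Whitney U")
        normal = False
    else:
        normal = (
            stats.shapiro(a).pvalue > normality_alpha
            and stats.shapiro(b).pvalue > normality_alpha
        )
    if normal:
        res = stats.ttest_ind(a, b)
        return TestResult("t-test", float(res.statistic), float(res.pvalue), n_a=a.size, n_b=b.size)
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return TestResult(
        "mann-whitney", float(res.statistic), float(res.pvalue), n_a=a.size, n_b=b.size
    )


def compare_categorical(
    a_yes: int,
    a_n: int,
    b_yes: int,
    b_n: int,
    method: str = "chi-square",
) -> TestResult:
    """2x2 categorical comparison of yes-counts between two groups.

    methods: "chi-square" (Pearson, df 1, no continuity correction),
    "fisher-one-sided" (upper hypergeometric tail P(X >= a_yes)),
    "fisher-two-sided" (sum of table probabilities <= the observed
    table's).  An empty margin yields p = 1 with a warning.
    """
    if a_yes > a_n or b_yes > b_n or min(a_yes, b_yes) < 0:
        raise ValueError("counts must be non-negative and at most the group size")
    table = np.array([[a_yes, a_n - a_yes], [b_yes, b_n - b_yes]])
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        warnings.warn("empty margin in 2x2 table; p = 1")
        return TestResult(method, 0.0, 1.0, n_a=a_n, n_b=b_n)
    if method == "chi-square":
        res = stats.chi2_contingency(table, correction=False)
        return TestResult("chi-square", float(res.statistic), float(res.pvalue), n_a=a_n, n_b=b_n)
    total_yes = a_yes + b_yes
    if method == "fisher-one-sided":
        # upper tail of Hypergeometric(N=a_n+b_n, K=total_yes, n=a_n)
        p = float(stats.hypergeom.sf(a_yes - 1, a_n + b_n, total_yes, a_n))
        odds = stats.contingency.odds_ratio(table, kind="sample").statistic
        return TestResult("fisher-one-sided", float(odds), min(p, 1.0), n_a=a_n, n_b=b_n)
    if method == "fisher-two-sided":
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        return TestResult("fisher-two-sided", float(odds), float(p), n_a=a_n, n_b=b_n)
    raise ValueError(f"unknown method {method!r}")


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1).

    NaN entries are ignored and returned as NaN.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        if p[ok].min() < 0 or p[ok].max() > 1:
            raise ValueError("p-values must lie in [0, 1]")
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def spearman_matrix(
    metrics: pd.DataFrame,
    scores: pd.DataFrame,
    min_n: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Tie-corrected Spearman correlations of every metric against every
    score, with BH-FDR across the whole matrix.

    Missing data are handled pairwise; pairs with fewer than ``min_n``
    complete observations, or with a constant column, are reported as NaN.
    Returns ``(rho, p, p_adjusted)`` DataFrames (metrics x scores).
    """
    rho = pd.DataFrame(index=metrics.columns, columns=scores.columns, dtype=float)
    pval = rho.copy()
    for m in metrics.columns:
        for s in scores.columns:
            x = metrics[m].to_numpy(dtype=float)
            y = scores[s].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < min_n or np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
                continue
            r, p = stats.spearmanr(x[ok], y[ok])
            rho.loc[m, s] = r
            pval.loc[m, s] = p
    adj = pval.copy()
    adj.loc[:, :] = bh_fdr(pval.to_numpy().ravel()).reshape(pval.shape)
    return rho, pval, adj


def posthoc_group_in_mask(
    wd_maps,
    mask: np.ndarray,
    group: np.ndarray,
    age: np.ndarray,
    mean_fd: np.ndarray,
) -> TestResult:
    """Between-group comparison of mean weighted degree within a mask.

    Mean WD over the mask is extracted per subject and regressed on a
    group indicator with age and mean framewise displacement as
    covariates; the group coefficient's t and two-sided p are reported.
    """
    import statsmodels.api as sm

    if not np.asarray(mask).any():
        raise ValueError("empty mask")
    mask = np.asarray(mask, dtype=bool)
    means = []
    for m in wd_maps:
        vol = m.to_volume()
        means.append(float(vol[mask & m.mask].mean()))
    y = np.asarray(means)
    g = np.asarray(group)
    if g.dtype.kind in "UO":
        levels = pd.unique(g)
        if levels.size != 2:
            raise ValueError("group must have exactly two levels")
        g = (g == levels[1]).astype(float)
    X = sm.add_constant(
        np.column_stack([g, np.asarray(age, float), np.asarray(mean_fd, float)])
    )
    if np.ptp(y) == 0:
        warnings.warn("degenerate model: identical mean weighted degree for all subjects")
        return TestResult("glm-group", 0.0, 1.0, n_a=int((g == 0).sum()), n_b=int((g == 1).sum()))
    fit = sm.OLS(y, X).fit()
    return TestResult(
        "glm-group",
        float(fit.tvalues[1]),
        float(fit.pvalues[1]),
        n_a=int((g == 0).sum()),
        n_b=int((g == 1).sum()),
    )
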