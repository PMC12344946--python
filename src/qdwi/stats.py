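"""Inferential statistics for two-group parameter comparisons.

The comparison of a diffusion parameter between two molecular groups is
gated on distributional checks: Shapiro-Wilk normality per group (alpha
0.05, both groups must pass), then Levene's test for homogeneity of
variance (alpha 0.05) to choose between the pooled and Welch t-test;
non-normal data fall back to the two-sided Mann-Whitney U test.  Group
summaries are reported as mean +/- SD on the t-test path and as
median (Q1, Q3) on the U-test path.

Nine parameters are each tested against two molecular questions (IDH
mutation, 1p/19q codeletion), and the resulting 18 raw p-values are
adjusted together by the Benjamini-Hochberg step-up procedure.  Effect
sizes are Cohen's d on the raw values regardless of the gate outcome
(|d| > 0.8 read as a strong effect), with the group order fixed as
(wild-type, mutant) and (non-codeleted, codeleted) so that a negative d
means the second group is higher.  Inter-rater agreement uses the
single-rater, absolute-agreement, two-way random-effects intraclass
correlation ICC(2,1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .voi import CohortTable

__all__ = ["GroupComparison", "ICCResult", "compare_groups", "adjust_bh",
           "cohens_d", "chi_square_categorical", "icc_two_way_random",
           "run_group_comparisons", "NORMALITY_ALPHA"]

NORMALITY_ALPHA = 0.05


@dataclass(frozen=True)
class GroupComparison:
    """Outcome of one two-group comparison."""

    parameter: str
    question: str
    test: str                 # "t" | "welch-t" | "mann-whitney-u"
    statistic: float
    p: float
    cohens_d: float
    summary_a: str
    summary_b: str
    shapiro_p: tuple[float, float]
    levene_p: float | None
    p_adjusted: float | None = None


@dataclass(frozen=True)
class ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single rater."""

    icc: float
    ci_95: tuple[float, float]
    model: str = "two-way random, absolute agreement, single rater"

    def __post_init__(self) -> None:
        lo, hi = self.ci_95
        if not (lo <= self.icc <= hi):
            raise ValueError("ICC estimate must lie inside its CI")


def _summary_normal(x: np.ndarray) -> str:
    return f"{np.mean(x):.3f} ± {np.std(x, ddof=1):.3f}"


def _summary_quartiles(x: np.ndarray) -> str:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:.3f}({q1:.3f},{q3:.3f})"


def cohens_d(a, b) -> float:
    """Cohen's d = (mean(a) - mean(b)) / pooled SD."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per group")
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    pooled = np.sqrt(((len(a) - 1) * va + (len(b) - 1) * vb)
                     / (len(a) + len(b) - 2))
    if pooled == 0:
        raise ValueError("zero pooled standard deviation")
    return float((np.mean(a) - np.mean(b)) / pooled)


def compare_groups(a, b, parameter: str = "", question: str = ""
                   ) -> GroupComparison:
    """Normality-gated two-group test; see the module docstring for the gate."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 values per group")
    if np.var(a) == 0 and np.var(b) == 0:
        raise ValueError("zero variance in both groups")
    sw_a = float(sps.shapiro(a).pvalue) if np.var(a) > 0 else 0.0
    sw_b = float(sps.shapiro(b).pvalue) if np.var(b) > 0 else 0.0
    both_normal = sw_a > NORMALITY_ALPHA and sw_b > NORMALITY_ALPHA
    levene_p: float | None = None
    if both_normal:
        levene_p = float(sps.levene(a, b).pvalue)
        equal_var = levene_p > NORMALITY_ALPHA
        res = sps.ttest_ind(a, b, equal_var=equal_var)
        test = "t" if equal_var else "welch-t"
        summary_a, summary_b = _summary_normal(a), _summary_normal(b)
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        test = "mann-whitney-u"
        summary_a, summary_b = _summary_quartiles(a), _summary_quartiles(b)
    return GroupComparison(parameter=parameter, question=question, test=test,
                           statistic=float(res.statistic),
                           p=float(res.pvalue),
                           cohens_d=cohens_d(a, b),
                           summary_a=summary_a, summary_b=summary_b,
                           shapiro_p=(sw_a, sw_b), levene_p=levene_p)


def adjust_bh(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("expected a non-empty 1D array of p-values")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def chi_square_categorical(table, correction: bool | None = None
                           ) -> tuple[float, float]:
    """Pearson chi-square test on a 2xk contingency table of counts.

    ``correction=None`` applies the default policy: Yates continuity
    correction for 2x2 tables with any expected count below 10, no
    correction otherwise.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("expected a 2D table of non-negative integer counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero marginal in the contingency table")
    if correction is None:
        expected = sps.contingency.expected_freq(t)
        correction = t.shape == (2, 2) and bool(np.any(expected < 10))
    res = sps.chi2_contingency(t, correction=correction)
    return float(res.statistic), float(res.pvalue)


def icc_two_way_random(ratings) -> ICCResult:
    """ICC(2,1) from the two-way ANOVA decomposition, with 95% CI via F bounds.

    ``ratings`` is a (subjects x raters) matrix with no missing cells.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 5 or x.shape[1] < 2:
        raise ValueError("need >= 5 subjects and >= 2 raters")
    if np.any(~np.isfinite(x)):
        raise ValueError("ratings must not contain missing cells")
    if np.ptp(x) == 0:
        raise ValueError("constant ratings matrix: ICC undefined")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sse = np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    if mse == 0:
        # exact agreement up to rater offsets: no residual uncertainty
        return ICCResult(icc=float(icc), ci_95=(float(icc), float(icc)))
    # Satterthwaite df for the column/error composite (McGraw & Wong 1996)
    alpha = 0.05
    fj = msc / mse
    a = k * icc / (n * (1 - icc))
    bq = 1 + k * icc * (n - 1) / (n * (1 - icc))
    v = ((a * fj + bq) ** 2 /
         (a ** 2 * fj ** 2 / (k - 1) + bq ** 2 / ((n - 1) * (k - 1))))
    f_lo = sps.f.ppf(1 - alpha / 2, n - 1, v)
    f_hi = sps.f.ppf(1 - alpha / 2, v, n - 1)
    denom_l = f_lo * (k * msc + (k * n - k - n) * mse) + n * msr
    lo = n * (msr - f_lo * mse) / denom_l
    denom_u = k * msc + (k * n - k - n) * mse + n * f_hi * msr
    hi = n * (f_hi * msr - mse) / denom_u
    lo, hi = min(lo, icc), max(hi, icc)
    return ICCResult(icc=float(icc), ci_95=(float(lo), float(hi)))


#: (question, column, ordered group levels) — the first-listed level is group
#: "a" in the d sign convention
QUESTIONS = (
    ("IDH", "idh_status", ("wild-type", "mutant"), {}),
    ("1p/19q", "codeletion_status", ("non-codeleted", "codeleted"),
     {"idh_status": "mutant"}),
)


def run_group_comparisons(cohort: CohortTable) -> pd.DataFrame:
    """All parameter x question comparisons with joint BH adjustment.

    Returns one row per hypothesis (9 parameters x 2 questions) with the
    gate outcome, test statistic, raw and BH-adjusted p, Cohen's d and the
    per-group summaries; both raw and adjusted p-values are reported.
    """
    results: list[GroupComparison] = []
    for question, column, (lvl_a, lvl_b), extra in QUESTIONS:
        for param in cohort.parameters:
            a = cohort.values_for(param, **{column: lvl_a}, **extra)
            b = cohort.values_for(param, **{column: lvl_b}, **extra)
            results.append(compare_groups(a, b, parameter=param,
                                          question=question))
    adjusted = adjust_bh([r.p for r in results])
    rows = []
    for r, padj in zip(results, adjusted):
        rows.append({
            "question": r.question, "parameter": r.parameter,
            "group_a_summary": r.summary_a, "group_b_summary": r.summary_b,
            "test": r.test, "statistic": r.statistic,
            "p_raw": r.p, "p_bh": float(padj), "cohens_d": r.cohens_d,
        })
    return pd.DataFrame(rows)
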