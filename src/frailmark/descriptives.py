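"""Two-group descriptive statistics, effect sizes and demographic summaries."""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, ValidationError
from .synthetic_cohort import Cohort, PHENOTYPES

__all__ = [
    "GroupComparison",
    "EffectSize",
    "cohens_d",
    "classify_effect",
    "compare_feature",
    "rank_sum_test",
    "demographics_table",
    "feature_table",
    "chi_square_2x2",
]

NORMALITY_ALPHA = 0.05
EXACT_RANKSUM_MAX_N = 10


@dataclass
class GroupComparison:
    feature: str
    rg_summary: Tuple[float, Optional[float], int]  # (mean, sd, n)
    fg_summary: Tuple[float, Optional[float], int]
    test_used: str  # "parametric" | "rank" | "chi_square"
    statistic: float
    p_value: float
    bmi_adjusted_p: Optional[float] = None


@dataclass
class EffectSize:
    feature: str
    d: float
    magnitude: str  # "negligible" | "small" | "medium" | "large"


def cohens_d(mean1: float, sd1: float, mean2: float, sd2: float) -> float:
    """Standardized mean difference |m1 - m2| / sqrt((s1^2 + s2^2) / 2).

    The denominator is the unweighted pooled SD (the quadratic mean of the two
    group SDs), not the sample-size-weighted pooled SD.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValidationError("standard deviations must be positive")
    return abs(mean1 - mean2) / math.sqrt((sd1**2 + sd2**2) / 2.0)


def classify_effect(d: float) -> str:
    """Magnitude band for an absolute standardized mean difference."""
    if d < 0:
        raise ValidationError("effect size must be non-negative")
    if d < 0.2:
        return "negligible"
    if d < 0.5:
        return "small"
    if d < 0.8:
        return "medium"
    return "large"


def rank_sum_test(x: Sequence[float], y: Sequence[float],
                  exact: Optional[bool] = None) -> Tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; exact enumeration for small samples.

    Returns ``(U, p)`` where U is the Mann-Whitney statistic of ``x``.  When
    ``len(x) + len(y) <= 10`` (or ``exact=True``) the p-value enumerates all
    group assignments, using the symmetric tail |W - E[W]| >= observed;
    otherwise a tie-corrected normal approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx == 0 or ny == 0:
        raise InsufficientDataError("both groups must be non-empty")
    if exact is None:
        exact = nx + ny <= EXACT_RANKSUM_MAX_N
    ranks = stats.rankdata(np.concatenate([x, y]))
    w = float(ranks[:nx].sum())
    u = w - nx * (nx + 1) / 2.0
    if exact:
        e_w = nx * (nx + ny + 1) / 2.0
        obs = abs(w - e_w)
        total = math.comb(nx + ny, nx)
        count = sum(
            1
            for idx in combinations(range(nx + ny), nx)
            if abs(sum(ranks[i] for i in idx) - e_w) >= obs - 1e-12
        )
        return u, count / total
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return u, float(res.pvalue)


def _both_groups_normal(x: np.ndarray, y: np.ndarray, alpha: float) -> bool:
    for g in (x, y):
        if len(g) < 3:
            raise InsufficientDataError(
                "normality screening needs at least 3 values per group"
            )
        if np.ptp(g) == 0.0:  # Shapiro-Wilk is undefined for constant data
            continue
        if stats.shapiro(g).pvalue <= alpha:
            return False
    return True


def compare_feature(
    rg_values: Sequence[float],
    fg_values: Sequence[float],
    covariate: Optional[Sequence[float]] = None,
    feature: str = "",
    alpha: float = NORMALITY_ALPHA,
) -> GroupComparison:
    """Two-group comparison with normality screening.

    Each group is screened with the Shapiro-Wilk test at ``alpha``; if both
    pass, a two-sample t test is used, otherwise the rank-sum test.  When a
    covariate is supplied (robust values first, then frail, matching the
    concatenation order), the group-term p-value from an ordinary
    least-squares fit of ``value ~ group + covariate`` is also reported.
    """
    x = np.asarray(rg_values, dtype=float)
    y = np.asarray(fg_values, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise InsufficientDataError("both groups must be non-empty")

    if _both_groups_normal(x, y, alpha):
        res = stats.ttest_ind(x, y, equal_var=True)
        test_used, statistic, p = "parametric", float(res.statistic), float(res.pvalue)
        if math.isnan(p):  # both groups constant and equal
            statistic, p = 0.0, 1.0
    else:
        statistic, p = rank_sum_test(x, y)
        test_used = "rank"

    adjusted_p = None
    if covariate is not None:
        cov = np.asarray(covariate, dtype=float)
        if len(cov) != len(x) + len(y):
            raise ValidationError(
                "covariate must cover all robust-then-frail values"
            )
        import statsmodels.api as sm

        group = np.concatenate([np.zeros(len(x)), np.ones(len(y))])
        design = sm.add_constant(np.column_stack([group, cov]))
        fit = sm.OLS(np.concatenate([x, y]), design).fit()
        adjusted_p = float(fit.pvalues[1])

    def _summary(v: np.ndarray) -> Tuple[float, Optional[float], int]:
        sd = float(np.std(v, ddof=1)) if len(v) > 1 else None
        return float(np.mean(v)), sd, len(v)

    return GroupComparison(
        feature=feature,
        rg_summary=_summary(x),
        fg_summary=_summary(y),
        test_used=test_used,
        statistic=statistic,
        p_value=min(p, 1.0),
        bmi_adjusted_p=adjusted_p,
    )


def chi_square_2x2(table: Sequence[Sequence[float]]) -> Tuple[float, float]:
    """Pearson chi-square statistic and p-value, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValidationError("expected a 2x2 table")
    res = stats.chi2_contingency(t, correction=False)
    return float(res.statistic), float(res.pvalue)


def feature_table(cohort: Cohort, adjust_for_bmi: bool = True) -> pd.DataFrame:
    """Per-feature group comparison table: moments, p-values, effect sizes."""
    if len(cohort) == 0:
        raise InsufficientDataError("empty cohort")
    labels = cohort.labels()
    bmi = np.array([p.bmi for p in cohort])
    feature_names = list(cohort[0].features)
    rows = []
    for name in feature_names:
        vals = cohort.values(name)
        rg, fg = vals[labels == 0], vals[labels == 1]
        cov = np.concatenate([bmi[labels == 0], bmi[labels == 1]]) if adjust_for_bmi else None
        cmp_ = compare_feature(rg, fg, covariate=cov, feature=name)
        d = cohens_d(
            cmp_.rg_summary[0], cmp_.rg_summary[1] or 1.0,
            cmp_.fg_summary[0], cmp_.fg_summary[1] or 1.0,
        )
        rows.append(
            {
                "feature": name,
                "rg_mean": cmp_.rg_summary[0],
                "rg_sd": cmp_.rg_summary[1],
                "rg_n": cmp_.rg_summary[2],
                "fg_mean": cmp_.fg_summary[0],
                "fg_sd": cmp_.fg_summary[1],
                "fg_n": cmp_.fg_summary[2],
                "test": cmp_.test_used,
                "statistic": cmp_.statistic,
                "p_value": cmp_.p_value,
                "bmi_adjusted_p": cmp_.bmi_adjusted_p,
                "effect_size": d,
                "effect_magnitude": classify_effect(d),
            }
        )
    return pd.DataFrame(rows)


def demographics_table(cohort: Cohort) -> pd.DataFrame:
    """Per-group demographic and phenotype summary rows.

    Continuous variables report mean and SD (SD absent for n < 2); gender and
    phenotype flags report count and percentage; gender additionally gets a
    2x2 chi-square test across groups.
    """
    if len(cohort) == 0:
        raise InsufficientDataError("empty cohort")
    labels = cohort.labels()
    rows: List[dict] = []

    def _groups(values: np.ndarray):
        return values[labels == 0], values[labels == 1]

    continuous = {
        "age": np.array([p.age for p in cohort]),
        "height_cm": np.array([p.height for p in cohort]),
        "weight_kg": np.array([p.weight for p in cohort]),
        "bmi": np.array([p.bmi for p in cohort]),
    }
    for name, vals in continuous.items():
        rg, fg = _groups(vals)
        rows.append(
            {
                "variable": name,
                "rg_value": float(np.mean(rg)) if len(rg) else None,
                "rg_sd": float(np.std(rg, ddof=1)) if len(rg) > 1 else None,
                "rg_n": len(rg),
                "fg_value": float(np.mean(fg)) if len(fg) else None,
                "fg_sd": float(np.std(fg, ddof=1)) if len(fg) > 1 else None,
                "fg_n": len(fg),
                "statistic": None,
                "p_value": None,
            }
        )

    female = np.array([1 if p.gender == "female" else 0 for p in cohort])
    rg_f, fg_f = _groups(female)
    stat = p = None
    t = [[int(rg_f.sum()), int(len(rg_f) - rg_f.sum())],
         [int(fg_f.sum()), int(len(fg_f) - fg_f.sum())]]
    if len(rg_f) and len(fg_f) and 0 < female.sum() < len(female):
        stat, p = chi_square_2x2(t)
    rows.append(
        {
            "variable": "female",
            "rg_value": int(rg_f.sum()),
            "rg_sd": None,
            "rg_n": len(rg_f),
            "fg_value": int(fg_f.sum()),
            "fg_sd": None,
            "fg_n": len(fg_f),
            "statistic": stat,
            "p_value": p,
        }
    )

    for ph in PHENOTYPES:
        flags = cohort.phenotype(ph)
        rg_c, fg_c = _groups(flags)
        rows.append(
            {
                "variable": f"presence_of_{ph}",
                "rg_value": int(rg_c.sum()),
                "rg_sd": None,
                "rg_n": len(rg_c),
                "fg_value": int(fg_c.sum()),
                "fg_sd": None,
                "fg_n": len(fg_c),
                "statistic": None,
                "p_value": None,
            }
        )
    return pd.DataFrame(rows)
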