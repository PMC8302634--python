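"""Cohort-level statistics: FI-by-grade comparison, OR-FI correlation, reliability.

Mirrors the clinical reporting layer: one-way ANOVA of fatty infiltration
across Goutallier grades with Bonferroni-adjusted pairwise post hoc t tests,
Pearson correlation between occupation ratio and fatty infiltration, and the
reliability coefficients used for grading agreement (weighted kappa between
ordinal raters, ICC(2,1) — two-way random, single measure, absolute
agreement — between continuous measurements).  The kappa weighting scheme
and the ICC model are echoed in every output because neither is universal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError, UsageError

GRADE_ORDER = (0, 1, 2, 3, 4)


def validate_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Check the (case_id, grade, fi_pct, occupation_ratio) cohort schema."""
    required = {"case_id", "grade", "fi_pct", "occupation_ratio"}
    missing = required - set(table.columns)
    if missing:
        raise DataError(f"cohort table lacks columns {sorted(missing)}")
    if table["case_id"].duplicated().any():
        raise DataError("duplicate case_id in cohort table")
    if not table["grade"].isin(GRADE_ORDER).all():
        raise DataError("grades must be integers 0..4")
    fi = table["fi_pct"].to_numpy(dtype=float)
    if ((fi < 0) | (fi > 100)).any():
        raise DataError("fi_pct outside [0, 100]")
    return table


@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    pairwise_p_adjusted: dict[tuple[int, int], float]
    per_grade: pd.DataFrame  # mean, sd, lower (min), upper (max), n per grade

    def to_dict(self) -> dict:
        return {
            "f_statistic": self.f_statistic,
            "p_value": self.p_value,
            "pairwise_p_adjusted": {f"{a}v{b}": p for (a, b), p in self.pairwise_p_adjusted.items()},
            "per_grade": self.per_grade.to_dict(orient="index"),
        }


def anova_bonferroni(table: pd.DataFrame, value_col: str = "fi_pct") -> AnovaResult:
    """One-way ANOVA of *value_col* across grades + Bonferroni post hoc tests.

    Pairwise two-sample t tests have their p-values multiplied by the number
    of comparisons (capped at 1).  The per-grade summary reports mean, SD and
    the observed min/max as the lower/upper limits.
    """
    if not {"grade", value_col} <= set(table.columns):
        raise DataError(f"ANOVA needs 'grade' and {value_col!r} columns")
    groups = {int(g): grp[value_col].to_numpy(dtype=float)
              for g, grp in table.groupby("grade")}
    degenerate = [g for g, v in groups.items() if len(v) < 2]
    if len(groups) < 2 or degenerate:
        raise DataError(f"ANOVA needs >= 2 groups with >= 2 members; offending grades: {degenerate}")
    values = list(groups.values())
    if all(np.ptp(v) == 0 for v in values) and np.ptp(np.concatenate(values)) == 0:
        raise DataError("zero variance everywhere; F statistic undefined")
    f_stat, p = sps.f_oneway(*values)
    keys = sorted(groups)
    n_comp = len(keys) * (len(keys) - 1) // 2
    pairwise = {}
    for i, a in enumerate(keys):
        for b in keys[i + 1:]:
            t = sps.ttest_ind(groups[a], groups[b])
            pairwise[(a, b)] = min(1.0, t.pvalue * n_comp)
    per_grade = pd.DataFrame({
        g: {"n": len(v), "mean": v.mean(), "sd": v.std(ddof=1),
            "lower_limit": v.min(), "upper_limit": v.max()}
        for g, v in groups.items()
    }).T.sort_index()
    return AnovaResult(float(f_stat), float(p), pairwise, per_grade)


def pearson(table: pd.DataFrame, x_col: str = "occupation_ratio",
            y_col: str = "fi_pct") -> tuple[float, float]:
    """Pearson product-moment r and two-sided p between two cohort columns."""
    x = table[x_col].to_numpy(dtype=float)
    y = table[y_col].to_numpy(dtype=float)
    if len(x) < 3:
        raise DataError("Pearson correlation needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DataError("zero variance in a correlation column")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def weighted_kappa(rater_a, rater_b, weights: str = "linear") -> float:
    """Weighted Cohen's kappa on the 5x5 Goutallier contingency table."""
    from sklearn.metrics import cohen_kappa_score

    a = np.asarray(rater_a, dtype=int)
    b = np.asarray(rater_b, dtype=int)
    if a.shape != b.shape:
        raise UsageError("rating vectors must have equal length")
    if not (np.isin(a, GRADE_ORDER).all() and np.isin(b, GRADE_ORDER).all()):
        raise DataError("ratings must be grades 0..4")
    if weights not in ("linear", "quadratic"):
        raise UsageError(f"weights must be linear or quadratic, got {weights!r}")
    return float(cohen_kappa_score(a, b, labels=list(GRADE_ORDER), weights=weights))


def icc(values_a, values_b) -> float:
    """ICC(2,1): two-way random effects, single measure, absolute agreement."""
    import pingouin as pg

    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise UsageError("measurement vectors must have equal length")
    if len(a) < 3:
        raise DataError("ICC needs at least 3 paired measurements")
    n = len(a)
    df = pd.DataFrame({
        "target": np.r_[np.arange(n), np.arange(n)],
        "rater": ["a"] * n + ["b"] * n,
        "rating": np.r_[a, b],
    })
    import warnings

    with warnings.catch_warnings():
        # degenerate inputs (zero residual variance) trip pingouin's CI math;
        # the point estimate itself is well defined
        warnings.simplefilter("ignore", RuntimeWarning)
        res = pg.intraclass_corr(data=df, targets="target", raters="rater", ratings="rating")
    # the two-way random / single / absolute-agreement row is labelled
    # "ICC2" or "ICC(A,1)" depending on the pingouin release
    row = res[res["Type"].isin(["ICC2", "ICC(A,1)"])]
    return float(row["ICC"].iloc[0])


def cohort_statistics(table: pd.DataFrame, kappa_weights: str = "linear") -> dict:
    """Full statistics bundle for a cohort table (JSON-serialisable)."""
    table = validate_cohort(table)
    out: dict = {}
    try:
        out["anova"] = anova_bonferroni(table).to_dict()
    except DataError as exc:
        out["anova"] = {"error": str(exc)}
    r, p = pearson(table)
    out["pearson"] = {"r": r, "p_value": p,
                      "x": "occupation_ratio", "y": "fi_pct"}
    out["kappa_weights_scheme"] = kappa_weights
    out["icc_model"] = "ICC(2,1) two-way random, single measure, absolute agreement"
    return out
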