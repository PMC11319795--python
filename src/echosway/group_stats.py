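"""Group-comparison and reliability statistics for cohort tables.

Covers the statistics used to compare young and older groups on ultrasound
and sway variables: pooled-variance Student t-tests (from raw samples or
from printed mean ± SD summaries), Fisher's exact test for sex ratios,
test-retest reliability via the two-way random-effects absolute-agreement
single-measure ICC(2,1), a two-way condition x age-group ANOVA with
classical eta-squared and Bonferroni-corrected post-hoc t-tests, and the
conventional verbal labels for correlation strength.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats
import statsmodels.api as sm
from statsmodels.formula.api import ols

__all__ = [
    "SummaryStats",
    "TTestResult",
    "ICCResult",
    "AnovaResult",
    "ttest_from_summary",
    "ttest_raw",
    "fisher_exact_2x2",
    "icc_test_retest",
    "anova_condition_by_age",
    "bonferroni",
    "label_correlation_strength",
]


@dataclass(frozen=True)
class SummaryStats:
    """Printed two-group summary: n, mean, SD per group for one variable."""

    n1: int
    mean1: float
    sd1: float
    n2: int
    mean2: float
    sd2: float
    variable: str = ""

    def __post_init__(self) -> None:
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("each group needs n >= 2")
        if self.sd1 < 0 or self.sd2 < 0:
            raise ValueError("SDs must be non-negative")


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    cohens_d: float
    method: str = "student_t.pooled"


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci95: tuple[float, float]
    model: str = "icc2_1"


@dataclass(frozen=True)
class AnovaResult:
    """Per-effect F tests plus Bonferroni-adjusted pairwise condition t-tests."""

    effects: pd.DataFrame  # index: condition, group, condition:group; cols F, df_num, df_den, p, eta_squared
    posthoc: pd.DataFrame  # pairwise condition comparisons


def ttest_from_summary(s: SummaryStats) -> TTestResult:
    """Pooled-variance Student t-test from group means and SDs.

    sp² = ((n1−1)sd1² + (n2−1)sd2²)/(n1+n2−2); t = (m1−m2)/(sp·√(1/n1+1/n2));
    Cohen's d = |m1−m2|/sp; two-sided p from the t distribution with
    df = n1+n2−2.  Zero pooled SD with unequal means yields an infinite t
    (reported as ±inf with p = 0).
    """
    df = s.n1 + s.n2 - 2
    sp2 = ((s.n1 - 1) * s.sd1**2 + (s.n2 - 1) * s.sd2**2) / df
    diff = s.mean1 - s.mean2
    if sp2 == 0:
        if diff == 0:
            return TTestResult(t=0.0, df=df, p=1.0, cohens_d=0.0)
        t = math.inf if diff > 0 else -math.inf
        return TTestResult(t=t, df=df, p=0.0, cohens_d=math.inf)
    sp = math.sqrt(sp2)
    t = diff / (sp * math.sqrt(1 / s.n1 + 1 / s.n2))
    p = 2 * stats.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=df, p=float(p), cohens_d=abs(diff) / sp)


def ttest_raw(x1: Sequence[float], x2: Sequence[float], variable: str = "") -> TTestResult:
    """Student t-test on raw samples; exactly equals the summary-statistics path."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if len(x1) < 2 or len(x2) < 2:
        raise ValueError("each group needs n >= 2")
    s = SummaryStats(
        n1=len(x1), mean1=float(x1.mean()), sd1=float(x1.std(ddof=1)),
        n2=len(x2), mean2=float(x2.mean()), sd2=float(x2.std(ddof=1)),
        variable=variable,
    )
    return ttest_from_summary(s)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Sums hypergeometric probabilities of tables (at fixed margins) no more
    likely than the observed one.
    """
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("counts must be non-negative")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def icc_test_retest(values: np.ndarray) -> ICCResult:
    """ICC(2,1) with 95% CI for a subjects x replicates layout.

    Two-way random effects, absolute agreement, single measure — the
    conservative reading of test-retest reliability for single images.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("need at least 2 subjects and 2 replicates")
    n, k = values.shape
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), k),
            "rater": np.tile(np.arange(k), n),
            "score": values.ravel(),
        }
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        # degenerate layouts (identical replicates) hit 0/0 in auxiliary
        # forms we do not report
        table = pg.intraclass_corr(data=long, targets="subject", raters="rater", ratings="score")
    table = table.set_index("Type")
    # absolute-agreement single-measure row: labelled ICC2 or ICC(A,1)
    key = "ICC2" if "ICC2" in table.index else "ICC(A,1)"
    row = table.loc[key]
    ci_col = "CI95%" if "CI95%" in table.columns else "CI95"
    lo, hi = row[ci_col]
    return ICCResult(icc=float(row["ICC"]), ci95=(float(lo), float(hi)))


def anova_condition_by_age(table: pd.DataFrame, dv: str = "sdCOP_AP_norm") -> AnovaResult:
    """Two-way fixed-effects ANOVA (condition x group) with interaction.

    ``table`` holds one row per subject x condition with columns
    ``subject``, ``group``, ``condition`` and the dependent variable ``dv``
    (normally the height-normalized sdCOP).  Eta-squared is classical
    (SS_effect/SS_total).  Post-hoc: pairwise Student t-tests between
    conditions with Bonferroni-multiplied p-values.
    """
    for col in ("group", "condition", dv):
        if col not in table.columns:
            raise ValueError(f"table lacks required column {col!r}")
    counts = table.groupby(["group", "condition"], observed=True).size()
    full = {(g, c) for g in table["group"].unique() for c in table["condition"].unique()}
    missing = full - set(counts.index)
    if missing:
        raise ValueError(f"empty design cells: {sorted(missing)}")
    data = table.rename(columns={dv: "_dv"})
    model = ols("_dv ~ C(condition) * C(group)", data=data).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    ss_total = float(aov["sum_sq"].sum())
    df_den = int(aov.loc["Residual", "df"])
    ss_res = float(aov.loc["Residual", "sum_sq"])
    # rebuild F from the sums of squares with explicit degenerate handling
    # (constant data gives 0/0, which must read as "no effect", F = 0)
    tol = 1e-12 * max(1.0, ss_total)
    rows = {}
    for label, name in [
        ("C(condition)", "condition"),
        ("C(group)", "group"),
        ("C(condition):C(group)", "condition:group"),
    ]:
        ss_eff = float(aov.loc[label, "sum_sq"])
        df_num = int(aov.loc[label, "df"])
        if ss_eff <= tol:
            f_val, p_val = 0.0, 1.0
        elif ss_res <= tol:
            f_val, p_val = math.inf, 0.0
        else:
            f_val = (ss_eff / df_num) / (ss_res / df_den)
            p_val = float(stats.f.sf(f_val, df_num, df_den))
        rows[name] = {
            "F": f_val,
            "df_num": df_num,
            "df_den": df_den,
            "p": p_val,
            "eta_squared": ss_eff / ss_total if ss_total > tol else 0.0,
        }
    effects = pd.DataFrame(rows).T[["F", "df_num", "df_den", "p", "eta_squared"]]

    conds = list(dict.fromkeys(table["condition"]))
    pairs = [(a, b) for idx, a in enumerate(conds) for b in conds[idx + 1 :]]
    m = len(pairs)
    ph = []
    for a, b in pairs:
        res = ttest_raw(
            data.loc[data["condition"] == a, "_dv"], data.loc[data["condition"] == b, "_dv"]
        )
        ph.append(
            {"cond_a": a, "cond_b": b, "t": res.t, "df": res.df,
             "p_raw": res.p, "p_bonferroni": bonferroni(res.p, m)}
        )
    return AnovaResult(effects=effects, posthoc=pd.DataFrame(ph))


def bonferroni(p_raw: float, m: int) -> float:
    """Bonferroni adjustment: min(1, m * p_raw)."""
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    return min(1.0, m * p_raw)


#: verbal labels for |r|, upper bound inclusive
_STRENGTH_BINS = [
    (0.20, "very weak"),
    (0.40, "weak"),
    (0.60, "moderate"),
    (0.80, "strong"),
    (1.0 + 1e-12, "very strong"),
]


def label_correlation_strength(r: float) -> str:
    """Map |r| to {very weak, weak, moderate, strong, very strong}."""
    a = abs(r)
    if a > 1:
        raise ValueError("|r| cannot exceed 1")
    for upper, label in _STRENGTH_BINS:
        if a < upper:
            return label
    return "very strong"
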