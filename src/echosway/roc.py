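"""Empirical ROC analysis for single-parameter young/old classification.

The ROC curve is built non-parametrically from every distinct score
threshold; the AUC is the trapezoidal area, which equals the Mann-Whitney
probability estimate with ties counted 1/2.  Pairwise AUC comparison between
two parameters measured on the same subjects uses the DeLong placement-value
covariance and a two-sided normal z-test.

Score orientation for each ultrasound parameter is fixed a priori from the
direction of the young/old group difference (never flipped to the data), so
an AUC below 0.5 indicates a parameter behaving against its expected
direction rather than a silently optimistic flip.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ROCResult",
    "AUCComparison",
    "PARAMETER_ORIENTATION",
    "empirical_roc",
    "mann_whitney_auc",
    "classify_parameter",
    "compare_auc_paired",
    "pairwise_auc_matrix",
]

#: a-priori score sign per VL parameter so that, under the expected ageing
#: direction, a higher oriented score predicts the older class (AUC >= 0.5):
#: EI, Entropy, Contrast increase with age (+1); MT, ASM, IDM, Correlation
#: and SAT decrease (-1).
PARAMETER_ORIENTATION = {
    "EI": +1, "Entropy": +1, "Contrast": +1,
    "MT_cm": -1, "SAT_cm": -1, "ASM": -1, "IDM": -1, "Correlation": -1,
    "MT": -1, "SAT": -1,
}


@dataclass(frozen=True)
class ROCResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    positive_class: object
    orientation: int


@dataclass(frozen=True)
class AUCComparison:
    auc1: float
    auc2: float
    z: float
    p: float
    method: str = "delong.paired"


def _validate(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    if np.isnan(scores).any():
        raise ValueError("missing scores are not allowed")
    return scores, labels


def empirical_roc(scores, labels, positive_label=1, orientation: int = 1) -> ROCResult:
    """Empirical (non-parametric) ROC curve and trapezoidal AUC.

    ``orientation`` multiplies the scores before thresholding; +1 means a
    higher raw score predicts the positive class.
    """
    scores, labels = _validate(scores, labels)
    pos = labels == positive_label
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    s = orientation * scores
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    pos_sorted = pos[order].astype(float)
    tp = np.cumsum(pos_sorted)
    fp = np.cumsum(1.0 - pos_sorted)
    # keep only the last index of each tied score block
    distinct = np.r_[np.diff(s_sorted) != 0, True]
    tpr = np.r_[0.0, tp[distinct] / n_pos]
    fpr = np.r_[0.0, fp[distinct] / n_neg]
    thresholds = np.r_[np.inf, s_sorted[distinct]]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(
        thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc,
        positive_class=positive_label, orientation=orientation,
    )


def mann_whitney_auc(scores, labels, positive_label=1, orientation: int = 1) -> float:
    """Rank-sum AUC estimate with ties counted 1/2 (equals the trapezoid)."""
    scores, labels = _validate(scores, labels)
    pos = labels == positive_label
    if pos.all() or not pos.any():
        raise ValueError("both classes must be present")
    s = orientation * scores
    ranks = stats.rankdata(s)
    n_pos = pos.sum()
    n_neg = len(s) - n_pos
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def classify_parameter(cohort: pd.DataFrame, parameter: str,
                       group_col: str = "group", positive_group: str = "old") -> ROCResult:
    """ROC for classifying the older group from one ultrasound parameter.

    Orientation is the fixed a-priori sign for that parameter (see
    ``PARAMETER_ORIENTATION``), so no data-driven flipping inflates the AUC.
    """
    if parameter not in cohort.columns:
        raise ValueError(f"unknown parameter {parameter!r}")
    if parameter not in PARAMETER_ORIENTATION:
        raise ValueError(f"no a-priori orientation defined for {parameter!r}")
    labels = (cohort[group_col] == positive_group).astype(int).to_numpy()
    return empirical_roc(
        cohort[parameter].to_numpy(), labels, positive_label=1,
        orientation=PARAMETER_ORIENTATION[parameter],
    )


# ---------------------------------------------------------------------------
# DeLong paired comparison
# ---------------------------------------------------------------------------

def _placements(scores, pos_mask):
    """Placement values V10 (per positive) and V01 (per negative)."""
    x = scores[pos_mask]   # positives
    y = scores[~pos_mask]  # negatives
    # V10_i = P(score_neg < x_i) + 0.5 P(= x_i); vectorized via broadcasting
    cmp = (x[:, None] > y[None, :]).astype(float) + 0.5 * (x[:, None] == y[None, :])
    v10 = cmp.mean(axis=1)
    v01 = cmp.mean(axis=0)
    return v10, v01


def compare_auc_paired(scores_a, scores_b, labels, positive_label=1,
                       orientation_a: int = 1, orientation_b: int = 1) -> AUCComparison:
    """DeLong z-test comparing two AUCs measured on the same subjects.

    The variance of the AUC difference accounts for the correlation between
    the two placement-value sets; z = (auc_a - auc_b)/se_diff with a
    two-sided normal p.  Identical (or co-monotone) scores give se_diff = 0
    and are reported as z = 0, p = 1.
    """
    scores_a, labels = _validate(scores_a, labels)
    scores_b, _ = _validate(scores_b, labels)
    if len(scores_a) != len(scores_b):
        raise ValueError("paired score vectors must have the same length")
    pos = labels == positive_label
    if pos.all() or not pos.any():
        raise ValueError("both classes must be present")
    sa = orientation_a * scores_a
    sb = orientation_b * scores_b
    v10a, v01a = _placements(sa, pos)
    v10b, v01b = _placements(sb, pos)
    auc_a = float(v10a.mean())
    auc_b = float(v10b.mean())
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    var_diff = (
        (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    )
    if var_diff <= 0 or not np.isfinite(var_diff):
        return AUCComparison(auc1=auc_a, auc2=auc_b, z=0.0, p=1.0)
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    p = 2 * stats.norm.sf(abs(z))
    return AUCComparison(auc1=auc_a, auc2=auc_b, z=float(z), p=float(p))


def pairwise_auc_matrix(cohort: pd.DataFrame, parameters: list[str],
                        group_col: str = "group", positive_group: str = "old") -> pd.DataFrame:
    """All pairwise DeLong comparisons among the given parameters."""
    labels = (cohort[group_col] == positive_group).astype(int).to_numpy()
    rows = []
    for i, pa in enumerate(parameters):
        for pb in parameters[i + 1 :]:
            cmp = compare_auc_paired(
                cohort[pa].to_numpy(), cohort[pb].to_numpy(), labels,
                orientation_a=PARAMETER_ORIENTATION[pa],
                orientation_b=PARAMETER_ORIENTATION[pb],
            )
            rows.append({"param_a": pa, "param_b": pb, "auc_a": cmp.auc1,
                         "auc_b": cmp.auc2, "z": cmp.z, "p": cmp.p})
    return pd.DataFrame(rows)
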