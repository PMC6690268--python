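"""ROC construction, AUC with DeLong variance, correlated-curve comparison,
confusion-matrix metrics, and Youden-based cut-point optimizers.

Cut-points on accelerometer counts per minute (CPM) are directional: sedentary
behavior is flagged by *low* counts (an epoch is predicted sedentary when its
CPM falls at or below the threshold, ``positive_if_le``), whereas
moderate-to-vigorous activity is flagged by *high* counts
(``positive_if_ge``).  Candidate thresholds are exactly the observed score
values plus -inf/+inf sentinels, so a reported cut-point is always an achieved
integer CPM.

All rates are carried as proportions internally; :class:`ThresholdMetrics`
converts to percent at the reporting boundary, where the Youden index is
``J = sensitivity + specificity - 100``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import (
    CalibrationInconsistencyError,
    DegenerateInputError,
    DegenerateVarianceError,
    DomainError,
)

POSITIVE_IF_LE = "positive_if_le"
POSITIVE_IF_GE = "positive_if_ge"
_DIRECTIONS = (POSITIVE_IF_LE, POSITIVE_IF_GE)


def _validate(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-d sequences")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be coded 0/1")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DegenerateInputError("both classes must be present")
    return scores, labels, n_pos, n_neg


def _check_direction(direction):
    if direction not in _DIRECTIONS:
        raise ValueError(f"direction must be one of {_DIRECTIONS}, got {direction!r}")


@dataclass(frozen=True)
class ThresholdMetrics:
    """Confusion-matrix summary at one CPM threshold, rates in percent.

    ``ppv``/``npv`` are ``None`` when their denominator is empty (no predicted
    positives / negatives) rather than coerced to zero.
    """

    threshold: float
    sensitivity: float
    specificity: float
    accuracy: float
    ppv: float | None
    npv: float | None
    youden_j: float
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    @property
    def fpr(self) -> float:
        """False-positive ratio as a proportion in [0, 1]."""
        return self.fp / (self.fp + self.tn)

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "ppv": self.ppv,
            "npv": self.npv,
            "youden_j": self.youden_j,
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
        }


def _metrics_from_counts(threshold, tp, fp, fn, tn) -> ThresholdMetrics:
    se = tp / (tp + fn)
    sp = tn / (tn + fp)
    acc = (tp + tn) / (tp + fp + fn + tn)
    ppv = 100.0 * tp / (tp + fp) if (tp + fp) > 0 else None
    npv = 100.0 * tn / (tn + fn) if (tn + fn) > 0 else None
    sens, spec = 100.0 * se, 100.0 * sp
    return ThresholdMetrics(
        threshold=threshold,
        sensitivity=sens,
        specificity=spec,
        accuracy=100.0 * acc,
        ppv=ppv,
        npv=npv,
        youden_j=sens + spec - 100.0,
        tp=int(tp),
        fp=int(fp),
        fn=int(fn),
        tn=int(tn),
    )


@dataclass(frozen=True)
class ROCCurve:
    """Empirical ROC over all observed thresholds plus sentinels.

    Thresholds run from strictest (nothing predicted positive) to loosest
    (everything predicted positive), so ``tpr`` and ``fpr`` are jointly
    nondecreasing and the curve passes through (0, 0) and (1, 1).
    """

    direction: str
    thresholds: np.ndarray  # sweep order, sentinels at both ends
    tp: np.ndarray  # cumulative true positives per threshold
    fp: np.ndarray
    n_pos: int
    n_neg: int

    @property
    def tpr(self) -> np.ndarray:
        return self.tp / self.n_pos

    @property
    def fpr(self) -> np.ndarray:
        return self.fp / self.n_neg

    def trapezoid_auc(self) -> float:
        """Area under the curve by the trapezoid rule over (fpr, tpr)."""
        return float(np.trapezoid(self.tpr, self.fpr))

    def metrics_at(self, i: int) -> ThresholdMetrics:
        tp, fp = int(self.tp[i]), int(self.fp[i])
        return _metrics_from_counts(
            float(self.thresholds[i]), tp, fp, self.n_pos - tp, self.n_neg - fp
        )


def roc_curve(scores, labels, direction: str) -> ROCCurve:
    """Build the empirical ROC curve of CPM scores against 0/1 labels.

    Under ``positive_if_le`` an epoch is predicted positive when its score is
    <= the threshold; under ``positive_if_ge`` when >=.  One point per
    distinct observed score, plus -inf/+inf sentinels.
    """
    _check_direction(direction)
    scores, labels, n_pos, n_neg = _validate(scores, labels)
    uniq = np.unique(scores)
    # counts of positives / negatives at each unique score value
    idx = np.searchsorted(uniq, scores)
    pos_at = np.bincount(idx, weights=labels, minlength=uniq.size)
    neg_at = np.bincount(idx, weights=1 - labels, minlength=uniq.size)
    if direction == POSITIVE_IF_LE:
        sweep = uniq  # ascending: threshold grows, predicted-positive set grows
        tp_obs = np.cumsum(pos_at)
        fp_obs = np.cumsum(neg_at)
        lo_sentinel, hi_sentinel = -np.inf, np.inf
    else:
        sweep = uniq[::-1]  # descending
        tp_obs = np.cumsum(pos_at[::-1])
        fp_obs = np.cumsum(neg_at[::-1])
        lo_sentinel, hi_sentinel = np.inf, -np.inf
    thresholds = np.concatenate(([lo_sentinel], sweep, [hi_sentinel]))
    tp = np.concatenate(([0], tp_obs, [n_pos])).astype(int)
    fp = np.concatenate(([0], fp_obs, [n_neg])).astype(int)
    return ROCCurve(direction, thresholds, tp, fp, n_pos, n_neg)


def auc(scores, labels, direction: str) -> float:
    """Tie-corrected pairwise AUC (Mann-Whitney form).

    Probability that a random positive epoch scores on the positive side of a
    random negative epoch, counting ties as 1/2; identical to the trapezoid
    area under :func:`roc_curve`.
    """
    _check_direction(direction)
    scores, labels, n_pos, n_neg = _validate(scores, labels)
    if direction == POSITIVE_IF_LE:
        scores = -scores
    ranks = stats.rankdata(scores)
    rank_sum_pos = ranks[labels == 1].sum()
    return float((rank_sum_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def confusion_metrics(scores, labels, threshold, direction: str) -> ThresholdMetrics:
    """Se/Sp/Acc/PPV/NPV/J at a single threshold."""
    _check_direction(direction)
    scores, labels, n_pos, n_neg = _validate(scores, labels)
    if direction == POSITIVE_IF_LE:
        pred = scores <= threshold
    else:
        pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    return _metrics_from_counts(float(threshold), tp, fp, n_pos - tp, n_neg - fp)


def _best_index(curve: ROCCurve, feasible: np.ndarray) -> int:
    """Argmax of J over feasible sweep positions with the documented
    tie-breaks: higher sensitivity first, then the more conservative
    activity estimate (lower SB bound / higher MVPA bound)."""
    # exact integer arithmetic: J = tp/n_pos - fp/n_neg has the same argmax
    # as tp*n_neg - fp*n_pos, so the maximization is rounding-free
    j_num = curve.tp.astype(object) * curve.n_neg - curve.fp.astype(object) * curve.n_pos
    j_feas = np.where(feasible, j_num, -(curve.n_pos * curve.n_neg + 1))
    cand = np.flatnonzero(j_feas == j_feas.max())
    # prefer higher sensitivity
    best_tp = curve.tp[cand].max()
    cand = cand[curve.tp[cand] == best_tp]
    # conservative residual tie-break: strictest threshold = earliest in sweep
    # (lowest value under positive_if_le, highest under positive_if_ge)
    return int(cand[0])


def youden_cutpoint(curve: ROCCurve) -> ThresholdMetrics:
    """Threshold maximizing the Youden index J = Se + Sp - 100 over the full
    sweep of observed thresholds."""
    feasible = np.ones(curve.thresholds.size, dtype=bool)
    return curve.metrics_at(_best_index(curve, feasible))


def constrained_cutpoint(
    curve: ROCCurve, max_fpr: float = 0.10, boundary: str = "le"
) -> ThresholdMetrics:
    """Threshold maximizing J subject to a false-positive-ratio ceiling.

    ``boundary`` selects whether the ceiling is inclusive (``"le"``, default,
    fpr <= max_fpr) or strict (``"lt"``).  The strictest sentinel has fpr = 0,
    so the feasible set is never empty.
    """
    if not 0 <= max_fpr < 1:
        raise DomainError(f"max_fpr must be in [0, 1), got {max_fpr}")
    if boundary not in ("le", "lt"):
        raise ValueError("boundary must be 'le' or 'lt'")
    fpr = curve.fpr
    feasible = fpr <= max_fpr if boundary == "le" else fpr < max_fpr
    feasible[0] = True  # strictest sentinel, fpr exactly 0
    return curve.metrics_at(_best_index(curve, feasible))


def lpa_band(
    sb_metrics: ThresholdMetrics, mvpa_metrics: ThresholdMetrics
) -> tuple[float, float]:
    """Open CPM interval between the SB and MVPA boundaries: light activity
    is everything strictly between them."""
    sb_t, mvpa_t = sb_metrics.threshold, mvpa_metrics.threshold
    if not sb_t < mvpa_t:
        raise CalibrationInconsistencyError(
            f"SB bound ({sb_t}) must lie below the MVPA bound ({mvpa_t})"
        )
    return (sb_t, mvpa_t)


# ---------------------------------------------------------------------------
# DeLong machinery: placement values (structural components) give the AUC
# variance and the covariance between two curves built on paired epochs.
# ---------------------------------------------------------------------------


def _placements(scores, labels):
    """Per-epoch placement values V10 (positives) and V01 (negatives)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    all_ranks = stats.rankdata(np.concatenate([pos, neg]))
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    auc_val = (all_ranks[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (all_ranks[:m] - pos_ranks) / n  # placement of each positive
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m  # placement of each negative
    return auc_val, v10, v01


def auc_variance(scores, labels, direction: str) -> tuple[float, float]:
    """AUC and its DeLong variance for one curve."""
    _check_direction(direction)
    scores, labels, n_pos, n_neg = _validate(scores, labels)
    if direction == POSITIVE_IF_LE:
        scores = -scores
    auc_val, v10, v01 = _placements(scores, labels)
    var = np.var(v10, ddof=1) / n_pos + np.var(v01, ddof=1) / n_neg
    return float(auc_val), float(var)


@dataclass(frozen=True)
class AucResult:
    """AUC point estimate with DeLong variance and a normal-theory CI."""

    auc: float
    variance: float
    ci_low: float
    ci_high: float
    level: float = 0.95

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "variance": self.variance,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "level": self.level,
        }


def auc_ci(auc_val: float, variance: float, level: float = 0.95) -> tuple[float, float]:
    """Normal-approximation interval ``auc ± z * sqrt(var)``, clipped to [0, 1]."""
    if variance < 0:
        raise DomainError(f"variance must be non-negative, got {variance}")
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(variance)
    return (max(0.0, auc_val - half), min(1.0, auc_val + half))


def auc_with_ci(scores, labels, direction: str, level: float = 0.95) -> AucResult:
    """Convenience: AUC, DeLong variance, and CI in one object."""
    auc_val, var = auc_variance(scores, labels, direction)
    lo, hi = auc_ci(auc_val, var, level)
    return AucResult(auc=auc_val, variance=var, ci_low=lo, ci_high=hi, level=level)


@dataclass(frozen=True)
class DeLongResult:
    """Two-sided comparison of correlated AUCs on paired epochs."""

    auc_a: float
    auc_b: float
    var_a: float
    var_b: float
    covariance: float
    z_statistic: float
    p_value: float

    def to_dict(self) -> dict:
        return {
            "auc_a": self.auc_a,
            "auc_b": self.auc_b,
            "var_a": self.var_a,
            "var_b": self.var_b,
            "covariance": self.covariance,
            "z_statistic": self.z_statistic,
            "p_value": self.p_value,
        }


def delong_test(scores_a, scores_b, labels, directions=POSITIVE_IF_GE) -> DeLongResult:
    """DeLong's test for two correlated ROC curves.

    ``scores_a`` and ``scores_b`` are paired measurements on the same epochs
    (same ``labels``); ``directions`` is a single direction applied to both or
    a pair ``(dir_a, dir_b)``.  The z statistic is
    ``(auc_a - auc_b) / sqrt(var_a + var_b - 2 cov)`` with a two-sided normal
    p-value.
    """
    if isinstance(directions, str):
        directions = (directions, directions)
    dir_a, dir_b = directions
    _check_direction(dir_a)
    _check_direction(dir_b)
    scores_a, labels_arr, n_pos, n_neg = _validate(scores_a, labels)
    scores_b, _, _, _ = _validate(scores_b, labels)
    sa = -scores_a if dir_a == POSITIVE_IF_LE else scores_a
    sb = -scores_b if dir_b == POSITIVE_IF_LE else scores_b
    auc_a, v10_a, v01_a = _placements(sa, labels_arr)
    auc_b, v10_b, v01_b = _placements(sb, labels_arr)
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    s = s10 / n_pos + s01 / n_neg
    var_term = s[0, 0] + s[1, 1] - 2 * s[0, 1]
    diff = auc_a - auc_b
    if var_term <= 0 or not np.isfinite(var_term) or np.sqrt(var_term) < 1e-15:
        if abs(diff) < 1e-12:
            z, p = 0.0, 1.0
        else:
            raise DegenerateVarianceError(
                "zero variance of the AUC difference with unequal AUCs"
            )
    else:
        z = diff / np.sqrt(var_term)
        p = 2 * stats.norm.sf(abs(z))
    return DeLongResult(
        auc_a=float(auc_a),
        auc_b=float(auc_b),
        var_a=float(s[0, 0]),
        var_b=float(s[1, 1]),
        covariance=float(s[0, 1]),
        z_statistic=float(z),
        p_value=float(p),
    )
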