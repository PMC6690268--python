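"""ROC curves, AUC, DeLong machinery and cut-point optimizers against
independent oracles."""

from fractions import Fraction

import numpy as np
import pytest

from wristcal import (
    POSITIVE_IF_GE,
    POSITIVE_IF_LE,
    auc,
    auc_ci,
    auc_with_ci,
    confusion_metrics,
    constrained_cutpoint,
    delong_test,
    lpa_band,
    roc_curve,
    youden_cutpoint,
)
from wristcal.errors import (
    CalibrationInconsistencyError,
    DegenerateInputError,
    DegenerateVarianceError,
    DomainError,
)


def brute_force_auc(scores, labels, direction):
    """O(n^2) pairwise probability: concordant + half ties over all pos-neg pairs."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p == n:
                total += 0.5
            elif (p > n) == (direction == POSITIVE_IF_GE):
                total += 1.0
    return total / (len(pos) * len(neg))


def exhaustive_best(scores, labels, direction, max_fpr=None):
    """Exact-rational scan over every observed threshold plus sentinels,
    replicating the documented tie-breaks (higher Se, then strictest)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    n_pos, n_neg = int(labels.sum()), int((1 - labels).sum())
    uniq = sorted(set(scores))
    if direction == POSITIVE_IF_LE:
        sweep = [-np.inf] + uniq + [np.inf]
    else:
        sweep = [np.inf] + uniq[::-1] + [-np.inf]
    best = None
    for t in sweep:
        pred = scores <= t if direction == POSITIVE_IF_LE else scores >= t
        tp = int(np.sum(pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == 0)))
        fpr = Fraction(fp, n_neg)
        if max_fpr is not None and fpr > Fraction(max_fpr).limit_denominator(1000):
            continue
        j = Fraction(tp, n_pos) - fpr
        key = (j, Fraction(tp, n_pos))
        if best is None or key > best[0]:
            best = (key, t)
    return best[1], float(best[0][0])


class TestRocCurve:
    def test_perfect_separation_hits_corner(self):
        curve = roc_curve([10, 20, 30, 40], [1, 1, 0, 0], POSITIVE_IF_LE)
        pts = set(zip(curve.fpr.tolist(), curve.tpr.tolist()))
        assert (0.0, 1.0) in pts
        assert curve.trapezoid_auc() == pytest.approx(1.0)

    def test_endpoints_and_monotone(self, rng):
        scores = rng.integers(0, 50, size=80)
        labels = rng.integers(0, 2, size=80)
        labels[:2] = [0, 1]
        curve = roc_curve(scores, labels, POSITIVE_IF_GE)
        assert curve.tpr[0] == 0 and curve.fpr[0] == 0
        assert curve.tpr[-1] == 1 and curve.fpr[-1] == 1
        assert (np.diff(curve.tpr) >= 0).all() and (np.diff(curve.fpr) >= 0).all()

    def test_tied_scores_collapse_to_one_point(self):
        # hand-enumerated sweep: scores {5:pos,pos,neg; 9:neg}
        curve = roc_curve([5, 5, 5, 9], [1, 1, 0, 0], POSITIVE_IF_LE)
        assert curve.thresholds.tolist() == [-np.inf, 5, 9, np.inf]
        assert curve.tp.tolist() == [0, 2, 2, 2]
        assert curve.fp.tolist() == [0, 1, 2, 2]

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateInputError):
            roc_curve([1, 2, 3], [1, 1, 1], POSITIVE_IF_GE)


class TestAuc:
    def test_reference_values(self):
        assert auc([10, 20, 30, 40], [1, 1, 0, 0], POSITIVE_IF_LE) == 1.0
        assert auc([7, 7, 7, 7], [0, 1, 0, 1], POSITIVE_IF_GE) == 0.5
        # brute force over the 4 pos-neg pairs: 2 concordant, 1 tie-free discordant
        assert auc([1, 2, 3, 4], [0, 1, 0, 1], POSITIVE_IF_GE) == pytest.approx(0.75)

    def test_three_routes_agree_with_ties(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 60))
            scores = rng.integers(0, 12, size=n)  # heavy ties
            labels = rng.integers(0, 2, size=n)
            labels[:2] = [0, 1]
            for direction in (POSITIVE_IF_LE, POSITIVE_IF_GE):
                pairwise = auc(scores, labels, direction)
                trap = roc_curve(scores, labels, direction).trapezoid_auc()
                brute = brute_force_auc(scores, labels, direction)
                np.testing.assert_allclose(pairwise, trap, rtol=1e-12)
                np.testing.assert_allclose(pairwise, brute, rtol=1e-12)

    def test_direction_flip_complements_auc(self, rng):
        scores = rng.permutation(100).astype(float)  # no ties
        labels = rng.integers(0, 2, size=100)
        labels[:2] = [0, 1]
        a_le = auc(scores, labels, POSITIVE_IF_LE)
        a_ge = auc(scores, labels, POSITIVE_IF_GE)
        np.testing.assert_allclose(a_le + a_ge, 1.0, rtol=1e-12)

    def test_sklearn_cross_check(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.integers(0, 30, size=200).astype(float)
        labels = rng.integers(0, 2, size=200)
        labels[:2] = [0, 1]
        np.testing.assert_allclose(
            auc(scores, labels, POSITIVE_IF_GE),
            roc_auc_score(labels, scores),
            rtol=1e-12,
        )


class TestConfusionMetrics:
    def test_hand_counted_table(self):
        # threshold 250, positive if <=: TP=2 FP=0 FN=1 TN=2
        m = confusion_metrics([100, 200, 300, 400, 500], [1, 1, 0, 1, 0], 250, POSITIVE_IF_LE)
        assert m.sensitivity == pytest.approx(66.6667, abs=1e-3)
        assert m.specificity == 100.0
        assert m.accuracy == 80.0
        assert m.ppv == 100.0
        assert m.npv == pytest.approx(66.6667, abs=1e-3)
        assert m.youden_j == pytest.approx(66.6667, abs=1e-3)

    @pytest.mark.parametrize("threshold,se,sp", [(np.inf, 100.0, 0.0), (-np.inf, 0.0, 100.0)])
    def test_sentinels(self, threshold, se, sp):
        m = confusion_metrics([1, 2, 3, 4], [0, 1, 0, 1], threshold, POSITIVE_IF_LE)
        assert (m.sensitivity, m.specificity) == (se, sp)
        assert m.youden_j == 0.0

    def test_undefined_predictive_values_are_missing(self):
        m = confusion_metrics([1, 2, 3, 4], [0, 1, 0, 1], -np.inf, POSITIVE_IF_LE)
        assert m.ppv is None  # no predicted positives, not coerced to 0

    def test_direction_flip_swaps_se_sp(self, rng):
        scores = rng.permutation(40).astype(float)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        t = 17.5  # between observed values, so <= and >= partition cleanly
        m_le = confusion_metrics(scores, labels, t, POSITIVE_IF_LE)
        m_ge = confusion_metrics(scores, 1 - labels, t, POSITIVE_IF_GE)
        assert m_le.sensitivity == pytest.approx(m_ge.specificity)
        assert m_le.specificity == pytest.approx(m_ge.sensitivity)


class TestOptimizers:
    def test_perfect_curve_reaches_j100(self):
        curve = roc_curve([10, 20, 30, 40], [1, 1, 0, 0], POSITIVE_IF_LE)
        best = youden_cutpoint(curve)
        assert best.youden_j == 100.0
        assert best.threshold == 20

    def test_uninformative_curve_j0(self):
        curve = roc_curve([7, 7, 7, 7], [0, 1, 0, 1], POSITIVE_IF_LE)
        assert youden_cutpoint(curve).youden_j == 0.0

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(60):
            n = int(rng.integers(8, 100))
            scores = rng.integers(0, 25, size=n)
            labels = rng.integers(0, 2, size=n)
            labels[:2] = [0, 1]
            for direction in (POSITIVE_IF_LE, POSITIVE_IF_GE):
                curve = roc_curve(scores, labels, direction)
                got = youden_cutpoint(curve)
                want_t, want_j = exhaustive_best(scores, labels, direction)
                assert got.threshold == want_t
                np.testing.assert_allclose(got.youden_j / 100, want_j, atol=1e-12)

    def test_constraint_changes_optimum_when_binding(self):
        # global optimum (threshold 9) sits at fpr 0.2; within fpr <= 0.10
        # threshold 10 wins instead (14-point constructed instance)
        scores = [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 9, 10, 11, 12]
        labels = [0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 1, 1, 1, 1]
        curve = roc_curve(scores, labels, POSITIVE_IF_GE)
        free = youden_cutpoint(curve)
        constrained = constrained_cutpoint(curve, max_fpr=0.10)
        want_t, want_j = exhaustive_best(scores, labels, POSITIVE_IF_GE, max_fpr=0.10)
        assert free.fpr > 0.10  # the constraint really binds
        assert constrained.threshold == want_t
        assert constrained.threshold != free.threshold
        assert constrained.fpr <= 0.10
        assert constrained.youden_j <= free.youden_j

    def test_inactive_constraint_equals_youden(self, rng):
        scores = rng.integers(0, 30, size=60)
        labels = rng.integers(0, 2, size=60)
        labels[:2] = [0, 1]
        curve = roc_curve(scores, labels, POSITIVE_IF_GE)
        free = youden_cutpoint(curve)
        assert constrained_cutpoint(curve, max_fpr=1 - 1e-9).threshold == free.threshold

    def test_only_sentinel_feasible(self):
        # every observed threshold misclassifies the lone negative epoch
        curve = roc_curve([5, 5, 5], [1, 1, 0], POSITIVE_IF_GE)
        m = constrained_cutpoint(curve, max_fpr=0.10)
        assert (m.sensitivity, m.specificity) == (0.0, 100.0)

    def test_constrained_never_beats_unconstrained(self, rng):
        for _ in range(40):
            scores = rng.integers(0, 15, size=50)
            labels = rng.integers(0, 2, size=50)
            labels[:2] = [0, 1]
            curve = roc_curve(scores, labels, POSITIVE_IF_GE)
            assert (
                constrained_cutpoint(curve, 0.10).youden_j
                <= youden_cutpoint(curve).youden_j + 1e-12
            )


class TestLpaBand:
    def test_published_band_shapes(self):
        sb = confusion_metrics([100, 700], [1, 0], 165, POSITIVE_IF_LE)
        mvpa = confusion_metrics([100, 700], [0, 1], 685, POSITIVE_IF_GE)
        assert lpa_band(sb, mvpa) == (165, 685)
        sb2 = confusion_metrics([100, 800], [1, 0], 134, POSITIVE_IF_LE)
        mvpa2 = confusion_metrics([100, 800], [0, 1], 704, POSITIVE_IF_GE)
        assert lpa_band(sb2, mvpa2) == (134, 704)

    def test_ordering_violation(self):
        sb = confusion_metrics([100, 700], [1, 0], 300, POSITIVE_IF_LE)
        mvpa = confusion_metrics([100, 700], [0, 1], 200, POSITIVE_IF_GE)
        with pytest.raises(CalibrationInconsistencyError):
            lpa_band(sb, mvpa)


class TestDeLong:
    def test_self_comparison_is_null(self):
        s = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0])
        labels = np.array([0, 0, 1, 0, 1, 1])
        r = delong_test(s, s, labels)
        assert r.z_statistic == 0.0 and r.p_value == 1.0

    def test_degenerate_variance_with_unequal_aucs(self):
        # constant-difference streams with zero placement spread
        a = np.array([1.0, 1.0, 2.0, 2.0])
        b = np.array([2.0, 2.0, 1.0, 1.0])
        labels = np.array([0, 0, 1, 1])
        with pytest.raises(DegenerateVarianceError):
            delong_test(a, b, labels)

    def test_variance_matches_bootstrap(self, rng):
        n = 60
        signal = rng.normal(size=n)
        labels = (signal + rng.normal(size=n) > 0).astype(int)
        a = signal + rng.normal(scale=0.8, size=n)
        b = signal + rng.normal(scale=0.8, size=n)
        r = delong_test(a, b, labels)
        var_delong = r.var_a + r.var_b - 2 * r.covariance
        diffs = []
        for _ in range(10_000):
            idx = rng.integers(0, n, size=n)
            lab = labels[idx]
            if lab.sum() in (0, n):
                continue
            from wristcal import auc as auc_fn

            diffs.append(
                auc_fn(a[idx], lab, POSITIVE_IF_GE) - auc_fn(b[idx], lab, POSITIVE_IF_GE)
            )
        var_boot = np.var(diffs, ddof=1)
        assert abs(var_delong - var_boot) / var_boot < 0.15

    def test_direction_handling(self, rng):
        scores_a = rng.normal(size=80)
        scores_b = rng.normal(size=80)
        labels = rng.integers(0, 2, size=80)
        labels[:2] = [0, 1]
        r1 = delong_test(scores_a, scores_b, labels, POSITIVE_IF_GE)
        r2 = delong_test(-scores_a, -scores_b, labels, POSITIVE_IF_LE)
        np.testing.assert_allclose(r1.z_statistic, r2.z_statistic, rtol=1e-12)


class TestAucCi:
    def test_hand_arithmetic(self):
        lo, hi = auc_ci(0.5, 0.0025, level=0.95)
        assert lo == pytest.approx(0.402, abs=5e-4)  # 0.5 - 1.95996 * 0.05
        assert hi == pytest.approx(0.598, abs=5e-4)

    def test_degenerate_and_clipped(self):
        assert auc_ci(0.7, 0.0) == (0.7, 0.7)
        assert auc_ci(0.99, 0.01)[1] == 1.0
        with pytest.raises(DomainError):
            auc_ci(0.5, -1e-3)

    def test_result_brackets_estimate(self, rng):
        scores = rng.normal(size=100)
        labels = rng.integers(0, 2, size=100)
        labels[:2] = [0, 1]
        res = auc_with_ci(scores, labels, POSITIVE_IF_GE)
        assert res.ci_low <= res.auc <= res.ci_high
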