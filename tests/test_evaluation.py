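"""Detection matching, PR/AP, kappa and grade-agreement statistics."""

import numpy as np
import pytest

from acnekit.annotations import LesionInstance
from acnekit.codec import Detection
from acnekit.evaluation import (box_iou, cohen_kappa, detection_report,
                                error_recall_curve, f1, grade_agreement_report,
                                match_detections, merge_matches, pr_curve_ap)
from acnekit.grading import Grade


def oracle_ap(outcomes, n_gt):
    """Enumerate recall steps; interpolated precision by scanning all ranks."""
    tp = fp = 0
    points = []
    for ok in outcomes:
        tp += ok
        fp += not ok
        points.append((tp / n_gt, tp / (tp + fp)))
    ap, prev_r = 0.0, 0.0
    for i, (r, _) in enumerate(points):
        if outcomes[i]:
            p_best = max(p for rr, p in points if rr >= r)
            ap += (r - prev_r) * p_best
            prev_r = r
    return ap


class TestMatching:
    def test_single_pair_above_threshold(self):
        preds = [Detection("papule", 0.9, (0, 0, 10, 10))]
        gts = [LesionInstance("papule", box=(2, 0, 10, 10))]  # IoU = 8/12
        m = match_detections(preds, gts, iou_min=0.5)
        assert m.tallies("papule") == (1, 0, 0)

    def test_low_iou_pair_not_matched(self):
        # boxes (0,0,2,2) and (1,1,2,2): inter 1, union 7
        assert box_iou((0, 0, 2, 2), (1, 1, 2, 2)) == pytest.approx(1 / 7)
        preds = [Detection("papule", 0.9, (0, 0, 2, 2))]
        gts = [LesionInstance("papule", box=(1, 1, 2, 2))]
        m = match_detections(preds, gts, iou_min=0.5)
        assert m.tallies("papule") == (0, 1, 1)

    def test_no_predictions_all_missed(self):
        gts = [LesionInstance("comedone", box=(i * 10, 0, 4, 4)) for i in range(3)]
        m = match_detections([], gts)
        assert m.tallies("comedone") == (0, 0, 3)

    def test_each_gt_matched_at_most_once(self):
        gts = [LesionInstance("papule", box=(0, 0, 10, 10))]
        preds = [Detection("papule", 0.9, (0, 0, 10, 10)),
                 Detection("papule", 0.8, (1, 0, 10, 10))]
        m = match_detections(preds, gts)
        tp, fp, fn = m.tallies("papule")
        assert (tp, fp, fn) == (1, 1, 0)

    def test_higher_score_matches_first(self):
        gts = [LesionInstance("papule", box=(0, 0, 10, 10))]
        preds = [Detection("papule", 0.5, (2, 2, 10, 10)),
                 Detection("papule", 0.9, (0, 0, 10, 10))]
        m = match_detections(preds, gts)
        flags = sorted(m.flags["papule"], key=lambda t: -t[0])
        assert flags[0] == (0.9, True) and flags[1][1] is False

    def test_classes_do_not_cross_match(self):
        preds = [Detection("papule", 0.9, (0, 0, 10, 10))]
        gts = [LesionInstance("pustule", box=(0, 0, 10, 10))]
        m = match_detections(preds, gts)
        assert m.tallies("papule") == (0, 1, 0)
        assert m.tallies("pustule") == (0, 0, 1)


class TestPRCurveAP:
    def test_perfect_single_detection(self):
        _, _, ap, max_recall = pr_curve_ap([(0.9, True)], n_gt=1)
        assert ap == 1.0 and max_recall == 1.0

    def test_hand_walked_tp_fp_tp(self):
        flags = [(0.9, True), (0.8, False), (0.7, True)]
        _, _, ap, _ = pr_curve_ap(flags, n_gt=2)
        assert ap == pytest.approx(0.5 * 1.0 + 0.5 * (2 / 3))

    def test_matches_oracle_on_random_rankings(self):
        rng = np.random.default_rng(77)
        for _ in range(50):
            n = int(rng.integers(1, 20))
            outcomes = (rng.uniform(size=n) < 0.6).tolist()
            n_gt = sum(outcomes) + int(rng.integers(0, 5))
            if n_gt == 0:
                continue
            flags = [(1.0 - i * 1e-3, ok) for i, ok in enumerate(outcomes)]
            _, _, ap, _ = pr_curve_ap(flags, n_gt)
            assert ap == pytest.approx(oracle_ap(outcomes, n_gt), abs=1e-9)

    def test_no_gt_with_predictions_flagged_nan(self):
        _, _, ap, _ = pr_curve_ap([(0.9, False)], n_gt=0)
        assert np.isnan(ap)

    def test_ap_bounds_and_perfect_ordering(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n_tp = int(rng.integers(1, 6))
            n_fp = int(rng.integers(0, 6))
            perfect = [(1.0 - i * 1e-3, True) for i in range(n_tp)] + \
                      [(0.5 - i * 1e-3, False) for i in range(n_fp)]
            _, _, ap, _ = pr_curve_ap(perfect, n_gt=n_tp)
            assert ap == 1.0  # every GT matched before any FP
            mixed = [(1.0, False)] + [(0.9 - i * 1e-3, True) for i in range(n_tp)]
            _, _, ap2, _ = pr_curve_ap(mixed, n_gt=n_tp)
            assert 0.0 <= ap2 < 1.0


class TestErrorRecall:
    def test_perfect_ranking_zero_error(self):
        err, _ = error_recall_curve([(0.9, True), (0.8, True)], n_gt=2)
        assert np.allclose(err, 0.0)

    def test_hand_walked_fp_then_tp(self):
        err, rec = error_recall_curve([(0.9, False), (0.8, True)], n_gt=1)
        assert err.tolist() == [1.0, 0.5]
        assert rec.tolist() == [0.0, 1.0]

    def test_identity_with_precision(self):
        flags = [(0.9, True), (0.8, False), (0.7, True)]
        prec, _, _, _ = pr_curve_ap(flags, n_gt=3)
        err, _ = error_recall_curve(flags, n_gt=3)
        assert np.allclose(err, 1.0 - prec)


class TestF1:
    @pytest.mark.parametrize("p,r,want", [(1.0, 1.0, 1.0),
                                          (0.5, 1.0, 2 / 3),
                                          (0.0, 0.0, 0.0)])
    def test_values(self, p, r, want):
        assert f1(p, r) == pytest.approx(want)


class TestKappa:
    def test_identical_labelings(self):
        assert cohen_kappa([1, 2, 3, 1], [1, 2, 3, 1]) == 1.0

    def test_hand_example(self):
        # p_o = 0.75, p_e = 0.5 -> kappa = 0.5
        assert cohen_kappa([1, 1, 2, 2], [1, 2, 2, 2]) == pytest.approx(0.5)

    def test_relabeling_invariance(self):
        a, b = [0, 0, 1, 2, 2, 1], [0, 1, 1, 2, 0, 1]
        relabel = {0: "x", 1: "y", 2: "z"}
        assert cohen_kappa(a, b) == pytest.approx(
            cohen_kappa([relabel[v] for v in a], [relabel[v] for v in b]))

    def test_near_zero_for_independent_labels(self):
        rng = np.random.default_rng(99)
        a = rng.integers(0, 5, 10000).tolist()
        b = rng.integers(0, 5, 10000).tolist()
        assert abs(cohen_kappa(a, b)) < 0.05

    def test_matches_sklearn(self):
        from sklearn.metrics import cohen_kappa_score
        rng = np.random.default_rng(3)
        a = rng.integers(0, 4, 200).tolist()
        b = rng.integers(0, 4, 200).tolist()
        assert cohen_kappa(a, b) == pytest.approx(cohen_kappa_score(a, b))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cohen_kappa([1], [1, 2])


class TestGradeAgreement:
    def test_perfect_predictions(self):
        grades = [Grade.I, Grade.II, Grade.III, Grade.IV]
        rep = grade_agreement_report(grades, grades)
        assert rep["accuracy"] == 1.0 and rep["kappa"] == 1.0
        cm = rep["confusion_matrix"]
        assert np.trace(cm) == 4 and cm.sum() == 4

    def test_downgrade_fraction(self):
        rep = grade_agreement_report([Grade.I, Grade.III],
                                     [Grade.II, Grade.III])
        assert rep["accuracy"] == 0.5
        assert rep["downgrade_fraction"] == 1.0

    def test_cross_grade_fraction(self):
        rep = grade_agreement_report([Grade.I, Grade.IV],
                                     [Grade.III, Grade.IV])
        assert rep["cross_grade_fraction"] == 0.5

    def test_marginals_match_label_histograms(self):
        rng = np.random.default_rng(8)
        pred = [Grade(int(v)) for v in rng.integers(0, 5, 60)]
        ref = [Grade(int(v)) for v in rng.integers(0, 5, 60)]
        cm = grade_agreement_report(pred, ref)["confusion_matrix"]
        for g in range(5):
            assert cm[g].sum() == sum(1 for r in ref if int(r) == g)
            assert cm[:, g].sum() == sum(1 for p in pred if int(p) == g)

    def test_sensitivity_specificity_one_vs_rest_oracle(self):
        # hand-built 3-grade problem embedded in the 5×5 matrix
        pred = [Grade.I] * 5 + [Grade.II] * 3 + [Grade.I, Grade.III]
        ref = [Grade.I] * 4 + [Grade.II] * 4 + [Grade.III] * 2
        rep = grade_agreement_report(pred, ref)
        for g in (Grade.I, Grade.II, Grade.III):
            tp = sum(1 for p, r in zip(pred, ref) if p == g and r == g)
            fn = sum(1 for p, r in zip(pred, ref) if p != g and r == g)
            fp = sum(1 for p, r in zip(pred, ref) if p == g and r != g)
            tn = len(ref) - tp - fn - fp
            assert rep["per_grade"][g.name]["sensitivity"] == pytest.approx(
                tp / (tp + fn))
            assert rep["per_grade"][g.name]["specificity"] == pytest.approx(
                tn / (tn + fp))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            grade_agreement_report([], [])


def test_detection_report_aggregates_images():
    gts1 = [LesionInstance("papule", box=(0, 0, 10, 10))]
    gts2 = [LesionInstance("papule", box=(20, 20, 10, 10))]
    m1 = match_detections([Detection("papule", 0.9, (0, 0, 10, 10))], gts1)
    m2 = match_detections([Detection("papule", 0.8, (40, 40, 10, 10))], gts2)
    rep = detection_report(merge_matches([m1, m2]))
    row = rep["papule"]
    assert (row["tp"], row["fp"], row["fn"]) == (1, 1, 1)
    assert row["precision"] == 0.5 and row["recall"] == 0.5
    assert row["accuracy"] == pytest.approx(1 / 3)  # TP/(TP+FP+FN)
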