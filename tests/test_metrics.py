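"""Evaluation metrics: IoU, AP, landmark error, pair protocol, accounting."""

import math

import numpy as np
import pytest

from wildface import (
    BoxRect,
    LandmarkSet,
    ScoredBox,
    box_iou,
    confusion_and_accuracy,
    detection_pr_ap,
    landmark_normalized_error,
    make_verification_pairs,
    pipeline_accounting,
    positive_pair_budget,
    verification_metrics,
)
from wildface.annotations import AnnotationError, LANDMARK_NAMES


class TestBoxIou:
    def test_identical_boxes(self):
        b = BoxRect(3, 4, 10, 12)
        assert box_iou(b, b) == 1.0

    def test_disjoint_boxes(self):
        assert box_iou(BoxRect(0, 0, 5, 5), BoxRect(10, 10, 5, 5)) == 0.0

    def test_half_overlap_arithmetic(self):
        assert box_iou(BoxRect(0, 0, 10, 10), BoxRect(5, 0, 10, 10)) == pytest.approx(1 / 3)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_pixel_set_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a = BoxRect(*map(int, rng.integers(0, 15, 2)), *map(int, rng.integers(1, 15, 2)))
        b = BoxRect(*map(int, rng.integers(0, 15, 2)), *map(int, rng.integers(1, 15, 2)))
        sa = {(x, y) for x in range(a.left, a.right) for y in range(a.top, a.bottom)}
        sb = {(x, y) for x in range(b.left, b.right) for y in range(b.top, b.bottom)}
        expected = len(sa & sb) / len(sa | sb)
        assert box_iou(a, b) == pytest.approx(expected)


def ap_brute_force(tp_flags, n_truth):
    """Independent all-point interpolation oracle by prefix enumeration."""
    prefixes = []
    tp = 0
    for k, f in enumerate(tp_flags, start=1):
        tp += f
        prefixes.append((tp / n_truth, tp / k))
    ap, prev_r = 0.0, 0.0
    for r, _ in prefixes:
        if r <= prev_r:
            continue
        p_interp = max(p for rr, p in prefixes if rr >= r)
        ap += (r - prev_r) * p_interp
        prev_r = r
    return ap


class TestDetectionPrAp:
    def _one_image(self, ranked_ious, truths_n):
        truths = [[BoxRect(100 * i, 0, 50, 50) for i in range(truths_n)]]
        preds = [[]]
        for rank, (iou_target, truth_i) in enumerate(ranked_ious):
            if iou_target >= 0.5:
                preds[0].append(ScoredBox(truths[0][truth_i], 1.0 - 0.01 * rank))
            else:
                preds[0].append(ScoredBox(BoxRect(0, 1000 + 60 * rank, 50, 50), 1.0 - 0.01 * rank))
        return preds, truths

    def test_perfect_detection(self):
        preds, truths = self._one_image([(1.0, 0), (1.0, 1)], 2)
        m = detection_pr_ap(preds, truths)
        assert (m.precision, m.recall, m.average_precision) == (1.0, 1.0, 1.0)

    def test_no_predictions(self):
        m = detection_pr_ap([[]], [[BoxRect(0, 0, 10, 10)]])
        assert m.recall == 0.0 and m.average_precision == 0.0

    def test_hand_computed_interpolated_ap(self):
        # ranked [TP, FP, TP] over 2 truths: AP = 1 * 0.5 + (2/3) * 0.5
        preds, truths = self._one_image([(1.0, 0), (0.0, 0), (1.0, 1)], 2)
        m = detection_pr_ap(preds, truths)
        assert m.average_precision == pytest.approx(1 * 0.5 + (2 / 3) * 0.5)

    def test_no_truth_no_predictions_flagged(self):
        m = detection_pr_ap([[]], [[]])
        assert m.average_precision == 1.0 and m.degenerate

    def test_truth_matched_at_most_once(self):
        t = BoxRect(0, 0, 50, 50)
        preds = [[ScoredBox(t, 0.9), ScoredBox(t, 0.8)]]
        m = detection_pr_ap(preds, [[t]])
        assert m.recall == 1.0 and m.precision == 0.5

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_enumeration_oracle_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n_img = int(rng.integers(2, 6))
        preds, truths = [], []
        for _ in range(n_img):
            truths.append(
                [BoxRect(int(rng.integers(0, 200)), int(rng.integers(0, 200)), 30, 30)
                 for _ in range(int(rng.integers(0, 4)))]
            )
            img_preds = []
            for _ in range(int(rng.integers(0, 10))):
                if truths[-1] and rng.random() < 0.5:
                    t = truths[-1][int(rng.integers(len(truths[-1])))]
                    r = BoxRect(t.left + int(rng.integers(-5, 6)), t.top + int(rng.integers(-5, 6)),
                                30, 30)
                else:
                    r = BoxRect(int(rng.integers(300, 600)), int(rng.integers(300, 600)), 30, 30)
                img_preds.append(ScoredBox(r, float(rng.normal())))
            preds.append(img_preds)
        n_truth = sum(len(t) for t in truths)
        if n_truth == 0:
            return
        m = detection_pr_ap(preds, truths)
        # reconstruct the greedy TP flags independently, then compare AP
        pooled = sorted(
            ((sb.score, i, sb) for i, sbs in enumerate(preds) for sb in sbs),
            key=lambda t: -t[0],
        )
        used = [set() for _ in truths]
        flags = []
        for score, i, sb in pooled:
            cands = [
                (box_iou(sb.rect, t), j)
                for j, t in enumerate(truths[i])
                if j not in used[i] and box_iou(sb.rect, t) >= 0.5
            ]
            if cands:
                best = max(cands, key=lambda c: (c[0], -c[1]))
                used[i].add(best[1])
                flags.append(True)
            else:
                flags.append(False)
        if flags:
            assert m.average_precision == pytest.approx(ap_brute_force(flags, n_truth))


class TestLandmarkError:
    def _lm(self, offset=0.0):
        pts = {n: (10.0 * i + offset, 5.0 * i) for i, n in enumerate(LANDMARK_NAMES)}
        return LandmarkSet(pts)

    def test_perfect_prediction_zero(self):
        lm = self._lm()
        assert landmark_normalized_error(lm, lm) == 0.0

    def test_unit_interocular_displacement(self):
        truth = self._lm()
        io = truth.interocular()
        pred = LandmarkSet({n: (x + io, y) for n, (x, y) in truth.points.items()})
        assert landmark_normalized_error(pred, truth) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_case_matches_hand_computation(self, seed):
        rng = np.random.default_rng(seed)
        truth = self._lm()
        pred_pts = {n: (x + rng.normal(), y + rng.normal()) for n, (x, y) in truth.points.items()}
        pred = LandmarkSet(pred_pts)
        io = math.dist(truth["leye"], truth["reye"])
        expected = np.mean([math.dist(pred[n], truth[n]) / io for n in LANDMARK_NAMES])
        assert landmark_normalized_error(pred, truth) == pytest.approx(expected)


class TestPairBudget:
    def test_published_budget(self):
        assert positive_pair_budget(8, 115) == 3220

    def test_fractional_mean_rounds(self):
        assert positive_pair_budget(8.12, 115) == 3220

    def test_minimal_case(self):
        assert positive_pair_budget(2, 1) == 1

    def test_matches_exhaustive_enumeration(self):
        n, m = 4, 10
        pairs = [(a, b) for a in range(n) for b in range(a + 1, n)]
        assert positive_pair_budget(n, m) == len(pairs) * m

    def test_too_few_chips_rejected(self):
        with pytest.raises(AnnotationError):
            positive_pair_budget(1, 10)


class TestVerificationPairs:
    def test_balanced_unique_non_self(self):
        rng = np.random.default_rng(0)
        labels = [f"id{i}" for i in range(20) for _ in range(8)]
        ps = make_verification_pairs(labels, n_pos=300, n_neg=300, rng=rng)
        assert ps.n_pos == 300 and ps.n_neg == 300
        seen = set()
        for i, j, same in ps.pairs:
            assert i != j
            key = (min(i, j), max(i, j))
            assert key not in seen
            seen.add(key)
            assert same == (labels[i] == labels[j])

    def test_single_possible_pair(self):
        ps = make_verification_pairs(["a", "a"], n_pos=1, n_neg=0, rng=np.random.default_rng(0))
        assert ps.pairs == [(0, 1, True)]

    def test_over_budget_reports_available(self):
        with pytest.raises(AnnotationError, match="only 1"):
            make_verification_pairs(["a", "a", "b"], n_pos=2, n_neg=1)

    def test_seed_determinism(self):
        labels = [f"id{i}" for i in range(10) for _ in range(5)]
        a = make_verification_pairs(labels, 50, 50, np.random.default_rng(4))
        b = make_verification_pairs(labels, 50, 50, np.random.default_rng(4))
        assert a.pairs == b.pairs


class TestVerificationMetrics:
    def test_perfect_separation(self):
        labels = ["a"] * 4 + ["b"] * 4
        ps = make_verification_pairs(labels, 6, 6, np.random.default_rng(0))
        d = np.array([0.1 if s else 0.9 for _, _, s in ps.pairs])
        m = verification_metrics(ps, d)
        assert m.accuracy == 1.0 and 0.1 < m.threshold < 0.9

    def test_accuracy_formula(self):
        # TPR 0.9, TNR 0.7 at a fixed threshold -> accuracy 0.8
        labels = ["a"] * 5 + ["b"] * 5
        ps = make_verification_pairs(labels, 10, 10, np.random.default_rng(1))
        d = np.empty(20)
        pos = [k for k, (_, _, s) in enumerate(ps.pairs) if s]
        neg = [k for k, (_, _, s) in enumerate(ps.pairs) if not s]
        for idx, k in enumerate(pos):
            d[k] = 0.1 if idx < 9 else 0.9  # 9/10 below threshold
        for idx, k in enumerate(neg):
            d[k] = 0.9 if idx < 7 else 0.1  # 7/10 above threshold
        m = verification_metrics(ps, d, thresholds=np.array([0.5]))
        assert (m.tpr, m.tnr) == (0.9, 0.7)
        assert m.accuracy == pytest.approx(0.8)

    def test_reduces_to_proportion_correct_when_rates_equal(self):
        labels = ["a"] * 4 + ["b"] * 4
        ps = make_verification_pairs(labels, 6, 6, np.random.default_rng(2))
        d = np.array([0.2 if s else 0.8 for _, _, s in ps.pairs])
        m = verification_metrics(ps, d, thresholds=np.array([0.5]))
        assert m.accuracy == 1.0 == m.tpr == m.tnr

    def test_permutation_null_near_half(self):
        rng = np.random.default_rng(3)
        labels = [f"id{i}" for i in range(40) for _ in range(13)]
        ps = make_verification_pairs(labels, 3000, 3000, rng)
        E = rng.normal(size=(len(labels), 16))  # labels carry no signal
        d = np.linalg.norm(E[[i for i, _, _ in ps.pairs]] - E[[j for _, j, _ in ps.pairs]], axis=1)
        m = verification_metrics(ps, d)
        assert abs(m.accuracy - 0.5) <= 0.05

    def test_empty_class_rejected(self):
        from wildface.metrics import PairSet

        with pytest.raises(AnnotationError):
            verification_metrics(PairSet([(0, 1, True)]), np.array([0.2]))

    def test_fold_summary_mean_sd(self):
        from wildface import verification_fold_summary
        from wildface.metrics import VerificationMetrics

        folds = [VerificationMetrics(1, 1, a, 0.5) for a in (0.8, 0.9, 1.0)]
        mean, sd = verification_fold_summary(folds)
        assert mean == pytest.approx(0.9)
        assert sd == pytest.approx(np.std([0.8, 0.9, 1.0]))


TABLE_STYLE_CONFUSION = {
    # true label -> list of (predicted label, count); one published-style row
    "Bella": [("Bella", 7), ("Lenore", 4)],
    "Lenore": [("Lenore", 11), ("Frank", 2)],
    "Frank": [("Frank", 4)],
}


class TestConfusionReport:
    def _lists(self, table):
        pred, true = [], []
        for t, row in table.items():
            for p, c in row:
                pred.extend([p] * c)
                true.extend([t] * c)
        return pred, true

    def test_row_percentages(self):
        pred, true = self._lists(TABLE_STYLE_CONFUSION)
        rep = confusion_and_accuracy(pred, true, {"Bella", "Lenore", "Frank"})
        assert rep.per_class_percent["Bella"] == 63.64
        assert rep.per_class_percent["Lenore"] == 84.62
        assert rep.per_class_percent["Frank"] == 100.0

    def test_all_correct(self):
        rep = confusion_and_accuracy(["a", "b"], ["a", "b"], {"a", "b"})
        assert rep.overall_accuracy == 1.0
        assert all(v == 100.0 for v in rep.per_class_percent.values())

    def test_unseen_label_exclusion_and_overall(self):
        # 932 classifiable with 782 correct -> 83.9%; 2 excluded
        pred = ["x"] * 782 + ["wrong"] * 150 + ["x", "x"]
        true = ["x"] * 782 + ["x"] * 150 + ["ghost1", "ghost2"]
        rep = confusion_and_accuracy(pred, true, {"x", "wrong"})
        assert rep.n_classifiable == 932 and rep.n_excluded == 2
        assert round(100 * rep.overall_accuracy, 1) == 83.9

    def test_row_sums_reconcile(self):
        pred, true = self._lists(TABLE_STYLE_CONFUSION)
        rep = confusion_and_accuracy(pred, true, set(true))
        for lab in ("Bella", "Lenore", "Frank"):
            i = rep.labels.index(lab)
            assert rep.matrix[i].sum() == sum(c for _, c in TABLE_STYLE_CONFUSION[lab])
        assert rep.n_classifiable + rep.n_excluded == len(true)

    def test_mean_percent_is_unweighted(self):
        pred, true = self._lists(TABLE_STYLE_CONFUSION)
        rep = confusion_and_accuracy(pred, true, set(true))
        assert rep.mean_percent == pytest.approx(round((63.64 + 84.62 + 100.0) / 3, 2))


class TestPipelineAccounting:
    def test_embedding_count_includes_extras(self):
        t = BoxRect(0, 0, 60, 60)
        dets_ok = [ScoredBox(t, 0.9)]
        dets_extra = [ScoredBox(t, 0.9), ScoredBox(BoxRect(200, 200, 60, 60), 0.6)]
        detections = [dets_extra, dets_extra] + [dets_ok] * 2 + [[]]
        truths = [[t]] * 5
        acc = pipeline_accounting(detections, truths, ["a"] * 5, ["a"] * 5, {"a"})
        assert acc.correct_faces == 4 and acc.extra_faces == 2
        assert acc.embeddings == 6
        assert acc.source_images == 5

    def test_perfect_run(self):
        t = BoxRect(0, 0, 60, 60)
        acc = pipeline_accounting(
            [[ScoredBox(t, 1.0)]] * 3, [[t]] * 3, ["a", "b", "a"], ["a", "b", "a"], {"a", "b"}
        )
        assert acc.detection_accuracy == 1.0 and acc.end_to_end_accuracy == 1.0

    def test_end_to_end_bounded_by_classifier_accuracy(self):
        # detection drops two images the classifier would have gotten right,
        # so cumulative accuracy cannot exceed classifier-only accuracy
        t = BoxRect(0, 0, 60, 60)
        n = 10
        pred = ["a"] * 8 + ["b"] * 2
        true = ["a"] * n
        dets = [[] if i < 2 else [ScoredBox(t, 1.0)] for i in range(n)]
        acc = pipeline_accounting(dets, [[t]] * n, pred, true, {"a", "b"})
        classifier_only = np.mean([p == t_ for p, t_ in zip(pred, true)])
        assert acc.end_to_end_accuracy == pytest.approx(6 / 8)
        assert acc.end_to_end_accuracy <= classifier_only + 1e-9
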