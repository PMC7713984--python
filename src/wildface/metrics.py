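"""Evaluation metrics and protocols.

Covers detection precision/recall and interpolated average precision at an
IoU threshold, interocular-normalized landmark error, the balanced
matched/unmatched verification-pair protocol with its TPR/TNR accuracy
formula, identity confusion reporting with the unseen-label exclusion rule,
and end-to-end pipeline accounting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .annotations import AnnotationError, BoxRect, LANDMARK_NAMES, LandmarkSet
from .detection import ScoredBox


# ---------------------------------------------------------------------------
# Detection


def box_iou(a: BoxRect, b: BoxRect) -> float:
    """Intersection over union on the half-open pixel sets of two boxes."""
    iw = max(0, min(a.right, b.right) - max(a.left, b.left))
    ih = max(0, min(a.bottom, b.bottom) - max(a.top, b.top))
    inter = iw * ih
    if inter == 0:
        return 0.0
    return inter / (a.area + b.area - inter)


@dataclass
class DetectionMetrics:
    precision: float
    recall: float
    average_precision: float
    iou_threshold: float = 0.5
    n_truth: int = 0
    n_predictions: int = 0
    degenerate: bool = False


def detection_pr_ap(
    predictions: list[list[ScoredBox]],
    truths: list[list[BoxRect]],
    iou_threshold: float = 0.5,
) -> DetectionMetrics:
    """Precision, recall and all-point interpolated AP over a detection run.

    Predictions are pooled across images and ranked by score; each is matched
    greedily to the highest-IoU unmatched truth in its image (IoU >= the
    threshold, ties to the first truth index).  AP is the area under the
    precision-recall curve after replacing precision at recall r by the
    maximum precision at any recall >= r.
    """
    if len(predictions) != len(truths):
        raise AnnotationError("predictions and truths must align per image")
    n_truth = sum(len(t) for t in truths)
    pooled = [
        (sb.score, img_i, sb)
        for img_i, sbs in enumerate(predictions)
        for sb in sbs
    ]
    if n_truth == 0 and not pooled:
        return DetectionMetrics(1.0, 1.0, 1.0, iou_threshold, 0, 0, degenerate=True)
    order = sorted(range(len(pooled)), key=lambda i: (-pooled[i][0], i))
    matched: list[set[int]] = [set() for _ in truths]
    tp_flags = []
    for i in order:
        _, img_i, sb = pooled[i]
        best, best_iou = None, iou_threshold
        for j, t in enumerate(truths[img_i]):
            if j in matched[img_i]:
                continue
            v = box_iou(sb.rect, t)
            if v >= best_iou and (best is None or v > best_iou):
                best, best_iou = j, v
        if best is not None:
            matched[img_i].add(best)
            tp_flags.append(True)
        else:
            tp_flags.append(False)
    if not tp_flags:
        return DetectionMetrics(1.0, 0.0, 0.0, iou_threshold, n_truth, 0)
    tp = np.cumsum(tp_flags)
    fp = np.cumsum([not f for f in tp_flags])
    recalls = tp / max(1, n_truth)
    precisions = tp / (tp + fp)
    # all-point interpolation: monotone non-increasing precision envelope
    env = np.maximum.accumulate(precisions[::-1])[::-1]
    ap = 0.0
    prev_r = 0.0
    for r, p in zip(recalls, env):
        if r > prev_r:
            ap += (r - prev_r) * p
            prev_r = r
    return DetectionMetrics(
        precision=float(precisions[-1]),
        recall=float(recalls[-1]),
        average_precision=float(ap),
        iou_threshold=iou_threshold,
        n_truth=n_truth,
        n_predictions=len(tp_flags),
    )


# ---------------------------------------------------------------------------
# Landmarks


def landmark_normalized_error(pred: LandmarkSet, truth: LandmarkSet) -> float:
    """Mean over the 6 landmarks of pixel distance / interocular(truth)."""
    io = truth.interocular()
    if io <= 0:
        raise AnnotationError("truth interocular distance is zero")
    dists = [
        math.dist(pred[n], truth[n]) / io
        for n in LANDMARK_NAMES
    ]
    return float(np.mean(dists))


def landmark_error_report(preds: list[LandmarkSet], truths: list[LandmarkSet]) -> tuple[float, float]:
    """Dataset-level mean +/- SD of the normalized landmark error."""
    errs = [landmark_normalized_error(p, t) for p, t in zip(preds, truths)]
    return float(np.mean(errs)), float(np.std(errs))


# ---------------------------------------------------------------------------
# Verification protocol


def positive_pair_budget(n: float, m: int) -> int:
    """Number of same-identity pairs: C(n, 2) x m identities.

    A fractional mean chips-per-identity is rounded to the nearest integer
    (8.12 average chips over 115 identities gives 28 x 115 = 3,220).
    """
    n_int = int(round(n))
    if n_int < 2:
        raise AnnotationError("need at least 2 chips per identity")
    if m < 1:
        raise AnnotationError("need at least 1 identity")
    return math.comb(n_int, 2) * m


@dataclass
class PairSet:
    """Balanced unique verification pairs over chip indices."""

    pairs: list[tuple[int, int, bool]]  # (i, j, same_flag) with i < j

    @property
    def n_pos(self) -> int:
        return sum(1 for _, _, s in self.pairs if s)

    @property
    def n_neg(self) -> int:
        return sum(1 for _, _, s in self.pairs if not s)


def make_verification_pairs(
    labels: list[str],
    n_pos: int = 3000,
    n_neg: int = 3000,
    rng: np.random.Generator | None = None,
) -> PairSet:
    """Sample unique matched and unmatched chip pairs, uniformly without
    replacement over all eligible pairs; no chip is paired with itself."""
    rng = rng if rng is not None else np.random.default_rng(0)
    labels = list(labels)
    n = len(labels)
    by_label: dict[str, list[int]] = {}
    for i, lab in enumerate(labels):
        by_label.setdefault(lab, []).append(i)
    pos_all = [
        (idx[a], idx[b])
        for idx in by_label.values()
        for a in range(len(idx))
        for b in range(a + 1, len(idx))
    ]
    if n_pos > len(pos_all):
        raise AnnotationError(
            f"requested {n_pos} matched pairs but only {len(pos_all)} exist"
        )
    total_pairs = n * (n - 1) // 2
    n_neg_avail = total_pairs - len(pos_all)
    if n_neg > n_neg_avail:
        raise AnnotationError(
            f"requested {n_neg} unmatched pairs but only {n_neg_avail} exist"
        )
    chosen_pos = [pos_all[i] for i in rng.choice(len(pos_all), size=n_pos, replace=False)]
    pairs = [(min(i, j), max(i, j), True) for i, j in chosen_pos]
    # negatives: rejection-sample when sparse, enumerate when dense
    neg: set[tuple[int, int]] = set()
    if n_neg > 0:
        if n_neg > 0.4 * n_neg_avail:
            all_neg = [
                (i, j)
                for i in range(n)
                for j in range(i + 1, n)
                if labels[i] != labels[j]
            ]
            idx = rng.choice(len(all_neg), size=n_neg, replace=False)
            neg = {all_neg[i] for i in idx}
        else:
            while len(neg) < n_neg:
                i, j = rng.integers(0, n, size=2)
                if i == j or labels[i] == labels[j]:
                    continue
                neg.add((min(int(i), int(j)), max(int(i), int(j))))
    pairs.extend((i, j, False) for i, j in sorted(neg))
    return PairSet(pairs=pairs)


@dataclass
class VerificationMetrics:
    tpr: float
    tnr: float
    accuracy: float
    threshold: float
    roc: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))  # (FPR, TPR)


def verification_metrics(
    pairset: PairSet,
    distances: np.ndarray,
    thresholds: np.ndarray | None = None,
) -> VerificationMetrics:
    """Sweep thresholds over pair distances; a pair matches iff d < threshold.

    Accuracy is the class-balanced (TPR x 0.5) + (TNR x 0.5); the reported
    operating point is the sweep's accuracy maximizer, and ``roc`` holds the
    (1 - TNR, TPR) curve.
    """
    distances = np.asarray(distances, dtype=float)
    if len(distances) != len(pairset.pairs):
        raise AnnotationError("one distance per pair required")
    same = np.array([s for _, _, s in pairset.pairs], dtype=bool)
    if not same.any() or same.all():
        raise AnnotationError("verification needs both matched and unmatched pairs")
    if thresholds is None:
        uniq = np.unique(distances)
        mids = (uniq[:-1] + uniq[1:]) / 2.0
        thresholds = np.concatenate([[uniq[0] - 1e-9], mids, [uniq[-1] + 1e-9]])
    rows = []
    for thr in np.asarray(thresholds, dtype=float):
        match = distances < thr
        tpr = float(match[same].mean())
        tnr = float((~match[~same]).mean())
        rows.append((thr, tpr, tnr, 0.5 * tpr + 0.5 * tnr))
    best = max(rows, key=lambda r: r[3])
    roc = np.array([(1.0 - tnr, tpr) for _, tpr, tnr, _ in rows])
    return VerificationMetrics(tpr=best[1], tnr=best[2], accuracy=best[3], threshold=best[0], roc=roc)


def verification_fold_summary(fold_metrics: list[VerificationMetrics]) -> tuple[float, float]:
    """Mean and SD of balanced verification accuracy across k folds."""
    if not fold_metrics:
        raise AnnotationError("no folds to summarize")
    accs = [m.accuracy for m in fold_metrics]
    return float(np.mean(accs)), float(np.std(accs))


def accuracy_at_threshold(pairset: PairSet, distances: np.ndarray, threshold: float) -> float:
    """Balanced verification accuracy at a fixed decision threshold."""
    m = verification_metrics(pairset, distances, thresholds=np.array([threshold]))
    return m.accuracy


# ---------------------------------------------------------------------------
# Classification accounting


@dataclass
class ConfusionReport:
    labels: list[str]
    matrix: np.ndarray  # K x K counts, rows = true, cols = predicted
    per_class_percent: dict[str, float]
    mean_percent: float
    overall_accuracy: float
    n_classifiable: int
    n_excluded: int


def confusion_and_accuracy(
    predicted: list[str],
    true: list[str],
    training_labels: set[str] | list[str],
) -> ConfusionReport:
    """Confusion matrix and accuracy with the unseen-label exclusion rule.

    Test items whose true identity never appears in training cannot be
    classified by a closed-set model; they are excluded and counted.  Overall
    accuracy is correct / classifiable; per-class percent correct is the row
    diagonal over the row sum (2 decimals); the mean percent is the
    unweighted mean over classes present in the test set.
    """
    if len(predicted) != len(true):
        raise AnnotationError("predicted and true labels must align")
    training_labels = set(training_labels)
    keep = [i for i, t in enumerate(true) if t in training_labels]
    n_excluded = len(true) - len(keep)
    if not keep:
        raise AnnotationError("no classifiable test items")
    t_kept = [true[i] for i in keep]
    p_kept = [predicted[i] for i in keep]
    labels = sorted(set(t_kept) | set(p_kept))
    index = {lab: i for i, lab in enumerate(labels)}
    K = len(labels)
    mat = np.zeros((K, K), dtype=int)
    for t, p in zip(t_kept, p_kept):
        mat[index[t], index[p]] += 1
    per_class = {}
    for lab in labels:
        row = mat[index[lab]]
        total = row.sum()
        if total > 0:
            per_class[lab] = round(100.0 * row[index[lab]] / total, 2)
    mean_percent = round(float(np.mean(list(per_class.values()))), 2)
    overall = float(np.trace(mat)) / len(keep)
    return ConfusionReport(
        labels=labels,
        matrix=mat,
        per_class_percent=per_class,
        mean_percent=mean_percent,
        overall_accuracy=overall,
        n_classifiable=len(keep),
        n_excluded=n_excluded,
    )


# ---------------------------------------------------------------------------
# Pipeline accounting


@dataclass
class PipelineAccounting:
    source_images: int
    correct_faces: int
    extra_faces: int
    embeddings: int
    classifiable: int
    excluded: int
    correct_ids: int
    detection_accuracy: float
    end_to_end_accuracy: float


def pipeline_accounting(
    detections: list[list[ScoredBox]],
    truths: list[list[BoxRect]],
    predicted_ids: list[str | None],
    true_ids: list[str | None],
    training_labels: set[str] | list[str],
    iou_threshold: float = 0.5,
) -> PipelineAccounting:
    """Cumulative-error accounting of a full pipeline run.

    Per source image: a detection matching a truth box at the IoU threshold is
    a correct face; remaining detections are erroneous extras.  Every face
    (correct or extra) yields an embedding.  Images whose true identity was
    never trained on are excluded from classification accounting.  Detection
    accuracy is correct faces / source images; end-to-end accuracy is correct
    identifications / classifiable source images.
    """
    n = len(truths)
    training_labels = set(training_labels)
    correct_faces = extra_faces = 0
    classifiable = excluded = correct_ids = 0
    for dets, ts, pid, tid in zip(detections, truths, predicted_ids, true_ids):
        matched: set[int] = set()
        img_correct = 0
        for sb in sorted(dets, key=lambda s: -s.score):
            best, best_iou = None, iou_threshold
            for j, t in enumerate(ts):
                if j in matched:
                    continue
                v = box_iou(sb.rect, t)
                if v >= best_iou:
                    best, best_iou = j, v
            if best is not None:
                matched.add(best)
                img_correct += 1
        correct_faces += img_correct
        extra_faces += len(dets) - img_correct
        if img_correct == 0 or tid is None:
            continue
        if tid not in training_labels:
            excluded += 1
            continue
        classifiable += 1
        if pid == tid:
            correct_ids += 1
    return PipelineAccounting(
        source_images=n,
        correct_faces=correct_faces,
        extra_faces=extra_faces,
        embeddings=correct_faces + extra_faces,
        classifiable=classifiable,
        excluded=excluded,
        correct_ids=correct_ids,
        detection_accuracy=correct_faces / n if n else 0.0,
        end_to_end_accuracy=correct_ids / classifiable if classifiable else 0.0,
    )
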