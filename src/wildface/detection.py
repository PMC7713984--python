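"""Sliding-window face detection over an image pyramid.

The detector scores HOG windows with a linear max-margin scorer (hinge loss
on positive windows plus hard negatives re-mined from the training images),
slides it across an image pyramid, and prunes overlapping hits with greedy
non-maximum suppression.  The estimator follows scikit-learn conventions:
``fit(images, annotations)`` then ``detect(image)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import joblib
import numpy as np
from PIL import Image
from skimage.color import rgb2gray
from skimage.feature import hog
from sklearn.base import BaseEstimator
from sklearn.svm import LinearSVC

from .annotations import AnnotatedImage, AnnotationError, BoxRect


@dataclass(frozen=True)
class ScoredBox:
    rect: BoxRect
    score: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.score):
            raise AnnotationError("detection score must be finite")


def _iou(a: BoxRect, b: BoxRect) -> float:
    iw = max(0, min(a.right, b.right) - max(a.left, b.left))
    ih = max(0, min(a.bottom, b.bottom) - max(a.top, b.top))
    inter = iw * ih
    if inter == 0:
        return 0.0
    return inter / (a.area + b.area - inter)


def non_max_suppression(boxes: list[ScoredBox], overlap_threshold: float = 0.45) -> list[ScoredBox]:
    """Greedy NMS: accept by descending score, drop boxes overlapping an
    accepted box with IoU above the threshold."""
    if not 0.0 <= overlap_threshold <= 1.0:
        raise AnnotationError("overlap threshold must lie in [0, 1]")
    order = sorted(range(len(boxes)), key=lambda i: (-boxes[i].score, i))
    kept: list[ScoredBox] = []
    for i in order:
        if all(_iou(boxes[i].rect, k.rect) <= overlap_threshold for k in kept):
            kept.append(boxes[i])
    return kept


def _to_gray(pixels: np.ndarray) -> np.ndarray:
    if pixels.ndim == 3:
        return rgb2gray(pixels)
    return pixels.astype(float) / 255.0


def _resize_gray(gray: np.ndarray, out_w: int, out_h: int) -> np.ndarray:
    im = Image.fromarray((np.clip(gray, 0, 1) * 255).astype(np.uint8))
    return np.asarray(im.resize((out_w, out_h), Image.BILINEAR)).astype(float) / 255.0


class FaceDetector(BaseEstimator):
    """HOG + linear sliding-window face detector with an image pyramid.

    Parameters
    ----------
    window : int
        Detection window height in pixels; the width is derived from the
        median aspect ratio of the training boxes at fit time.
    pyramid_factor : float
        Downscale ratio between pyramid levels, in (1, 2].
    upscale_levels : int
        Number of pyramid levels above the native resolution, so faces
        slightly smaller than the window remain detectable.
    nms_overlap : float
        IoU above which overlapping detections are suppressed.
    mining_rounds : int
        Hard-negative re-mining passes over the training images.
    C : float
        Inverse regularization of the linear hinge-loss scorer.
    """

    def __init__(
        self,
        window: int = 64,
        cell: int = 8,
        pyramid_factor: float = 1.2,
        upscale_levels: int = 1,
        nms_overlap: float = 0.45,
        score_threshold: float | None = None,
        mining_rounds: int = 2,
        negatives_per_image: int = 8,
        C: float = 1.0,
        seed: int = 0,
    ) -> None:
        self.window = window
        self.cell = cell
        self.pyramid_factor = pyramid_factor
        self.upscale_levels = upscale_levels
        self.nms_overlap = nms_overlap
        self.score_threshold = score_threshold
        self.mining_rounds = mining_rounds
        self.negatives_per_image = negatives_per_image
        self.C = C
        self.seed = seed

    # -- feature helpers ----------------------------------------------------

    def _window_shape(self) -> tuple[int, int]:
        return self._win_h_, self._win_w_

    def _hog_map(self, gray: np.ndarray) -> np.ndarray:
        return hog(
            gray,
            orientations=9,
            pixels_per_cell=(self.cell, self.cell),
            cells_per_block=(2, 2),
            block_norm="L2-Hys",
            feature_vector=False,
        )

    def _window_features(self, gray_win: np.ndarray) -> np.ndarray:
        return self._hog_map(gray_win).ravel()

    def _crop_window(self, gray: np.ndarray, box: BoxRect) -> np.ndarray:
        h, w = gray.shape
        x0, y0 = max(0, box.left), max(0, box.top)
        x1, y1 = min(w, box.right), min(h, box.bottom)
        if x1 <= x0 or y1 <= y0:
            raise AnnotationError("training box lies outside the image")
        crop = gray[y0:y1, x0:x1]
        return _resize_gray(crop, self._win_w_, self._win_h_)

    # -- training -----------------------------------------------------------

    def fit(self, images: list[np.ndarray], annotations: list[AnnotatedImage]) -> "FaceDetector":
        if self.window < 32:
            raise AnnotationError("window must be at least 32 px")
        if not 1.0 < self.pyramid_factor <= 2.0:
            raise AnnotationError("pyramid factor must lie in (1, 2]")
        rng = np.random.default_rng(self.seed)

        boxes = [(i, f.box) for i, ann in enumerate(annotations) for f in ann.faces]
        if not boxes:
            raise AnnotationError("no training boxes")
        min_allowed = self.window / (self.pyramid_factor ** self.upscale_levels)
        too_small = [
            annotations[i].path
            for i, b in boxes
            if min(b.width, b.height) < min_allowed - 0.5
        ]
        if too_small:
            raise AnnotationError(
                "training boxes smaller than the detection window in: "
                + ", ".join(sorted(set(too_small)))
            )
        aspect = float(np.median([b.width / b.height for _, b in boxes]))
        self._win_h_ = self.window
        self._win_w_ = max(self.cell * 2, int(round(self.window * aspect / self.cell)) * self.cell)

        grays = [_to_gray(px) for px in images]
        pos = [self._window_features(self._crop_window(grays[i], b)) for i, b in boxes]
        neg = []
        for i, gray in enumerate(grays):
            neg.extend(self._random_negatives(gray, annotations[i], rng))
        X = np.array(pos + neg)
        y = np.array([1] * len(pos) + [0] * len(neg))
        self._fit_scorer(X, y)

        for _ in range(self.mining_rounds):
            mined = []
            for i, gray in enumerate(grays):
                for sb in self._raw_detect(gray, threshold=-0.5)[:20]:
                    if all(_iou(sb.rect, f.box) < 0.2 for f in annotations[i].faces):
                        mined.append(self._window_features(self._crop_window(gray, sb.rect)))
            if not mined:
                break
            X = np.vstack([X, np.array(mined)])
            y = np.concatenate([y, np.zeros(len(mined), dtype=int)])
            self._fit_scorer(X, y)

        if self.score_threshold is None:
            self.score_threshold_ = self._calibrate_threshold(grays, annotations)
        else:
            self.score_threshold_ = float(self.score_threshold)
        return self

    def _fit_scorer(self, X: np.ndarray, y: np.ndarray) -> None:
        svc = LinearSVC(C=self.C, random_state=self.seed, max_iter=20000, tol=1e-5)
        svc.fit(X, y)
        self.coef_ = svc.coef_.ravel().copy()
        self.intercept_ = float(svc.intercept_[0])

    def _random_negatives(self, gray, annotation, rng) -> list[np.ndarray]:
        h, w = gray.shape
        out = []
        tries = 0
        while len(out) < self.negatives_per_image and tries < 60:
            tries += 1
            bw = int(rng.uniform(self._win_w_ * 0.8, min(w, self._win_w_ * 2.5)))
            bh = int(round(bw * self._win_h_ / self._win_w_))
            if bw >= w or bh >= h:
                continue
            x = int(rng.integers(0, w - bw))
            y = int(rng.integers(0, h - bh))
            cand = BoxRect(x, y, bw, bh)
            if all(_iou(cand, f.box) < 0.2 for f in annotation.faces):
                out.append(self._window_features(self._crop_window(gray, cand)))
        return out

    def _calibrate_threshold(self, grays, annotations) -> float:
        """Pick the raw-score threshold maximizing F1 on the training images."""
        scored: list[tuple[float, bool]] = []
        n_truth = 0
        for gray, ann in zip(grays, annotations):
            n_truth += len(ann.faces)
            dets = non_max_suppression(self._raw_detect(gray, threshold=-1.0), self.nms_overlap)
            matched: set[int] = set()
            for sb in dets:
                best, best_iou = None, 0.5
                for j, f in enumerate(ann.faces):
                    v = _iou(sb.rect, f.box)
                    if j not in matched and v >= best_iou:
                        best, best_iou = j, v
                if best is not None:
                    matched.add(best)
                scored.append((sb.score, best is not None))
        if not scored:
            return 0.0
        scored.sort(key=lambda t: -t[0])
        best_f1, best_thr = -1.0, 0.0
        tp = fp = 0
        for k, (s, is_tp) in enumerate(scored):
            tp += is_tp
            fp += not is_tp
            recall = tp / max(1, n_truth)
            precision = tp / (tp + fp)
            f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
            if f1 > best_f1:
                nxt = scored[k + 1][0] if k + 1 < len(scored) else s - 1e-3
                best_f1, best_thr = f1, (s + nxt) / 2.0
        return best_thr

    # -- inference ----------------------------------------------------------

    def _pyramid_scales(self, h: int, w: int):
        f = self.pyramid_factor
        s = f ** self.upscale_levels
        min_dim = max(self._win_h_, self._win_w_)
        while min(h * s, w * s) >= min_dim and s > 1e-3:
            yield s
            s /= f

    def _raw_detect(self, gray: np.ndarray, threshold: float, cap: int = 300) -> list[ScoredBox]:
        h, w = gray.shape
        win_cells_y = self._win_h_ // self.cell
        win_cells_x = self._win_w_ // self.cell
        wb_y, wb_x = win_cells_y - 1, win_cells_x - 1  # 2x2-cell blocks
        out: list[ScoredBox] = []
        for s in self._pyramid_scales(h, w):
            lw, lh = int(round(w * s)), int(round(h * s))
            level = gray if (lw == w and lh == h) else _resize_gray(gray, lw, lh)
            fmap = self._hog_map(level)
            nby, nbx = fmap.shape[:2]
            if nby < wb_y or nbx < wb_x:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(fmap, (wb_y, wb_x), axis=(0, 1))
            ny, nx = windows.shape[:2]
            # window layout (ny, nx, 2, 2, 9, wb_y, wb_x) -> match ravel order of
            # fmap[by:by+wb_y, bx:bx+wb_x] which is (wb_y, wb_x, 2, 2, 9)
            flat = windows.transpose(0, 1, 5, 6, 2, 3, 4).reshape(ny * nx, -1)
            scores = flat @ self.coef_ + self.intercept_
            hits = np.flatnonzero(scores > threshold)
            for idx in hits:
                by, bx = divmod(int(idx), nx)
                out.append(
                    ScoredBox(
                        BoxRect(
                            int(round(bx * self.cell / s)),
                            int(round(by * self.cell / s)),
                            max(1, int(round(self._win_w_ / s))),
                            max(1, int(round(self._win_h_ / s))),
                        ),
                        float(scores[idx]),
                    )
                )
        out.sort(key=lambda sb: -sb.score)
        return out[:cap]

    def detect(self, pixels: np.ndarray, threshold: float | None = None) -> list[ScoredBox]:
        """Detections above threshold after NMS, best first, in image coords."""
        thr = self.score_threshold_ if threshold is None else threshold
        raw = self._raw_detect(_to_gray(pixels), thr)
        return non_max_suppression(raw, self.nms_overlap)

    # -- persistence ---------------------------------------------------------

    def save(self, path: str) -> None:
        joblib.dump(
            {
                "format": "wildface-detector-v1",
                "params": self.get_params(),
                "win_h": self._win_h_,
                "win_w": self._win_w_,
                "coef": self.coef_,
                "intercept": self.intercept_,
                "score_threshold": self.score_threshold_,
            },
            path,
        )

    @classmethod
    def load(cls, path: str) -> "FaceDetector":
        blob = joblib.load(path)
        if blob.get("format") != "wildface-detector-v1":
            raise AnnotationError(f"{path} is not a detector model file")
        det = cls(**blob["params"])
        det._win_h_ = blob["win_h"]
        det._win_w_ = blob["win_w"]
        det.coef_ = blob["coef"]
        det.intercept_ = blob["intercept"]
        det.score_threshold_ = blob["score_threshold"]
        return det


def train_detector(images, annotations, cfg: dict | None = None, seed: int = 0) -> FaceDetector:
    """Functional wrapper over :class:`FaceDetector`."""
    det = FaceDetector(seed=seed, **(cfg or {}))
    return det.fit(images, annotations)


def detect_faces(model: FaceDetector, pixels: np.ndarray) -> list[ScoredBox]:
    return model.detect(pixels)
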