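"""Cascaded-regression landmark localization inside a detected face box.

A shape (the 6 landmarks) is initialized from the training-set mean shape in
box-normalized coordinates and refined through a cascade of regression
stages.  Each stage reads sparse pixel-difference features at points indexed
relative to the current shape estimate (offsets are carried through the
similarity transform aligning the mean shape to the current shape, so the
cascade tolerates in-plane rotation), and regresses a shape update with a
ridge model.  Training replicates each face under several jittered
initializations so the cascade learns to pull a perturbed start onto the
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import joblib
import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator
from sklearn.linear_model import Ridge

from .annotations import AnnotatedImage, AnnotationError, BoxRect, LandmarkSet
from .detection import _to_gray


def _box_frame(box: BoxRect) -> tuple[np.ndarray, np.ndarray]:
    origin = np.array([box.left, box.top], dtype=float)
    size = np.array([box.width, box.height], dtype=float)
    return origin, size


def _similarity_to(mean: np.ndarray, current: np.ndarray) -> np.ndarray:
    """Least-squares 2x2 rotation+scale matrix mapping mean-shape offsets into
    the current shape's frame (both shapes centered)."""
    mc = mean - mean.mean(axis=0)
    cc = current - current.mean(axis=0)
    # complex least squares: minimize |a*m - c|
    m = mc[:, 0] + 1j * mc[:, 1]
    c = cc[:, 0] + 1j * cc[:, 1]
    denom = np.vdot(m, m).real
    a = np.vdot(m, c) / denom if denom > 1e-12 else 1.0 + 0j
    return np.array([[a.real, -a.imag], [a.imag, a.real]])


def _sample_pixels(gray: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Bilinear intensity samples at (x, y) points with edge replication."""
    coords = np.stack([pts[:, 1], pts[:, 0]])
    return ndimage.map_coordinates(gray, coords, order=1, mode="nearest")


class ShapeRegressor(BaseEstimator):
    """Cascade of ridge regressions on pixel-difference features.

    With ``depth=0`` prediction returns the mean shape mapped into the box —
    the cascade's initialization semantics.
    """

    def __init__(
        self,
        depth: int = 8,
        n_features: int = 400,
        feature_radius: float = 0.25,
        radius_decay: float = 0.82,
        jitters: int = 10,
        alpha: float = 1.0,
        seed: int = 0,
    ) -> None:
        self.depth = depth
        self.n_features = n_features
        self.feature_radius = feature_radius
        self.radius_decay = radius_decay
        self.jitters = jitters
        self.alpha = alpha
        self.seed = seed

    # -- internals -----------------------------------------------------------

    def _stage_features(self, gray, shapes_px, sizes, stage):
        """Pixel-difference features for a batch of current shapes (one image)."""
        anchors = stage["anchors"]
        offsets = stage["offsets"]  # (n_features, 2, 2) in box-size units
        feats = np.empty((shapes_px.shape[0], len(anchors)))
        for i, (shape_px, size) in enumerate(zip(shapes_px, sizes)):
            R = _similarity_to(self.mean_shape_, shape_px / size)
            pts_a = shape_px[anchors[:, 0]] + (offsets[:, 0] @ R.T) * size
            pts_b = shape_px[anchors[:, 1]] + (offsets[:, 1] @ R.T) * size
            feats[i] = _sample_pixels(gray, pts_a) - _sample_pixels(gray, pts_b)
        return feats

    def _make_stage(self, rng, radius):
        anchors = rng.integers(0, 6, size=(self.n_features, 2))
        offsets = rng.uniform(-radius, radius, size=(self.n_features, 2, 2))
        return {"anchors": anchors, "offsets": offsets}

    # -- API ------------------------------------------------------------------

    def fit(self, images: list[np.ndarray], annotations: list[AnnotatedImage]) -> "ShapeRegressor":
        faces = []
        for px, ann in zip(images, annotations):
            gray = _to_gray(px)
            for f in ann.faces:
                if f.landmarks is None:
                    raise AnnotationError(f"face in {ann.path!r} lacks landmarks")
                faces.append((gray, f.box, f.landmarks.to_array()))
        if not faces:
            raise AnnotationError("no annotated faces to train on")
        rng = np.random.default_rng(self.seed)

        norm = []
        for _, box, lm in faces:
            origin, size = _box_frame(box)
            norm.append((lm - origin) / size)
        self.mean_shape_ = np.mean(norm, axis=0)

        # per-sample state: (face index, current shape in pixels)
        sample_face = []
        shapes = []
        targets = []
        for fi, (_, box, lm) in enumerate(faces):
            origin, size = _box_frame(box)
            for _ in range(self.jitters):
                jit = 1.0 + rng.uniform(-0.15, 0.15)
                shift = rng.uniform(-0.1, 0.1, size=2) * size
                start = origin + shift + (self.mean_shape_ - 0.5) * size * jit + 0.5 * size
                sample_face.append(fi)
                shapes.append(start)
                targets.append(lm)
        shapes = np.array(shapes)
        targets = np.array(targets)
        sample_face = np.array(sample_face)
        sizes = np.array([_box_frame(faces[fi][1])[1] for fi in sample_face])

        self.stages_ = []
        radius = self.feature_radius
        for _ in range(self.depth):
            stage = self._make_stage(rng, radius)
            feats = np.empty((len(shapes), self.n_features))
            for fi in np.unique(sample_face):
                mask = sample_face == fi
                feats[mask] = self._stage_features(faces[fi][0], shapes[mask], sizes[mask], stage)
            delta = (targets - shapes) / sizes[:, None, :]
            reg = Ridge(alpha=self.alpha)
            reg.fit(feats, delta.reshape(len(shapes), -1))
            stage["coef"] = reg.coef_.copy()
            stage["intercept"] = reg.intercept_.copy()
            pred = reg.predict(feats).reshape(-1, 6, 2)
            shapes = shapes + pred * sizes[:, None, :]
            self.stages_.append(stage)
            radius *= self.radius_decay
        return self

    def predict(self, pixels: np.ndarray, box: BoxRect) -> LandmarkSet:
        """Predict the 6 landmarks, in image coordinates."""
        if box.width <= 0 or box.height <= 0:
            raise AnnotationError("degenerate box")
        gray = _to_gray(pixels)
        origin, size = _box_frame(box)
        shape = origin + self.mean_shape_ * size
        for stage in getattr(self, "stages_", []):
            feats = self._stage_features(gray, shape[None], size[None], stage)
            delta = (feats @ stage["coef"].T + stage["intercept"]).reshape(6, 2)
            shape = shape + delta * size
        return LandmarkSet.from_array(shape)

    # -- persistence ----------------------------------------------------------

    def save(self, path: str) -> None:
        joblib.dump(
            {
                "format": "wildface-shape-v1",
                "params": self.get_params(),
                "mean_shape": self.mean_shape_,
                "stages": self.stages_,
            },
            path,
        )

    @classmethod
    def load(cls, path: str) -> "ShapeRegressor":
        blob = joblib.load(path)
        if blob.get("format") != "wildface-shape-v1":
            raise AnnotationError(f"{path} is not a shape model file")
        model = cls(**blob["params"])
        model.mean_shape_ = blob["mean_shape"]
        model.stages_ = blob["stages"]
        return model


def train_shape_predictor(images, annotations, cfg: dict | None = None, seed: int = 0) -> ShapeRegressor:
    return ShapeRegressor(seed=seed, **(cfg or {})).fit(images, annotations)


def predict_landmarks(model: ShapeRegressor, pixels: np.ndarray, box: BoxRect) -> LandmarkSet:
    return model.predict(pixels, box)
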