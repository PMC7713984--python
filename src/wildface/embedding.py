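"""Metric-learning face encoder.

A chip is summarized by a fixed feature map (grid HOG of the grayscale chip
plus coarse chromaticity statistics, so both geometry and fur color carry
identity signal) and projected by a learned linear map into a 128-D Euclidean
embedding.  The projection is trained with a pairwise hinge loss on balanced
mini-batches: all same-identity pairs in the batch are counted as positives
and, with hard-negative mining on, only the equally many smallest-distance
different-identity pairs are counted as negatives.  Every time a chip enters
a batch it is re-augmented (similarity jitter plus color perturbation), so
the encoder never sees the same pixels twice.

With threshold ``T`` and margin ``M``, a counted matched pair at distance
``d`` contributes ``max(0, d - T + M)`` and a counted unmatched pair
``max(0, T - d + M)``; the loss is the mean over counted pairs, and is zero
exactly when matched pairs sit below ``T - M`` and unmatched pairs above
``T + M``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import joblib
import numpy as np
from scipy import ndimage
from skimage.color import rgb2gray
from skimage.feature import hog
from sklearn.base import BaseEstimator

from .annotations import AnnotationError
from .chips import FaceChip

EMBED_DIM = 128


@dataclass(frozen=True)
class PairLossSpec:
    """Distance threshold and margin of the pairwise hinge loss."""

    distance_threshold: float = 0.6
    margin: float = 0.04

    def __post_init__(self) -> None:
        if not self.distance_threshold > self.margin > 0:
            raise AnnotationError("need distance_threshold > margin > 0")


@dataclass(frozen=True)
class BatchSpec:
    identities_per_batch: int = 5
    chips_per_identity: int = 8
    hard_negative: bool = True

    def __post_init__(self) -> None:
        if self.identities_per_batch < 2 or self.chips_per_identity < 2:
            raise AnnotationError("batch needs >= 2 identities and >= 2 chips per identity")


@dataclass(frozen=True)
class AugmentSpec:
    """Magnitudes of per-inclusion chip augmentation."""

    max_shift: float = 6.0  # pixels
    max_rotation: float = 10.0  # degrees
    scale_range: tuple[float, float] = (0.9, 1.1)
    gain_range: tuple[float, float] = (0.8, 1.2)
    gamma_range: tuple[float, float] = (0.8, 1.25)

    @classmethod
    def none(cls) -> "AugmentSpec":
        return cls(0.0, 0.0, (1.0, 1.0), (1.0, 1.0), (1.0, 1.0))


# ---------------------------------------------------------------------------
# Loss


def _counted_pairs(distances: np.ndarray, same_flags: np.ndarray, hard_negative: bool) -> np.ndarray:
    """Boolean mask of pairs entering the loss (1:1 mining of negatives)."""
    counted = np.ones(len(distances), dtype=bool)
    if hard_negative:
        n_pos = int(same_flags.sum())
        neg_idx = np.flatnonzero(~same_flags)
        if len(neg_idx) > n_pos:
            hardest = neg_idx[np.argsort(distances[neg_idx], kind="stable")[:n_pos]]
            counted[neg_idx] = False
            counted[hardest] = True
    return counted


def pairwise_hinge_loss(
    distances: np.ndarray,
    same_flags: np.ndarray,
    spec: PairLossSpec = PairLossSpec(),
    hard_negative: bool = True,
) -> float:
    """Mean pairwise hinge loss over counted pairs.

    ``distances`` holds one Euclidean distance per unordered in-batch pair and
    ``same_flags`` marks matched (same-identity) pairs.
    """
    distances = np.asarray(distances, dtype=float)
    same_flags = np.asarray(same_flags, dtype=bool)
    if distances.shape != same_flags.shape:
        raise AnnotationError("distances and same_flags must align")
    T, M = spec.distance_threshold, spec.margin
    counted = _counted_pairs(distances, same_flags, hard_negative)
    per_pair = np.where(
        same_flags,
        np.maximum(0.0, distances - T + M),
        np.maximum(0.0, T - distances + M),
    )
    if not counted.any():
        return 0.0
    return float(per_pair[counted].mean())


# ---------------------------------------------------------------------------
# Batching and augmentation


def build_training_batch(
    chips_by_label: dict[str, list],
    spec: BatchSpec,
    rng: np.random.Generator,
) -> tuple[list, list[str]]:
    """Sample a balanced mini-batch: k identities x up-to-m chips, without
    replacement within the batch."""
    eligible = [lab for lab, chips in chips_by_label.items() if len(chips) >= 2]
    if len(eligible) < spec.identities_per_batch:
        raise AnnotationError(
            f"need {spec.identities_per_batch} identities with >=2 chips, have {len(eligible)}"
        )
    labels = list(rng.choice(eligible, size=spec.identities_per_batch, replace=False))
    batch, batch_labels = [], []
    for lab in labels:
        chips = chips_by_label[lab]
        take = min(spec.chips_per_identity, len(chips))
        idx = rng.choice(len(chips), size=take, replace=False)
        for i in idx:
            batch.append(chips[int(i)])
            batch_labels.append(lab)
    return batch, batch_labels


def augment_chip(
    chip: FaceChip | np.ndarray,
    rng: np.random.Generator,
    magnitudes: AugmentSpec = AugmentSpec(),
) -> np.ndarray:
    """Random similarity jitter plus color perturbation; zero magnitudes
    return the input pixels bit-identically."""
    pixels = chip.pixels if isinstance(chip, FaceChip) else np.asarray(chip)
    m = magnitudes
    shift = rng.uniform(-m.max_shift, m.max_shift, size=2)
    theta = math.radians(rng.uniform(-m.max_rotation, m.max_rotation))
    scale = rng.uniform(*m.scale_range)
    gains = rng.uniform(*m.gain_range, size=3)
    gamma = rng.uniform(*m.gamma_range)

    out = pixels
    if shift.any() or theta != 0.0 or scale != 1.0:
        h, w = pixels.shape[:2]
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        c, s = math.cos(theta), math.sin(theta)
        A = np.array([[c, -s], [s, c]]) * scale
        Ainv = np.linalg.inv(A)
        yy, xx = np.mgrid[0:h, 0:w].astype(float)
        dx, dy = xx - cx - shift[0], yy - cy - shift[1]
        sx = Ainv[0, 0] * dx + Ainv[0, 1] * dy + cx
        sy = Ainv[1, 0] * dx + Ainv[1, 1] * dy + cy
        out = np.empty_like(pixels)
        for ch in range(pixels.shape[2]):
            out[..., ch] = np.clip(
                np.rint(
                    ndimage.map_coordinates(
                        pixels[..., ch].astype(float), [sy, sx], order=1, mode="nearest"
                    )
                ),
                0,
                255,
            )
    if gamma != 1.0 or np.any(gains != 1.0):
        x = out.astype(float) / 255.0
        x = np.power(np.clip(x, 0, 1), gamma) * gains[None, None, :]
        out = (np.clip(x, 0, 1) * 255).round().astype(np.uint8)
    return out


# ---------------------------------------------------------------------------
# Encoder


def _chip_features(pixels: np.ndarray, cell: int, chroma_grid: int = 6) -> np.ndarray:
    gray = rgb2gray(pixels)
    g = hog(
        gray,
        orientations=9,
        pixels_per_cell=(cell, cell),
        cells_per_block=(2, 2),
        block_norm="L2-Hys",
        feature_vector=True,
    )
    h, w = pixels.shape[:2]
    ys = np.linspace(0, h, chroma_grid + 1).astype(int)
    xs = np.linspace(0, w, chroma_grid + 1).astype(int)
    chroma = []
    for i in range(chroma_grid):
        for j in range(chroma_grid):
            cellpx = pixels[ys[i] : ys[i + 1], xs[j] : xs[j + 1]].astype(float)
            mean = cellpx.mean(axis=(0, 1)) + 1e-6
            total = mean.sum()
            chroma.extend([mean[0] / total, mean[1] / total])
    return np.concatenate([g, np.asarray(chroma)])


class MetricEmbedder(BaseEstimator):
    """Linear metric-learning head over fixed chip features.

    ``fit(chips, labels)`` trains the projection with pairwise hinge loss and
    hard-negative-mined balanced batches; ``transform(chips)`` returns 128-D
    embeddings.  ``chips`` may be ``FaceChip`` objects or raw pixel arrays of
    the configured ``chip_size``.
    """

    def __init__(
        self,
        chip_size: int = 150,
        loss_spec: PairLossSpec = PairLossSpec(),
        batch_spec: BatchSpec = BatchSpec(),
        augment: AugmentSpec = AugmentSpec(),
        epochs: int = 10,
        batches_per_epoch: int = 20,
        lr: float = 1e-4,
        seed: int = 0,
    ) -> None:
        self.chip_size = chip_size
        self.loss_spec = loss_spec
        self.batch_spec = batch_spec
        self.augment = augment
        self.epochs = epochs
        self.batches_per_epoch = batches_per_epoch
        self.lr = lr
        self.seed = seed

    # -- internals ------------------------------------------------------------

    def _pixels(self, chip) -> np.ndarray:
        px = chip.pixels if isinstance(chip, FaceChip) else np.asarray(chip)
        if px.shape[0] != self.chip_size or px.shape[1] != self.chip_size:
            raise AnnotationError(
                f"chip size {px.shape[1]}x{px.shape[0]} does not match the "
                f"model's expected {self.chip_size}x{self.chip_size}"
            )
        return px

    def _features(self, pixels: np.ndarray) -> np.ndarray:
        return _chip_features(pixels, cell=max(8, self.chip_size // 10))

    def _standardize(self, F: np.ndarray) -> np.ndarray:
        return (F - self._mu_) / self._sd_

    # -- API --------------------------------------------------------------------

    def fit(self, chips: list, labels: list[str]) -> "MetricEmbedder":
        if len(chips) != len(labels):
            raise AnnotationError("chips and labels must align")
        by_label: dict[str, list[int]] = {}
        for i, lab in enumerate(labels):
            by_label.setdefault(lab, []).append(i)
        if sum(len(v) >= 2 for v in by_label.values()) < 2:
            raise AnnotationError("need at least 2 identities with >= 2 chips each")
        rng = np.random.default_rng(self.seed)
        pixels = [self._pixels(c) for c in chips]

        base = np.array([self._features(px) for px in pixels])
        self._mu_ = base.mean(axis=0)
        self._sd_ = base.std(axis=0) + 1e-6
        d = base.shape[1]
        # start with typical inter-chip distances near the loss threshold T:
        # for standardized features, dist^2 ~ 2 * EMBED_DIM * d * sigma^2
        T = self.loss_spec.distance_threshold
        sigma = T / math.sqrt(2.0 * EMBED_DIM * d)
        self.W_ = rng.normal(0.0, sigma, size=(d, EMBED_DIM))

        # Adam state
        mW = np.zeros_like(self.W_)
        vW = np.zeros_like(self.W_)
        b1, b2, eps = 0.9, 0.999, 1e-8
        step = 0
        T, M = self.loss_spec.distance_threshold, self.loss_spec.margin
        self.loss_history_ = []
        index_by_label = {lab: idx for lab, idx in by_label.items()}
        for _ in range(self.epochs):
            epoch_losses = []
            for _ in range(self.batches_per_epoch):
                idx_batch, lab_batch = build_training_batch(index_by_label, self.batch_spec, rng)
                X = np.array(
                    [
                        self._features(augment_chip(pixels[i], rng, self.augment))
                        for i in idx_batch
                    ]
                )
                X = self._standardize(X)
                E = X @ self.W_
                n = len(idx_batch)
                ii, jj = np.triu_indices(n, k=1)
                diffs = E[ii] - E[jj]
                dist = np.sqrt((diffs**2).sum(axis=1)) + 1e-9
                same = np.array([lab_batch[a] == lab_batch[b] for a, b in zip(ii, jj)])
                counted = _counted_pairs(dist, same, self.batch_spec.hard_negative)
                active_pos = counted & same & (dist > T - M)
                active_neg = counted & ~same & (dist < T + M)
                n_counted = max(1, int(counted.sum()))
                per_pair = np.where(
                    same, np.maximum(0, dist - T + M), np.maximum(0, T - dist + M)
                )
                epoch_losses.append(per_pair[counted].mean() if counted.any() else 0.0)
                # gradient wrt embeddings
                gE = np.zeros_like(E)
                sign = np.zeros(len(dist))
                sign[active_pos] = 1.0
                sign[active_neg] = -1.0
                scale = sign / (dist * n_counted)
                gpair = diffs * scale[:, None]
                np.add.at(gE, ii, gpair)
                np.add.at(gE, jj, -gpair)
                gW = X.T @ gE
                step += 1
                mW = b1 * mW + (1 - b1) * gW
                vW = b2 * vW + (1 - b2) * gW**2
                mhat = mW / (1 - b1**step)
                vhat = vW / (1 - b2**step)
                self.W_ -= self.lr * mhat / (np.sqrt(vhat) + eps)
            self.loss_history_.append(float(np.mean(epoch_losses)))
        return self

    def transform(self, chips: list) -> np.ndarray:
        """Embed chips: (n, 128) array; deterministic for fixed pixels."""
        F = np.array([self._features(self._pixels(c)) for c in chips])
        return self._standardize(F) @ self.W_

    def embed(self, chip) -> np.ndarray:
        e = self.transform([chip])[0]
        if not np.all(np.isfinite(e)):
            raise AnnotationError("non-finite embedding")
        return e

    # -- persistence --------------------------------------------------------------

    def save(self, path: str) -> None:
        joblib.dump(
            {
                "format": "wildface-embed-v1",
                "params": self.get_params(),
                "mu": self._mu_,
                "sd": self._sd_,
                "W": self.W_,
                "loss_history": getattr(self, "loss_history_", []),
            },
            path,
        )

    @classmethod
    def load(cls, path: str) -> "MetricEmbedder":
        blob = joblib.load(path)
        if blob.get("format") != "wildface-embed-v1":
            raise AnnotationError(f"{path} is not an embedder model file")
        model = cls(**blob["params"])
        model._mu_ = blob["mu"]
        model._sd_ = blob["sd"]
        model.W_ = blob["W"]
        model.loss_history_ = blob["loss_history"]
        return model


def train_embedder(chips, labels, cfg: dict | None = None, seed: int = 0) -> MetricEmbedder:
    return MetricEmbedder(seed=seed, **(cfg or {})).fit(chips, labels)


def embed_chip(model: MetricEmbedder, chip) -> np.ndarray:
    """128-D embedding of one chip."""
    return model.embed(chip)
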