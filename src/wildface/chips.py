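"""Eye-anchored similarity alignment and canonical face-chip extraction.

A face chip is a fixed-size (default 150x150) crop warped so that the two
eye landmarks land on canonical positions (defaults: 30%/70% of the width at
40% of the height).  Only the eyes drive the alignment; the remaining
landmarks ride along.  The two-point similarity transform has a closed-form
solution, computed here in complex arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .annotations import AnnotationError, BoxRect, LandmarkSet


@dataclass(frozen=True)
class ChipSpec:
    size: int = 150
    left_eye: tuple[float, float] | None = None
    right_eye: tuple[float, float] | None = None

    def eye_positions(self) -> tuple[np.ndarray, np.ndarray]:
        le = self.left_eye if self.left_eye is not None else (0.30 * self.size, 0.40 * self.size)
        re = self.right_eye if self.right_eye is not None else (0.70 * self.size, 0.40 * self.size)
        le, re = np.asarray(le, float), np.asarray(re, float)
        if not (0 <= le[0] < re[0] <= self.size) or not (0 <= le[1] <= self.size):
            raise AnnotationError("canonical eye positions must lie inside the chip, left of right")
        return le, re


@dataclass(frozen=True)
class SimilarityTransform:
    """x' = scale * R(rotation) @ x + translation."""

    rotation: float
    scale: float
    translation: tuple[float, float]

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise AnnotationError("similarity scale must be positive")

    @property
    def matrix(self) -> np.ndarray:
        c, s = math.cos(self.rotation), math.sin(self.rotation)
        return self.scale * np.array([[c, -s], [s, c]])

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, float))
        return pts @ self.matrix.T + np.asarray(self.translation)

    def inverse(self) -> "SimilarityTransform":
        inv_scale = 1.0 / self.scale
        c, s = math.cos(-self.rotation), math.sin(-self.rotation)
        tx, ty = self.translation
        itx = -inv_scale * (c * tx - s * ty)
        ity = -inv_scale * (s * tx + c * ty)
        return SimilarityTransform(-self.rotation, inv_scale, (itx, ity))

    @classmethod
    def from_point_pairs(cls, src_a, src_b, dst_a, dst_b) -> "SimilarityTransform":
        """Unique similarity mapping two source points onto two targets."""
        s = complex(*map(float, src_b)) - complex(*map(float, src_a))
        if abs(s) < 1e-12:
            raise AnnotationError("source points coincide; cannot solve alignment")
        d = complex(*map(float, dst_b)) - complex(*map(float, dst_a))
        alpha = d / s
        beta = complex(*map(float, dst_a)) - alpha * complex(*map(float, src_a))
        return cls(
            rotation=math.atan2(alpha.imag, alpha.real),
            scale=abs(alpha),
            translation=(beta.real, beta.imag),
        )


@dataclass
class FaceChip:
    """Canonical aligned face crop plus provenance back to the source image."""

    pixels: np.ndarray  # (size, size, 3) uint8
    source_path: str = ""
    source_box: BoxRect | None = None
    transform: SimilarityTransform | None = None
    identity: str | None = None

    @property
    def size(self) -> int:
        return self.pixels.shape[0]

    def to_source_coords(self, pts: np.ndarray) -> np.ndarray:
        """Map chip coordinates back into the source image."""
        if self.transform is None:
            raise AnnotationError("chip has no provenance transform")
        return self.transform.inverse().apply(pts)


def compute_chip_transform(landmarks: LandmarkSet, spec: ChipSpec = ChipSpec()) -> SimilarityTransform:
    """Similarity transform sending the eye landmarks to canonical positions."""
    if landmarks.interocular() <= 1e-9:
        raise AnnotationError("interocular distance is zero; cannot align")
    le, re = spec.eye_positions()
    return SimilarityTransform.from_point_pairs(landmarks["leye"], landmarks["reye"], le, re)


def extract_chip(
    pixels: np.ndarray,
    transform: SimilarityTransform,
    spec: ChipSpec = ChipSpec(),
    source_path: str = "",
    source_box: BoxRect | None = None,
    identity: str | None = None,
) -> FaceChip:
    """Inverse-warp the source image into the canonical chip frame.

    Bilinear sampling; out-of-frame samples use edge replication.
    """
    size = spec.size
    inv = transform.inverse()
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    dst = np.stack([xx.ravel(), yy.ravel()], axis=1)
    src = inv.apply(dst)
    coords = np.stack([src[:, 1].reshape(size, size), src[:, 0].reshape(size, size)])
    img = np.asarray(pixels)
    if img.ndim == 2:
        img = np.repeat(img[..., None], 3, axis=2)
    out = np.empty((size, size, 3), dtype=np.uint8)
    for c in range(3):
        ch = ndimage.map_coordinates(img[..., c].astype(float), coords, order=1, mode="nearest")
        out[..., c] = np.clip(np.rint(ch), 0, 255).astype(np.uint8)
    return FaceChip(
        pixels=out,
        source_path=source_path,
        source_box=source_box,
        transform=transform,
        identity=identity,
    )


def chip_face(
    pixels: np.ndarray,
    landmarks: LandmarkSet,
    spec: ChipSpec = ChipSpec(),
    **provenance,
) -> FaceChip:
    """Convenience: transform + extraction in one call."""
    t = compute_chip_transform(landmarks, spec)
    return extract_chip(pixels, t, spec, **provenance)
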