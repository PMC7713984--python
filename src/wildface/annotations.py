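"""Annotation data model, XML dialect I/O, image loading, scaling and splits.

The on-disk annotation format is the imglab-style XML dialect::

    <dataset><name/><images>
      <image file='PATH' width='W' height='H'>
        <box top='T' left='L' width='W' height='H'>
          <label>ID</label>
          <part name='leye' x='X' y='Y'/>...
        </box>
      </image>
    </images></dataset>

Boxes are 0-based, origin top-left, and span the half-open pixel ranges
``[left, left+width) x [top, top+height)``.  Box attributes are printed as
integers; part coordinates are printed as decimals so sub-pixel ground truth
survives a round trip.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from lxml import etree
from PIL import Image

LANDMARK_NAMES: tuple[str, ...] = ("leye", "reye", "nose", "lear", "rear", "head")

SUPPORTED_IMAGE_SUFFIXES = {".jpg", ".jpeg", ".png"}


class AnnotationError(ValueError):
    """Raised when annotations violate the data-model contracts."""


@dataclass(frozen=True)
class BoxRect:
    """Axis-aligned face box: half-open pixel ranges, 0-based, origin top-left."""

    left: int
    top: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise AnnotationError(
                f"box width/height must be positive, got {self.width}x{self.height}"
            )

    @property
    def right(self) -> int:
        return self.left + self.width

    @property
    def bottom(self) -> int:
        return self.top + self.height

    @property
    def area(self) -> int:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (self.left + self.width / 2.0, self.top + self.height / 2.0)

    def scaled(self, s: float) -> "BoxRect":
        left = int(round(self.left * s))
        top = int(round(self.top * s))
        return BoxRect(
            left=left,
            top=top,
            width=max(1, int(round(self.width * s))),
            height=max(1, int(round(self.height * s))),
        )

    def shifted(self, dx: int, dy: int) -> "BoxRect":
        return BoxRect(self.left + dx, self.top + dy, self.width, self.height)

    def intersects_frame(self, width: int, height: int) -> bool:
        return self.left < width and self.top < height and self.right > 0 and self.bottom > 0


@dataclass(frozen=True)
class LandmarkSet:
    """The six named facial landmarks, in pixel coordinates (real-valued)."""

    points: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        names = set(self.points)
        if names != set(LANDMARK_NAMES):
            missing = set(LANDMARK_NAMES) - names
            extra = names - set(LANDMARK_NAMES)
            raise AnnotationError(
                f"landmark names must be exactly {LANDMARK_NAMES}; "
                f"missing={sorted(missing)} unknown={sorted(extra)}"
            )
        if self.points["leye"] == self.points["reye"]:
            raise AnnotationError("left and right eye landmarks coincide")

    def __getitem__(self, name: str) -> tuple[float, float]:
        return self.points[name]

    def to_array(self) -> np.ndarray:
        """(6, 2) array in canonical name order."""
        return np.array([self.points[n] for n in LANDMARK_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "LandmarkSet":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (6, 2):
            raise AnnotationError(f"expected (6, 2) landmark array, got {arr.shape}")
        return cls({n: (float(x), float(y)) for n, (x, y) in zip(LANDMARK_NAMES, arr)})

    def interocular(self) -> float:
        (lx, ly), (rx, ry) = self.points["leye"], self.points["reye"]
        return math.hypot(rx - lx, ry - ly)

    def transformed(self, fn) -> "LandmarkSet":
        return LandmarkSet({n: tuple(map(float, fn(p))) for n, p in self.points.items()})


@dataclass
class FaceAnnotation:
    box: BoxRect
    landmarks: LandmarkSet | None = None
    identity: str | None = None


@dataclass
class AnnotatedImage:
    path: str
    width: int
    height: int
    faces: list[FaceAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise AnnotationError(f"image {self.path!r} has non-positive size")
        for f in self.faces:
            if not f.box.intersects_frame(self.width, self.height):
                raise AnnotationError(
                    f"face box {f.box} does not intersect frame of {self.path!r}"
                )


@dataclass(frozen=True)
class ScalePolicy:
    """Detection-time image scaling rules.

    Images are scaled down to fit ``max_width x max_height``; at test time, if
    that would leave the smallest annotated face under ``min_face`` pixels, the
    image is instead scaled so that face reaches ``min_face`` and then cropped
    to the frame size around it.
    """

    max_width: int = 2000
    max_height: int = 1500
    min_face: int = 200

    def __post_init__(self) -> None:
        if self.max_width < self.min_face or self.max_height < self.min_face:
            raise AnnotationError("frame must be at least min_face in both dimensions")


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.8
    k: int = 5
    mode: str = "by_chip"  # or "by_label"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise AnnotationError("train_fraction must lie in (0, 1)")
        if self.k < 2:
            raise AnnotationError("k must be at least 2")
        if self.mode not in ("by_chip", "by_label"):
            raise AnnotationError(f"unknown fold mode {self.mode!r}")


# ---------------------------------------------------------------------------
# XML dialect


def _format_float(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def read_dataset_xml(path: str | Path) -> list[AnnotatedImage]:
    """Parse an annotation XML file into the data model.

    Raises a parse error naming the line for malformed XML, and a validation
    error naming the image and part for unknown landmark names.
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise AnnotationError(f"malformed annotation XML {path}: {exc}") from exc
    root = tree.getroot()
    dataset: list[AnnotatedImage] = []
    for img_el in root.iter("image"):
        file_attr = img_el.get("file")
        if file_attr is None:
            raise AnnotationError(f"{path}: <image> element without file attribute")
        width = img_el.get("width")
        height = img_el.get("height")
        if width is None or height is None:
            with Image.open(file_attr) as im:
                w, h = im.size
        else:
            w, h = int(width), int(height)
        faces = []
        for box_el in img_el.iter("box"):
            box = BoxRect(
                left=int(box_el.get("left")),
                top=int(box_el.get("top")),
                width=int(box_el.get("width")),
                height=int(box_el.get("height")),
            )
            label_el = box_el.find("label")
            identity = label_el.text if label_el is not None else None
            points: dict[str, tuple[float, float]] = {}
            for part_el in box_el.iter("part"):
                name = part_el.get("name")
                if name not in LANDMARK_NAMES:
                    raise AnnotationError(
                        f"{path}: image {file_attr!r} has unknown part name {name!r}"
                    )
                points[name] = (float(part_el.get("x")), float(part_el.get("y")))
            landmarks = LandmarkSet(points) if points else None
            faces.append(FaceAnnotation(box=box, landmarks=landmarks, identity=identity))
        dataset.append(AnnotatedImage(path=file_attr, width=w, height=h, faces=faces))
    return dataset


def write_dataset_xml(dataset: Sequence[AnnotatedImage], path: str | Path, name: str = "") -> None:
    """Write the data model back out in the annotation dialect (input order)."""
    root = etree.Element("dataset")
    etree.SubElement(root, "name").text = name or None
    images_el = etree.SubElement(root, "images")
    for img in dataset:
        img_el = etree.SubElement(
            images_el,
            "image",
            file=str(img.path),
            width=str(img.width),
            height=str(img.height),
        )
        for face in img.faces:
            box_el = etree.SubElement(
                img_el,
                "box",
                top=str(face.box.top),
                left=str(face.box.left),
                width=str(face.box.width),
                height=str(face.box.height),
            )
            if face.identity is not None:
                etree.SubElement(box_el, "label").text = face.identity
            if face.landmarks is not None:
                for n in LANDMARK_NAMES:
                    x, y = face.landmarks[n]
                    etree.SubElement(
                        box_el, "part", name=n, x=_format_float(x), y=_format_float(y)
                    )
    tree = etree.ElementTree(root)
    tree.write(str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8")


# ---------------------------------------------------------------------------
# Image loading


def load_image(path: str | Path) -> np.ndarray:
    """Load a JPEG/PNG image as an 8-bit RGB array (grayscale promoted)."""
    path = Path(path)
    if path.suffix.lower() not in SUPPORTED_IMAGE_SUFFIXES:
        raise AnnotationError(
            f"unsupported image format {path.suffix!r} for {path}; "
            "RAW or other formats must be converted to JPEG/PNG first"
        )
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def save_image(pixels: np.ndarray, path: str | Path) -> None:
    Image.fromarray(np.asarray(pixels, dtype=np.uint8)).save(str(path))


# ---------------------------------------------------------------------------
# Detection-scale policy


def _resize(pixels: np.ndarray, out_w: int, out_h: int) -> np.ndarray:
    im = Image.fromarray(np.asarray(pixels, dtype=np.uint8))
    return np.asarray(im.resize((out_w, out_h), Image.BILINEAR))


def scale_for_detection(
    pixels: np.ndarray,
    annotation: AnnotatedImage,
    policy: ScalePolicy = ScalePolicy(),
    is_test: bool = False,
) -> tuple[np.ndarray, AnnotatedImage, float]:
    """Apply the detection-scale policy to one image and its annotations.

    Returns the (possibly) rescaled pixels, annotations mapped into the output
    frame, and the uniform scale factor applied.  At test time a face that
    would fall below ``policy.min_face`` forces a larger scale followed by a
    frame-sized crop centered on that face.
    """
    h, w = pixels.shape[:2]
    if h < 1 or w < 1:
        raise AnnotationError("image smaller than 1x1")
    fit = min(1.0, policy.max_width / w, policy.max_height / h)
    scale = fit
    crop = None
    if is_test and annotation.faces:
        min_dim = min(min(f.box.width, f.box.height) for f in annotation.faces)
        if min_dim * fit < policy.min_face:
            scale = policy.min_face / min_dim
            face = min(annotation.faces, key=lambda f: min(f.box.width, f.box.height))
            if face.box.width * scale > policy.max_width or face.box.height * scale > policy.max_height:
                raise AnnotationError(
                    f"face {face.box} in {annotation.path!r} cannot fit the "
                    f"{policy.max_width}x{policy.max_height} frame at min_face scale"
                )
            crop = face

    out_w, out_h = max(1, int(round(w * scale))), max(1, int(round(h * scale)))
    out = pixels if scale == 1.0 else _resize(pixels, out_w, out_h)

    def map_face(f: FaceAnnotation, dx: int = 0, dy: int = 0) -> FaceAnnotation:
        lm = None
        if f.landmarks is not None:
            lm = f.landmarks.transformed(lambda p: (p[0] * scale - dx, p[1] * scale - dy))
        return FaceAnnotation(box=f.box.scaled(scale).shifted(-dx, -dy), landmarks=lm, identity=f.identity)

    if crop is None:
        faces = [map_face(f) for f in annotation.faces]
        ann = AnnotatedImage(path=annotation.path, width=out_w, height=out_h, faces=faces)
        return out, ann, scale

    # crop branch: frame centered on the offending face, clamped to bounds
    cx, cy = crop.box.center
    cx, cy = cx * scale, cy * scale
    crop_w, crop_h = min(policy.max_width, out_w), min(policy.max_height, out_h)
    x0 = int(round(min(max(0, cx - crop_w / 2), out_w - crop_w)))
    y0 = int(round(min(max(0, cy - crop_h / 2), out_h - crop_h)))
    out = out[y0 : y0 + crop_h, x0 : x0 + crop_w]
    faces = [
        map_face(f, dx=x0, dy=y0)
        for f in annotation.faces
        if f.box.scaled(scale).shifted(-x0, -y0).intersects_frame(crop_w, crop_h)
    ]
    ann = AnnotatedImage(path=annotation.path, width=crop_w, height=crop_h, faces=faces)
    return out, ann, scale


# ---------------------------------------------------------------------------
# Partitioning


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def split_train_test(items: Sequence, spec: SplitSpec) -> tuple[list, list]:
    """Seed-deterministic random train/test partition.

    The train count is round-half-away-from-zero of ``n * train_fraction``
    (4,675 items at 0.8 give a 3,740/935 split).
    """
    n = len(items)
    if n < 2:
        raise AnnotationError("need at least 2 items to split")
    n_train = _round_half_away(n * spec.train_fraction)
    n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    train = [items[i] for i in perm[:n_train]]
    test = [items[i] for i in perm[n_train:]]
    return train, test


def kfold_split(items: Sequence, labels: Sequence[str], spec: SplitSpec) -> list[list[int]]:
    """Partition item indices into k folds, by chip or by identity label.

    ``by_chip`` shuffles items and splits them as evenly as possible (sizes
    differ by at most one, larger folds first).  ``by_label`` assigns every
    item of an identity to a single fold, so fold identity sets are disjoint.
    """
    n = len(items)
    if len(labels) != n:
        raise AnnotationError("items and labels must align")
    rng = np.random.default_rng(spec.seed)
    if spec.mode == "by_chip":
        if spec.k > n:
            raise AnnotationError(f"cannot make {spec.k} folds from {n} chips")
        perm = rng.permutation(n)
        return [list(map(int, part)) for part in np.array_split(perm, spec.k)]
    # by_label
    uniq = list(dict.fromkeys(labels))
    if spec.k > len(uniq):
        raise AnnotationError(
            f"by_label folding needs at least k={spec.k} labels, got {len(uniq)}"
        )
    order = rng.permutation(len(uniq))
    fold_of_label = {uniq[j]: int(i % spec.k) for i, j in enumerate(order)}
    folds: list[list[int]] = [[] for _ in range(spec.k)]
    for i, lab in enumerate(labels):
        folds[fold_of_label[lab]].append(i)
    return folds
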