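"""End-to-end orchestration: images in, identity-annotated XML out.

A :class:`ModelBundle` holds the four trained stage models (detector, shape
regressor, embedder, classifier) with compatibility validation, and
:func:`run_full_pipeline` chains detection, landmark localization, chip
extraction, embedding and classification over a directory of photographs,
producing the annotation XML plus per-stage accounting.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np

from .annotations import (
    AnnotatedImage,
    AnnotationError,
    FaceAnnotation,
    SUPPORTED_IMAGE_SUFFIXES,
    load_image,
    write_dataset_xml,
)
from .chips import ChipSpec, chip_face
from .classification import IdentityClassifier
from .detection import FaceDetector
from .embedding import EMBED_DIM, MetricEmbedder
from .shapes import ShapeRegressor

logger = logging.getLogger("wildface")


@dataclass
class ModelBundle:
    detector: FaceDetector
    shape: ShapeRegressor
    embedder: MetricEmbedder
    classifier: IdentityClassifier
    chip_spec: ChipSpec = field(default_factory=ChipSpec)
    version: str = "1"
    seeds: dict = field(default_factory=dict)

    def validate(self) -> None:
        """Check stage input/output contracts line up before processing."""
        if self.chip_spec.size != self.embedder.chip_size:
            raise AnnotationError(
                f"chip size {self.chip_spec.size} does not match embedder input "
                f"{self.embedder.chip_size}"
            )
        if getattr(self.classifier, "dim_", EMBED_DIM) != EMBED_DIM:
            raise AnnotationError("classifier dimension does not match the embedding size")

    def config_digest(self) -> str:
        payload = json.dumps(
            {
                "version": self.version,
                "seeds": self.seeds,
                "chip": [self.chip_spec.size],
                "detector": repr(sorted(self.detector.get_params().items())),
                "embedder": repr(sorted(self.embedder.get_params().items())),
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def save(self, path: str | Path) -> None:
        joblib.dump({"format": "wildface-bundle-v1", "bundle": self}, path)

    @classmethod
    def load(cls, path: str | Path) -> "ModelBundle":
        blob = joblib.load(path)
        if blob.get("format") != "wildface-bundle-v1":
            raise AnnotationError(f"{path} is not a model bundle file")
        return blob["bundle"]


def process_image(pixels: np.ndarray, bundle: ModelBundle, path: str = "") -> AnnotatedImage:
    """Run all stages on one decoded image."""
    h, w = pixels.shape[:2]
    faces = []
    for sb in bundle.detector.detect(pixels):
        landmarks = bundle.shape.predict(pixels, sb.rect)
        chip = chip_face(pixels, landmarks, bundle.chip_spec, source_path=path, source_box=sb.rect)
        embedding = bundle.embedder.embed(chip)
        result = bundle.classifier.classify(embedding)
        faces.append(FaceAnnotation(box=sb.rect, landmarks=landmarks, identity=result.label))
    return AnnotatedImage(path=path, width=w, height=h, faces=faces)


def run_pipeline_on_arrays(
    images: list[np.ndarray],
    names: list[str],
    bundle: ModelBundle,
) -> tuple[list[AnnotatedImage], dict]:
    """In-memory pipeline run; returns annotations and per-stage counts."""
    bundle.validate()
    out = []
    counts = {"images": 0, "faces": 0, "chips": 0, "embeddings": 0, "ids": 0}
    for px, name in zip(images, names):
        ann = process_image(px, bundle, path=name)
        counts["images"] += 1
        counts["faces"] += len(ann.faces)
        counts["chips"] += len(ann.faces)
        counts["embeddings"] += len(ann.faces)
        counts["ids"] += sum(1 for f in ann.faces if f.identity is not None)
        out.append(ann)
    return out, counts


def run_full_pipeline(
    image_dir: str | Path,
    bundle: ModelBundle,
    out_path: str | Path,
) -> tuple[list[AnnotatedImage], dict]:
    """Annotate every image in a directory; returns (dataset, accounting).

    Undecodable files are logged and skipped (counted as warnings); images
    with no detected face are still listed with zero boxes.  Deterministic
    given the bundle; files are processed in sorted-name order and the output
    does not depend on processing order.
    """
    bundle.validate()
    image_dir = Path(image_dir)
    paths = sorted(
        p for p in image_dir.iterdir() if p.suffix.lower() in SUPPORTED_IMAGE_SUFFIXES
    )
    if not paths:
        raise AnnotationError(f"no JPEG/PNG images found in {image_dir}")
    dataset: list[AnnotatedImage] = []
    warnings = 0
    counts = {"images": 0, "faces": 0, "chips": 0, "embeddings": 0, "ids": 0}
    for p in paths:
        try:
            pixels = load_image(p)
        except Exception as exc:  # undecodable file
            logger.warning("skipping undecodable image %s: %s", p, exc)
            warnings += 1
            continue
        ann = process_image(pixels, bundle, path=str(p))
        counts["images"] += 1
        counts["faces"] += len(ann.faces)
        counts["chips"] += len(ann.faces)
        counts["embeddings"] += len(ann.faces)
        counts["ids"] += sum(1 for f in ann.faces if f.identity is not None)
        dataset.append(ann)
        logger.info("%s: %d face(s)", p.name, len(ann.faces))
    write_dataset_xml(dataset, out_path)
    accounting = {
        "warnings": warnings,
        "config_digest": bundle.config_digest(),
        **counts,
    }
    prov_path = Path(out_path).with_suffix(".provenance.json")
    prov_path.write_text(json.dumps(accounting, indent=2, sort_keys=True))
    return dataset, accounting
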