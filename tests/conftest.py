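import numpy as np
import pytest

from wildface import chip_face, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """8 identities x 6 images: shared fixture for fast unit tests."""
    return generate_dataset(8, 6, seed=101)


@pytest.fixture(scope="session")
def small_chips(small_dataset):
    chips, labels = [], []
    for px, ann in zip(small_dataset.images, small_dataset.annotations):
        face = ann.faces[0]
        chips.append(chip_face(px, face.landmarks).pixels)
        labels.append(face.identity)
    return chips, labels


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(7)


def random_annotated_dataset(rng, n_images=5):
    """Random in-memory annotation structures (no pixel data) for I/O tests."""
    from wildface import AnnotatedImage, BoxRect, FaceAnnotation, LandmarkSet
    from wildface.annotations import LANDMARK_NAMES

    out = []
    for i in range(n_images):
        w, h = int(rng.integers(200, 2000)), int(rng.integers(200, 2000))
        faces = []
        for _ in range(int(rng.integers(0, 3))):
            bw, bh = int(rng.integers(20, w // 2 + 21)), int(rng.integers(20, h // 2 + 21))
            box = BoxRect(int(rng.integers(0, w - bw)), int(rng.integers(0, h - bh)), bw, bh)
            landmarks = None
            if rng.random() < 0.7:
                pts = {}
                for j, name in enumerate(LANDMARK_NAMES):
                    pts[name] = (
                        box.left + float(rng.uniform(0, bw)) + j,  # j keeps eyes distinct
                        box.top + float(rng.uniform(0, bh)),
                    )
                landmarks = LandmarkSet(pts)
            identity = None if rng.random() < 0.3 else f"bear_{int(rng.integers(0, 9))}"
            faces.append(FaceAnnotation(box=box, landmarks=landmarks, identity=identity))
        out.append(AnnotatedImage(path=f"img_{i:03d}.jpg", width=w, height=h, faces=faces))
    return out
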