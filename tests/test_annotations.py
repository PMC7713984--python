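"""Data model, XML dialect round-trip, scale policy and partitioning."""

import numpy as np
import pytest

from wildface import (
    AnnotatedImage,
    AnnotationError,
    BoxRect,
    FaceAnnotation,
    LandmarkSet,
    ScalePolicy,
    SplitSpec,
    kfold_split,
    read_dataset_xml,
    scale_for_detection,
    split_train_test,
    write_dataset_xml,
)
from conftest import random_annotated_dataset


class TestDataModel:
    def test_box_rejects_nonpositive_size(self):
        with pytest.raises(AnnotationError):
            BoxRect(0, 0, 0, 10)

    def test_landmarks_require_all_six_names(self):
        with pytest.raises(AnnotationError, match="missing"):
            LandmarkSet({"leye": (0, 0), "reye": (1, 0)})

    def test_landmarks_reject_coincident_eyes(self):
        pts = {n: (float(i), 0.0) for i, n in enumerate(
            ["leye", "reye", "nose", "lear", "rear", "head"])}
        pts["reye"] = pts["leye"]
        with pytest.raises(AnnotationError, match="coincide"):
            LandmarkSet(pts)


class TestXmlDialect:
    def test_single_image_box_parts_label(self, tmp_path):
        xml = tmp_path / "d.xml"
        xml.write_text(
            """<?xml version='1.0'?><dataset><name/><images>
            <image file='toffee.jpg' width='640' height='480'>
              <box top='10' left='20' width='100' height='110'>
                <label>Toffee</label>
                <part name='leye' x='40' y='50'/><part name='reye' x='90' y='50'/>
                <part name='nose' x='65' y='80'/><part name='lear' x='30' y='20'/>
                <part name='rear' x='105' y='20'/><part name='head' x='65' y='12'/>
              </box>
            </image></images></dataset>"""
        )
        ds = read_dataset_xml(xml)
        assert len(ds) == 1 and len(ds[0].faces) == 1
        face = ds[0].faces[0]
        assert face.identity == "Toffee"
        assert face.box == BoxRect(20, 10, 100, 110)
        assert face.landmarks["leye"] == (40.0, 50.0)

    def test_image_with_no_boxes(self, tmp_path):
        xml = tmp_path / "d.xml"
        xml.write_text(
            "<?xml version='1.0'?><dataset><name/><images>"
            "<image file='empty.jpg' width='10' height='10'/></images></dataset>"
        )
        ds = read_dataset_xml(xml)
        assert len(ds) == 1 and ds[0].faces == []

    def test_malformed_xml_raises(self, tmp_path):
        xml = tmp_path / "bad.xml"
        xml.write_text("<dataset><images><image file='x'")
        with pytest.raises(AnnotationError, match="malformed"):
            read_dataset_xml(xml)

    def test_unknown_part_name_raises(self, tmp_path):
        xml = tmp_path / "d.xml"
        xml.write_text(
            "<?xml version='1.0'?><dataset><images>"
            "<image file='x.jpg' width='10' height='10'>"
            "<box top='1' left='1' width='5' height='5'>"
            "<part name='tail' x='1' y='1'/></box></image></images></dataset>"
        )
        with pytest.raises(AnnotationError, match="tail"):
            read_dataset_xml(xml)

    def test_empty_dataset_roundtrip(self, tmp_path):
        p = tmp_path / "empty.xml"
        write_dataset_xml([], p)
        assert read_dataset_xml(p) == []

    def test_face_without_landmarks_emits_no_parts(self, tmp_path):
        ds = [AnnotatedImage(path="a.jpg", width=50, height=50,
                             faces=[FaceAnnotation(box=BoxRect(1, 2, 10, 10))])]
        p = tmp_path / "d.xml"
        write_dataset_xml(ds, p)
        assert b"<part" not in p.read_bytes()
        back = read_dataset_xml(p)
        assert back[0].faces[0].landmarks is None

    @pytest.mark.parametrize("seed", range(20))
    def test_roundtrip_identity_on_random_datasets(self, tmp_path, seed):
        rng = np.random.default_rng(seed)
        ds = random_annotated_dataset(rng, n_images=4)
        p = tmp_path / "d.xml"
        write_dataset_xml(ds, p)
        back = read_dataset_xml(p)
        assert len(back) == len(ds)
        for a, b in zip(ds, back):
            assert (a.path, a.width, a.height) == (b.path, b.width, b.height)
            assert len(a.faces) == len(b.faces)
            for fa, fb in zip(a.faces, b.faces):
                assert fa.box == fb.box
                assert fa.identity == fb.identity
                if fa.landmarks is None:
                    assert fb.landmarks is None
                else:
                    assert fa.landmarks.points == fb.landmarks.points


class TestScalePolicy:
    def _image(self, w, h, faces):
        return np.zeros((h, w, 3), dtype=np.uint8), AnnotatedImage(
            path="x.jpg", width=w, height=h, faces=faces
        )

    def test_downscale_to_frame(self):
        px, ann = self._image(4000, 3000, [FaceAnnotation(box=BoxRect(1000, 1000, 600, 600))])
        out, out_ann, s = scale_for_detection(px, ann, ScalePolicy())
        assert s == pytest.approx(0.5)
        assert out.shape[:2] == (1500, 2000)
        assert out_ann.faces[0].box == BoxRect(500, 500, 300, 300)

    def test_small_image_unchanged(self):
        px, ann = self._image(1000, 800, [])
        out, _, s = scale_for_detection(px, ann, ScalePolicy())
        assert s == 1.0 and out.shape[:2] == (800, 1000)

    def test_test_time_min_face_crop(self):
        # plain fit would shrink the 400px face to 100px; min_face forces
        # scale 0.5 and a centered frame crop
        px, ann = self._image(8000, 6000, [FaceAnnotation(box=BoxRect(3800, 2800, 400, 400))])
        out, out_ann, s = scale_for_detection(px, ann, ScalePolicy(), is_test=True)
        assert s == pytest.approx(0.5)
        assert out.shape[:2] == (1500, 2000)
        fb = out_ann.faces[0].box
        assert (fb.width, fb.height) == (200, 200)
        # face centered in the cropped frame
        assert abs(fb.center[0] - 1000) <= 1 and abs(fb.center[1] - 750) <= 1

    def test_aspect_ratio_preserved(self):
        px, ann = self._image(3123, 1717, [])
        out, _, s = scale_for_detection(px, ann, ScalePolicy())
        in_ratio = 3123 / 1717
        out_ratio = out.shape[1] / out.shape[0]
        assert abs(out_ratio / in_ratio - 1) < 0.01

    def test_landmark_at_box_center_stays_at_center(self):
        pts = {"leye": (1940.0, 1450.0), "reye": (2060.0, 1450.0), "nose": (2000.0, 1550.0),
               "lear": (1900.0, 1380.0), "rear": (2100.0, 1380.0), "head": (2000.0, 1500.0)}
        face = FaceAnnotation(box=BoxRect(1700, 1200, 600, 600), landmarks=LandmarkSet(pts))
        px, ann = self._image(4000, 3000, [face])
        _, out_ann, s = scale_for_detection(px, ann, ScalePolicy())
        f = out_ann.faces[0]
        assert f.landmarks["head"] == pytest.approx(f.box.center, abs=1.0)

    def test_oversized_test_face_raises(self):
        px, ann = self._image(400, 400, [FaceAnnotation(box=BoxRect(0, 0, 120, 180))])
        policy = ScalePolicy(max_width=300, max_height=250, min_face=200)
        with pytest.raises(AnnotationError, match="cannot fit"):
            scale_for_detection(px, ann, policy, is_test=True)


class TestSplits:
    def test_golden_dataset_split_arithmetic(self):
        train, test = split_train_test(list(range(4675)), SplitSpec(seed=0))
        assert (len(train), len(test)) == (3740, 935)

    def test_small_split(self):
        train, test = split_train_test(list(range(10)), SplitSpec(seed=1))
        assert (len(train), len(test)) == (8, 2)

    @pytest.mark.parametrize("seed", range(10))
    def test_split_partitions_and_is_seed_deterministic(self, seed):
        items = list(range(57))
        a = split_train_test(items, SplitSpec(seed=seed))
        b = split_train_test(items, SplitSpec(seed=seed))
        assert a == b
        assert sorted(a[0] + a[1]) == items
        other = split_train_test(items, SplitSpec(seed=seed + 1000))
        assert other[0] != a[0]  # different permutation, same sizes
        assert len(other[0]) == len(a[0])

    def test_too_few_items_raises(self):
        with pytest.raises(AnnotationError):
            split_train_test([1], SplitSpec())

    def test_fold_sizes_by_chip(self):
        items = list(range(4674))
        folds = kfold_split(items, ["x"] * 4674, SplitSpec(k=5, mode="by_chip", seed=0))
        assert sorted(len(f) for f in folds) == [934, 935, 935, 935, 935]
        all_idx = sorted(i for f in folds for i in f)
        assert all_idx == items

    def test_by_label_one_label_per_fold(self):
        labels = [f"b{i}" for i in range(5) for _ in range(3)]
        folds = kfold_split(list(range(15)), labels, SplitSpec(k=5, mode="by_label", seed=0))
        for f in folds:
            assert len({labels[i] for i in f}) == 1

    @pytest.mark.parametrize("seed", range(20))
    def test_by_label_folds_have_disjoint_identities(self, seed):
        rng = np.random.default_rng(seed)
        labels = [f"id{int(v)}" for v in rng.integers(0, 12, size=80)]
        k = 4
        folds = kfold_split(list(range(80)), labels, SplitSpec(k=k, mode="by_label", seed=seed))
        sets = [{labels[i] for i in f} for f in folds]
        for i in range(k):
            for j in range(i + 1, k):
                assert not (sets[i] & sets[j])
        assert sorted(x for f in folds for x in f) == list(range(80))

    def test_by_label_fewer_labels_than_k_raises(self):
        with pytest.raises(AnnotationError):
            kfold_split([1, 2, 3], ["a", "a", "b"], SplitSpec(k=3, mode="by_label"))
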