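import math

import numpy as np
import pytest

from pestbox.dataset_io import (
    AnchorSet,
    AugmentationPlan,
    DEFAULT_ANCHORS,
    ScheduleConfig,
    SplitSpec,
    _kmeans_iou,
    augment,
    cosine_schedule,
    kmeans_anchors,
    read_voc_xml,
    schedule_curve,
    split_dataset,
    write_voc_xml,
)
from pestbox.geometry import Annotation, Box, ImageSize


class TestVocXml:
    def _annots(self):
        return [
            Annotation("scene_00001", 4, Box(10, 20, 30, 40)),
            Annotation("scene_00001", 19, Box(100, 200, 165, 260)),
        ]

    def test_round_trip_byte_identical(self, tmp_path):
        p1, p2 = tmp_path / "a.xml", tmp_path / "b.xml"
        write_voc_xml(p1, ImageSize(2095, 1944), self._annots(), image_id="scene_00001")
        size, annots = read_voc_xml(p1)
        assert size == ImageSize(2095, 1944)
        assert annots == self._annots()
        write_voc_xml(p2, size, annots, image_id="scene_00001")
        assert p1.read_bytes() == p2.read_bytes()

    def test_pixel_index_conversion(self, tmp_path):
        # VOC's 1-based inclusive (11,21,30,40) is the geometric box (10,20,30,40)
        path = tmp_path / "c.xml"
        path.write_text(
            "<annotation><filename>x.jpg</filename>"
            "<size><width>100</width><height>100</height></size>"
            "<object><name>Bollworm</name><bndbox>"
            "<xmin>11</xmin><ymin>21</ymin><xmax>30</xmax><ymax>40</ymax>"
            "</bndbox></object></annotation>"
        )
        _, annots = read_voc_xml(path)
        assert annots[0].box == Box(10, 20, 30, 40)
        assert annots[0].box.area == 400
        assert annots[0].class_id == 4

    def test_unknown_class_named_in_error(self, tmp_path):
        path = tmp_path / "bad.xml"
        path.write_text(
            "<annotation><size><width>10</width><height>10</height></size>"
            "<object><name>Martian weevil</name><bndbox>"
            "<xmin>1</xmin><ymin>1</ymin><xmax>5</xmax><ymax>5</ymax>"
            "</bndbox></object></annotation>"
        )
        with pytest.raises(ValueError, match="Martian weevil"):
            read_voc_xml(path)

    def test_inverted_box_rejected(self, tmp_path):
        path = tmp_path / "inv.xml"
        path.write_text(
            "<annotation><size><width>10</width><height>10</height></size>"
            "<object><name>Bollworm</name><bndbox>"
            "<xmin>8</xmin><ymin>1</ymin><xmax>3</xmax><ymax>5</ymax>"
            "</bndbox></object></annotation>"
        )
        with pytest.raises(ValueError, match="object 0"):
            read_voc_xml(path)

    def test_malformed_xml_rejected(self, tmp_path):
        path = tmp_path / "broken.xml"
        path.write_text("<annotation><size>")
        with pytest.raises(ValueError, match="malformed"):
            read_voc_xml(path)


class TestSplitDataset:
    def test_largest_remainder_sizes(self):
        train, val, test = split_dataset([f"im{i}" for i in range(10)])
        assert (len(train), len(val), len(test)) == (7, 2, 1)

    def test_deterministic(self):
        ids = [f"im{i}" for i in range(57)]
        assert split_dataset(ids, SplitSpec(seed=3)) == split_dataset(ids, SplitSpec(seed=3))
        assert split_dataset(ids, SplitSpec(seed=3)) != split_dataset(ids, SplitSpec(seed=4))

    @pytest.mark.parametrize("n", [3, 10, 101, 997])
    def test_partition_invariants(self, n):
        ids = [f"im{i}" for i in range(n)]
        train, val, test = split_dataset(ids, SplitSpec(seed=1))
        assert len(train) + len(val) + len(test) == n
        assert set(train) | set(val) | set(test) == set(ids)
        assert not (set(train) & set(val)) and not (set(val) & set(test)) and not (set(train) & set(test))

    def test_bad_ratios_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec(ratios=(0.5, 0.2, 0.2))


class TestAugment:
    def _scene(self):
        rng = np.random.default_rng(0)
        image = rng.random((50, 100, 3))
        annots = [
            Annotation("im", 16, Box(10, 20, 30, 40)),
            Annotation("im", 2, Box(60, 5, 80, 25)),
        ]
        return image, annots

    def test_hflip_box_mapping(self):
        image, annots = self._scene()
        plan = AugmentationPlan(transforms=("hflip",), variants_per_image=1, seed=0)
        variants = augment(image, annots, plan)
        assert len(variants) == 1
        img, new_annots = variants[0]
        assert new_annots[0].box == Box(100 - 30, 20, 100 - 10, 40)
        np.testing.assert_allclose(img, image[:, ::-1])

    def test_flip_twice_is_identity(self):
        image, annots = self._scene()
        plan = AugmentationPlan(transforms=("hflip",), variants_per_image=1, seed=0)
        (img1, a1), = augment(image, annots, plan)
        (img2, a2), = augment(img1, a1, plan)
        assert [a.box for a in a2] == [a.box for a in annots]
        np.testing.assert_allclose(img2, image)

    def test_hue_shift_leaves_boxes_unchanged(self):
        image, annots = self._scene()
        plan = AugmentationPlan(transforms=("hue",), variants_per_image=3, seed=1)
        for img, new_annots in augment(image, annots, plan):
            assert [a.box for a in new_annots] == [a.box for a in annots]
            assert img.shape == image.shape

    def test_non_target_image_not_augmented(self):
        image, annots = self._scene()
        plan = AugmentationPlan(target_classes=frozenset({23}), seed=0)
        assert augment(image, annots, plan) == []

    def test_boxes_stay_inside_image_and_keep_class(self):
        image, annots = self._scene()
        plan = AugmentationPlan(variants_per_image=8, seed=5)
        for img, new_annots in augment(image, annots, plan):
            assert {a.class_id for a in new_annots} <= {a.class_id for a in annots}
            for a in new_annots:
                assert 0 <= a.box.x1 < a.box.x2 <= 100
                assert 0 <= a.box.y1 < a.box.y2 <= 50

    def test_unknown_transform_rejected(self):
        with pytest.raises(ValueError, match="unknown transforms"):
            AugmentationPlan(transforms=("mosaic",))


class TestKMeansAnchors:
    def test_single_cluster_of_identical_pairs(self):
        wh = [(30.0, 40.0)] * 20
        anchors = kmeans_anchors(wh, k=1, seed=0)
        assert anchors.anchors == ((30.0, 40.0),)
        assert anchors.mean_iou == pytest.approx(1.0)

    def test_k_equals_distinct_pairs_perfect_objective(self):
        wh = [(10.0, 10.0), (30.0, 15.0), (80.0, 90.0)] * 5
        anchors = kmeans_anchors(wh, k=3, seed=0)
        assert anchors.mean_iou == pytest.approx(1.0)
        assert set(anchors.anchors) == set(wh[:3])

    def test_two_tight_clusters(self, rng):
        a = rng.normal([10, 12], 0.5, size=(40, 2))
        b = rng.normal([100, 80], 2.0, size=(40, 2))
        wh = np.vstack([a, b])
        anchors = kmeans_anchors(wh, k=2, seed=1)
        (w1, h1), (w2, h2) = anchors.anchors
        assert 8 < w1 < 12 and 10 < h1 < 14
        assert 90 < w2 < 110 and 70 < h2 < 90

    def test_k_larger_than_distinct_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            kmeans_anchors([(10.0, 10.0)] * 5, k=2)

    def test_objective_monotone_nonincreasing(self, rng):
        wh = rng.uniform(5, 200, size=(300, 2))
        _, history = _kmeans_iou(wh, 9, np.random.default_rng(0))
        assert all(a >= b - 1e-12 for a, b in zip(history, history[1:]))

    def test_input_order_invariance_with_fixed_init(self, rng):
        wh = rng.uniform(5, 200, size=(200, 2))
        init = wh[:5].copy()
        c1, _ = _kmeans_iou(wh, 5, np.random.default_rng(0), init_centers=init)
        perm = rng.permutation(len(wh))
        c2, _ = _kmeans_iou(wh[perm], 5, np.random.default_rng(0), init_centers=init)
        np.testing.assert_allclose(np.sort(c1, axis=0), np.sort(c2, axis=0))

    def test_default_anchors_area_sorted(self):
        areas = [w * h for w, h in DEFAULT_ANCHORS]
        assert areas == sorted(areas)
        assert len(DEFAULT_ANCHORS) == 9

    def test_csv_round_trip(self, tmp_path):
        anchors = AnchorSet(DEFAULT_ANCHORS)
        anchors.save_csv(tmp_path / "anchors.csv")
        loaded = AnchorSet.load_csv(tmp_path / "anchors.csv")
        assert loaded.anchors == tuple((float(w), float(h)) for w, h in DEFAULT_ANCHORS)


class TestCosineSchedule:
    def test_cosine_phase_endpoints(self):
        cfg = ScheduleConfig()
        assert cfg.at(cfg.cosine_start) == pytest.approx(0.001)
        assert cfg.at(cfg.total_epochs) == pytest.approx(0.0001)

    def test_cosine_midpoint(self):
        cfg = ScheduleConfig()
        mid = cfg.cosine_start + (cfg.total_epochs - cfg.cosine_start) / 2
        assert cfg.at(int(mid)) == pytest.approx((0.001 + 0.0001) / 2)

    def test_warmup_ramps_linearly_from_minimum(self):
        cfg = ScheduleConfig()
        assert cfg.at(0) == pytest.approx(0.0001)
        deltas = np.diff([cfg.at(e) for e in range(cfg.warmup_epochs + 1)])
        np.testing.assert_allclose(deltas, deltas[0])

    def test_continuous_and_nonincreasing_after_warmup(self):
        curve = schedule_curve(ScheduleConfig())
        jumps = np.abs(np.diff(curve))
        assert jumps.max() < 2e-4  # no discontinuity at phase boundaries
        cosine = curve[ScheduleConfig().cosine_start :]
        assert np.all(np.diff(cosine) <= 1e-15)

    def test_epoch_out_of_range_rejected(self):
        cfg = ScheduleConfig(t_cur=250)
        with pytest.raises(ValueError, match="outside"):
            cosine_schedule(cfg)

    def test_cosine_schedule_uses_t_cur(self):
        cfg = ScheduleConfig(t_cur=10)
        assert cosine_schedule(cfg) == cfg.at(10)
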