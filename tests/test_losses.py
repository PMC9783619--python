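import math

import numpy as np
import pytest

from pestbox.geometry import Annotation, Box, ImageSize
from pestbox.losses import (
    EPS,
    GridSpec,
    LossWeights,
    PredictionGrid,
    TargetAssignment,
    assign_targets,
    class_loss,
    confidence_loss,
    coord_loss,
    default_grid_specs,
    focal_term,
    total_loss,
)


def tiny_spec(num_classes=2, K=2, M=1, anchors=((20, 20),)):
    return GridSpec(K=K, M=M, anchors=anchors, num_classes=num_classes)


def one_slot_assignment(c_hat=1.0):
    """A 1x1x1 grid whose single slot is a positive (object) slot."""
    spec = GridSpec(K=1, M=1, anchors=((20, 20),), num_classes=1)
    tgt = TargetAssignment.empty(spec)
    tgt.obj_mask[0, 0, 0] = True
    tgt.noobj_mask[0, 0, 0] = False
    tgt.target_boxes[0, 0, 0] = (0, 0, 20, 20)
    tgt.target_wh[0, 0, 0] = (20 / 416, 20 / 416)
    tgt.target_class[0, 0, 0, 0] = 1.0
    tgt.target_conf[0, 0, 0] = c_hat
    return spec, tgt


def grid_with_objectness(spec, tgt, objectness):
    boxes = tgt.target_boxes.copy()
    boxes[~tgt.obj_mask] = (0, 0, 1, 1)
    return PredictionGrid(
        spec=spec,
        boxes=boxes,
        objectness=objectness,
        class_probs=tgt.target_class.copy(),
    )


class TestFocalTerm:
    def test_zero_at_certainty(self):
        assert focal_term(1.0, alpha=0.25, gamma=2.0) == 0.0

    def test_gamma_zero_is_scaled_cross_entropy(self, rng):
        p = rng.uniform(0.01, 0.99, size=50)
        np.testing.assert_allclose(focal_term(p, 0.3, 0.0), -0.3 * np.log(p), rtol=1e-12)

    def test_worked_hundredfold_ratio(self):
        # at p_t = 0.9 the gamma=2 modulator (1-p_t)^2 lowers the loss 100x
        ce = focal_term(0.9, alpha=1.0, gamma=0.0)
        fl = focal_term(0.9, alpha=1.0, gamma=2.0)
        assert ce / fl == pytest.approx(100.0, rel=1e-9)

    def test_monotone_in_gamma_for_easy_samples(self):
        values = [focal_term(0.75, 1.0, g) for g in np.linspace(0, 5, 21)]
        assert all(a >= b - 1e-15 for a, b in zip(values, values[1:]))

    def test_finite_at_zero_probability(self):
        v = focal_term(0.0, 1.0, 2.0)
        assert np.isfinite(v)
        assert v == pytest.approx(-math.log(EPS), rel=1e-6)


class TestAssignTargets:
    def test_no_annotations(self):
        tgt = assign_targets([], tiny_spec())
        assert not tgt.obj_mask.any()
        assert tgt.noobj_mask.all()

    def test_center_cell_selection(self):
        specs = default_grid_specs(num_classes=24)
        ann = Annotation("img", 0, Box(208 - 70, 208 - 55, 208 + 70, 208 + 55))
        assigns = assign_targets([ann], specs)
        # (140, 110) is exactly the coarse-scale anchor; cell = floor(208/32) = 6
        coarse = assigns[0]
        assert coarse.obj_mask[6, 6, 0]
        assert coarse.obj_mask.sum() + assigns[1].obj_mask.sum() + assigns[2].obj_mask.sum() == 1

    def test_exact_anchor_match_wins(self):
        specs = default_grid_specs(num_classes=24)
        for si, spec in enumerate(specs):
            for ai, (aw, ah) in enumerate(spec.anchors):
                ann = Annotation("img", 3, Box(200 - aw / 2, 200 - ah / 2, 200 + aw / 2, 200 + ah / 2))
                assigns = assign_targets([ann], specs)
                slots = [a.obj_mask.sum() for a in assigns]
                assert slots[si] == 1 and sum(slots) == 1
                assert assigns[si].obj_mask[..., ai].any()

    def test_slot_conflict_larger_area_wins(self):
        spec = GridSpec(K=1, M=1, anchors=((100, 100),), num_classes=2, input_size=ImageSize(416, 416))
        small = Annotation("img", 0, Box(150, 150, 250, 250))
        large = Annotation("img", 1, Box(100, 100, 300, 300))
        with pytest.warns(UserWarning):
            tgt = assign_targets([small, large], spec)
        assert tgt.obj_mask.sum() == 1
        assert tgt.target_class[0, 0, 0, 1] == 1.0

    def test_masks_are_complementary(self):
        specs = default_grid_specs(num_classes=24)
        anns = [Annotation("img", i % 24, Box(30 * i + 5, 20 * i + 5, 30 * i + 25, 20 * i + 30)) for i in range(8)]
        for tgt in assign_targets(anns, specs):
            assert not (tgt.obj_mask & tgt.noobj_mask).any()
            assert (tgt.obj_mask | tgt.noobj_mask).all()


class TestCoordLoss:
    def test_perfect_boxes_zero(self):
        spec, tgt = one_slot_assignment()
        pred = PredictionGrid.perfect(tgt)
        assert coord_loss(pred, tgt) == pytest.approx(0.0, abs=1e-12)

    def test_small_box_weighting(self):
        # same geometric error, tiny target (w*h = 0.01) vs full-image target:
        # loss ratio equals (2 - 0.01) / (2 - 1) = 1.99
        spec, tgt_small = one_slot_assignment()
        tgt_small.target_wh[0, 0, 0] = (0.1, 0.1)
        _, tgt_full = one_slot_assignment()
        tgt_full.target_wh[0, 0, 0] = (1.0, 1.0)
        pred = PredictionGrid.perfect(tgt_small)
        pred.boxes[0, 0, 0] = (2, 2, 22, 22)  # shifted
        small = coord_loss(pred, tgt_small)
        full = coord_loss(pred, tgt_full)
        assert small / full == pytest.approx(1.99, rel=1e-12)

    def test_lambda_coord_scales_linearly(self):
        spec, tgt = one_slot_assignment()
        pred = PredictionGrid.perfect(tgt)
        pred.boxes[0, 0, 0] = (5, 5, 25, 25)
        one = coord_loss(pred, tgt, LossWeights(lambda_coord=1.0))
        two = coord_loss(pred, tgt, LossWeights(lambda_coord=2.0))
        assert two == pytest.approx(2 * one)

    def test_shape_mismatch_rejected(self):
        spec, tgt = one_slot_assignment()
        other = TargetAssignment.empty(tiny_spec(num_classes=1, K=2))
        pred = PredictionGrid.perfect(tgt)
        with pytest.raises(ValueError, match="grid"):
            coord_loss(pred, other)


class TestClassLoss:
    def test_perfect_prediction_near_zero(self):
        spec, tgt = one_slot_assignment()
        pred = PredictionGrid.perfect(tgt)
        assert class_loss(pred, tgt) == pytest.approx(0.0, abs=1e-5)

    def test_uniform_two_class_example(self):
        spec = GridSpec(K=1, M=1, anchors=((20, 20),), num_classes=2)
        tgt = TargetAssignment.empty(spec)
        tgt.obj_mask[0, 0, 0] = True
        tgt.noobj_mask[0, 0, 0] = False
        tgt.target_class[0, 0, 0, 0] = 1.0
        pred = PredictionGrid(
            spec=spec,
            boxes=np.broadcast_to(np.array([0, 0, 1, 1.0]), (1, 1, 1, 4)).copy(),
            objectness=np.ones((1, 1, 1)),
            class_probs=np.full((1, 1, 1, 2), 0.5),
        )
        assert class_loss(pred, tgt) == pytest.approx(2 * math.log(2), rel=1e-9)

    def test_no_positive_slots_zero(self):
        spec = tiny_spec()
        tgt = TargetAssignment.empty(spec)
        pred = PredictionGrid(
            spec=spec,
            boxes=np.broadcast_to(np.array([0, 0, 1, 1.0]), (2, 2, 1, 4)).copy(),
            objectness=np.full((2, 2, 1), 0.7),
            class_probs=np.full((2, 2, 1, 2), 0.3),
        )
        assert class_loss(pred, tgt) == 0.0


class TestConfidenceLoss:
    def test_perfect_confidences_near_zero(self):
        spec, tgt = one_slot_assignment()
        pred = PredictionGrid.perfect(tgt)
        assert confidence_loss(pred, tgt) == pytest.approx(0.0, abs=1e-5)

    def test_gamma_zero_reduces_to_bce(self, rng):
        specs = default_grid_specs(num_classes=24)
        anns = [
            Annotation("img", int(rng.integers(24)), Box(x, y, x + w, y + h))
            for x, y, w, h in rng.uniform([0, 0, 5, 5], [300, 300, 100, 100], size=(10, 4))
        ]
        tgts = assign_targets(anns, specs)
        w = LossWeights(alpha=1.0, lambda_noobj=1.0, gamma=0.0)
        for tgt in tgts:
            c = rng.uniform(0.01, 0.99, size=tgt.obj_mask.shape)
            pred = grid_with_objectness(tgt.spec, tgt, c)
            # independent BCE objectness oracle
            cc = np.clip(c, 1e-7, 1 - 1e-7)
            bce = -(tgt.target_conf * np.log(cc) + (1 - tgt.target_conf) * np.log(1 - cc))
            expected = bce[tgt.obj_mask].sum() + bce[tgt.noobj_mask].sum()
            assert confidence_loss(pred, tgt, w) == pytest.approx(expected, abs=1e-9)

    def test_focal_hundredfold_reduction_on_single_slot(self):
        spec, tgt = one_slot_assignment()
        pred = grid_with_objectness(spec, tgt, np.full((1, 1, 1), 0.9))
        plain = confidence_loss(pred, tgt, LossWeights(alpha=0.1, gamma=0.0))
        focal = confidence_loss(pred, tgt, LossWeights(alpha=0.1, gamma=2.0))
        assert plain / focal == pytest.approx(100.0, rel=1e-9)

    def test_finite_at_extreme_predictions(self):
        spec, tgt = one_slot_assignment()
        for value in (0.0, 1.0):
            pred = grid_with_objectness(spec, tgt, np.full((1, 1, 1), value))
            assert np.isfinite(confidence_loss(pred, tgt))

    def test_noobj_term_added_not_subtracted(self):
        spec = tiny_spec(num_classes=1)
        tgt = TargetAssignment.empty(spec)  # all background
        pred = PredictionGrid(
            spec=spec,
            boxes=np.broadcast_to(np.array([0, 0, 1, 1.0]), (2, 2, 1, 4)).copy(),
            objectness=np.full((2, 2, 1), 0.8),  # confidently wrong
            class_probs=np.ones((2, 2, 1, 1)),
        )
        assert confidence_loss(pred, tgt) > 0.0


class TestTotalLoss:
    def test_components_sum(self, rng):
        specs = default_grid_specs(num_classes=24)
        anns = [
            Annotation("img", int(rng.integers(24)), Box(x, y, x + w, y + h))
            for x, y, w, h in rng.uniform([0, 0, 5, 5], [300, 300, 80, 80], size=(6, 4))
        ]
        tgts = assign_targets(anns, specs)
        preds = []
        for tgt in tgts:
            pred = PredictionGrid.perfect(tgt)
            pred.objectness = np.clip(pred.objectness + rng.uniform(0, 0.1, pred.objectness.shape), 0, 1)
            preds.append(pred)
        w = LossWeights()
        breakdown = total_loss(preds, tgts, w)
        assert breakdown.total == pytest.approx(breakdown.coord + breakdown.cls + breakdown.conf)
        assert breakdown.coord == pytest.approx(sum(coord_loss(p, t, w) for p, t in zip(preds, tgts)))
        assert breakdown.conf == pytest.approx(sum(confidence_loss(p, t, w) for p, t in zip(preds, tgts)))

    def test_perfect_prediction_near_zero_total(self):
        spec, tgt = one_slot_assignment()
        pred = PredictionGrid.perfect(tgt)
        assert total_loss(pred, tgt).total == pytest.approx(0.0, abs=1e-4)

    def test_scale_count_mismatch_rejected(self):
        spec, tgt = one_slot_assignment()
        pred = PredictionGrid.perfect(tgt)
        with pytest.raises(ValueError, match="grids"):
            total_loss([pred, pred], [tgt])
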