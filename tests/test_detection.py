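import itertools
import logging

import numpy as np
import pytest

from autopatch import (
    PhantomCellDetector,
    PhantomSpec,
    ScoredBox,
    detect_cells_2d,
    expand_center_box,
    generate_cell_phantom_stack,
    merge_boxes_3d,
    rank_detections,
)
from autopatch.annotations import intersect_rects, rect_area


def B(k, x, y, w=20.0, h=20.0, conf=1.0):
    return ScoredBox(slice_index=k, x=x, y=y, w=w, h=h, confidence=conf)


def per_slice(boxes, n_slices):
    out = [[] for _ in range(n_slices)]
    for b in boxes:
        out[b.slice_index].append(b)
    return out


# -- Z merging --------------------------------------------------------------


def test_sixty_percent_intersection_rule_worked_example():
    # A at (10,10) 20x20 on slice 5, B at (12,10) 20x20 on slice 6:
    # intersection 18*20 = 360 px^2, smaller box 400 px^2 -> ratio 0.9 >= 0.6
    dets = merge_boxes_3d(per_slice([B(5, 10, 10), B(6, 12, 10)], 8))
    assert len(dets) == 1
    assert dets[0].depth_slices == 2


def test_below_ratio_boxes_stay_separate():
    # shift 9 px: intersection 11*20 = 220 / 400 = 0.55 < 0.6
    dets = merge_boxes_3d(per_slice([B(5, 10, 10), B(6, 19, 10)], 8))
    assert len(dets) == 2


def test_single_box_yields_depth_one_detection():
    dets = merge_boxes_3d(per_slice([B(3, 5, 5)], 6))
    assert len(dets) == 1
    assert dets[0].depth_slices == 1
    assert dets[0].confidence == 1.0


def test_three_slice_gap_rule_boundary():
    merged = merge_boxes_3d(per_slice([B(5, 10, 10), B(8, 10, 10)], 12))
    assert len(merged) == 1  # two empty slices between -> still united
    split = merge_boxes_3d(per_slice([B(5, 10, 10), B(9, 10, 10)], 12))
    assert len(split) == 2  # three empty slices between -> separate cells


def test_running_intersection_region_is_tracked():
    # boxes drift right by 8 px per slice; each consecutive pair overlaps well
    # but the running intersection shrinks and eventually rejects the drifter
    boxes = [B(k, 10 + 8 * k, 10) for k in range(4)]
    dets = merge_boxes_3d(per_slice(boxes, 6))
    assert len(dets) >= 2


def test_five_slice_annotation_reconstructs_single_detection():
    center = B(10, 30, 40)
    boxes = expand_center_box(center, n_slices=30)
    dets = merge_boxes_3d(per_slice(boxes, 30))
    assert len(dets) == 1
    assert dets[0].depth_slices == 5


def test_merge_partition_property():
    rng = np.random.default_rng(5)
    boxes = []
    for k in range(10):
        for _ in range(rng.integers(0, 4)):
            boxes.append(
                B(k, float(rng.uniform(0, 80)), float(rng.uniform(0, 80)), conf=float(rng.uniform(0.1, 1)))
            )
    dets = merge_boxes_3d(per_slice(boxes, 10))
    members = [b for d in dets for b in d.boxes]
    assert len(members) == len(boxes)
    assert set(map(id, members)) == set(map(id, boxes)) or sorted(
        (b.slice_index, b.x, b.y) for b in members
    ) == sorted((b.slice_index, b.x, b.y) for b in boxes)


def test_merge_invariant_to_within_slice_permutation():
    rng = np.random.default_rng(7)
    boxes = [
        B(k, float(rng.uniform(0, 60)), float(rng.uniform(0, 60)), conf=float(rng.uniform(0.1, 1)))
        for k in range(6)
        for _ in range(3)
    ]
    ref = merge_boxes_3d(per_slice(boxes, 6))
    for _ in range(5):
        shuffled = per_slice(boxes, 6)
        for sl in shuffled:
            rng.shuffle(sl)
        out = merge_boxes_3d(shuffled)
        assert [sorted((b.slice_index, b.x, b.y) for b in d.boxes) for d in out] == [
            sorted((b.slice_index, b.x, b.y) for b in d.boxes) for d in ref
        ]


def test_confidence_is_max_and_centroid_weighted():
    dets = merge_boxes_3d(
        per_slice([B(5, 10, 10, conf=0.4), B(6, 10, 10, conf=0.8)], 8), pixel_size_um=1.0, z_step_um=1.0
    )
    assert len(dets) == 1
    assert dets[0].confidence == pytest.approx(0.8)
    # confidence-weighted slice centroid: (5*0.4 + 6*0.8) / 1.2
    assert dets[0].centroid_um[2] == pytest.approx((5 * 0.4 + 6 * 0.8) / 1.2)


# -- ranking ----------------------------------------------------------------


def test_rank_orders_by_descending_confidence():
    dets = merge_boxes_3d(
        per_slice([B(0, 0, 0, conf=0.2), B(2, 50, 50, conf=0.9), B(4, 120, 0, conf=0.5)], 6)
    )
    ranked = rank_detections(dets)
    assert [round(d.confidence, 1) for d in ranked] == [0.9, 0.5, 0.2]


def test_rank_tie_break_is_spatial_and_permutation_stable():
    boxes = [B(0, 0, 0, conf=0.5), B(0, 60, 0, conf=0.5), B(0, 0, 60, conf=0.5)]
    ref = rank_detections(merge_boxes_3d(per_slice(boxes, 2)))
    for perm in itertools.permutations(boxes):
        out = rank_detections(merge_boxes_3d(per_slice(list(perm), 2)))
        assert [tuple(np.round(d.centroid_um, 6)) for d in out] == [
            tuple(np.round(d.centroid_um, 6)) for d in ref
        ]


# -- per-slice detector -----------------------------------------------------


def test_blank_image_yields_no_detections():
    det = PhantomCellDetector(pixel_size_um=0.115)
    assert det(np.full((200, 260), 0.5)) == []


def test_failing_detector_surfaces_empty_list_and_warning(caplog):
    def broken(image):
        raise RuntimeError("inference backend gone")

    with caplog.at_level(logging.WARNING, logger="autopatch.detection"):
        out = detect_cells_2d(np.zeros((10, 10)), broken, slice_index=3)
    assert out == []
    assert any("detector failed" in rec.message for rec in caplog.records)


@pytest.fixture(scope="module")
def coplanar_phantom():
    # thin stack forces all somata to one focal plane: the in-focus slice test
    spec = PhantomSpec(stack_shape=(9, 520, 696), n_cells=10, seed=5)
    stack, cells = generate_cell_phantom_stack(spec)
    return stack, cells


def test_in_focus_recall_at_iou_half(coplanar_phantom):
    stack, cells = coplanar_phantom
    det = PhantomCellDetector(stack.pixel_size_um)
    boxes = det(stack.voxels[4])
    px = stack.pixel_size_um
    hits = 0
    for c in cells:
        cx, cy, r = c.centroid_um[0] / px, c.centroid_um[1] / px, c.radius_um / px
        gt = (cx - r, cy - r, cx + r, cy + r)
        best = 0.0
        for b in boxes:
            inter = rect_area(intersect_rects(gt, b.rect()))
            best = max(best, inter / (rect_area(gt) + b.area - inter))
        hits += best >= 0.5
    assert hits / len(cells) >= 0.9


def test_detector_centroids_subpixel_on_clean_background():
    spec = PhantomSpec(
        stack_shape=(9, 520, 696), n_cells=10, seed=5, background_texture_scale=0.001, noise_sigma=0.0
    )
    stack, cells = generate_cell_phantom_stack(spec)
    det = PhantomCellDetector(stack.pixel_size_um)
    boxes = det(stack.voxels[4])
    px = stack.pixel_size_um
    for c in cells:
        cx, cy = c.centroid_um[0] / px, c.centroid_um[1] / px
        d = min(np.hypot(b.center[0] - cx, b.center[1] - cy) for b in boxes)
        assert d < 2.0


def test_full_stack_pipeline_recovers_all_cells(cell_stack):
    stack, cells = cell_stack["stack"], cell_stack["cells"]
    det = PhantomCellDetector(stack.pixel_size_um)
    per = [detect_cells_2d(stack.voxels[k], det, k) for k in range(stack.n_slices)]
    dets = merge_boxes_3d(per, stack.pixel_size_um, stack.z_step_um)
    from autopatch import evaluate_detections

    m = evaluate_detections(dets, [c.centroid_um for c in cells])
    assert m.recall >= 90.0
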