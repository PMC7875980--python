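"""Detection evaluation: spatial matching and precision/recall/F1.

A detection matches a ground-truth object when their centroids are at most
5 um apart in the lateral plane and 3 um apart along Z (two separate
tolerances).  Unmatched detections are false positives, unmatched ground
truth false negatives.  Matching is greedy by ascending lateral distance,
which coincides with the optimal assignment whenever the tolerance
neighbourhoods are disjoint (a property the test suite checks exhaustively
on small instances).

Metrics are reported in percent: P = TP/(TP+FP), R = TP/(TP+FN),
F1 = 2PR/(P+R), with the convention that an empty denominator gives 0.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .detection import merge_boxes_3d

LATERAL_TOL_UM = 5.0
Z_TOL_UM = 3.0


@dataclasses.dataclass(frozen=True)
class DetectionMetrics:
    """Counts and derived rates (percent, as printed in reports)."""

    TP: int
    FP: int
    FN: int
    precision: float
    recall: float
    f1: float


def precision_recall_f1(TP: int, FP: int, FN: int) -> DetectionMetrics:
    """Compute the metrics (in percent) from raw counts."""
    if min(TP, FP, FN) < 0:
        raise ValueError("counts must be non-negative")
    p = 100.0 * TP / (TP + FP) if TP + FP > 0 else 0.0
    r = 100.0 * TP / (TP + FN) if TP + FN > 0 else 0.0
    f1 = f1_from_pr(p, r)
    return DetectionMetrics(TP, FP, FN, p, r, f1)


def f1_from_pr(precision_pct: float, recall_pct: float) -> float:
    """Harmonic mean of precision and recall, both in percent."""
    if precision_pct + recall_pct == 0:
        return 0.0
    return 2.0 * precision_pct * recall_pct / (precision_pct + recall_pct)


def _centroid(obj) -> np.ndarray:
    if hasattr(obj, "centroid_um"):
        return np.asarray(obj.centroid_um, dtype=float)
    return np.asarray(obj, dtype=float)


def match_detections(dets, gts, lateral_tol_um: float = LATERAL_TOL_UM, z_tol_um: float = Z_TOL_UM):
    """Greedy one-to-one matching of detections against ground truth.

    Candidate pairs must satisfy both tolerances; pairs are consumed in
    ascending lateral-distance order.  Returns ``(pairs, fp_indices,
    fn_indices)`` where pairs are ``(det_index, gt_index)`` tuples.
    """
    det_c = [_centroid(d) for d in dets]
    gt_c = [_centroid(g) for g in gts]
    candidates = []
    for i, dc in enumerate(det_c):
        for j, gc in enumerate(gt_c):
            lateral = float(np.hypot(dc[0] - gc[0], dc[1] - gc[1]))
            dz = abs(dc[2] - gc[2])
            if lateral <= lateral_tol_um and dz <= z_tol_um:
                candidates.append((lateral, i, j))
    candidates.sort()
    used_d, used_g, pairs = set(), set(), []
    for _, i, j in candidates:
        if i in used_d or j in used_g:
            continue
        used_d.add(i)
        used_g.add(j)
        pairs.append((i, j))
    fp = [i for i in range(len(dets)) if i not in used_d]
    fn = [j for j in range(len(gts)) if j not in used_g]
    return pairs, fp, fn


def evaluate_detections(dets, gts, lateral_tol_um: float = LATERAL_TOL_UM, z_tol_um: float = Z_TOL_UM) -> DetectionMetrics:
    """Match then score; the usual one-call evaluation."""
    pairs, fp, fn = match_detections(dets, gts, lateral_tol_um, z_tol_um)
    return precision_recall_f1(len(pairs), len(fp), len(fn))


def annotator_agreement(
    boxes_a,
    boxes_b,
    n_slices: int,
    pixel_size_um: float,
    z_step_um: float = 1.0,
    lateral_tol_um: float = LATERAL_TOL_UM,
    z_tol_um: float = Z_TOL_UM,
) -> DetectionMetrics:
    """Agreement between two annotation sets over the same stack.

    Set A is treated as ground truth and set B as detections: both are
    Z-merged into 3D objects, matched with the standard tolerances and
    scored.  Swapping A and B swaps precision and recall.
    """

    def to_dets(boxes):
        per_slice = [[] for _ in range(n_slices)]
        for b in boxes:
            if not 0 <= b.slice_index < n_slices:
                raise ValueError(f"box slice {b.slice_index} outside stack of {n_slices} slices")
            per_slice[b.slice_index].append(b)
        return merge_boxes_3d(per_slice, pixel_size_um, z_step_um)

    return evaluate_detections(to_dets(boxes_b), to_dets(boxes_a), lateral_tol_um, z_tol_um)
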