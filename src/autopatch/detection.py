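"""Per-slice cell detection and Z-merging of 2D boxes into 3D detections.

Any callable ``image -> list[ScoredBox]`` can serve as the per-slice
detector, so a trained network can be wired in; the package ships a
classical blob detector adequate for the synthetic phantoms.  The Z-merging
implements the published rule set: boxes on different slices are united when
their intersection is at least 60% of the smaller box, the comparison is
iterated against the running intersection region, and boxes up to three
slices apart (two empty slices between) may still join.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import ndimage
from skimage import feature

from .annotations import ScoredBox, intersect_rects, rect_area

logger = logging.getLogger("autopatch.detection")

MERGE_MIN_RATIO = 0.6
MERGE_MAX_SLICE_GAP = 3
#: Floor (px^2) below which the running intersection region is not shrunk
#: further, to avoid vanishing comparison regions.
MERGE_MIN_REGION_PX2 = 4.0


@dataclasses.dataclass
class Detection3D:
    """A Z-merged 3D detection.

    ``confidence`` is the maximum over member boxes; ``centroid_um`` the
    confidence-weighted mean of member box centers, in stage micrometres;
    ``depth_slices`` the slice span (last - first + 1).
    """

    boxes: list
    centroid_um: np.ndarray
    confidence: float
    depth_slices: int

    def __post_init__(self) -> None:
        self.centroid_um = np.asarray(self.centroid_um, dtype=float)


def _fit_blob_center(band: np.ndarray, r: float, c: float, half: int) -> tuple:
    """Sub-pixel blob center from a least-squares isotropic-Gaussian fit.

    Falls back to the raw peak if the fit fails or wanders out of the window.
    """
    n_rows, n_cols = band.shape
    r0, r1 = max(0, int(r) - half), min(n_rows, int(r) + half + 1)
    c0, c1 = max(0, int(c) - half), min(n_cols, int(c) + half + 1)
    win = band[r0:r1, c0:c1].astype(float)
    rr, cc = np.mgrid[r0:r1, c0:c1]

    def model(p):
        amp, rc, cc_, sig, off = p
        return amp * np.exp(-((rr - rc) ** 2 + (cc - cc_) ** 2) / (2.0 * sig**2)) + off

    p = np.array([float(win.max() - win.min()), r, c, half / 2.5, float(win.min())])
    try:
        from scipy.optimize import least_squares

        fit = least_squares(
            lambda p: (model(p) - win).ravel(),
            p,
            bounds=(
                [0.0, r0, c0, 1.0, -np.inf],
                [np.inf, r1 - 1, c1 - 1, 4.0 * half, np.inf],
            ),
            max_nfev=60,
        )
        rc, cc_ = float(fit.x[1]), float(fit.x[2])
        if abs(rc - r) <= half and abs(cc_ - c) <= half:
            return rc, cc_
    except Exception:
        pass
    return float(r), float(c)


class PhantomCellDetector:
    """Classical reference detector for synthetic phantoms.

    Band-passes the slice (difference of Gaussians at the soma scale) and
    runs Laplacian-of-Gaussian blob detection; the box side is four times the
    detected blob sigma and the confidence is the blob response normalized to
    the strongest blob in the image.
    """

    def __init__(self, pixel_size_um: float, radius_range_um=(3.0, 8.0), threshold: float = 0.08):
        self.pixel_size_um = pixel_size_um
        self.radius_range_um = radius_range_um
        self.threshold = threshold

    def __call__(self, image: np.ndarray) -> list:
        img = np.asarray(image, dtype=float)
        r_lo, r_hi = self.radius_range_um
        px = self.pixel_size_um
        # band-pass at the soma scale: small-scale texture and noise smoothed
        # away, slow background removed
        sm = ndimage.gaussian_filter(img, sigma=r_lo / 2.5 / px)
        bg = ndimage.gaussian_filter(img, sigma=2.0 * r_hi / px)
        band = sm - bg
        peaks = feature.peak_local_max(
            band, min_distance=max(1, int(r_lo / px)), threshold_abs=self.threshold
        )
        if len(peaks) == 0:
            return []
        responses = band[peaks[:, 0], peaks[:, 1]]
        peak_resp = float(responses.max())
        boxes = []
        side = (r_lo + r_hi) / px  # nominal soma diameter, in pixels
        half = int(round(side / 2))
        n_rows, n_cols = band.shape
        for (r, c), resp in zip(peaks, responses):
            # texture ripple shifts the raw peak on the flat soma bump; a
            # least-squares Gaussian fit over the window averages it out
            r_c, c_c = _fit_blob_center(band, float(r), float(c), half)
            conf = float(np.clip(resp / peak_resp, 0.0, 1.0))
            boxes.append(
                ScoredBox(
                    slice_index=0, x=c_c - side / 2, y=r_c - side / 2, w=side, h=side, confidence=conf
                )
            )
        return boxes


def detect_cells_2d(image: np.ndarray, detector, slice_index: int = 0) -> list:
    """Run a per-slice detector; failures surface as an empty list + warning."""
    try:
        boxes = detector(image)
    except Exception:  # detector plug-ins are third-party code
        logger.warning("cell detector failed on slice %d", slice_index, exc_info=True)
        return []
    return [dataclasses.replace(b, slice_index=slice_index) for b in boxes]


def detect_cells_stack(stack, detector=None) -> list:
    """Apply the detector to every slice; returns per-slice box lists."""
    if detector is None:
        detector = PhantomCellDetector(stack.pixel_size_um)
    return [detect_cells_2d(stack.voxels[k], detector, k) for k in range(stack.n_slices)]


def _canonical(boxes) -> list:
    return sorted(boxes, key=lambda b: (b.x, b.y, b.w, b.h, b.confidence, b.label))


class _Open:
    __slots__ = ("members", "region", "last_slice", "order")

    def __init__(self, box: ScoredBox, order: int):
        self.members = [box]
        self.region = box.rect()
        self.last_slice = box.slice_index
        self.order = order


def merge_boxes_3d(
    per_slice: list, pixel_size_um: float = 1.0, z_step_um: float = 1.0
) -> list:
    """Unite per-slice boxes along Z into 3D detections.

    Boxes are processed in ascending slice order (canonically sorted within a
    slice, so the result is invariant to within-slice permutation).  A box
    joins an open detection when the area of its intersection with the
    running intersection region is at least 60% of the smaller of the two,
    and the slice gap to the detection's last member is at most three.  Every
    input box ends up in exactly one detection.
    """
    open_dets: list = []
    closed: list = []
    order = 0
    for k, boxes in enumerate(per_slice):
        # retire detections that can no longer be extended
        still = []
        for d in open_dets:
            if k - d.last_slice > MERGE_MAX_SLICE_GAP:
                closed.append(d)
            else:
                still.append(d)
        open_dets = still
        for box in _canonical(boxes):
            best = None
            for d in open_dets:
                if d.last_slice >= box.slice_index:
                    continue  # boxes of different Z slices are compared
                inter = intersect_rects(d.region, box.rect())
                a_inter = rect_area(inter)
                denom = min(rect_area(d.region), box.area)
                ratio = a_inter / denom if denom > 0 else 0.0
                if ratio >= MERGE_MIN_RATIO:
                    key = (ratio, -d.order)
                    if best is None or key > best[0]:
                        best = (key, d, inter)
            if best is None:
                open_dets.append(_Open(box, order))
                order += 1
            else:
                _, d, inter = best
                d.members.append(box)
                d.last_slice = box.slice_index
                if inter is not None and rect_area(inter) >= MERGE_MIN_REGION_PX2:
                    d.region = inter
    closed.extend(open_dets)
    closed.sort(key=lambda d: d.order)
    out = []
    for d in closed:
        confs = np.array([b.confidence for b in d.members])
        weights = confs if confs.sum() > 0 else np.ones(len(confs))
        centers = np.array([[*b.center, b.slice_index] for b in d.members], dtype=float)
        cx, cy, cz = (centers * weights[:, None]).sum(axis=0) / weights.sum()
        slices = [b.slice_index for b in d.members]
        out.append(
            Detection3D(
                boxes=list(d.members),
                centroid_um=np.array([cx * pixel_size_um, cy * pixel_size_um, cz * z_step_um]),
                confidence=float(confs.max()),
                depth_slices=max(slices) - min(slices) + 1,
            )
        )
    return out


def rank_detections(dets: list) -> list:
    """Order detections by descending confidence (healthier cells first).

    Equal confidences are broken deterministically by the (slice, y, x) of
    the centroid so a permuted input yields the identical order.
    """
    return sorted(
        dets,
        key=lambda d: (-d.confidence, d.centroid_um[2], d.centroid_um[1], d.centroid_um[0]),
    )
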