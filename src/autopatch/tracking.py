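"""3D tracking of the target cell during pipette approach.

Lateral drift is tracked with a sparse pyramidal Kanade-Lucas-Tomasi (KLT)
feature tracker against a template image captured at optimal focus before the
patching process starts; the reported displacement is the median over inlier
features.  Axial drift is tracked by a focus measure: a small stack is taken
around the most recent focus position and, for every slice, the standard
deviation of its difference against the template is computed over the
template box — the minimum marks the slice the cell actually sits on.

Tracking queries are made only while the pipette is halted, so the measured
displacement reflects tissue drift rather than motion blur.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from skimage import feature, transform

from .annotations import ScoredBox
from .errors import AutopatchError, TrackingLostError
from .imaging import ImageStack

MAX_FEATURES = 30
PYRAMID_LEVELS = 3
WINDOW_PX = 15
LK_ITERS = 20
#: half-depth of the Z-tracking mini stack, in slices
MINI_STACK_HALF_DEPTH = 3


@dataclasses.dataclass
class TrackState:
    """Tracker state: the pre-patch template and its features.

    ``features`` are (row, col) pixel positions inside ``template_box`` on
    the template image; ``current_offset_um`` accumulates the measured drift
    of the target in stage micrometres.
    """

    template: np.ndarray
    template_box: ScoredBox
    features: np.ndarray
    pixel_size_um: float
    z_step_um: float = 1.0
    current_offset_um: np.ndarray = dataclasses.field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.template = np.asarray(self.template, dtype=float)
        self.features = np.asarray(self.features, dtype=float).reshape(-1, 2)
        self.current_offset_um = np.asarray(self.current_offset_um, dtype=float)


def select_features(image: np.ndarray, box: ScoredBox, max_features: int = MAX_FEATURES) -> np.ndarray:
    """Minimum-eigenvalue (Shi-Tomasi) corners inside the box, strongest first."""
    img = np.asarray(image, dtype=float)
    response = feature.corner_shi_tomasi(img)
    x0, y0, x1, y1 = (int(round(v)) for v in box.rect())
    masked = np.full_like(response, -np.inf)
    masked[max(y0, 0):y1, max(x0, 0):x1] = response[max(y0, 0):y1, max(x0, 0):x1]
    peaks = feature.peak_local_max(masked, min_distance=3, num_peaks=max_features)
    if len(peaks) == 0:
        return np.zeros((0, 2))
    resp = masked[peaks[:, 0], peaks[:, 1]]
    keep = resp > max(1e-10, 0.01 * float(resp.max()))
    return peaks[keep].astype(float)


def make_track_state(template: np.ndarray, box: ScoredBox, pixel_size_um: float, z_step_um: float = 1.0) -> TrackState:
    """Capture the template (at optimal focus) and pick trackable features."""
    feats = select_features(template, box)
    if len(feats) < 4:
        raise TrackingLostError(f"only {len(feats)} trackable features inside the template box")
    return TrackState(template, box, feats, pixel_size_um, z_step_um)


def _pyramid(img: np.ndarray, levels: int) -> list:
    pyr = [img]
    for _ in range(levels - 1):
        pyr.append(transform.pyramid_reduce(pyr[-1], downscale=2, channel_axis=None))
    return pyr


def _sample(img: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    return ndimage.map_coordinates(img, [rows, cols], order=1, mode="nearest")


def _lk_track_point(tmpl_pyr, frame_pyr, grad_pyr, point_rc, window=WINDOW_PX):
    """Track one feature coarse-to-fine.  Returns (displacement_rc, ok)."""
    half = window // 2
    offs = np.arange(-half, half + 1, dtype=float)
    orow, ocol = np.meshgrid(offs, offs, indexing="ij")
    d = np.zeros(2)
    for level in range(len(tmpl_pyr) - 1, -1, -1):
        scale = 2.0**level
        p = point_rc / scale
        rows = p[0] + orow.ravel()
        cols = p[1] + ocol.ravel()
        t_win = _sample(tmpl_pyr[level], rows, cols)
        gr = _sample(grad_pyr[level][0], rows, cols)
        gc = _sample(grad_pyr[level][1], rows, cols)
        G = np.array([[np.sum(gr * gr), np.sum(gr * gc)], [np.sum(gr * gc), np.sum(gc * gc)]])
        eigvals = np.linalg.eigvalsh(G)
        if eigvals[0] < 1e-6:
            return d * 0, False
        Ginv = np.linalg.inv(G)
        dl = d / scale
        for _ in range(LK_ITERS):
            f_win = _sample(frame_pyr[level], rows + dl[0], cols + dl[1])
            err = f_win - t_win
            b = np.array([np.sum(err * gr), np.sum(err * gc)])
            delta = -Ginv @ b
            dl = dl + delta
            if np.linalg.norm(delta) < 0.01:
                break
        if np.linalg.norm(dl) > window:  # diverged
            return d * 0, False
        d = dl * scale
    shape = np.array(tmpl_pyr[0].shape, dtype=float)
    target = point_rc + d
    if np.any(target < 0) or np.any(target > shape - 1):
        return d, False
    return d, True


def track_lateral(state: TrackState, frame: np.ndarray):
    """Lateral drift of the cell between the template and ``frame``.

    Pyramidal KLT per feature; the reported displacement is the median over
    the inlier features, converted to micrometres.  When more than half the
    features are lost they are refreshed from the template; if all are lost a
    :class:`TrackingLostError` is raised.
    """
    if len(state.features) < 4:
        raise TrackingLostError("fewer than 4 features to track")
    frame = np.asarray(frame, dtype=float)
    tmpl_pyr = _pyramid(state.template, PYRAMID_LEVELS)
    frame_pyr = _pyramid(frame, PYRAMID_LEVELS)
    grad_pyr = [np.gradient(t) for t in tmpl_pyr]
    disps, ok_mask = [], []
    for p in state.features:
        d, ok = _lk_track_point(tmpl_pyr, frame_pyr, grad_pyr, p)
        disps.append(d)
        ok_mask.append(ok)
    ok_mask = np.asarray(ok_mask)
    if not ok_mask.any():
        raise TrackingLostError("all features lost")
    disps = np.asarray(disps)[ok_mask]
    med_rc = np.median(disps, axis=0)
    if ok_mask.sum() < 0.5 * len(state.features):
        state.features = select_features(state.template, state.template_box)
    dx_um = med_rc[1] * state.pixel_size_um
    dy_um = med_rc[0] * state.pixel_size_um
    return float(dx_um), float(dy_um)


def track_z(state: TrackState, mini_stack: ImageStack) -> float:
    """Axial drift from a focus mini-stack centred on the last focus position.

    For each slice the standard deviation of ``slice - template`` over the
    template box is computed; the minimum marks the cell's current slice.
    ``dz = (argmin - center) * z_step`` — positive means the cell moved up
    (toward higher slice indices).  The slice count must be odd so the
    center is well defined.
    """
    n = mini_stack.n_slices
    if n % 2 == 0:
        raise AutopatchError("mini-stack must have an odd number of slices")
    x0, y0, x1, y1 = (int(round(v)) for v in state.template_box.rect())
    tmpl_win = state.template[y0:y1, x0:x1]
    stds = np.array(
        [float(np.std(mini_stack.voxels[k, y0:y1, x0:x1] - tmpl_win)) for k in range(n)]
    )
    dz_slices = int(np.argmin(stds)) - n // 2
    return dz_slices * mini_stack.z_step_um


def focus_curve(state: TrackState, mini_stack: ImageStack) -> np.ndarray:
    """The per-slice stddev-of-difference curve used by :func:`track_z`."""
    x0, y0, x1, y1 = (int(round(v)) for v in state.template_box.rect())
    tmpl_win = state.template[y0:y1, x0:x1]
    return np.array(
        [float(np.std(mini_stack.voxels[k, y0:y1, x0:x1] - tmpl_win)) for k in range(mini_stack.n_slices)]
    )


def update_target(state: TrackState, dxyz_um) -> TrackState:
    """Accumulate a measured displacement into the tracked target offset."""
    dxyz = np.asarray(dxyz_um, dtype=float)
    return dataclasses.replace(state, current_offset_um=state.current_offset_um + dxyz)
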