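"""Synthetic DIC-like image phantoms with ground truth.

The generator emulates the appearance of unlabeled brain-slice stacks well
enough to exercise the full pipeline: a textured background, blurred
elliptical cell somata that are brightest and sharpest at their true focal
slice, and the dark two-walled silhouette of a patch pipette whose contrast
fades with defocus.  It makes no attempt at optical physics (no DIC shear);
see docs/methods.md for what that implies about the tests.
"""

from __future__ import annotations

import dataclasses
import json
import math

import numpy as np
from scipy import ndimage

from .errors import AutopatchError, BoundsError, PlacementError
from .imaging import DEFAULT_PIXEL_SIZE_UM, ImageStack
from .pipette import PipetteModel

#: Axial sharpness decay of a soma: visibility falls off as a Gaussian of the
#: z-distance from the true focal slice with this sigma, which reproduces the
#: roughly five-slice depth over which annotators can see a cell at 1 um
#: spacing.
CELL_SIGMA_Z_UM = 3.0


@dataclasses.dataclass
class PhantomSpec:
    """Recipe for a synthetic cell stack.

    Defaults mirror the reference acquisition: 60 slices at 1 um spacing and
    the 0.115 um lateral pixel size of the 40x DIC setup (the lateral field is
    cropped relative to the full 1392x1040 sensor to keep phantoms light).
    """

    stack_shape: tuple = (60, 260, 348)  # (n_slices, n_rows, n_cols)
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    z_step_um: float = 1.0
    n_cells: int = 5
    cell_radius_um: tuple = (4.0, 6.0)
    cell_contrast: float = 0.35
    background_texture_scale: float = 8.0  # px
    noise_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.stack_shape) != 3 or self.stack_shape[0] < 1:
            raise AutopatchError("stack_shape must be (n_slices>=1, n_rows, n_cols)")
        if not self.pixel_size_um > 0:
            raise AutopatchError("pixel_size_um must be positive")
        if self.n_cells < 0:
            raise AutopatchError("n_cells must be non-negative")


@dataclasses.dataclass
class GroundTruthCell:
    """A phantom cell with the electrode-physics parameters the rig needs.

    ``seal_rate_per_mbar_s`` is the seal-growth rate constant per mbar of
    applied vacuum (see :mod:`autopatch.rig`); ``rupture_threshold_mbar_s`` is
    the cumulative suction impulse that ruptures the gigasealed patch.
    """

    centroid_um: np.ndarray  # stage frame, z up = increasing slice index
    radius_um: float
    sealable: bool = True
    seal_rate_per_mbar_s: float = 0.0023
    rupture_threshold_mbar_s: float = 250.0
    access_resistance_Mohm: float = 30.0

    def __post_init__(self) -> None:
        self.centroid_um = np.asarray(self.centroid_um, dtype=float)
        if not self.radius_um > 0:
            raise AutopatchError("radius_um must be positive")
        if not self.access_resistance_Mohm > 0:
            raise AutopatchError("access_resistance_Mohm must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["centroid_um"] = [float(v) for v in self.centroid_um]
        return d


def write_ground_truth(cells, path) -> None:
    with open(path, "w") as fh:
        json.dump({"frame": "stage_um_z_up", "cells": [c.to_dict() for c in cells]}, fh, indent=1)


def read_ground_truth(path) -> list:
    with open(path) as fh:
        payload = json.load(fh)
    return [GroundTruthCell(**rec) for rec in payload["cells"]]


def _draw_access_resistance(rng: np.random.Generator) -> float:
    """Whole-cell access resistance, lognormal with median 30 MOhm."""
    return float(rng.lognormal(mean=math.log(30.0), sigma=0.45))


def synthesize_population(
    n_cells: int, sealable_fraction: float = 0.6, seed: int = 0, spacing_um: float = 40.0
) -> list:
    """Image-free cell population for pure rig simulations.

    Cells are laid out on a line with generous spacing; a seeded Bernoulli
    draw decides which are sealable.
    """
    rng = np.random.default_rng(seed)
    cells = []
    for i in range(n_cells):
        cells.append(
            GroundTruthCell(
                centroid_um=np.array([50.0 + i * spacing_um, 50.0, 20.0]),
                radius_um=float(rng.uniform(4.0, 6.0)),
                sealable=bool(rng.random() < sealable_fraction),
                access_resistance_Mohm=_draw_access_resistance(rng),
            )
        )
    return cells


def _background(shape, texture_scale, rng) -> np.ndarray:
    """Static tissue-like texture shared by all slices, around a 0.5 base."""
    n_z, n_rows, n_cols = shape
    tex = rng.normal(size=(n_rows, n_cols))
    tex = ndimage.gaussian_filter(tex, sigma=texture_scale, mode="nearest")
    std = tex.std()
    if std > 0:
        tex = tex / std * 0.04
    return np.broadcast_to(0.5 + tex, (n_z, n_rows, n_cols)).copy()


def generate_cell_phantom_stack(spec: PhantomSpec):
    """Generate a phantom stack and its ground-truth cell list.

    Somata are non-overlapping blurred ellipses, brightest at their true
    focal slice and progressively dimmer and blurrier away from it.  A fixed
    seed gives bit-identical output.

    Raises :class:`PlacementError` when the requested density cannot be
    placed without overlap.
    """
    rng = np.random.default_rng(spec.seed)
    n_z, n_rows, n_cols = spec.stack_shape
    vox = _background(spec.stack_shape, spec.background_texture_scale, rng)
    px = spec.pixel_size_um
    r_lo, r_hi = spec.cell_radius_um
    ext_x, ext_y, ext_z = n_cols * px, n_rows * px, n_z * spec.z_step_um

    centers, radii = [], []
    min_sep = 2.0 * r_hi
    margin_xy = r_hi + 2.0
    margin_z = 4.0
    if spec.n_cells > 0 and (2 * margin_xy >= ext_x or 2 * margin_xy >= ext_y):
        raise PlacementError(
            f"field of view {ext_x:.1f}x{ext_y:.1f} um too small for somata of radius up to {r_hi} um"
        )
    for _ in range(spec.n_cells):
        placed = False
        for _attempt in range(2000):
            c = np.array(
                [
                    rng.uniform(margin_xy, ext_x - margin_xy),
                    rng.uniform(margin_xy, ext_y - margin_xy),
                    rng.uniform(margin_z, max(margin_z + 1e-6, ext_z - margin_z)),
                ]
            )
            if all(np.linalg.norm(c - p) > min_sep for p in centers):
                centers.append(c)
                radii.append(float(rng.uniform(r_lo, r_hi)))
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place {spec.n_cells} non-overlapping cells in this volume"
            )

    cells = []
    for c, r in zip(centers, radii):
        aspect = rng.uniform(0.8, 1.25)
        angle = rng.uniform(0.0, math.pi)
        _render_soma(vox, spec, c, r, aspect, angle)
        cells.append(
            GroundTruthCell(
                centroid_um=c,
                radius_um=r,
                sealable=True,
                access_resistance_Mohm=_draw_access_resistance(rng),
            )
        )
    if spec.noise_sigma > 0:
        vox += rng.normal(0.0, spec.noise_sigma, size=vox.shape)
    np.clip(vox, 0.0, 1.0, out=vox)
    stack = ImageStack(vox.astype(np.float32), px, spec.z_step_um)
    return stack, cells


def _render_soma(vox, spec, center_um, radius_um, aspect, angle) -> None:
    px = spec.pixel_size_um
    n_z, n_rows, n_cols = vox.shape
    sig_xy = radius_um / 2.0  # in-focus Gaussian width; "radius" ~ 2 sigma
    cx, cy, cz = center_um
    half_px = int(math.ceil((radius_um * 2.5) / px)) + 4
    c0 = int(round(cx / px))
    r0 = int(round(cy / px))
    cs = slice(max(0, c0 - half_px), min(n_cols, c0 + half_px + 1))
    rs = slice(max(0, r0 - half_px), min(n_rows, r0 + half_px + 1))
    xs = (np.arange(cs.start, cs.stop) * px - cx)[None, :]
    ys = (np.arange(rs.start, rs.stop) * px - cy)[:, None]
    ca, sa = math.cos(angle), math.sin(angle)
    u = xs * ca + ys * sa
    v = -xs * sa + ys * ca
    for k in range(n_z):
        zdist = abs(k * spec.z_step_um - cz)
        amp = spec.cell_contrast * math.exp(-(zdist**2) / (2 * CELL_SIGMA_Z_UM**2))
        if amp < 1e-3:
            continue
        blur = math.sqrt(1.0 + (zdist / CELL_SIGMA_Z_UM) ** 2)
        su = sig_xy * aspect * blur
        sv = sig_xy / aspect * blur
        vox[k, rs, cs] += (amp / blur) * np.exp(-0.5 * ((u / su) ** 2 + (v / sv) ** 2))


# ---------------------------------------------------------------------------
# Pipette rendering (forward model for localization tests)


def render_pipette(
    stack: ImageStack,
    model: PipetteModel,
    contrast: float = 0.6,
    sigma_z_um: float = 3.0,
    max_len_um: float = 60.0,
) -> ImageStack:
    """Composite the dark two-walled silhouette of a pipette into a stack.

    Each wall is a ray from the tip along a wall-cylinder axis; darkness is
    maximal on the wall centerline at its focal depth and fades (and widens)
    with defocus.  The composite is multiplicative: ``I *= 1 - D`` with D up
    to ``contrast``.  Zero contrast returns an unchanged copy.

    Raises :class:`BoundsError` if the tip lies outside the volume.
    """
    out = stack.copy()
    if contrast == 0.0:
        return out
    ext = stack.extent_um()
    if np.any(model.tip_um < 0) or np.any(model.tip_um > ext):
        raise BoundsError(f"pipette tip {model.tip_um} outside volume extent {ext}")
    n_z, n_rows, n_cols = stack.voxels.shape
    px, zs = stack.pixel_size_um, stack.z_step_um
    sw0 = model.wall_radius_um
    # restrict the computation to the in-plane bounding box of the silhouette
    ends = [model.tip_um] + [model.tip_um + max_len_um * w for w in model.wall_directions()]
    margin = 8.0 * sw0 + 4.0
    c_lo = max(0, int((min(e[0] for e in ends) - margin) / px))
    c_hi = min(n_cols, int((max(e[0] for e in ends) + margin) / px) + 1)
    r_lo = max(0, int((min(e[1] for e in ends) - margin) / px))
    r_hi = min(n_rows, int((max(e[1] for e in ends) + margin) / px) + 1)
    x_um = np.arange(c_lo, c_hi) * px
    y_um = np.arange(r_lo, r_hi) * px
    X, Y = np.meshgrid(x_um, y_um)  # (rows, cols)
    darkness = np.zeros((n_z, r_hi - r_lo, c_hi - c_lo), dtype=np.float32)
    for w in model.wall_directions():
        u_xy = np.array([w[0], w[1]])
        nrm2 = float(u_xy @ u_xy)
        if nrm2 < 1e-12:
            continue
        dx = X - model.tip_um[0]
        dy = Y - model.tip_um[1]
        s = (dx * u_xy[0] + dy * u_xy[1]) / nrm2
        s_clamped = np.clip(s, 0.0, max_len_um)
        rx = dx - s_clamped * u_xy[0]
        ry = dy - s_clamped * u_xy[1]
        d2 = rx**2 + ry**2
        z_ray = model.tip_um[2] + s_clamped * w[2]
        for k in range(n_z):
            dz = k * zs - z_ray
            widen = 1.0 + (dz / sigma_z_um) ** 2
            sw2 = sw0**2 * widen
            amp = np.exp(-(dz**2) / (2 * sigma_z_um**2)) / np.sqrt(widen)
            darkness[k] += (amp * np.exp(-d2 / (2 * sw2))).astype(np.float32)
    np.clip(darkness, 0.0, 1.0, out=darkness)
    sub = out.voxels[:, r_lo:r_hi, c_lo:c_hi]
    out.voxels[:, r_lo:r_hi, c_lo:c_hi] = (sub * (1.0 - contrast * darkness)).astype(
        stack.voxels.dtype, copy=False
    )
    return out


def generate_pipette_phantom(
    seed: int = 0,
    stack_shape: tuple = (80, 400, 520),
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    z_step_um: float = 1.0,
    noise_sigma: float = 0.0,
    texture_scale_px: float = 8.0,
    contrast: float = 0.6,
):
    """A background-plus-pipette stack with a randomized ground-truth pose.

    The tip lands in the central third of the field with the shank leaving
    through a border, yaw uniform over the circle and tilt within a few
    degrees of the nominal 33-degree manipulator angle.  Returns
    ``(stack, true_model)``.
    """
    rng = np.random.default_rng(seed)
    n_z, n_rows, n_cols = stack_shape
    ext_x, ext_y, ext_z = n_cols * pixel_size_um, n_rows * pixel_size_um, n_z * z_step_um
    tip = np.array(
        [
            rng.uniform(0.4 * ext_x, 0.6 * ext_x),
            rng.uniform(0.4 * ext_y, 0.6 * ext_y),
            rng.uniform(0.3 * ext_z, 0.55 * ext_z),
        ]
    )
    model = PipetteModel(
        tip_um=tip,
        yaw_rad=float(rng.uniform(0.0, 2 * math.pi)),
        tilt_rad=float(math.radians(33.0) + rng.uniform(-0.1, 0.1)),
        half_opening_rad=float(rng.uniform(0.10, 0.18)),
        wall_radius_um=1.0,
    )
    vox = _background(stack_shape, texture_scale_px, rng)
    stack = ImageStack(vox, pixel_size_um, z_step_um)
    stack = render_pipette(stack, model, contrast=contrast)
    if noise_sigma > 0:
        stack.voxels = stack.voxels + rng.normal(0.0, noise_sigma, size=stack.voxels.shape)
    np.clip(stack.voxels, 0.0, 1.0, out=stack.voxels)
    stack.voxels = stack.voxels.astype(np.float32)
    return stack, model
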