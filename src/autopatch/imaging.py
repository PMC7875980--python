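"""Image-stack container, TIFF I/O, pixel calibration and illumination correction.

A stack is a 3D intensity volume indexed ``(slice, row, col)``.  The global
coordinate convention used throughout the package:

* 0-based slice index; pixel boxes are half-open ``[x, x+w) x [y, y+h)``;
* micrometre positions are ``pixel * pixel_size_um`` laterally and
  ``slice_index * z_step_um`` axially;
* stage z increases with slice index ("up"); the pipette descends in -z.
"""

from __future__ import annotations

import dataclasses
import json
import logging

import numpy as np
import tifffile
from scipy import ndimage

from .errors import AutopatchError

logger = logging.getLogger("autopatch.imaging")

#: Lateral calibration of the reference 40x DIC setup: 1392 x 1040 px imaging
#: a 160.08 x 119.6 um field of view, i.e. 0.115 um per pixel.
DEFAULT_PIXEL_SIZE_UM = 160.08 / 1392
DEFAULT_Z_STEP_UM = 1.0

_META_KEY = "autopatch_metadata"


@dataclasses.dataclass
class ImageStack:
    """Calibrated 3D intensity volume.

    Parameters
    ----------
    voxels:
        Array of shape ``(n_slices, n_rows, n_cols)``.
    pixel_size_um:
        Lateral size of one pixel in micrometres.
    z_step_um:
        Axial distance between consecutive slices in micrometres.
    """

    voxels: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    z_step_um: float = DEFAULT_Z_STEP_UM

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise AutopatchError(
                f"stack must be 3D with all dimensions >= 1, got shape {self.voxels.shape}"
            )
        if not (self.pixel_size_um > 0 and self.z_step_um > 0):
            raise AutopatchError("pixel_size_um and z_step_um must be positive")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape(self) -> tuple:
        return self.voxels.shape

    def extent_um(self) -> np.ndarray:
        """Physical (x, y, z) extent of the volume in micrometres."""
        n_z, n_rows, n_cols = self.voxels.shape
        return np.array(
            [n_cols * self.pixel_size_um, n_rows * self.pixel_size_um, n_z * self.z_step_um]
        )

    def copy(self) -> "ImageStack":
        return ImageStack(self.voxels.copy(), self.pixel_size_um, self.z_step_um)


def um_per_pixel(fov_um: tuple, shape_px: tuple) -> tuple:
    """Pixel size from a field of view and the sensor shape, element-wise.

    ``um_per_pixel((160.08, 119.6), (1392, 1040))`` gives ``(0.115, 0.115)``.
    """
    fov = np.asarray(fov_um, dtype=float)
    shape = np.asarray(shape_px, dtype=float)
    if fov.shape != shape.shape:
        raise AutopatchError("fov_um and shape_px must have the same length")
    if np.any(fov <= 0) or np.any(shape <= 0):
        raise AutopatchError("field of view and pixel shape must be positive")
    return tuple(fov / shape)


def write_stack(stack: ImageStack, path) -> None:
    """Write a stack as a multi-page TIFF with calibration in the description tag."""
    meta = {
        _META_KEY: {
            "pixel_size_um": stack.pixel_size_um,
            "z_step_um": stack.z_step_um,
        }
    }
    tifffile.imwrite(path, stack.voxels, description=json.dumps(meta))


def read_stack(path) -> ImageStack:
    """Read a multi-page TIFF written by :func:`write_stack`.

    If the calibration metadata is absent (a foreign TIFF), defaults are applied
    and a warning is logged.
    """
    with tifffile.TiffFile(path) as tif:
        voxels = tif.asarray()
        desc = tif.pages[0].description or ""
    if voxels.ndim == 2:
        voxels = voxels[None]
    if voxels.ndim != 3:
        raise AutopatchError(f"expected 2D/3D TIFF, got {voxels.ndim}D in {path}")
    pixel_size, z_step = DEFAULT_PIXEL_SIZE_UM, DEFAULT_Z_STEP_UM
    found = False
    if desc:
        try:
            meta = json.loads(desc).get(_META_KEY)
            if meta is not None:
                pixel_size = float(meta["pixel_size_um"])
                z_step = float(meta["z_step_um"])
                found = True
        except (json.JSONDecodeError, KeyError, TypeError, ValueError):
            pass
    if not found:
        logger.warning(
            "no calibration metadata in %s; applying defaults (%.4f um/px, %.1f um z-step)",
            path,
            pixel_size,
            z_step,
        )
    return ImageStack(voxels, pixel_size, z_step)


def flatfield_correct(stack: ImageStack, sigma_px: float = 50.0) -> ImageStack:
    """Background illumination correction.

    Every slice is divided by a heavily Gaussian-smoothed copy of itself (the
    background estimate) and rescaled so the slice mean is preserved.  The
    smoothing scale must be larger than any soma but smaller than the
    vignetting scale; 50 px is the default for the reference optics.
    """
    out = np.empty_like(stack.voxels, dtype=np.float64)
    for k in range(stack.n_slices):
        sl = stack.voxels[k].astype(np.float64)
        bg = ndimage.gaussian_filter(sl, sigma=sigma_px, mode="nearest")
        if np.all(bg == 0):
            raise AutopatchError(f"slice {k} has a constant-zero background")
        flat = sl / bg
        mean_flat = flat.mean()
        if mean_flat == 0:
            raise AutopatchError(f"slice {k} is identically zero")
        out[k] = flat * (sl.mean() / mean_flat)
    return ImageStack(out, stack.pixel_size_um, stack.z_step_um)
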