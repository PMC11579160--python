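"""Model input/target construction from organ masks.

The segmentation models never see CT gray values - only contour-derived
geometry.  Each case is turned into 256-level grayscale data in four steps:

1. every organ mask is resampled to a 1 mm isotropic grid (cubic spline on
   the 0/1 field, thresholded at 0.5);
2. bladder and prostate are combined into one input volume at brightness
   64 and 128 (prostate wins on overlap), the urethra target is encoded at
   255;
3. a 128 x 128 x 128 window is cut around the prostate: centered on its
   in-plane centroid, with the prostate apex a fixed margin above the
   inferior edge ("prostate at the bottom of the image");
4. for the 2D models the window is collapsed along Y (coronal) or X
   (sagittal) by maximum intensity and upsampled x2 to 256 x 256
   (0.5 mm/px) - cubic for inputs, nearest-neighbor for targets.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage

from .core import (
    MaskVolume,
    GrayscaleVolume,
    ProjectionImage,
    GeometryError,
    AnatomyError,
)

logger = logging.getLogger(__name__)

CROP_SIZE = 128
CROP_INFERIOR_MARGIN = 10  # voxels between prostate apex and window bottom
PROJECTION_SIZE = 256
LEVEL_BLADDER = 64
LEVEL_PROSTATE = 128
LEVEL_URETHRA = 255


def resample_isotropic(mask: MaskVolume, *, order: int = 3) -> MaskVolume:
    """Resample a binary mask to a 1 mm isotropic grid.

    The binary field is interpolated with a cubic spline and thresholded at
    0.5 (ties count as inside).  The output grid shares the input's origin
    and covers the same world extent of voxel centers.
    """
    spacing = mask.spacing
    if np.allclose(spacing, 1.0):
        return mask.copy()
    old_shape = np.asarray(mask.shape)
    new_shape = np.round((old_shape - 1) * spacing).astype(int) + 1
    out = np.zeros(tuple(new_shape), dtype=bool)
    nz = np.argwhere(mask.voxels)
    if nz.size:
        # restrict interpolation to the mask's bounding box (plus spline
        # support margin); everything else interpolates to zero anyway
        lo_in = np.maximum(nz.min(axis=0) - 4, 0)
        hi_in = np.minimum(nz.max(axis=0) + 4, old_shape - 1)
        axes_idx, axes_coord = [], []
        for i in range(3):
            idx = np.arange(new_shape[i])
            src = idx / spacing[i]
            sel = (src >= lo_in[i]) & (src <= hi_in[i])
            axes_idx.append(idx[sel])
            axes_coord.append(src[sel] - lo_in[i])
        sub = mask.voxels[tuple(slice(l, h + 1)
                                for l, h in zip(lo_in, hi_in))]
        coords = np.meshgrid(*axes_coord, indexing="ij")
        field = ndimage.map_coordinates(sub.astype(np.float32), coords,
                                        order=order, mode="constant",
                                        cval=0.0)
        out[np.ix_(*axes_idx)] = field >= 0.5
    return MaskVolume(out, np.ones(3), mask.origin.copy(),
                      mask.organ_label)


def encode_input(bladder: MaskVolume, prostate: MaskVolume) -> GrayscaleVolume:
    """Combine bladder and prostate masks into the grayscale input volume.

    Bladder voxels get level 64, prostate voxels 128; where the contours
    overlap the prostate wins (the urethra lives in the prostate, so its
    geometry is the stronger cue).
    """
    if not bladder.same_grid(prostate):
        raise GeometryError("bladder and prostate are not on the same grid")
    levels = np.zeros(bladder.shape, dtype=np.uint8)
    levels[bladder.voxels] = LEVEL_BLADDER
    levels[prostate.voxels] = LEVEL_PROSTATE
    return GrayscaleVolume(levels, bladder.origin.copy(), "input",
                           bladder.spacing.copy())


def encode_target(urethra: MaskVolume) -> GrayscaleVolume:
    """Encode the urethra mask as the grayscale target volume (level 255)."""
    levels = np.where(urethra.voxels, LEVEL_URETHRA, 0).astype(np.uint8)
    return GrayscaleVolume(levels, urethra.origin.copy(), "target",
                           urethra.spacing.copy())


def crop_window(prostate: MaskVolume, size: int = CROP_SIZE,
                margin: int = CROP_INFERIOR_MARGIN) -> np.ndarray:
    """Start indices (possibly negative) of the prostate-anchored window.

    X and Y centers sit on the prostate centroid (rounded to the nearest
    voxel); along Z the most inferior prostate voxel is placed ``margin``
    voxels above the inferior window edge.
    """
    if not prostate.voxels.any():
        raise AnatomyError("prostate mask is empty; cannot anchor the crop")
    idx = np.argwhere(prostate.voxels)
    centroid = idx.mean(axis=0)
    cx, cy = np.round(centroid[:2]).astype(int)
    z_inf = int(idx[:, 2].max())
    z_sup = int(idx[:, 2].min())
    if z_inf - z_sup + 1 > size - margin:
        logger.warning(
            "prostate spans %d voxels in Z; window of %d with margin %d "
            "truncates its superior part", z_inf - z_sup + 1, size, margin)
    start = np.array([cx - size // 2, cy - size // 2,
                      z_inf - (size - 1 - margin)])
    return start


def apply_window(volume: GrayscaleVolume, start: np.ndarray,
                 size: int = CROP_SIZE) -> GrayscaleVolume:
    """Extract a zero-padded cubic window starting at ``start`` indices."""
    src = volume.intensities
    out = np.zeros((size, size, size), dtype=src.dtype)
    lo = np.maximum(start, 0)
    hi = np.minimum(start + size, src.shape)
    dst_lo = lo - start
    dst_hi = dst_lo + (hi - lo)
    if np.all(hi > lo):
        out[dst_lo[0]:dst_hi[0], dst_lo[1]:dst_hi[1], dst_lo[2]:dst_hi[2]] = \
            src[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    origin = volume.origin + start * volume.spacing
    return GrayscaleVolume(out, origin, volume.provenance, volume.spacing.copy())


def window_mask(mask: MaskVolume, start: np.ndarray,
                size: int = CROP_SIZE) -> MaskVolume:
    """Crop a binary mask with the same window geometry as the volumes."""
    as_gray = GrayscaleVolume(mask.voxels.astype(np.uint8),
                              mask.origin, "target", mask.spacing)
    cropped = apply_window(as_gray, start, size)
    return MaskVolume(cropped.intensities > 0, cropped.spacing,
                      cropped.origin, mask.organ_label)


def crop_to_prostate(volume: GrayscaleVolume, prostate: MaskVolume,
                     size: int = CROP_SIZE,
                     margin: int = CROP_INFERIOR_MARGIN) -> GrayscaleVolume:
    """Cut the prostate-anchored 128-cube out of an encoded volume."""
    if volume.shape != prostate.shape:
        raise GeometryError("volume and prostate mask grids differ")
    return apply_window(volume, crop_window(prostate, size, margin), size)


def project(volume: GrayscaleVolume, plane: str) -> ProjectionImage:
    """Maximum-intensity projection of a cropped volume, upsampled x2.

    ``plane="coronal"`` collapses Y (image axes X x Z); ``"sagittal"``
    collapses X (image axes Y x Z).  The 128 x 128 projection is upsampled
    to 256 x 256 at 0.5 mm/px - cubic interpolation for input volumes,
    nearest-neighbor for binary-leveled targets.  Pixel ``(u, v)`` maps to
    in-plane mm ``window_origin[axis] + 0.5 u`` and slice mm
    ``window_origin[2] + 0.5 v``; v grows inferiorly, keeping the prostate
    at the bottom.
    """
    if volume.shape != (CROP_SIZE,) * 3:
        raise GeometryError(
            f"projection expects a {CROP_SIZE}^3 crop, got {volume.shape}")
    if plane == "coronal":
        flat = volume.intensities.max(axis=1)
    elif plane == "sagittal":
        flat = volume.intensities.max(axis=0)
    else:
        raise GeometryError(f"unknown projection plane {plane!r}")
    order = 3 if volume.provenance == "input" else 0
    up = ndimage.zoom(flat.astype(np.float32), 2, order=order,
                      grid_mode=True, mode="grid-constant")
    up = np.clip(np.rint(up), 0, 255).astype(np.uint8)
    return ProjectionImage(up, plane, volume.origin.copy(), volume.provenance)
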