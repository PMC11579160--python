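"""From raw segmentation output to the final 5 mm cylindrical urethra.

Model predictions can be irregularly shaped, so they are never used
directly as the urethra.  Instead, a per-slice coordinate is computed on
every 1 mm X-Y plane in which the prostate is present:

* 2D variant: the X coordinate is the centroid of predicted pixels in the
  coronal image rows overlapping that slice, the Y coordinate likewise
  from the sagittal image;
* 3D variant: the in-plane centroid of the predicted voxels of that slice.

Slices where the model predicted nothing are filled in afterwards (linear
interpolation inside the prediction's extent, nearest-value extrapolation
at the ends).  A circle of fixed diameter (default 5 mm) is then drawn
around each coordinate, the stack of discs forming the cylindrical
urethra, which is finally resampled back to the original CT grid.

Coordinates are expressed in the crop-window frame: mm relative to the
window origin, so voxel ``i`` of the 1 mm crop grid sits at ``i`` mm and
projection pixel ``u`` (0.5 mm/px) at ``0.5 u`` mm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import MaskVolume, EmptyPredictionError, GeometryError
from .structio import GridSpec

DEFAULT_DIAMETER_MM = 5.0

SOURCE_PREDICTED = "predicted"
SOURCE_INTERPOLATED = "interpolated"
SOURCE_EXTRAPOLATED = "extrapolated"
SOURCE_MISSING = "missing"


@dataclass
class CoordinateSeries:
    """Per-slice urethra coordinates on the 1 mm crop grid.

    ``z_index`` are strictly increasing slice indices (one per
    prostate-containing slice); ``x_mm``/``y_mm`` are window-frame
    coordinates with NaN where the model predicted nothing; the source
    arrays record, per coordinate, how each value was obtained.
    """

    z_index: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray
    source_x: np.ndarray
    source_y: np.ndarray

    def __post_init__(self) -> None:
        self.z_index = np.asarray(self.z_index, dtype=int)
        self.x_mm = np.asarray(self.x_mm, dtype=float)
        self.y_mm = np.asarray(self.y_mm, dtype=float)
        self.source_x = np.asarray(self.source_x, dtype=object)
        self.source_y = np.asarray(self.source_y, dtype=object)
        n = self.z_index.size
        for arr in (self.x_mm, self.y_mm, self.source_x, self.source_y):
            if arr.shape != (n,):
                raise GeometryError("coordinate series arrays must align")
        if n > 1 and not np.all(np.diff(self.z_index) > 0):
            raise GeometryError("z indices must be strictly increasing")

    @property
    def complete(self) -> bool:
        return not (np.isnan(self.x_mm).any() or np.isnan(self.y_mm).any())

    def __len__(self) -> int:
        return int(self.z_index.size)


def _as_array(mask) -> np.ndarray:
    """Accept a bare boolean array or a PredictionMask-like object."""
    return np.asarray(getattr(mask, "mask", mask)).astype(bool)


def _row_centroids(img: np.ndarray, z_indices: np.ndarray,
                   mm_per_px: float = 0.5) -> np.ndarray:
    """Centroid (mm) of predicted pixels in the rows overlapping each slice.

    ``img`` is indexed ``[u, v]``; 1 mm slice ``k`` overlaps the two 0.5 mm
    rows ``v = 2k`` and ``2k + 1``, which are pooled before taking the
    centroid.  NaN where no pixel is predicted.
    """
    out = np.full(z_indices.shape, np.nan)
    us = np.arange(img.shape[0], dtype=float)
    for i, k in enumerate(z_indices):
        rows = img[:, 2 * k:2 * k + 2]
        weight = rows.sum(axis=1).astype(float)
        total = weight.sum()
        if total > 0:
            out[i] = (us @ weight) / total * mm_per_px
    return out


def coords_from_projections(coronal, sagittal,
                            prostate_z: np.ndarray) -> CoordinateSeries:
    """Per-slice (X, Y) from the coronal and sagittal 2D predictions."""
    cor = _as_array(coronal)
    sag = _as_array(sagittal)
    if cor.shape != sag.shape:
        raise GeometryError("coronal and sagittal masks differ in shape")
    if not cor.any() and not sag.any():
        raise EmptyPredictionError("both 2D predictions are entirely empty")
    z = np.asarray(prostate_z, dtype=int)
    x = _row_centroids(cor, z)
    y = _row_centroids(sag, z)
    return CoordinateSeries(
        z, x, y,
        np.where(np.isnan(x), SOURCE_MISSING, SOURCE_PREDICTED),
        np.where(np.isnan(y), SOURCE_MISSING, SOURCE_PREDICTED),
    )


def coords_from_volume(pred, prostate_z: np.ndarray) -> CoordinateSeries:
    """Per-slice (X, Y) centroids of a 3D prediction on the crop grid."""
    vol = _as_array(pred)
    if vol.ndim != 3:
        raise GeometryError("3D coordinate extraction expects a volume")
    if not vol.any():
        raise EmptyPredictionError("3D prediction is entirely empty")
    z = np.asarray(prostate_z, dtype=int)
    x = np.full(z.shape, np.nan)
    y = np.full(z.shape, np.nan)
    for i, k in enumerate(z):
        sl = vol[:, :, k]
        n = sl.sum()
        if n:
            idx = np.argwhere(sl)
            x[i], y[i] = idx.mean(axis=0)
    src = lambda a: np.where(np.isnan(a), SOURCE_MISSING, SOURCE_PREDICTED)
    return CoordinateSeries(z, x, y, src(x), src(y))


def _fill_axis(z: np.ndarray, vals: np.ndarray, sources: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray]:
    known = ~np.isnan(vals)
    if not known.any():
        raise EmptyPredictionError("an axis has no predicted coordinates at all")
    if known.all():
        return vals, sources
    filled = vals.copy()
    out_src = sources.copy()
    zk, vk = z[known].astype(float), vals[known]
    gaps = ~known
    filled[gaps] = np.interp(z[gaps].astype(float), zk, vk)
    interior = gaps & (z >= zk[0]) & (z <= zk[-1])
    out_src[interior] = SOURCE_INTERPOLATED
    out_src[gaps & ~interior] = SOURCE_EXTRAPOLATED
    return filled, out_src


def fill_missing(series: CoordinateSeries) -> CoordinateSeries:
    """Complete a series: linear interpolation in z inside the predicted
    extent, nearest-value extrapolation beyond it; sources relabeled."""
    x, sx = _fill_axis(series.z_index, series.x_mm, series.source_x)
    y, sy = _fill_axis(series.z_index, series.y_mm, series.source_y)
    return CoordinateSeries(series.z_index.copy(), x, y, sx, sy)


@dataclass
class CylinderMask:
    """Reconstructed urethra: stacked discs of fixed diameter."""

    mask: MaskVolume
    diameter_mm: float = DEFAULT_DIAMETER_MM


def build_cylinder(series: CoordinateSeries,
                   diameter_mm: float = DEFAULT_DIAMETER_MM,
                   grid: GridSpec | None = None,
                   grid_shape: tuple[int, int, int] = (128, 128, 128),
                   window_origin: np.ndarray | None = None) -> CylinderMask:
    """Draw a disc of ``diameter_mm`` around each slice coordinate.

    Membership is voxel-center distance <= radius, boundary inclusive
    (21 voxels per slice for 5 mm diameter on a center-aligned 1 mm grid).
    The cylinder axis follows the per-slice coordinates; it need not be
    straight.  Requires a complete series.
    """
    if diameter_mm <= 0:
        raise ValueError("cylinder diameter must be positive")
    if not series.complete:
        raise EmptyPredictionError(
            "series has missing coordinates; run fill_missing first")
    if grid is None:
        origin = np.zeros(3) if window_origin is None else np.asarray(window_origin)
        grid = GridSpec(tuple(grid_shape), (1.0, 1.0, 1.0), tuple(origin))
    shape = tuple(grid.shape)
    spacing = np.asarray(grid.spacing, dtype=float)
    radius = diameter_mm / 2.0

    vox = np.zeros(shape, dtype=bool)
    gx = np.arange(shape[0]) * spacing[0]   # window-frame voxel centers
    gy = np.arange(shape[1]) * spacing[1]
    for k, xc, yc in zip(series.z_index, series.x_mm, series.y_mm):
        if not (0 <= k < shape[2]):
            continue
        d2 = (gx[:, None] - xc) ** 2 + (gy[None, :] - yc) ** 2
        vox[:, :, k] = d2 <= radius ** 2
    mask = MaskVolume(vox, spacing, np.asarray(grid.origin, dtype=float),
                      "urethra_reconstructed")
    return CylinderMask(mask, diameter_mm)


def resample_to_original(cyl: CylinderMask, original_grid: GridSpec
                         ) -> CylinderMask:
    """Resample the cylinder to the original CT grid (cubic spline, 0.5).

    The binary field is interpolated with a cubic spline at the original
    grid's voxel centers and thresholded at 0.5 (ties inside).
    """
    src = cyl.mask
    shape = tuple(original_grid.shape)
    spacing = np.asarray(original_grid.spacing, dtype=float)
    origin = np.asarray(original_grid.origin, dtype=float)
    if np.allclose(spacing, src.spacing) and np.allclose(origin, src.origin) \
            and shape == src.shape:
        return CylinderMask(src.copy(), cyl.diameter_mm)
    out = np.zeros(shape, dtype=bool)
    nz = np.argwhere(src.voxels)
    if nz.size:
        # only evaluate the spline near the cylinder's bounding box
        lo_in = np.maximum(nz.min(axis=0) - 4, 0)
        hi_in = np.minimum(nz.max(axis=0) + 4,
                           np.asarray(src.shape) - 1)
        axes_idx, axes_coord = [], []
        for i in range(3):
            idx = np.arange(shape[i])
            c = (origin[i] + idx * spacing[i] - src.origin[i]) / src.spacing[i]
            sel = (c >= lo_in[i]) & (c <= hi_in[i])
            axes_idx.append(idx[sel])
            axes_coord.append(c[sel] - lo_in[i])
        sub = src.voxels[tuple(slice(l, h + 1)
                               for l, h in zip(lo_in, hi_in))]
        coords = np.meshgrid(*axes_coord, indexing="ij")
        field = ndimage.map_coordinates(sub.astype(np.float32), coords,
                                        order=3, mode="constant", cval=0.0)
        out[np.ix_(*axes_idx)] = field >= 0.5
    mask = MaskVolume(out, spacing, origin, src.organ_label)
    return CylinderMask(mask, cyl.diameter_mm)


def prostate_slice_range(prostate_crop: MaskVolume) -> np.ndarray:
    """Indices of crop-grid slices containing at least one prostate voxel."""
    return np.flatnonzero(prostate_crop.voxels.any(axis=(0, 1)))
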