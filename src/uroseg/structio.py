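"""Structure-set and mask I/O: polygons-per-slice <-> binary voxel masks.

Planning systems exchange organ outlines as DICOM RT Structure Sets: for
each named structure, a stack of closed planar polygons in patient mm
coordinates, one or more per CT slice.  This module converts between that
representation and axis-aligned binary :class:`~uroseg.core.MaskVolume`
grids, and round-trips masks through NIfTI-1 files.

Rasterization uses the even-odd rule (a point is inside if it falls inside
an odd number of the slice's polygons), with voxel centers lying exactly on
a polygon edge counted as inside - a deterministic tie-break.  Only
axis-aligned grids are supported; oblique acquisitions are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import nibabel as nib
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid
from skimage import measure

from .core import (
    MaskVolume,
    GeometryError,
    MissingStructureError,
    FormatError,
)

__all__ = [
    "GridSpec", "ContourSet", "rasterize", "mask_to_contours",
    "read_mask", "write_mask", "read_structure_set", "write_structure_set",
    "MaskVolume",
]

_RTSTRUCT_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.3"
_EDGE_TOL = 1e-9


@dataclass
class GridSpec:
    """Axis-aligned sampling grid: shape, mm spacing and mm origin."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @classmethod
    def of(cls, mask: MaskVolume) -> "GridSpec":
        return cls(tuple(mask.shape), tuple(mask.spacing), tuple(mask.origin))


@dataclass
class ContourSet:
    """All contours of one organ: ``(z_mm, (n, 2) xy-mm polygon)`` pairs.

    Multiple polygons may share a slice (islands, or rings under the
    even-odd rule).  Each polygon is closed implicitly (last vertex
    connects back to the first) and must have at least 3 vertices.
    """

    organ_label: str
    polygons: list[tuple[float, np.ndarray]] = field(default_factory=list)

    def add(self, z_mm: float, xy: np.ndarray) -> None:
        xy = np.asarray(xy, dtype=float)
        if xy.ndim != 2 or xy.shape[1] != 2 or xy.shape[0] < 3:
            raise GeometryError("polygon must be an (n>=3, 2) array")
        self.polygons.append((float(z_mm), xy))

    def slice_zs(self) -> np.ndarray:
        return np.unique([z for z, _ in self.polygons])

    def __len__(self) -> int:
        return len(self.polygons)


# ---------------------------------------------------------------------------
# rasterization


def _crossing_parity(px: np.ndarray, py: np.ndarray,
                     poly: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Even-odd crossing parity and on-edge flags for a flat point cloud."""
    inside = np.zeros(px.shape, dtype=bool)
    onedge = np.zeros(px.shape, dtype=bool)
    x1, y1 = poly[:, 0], poly[:, 1]
    x2, y2 = np.roll(x1, -1), np.roll(y1, -1)
    for ax, ay, bx, by in zip(x1, y1, x2, y2):
        dx, dy = bx - ax, by - ay
        seg_len = max(float(np.hypot(dx, dy)), _EDGE_TOL)
        cross = dx * (py - ay) - dy * (px - ax)
        on = (
            (np.abs(cross) <= _EDGE_TOL * seg_len)
            & (px >= min(ax, bx) - _EDGE_TOL) & (px <= max(ax, bx) + _EDGE_TOL)
            & (py >= min(ay, by) - _EDGE_TOL) & (py <= max(ay, by) + _EDGE_TOL)
        )
        onedge |= on
        if dy == 0.0:
            continue  # horizontal edge never crosses the +x ray test
        spans = (ay > py) != (by > py)
        if np.any(spans):
            xint = ax + (py - ay) * dx / dy
            inside ^= spans & (px < xint)
    return inside, onedge


def rasterize(contours: ContourSet, grid: GridSpec) -> MaskVolume:
    """Voxelize one organ's contours onto ``grid`` (even-odd rule).

    A voxel is set when its center falls inside an odd number of the
    slice's polygons, or exactly on any polygon edge.  Slices without
    polygons stay empty.  Raises :class:`GeometryError` for polygons that
    do not lie on a slice plane or extend beyond the grid.
    """
    shape = tuple(grid.shape)
    spacing = np.asarray(grid.spacing, dtype=float)
    origin = np.asarray(grid.origin, dtype=float)
    vox = np.zeros(shape, dtype=bool)

    gx = origin[0] + np.arange(shape[0]) * spacing[0]
    gy = origin[1] + np.arange(shape[1]) * spacing[1]
    px, py = np.meshgrid(gx, gy, indexing="ij")
    px, py = px.ravel(), py.ravel()

    by_slice: dict[int, list[np.ndarray]] = {}
    for z_mm, poly in contours.polygons:
        k_float = (z_mm - origin[2]) / spacing[2]
        k = int(round(k_float))
        if abs(k_float - k) > 1e-3:
            raise GeometryError(
                f"contour at z={z_mm:.3f} mm is not coplanar with any slice")
        if not (0 <= k < shape[2]):
            raise GeometryError(f"contour slice z={z_mm:.3f} mm outside grid")
        lo = np.array([gx[0], gy[0]]) - spacing[:2] / 2
        hi = np.array([gx[-1], gy[-1]]) + spacing[:2] / 2
        if np.any(poly < lo) or np.any(poly > hi):
            raise GeometryError(
                f"polygon vertex outside grid on slice z={z_mm:.3f} mm")
        by_slice.setdefault(k, []).append(poly)

    for k, polys in by_slice.items():
        parity = np.zeros(px.shape, dtype=bool)
        onedge = np.zeros(px.shape, dtype=bool)
        for poly in polys:
            ins, on = _crossing_parity(px, py, poly)
            parity ^= ins
            onedge |= on
        vox[:, :, k] = (parity | onedge).reshape(shape[:2])

    return MaskVolume(vox, spacing, origin, contours.organ_label)


def mask_to_contours(mask: MaskVolume) -> ContourSet:
    """Trace per-slice iso-contours of a binary mask (marching squares).

    The contour runs half a voxel outside the outermost foreground voxel
    centers, so rasterizing it back reproduces the mask exactly on convex
    shapes.
    """
    cs = ContourSet(mask.organ_label)
    for k in range(mask.shape[2]):
        sl = mask.voxels[:, :, k]
        if not sl.any():
            continue
        padded = np.pad(sl.astype(float), 1)
        for contour in measure.find_contours(padded, 0.5):
            idx = contour - 1.0  # undo pad
            if np.allclose(idx[0], idx[-1]):
                idx = idx[:-1]
            if idx.shape[0] < 3:
                continue
            xy = mask.origin[:2] + idx * mask.spacing[:2]
            cs.add(mask.origin[2] + k * mask.spacing[2], xy)
    return cs


# ---------------------------------------------------------------------------
# NIfTI masks


def write_mask(mask: MaskVolume, path: str | Path) -> None:
    """Write a binary mask as NIfTI-1 with a diagonal affine."""
    affine = np.diag(list(mask.spacing) + [1.0])
    affine[:3, 3] = mask.origin
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), affine)
    nib.save(img, str(path))


def read_mask(path: str | Path, organ_label: str = "") -> MaskVolume:
    """Read a NIfTI-1 mask; only axis-aligned, positively oriented affines.

    Raises :class:`FormatError` for oblique or flipped orientations and for
    non-3D images.
    """
    img = nib.load(str(path))
    affine = img.affine
    rot = affine[:3, :3]
    if not np.allclose(rot - np.diag(np.diag(rot)), 0.0, atol=1e-4):
        raise FormatError(f"{path}: non-axis-aligned affine not supported")
    spacing = np.diag(rot)
    if np.any(spacing <= 0):
        raise FormatError(f"{path}: flipped or degenerate affine not supported")
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, got {data.ndim}D")
    return MaskVolume(data > 0.5, spacing, affine[:3, 3], organ_label)


# ---------------------------------------------------------------------------
# DICOM RT Structure Set (minimal dialect)


def write_structure_set(contour_sets: list[ContourSet], path: str | Path,
                        description: str = "uroseg phantom") -> None:
    """Write a minimal RT Structure Set containing the given organs.

    Only the elements needed to round-trip contours are emitted (structure
    names, closed planar polygons in patient mm); there is no referenced
    image series.
    """
    file_meta = FileMetaDataset()
    file_meta.MediaStorageSOPClassUID = _RTSTRUCT_SOP_CLASS
    file_meta.MediaStorageSOPInstanceUID = generate_uid()
    file_meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = file_meta
    ds.SOPClassUID = _RTSTRUCT_SOP_CLASS
    ds.SOPInstanceUID = file_meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTSTRUCT"
    ds.StructureSetLabel = description[:16]  # SH VR limit
    ds.PatientName = "phantom"
    ds.PatientID = "phantom"
    frame_uid = generate_uid()
    ds.FrameOfReferenceUID = frame_uid

    ds.StructureSetROISequence = []
    ds.ROIContourSequence = []
    for number, cs in enumerate(contour_sets, start=1):
        roi = Dataset()
        roi.ROINumber = number
        roi.ReferencedFrameOfReferenceUID = frame_uid
        roi.ROIName = cs.organ_label
        roi.ROIGenerationAlgorithm = "AUTOMATIC"
        ds.StructureSetROISequence.append(roi)

        rc = Dataset()
        rc.ReferencedROINumber = number
        rc.ContourSequence = []
        for z_mm, poly in cs.polygons:
            c = Dataset()
            c.ContourGeometricType = "CLOSED_PLANAR"
            c.NumberOfContourPoints = poly.shape[0]
            data = np.column_stack([poly, np.full(poly.shape[0], z_mm)])
            c.ContourData = [f"{v:.6f}" for v in data.ravel()]
            rc.ContourSequence.append(c)
        ds.ROIContourSequence.append(rc)

    pydicom.dcmwrite(path, ds, enforce_file_format=True)


def _normalize_organ_map(organ_map: dict[str, list[str]] | None
                         ) -> dict[str, list[str]]:
    if organ_map is None:
        organ_map = {
            "bladder": ["bladder", "urinary bladder", "vessie"],
            "prostate": ["prostate"],
            "urethra": ["urethra", "prostatic urethra", "uretra"],
        }
    return {canon: [a.lower() for a in aliases]
            for canon, aliases in organ_map.items()}


def read_structure_set(path: str | Path,
                       organ_map: dict[str, list[str]] | None = None,
                       ) -> list[ContourSet]:
    """Read an RT Structure Set, resolving organ names case-insensitively.

    ``organ_map`` maps canonical organ labels to alias lists; every
    requested organ must resolve to exactly one structure in the file or a
    :class:`MissingStructureError` is raised naming the organ.
    """
    organ_map = _normalize_organ_map(organ_map)
    ds = pydicom.dcmread(path)
    if getattr(ds, "SOPClassUID", "") != _RTSTRUCT_SOP_CLASS:
        raise FormatError(f"{path}: not an RT Structure Set")

    by_number: dict[int, str] = {}
    for roi in getattr(ds, "StructureSetROISequence", []):
        by_number[int(roi.ROINumber)] = str(roi.ROIName)

    name_to_canon: dict[str, str] = {}
    for canon, aliases in organ_map.items():
        for number, name in by_number.items():
            if name.lower() in aliases:
                name_to_canon[name] = canon

    results: dict[str, ContourSet] = {c: ContourSet(c) for c in organ_map}
    found: set[str] = set()
    for rc in getattr(ds, "ROIContourSequence", []):
        name = by_number.get(int(rc.ReferencedROINumber))
        canon = name_to_canon.get(name)
        if canon is None:
            continue
        found.add(canon)
        for c in getattr(rc, "ContourSequence", []):
            pts = np.asarray([float(v) for v in c.ContourData]).reshape(-1, 3)
            zs = pts[:, 2]
            if np.ptp(zs) > 1e-3:
                raise GeometryError(
                    f"{name}: contour not coplanar (z spread {np.ptp(zs):.3g} mm)")
            results[canon].add(float(zs[0]), pts[:, :2])

    missing = sorted(set(organ_map) - found)
    if missing:
        raise MissingStructureError(
            f"structure(s) not found in {path}: {', '.join(missing)}")
    return [results[c] for c in organ_map]
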