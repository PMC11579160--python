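"""Shared geometric types and error taxonomy.

Conventions used across the package
-----------------------------------
* Axes: X = patient left-right, Y = anterior-posterior, Z = the CT slice
  axis (superior-inferior).  The Z *index* increases toward the inferior
  (feet) direction, so "top of the prostate" means small z.
* Arrays are indexed ``[x, y, z]``.
* Voxel-center convention: the world position of voxel ``(i, j, k)`` is
  ``origin + (i, j, k) * spacing`` (mm).  All grids are axis aligned.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np


class UrosegError(Exception):
    """Base class for errors raised by this package."""


class SizingError(UrosegError):
    """The requested grid cannot contain the requested anatomy."""


class GeometryError(UrosegError):
    """Inconsistent grids, off-slice polygons, or out-of-grid vertices."""


class MissingStructureError(UrosegError):
    """A requested organ is absent from a structure set."""


class FormatError(UrosegError):
    """A file is syntactically readable but in an unsupported dialect."""


class AnatomyError(UrosegError):
    """An anatomically required mask (e.g. the prostate) is empty."""


class EmptyPredictionError(UrosegError):
    """A prediction mask contains no foreground anywhere."""


class ConfigurationError(UrosegError):
    """Invalid training / splitting configuration."""


@dataclass
class MaskVolume:
    """Binary occupancy of one organ on an axis-aligned CT grid.

    Attributes
    ----------
    voxels : (nx, ny, nz) bool array
    spacing : (3,) float array, mm per voxel along x, y, z
    origin : (3,) float array, world mm of voxel (0, 0, 0)
    organ_label : free-text organ name
    """

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    organ_label: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise GeometryError("mask voxels must be a 3D array")
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.spacing.shape != (3,) or self.origin.shape != (3,):
            raise GeometryError("spacing and origin must be length-3")
        if not np.all(self.spacing > 0):
            raise GeometryError("spacing must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def world_of(self, index: np.ndarray) -> np.ndarray:
        """World mm coordinates of (possibly fractional) voxel indices."""
        return self.origin + np.asarray(index, dtype=float) * self.spacing

    def index_of(self, world: np.ndarray) -> np.ndarray:
        """Fractional voxel indices of world mm coordinates."""
        return (np.asarray(world, dtype=float) - self.origin) / self.spacing

    def same_grid(self, other: "MaskVolume", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def copy(self) -> "MaskVolume":
        return replace(self, voxels=self.voxels.copy(),
                       spacing=self.spacing.copy(), origin=self.origin.copy())


@dataclass
class GrayscaleVolume:
    """256-level encoded model input or target on a 1 mm isotropic grid.

    ``provenance`` distinguishes inputs (levels {0, 64, 128}) from targets
    (levels {0, 255}); it also selects the interpolation used when the
    volume is later projected and upsampled.
    """

    intensities: np.ndarray
    origin: np.ndarray
    provenance: Literal["input", "target"]
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.uint8)
        if self.intensities.ndim != 3:
            raise GeometryError("grayscale volume must be 3D")
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape


@dataclass
class ProjectionImage:
    """2D projection of an encoded volume, 256 x 256 at 0.5 mm/px.

    ``plane`` is ``"coronal"`` (Y collapsed; columns = X) or ``"sagittal"``
    (X collapsed; columns = Y).  Pixel ``(u, v)`` maps to in-plane world
    coordinate ``window_origin[axis] + 0.5 * u`` mm and slice coordinate
    ``window_origin[2] + 0.5 * v`` mm; rows (v) increase inferiorly so the
    prostate sits at the bottom of the image.
    """

    intensities: np.ndarray
    plane: Literal["coronal", "sagittal"]
    window_origin: np.ndarray
    provenance: Literal["input", "target"] = "input"
    mm_per_px: float = 0.5

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 2:
            raise GeometryError("projection image must be 2D")
        if self.plane not in ("coronal", "sagittal"):
            raise GeometryError(f"unknown plane {self.plane!r}")
        self.window_origin = np.asarray(self.window_origin, dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape


@dataclass
class Centerline:
    """Per-slice urethral midpoints: arrays of equal length.

    ``z`` are slice-center world positions in mm (strictly increasing,
    at most one record per slice); ``x`` and ``y`` are the in-plane
    midpoint world coordinates in mm.
    """

    z: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.z.shape == self.x.shape == self.y.shape):
            raise GeometryError("centerline arrays must have equal length")
        if self.z.ndim != 1:
            raise GeometryError("centerline arrays must be 1D")
        if self.z.size > 1 and not np.all(np.diff(self.z) > 0):
            raise GeometryError("centerline z must be strictly increasing")

    def __len__(self) -> int:
        return int(self.z.size)

    def as_array(self) -> np.ndarray:
        """(n, 3) array of (z, x, y) rows."""
        return np.column_stack([self.z, self.x, self.y])
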