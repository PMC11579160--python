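"""Synthetic pelvic phantoms with analytically known urethral centerlines.

Clinical planning-CT cohorts with catheter-defined urethra ground truth are
not publicly shareable, so every stage of the pipeline is exercised on
synthetic anatomies instead: an ellipsoidal prostate, an ellipsoidal bladder
sitting superior to it (abutting or slightly overlapping at the bladder
neck), and a smooth parametric urethral path running from the bladder neck
to the prostate apex.  The path's exact per-slice midpoints are known in
closed form, which turns centerline-distance evaluation into a test with an
analytic oracle.

The generator reproduces the population characteristics of the EBRT cohort
it stands in for: prostate volumes log-normally distributed around
35.67 +/- 14.21 mL (range 14.59-100.60 mL), in-plane pixel sizes of
0.8-1.2 mm, slice thicknesses of 2.0 or 2.5 mm, and a minority of cases
with a pronounced left-right tilt of the urethra confined to the upper
third of the prostate - the known hard case for localization models.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .core import Centerline, MaskVolume, SizingError

URETHRA_RADIUS_MM = 2.5  # 5 mm diameter tube, fixed by the reconstruction model

_DEFAULT_GRID = (96, 96, 72)
_DEFAULT_SPACING = (1.0, 1.0, 2.0)


@dataclass
class PhantomParams:
    """Geometric parameters of one synthetic case.

    ``bladder_offset`` is the signed craniocaudal gap between the bladder's
    inferior pole and the prostate's superior pole: positive = gap,
    negative = overlap (the usual situation at the bladder neck).
    ``urethra_tilt_deg`` is the left-right angulation of the path in the
    superior third of the prostate; ``urethra_curvature`` is a
    dimensionless anterior bow (fraction of the prostate's A-P semi-axis).
    """

    prostate_semi_axes: tuple[float, float, float] = (20.5, 20.5, 20.5)
    bladder_semi_axes: tuple[float, float, float] = (27.0, 27.0, 22.0)
    bladder_offset: float = -2.0
    urethra_tilt_deg: float = 0.0
    urethra_curvature: float = 0.0
    voxel_spacing: tuple[float, float, float] = _DEFAULT_SPACING
    grid_shape: tuple[int, int, int] = _DEFAULT_GRID
    seed: int = 0

    def validate(self) -> None:
        if any(a <= 0 for a in self.prostate_semi_axes):
            raise ValueError("prostate semi-axes must be positive")
        if any(a <= 0 for a in self.bladder_semi_axes):
            raise ValueError("bladder semi-axes must be positive")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacing must be strictly positive")
        if any(n < 8 for n in self.grid_shape):
            raise ValueError("grid too small to be meaningful")

    def prostate_volume_ml(self) -> float:
        a, b, c = self.prostate_semi_axes
        return 4.0 / 3.0 * np.pi * a * b * c / 1000.0


@dataclass
class PhantomCase:
    """One synthetic anatomy with its analytic ground truth."""

    params: PhantomParams
    bladder: MaskVolume
    prostate: MaskVolume
    urethra: MaskVolume
    true_centerline: Centerline


@dataclass
class PopulationSpread:
    """Population variability of :func:`sample_population`.

    Defaults target the cohort the phantom emulates: mean prostate volume
    35.67 mL, SD 14.21 mL, hard range 14.59-100.60 mL, and 10% of cases
    with a strong (>= 15 degree) left-right urethral tilt.
    """

    volume_mean_ml: float = 35.67
    volume_sd_ml: float = 14.21
    volume_range_ml: tuple[float, float] = (14.59, 100.60)
    tilt_fraction: float = 0.1
    strong_tilt_deg: tuple[float, float] = (15.0, 25.0)
    mild_tilt_deg: float = 10.0
    max_curvature: float = 0.25


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _path_xy(t: np.ndarray, params: PhantomParams,
             center: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """In-plane world coordinates of the urethral path at parameter t.

    t = 0 at the bladder neck (superior prostate pole), t = 1 at the apex.
    The left-right tilt decays to zero over the superior third via a
    smoothstep; the anterior bow is a symmetric parabola.  Both offsets are
    clamped so the path stays strictly inside the prostate's in-plane
    cross-section (and hence inside the voxelized mask's convex hull).
    """
    t = np.asarray(t, dtype=float)
    a_x, a_y, a_z = params.prostate_semi_axes
    sx, sy, _ = params.voxel_spacing

    tilt_reach_mm = np.tan(np.radians(params.urethra_tilt_deg)) * (2.0 * a_z / 3.0)
    dx = tilt_reach_mm * (1.0 - _smoothstep(3.0 * t))
    dy = params.urethra_curvature * a_y * 4.0 * t * (1.0 - t)

    # local cross-section semi-axes of the ellipsoid at this depth
    zfrac = 2.0 * t - 1.0  # -1 at neck, +1 at apex
    shrink = np.sqrt(np.clip(1.0 - zfrac ** 2, 0.0, None))
    # reach of the voxelized cross-section is at least (r - spacing); stay
    # inside the rhombus spanned by the extreme voxel centers
    rx = np.maximum(1e-6, a_x * shrink - sx)
    ry = np.maximum(1e-6, a_y * shrink - sy)
    frac = np.abs(dx) / rx + np.abs(dy) / ry
    scale = np.where(frac > 0.9, 0.9 / np.maximum(frac, 1e-12), 1.0)
    return center[0] + dx * scale, center[1] + dy * scale


def _ellipsoid_mask(shape, spacing, origin, center, semi_axes) -> np.ndarray:
    idx = [np.arange(n) * s + o for n, s, o in zip(shape, spacing, origin)]
    gx, gy, gz = np.meshgrid(*idx, indexing="ij")
    a, b, c = semi_axes
    q = ((gx - center[0]) / a) ** 2 + ((gy - center[1]) / b) ** 2 \
        + ((gz - center[2]) / c) ** 2
    return q <= 1.0


def generate_phantom(params: PhantomParams) -> PhantomCase:
    """Build one synthetic case from explicit parameters.

    Fully deterministic: the same parameters always give bit-identical
    masks and centerline.  Raises :class:`SizingError` if the grid cannot
    contain both organs with a small safety margin.
    """
    params.validate()
    shape = np.asarray(params.grid_shape, dtype=int)
    spacing = np.asarray(params.voxel_spacing, dtype=float)
    origin = np.zeros(3)
    extent = (shape - 1) * spacing

    a_x, a_y, a_z = params.prostate_semi_axes
    b_x, b_y, b_z = params.bladder_semi_axes

    # prostate centered in-plane (snapped to a voxel center), apex a fixed
    # margin above the inferior grid edge
    inferior_margin = 3.0 * spacing[2]
    pc_xy = np.round((shape[:2] - 1) / 2.0) * spacing[:2]
    apex_z = extent[2] - inferior_margin
    prostate_center = np.array([pc_xy[0], pc_xy[1], apex_z - a_z])
    neck_z = prostate_center[2] - a_z

    bladder_center = np.array([pc_xy[0], pc_xy[1],
                               neck_z - params.bladder_offset - b_z])

    lateral_margin = np.array([spacing[0], spacing[1]])
    for label, c, ax in (("prostate", prostate_center, (a_x, a_y, a_z)),
                         ("bladder", bladder_center, (b_x, b_y, b_z))):
        lo = c[:2] - np.array(ax[:2])
        hi = c[:2] + np.array(ax[:2])
        if np.any(lo < lateral_margin) or np.any(hi > extent[:2] - lateral_margin):
            raise SizingError(f"{label} exceeds the grid laterally")
    if bladder_center[2] - b_z < spacing[2]:
        raise SizingError("grid too short craniocaudally for the bladder")
    if apex_z > extent[2]:
        raise SizingError("grid too short craniocaudally for the prostate")

    prostate_vox = _ellipsoid_mask(shape, spacing, origin,
                                   prostate_center, params.prostate_semi_axes)
    bladder_vox = _ellipsoid_mask(shape, spacing, origin,
                                  bladder_center, params.bladder_semi_axes)

    # urethral path sampled at the prostate-containing slice centers
    slice_has_prostate = prostate_vox.any(axis=(0, 1))
    z_indices = np.flatnonzero(slice_has_prostate)
    if z_indices.size == 0:
        raise SizingError("prostate rasterized to an empty mask")
    z_mm = origin[2] + z_indices * spacing[2]
    t = np.clip((z_mm - neck_z) / (2.0 * a_z), 0.0, 1.0)
    cx, cy = _path_xy(t, params, prostate_center)
    centerline = Centerline(z=z_mm, x=cx, y=cy)

    # 5 mm tube: in-plane distance to the path point of each slice
    gx = origin[0] + np.arange(shape[0]) * spacing[0]
    gy = origin[1] + np.arange(shape[1]) * spacing[1]
    urethra_vox = np.zeros(tuple(shape), dtype=bool)
    for k, xk, yk in zip(z_indices, cx, cy):
        d2 = (gx[:, None] - xk) ** 2 + (gy[None, :] - yk) ** 2
        urethra_vox[:, :, k] = d2 <= URETHRA_RADIUS_MM ** 2

    mk = lambda vox, label: MaskVolume(vox, spacing.copy(), origin.copy(), label)
    return PhantomCase(
        params=params,
        bladder=mk(bladder_vox, "bladder"),
        prostate=mk(prostate_vox, "prostate"),
        urethra=mk(urethra_vox, "urethra"),
        true_centerline=centerline,
    )


def _semi_axes_from_volume(volume_ml: float, ratio_xz: float,
                           ratio_yz: float) -> tuple[float, float, float]:
    volume_mm3 = volume_ml * 1000.0
    a_z = (3.0 * volume_mm3 / (4.0 * np.pi * ratio_xz * ratio_yz)) ** (1.0 / 3.0)
    return (ratio_xz * a_z, ratio_yz * a_z, a_z)


def sample_params(rng: np.random.Generator,
                  spread: PopulationSpread | None = None,
                  tilted: bool | None = None) -> PhantomParams:
    """Draw one case's parameters from the population model."""
    spread = spread or PopulationSpread()
    m, s = spread.volume_mean_ml, spread.volume_sd_ml
    sigma2 = np.log1p((s / m) ** 2)
    mu = np.log(m) - sigma2 / 2.0
    lo, hi = spread.volume_range_ml
    for _ in range(1000):
        vol = float(rng.lognormal(mu, np.sqrt(sigma2)))
        if lo <= vol <= hi:
            break
    else:  # pragma: no cover - pathological spread settings
        vol = float(np.clip(vol, lo, hi))

    ratio_xz = float(np.clip(rng.normal(1.0, 0.1), 0.75, 1.25))
    ratio_yz = float(np.clip(rng.normal(0.95, 0.1), 0.75, 1.25))
    prostate = _semi_axes_from_volume(vol, ratio_xz, ratio_yz)

    bladder = (float(rng.uniform(22, 32)), float(rng.uniform(22, 32)),
               float(rng.uniform(18, 28)))
    offset = float(rng.uniform(-4.0, 0.0))

    if tilted is None:
        tilted = bool(rng.random() < spread.tilt_fraction)
    if tilted:
        t_lo, t_hi = spread.strong_tilt_deg
        tilt = float(rng.choice([-1.0, 1.0]) * rng.uniform(t_lo, t_hi))
    else:
        tilt = float(rng.uniform(-spread.mild_tilt_deg, spread.mild_tilt_deg))
    curvature = float(rng.uniform(0.0, spread.max_curvature))

    s_ip = float(rng.choice([0.8, 1.0, 1.2]))
    s_z = float(rng.choice([2.0, 2.5]))
    n_ip = int(np.ceil(96.0 / s_ip)) + 1
    n_z = int(np.ceil(144.0 / s_z)) + 1

    return PhantomParams(
        prostate_semi_axes=prostate,
        bladder_semi_axes=bladder,
        bladder_offset=offset,
        urethra_tilt_deg=tilt,
        urethra_curvature=curvature,
        voxel_spacing=(s_ip, s_ip, s_z),
        grid_shape=(n_ip, n_ip, n_z),
        seed=int(rng.integers(0, 2 ** 31 - 1)),
    )


def sample_population(n: int, variability: PopulationSpread | None = None,
                      seed: int = 0) -> list[PhantomCase]:
    """Generate ``n`` independent cases; reproducible under ``seed``.

    A ``variability.tilt_fraction`` share of cases (in expectation) carry a
    strong (>= 15 degree) left-right urethral tilt.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return [generate_phantom(sample_params(rng, variability)) for _ in range(n)]


# ---------------------------------------------------------------------------
# on-disk representation: per-organ NIfTI masks + JSON sidecar


def save_case(case: PhantomCase, directory: str | Path) -> None:
    """Write a case as three NIfTI masks plus a JSON sidecar."""
    from . import structio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for organ in ("bladder", "prostate", "urethra"):
        structio.write_mask(getattr(case, organ), directory / f"{organ}.nii")
    sidecar = {
        "params": asdict(case.params),
        "true_centerline": {
            "z_mm": case.true_centerline.z.tolist(),
            "x_mm": case.true_centerline.x.tolist(),
            "y_mm": case.true_centerline.y.tolist(),
        },
    }
    (directory / "case.json").write_text(json.dumps(sidecar, indent=2))


def load_case(directory: str | Path) -> PhantomCase:
    """Inverse of :func:`save_case`."""
    from . import structio

    directory = Path(directory)
    sidecar = json.loads((directory / "case.json").read_text())
    p = sidecar["params"]
    for key in ("prostate_semi_axes", "bladder_semi_axes", "voxel_spacing",
                "grid_shape"):
        p[key] = tuple(p[key])
    params = PhantomParams(**p)
    cl = sidecar["true_centerline"]
    masks = {organ: structio.read_mask(directory / f"{organ}.nii", organ_label=organ)
             for organ in ("bladder", "prostate", "urethra")}
    return PhantomCase(
        params=params,
        true_centerline=Centerline(z=np.array(cl["z_mm"]),
                                   x=np.array(cl["x_mm"]),
                                   y=np.array(cl["y_mm"])),
        **masks,
    )
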