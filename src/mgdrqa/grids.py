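"""Domain types and grid geometry for dose distributions.

Conventions
-----------
* Patient coordinates are in mm; doses in Gy.
* ``DoseGrid.values`` is indexed ``[ix, iy, iz]``; axis 0 is the patient
  left–right axis (x, +left), axis 1 anterior–posterior (y, +anterior),
  axis 2 inferior–superior (z, +superior).
* Voxel indices are 0-based and a voxel's position is its **center**:
  ``origin + index * spacing``.  The grid extent is the half-open box
  ``[origin - spacing/2, origin + (shape - 1/2) * spacing)``.
* Gantry angles follow IEC 61217: at 0 deg the source sits anterior to the
  isocenter (on +y); the angle increases toward the patient's left, so the
  source position is ``iso + sad * (sin g, cos g, 0)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .errors import (
    CongruenceError,
    GeometryError,
    OutOfBoundsError,
)

__all__ = [
    "DoseGrid",
    "PlanarDose",
    "BeamGeometry",
    "StructureMask",
    "BeamSet",
    "PlanBundle",
    "trilinear_sample",
    "rasterize_structure",
    "points_in_polygon",
]


def _as_f64(x, n: int, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).reshape(-1)
    if arr.size != n:
        raise ValueError(f"{name} must have {n} components, got {arr.size}")
    return arr


@dataclass
class DoseGrid:
    """Regular 3D dose field in patient coordinates.

    Parameters
    ----------
    origin : (3,) array-like
        Position of voxel (0, 0, 0) **center** in mm.
    spacing : (3,) array-like
        Per-axis voxel step in mm, strictly positive.
    values : (nx, ny, nz) ndarray
        Dose in Gy; finite and non-negative.
    frame_id : str
        Opaque frame-of-reference token; grids that are combined voxelwise
        must share it.
    """

    origin: np.ndarray
    spacing: np.ndarray
    values: np.ndarray
    frame_id: str = "frame-0"

    def __post_init__(self) -> None:
        self.origin = _as_f64(self.origin, 3, "origin")
        self.spacing = _as_f64(self.spacing, 3, "spacing")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be strictly positive on all axes")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("doses must be finite")
        if np.any(self.values < 0):
            raise ValueError("doses must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def axis_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-center coordinates along each axis (mm)."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
            for a in range(3)
        )  # type: ignore[return-value]

    def voxel_centers(self) -> np.ndarray:
        """All voxel-center positions, shape ``(nx, ny, nz, 3)``."""
        cx, cy, cz = self.axis_coords()
        out = np.empty(self.shape + (3,), dtype=float)
        out[..., 0] = cx[:, None, None]
        out[..., 1] = cy[None, :, None]
        out[..., 2] = cz[None, None, :]
        return out

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Half-open bounding box ``(lo, hi)`` of the voxel-center lattice."""
        lo = self.origin.copy()
        hi = self.origin + (np.array(self.shape) - 1) * self.spacing
        return lo, hi

    def congruent_with(self, other: "DoseGrid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.origin, other.origin)
            and np.allclose(self.spacing, other.spacing)
            and self.frame_id == other.frame_id
        )

    def require_congruent(self, other: "DoseGrid") -> None:
        if not self.congruent_with(other):
            raise CongruenceError(
                "dose grids are not congruent "
                f"(shape {self.shape} vs {other.shape}, "
                f"origin {self.origin} vs {other.origin})"
            )

    def like(self, values: np.ndarray) -> "DoseGrid":
        """New grid with the same geometry and different values."""
        return DoseGrid(self.origin.copy(), self.spacing.copy(), values,
                        frame_id=self.frame_id)


@dataclass
class PlanarDose:
    """2D dose sample lattice on a plane perpendicular to the beam axis.

    The lattice lives in the beam's in-plane (u, v) frame: ``values[i, j]``
    sits at in-plane coordinates ``origin_uv + (i, j) * spacing`` mm relative
    to the central-axis (CAX) piercing point.  ``axis_u``/``axis_v`` give the
    3D directions of the in-plane axes (orthonormal); ``source_distance`` is
    the distance from the source to the plane along the beam axis in mm.
    """

    values: np.ndarray
    spacing: np.ndarray
    source_distance: float
    origin_uv: np.ndarray = field(default_factory=lambda: np.zeros(2))
    axis_u: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    axis_v: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    plane_origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2D array")
        self.spacing = _as_f64(self.spacing, 2, "spacing")
        self.origin_uv = _as_f64(self.origin_uv, 2, "origin_uv")
        self.axis_u = _as_f64(self.axis_u, 3, "axis_u")
        self.axis_v = _as_f64(self.axis_v, 3, "axis_v")
        self.plane_origin = _as_f64(self.plane_origin, 3, "plane_origin")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be strictly positive")
        if self.source_distance <= 0:
            raise ValueError("source_distance must be positive")
        for name, ax in (("axis_u", self.axis_u), ("axis_v", self.axis_v)):
            if not np.isclose(np.linalg.norm(ax), 1.0, atol=1e-9):
                raise GeometryError(f"{name} must be a unit vector")
        if not np.isclose(self.axis_u @ self.axis_v, 0.0, atol=1e-9):
            raise GeometryError("in-plane axes must be orthogonal")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("doses must be finite and non-negative")

    @property
    def u_coords(self) -> np.ndarray:
        return self.origin_uv[0] + self.spacing[0] * np.arange(self.values.shape[0])

    @property
    def v_coords(self) -> np.ndarray:
        return self.origin_uv[1] + self.spacing[1] * np.arange(self.values.shape[1])


@dataclass
class BeamGeometry:
    """Fixed-gantry beam geometry (IEC 61217 gantry convention).

    ``source_position`` is derived: it lies at distance ``sad`` from the
    isocenter along the gantry direction, in the axial plane of the isocenter.
    ``collimator_angle`` rotates the in-plane (u, v) axes about the beam axis.
    """

    gantry_angle: float
    collimator_angle: float = 0.0
    isocenter: np.ndarray = field(default_factory=lambda: np.zeros(3))
    sad: float = 1000.0

    def __post_init__(self) -> None:
        self.isocenter = _as_f64(self.isocenter, 3, "isocenter")
        if self.sad <= 0:
            raise ValueError("sad must be positive")

    @property
    def source_direction(self) -> np.ndarray:
        """Unit vector from isocenter toward the source."""
        g = np.deg2rad(self.gantry_angle)
        return np.array([np.sin(g), np.cos(g), 0.0])

    @property
    def beam_direction(self) -> np.ndarray:
        """Unit vector from the source toward the isocenter."""
        return -self.source_direction

    @property
    def source_position(self) -> np.ndarray:
        return self.isocenter + self.sad * self.source_direction

    def inplane_axes(self) -> tuple[np.ndarray, np.ndarray]:
        """Orthonormal (u, v) axes of the isocenter plane.

        Before collimator rotation, u is the cross-plane axis in the axial
        plane and v points superior; the collimator angle rotates both about
        the beam axis.
        """
        g = np.deg2rad(self.gantry_angle)
        u0 = np.array([np.cos(g), -np.sin(g), 0.0])
        v0 = np.array([0.0, 0.0, 1.0])
        c = np.deg2rad(self.collimator_angle)
        u = np.cos(c) * u0 + np.sin(c) * v0
        v = -np.sin(c) * u0 + np.cos(c) * v0
        return u, v


@dataclass
class StructureMask:
    """Boolean per-voxel structure mask congruent with a DoseGrid."""

    name: str
    mask: np.ndarray
    frame_id: str = "frame-0"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be a 3D boolean array")
        if not self.mask.any():
            raise ValueError(f"structure '{self.name}' has no voxels")

    def require_congruent(self, grid: DoseGrid) -> None:
        if self.mask.shape != grid.shape or self.frame_id != grid.frame_id:
            raise CongruenceError(
                f"mask '{self.name}' (shape {self.mask.shape}, frame "
                f"{self.frame_id}) does not match grid (shape {grid.shape}, "
                f"frame {grid.frame_id})"
            )

    @property
    def volume_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class BeamSet:
    """One treatment beam: geometry, planned 3D dose, planar planned/measured."""

    geometry: BeamGeometry
    planned_dose: DoseGrid
    planned_planar: PlanarDose
    measured_planar: PlanarDose
    name: str = "beam"


@dataclass
class PlanBundle:
    """A complete plan for the QA chain: beams, total dose, structures."""

    beams: list[BeamSet]
    total_planned: DoseGrid
    structures: list[StructureMask]
    prescription_dose: float

    def __post_init__(self) -> None:
        if len(self.beams) < 1:
            raise ValueError("a plan needs at least one beam")
        if self.prescription_dose <= 0:
            raise ValueError("prescription_dose must be positive")
        for b in self.beams:
            self.total_planned.require_congruent(b.planned_dose)
        for s in self.structures:
            s.require_congruent(self.total_planned)

    def structure(self, name: str) -> StructureMask:
        for s in self.structures:
            if s.name == name:
                return s
        raise KeyError(f"no structure named '{name}'")


# ---------------------------------------------------------------------------
# Sampling and rasterization
# ---------------------------------------------------------------------------

def trilinear_sample(grid: DoseGrid, point) -> float | np.ndarray:
    """Trilinear interpolation of the dose at one or many points (mm).

    Points must lie inside the voxel-center bounding box; outside points
    raise :class:`OutOfBoundsError` so the caller decides the fallback.
    Scalar in, scalar out; (N, 3) in, (N,) out.
    """
    pts = np.atleast_2d(np.asarray(point, dtype=float))
    lo, hi = grid.bounds()
    if np.any(pts < lo - 1e-9) or np.any(pts > hi + 1e-9):
        raise OutOfBoundsError(
            f"sample point outside grid voxel-center box [{lo}, {hi}]"
        )
    interp = RegularGridInterpolator(
        grid.axis_coords(), grid.values, method="linear",
        bounds_error=False, fill_value=None,
    )
    out = interp(np.clip(pts, lo, hi))
    if np.asarray(point).ndim == 1:
        return float(out[0])
    return out


def points_in_polygon(points: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Even–odd (crossing-number) point-in-polygon test, vectorized.

    ``points`` is (N, 2); ``vertices`` is (M, 2) describing a closed polygon
    (last edge joins vertex M-1 back to vertex 0).  A point on an edge may be
    classified either way; rasterization places voxel centers, which
    generically avoid edges.
    """
    points = np.asarray(points, dtype=float)
    vertices = np.asarray(vertices, dtype=float)
    if vertices.ndim != 2 or vertices.shape[0] < 3 or vertices.shape[1] != 2:
        raise GeometryError("polygon needs at least 3 (x, y) vertices")
    x, y = points[:, 0], points[:, 1]
    inside = np.zeros(len(points), dtype=bool)
    v1 = vertices
    v2 = np.roll(vertices, -1, axis=0)
    for (x1, y1), (x2, y2) in zip(v1, v2):
        # edge crosses the horizontal ray from (x, y) to +infinity
        cond = (y1 > y) != (y2 > y)
        with np.errstate(divide="ignore", invalid="ignore"):
            x_cross = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
        inside ^= cond & (x < x_cross)
    return inside


def rasterize_structure(
    contours: Sequence[tuple[float, np.ndarray]],
    grid: DoseGrid,
    name: str = "structure",
    allow_empty: bool = False,
) -> StructureMask:
    """Rasterize closed planar polygons into a voxel mask on ``grid``.

    Parameters
    ----------
    contours
        Sequence of ``(z_mm, vertices)`` pairs; each polygon lies on a plane
        parallel to the grid's axial (z) slices and ``vertices`` is an
        (M, 2) array of (x, y) mm.  A voxel is inside iff its **center** is
        inside the polygon of its slice (even–odd rule); several polygons on
        one slice are unioned.
    allow_empty
        If False (default) a mask with no voxels raises
        :class:`GeometryError`; if True the empty mask is returned as a
        plain boolean array wrapped in a mask-less sentinel ``None``.
    """
    mask = np.zeros(grid.shape, dtype=bool)
    cx, cy, cz = grid.axis_coords()
    xx, yy = np.meshgrid(cx, cy, indexing="ij")
    slice_pts = np.column_stack([xx.ravel(), yy.ravel()])
    for z_mm, vertices in contours:
        vertices = np.asarray(vertices, dtype=float)
        if vertices.shape[0] < 3:
            raise GeometryError("polygon needs at least 3 vertices")
        k = int(np.round((z_mm - grid.origin[2]) / grid.spacing[2]))
        if k < 0 or k >= grid.shape[2]:
            continue  # polygon off-grid contributes nothing
        if abs(grid.origin[2] + k * grid.spacing[2] - z_mm) > grid.spacing[2] / 2 + 1e-9:
            continue
        inside = points_in_polygon(slice_pts, vertices).reshape(len(cx), len(cy))
        mask[:, :, k] |= inside
    if not mask.any():
        if allow_empty:
            return None  # type: ignore[return-value]
        raise GeometryError(
            f"structure '{name}': no voxel center falls inside any polygon"
        )
    return StructureMask(name=name, mask=mask, frame_id=grid.frame_id)
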