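"""Measurement-guided dose reconstruction (MGDR).

The four-step chain that turns per-beam planar measurements into a predicted
3D patient dose:

1. Build a per-beam planar **relative error map** (measured / planned dose
   ratio on the detector lattice, 5 mm nodes), geometrically rescaled to the
   isocenter plane by the source-divergence factor ``sad / source_distance``.
2. For every voxel of the per-beam planned 3D dose, trace the ray from the
   source through the voxel center and intersect it with the isocenter plane.
3. Fetch the local error at the intersection by bilinear interpolation and
   multiply the planned voxel dose by it.  Rays that miss the map extent, and
   nodes invalidated by the low-dose cutoff, contribute a neutral ratio of
   1.0 — measurement error is never extrapolated beyond detector coverage.
4. Sum the per-beam predicted grids into the predicted total dose.

The error is applied multiplicatively (a ratio): identical measured and
planned planar doses reproduce the planned 3D dose exactly, and scaling all
measurements by k scales every covered predicted voxel by exactly k.  An
additive-difference mode is available for sensitivity studies.  Ratios are
clamped (default [0.5, 2.0]) so detector noise at near-zero planned dose
cannot explode the prediction; clamp and out-of-map events are counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .errors import DegenerateInputError, GeometryError
from .grids import BeamGeometry, DoseGrid, PlanarDose

__all__ = [
    "RelativeErrorMap", "ReconstructionInfo",
    "compute_error_map", "local_error_at", "reconstruct_beam", "predict_total",
]

log = logging.getLogger(__name__)


@dataclass
class RelativeErrorMap:
    """Per-beam 2D field of measured/planned dose ratios on the isocenter
    plane, in the beam's (u, v) frame.

    ``u``/``v`` are node coordinates in mm (already divergence-rescaled to
    the isocenter plane); ``ratio`` the dimensionless measured/planned ratio;
    ``valid`` marks nodes whose planned dose was at or above the low-dose
    cutoff.  ``mode`` records whether the map is applied as a ratio
    (multiplicative) or an additive dose difference.
    """

    u: np.ndarray
    v: np.ndarray
    ratio: np.ndarray
    valid: np.ndarray
    mode: str = "multiplicative"

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.ratio = np.asarray(self.ratio, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.ratio.shape != (self.u.size, self.v.size):
            raise ValueError("ratio shape must be (len(u), len(v))")
        if self.valid.shape != self.ratio.shape:
            raise ValueError("valid mask shape must match ratio")
        if np.any(np.diff(self.u) <= 0) or np.any(np.diff(self.v) <= 0):
            raise ValueError("node coordinates must be strictly increasing")
        r = self.ratio[self.valid]
        if r.size and (not np.all(np.isfinite(r)) or np.any(r <= 0)):
            if self.mode == "multiplicative":
                raise ValueError("valid ratios must be finite and positive")

    @property
    def spacing(self) -> np.ndarray:
        return np.array([
            float(np.mean(np.diff(self.u))) if self.u.size > 1 else 0.0,
            float(np.mean(np.diff(self.v))) if self.v.size > 1 else 0.0,
        ])


@dataclass
class ReconstructionInfo:
    """Diagnostics from one beam reconstruction."""

    covered: np.ndarray = None          # voxels whose ray hit a fully valid cell
    ratio: np.ndarray = None            # applied per-voxel ratio
    n_out_of_map: int = 0
    n_clamped: int = 0


def _resample_planar(planar: PlanarDose, u: np.ndarray,
                     v: np.ndarray) -> np.ndarray:
    """Bilinearly resample a planar dose onto target in-plane coordinates."""
    interp = RegularGridInterpolator(
        (planar.u_coords, planar.v_coords), planar.values,
        method="linear", bounds_error=False, fill_value=np.nan,
    )
    uu, vv = np.meshgrid(u, v, indexing="ij")
    return interp(np.column_stack([uu.ravel(), vv.ravel()])).reshape(uu.shape)


def compute_error_map(
    planned: PlanarDose,
    measured: PlanarDose,
    min_dose_fraction: float = 0.05,
    sad: float = 1000.0,
    mode: str = "multiplicative",
) -> RelativeErrorMap:
    """Per-beam relative dose error map from a planned/measured planar pair.

    The measured lattice defines the map nodes; the planned plane is
    resampled onto it if the lattices differ.  A node is valid where the
    planned dose is at least ``min_dose_fraction`` of the planned maximum.
    Node coordinates are rescaled from the measurement plane to the
    isocenter plane by ``sad / source_distance``.
    """
    if planned.source_distance != measured.source_distance:
        raise GeometryError(
            "planned and measured planes are at different source distances "
            f"({planned.source_distance} vs {measured.source_distance} mm)"
        )
    same_lattice = (
        planned.values.shape == measured.values.shape
        and np.allclose(planned.u_coords, measured.u_coords)
        and np.allclose(planned.v_coords, measured.v_coords)
    )
    if same_lattice:
        planned_vals = planned.values
    else:
        planned_vals = _resample_planar(planned, measured.u_coords,
                                        measured.v_coords)
        if np.all(np.isnan(planned_vals)):
            raise GeometryError("planned and measured lattices do not overlap")
    measured_vals = measured.values

    p_max = np.nanmax(planned_vals)
    if not np.isfinite(p_max) or p_max <= 0:
        raise DegenerateInputError("planned planar dose is identically zero")
    valid = np.isfinite(planned_vals) & (
        planned_vals >= min_dose_fraction * p_max
    )
    if not valid.any():
        raise DegenerateInputError(
            "all error-map nodes fall below the low-dose cutoff"
        )
    if mode == "multiplicative":
        ratio = np.ones_like(planned_vals)
        np.divide(measured_vals, planned_vals, out=ratio, where=valid)
    elif mode == "additive":
        ratio = np.zeros_like(planned_vals)
        np.subtract(measured_vals, planned_vals, out=ratio, where=valid)
    else:
        raise ValueError(f"unknown error mode '{mode}'")

    scale = sad / measured.source_distance  # divergence to isocenter plane
    return RelativeErrorMap(
        u=measured.u_coords * scale,
        v=measured.v_coords * scale,
        ratio=ratio,
        valid=valid,
        mode=mode,
    )


def _neutral(mode: str) -> float:
    return 1.0 if mode == "multiplicative" else 0.0


def local_error_at(emap: RelativeErrorMap, uv) -> float | np.ndarray:
    """Local error at in-plane position(s) by bilinear interpolation.

    Invalid nodes contribute the neutral error (ratio 1, or difference 0 in
    additive mode); positions outside the map extent return the neutral
    error as well.  Scalar (u, v) in, scalar out; (N, 2) in, (N,) out.
    """
    vals, _, _ = _interp_map(emap, np.atleast_2d(np.asarray(uv, dtype=float)))
    if np.asarray(uv).ndim == 1:
        return float(vals[0])
    return vals


def _interp_map(emap: RelativeErrorMap, pts: np.ndarray):
    """Bilinear map interpolation with neutral fill.

    Returns (values, out_of_map mask, fully_valid mask); ``fully_valid``
    marks points whose 4 surrounding nodes are all valid (their value is a
    pure measurement-derived interpolant).
    """
    neutral = _neutral(emap.mode)
    filled = np.where(emap.valid, emap.ratio, neutral)
    # interpolate the deviation from neutral so that a neutral (or uniform)
    # map reproduces its value exactly, not to within rounding of the
    # bilinear weights -- this keeps the identity property bitwise exact
    interp = RegularGridInterpolator(
        (emap.u, emap.v), filled - neutral, method="linear",
        bounds_error=False, fill_value=np.nan,
    )
    vals = interp(pts)
    out = ~np.isfinite(vals)
    vals = neutral + np.where(out, 0.0, vals)

    vinterp = RegularGridInterpolator(
        (emap.u, emap.v), emap.valid.astype(float), method="linear",
        bounds_error=False, fill_value=0.0,
    )
    fully_valid = vinterp(pts) >= 1.0 - 1e-9
    return vals, out, fully_valid & ~out


def reconstruct_beam(
    planned_beam: DoseGrid,
    emap: RelativeErrorMap,
    geom: BeamGeometry,
    clamp: tuple[float, float] = (0.5, 2.0),
    return_info: bool = False,
):
    """Per-beam tentative predicted 3D dose via ray-traced local error.

    For each voxel, the ray from the source through the voxel center is
    intersected with the isocenter plane; the local error at the hit is
    applied to the planned voxel dose.  Rays missing the map keep the
    planned dose.  Raises :class:`GeometryError` if any voxel lies on the
    source side of (or in) the source plane, where the ray cannot reach the
    isocenter plane going forward.
    """
    src = geom.source_position
    n = geom.beam_direction
    u_ax, v_ax = geom.inplane_axes()
    iso = geom.isocenter

    centers = planned_beam.voxel_centers().reshape(-1, 3)
    rel = centers - src
    denom = rel @ n
    bad = denom <= 1e-6
    if np.any(bad):
        i = int(np.argmax(bad))
        raise GeometryError(
            f"ray through voxel {np.unravel_index(i, planned_beam.shape)} is "
            "parallel to or behind the isocenter plane"
        )
    t = geom.sad / denom
    hits = src + t[:, None] * rel
    d = hits - iso
    uv = np.column_stack([d @ u_ax, d @ v_ax])

    ratio, out_of_map, fully_valid = _interp_map(emap, uv)

    lo, hi = clamp
    if emap.mode == "multiplicative":
        clamped = (ratio < lo) | (ratio > hi)
        ratio = np.clip(ratio, lo, hi)
        predicted = planned_beam.values.reshape(-1) * ratio
    else:
        clamped = np.zeros_like(ratio, dtype=bool)
        predicted = np.maximum(planned_beam.values.reshape(-1) + ratio, 0.0)

    n_out = int(out_of_map.sum())
    n_clamped = int(clamped.sum())
    if n_out:
        log.info("reconstruct_beam: %d / %d rays outside the error map "
                 "(neutral ratio applied)", n_out, len(ratio))
    if n_clamped:
        log.info("reconstruct_beam: %d ratios clamped to [%g, %g]",
                 n_clamped, lo, hi)

    grid = planned_beam.like(predicted.reshape(planned_beam.shape))
    if not return_info:
        return grid
    info = ReconstructionInfo(
        covered=fully_valid.reshape(planned_beam.shape),
        ratio=ratio.reshape(planned_beam.shape),
        n_out_of_map=n_out,
        n_clamped=n_clamped,
    )
    return grid, info


def predict_total(beams: list[DoseGrid]) -> DoseGrid:
    """Voxelwise sum of per-beam reconstructed grids (all congruent)."""
    if len(beams) < 1:
        raise DegenerateInputError("need at least one reconstructed beam")
    first = beams[0]
    total = np.zeros_like(first.values)
    for b in beams:
        first.require_congruent(b)
        total = total + b.values
    return first.like(total)
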