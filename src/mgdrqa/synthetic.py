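"""Synthetic tangential-breast phantom, analytic beam doses, and planar
"measurements" with injected delivery errors.

The generator emulates the study conditions of two tangentially opposed
6-MV beams (gantry 50 and 230 deg) on a phantom holding a PTV at the
isocenter, a large ipsilateral lung that mostly sits in the out-of-field
low-dose region but grazes the posterior field edge (the reason lung V20Gy
constraints exist for tangential breast plans), and a small heart.
Prescription 50 Gy.

The beam model is analytic, not a transport calculation: exponential depth
attenuation (mu = 0.005/mm tissue, reduced in lung), a short buildup,
inverse-square divergence, a double-sigmoid lateral penumbra (nominal
80-20% width about 6 mm plus a broad low-amplitude shoulder) and a 2%
out-of-field tail.  Its job is to produce the right statistical structure
(gradients, penumbra, out-of-field plateau) for exercising the QA chain,
not dosimetric realism.

Everything is deterministic for a fixed spec; optional multiplicative
detector noise is the only random element and is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError
from .grids import BeamGeometry, BeamSet, DoseGrid, PlanBundle, PlanarDose, \
    StructureMask
from .mgdr import _resample_planar

__all__ = [
    "PhantomSpec", "ErrorSpec", "Phantom", "BeamModel",
    "make_phantom", "simulate_beam_dose", "simulate_planar_pair",
    "make_plan_bundle", "default_beam_models", "default_tangential_bundle",
    "lung_blob_errors",
]

LUNG_DENSITY = 0.25   # relative radiological density of lung tissue
MU_TISSUE = 0.005     # linear attenuation, 1/mm (6 MV, water-equivalent)
BUILDUP_MM = 10.0


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of the desk-scale phantom (all mm, patient coordinates).

    Ellipsoids are axis-aligned ``(center, semi_axes)``.  Structures are
    resolved with priority PTV > heart > lung (later ones exclude earlier
    voxels), all clipped to the body outline.
    """

    shape: tuple[int, int, int] = (64, 64, 48)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    body_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    body_semi: tuple[float, float, float] = (62.0, 62.0, 70.0)
    ptv_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    ptv_semi: tuple[float, float, float] = (16.0, 14.0, 20.0)
    lung_center: tuple[float, float, float] = (28.9, -34.5, 0.0)
    lung_semi: tuple[float, float, float] = (28.0, 26.0, 34.0)
    heart_center: tuple[float, float, float] = (30.0, -40.0, -22.0)
    heart_semi: tuple[float, float, float] = (11.0, 11.0, 11.0)


@dataclass(frozen=True)
class ErrorSpec:
    """Injected delivery error applied to a measured planar dose.

    kind:
      ``none``          measured == planned
      ``global_scale``  measured = magnitude * planned (magnitude is the factor)
      ``gaussian_blob`` multiplicative Gaussian ratio bump: peak 1 + magnitude
                        at ``location`` (u, v mm on the plane), sigma ``width``
      ``edge_shift``    lateral field-edge shift by ``magnitude`` mm along u
    """

    kind: str = "none"
    magnitude: float = 0.0
    location: tuple[float, float] = (0.0, 0.0)
    width: float = 15.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "global_scale", "gaussian_blob",
                             "edge_shift"):
            raise ValueError(f"unknown error kind '{self.kind}'")
        if not np.isfinite(self.magnitude):
            raise ValueError("magnitude must be finite")
        if self.kind == "gaussian_blob" and self.width <= 0:
            raise ValueError("blob width must be positive")


@dataclass
class Phantom:
    """Template grid, structure masks, and radiological density."""

    template: DoseGrid
    masks: dict[str, StructureMask]
    density: np.ndarray  # relative density per voxel (0 outside body)


def _ellipsoid_mask(grid: DoseGrid, center, semi) -> np.ndarray:
    cx, cy, cz = grid.axis_coords()
    x = (cx - center[0]) / semi[0]
    y = (cy - center[1]) / semi[1]
    z = (cz - center[2]) / semi[2]
    return (x[:, None, None] ** 2 + y[None, :, None] ** 2
            + z[None, None, :] ** 2) <= 1.0


def make_phantom(spec: PhantomSpec = PhantomSpec()) -> Phantom:
    """Build congruent PTV / ipsilateral_lung / heart masks and the density
    grid on the template dose grid (voxel-center ellipsoid inclusion)."""
    shape = np.asarray(spec.shape, dtype=int)
    spacing = np.asarray(spec.spacing, dtype=float)
    origin = -(shape - 1) / 2.0 * spacing
    template = DoseGrid(origin, spacing, np.zeros(tuple(shape)),
                        frame_id="synthetic-phantom")

    body = _ellipsoid_mask(template, spec.body_center, spec.body_semi)
    ptv = _ellipsoid_mask(template, spec.ptv_center, spec.ptv_semi) & body
    heart = _ellipsoid_mask(template, spec.heart_center, spec.heart_semi) \
        & body & ~ptv
    lung = _ellipsoid_mask(template, spec.lung_center, spec.lung_semi) \
        & body & ~ptv & ~heart
    for name, m in (("PTV", ptv), ("ipsilateral_lung", lung),
                    ("heart", heart), ("body", body)):
        if not m.any():
            raise GeometryError(f"phantom structure '{name}' is empty")

    density = np.where(body, 1.0, 0.0)
    density[lung] = LUNG_DENSITY

    masks = {
        "PTV": StructureMask("PTV", ptv, template.frame_id),
        "ipsilateral_lung": StructureMask("ipsilateral_lung", lung,
                                          template.frame_id),
        "heart": StructureMask("heart", heart, template.frame_id),
        "body": StructureMask("body", body, template.frame_id),
    }
    return Phantom(template=template, masks=masks, density=density)


@dataclass(frozen=True)
class BeamModel:
    """Analytic divergent-beam dose model.

    ``field`` holds the aperture half-widths (hu, hv) in mm at the isocenter
    plane; ``output`` the dose (Gy) delivered at the isocenter.  The lateral
    profile along each axis is a double sigmoid: a sharp penumbra component
    (80-20% width ~6 mm) plus a broad low-amplitude shoulder that feeds the
    near-field low-dose region, on top of a flat out-of-field tail.
    """

    geometry: BeamGeometry
    field_halfwidths: tuple[float, float] = (32.0, 45.0)
    output: float = 25.0
    penumbra_w: float = 2.17        # sharp sigmoid scale, mm (80-20 ~ 6 mm)
    shoulder_w: float = 12.0        # broad shoulder sigmoid scale, mm
    shoulder_frac: float = 0.08     # amplitude of the broad component
    tail: float = 0.02              # out-of-field plateau, fraction of CAX

    def _edge(self, x: np.ndarray, half: float, w: float) -> np.ndarray:
        # product of two logistic field edges
        return 1.0 / (1.0 + np.exp(-(half - x) / w)) \
            / (1.0 + np.exp(-(half + x) / w))

    def lateral_factor(self, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        """Off-axis profile at isocenter-plane coordinates (u, v) mm."""
        hu, hv = self.field_halfwidths
        gu = (1 - self.shoulder_frac) * self._edge(u, hu, self.penumbra_w) \
            + self.shoulder_frac * self._edge(u, hu, self.shoulder_w)
        gv = (1 - self.shoulder_frac) * self._edge(v, hv, self.penumbra_w) \
            + self.shoulder_frac * self._edge(v, hv, self.shoulder_w)
        return self.tail + (1 - self.tail) * gu * gv

    def depth_factor(self, depth_mm: np.ndarray) -> np.ndarray:
        """Exponential attenuation with a short buildup region."""
        d = np.maximum(depth_mm, 0.0)
        return np.exp(-MU_TISSUE * d) * (-np.expm1(-(d + 0.5) / BUILDUP_MM))


def _radiological_depth(points: np.ndarray, source: np.ndarray,
                        phantom: Phantom, step: float = 3.0,
                        march: float = 216.0) -> np.ndarray:
    """Water-equivalent depth of each point along its ray from the source.

    Marches back from each point toward the source in ``step``-mm samples
    over the last ``march`` mm (the phantom diagonal is shorter), summing
    the density; outside-phantom samples contribute zero.
    """
    rel = points - source
    dist = np.linalg.norm(rel, axis=1, keepdims=True)
    unit = rel / dist
    n_steps = int(np.ceil(march / step))
    grid = phantom.template
    depth = np.zeros(len(points))
    for k in range(n_steps):
        s = (k + 0.5) * step
        q = points - unit * s
        idx = np.round((q - grid.origin) / grid.spacing).astype(int)
        ok = np.all((idx >= 0) & (idx < np.array(grid.shape)), axis=1)
        dens = np.zeros(len(points))
        sel = idx[ok]
        dens[ok] = phantom.density[sel[:, 0], sel[:, 1], sel[:, 2]]
        depth += dens * step
    return depth


def _beam_dose_at(points: np.ndarray, model: BeamModel,
                  phantom: Phantom | None) -> np.ndarray:
    """Unnormalized analytic dose at arbitrary points (phantom=None: water)."""
    geom = model.geometry
    src = geom.source_position
    n = geom.beam_direction
    u_ax, v_ax = geom.inplane_axes()
    rel = points - src
    w = rel @ n                       # distance from source along the axis
    if np.any(w <= 1e-6):
        raise GeometryError("point at or behind the source plane")
    scale = geom.sad / w              # divergence scaling to isocenter plane
    u = (rel @ u_ax) * scale
    v = (rel @ v_ax) * scale
    lat = model.lateral_factor(u, v)
    if phantom is None:
        depth = np.full(len(points), 50.0)
    else:
        depth = _radiological_depth(points, src, phantom)
    return lat * model.depth_factor(depth) * (geom.sad / w) ** 2


def simulate_beam_dose(phantom: Phantom, model: BeamModel) -> DoseGrid:
    """Per-beam 3D dose on the phantom grid, normalized so the dose at the
    isocenter equals ``model.output`` Gy."""
    grid = phantom.template
    src = model.geometry.source_position
    idx = np.round((src - grid.origin) / grid.spacing).astype(int)
    if np.all((idx >= 0) & (idx < np.array(grid.shape))) \
            and phantom.density[idx[0], idx[1], idx[2]] > 0:
        raise GeometryError("beam source lies inside the phantom")
    pts = grid.voxel_centers().reshape(-1, 3)
    raw = _beam_dose_at(pts, model, phantom)
    dose = grid.like(raw.reshape(grid.shape))
    # normalize on the voxelized dose (trilinear at the isocenter) so the
    # delivered output is exact on the grid the QA chain actually sees
    from .grids import trilinear_sample
    iso_raw = trilinear_sample(dose, model.geometry.isocenter)
    if iso_raw <= 0:
        raise GeometryError("isocenter receives no dose from this beam")
    return grid.like((model.output / iso_raw) * dose.values)


def _detector_lattice(extent: float = 80.0, spacing: float = 5.0):
    n = int(np.floor(extent / spacing))
    coords = spacing * np.arange(-n, n + 1)
    return coords


def simulate_planar_pair(
    model: BeamModel,
    error: ErrorSpec = ErrorSpec(),
    depth_mm: float = 50.0,
    source_distance: float = 1000.0,
    detector_extent: float = 80.0,
    detector_spacing: float = 5.0,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[PlanarDose, PlanarDose]:
    """Planned and measured planar doses on the detector lattice.

    The planned planar dose is the analytic beam model in a water slab at
    ``depth_mm`` (default 5 cm, detector plane at the isocenter distance);
    the measured one is the planned transformed by the error spec, plus
    optional multiplicative Gaussian noise.
    """
    coords = _detector_lattice(detector_extent, detector_spacing)
    uu, vv = np.meshgrid(coords, coords, indexing="ij")
    geom = model.geometry
    # lateral coordinates at the plane, divergence-referred to the isocenter
    scale = geom.sad / source_distance
    lat = model.lateral_factor(uu.ravel() * scale, vv.ravel() * scale)
    planned_vals = (
        model.output * lat * model.depth_factor(np.full(uu.size, depth_mm))
        * (geom.sad / source_distance) ** 2
    ).reshape(uu.shape)
    # normalize like the 3D beam: CAX value plays no role in the QA chain's
    # ratios, so keep the analytic value as-is.
    u_ax, v_ax = geom.inplane_axes()
    plane_origin = geom.source_position \
        + source_distance * geom.beam_direction
    common = dict(
        spacing=(detector_spacing, detector_spacing),
        source_distance=source_distance,
        origin_uv=(coords[0], coords[0]),
        axis_u=u_ax, axis_v=v_ax, plane_origin=plane_origin,
    )
    planned = PlanarDose(values=planned_vals, **common)

    measured_vals = _apply_error(planned, error)
    if noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        measured_vals = measured_vals * (
            1.0 + noise_sigma * rng.standard_normal(measured_vals.shape)
        )
        measured_vals = np.maximum(measured_vals, 0.0)
    measured = PlanarDose(values=measured_vals, **common)
    return planned, measured


def _apply_error(planned: PlanarDose, error: ErrorSpec) -> np.ndarray:
    vals = planned.values
    if error.kind == "none":
        return vals.copy()
    if error.kind == "global_scale":
        return vals * error.magnitude
    if error.kind == "gaussian_blob":
        u0, v0 = error.location
        uu, vv = np.meshgrid(planned.u_coords, planned.v_coords, indexing="ij")
        if not (planned.u_coords[0] <= u0 <= planned.u_coords[-1]
                and planned.v_coords[0] <= v0 <= planned.v_coords[-1]):
            import warnings
            warnings.warn("gaussian blob center lies outside the detector "
                          "extent", stacklevel=3)
        bump = 1.0 + error.magnitude * np.exp(
            -((uu - u0) ** 2 + (vv - v0) ** 2) / (2.0 * error.width ** 2)
        )
        return vals * bump
    if error.kind == "edge_shift":
        shifted = PlanarDose(
            values=vals, spacing=planned.spacing,
            source_distance=planned.source_distance,
            origin_uv=planned.origin_uv + np.array([error.magnitude, 0.0]),
            axis_u=planned.axis_u, axis_v=planned.axis_v,
            plane_origin=planned.plane_origin,
        )
        out = _resample_planar(shifted, planned.u_coords, planned.v_coords)
        # beyond the shifted lattice, extend the edge value
        return np.where(np.isfinite(out), out,
                        np.where(np.tile(planned.u_coords[:, None],
                                         (1, len(planned.v_coords)))
                                 < planned.u_coords[0] + error.magnitude,
                                 vals[0:1, :], vals[-1:, :]))
    raise ValueError(f"unknown error kind '{error.kind}'")


def default_beam_models(
    phantom_spec: PhantomSpec = PhantomSpec(),
    prescription: float = 50.0,
) -> list[BeamModel]:
    """The two tangentially opposed beams of the default study conditions."""
    iso = np.zeros(3)
    return [
        BeamModel(geometry=BeamGeometry(gantry_angle=50.0, isocenter=iso),
                  output=prescription / 2.0),
        BeamModel(geometry=BeamGeometry(gantry_angle=230.0, isocenter=iso),
                  output=prescription / 2.0),
    ]


def lung_blob_errors(magnitude: float = 0.2, width: float = 12.0,
                     center_u: float = 40.0) -> list[ErrorSpec]:
    """Per-beam Gaussian-blob errors aimed at the lung-traversing rays.

    The blob sits just outside the posterior field edge (in each beam's own
    (u, v) frame; the beams are opposed, so the u signs mirror), in the
    region near or below typical 2D lower thresholds, while its tail reaches
    the in-field lung sliver.
    """
    return [
        ErrorSpec(kind="gaussian_blob", magnitude=magnitude,
                  location=(center_u, 0.0), width=width),
        ErrorSpec(kind="gaussian_blob", magnitude=magnitude,
                  location=(-center_u, 0.0), width=width),
    ]


def make_plan_bundle(
    phantom: Phantom,
    models: list[BeamModel],
    errors: list[ErrorSpec] | None = None,
    prescription: float = 50.0,
    noise_sigma: float = 0.0,
    seed: int | None = None,
) -> PlanBundle:
    """Assemble a self-consistent plan bundle: per-beam 3D doses (total =
    their sum), planar planned/measured pairs with the injected errors, and
    the phantom structures."""
    if errors is None:
        errors = [ErrorSpec()] * len(models)
    if len(errors) != len(models):
        raise ValueError("need one error spec per beam")
    rng = np.random.default_rng(seed) if seed is not None else None
    beams = []
    total = np.zeros(phantom.template.shape)
    for i, (model, err) in enumerate(zip(models, errors)):
        dose3d = simulate_beam_dose(phantom, model)
        planned, measured = simulate_planar_pair(
            model, error=err, noise_sigma=noise_sigma, rng=rng,
        )
        beams.append(BeamSet(
            geometry=model.geometry, planned_dose=dose3d,
            planned_planar=planned, measured_planar=measured,
            name=f"beam{i + 1}",
        ))
        total = total + dose3d.values
    structures = [phantom.masks[k] for k in ("PTV", "ipsilateral_lung",
                                             "heart")]
    return PlanBundle(
        beams=beams,
        total_planned=phantom.template.like(total),
        structures=structures,
        prescription_dose=prescription,
    )


def default_tangential_bundle(
    errors: list[ErrorSpec] | None = None,
    prescription: float = 50.0,
    noise_sigma: float = 0.0,
    seed: int | None = None,
) -> PlanBundle:
    """Default two-beam study bundle on the default phantom."""
    phantom = make_phantom()
    models = default_beam_models(prescription=prescription)
    return make_plan_bundle(phantom, models, errors=errors,
                            prescription=prescription,
                            noise_sigma=noise_sigma, seed=seed)
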