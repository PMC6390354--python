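"""Gamma-index analysis (dose difference + distance to agreement).

The gamma index at a reference point r is

    gamma(r) = min over evaluated positions r' of
               sqrt( |r - r'|^2 / dta^2  +  (D_eval(r') - D_ref(r))^2 / dd^2 )

with dd the dose tolerance as an absolute dose (percent of a single global
normalization dose) and dta the distance criterion in mm.  The evaluated
distribution is continuously interpolated on a fine offset lattice
(``interp_step_fraction * dta`` per axis) and searched out to
``search_radius_factor * dta``.

The search is exhaustive but terminates each point early once no remaining
offset radius can beat its current best (the spatial term alone already
exceeds it) — an exact optimization, so results are identical to a dense
brute-force search at the same interpolation step.

Passing rates count evaluated (above lower-threshold) reference points with
gamma <= 1; gamma exactly 1.0 passes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .errors import DegenerateInputError, UndefinedRateError
from .grids import DoseGrid, PlanarDose, StructureMask

__all__ = ["GammaCriteria", "GammaResult", "gamma_field", "passing_rate"]

_PASS_EPS = 1e-9  # "gamma <= 1" with float-safe boundary


@dataclass(frozen=True)
class GammaCriteria:
    """Gamma criteria: global dose tolerance (%), DTA (mm), thresholding.

    ``normalization`` selects the single global dose the percentage criteria
    refer to: the maximum of the reference distribution (default, the common
    array-QA convention) or a caller-supplied prescription dose
    (``norm_dose``).  ``lower_threshold`` (percent of the normalization dose)
    excludes low-dose reference points from evaluation.
    """

    dose_tolerance: float
    dta: float
    normalization: str = "global_max_reference"
    lower_threshold: float = 10.0
    norm_dose: float | None = None
    search_radius_factor: float = 3.0
    interp_step_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.dose_tolerance <= 0:
            raise ValueError("dose_tolerance must be positive")
        if self.dta <= 0:
            raise ValueError("dta must be positive")
        if not (0 <= self.lower_threshold < 100):
            raise ValueError("lower_threshold must be in [0, 100)")
        if self.normalization not in ("global_max_reference", "prescription"):
            raise ValueError(f"unknown normalization '{self.normalization}'")
        if self.normalization == "prescription" and not self.norm_dose:
            raise ValueError("prescription normalization needs norm_dose")


@dataclass
class GammaResult:
    """Per-point gamma field plus the evaluated-set passing rate."""

    gamma: np.ndarray          # gamma where evaluated, NaN where excluded
    evaluated: np.ndarray      # bool, reference points above threshold
    norm_dose: float
    criteria: GammaCriteria

    @property
    def evaluated_count(self) -> int:
        return int(self.evaluated.sum())

    @property
    def passing_rate(self) -> float:
        return passing_rate(self)


def _lattice(dist) -> tuple[list[np.ndarray], np.ndarray]:
    """Coordinate axes + values for a DoseGrid, PlanarDose or (axes, values)."""
    if isinstance(dist, DoseGrid):
        return list(dist.axis_coords()), dist.values
    if isinstance(dist, PlanarDose):
        return [dist.u_coords, dist.v_coords], dist.values
    axes, values = dist
    return [np.asarray(a, dtype=float) for a in axes], np.asarray(values, dtype=float)


def _offset_table(dta: float, step_fraction: float, radius_factor: float,
                  ndim: int) -> tuple[np.ndarray, np.ndarray]:
    """All search offsets within the radius, sorted by distance."""
    step = step_fraction * dta
    radius = radius_factor * dta
    k = int(np.floor(radius / step + 1e-9))
    axis = step * np.arange(-k, k + 1)
    offs = np.array(list(itertools.product(*([axis] * ndim))))
    r = np.linalg.norm(offs, axis=1)
    keep = r <= radius + 1e-9
    offs, r = offs[keep], r[keep]
    order = np.argsort(r, kind="stable")
    return offs[order], r[order]


def gamma_field(reference, evaluated, criteria: GammaCriteria) -> GammaResult:
    """Compute the gamma field of ``evaluated`` against ``reference``.

    Both arguments may be :class:`DoseGrid`, :class:`PlanarDose`, or a plain
    ``(axes, values)`` pair; they need not be congruent — the evaluated
    distribution is interpolated at reference positions plus search offsets.
    Reference points below the lower threshold are excluded (NaN gamma).
    """
    ref_axes, ref_vals = _lattice(reference)
    ev_axes, ev_vals = _lattice(evaluated)
    ndim = len(ref_axes)
    if ndim != len(ev_axes):
        raise ValueError("reference and evaluated dimensionality differ")

    if criteria.normalization == "prescription":
        norm = float(criteria.norm_dose)  # validated in __post_init__
    else:
        norm = float(ref_vals.max())
    if norm <= 0:
        raise DegenerateInputError("normalization dose is not positive")
    dd = criteria.dose_tolerance / 100.0 * norm
    threshold = criteria.lower_threshold / 100.0 * norm

    eval_mask = ref_vals >= threshold
    n_pts = int(eval_mask.sum())
    if n_pts == 0:
        raise DegenerateInputError(
            "no reference point is at or above the lower threshold"
        )

    mesh = np.meshgrid(*ref_axes, indexing="ij")
    pts = np.column_stack([m[eval_mask] for m in mesh])
    ref_dose = ref_vals[eval_mask]

    interp = RegularGridInterpolator(
        ev_axes, ev_vals, method="linear", bounds_error=False,
        fill_value=np.nan,
    )

    offs, radii = _offset_table(
        criteria.dta, criteria.interp_step_fraction,
        criteria.search_radius_factor, ndim,
    )
    dta = criteria.dta
    step = criteria.interp_step_fraction * dta

    best_sq = np.full(n_pts, np.inf)
    active = np.arange(n_pts)
    # band the sorted offsets into radius shells of one interpolation step
    band_edges = np.searchsorted(
        radii, np.arange(0.0, radii[-1] + step, step), side="left"
    )
    band_edges = np.unique(np.append(band_edges, len(radii)))
    max_chunk = 4_000_000  # cap points x offsets per interpolation call

    for b0, b1 in zip(band_edges[:-1], band_edges[1:]):
        if b0 == b1:
            continue
        r_min = radii[b0]
        # exact early exit: the spatial term alone rules out farther shells
        keep = best_sq[active] > (r_min / dta) ** 2
        active = active[keep]
        if active.size == 0:
            break
        band = offs[b0:b1]
        band_r = radii[b0:b1]
        n_off = max(1, min(len(band), max_chunk // max(1, active.size)))
        for c0 in range(0, len(band), n_off):
            o = band[c0:c0 + n_off]
            r = band_r[c0:c0 + n_off]
            cand = pts[active][:, None, :] + o[None, :, :]
            vals = interp(cand.reshape(-1, ndim)).reshape(active.size, len(o))
            with np.errstate(invalid="ignore"):
                g_sq = (r[None, :] / dta) ** 2 + \
                       ((vals - ref_dose[active][:, None]) / dd) ** 2
            g_min = np.nanmin(g_sq, axis=1, initial=np.inf)
            np.minimum.at(best_sq, active, g_min)

    gamma = np.full(ref_vals.shape, np.nan)
    gamma[eval_mask] = np.sqrt(best_sq)
    return GammaResult(gamma=gamma, evaluated=eval_mask, norm_dose=norm,
                       criteria=criteria)


def passing_rate(result: GammaResult,
                 mask: StructureMask | np.ndarray | None = None) -> float:
    """Percent of evaluated reference points with gamma <= 1, optionally
    restricted to a structure mask.

    Raises :class:`UndefinedRateError` when the mask contains no evaluated
    point — the rate is undefined there, neither 0 nor 100.
    """
    sel = result.evaluated
    if mask is not None:
        m = mask.mask if isinstance(mask, StructureMask) else np.asarray(mask, bool)
        if m.shape != result.gamma.shape:
            raise ValueError("mask shape does not match the gamma lattice")
        sel = sel & m
    n = int(sel.sum())
    if n == 0:
        raise UndefinedRateError(
            "no evaluated reference point in the requested region"
        )
    n_pass = int(np.sum(result.gamma[sel] <= 1.0 + _PASS_EPS))
    return 100.0 * n_pass / n
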