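"""Independent brute-force oracles used only by the tests.

These deliberately avoid the implementation's search strategy: they perform
plain, dense minimization / enumeration so that agreement is meaningful.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.interpolate import RegularGridInterpolator


def brute_force_gamma(ref_axes, ref_vals, ev_axes, ev_vals,
                      dose_tol_pct, dta, lower_threshold_pct=0.0,
                      norm=None, step_fraction=0.1, radius_factor=3.0):
    """Dense exhaustive gamma search (no early exit, no banding).

    Returns the gamma array (NaN below threshold).
    """
    ref_vals = np.asarray(ref_vals, float)
    ev_vals = np.asarray(ev_vals, float)
    ndim = ref_vals.ndim
    if norm is None:
        norm = ref_vals.max()
    dd = dose_tol_pct / 100.0 * norm
    thresh = lower_threshold_pct / 100.0 * norm

    step = step_fraction * dta
    radius = radius_factor * dta
    k = int(np.floor(radius / step + 1e-9))
    axis = step * np.arange(-k, k + 1)
    offs = np.array(list(itertools.product(*([axis] * ndim))))
    offs = offs[np.linalg.norm(offs, axis=1) <= radius + 1e-9]
    r_sq = np.sum(offs ** 2, axis=1)

    interp = RegularGridInterpolator(
        [np.asarray(a, float) for a in ev_axes], ev_vals,
        method="linear", bounds_error=False, fill_value=np.nan)

    mesh = np.meshgrid(*[np.asarray(a, float) for a in ref_axes],
                       indexing="ij")
    pts = np.column_stack([mm.ravel() for mm in mesh])
    doses = ref_vals.ravel()
    gamma = np.full(doses.shape, np.nan)
    for i in range(len(pts)):
        if doses[i] < thresh:
            continue
        vals = interp(pts[i][None, :] + offs)
        with np.errstate(invalid="ignore"):
            g_sq = r_sq / dta ** 2 + ((vals - doses[i]) / dd) ** 2
        gamma[i] = np.sqrt(np.nanmin(g_sq))
    return gamma.reshape(ref_vals.shape)


def brute_force_reconstruct(planned, emap, geom, clamp=(0.5, 2.0)):
    """Per-voxel scalar ray-plane-bilinear oracle for beam reconstruction."""
    src = geom.source_position
    n = geom.beam_direction
    u_ax, v_ax = geom.inplane_axes()
    out = np.empty(planned.shape)
    centers = planned.voxel_centers()
    for idx in np.ndindex(planned.shape):
        p = centers[idx]
        rel = p - src
        t = geom.sad / float(rel @ n)
        hit = src + t * rel - geom.isocenter
        u, v = float(hit @ u_ax), float(hit @ v_ax)
        ratio = _bilinear_or_neutral(emap, u, v)
        ratio = min(max(ratio, clamp[0]), clamp[1])
        out[idx] = planned.values[idx] * ratio
    return out


def _bilinear_or_neutral(emap, u, v):
    us, vs = emap.u, emap.v
    if not (us[0] <= u <= us[-1] and vs[0] <= v <= vs[-1]):
        return 1.0
    i = min(np.searchsorted(us, u, side="right") - 1, len(us) - 2)
    j = min(np.searchsorted(vs, v, side="right") - 1, len(vs) - 2)
    fu = (u - us[i]) / (us[i + 1] - us[i])
    fv = (v - vs[j]) / (vs[j + 1] - vs[j])
    total = 0.0
    for di, wu in ((0, 1 - fu), (1, fu)):
        for dj, wv in ((0, 1 - fv), (1, fv)):
            r = emap.ratio[i + di, j + dj] if emap.valid[i + di, j + dj] else 1.0
            total += wu * wv * (r - 1.0)
    return 1.0 + total


def points_in_polygon_shapely(points, vertices):
    """shapely's point-in-polygon test, as an external oracle (equivalent to
    even-odd for simple polygons)."""
    from shapely.geometry import Point, Polygon

    poly = Polygon(np.asarray(vertices, float))
    return np.array([poly.contains(Point(*p))
                     for p in np.asarray(points, float)])
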