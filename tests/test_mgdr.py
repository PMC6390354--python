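import numpy as np
import pytest

import mgdrqa as m
from mgdrqa.errors import DegenerateInputError, GeometryError
from mgdrqa.mgdr import (
    RelativeErrorMap, compute_error_map, local_error_at, predict_total,
    reconstruct_beam,
)

from conftest import small_grid
from oracles import brute_force_reconstruct


def make_planar(values, spacing=5.0, sd=1000.0, origin_uv=None):
    values = np.asarray(values, dtype=float)
    if origin_uv is None:
        origin_uv = -spacing * (np.array(values.shape) - 1) / 2
    return m.PlanarDose(values=values, spacing=(spacing, spacing),
                        source_distance=sd, origin_uv=origin_uv)


def uniform_map(ratio, n=9, spacing=5.0):
    c = spacing * (np.arange(n) - (n - 1) / 2)
    return RelativeErrorMap(u=c, v=c, ratio=np.full((n, n), float(ratio)),
                            valid=np.ones((n, n), bool))


class TestComputeErrorMap:
    def test_identity_ratio_one(self, rng):
        p = make_planar(rng.uniform(1, 2, (9, 9)))
        emap = compute_error_map(p, p)
        assert emap.valid.all()
        assert np.array_equal(emap.ratio, np.ones((9, 9)))

    def test_uniform_scale(self, rng):
        vals = rng.uniform(1, 2, (9, 9))
        emap = compute_error_map(make_planar(vals), make_planar(1.03 * vals))
        assert np.allclose(emap.ratio[emap.valid], 1.03)

    def test_low_dose_node_invalid(self):
        vals = np.full((5, 5), 10.0)
        vals[0, 0] = 0.1  # 1% of max
        emap = compute_error_map(make_planar(vals), make_planar(vals),
                                 min_dose_fraction=0.05)
        assert not emap.valid[0, 0]
        assert emap.valid[2, 2]

    def test_divergence_scaling_to_isocenter_plane(self, rng):
        # a plane at half the SAD has its lateral coordinates doubled
        p = make_planar(rng.uniform(1, 2, (5, 5)), spacing=5.0, sd=500.0)
        emap = compute_error_map(p, p, sad=1000.0)
        assert np.allclose(np.diff(emap.u), 10.0)

    def test_all_invalid_is_degenerate(self):
        p = make_planar(np.full((3, 3), 1.0))
        with pytest.raises(DegenerateInputError):
            compute_error_map(p, p, min_dose_fraction=2.0)

    def test_nonoverlapping_lattices(self, rng):
        a = make_planar(rng.uniform(1, 2, (5, 5)), origin_uv=(0, 0))
        b = make_planar(rng.uniform(1, 2, (5, 5)), origin_uv=(1000, 1000))
        with pytest.raises(GeometryError):
            compute_error_map(a, b)


class TestLocalErrorAt:
    def test_node_hit_returns_node_ratio(self):
        emap = uniform_map(1.0)
        emap.ratio[4, 4] = 1.07
        assert local_error_at(emap, (0.0, 0.0)) == pytest.approx(1.07)

    def test_uniform_map_anywhere(self, rng):
        emap = uniform_map(1.05)
        for _ in range(10):
            uv = rng.uniform(-15, 15, 2)
            assert local_error_at(emap, uv) == pytest.approx(1.05, abs=1e-12)

    def test_bilinear_midpoint(self):
        emap = uniform_map(1.0, n=2, spacing=5.0)
        emap.ratio[:, :] = [[1.00, 1.10], [1.00, 1.10]]
        assert local_error_at(emap, (0.0, 0.0)) == pytest.approx(1.05)

    def test_outside_map_neutral(self):
        emap = uniform_map(1.30)
        assert local_error_at(emap, (1000.0, 0.0)) == 1.0

    def test_invalid_neighbor_contributes_neutral(self):
        emap = uniform_map(1.2, n=2, spacing=5.0)
        emap.valid[0, 0] = False
        # bilinear mix of three 1.2 nodes and one neutral 1.0 at the center
        assert local_error_at(emap, (0.0, 0.0)) == pytest.approx(
            0.25 * 1.0 + 0.75 * 1.2)


def beam_setup(gantry, shape=(16, 16, 16), spacing=4.0):
    geom = m.BeamGeometry(gantry_angle=gantry, isocenter=(0, 0, 0))
    grid = small_grid(np.ones(shape), spacing=(spacing,) * 3)
    return geom, grid


class TestReconstructBeam:
    def test_identity_map_bitwise(self, rng):
        geom, grid = beam_setup(50.0)
        grid = grid.like(rng.uniform(0, 2, grid.shape))
        pred = reconstruct_beam(grid, uniform_map(1.0, n=41), geom)
        assert np.array_equal(pred.values, grid.values)

    def test_uniform_map_scales_covered_voxels(self, rng):
        geom, grid = beam_setup(310.0)
        grid = grid.like(rng.uniform(0, 2, grid.shape))
        pred, info = reconstruct_beam(grid, uniform_map(1.05, n=41), geom,
                                      return_info=True)
        cov = info.covered
        assert cov.any()
        assert np.allclose(pred.values[cov], 1.05 * grid.values[cov],
                           rtol=1e-12)

    @pytest.mark.parametrize("gantry", [0.0, 50.0, 230.0, 310.0])
    def test_matches_brute_force_ray_oracle(self, gantry, rng):
        geom, grid = beam_setup(gantry)
        grid = grid.like(rng.uniform(0, 2, grid.shape))
        n = 15
        c = 10.0 * (np.arange(n) - (n - 1) / 2)
        ratio = rng.uniform(0.9, 1.15, (n, n))
        valid = rng.uniform(size=(n, n)) > 0.1
        valid[n // 2, n // 2] = True
        emap = RelativeErrorMap(u=c, v=c, ratio=ratio, valid=valid)
        pred = reconstruct_beam(grid, emap, geom)
        oracle = brute_force_reconstruct(grid, emap, geom)
        assert np.allclose(pred.values, oracle, rtol=1e-10, atol=1e-12)

    def test_blob_locality(self, rng):
        # perturbing one node changes only voxels whose ray hits fall within
        # one bilinear cell of that node
        geom, grid = beam_setup(0.0)
        grid = grid.like(np.full(grid.shape, 1.0))
        base = uniform_map(1.0, n=21)
        bumped = uniform_map(1.0, n=21)
        bumped.ratio[10, 10] = 1.5  # node at (u, v) = (0, 0)
        p0 = reconstruct_beam(grid, base, geom)
        p1 = reconstruct_beam(grid, bumped, geom)
        changed = ~np.isclose(p1.values, p0.values)
        # recompute the ray hits of changed voxels; all must be in the cell
        src = geom.source_position
        nvec = geom.beam_direction
        u_ax, v_ax = geom.inplane_axes()
        pts = grid.voxel_centers()[changed]
        rel = pts - src
        t = geom.sad / (rel @ nvec)
        hits = src + t[:, None] * rel
        uv = np.column_stack([(hits @ u_ax), (hits @ v_ax)])
        assert changed.any()
        assert np.all(np.abs(uv) < 5.0 + 1e-9)

    def test_clamping_counted(self, rng):
        geom, grid = beam_setup(0.0)
        emap = uniform_map(5.0, n=41)  # far beyond the clamp
        pred, info = reconstruct_beam(grid, emap, geom, clamp=(0.5, 2.0),
                                      return_info=True)
        assert info.n_clamped > 0
        assert pred.values.max() <= 2.0 + 1e-12

    def test_degenerate_ray_geometry(self):
        # voxels behind the source cannot project onto the isocenter plane
        geom = m.BeamGeometry(gantry_angle=0.0, isocenter=(0, 0, 0), sad=10.0)
        grid = small_grid(np.ones((8, 8, 8)), spacing=(4, 4, 4))
        with pytest.raises(GeometryError):
            reconstruct_beam(grid, uniform_map(1.0), geom)


class TestPredictTotal:
    def test_single_beam_unchanged(self, rng):
        g = small_grid(rng.uniform(0, 2, (4, 4, 4)))
        assert np.array_equal(predict_total([g]).values, g.values)

    def test_two_uniform_beams_sum(self):
        a = small_grid(np.ones((4, 4, 4)))
        b = small_grid(np.ones((4, 4, 4)))
        assert np.allclose(predict_total([a, b]).values, 2.0)

    def test_congruence_enforced(self):
        a = small_grid(np.ones((4, 4, 4)))
        b = small_grid(np.ones((4, 4, 4)), origin=(1, 0, 0))
        with pytest.raises(m.grids.CongruenceError):
            predict_total([a, b])


class TestPipelineProperties:
    def test_identity_end_to_end(self, identity_bundle):
        # measured == planned implies predicted == planned, per beam and total
        preds = []
        for beam in identity_bundle.beams:
            emap = compute_error_map(beam.planned_planar, beam.measured_planar)
            pred = reconstruct_beam(beam.planned_dose, emap, beam.geometry)
            assert np.array_equal(pred.values, beam.planned_dose.values)
            preds.append(pred)
        total = predict_total(preds)
        assert np.allclose(total.values, identity_bundle.total_planned.values,
                           rtol=0, atol=1e-12)

    @pytest.mark.parametrize("k", [0.95, 1.05])
    def test_homogeneity_scaling(self, k):
        # scaling all measured planar doses by k scales covered voxels by k
        bundle = m.default_tangential_bundle(
            errors=[m.ErrorSpec(kind="global_scale", magnitude=k)] * 2)
        for beam in bundle.beams:
            emap = compute_error_map(beam.planned_planar, beam.measured_planar)
            pred, info = reconstruct_beam(beam.planned_dose, emap,
                                          beam.geometry, return_info=True)
            cov = info.covered
            assert cov.any()
            assert np.allclose(pred.values[cov],
                               k * beam.planned_dose.values[cov], rtol=1e-9)
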