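import numpy as np
import pytest

import mgdrqa as m
from mgdrqa.errors import DegenerateInputError, InvalidParameterError
from mgdrqa.radbio import (
    NTCPParams, TCPParams, build_dvh, eud, load_registry, metric_D,
    metric_Dmean, metric_V, ntcp_relative_seriality, tcp,
)

from conftest import small_grid


def organ(doses, shape=None):
    """A grid + full mask holding the given voxel doses."""
    doses = np.asarray(doses, dtype=float).ravel()
    n = doses.size
    shape = shape or (n, 1, 1)
    g = small_grid(doses.reshape(shape))
    mask = m.StructureMask("organ", np.ones(shape, bool), g.frame_id)
    return g, mask


def two_level_curve(bin_width=0.01):
    g, mask = organ([10.0, 30.0, 10.0, 30.0])
    return build_dvh(g, mask, bin_width)


class TestBuildDvh:
    def test_uniform_single_bin(self):
        g, mask = organ(np.full(8, 50.0))
        c = build_dvh(g, mask, 0.01)
        assert np.count_nonzero(c.differential) == 1
        assert np.interp(49.9, c.bin_edges, c.cumulative) == 1.0

    def test_two_level_counting(self):
        c = two_level_curve()
        occ = c.differential[c.differential > 0]
        assert np.allclose(occ, [0.5, 0.5])
        assert np.interp(20.0, c.bin_edges, c.cumulative) == 0.5

    def test_normalization_for_any_bin_width(self, rng):
        g, mask = organ(rng.uniform(0, 60, 64))
        for bw in (0.01, 0.1, 1.7):
            c = build_dvh(g, mask, bw)
            assert c.differential.sum() == pytest.approx(1.0, abs=1e-12)
            assert c.cumulative[0] == pytest.approx(1.0, abs=1e-12)
            assert np.all(np.diff(c.cumulative) <= 1e-12)

    def test_empty_mask_rejected(self):
        g, mask = organ([1.0, 2.0])
        # an all-false mask is rejected at construction already
        with pytest.raises(ValueError):
            m.StructureMask("empty", np.zeros((2, 1, 1), bool), g.frame_id)
        # and a mask emptied after construction degenerates in build_dvh
        mask.mask[:] = False
        with pytest.raises(DegenerateInputError):
            build_dvh(g, mask, 0.01)


class TestDvhMetrics:
    def test_uniform_d95(self):
        g, mask = organ(np.full(8, 50.0))
        c = build_dvh(g, mask, 0.01)
        assert metric_D(c, 95.0) == pytest.approx(50.0, abs=0.01)

    def test_two_level_boundary_convention(self):
        c = two_level_curve()
        assert metric_D(c, 95.0) == pytest.approx(10.0, abs=0.01)
        # cumulative >= 0.5 still holds at 30 Gy, so D50% = 30
        assert metric_D(c, 50.0) == pytest.approx(30.0, abs=0.01)

    def test_d100_is_minimum_dose(self, rng):
        doses = rng.uniform(5, 40, 32)
        g, mask = organ(doses)
        c = build_dvh(g, mask, 0.01)
        assert metric_D(c, 100.0) == pytest.approx(doses.min(), abs=0.01)

    def test_v_metrics(self):
        g, mask = organ(np.full(8, 50.0))
        c = build_dvh(g, mask, 0.01)
        assert metric_V(c, 20.0) == 100.0
        assert metric_V(c, 60.0) == 0.0
        c2 = two_level_curve()
        assert metric_V(c2, 20.0) == pytest.approx(50.0)
        assert metric_V(c2, 0.0) == 100.0

    def test_dmean(self, rng):
        g, mask = organ([10.0, 30.0])
        assert metric_Dmean(g, mask) == 20.0
        doses = rng.uniform(0, 60, 50)
        g2, mask2 = organ(doses)
        c = build_dvh(g2, mask2, 0.01)
        # consistency: mean equals the dose-weighted differential DVH sum
        assert metric_Dmean(g2, mask2) == pytest.approx(
            float(np.sum(c.differential * c.bin_doses)), rel=1e-12)

    def test_d_v_inverse_on_decreasing_curve(self, rng):
        doses = rng.uniform(5, 55, 200)
        g, mask = organ(doses)
        c = build_dvh(g, mask, 0.05)
        for v in (20.0, 50.0, 80.0):
            assert metric_V(c, metric_D(c, v)) >= v - 1e-6


class TestEud:
    @pytest.mark.parametrize("a", [-7.23, 1.0, 8.0])
    def test_uniform_dose_identity(self, a):
        g, mask = organ(np.full(16, 42.5))
        c = build_dvh(g, mask, 0.01)
        assert eud(c, a) == pytest.approx(42.5, abs=1e-12)

    def test_a_one_is_dmean(self, rng):
        doses = rng.uniform(1, 60, 64)
        g, mask = organ(doses)
        c = build_dvh(g, mask, 0.01)
        assert eud(c, 1.0) == pytest.approx(metric_Dmean(g, mask), rel=1e-9)

    def test_negative_a_emphasizes_cold_spots(self):
        c = two_level_curve()
        # direct summation oracle over the two occupied bins
        expected = (0.5 * 10.0 ** -7.23 + 0.5 * 30.0 ** -7.23) ** (1 / -7.23)
        val = eud(c, -7.23)
        assert val == pytest.approx(expected, rel=1e-9)
        assert abs(val - 10.0) < abs(val - 20.0)  # closer to min than mean

    def test_bounded_and_monotone_in_a(self, rng):
        doses = rng.uniform(2, 58, 64)
        g, mask = organ(doses)
        c = build_dvh(g, mask, 0.01)
        vals = [eud(c, a) for a in (-8.0, -2.0, 1.0, 4.0, 12.0)]
        assert doses.min() - 0.02 <= vals[0] <= vals[-1] <= doses.max() + 0.02
        assert all(x <= y + 1e-9 for x, y in zip(vals, vals[1:]))

    def test_a_zero_invalid(self):
        with pytest.raises(InvalidParameterError):
            eud(two_level_curve(), 0.0)


class TestTcp:
    def params(self):
        return TCPParams(tcd50=45.0, gamma50=0.89, eud_a=-7.23)

    def test_tcd50_gives_half(self):
        assert tcp(45.0, self.params()) == pytest.approx(0.5, abs=1e-15)

    def test_limits_and_monotonicity(self):
        p = self.params()
        assert tcp(1e-3, p) < 1e-6
        assert tcp(1e4, p) > 1 - 1e-6
        doses = np.linspace(5, 120, 40)
        vals = [tcp(d, p) for d in doses]
        assert all(x < y for x, y in zip(vals, vals[1:]))

    def test_slope_at_tcd50(self):
        # d(TCP)/dD at TCD50 equals gamma50 / TCD50 for the 4*gamma50 exponent
        p = self.params()
        h = 1e-5
        slope = (tcp(p.tcd50 + h, p) - tcp(p.tcd50 - h, p)) / (2 * h)
        assert slope == pytest.approx(p.gamma50 / p.tcd50, rel=1e-6)

    def test_nonpositive_dose_invalid(self):
        with pytest.raises(InvalidParameterError):
            tcp(0.0, self.params())


class TestNtcpRelativeSeriality:
    @pytest.mark.parametrize("s", [0.012, 0.5, 1.0])
    def test_uniform_d50_gives_half(self, s):
        params = NTCPParams(d50=26.16, gamma=0.97, s=s)
        g, mask = organ(np.full(16, 26.16))
        c = build_dvh(g, mask, 0.01)
        assert ntcp_relative_seriality(c, params) == pytest.approx(
            0.5, abs=1e-12)

    def test_zero_dose_vanishes(self):
        params = NTCPParams(d50=52.3, gamma=1.28, s=1.0)
        g, mask = organ(np.zeros(8))
        c = build_dvh(g, mask, 0.01)
        p0 = 2.0 ** -np.exp(np.e * 1.28)
        assert ntcp_relative_seriality(c, params) == pytest.approx(p0, rel=1e-6)

    def test_half_organ_at_d50_serial(self):
        # two-bin direct evaluation: half at D50, half at 0, s = 1
        params = NTCPParams(d50=52.3, gamma=1.28, s=1.0)
        g, mask = organ([52.3, 52.3, 0.0, 0.0])
        c = build_dvh(g, mask, 0.01)
        p0 = 2.0 ** -np.exp(np.e * params.gamma)
        expected = 1.0 - (1 - 0.5) ** 0.5 * (1 - p0) ** 0.5
        got = ntcp_relative_seriality(c, params)
        assert got == pytest.approx(expected, rel=1e-9)
        assert got == pytest.approx(1 - np.sqrt(0.5), abs=1e-4)

    def test_s_one_series_closed_form(self, rng):
        params = NTCPParams(d50=30.0, gamma=1.1, s=1.0)
        doses = rng.uniform(0, 60, 64)
        g, mask = organ(doses)
        c = build_dvh(g, mask, 0.05)
        occ = c.differential > 0
        p = 2.0 ** -np.exp(np.e * params.gamma *
                           (1 - c.bin_doses[occ] / params.d50))
        expected = 1.0 - np.prod((1 - p) ** c.differential[occ])
        assert ntcp_relative_seriality(c, params) == pytest.approx(
            expected, rel=1e-9)

    def test_parallel_limit_uniform_dose(self):
        # s -> 0 with uniform dose approaches the single-voxel P
        g, mask = organ(np.full(16, 20.0))
        c = build_dvh(g, mask, 0.01)
        p_single = 2.0 ** -np.exp(np.e * 0.97 * (1 - 20.0 / 26.16))
        got = ntcp_relative_seriality(c, NTCPParams(26.16, 0.97, s=1e-6))
        assert got == pytest.approx(p_single, rel=1e-6)

    def test_monotone_under_uniform_scaling(self):
        params = NTCPParams(d50=26.16, gamma=0.97, s=0.012)
        vals = []
        for k in (0.6, 0.8, 1.0, 1.2, 1.5):
            g, mask = organ(k * np.array([5.0, 12.0, 20.0, 28.0]))
            vals.append(ntcp_relative_seriality(build_dvh(g, mask, 0.02),
                                                params))
        assert all(x <= y + 1e-12 for x, y in zip(vals, vals[1:]))

    def test_unnormalized_curve_invalid(self):
        c = two_level_curve()
        c.differential = c.differential * 0.5
        with pytest.raises(InvalidParameterError):
            ntcp_relative_seriality(c, NTCPParams(26.16, 0.97, 0.012))


class TestRegistry:
    def test_shipped_registry_contents(self):
        reg = load_registry()
        assert reg["PTV"]["model"] == "tcp_eud"
        assert reg["PTV"]["params"].eud_a == -7.23
        assert reg["PTV"]["params"].gamma50 == 0.89
        lung = reg["ipsilateral_lung"]["params"]
        assert (lung.d50, lung.gamma, lung.s) == (26.16, 0.97, 0.012)
        heart = reg["heart"]["params"]
        assert (heart.d50, heart.gamma, heart.s) == (52.3, 1.28, 1.0)

    def test_user_registry_file_override(self, tmp_path):
        p = tmp_path / "reg.yaml"
        p.write_text(
            "structures:\n"
            "  spinal_cord:\n"
            "    endpoint: myelitis\n"
            "    model: relative_seriality\n"
            "    d50: 68.6\n"
            "    gamma: 1.9\n"
            "    s: 4.0\n"
        )
        reg = load_registry(p)
        assert reg["spinal_cord"]["params"].s == 4.0
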