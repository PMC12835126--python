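"""Unit yield, efficiency, and the closed-form optimal spacing."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dualobserver import (
    DualObserverParams,
    LinearArraySpec,
    VolumeDecomposition,
    efficiency,
    linear_array_volumes,
    optimal_distance,
    optimal_efficiency,
    optimum_summary,
    sphere_volume,
    unit_yield,
    units_per_channel,
)


def _lens_ratio_efficiency_grid(m, r, g, d_grid):
    """Vectorized efficiency over a spacing grid (independent re-derivation
    from the lens formula, used as the brute-force optimum oracle)."""
    def v2(dd):
        out = np.where(
            dd < 2 * r,
            (np.pi / 3) * (4 * r**3 - 3 * r**2 * dd + dd**3 / 4),
            0.0,
        )
        return out

    v1 = 4 * np.pi / 3 * r**3
    return (
        1.0
        + 2 * (g - 1) * (m - 1) / m * v2(d_grid) / v1
        - (2 * g - 1) * max(m - 2, 0) / m * v2(2 * d_grid) / v1
    )


class TestUnitYield:
    def test_independent_electrodes(self):
        v1 = sphere_volume(42.0)
        dec = VolumeDecomposition(v_single=32 * v1, v_double=0.0, v_total=32 * v1)
        params = DualObserverParams(42.0, 1.64, 2122.0)
        assert unit_yield(dec, params) == pytest.approx(
            2122.0 * 32 * v1 / 1e9, rel=1e-12
        )

    def test_thalamus_single_electrode(self):
        """R=15 um, p=47639/mm3: one electrode observes 0.6735 units."""
        v1 = sphere_volume(15.0)
        dec = VolumeDecomposition(v_single=v1, v_double=0.0, v_total=v1)
        params = DualObserverParams(15.0, 0.83, 47639.0)
        assert unit_yield(dec, params) == pytest.approx(0.6735, abs=5e-4)

    def test_g_half_counts_total_volume(self):
        """G = 0.5 (no cooperation): N = p_single * v_total."""
        dec = linear_array_volumes(LinearArraySpec(8, 30.0), 40.0)
        params = DualObserverParams(40.0, 0.5, 1000.0)
        assert unit_yield(dec, params) == pytest.approx(
            1000.0 * dec.v_total / 1e9, rel=1e-12
        )


class TestEfficiency:
    @pytest.mark.parametrize("m,g", [(4, 0.2), (32, 1.0), (16, 3.5)])
    def test_no_overlap_is_unity(self, m, g):
        assert efficiency(m, 42.0, 84.0, g) == 1.0
        assert efficiency(m, 42.0, 120.0, g) == 1.0

    @pytest.mark.parametrize("d", [42.0, 55.0, 70.0, 83.9])
    def test_g1_flat_above_r(self, d):
        """At G = 1 efficiency does not depend on spacing once D >= R."""
        assert efficiency(32, 42.0, d, 1.0) == pytest.approx(1.0, rel=1e-12)

    def test_rat_ctx_values(self):
        assert efficiency(32, 42.0, 48.0, 1.64) == pytest.approx(1.2928, abs=1e-4)
        assert efficiency(32, 42.0, 37.0, 1.64) == pytest.approx(1.4301, abs=1e-4)

    def test_matches_unit_yield_ratio(self):
        """E == N / (p_single M V1) to machine precision."""
        rng = np.random.default_rng(11)
        for _ in range(50):
            m = int(rng.integers(1, 64))
            r = float(rng.uniform(5, 120))
            d = float(rng.uniform(0.2 * r, 2.5 * r))
            g = float(rng.uniform(0.0, 4.0))
            dec = linear_array_volumes(LinearArraySpec(m, d), r)
            params = DualObserverParams(r, g, 1234.0)
            ratio = unit_yield(dec, params) / (1234.0 * m * sphere_volume(r) / 1e9)
            assert efficiency(m, r, d, g) == pytest.approx(ratio, rel=1e-12)

    @given(
        m=st.integers(2, 64),
        r=st.floats(5, 120),
        frac=st.floats(0.1, 1.9),
        g_lo=st.floats(0.0, 3.0),
    )
    @settings(max_examples=200, derandomize=True)
    def test_strictly_increasing_in_g_with_overlap(self, m, r, frac, g_lo):
        d = frac * r
        e1 = efficiency(m, r, d, g_lo)
        e2 = efficiency(m, r, d, g_lo + 0.5)
        assert e2 > e1

    def test_curve_shape(self):
        """Fig-style shape checks: unique interior peak for G > 1, E <= 1
        everywhere in the overlap region for G < 0.5, E -> 1 from above
        as D -> 2R for G > 1."""
        m, r = 32, 42.0
        d_grid = np.linspace(0.05 * r, 2.2 * r, 4000)
        e_hi = np.array([efficiency(m, r, d, 2.0) for d in d_grid])
        i_max = int(np.argmax(e_hi))
        assert 0 < i_max < len(d_grid) - 1
        # single interior peak: increasing before, decreasing after (up to 2r)
        inside = d_grid < 2 * r
        diffs = np.diff(e_hi[inside])
        sign_changes = np.count_nonzero(np.diff(np.sign(diffs[diffs != 0])))
        assert sign_changes == 1
        assert e_hi[d_grid < 2 * r][-1] >= 1.0
        e_lo = np.array([efficiency(m, r, d, 0.3) for d in d_grid[inside]])
        assert np.all(e_lo <= 1.0 + 1e-12)


class TestOptimalDistance:
    @pytest.mark.parametrize(
        "m,r,g,expected_um",
        [(32, 42.0, 1.64, 37), (32, 107.0, 1.96, 91), (32, 20.0, 1.46, 18)],
    )
    def test_fitted_parameter_optima(self, m, r, g, expected_um):
        d_opt, flag = optimal_distance(m, r, g)
        assert flag == "interior_optimum"
        assert round(d_opt) == expected_um

    def test_g1_equals_r_exactly(self):
        for m in (4, 16, 64):
            d_opt, flag = optimal_distance(m, 42.0, 1.0)
            assert d_opt == 42.0
            assert flag == "boundary_g_le_1"

    def test_boundary_below_g1(self):
        d_opt, flag = optimal_distance(32, 15.0, 0.83)
        assert (d_opt, flag) == (15.0, "boundary_g_le_1")

    def test_large_g_large_m_limit(self):
        d_opt, _ = optimal_distance(100_000, 1.0, 1e6)
        assert d_opt == pytest.approx(math.sqrt(4 / 7), rel=1e-4)

    def test_small_arrays_rejected(self):
        with pytest.raises(ValueError):
            optimal_distance(3, 42.0, 1.5)

    def test_brute_force_argmax_oracle(self):
        """The closed form lands within one grid step of a dense numeric
        argmax of the efficiency curve, for random (m, r, g > 1)."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            m = int(rng.integers(4, 65))
            r = float(rng.uniform(5, 150))
            g = float(rng.uniform(1.01, 4.0))
            step = r / 2000
            d_grid = np.arange(step, 2.2 * r, step)
            e = _lens_ratio_efficiency_grid(m, r, g, d_grid)
            d_best = d_grid[int(np.argmax(e))]
            d_opt, flag = optimal_distance(m, r, g)
            assert flag == "interior_optimum"
            assert d_opt < r  # stationary point lives in the d < r regime
            assert abs(d_opt - d_best) <= step + 1e-12


class TestOptimalEfficiency:
    @pytest.mark.parametrize(
        "g,expected",
        [(1.64, 1.41), (2.07, 1.73), (1.46, 1.27), (1.96, 1.65), (1.86, 1.57),
         (1.95, 1.64)],
    )
    def test_approximation_two_decimals(self, g, expected):
        e_approx, _ = optimal_efficiency(32, 42.0, g)
        assert round(e_approx, 2) == expected

    def test_boundary_is_unity(self):
        assert optimal_efficiency(32, 15.0, 0.83) == (1.0, 1.0)

    def test_exact_at_least_one_for_synergy(self):
        for g in (1.1, 1.64, 3.0):
            e_approx, e_exact = optimal_efficiency(32, 42.0, g)
            assert e_exact >= 1.0
            assert e_approx == pytest.approx(0.76 * g + 0.16, rel=1e-12)


class TestUnitsPerChannel:
    def test_independent_regime_is_m_free(self):
        for m in (4, 16, 64):
            upc = units_per_channel(m, 42.0, 84.0, 1.64, 2122.0)
            assert upc == pytest.approx(2122.0 * sphere_volume(42.0) / 1e9, rel=1e-12)

    def test_rat_ctx_chain(self):
        indep = units_per_channel(32, 42.0, 84.0, 1.64, 2122.0)
        assert indep == pytest.approx(0.6585, abs=2e-4)
        opt = optimum_summary(32, DualObserverParams(42.0, 1.64, 2122.0))
        assert opt.opt_units_per_channel == pytest.approx(indep * 1.4064, rel=1e-6)
        assert round(opt.opt_units_per_channel, 2) == 0.93
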