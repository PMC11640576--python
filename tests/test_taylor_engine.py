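"""Taylor source-grid engine: derivative array correctness, reconstruction
accuracy against direct quadrature, and the displacement series."""

import numpy as np
import pytest

from octsim.dwi_reference import ex_incident, h_components
from octsim.taylor_engine import (DomainError, _bessel_derivative_weights,
                                  axial_derivative_fast, build_source_grid,
                                  choose_Dz0, compute_derivative_array,
                                  displaced_h, field_x_fast,
                                  h_derivative_direct, taylor_h)
from octsim.validation import integral_error


class TestSourceGrid:
    @pytest.mark.parametrize("rho_max,s_rho,expected", [
        (70.0, 28.0, 3),   # the recommended radial layout
        (28.0, 28.0, 1),   # one-cell cover
        (70.0, 70.0, 1),
    ])
    def test_radial_counts(self, rho_max, s_rho, expected):
        g = build_source_grid(rho_max, 100.0, s_rho, 100.0)
        assert g.n_rho == expected

    def test_axial_count_recommended(self):
        # 1 mm depth at 190 µm spacing needs 6 axial sources
        g = build_source_grid(70.0, 1000.0, 28.0, 190.0)
        assert g.n_z == 6

    def test_single_cell_source_at_center(self):
        g = build_source_grid(28.0, 100.0, 28.0, 100.0)
        assert g.rho_sources[0] == pytest.approx(14.0)

    def test_cell_centres_cover_within_half_spacing(self):
        g = build_source_grid(70.0, 1000.0, 28.0, 190.0)
        pts_r = np.linspace(0, 70, 101)
        pts_z = np.linspace(0, 1000, 101)
        dr = np.min(np.abs(pts_r[:, None] - g.rho_sources), axis=1)
        dz = np.min(np.abs(pts_z[:, None] - g.z_sources), axis=1)
        assert dr.max() <= 14.0 + 1e-9
        assert dz.max() <= 95.0 + 1e-9

    def test_n_total_formula(self):
        g = build_source_grid(70.0, 1000.0, 28.0, 190.0, d_rho=20, d_z=8)
        assert g.n_total(865) == 21 * 9 * 3 * 6 * 865

    def test_nearest_ties_break_to_lower_index(self):
        g = build_source_grid(56.0, 100.0, 28.0, 100.0)  # sources at 14, 42
        j, _ = g.nearest(np.array([28.0]), np.array([50.0]))
        assert j[0] == 0


class TestBesselDerivativeExpansion:
    def test_second_derivative_of_j2(self):
        # J2'' = (J0 - 2 J2 + J4) / 4
        w = _bessel_derivative_weights(2, 2)
        assert w == {0: 0.25, 2: -0.5, 4: 0.25}

    def test_negative_orders_folded_by_parity(self):
        # J0' = -J1: the m=1, c=0 expansion folds J_{-1} = -J1
        w = _bessel_derivative_weights(0, 1)
        assert w == {1: -1.0}


class TestDerivativeArray:
    def test_zeroth_entry_equals_direct_quadrature(self, sys_small, deriv_small):
        g = deriv_small.grid
        for j, l in [(0, 0), (2, 1)]:
            h0, h2 = h_components(g.rho_sources[j], g.z_sources[l],
                                  sys_small.k_grid, sys_small)
            atol0 = 1e-12 * np.abs(h0).max()
            np.testing.assert_allclose(deriv_small.S[0, 0, 0, j, l], h0[0],
                                       rtol=1e-9, atol=atol0)
            np.testing.assert_allclose(deriv_small.S[1, 0, 0, j, l], h2[0],
                                       rtol=1e-9, atol=1e-12 * np.abs(h2).max())

    def test_first_radial_derivative_matches_finite_difference(self, sys_small):
        k = sys_small.k_grid[:3]
        rho0, z0 = 20.0, 40.0
        d1 = h_derivative_direct(rho0, z0, k, sys_small, m=1, n=0)
        eps = 1e-3
        hp = h_components(rho0 + eps, z0, k, sys_small)
        hm = h_components(rho0 - eps, z0, k, sys_small)
        for c in (0, 1):
            fd = (hp[c][0] - hm[c][0]) / (2 * eps)
            np.testing.assert_allclose(d1[c], fd, rtol=1e-6)

    def test_first_axial_derivative_matches_finite_difference(self, sys_small):
        k = sys_small.k_grid[:3]
        rho0, z0 = 20.0, 40.0
        d1 = h_derivative_direct(rho0, z0, k, sys_small, m=0, n=1)
        eps = 1e-3
        hp = h_components(rho0, z0 + eps, k, sys_small)
        hm = h_components(rho0, z0 - eps, k, sys_small)
        for c in (0, 1):
            fd = (hp[c][0] - hm[c][0]) / (2 * eps)
            np.testing.assert_allclose(d1[c], fd, rtol=1e-6)

    def test_every_order_consistent_by_incremental_differences(self, sys_small):
        """Each stored derivative order must equal the central finite
        difference of the directly integrated order below it."""
        k = sys_small.k_grid[:2]
        rho0, z0 = 35.0, 60.0
        eps = 1e-3
        for m in range(1, 6):
            hi = h_derivative_direct(rho0, z0, k, sys_small, m=m, n=0)
            lo_p = h_derivative_direct(rho0 + eps, z0, k, sys_small, m=m - 1, n=0)
            lo_m = h_derivative_direct(rho0 - eps, z0, k, sys_small, m=m - 1, n=0)
            for c in (0, 1):
                fd = (lo_p[c] - lo_m[c]) / (2 * eps)
                np.testing.assert_allclose(hi[c], fd, rtol=1e-5, atol=1e-5 * np.abs(hi[c]).max() + 1e-12)
        for n in range(1, 6):
            hi = h_derivative_direct(rho0, z0, k, sys_small, m=0, n=n)
            lo_p = h_derivative_direct(rho0, z0 + eps, k, sys_small, m=0, n=n - 1)
            lo_m = h_derivative_direct(rho0, z0 - eps, k, sys_small, m=0, n=n - 1)
            for c in (0, 1):
                fd = (lo_p[c] - lo_m[c]) / (2 * eps)
                np.testing.assert_allclose(hi[c], fd, rtol=1e-5, atol=1e-5 * np.abs(hi[c]).max() + 1e-12)

    def test_array_matches_free_point_derivatives_at_sources(self, sys_small, deriv_small):
        g = deriv_small.grid
        for (m, n) in [(3, 2), (7, 5)]:
            d = h_derivative_direct(g.rho_sources[1], g.z_sources[0],
                                    sys_small.k_grid, sys_small, m=m, n=n)
            np.testing.assert_allclose(deriv_small.S[0, m, n, 1, 0], d[0], rtol=1e-10)
            np.testing.assert_allclose(deriv_small.S[1, m, n, 1, 0], d[1], rtol=1e-10)

    def test_hdf5_round_trip(self, deriv_small, tmp_path):
        from octsim.taylor_engine import DerivativeArray

        path = tmp_path / "deriv.h5"
        deriv_small.save(path, {"note": "test"})
        back = DerivativeArray.load(path)
        np.testing.assert_array_equal(back.S, deriv_small.S)
        np.testing.assert_array_equal(back.k_list, deriv_small.k_list)
        assert back.grid.d_rho == deriv_small.grid.d_rho


class TestTaylorReconstruction:
    def test_exact_at_source_points(self, deriv_small):
        g = deriv_small.grid
        h0, h2 = taylor_h(g.rho_sources[[1]], g.z_sources[[1]], deriv_small)
        np.testing.assert_allclose(h0[0], deriv_small.S[0, 0, 0, 1, 1], rtol=0)
        np.testing.assert_allclose(h2[0], deriv_small.S[1, 0, 0, 1, 1], rtol=0)

    def test_random_interior_points_match_direct_quadrature(self, sys_small, deriv_small):
        rng = np.random.default_rng(5)
        rho = rng.uniform(0, 70, 60)
        z = rng.uniform(-100, 100, 60)
        h0t, h2t = taylor_h(rho, z, deriv_small)
        h0r, h2r = h_components(rho, z, sys_small.k_grid, sys_small)
        assert integral_error(h0r, h0t) < 1e-9
        assert integral_error(h2r, h2t) < 1e-9

    def test_low_order_fine_grid_matches_to_1e6(self, sys_small):
        # order 4 on a fine grid is already at quadrature-level agreement
        g = build_source_grid(70.0, 100.0, 0.5, 10.0, d_rho=4, d_z=4)
        arr = compute_derivative_array(g, sys_small, sys_small.k_grid[:4])
        rng = np.random.default_rng(6)
        rho, z = rng.uniform(0, 70, 30), rng.uniform(0, 100, 30)
        h0t, _ = taylor_h(rho, z, arr)
        h0r, _ = h_components(rho, z, sys_small.k_grid[:4], sys_small)
        rel = np.abs(h0t - h0r) / np.abs(h0r).max()
        assert rel.max() < 1e-6

    def test_error_non_increasing_with_orders(self, sys_small):
        rng = np.random.default_rng(7)
        rho, z = rng.uniform(0, 70, 40), rng.uniform(0, 100, 40)
        h0r, _ = h_components(rho, z, sys_small.k_grid[:2], sys_small)
        errs = []
        for d in (2, 4, 8, 12):
            g = build_source_grid(70.0, 100.0, 28.0, 95.0, d_rho=d, d_z=min(d, 8))
            arr = compute_derivative_array(g, sys_small, sys_small.k_grid[:2])
            h0t, _ = taylor_h(rho, z, arr)
            errs.append(integral_error(h0r, h0t))
        assert all(errs[i + 1] <= errs[i] * (1 + 1e-9) for i in range(len(errs) - 1))

    def test_out_of_domain_raises(self, deriv_small):
        with pytest.raises(DomainError):
            taylor_h(np.array([100.0]), np.array([0.0]), deriv_small)
        with pytest.raises(DomainError):
            taylor_h(np.array([10.0]), np.array([900.0]), deriv_small)


class TestFastField:
    def test_on_axis_psi_independent(self, sys_small, deriv_small):
        e1 = field_x_fast([0.0], [0.3], [10.0], deriv_small, sys_small)
        e2 = field_x_fast([0.0], [2.5], [10.0], deriv_small, sys_small)
        # the reconstructed h2 vanishes at rho = 0 only to truncation level,
        # so the azimuthal dependence is bounded by that tiny residual
        np.testing.assert_allclose(e1, e2, rtol=0,
                                   atol=1e-8 * np.abs(e1).max())

    def test_matches_rigorous_field_within_budget(self, sys_small, deriv_small):
        rng = np.random.default_rng(8)
        n = 100
        rho = rng.uniform(0, 70, n)
        psi = rng.uniform(0, 2 * np.pi, n)
        z = rng.uniform(-100, 100, n)
        ef = field_x_fast(rho, psi, z, deriv_small, sys_small)
        er = ex_incident(rho, psi, z, sys_small.k_grid, sys_small)
        assert integral_error(er, ef) <= 3e-4

    def test_factored_phase_carries_fast_axial_oscillation(self, sys_small, deriv_small):
        # moving half a wavelength in depth flips the field phase by ~pi,
        # with only a slow residual from h
        k = sys_small.k_grid
        lam_c = 2 * np.pi / sys_small.k_center
        z0 = 20.0
        e1 = field_x_fast([5.0], [0.0], [z0], deriv_small, sys_small)
        e2 = field_x_fast([5.0], [0.0], [z0 + lam_c / (2 * sys_small.eta)],
                          deriv_small, sys_small)
        ic = np.argmin(np.abs(k - sys_small.k_center))
        dphi = np.angle(e2[0, ic] / e1[0, ic])
        assert abs(abs(dphi) - np.pi) < 0.1


class TestDisplacementSeries:
    @pytest.mark.parametrize("ms,expected", [(10.0, 2), (0.0, 0), (20.0, 3),
                                             (1.2, 1)])
    def test_series_order_rule(self, ms, expected):
        assert choose_Dz0(ms) == expected

    def test_negative_displacement_rejected(self):
        with pytest.raises(ValueError):
            choose_Dz0(-1.0)

    def test_zeroth_axial_derivative_is_taylor_h(self, deriv_small):
        rho = np.array([10.0, 40.0])
        z = np.array([-50.0, 80.0])
        a = taylor_h(rho, z, deriv_small)
        b = axial_derivative_fast(rho, z, 0, deriv_small)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_first_axial_derivative_matches_finite_difference(self, deriv_small):
        rho = np.array([25.0])
        z = np.array([30.0])
        d1 = axial_derivative_fast(rho, z, 1, deriv_small)
        eps = 1e-3
        hp = taylor_h(rho, z + eps, deriv_small)
        hm = taylor_h(rho, z - eps, deriv_small)
        for c in (0, 1):
            fd = (hp[c] - hm[c]) / (2 * eps)
            np.testing.assert_allclose(d1[c], fd, rtol=1e-6)

    def test_order_beyond_stored_raises(self, deriv_small):
        with pytest.raises(ValueError, match="d_z0"):
            axial_derivative_fast(np.array([10.0]), np.array([10.0]),
                                  deriv_small.grid.d_z0 + 1, deriv_small)

    def test_zero_displacement_identity(self, deriv_small):
        rho, z = np.array([15.0]), np.array([40.0])
        a = taylor_h(rho, z, deriv_small)
        b = displaced_h(rho, z, np.array([0.0]), deriv_small)
        np.testing.assert_array_equal(a[0], b[0])

    def test_displaced_matches_direct_evaluation(self, sys_small, deriv_small):
        rng = np.random.default_rng(9)
        rho = rng.uniform(0, 70, 50)
        z = rng.uniform(-80, 80, 50)
        delta = rng.uniform(-5, 5, 50)
        hd = displaced_h(rho, z, delta, deriv_small)
        hr = h_components(rho, z + delta, sys_small.k_grid, sys_small)
        assert integral_error(hr[0], hd[0]) <= 3e-4
        assert integral_error(hr[1], hd[1]) <= 3e-4

    def test_error_decreases_with_displacement_order(self, sys_small, deriv_small):
        rng = np.random.default_rng(10)
        rho = rng.uniform(0, 70, 50)
        z = rng.uniform(-80, 80, 50)
        delta = np.full(50, 5.0)
        hr = h_components(rho, z + delta, sys_small.k_grid, sys_small)
        errs = [integral_error(hr[0], displaced_h(rho, z, delta, deriv_small,
                                                  d_z0=d)[0])
                for d in (0, 1, 2)]
        assert errs[1] < errs[0] and errs[2] < errs[1]

    def test_composed_displacement_matches_direct_taylor(self, deriv_small):
        # a combined displacement delta1 + delta2 through the displacement
        # series agrees with the base Taylor reconstruction evaluated
        # directly at the displaced depth, within the truncation error
        rho, z = np.array([20.0]), np.array([10.0])
        d1, d2 = 1.5, 2.0
        composed = displaced_h(rho, z, np.array([d1 + d2]), deriv_small)
        direct = taylor_h(rho, z + d1 + d2, deriv_small)
        np.testing.assert_allclose(composed[0], direct[0], rtol=1e-4)
        np.testing.assert_allclose(composed[1], direct[1], rtol=1e-4)
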