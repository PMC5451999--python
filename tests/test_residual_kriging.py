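import numpy as np
import pytest
from scipy.spatial.distance import cdist, squareform, pdist
from shapely.geometry import box

from pm25ens import (GridSpec, VariogramModel, block_mean, daily_surfaces,
                     daily_variograms, empirical_variogram, fit_variogram,
                     fit_variogram_ml, krige, loo_krige,
                     simulate_gaussian_field, variogram_value)
from pm25ens.residual_kriging import KrigingError, EmpiricalVariogram


def _grid_coords(n_side, spacing):
    g = np.arange(n_side) * spacing
    xx, yy = np.meshgrid(g, g)
    return np.column_stack([xx.ravel(), yy.ravel()])


class TestEmpiricalVariogram:
    def test_hand_computed_collinear_example(self):
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        vals = np.array([0.0, 1.0, 2.0])
        # pad with far-away stations so the ≥10-station precondition holds
        far = np.column_stack([np.full(9, 1e6) + np.arange(9) * 1e5,
                               np.zeros(9)])
        coords = np.vstack([coords, far])
        vals = np.concatenate([vals, np.zeros(9)])
        emp = empirical_variogram(coords, vals, n_bins=2, max_lag=2.5,
                                  min_pairs=1)
        # lag-1 pairs: (0,1), (1,2) → γ = ½·mean(1,1) = 0.5
        # lag-2 pair: (0,2) → γ = ½·4 = 2.0
        np.testing.assert_allclose(emp.gamma[:2], [0.5, 2.0])
        np.testing.assert_array_equal(emp.counts[:2], [2, 1])

    def test_constant_residuals_zero_everywhere(self, network_coords):
        with pytest.warns(UserWarning, match="constant"):
            emp = empirical_variogram(network_coords,
                                      np.full(len(network_coords), 3.0))
        np.testing.assert_allclose(emp.gamma, 0.0)

    def test_permutation_invariant(self, network_coords, rng):
        vals = rng.standard_normal(len(network_coords))
        emp1 = empirical_variogram(network_coords, vals)
        perm = rng.permutation(len(vals))
        emp2 = empirical_variogram(network_coords[perm], vals[perm])
        np.testing.assert_allclose(emp1.gamma, emp2.gamma)
        np.testing.assert_array_equal(emp1.counts, emp2.counts)

    def test_too_few_stations_flagged(self, rng):
        with pytest.raises(KrigingError, match="no-kriging"):
            empirical_variogram(rng.random((5, 2)), rng.random(5))


class TestFitVariogram:
    def test_noiseless_exponential_recovery(self):
        c0, c, a0 = 1.0, 4.0, 30_000.0
        lags = np.linspace(5_000, 120_000, 8)
        emp = EmpiricalVariogram(
            day=0, lags=lags,
            gamma=variogram_value("exponential", lags, c0, c, a0),
            counts=np.full(8, 40), max_lag=120_000.0, n_stations=96)
        m = fit_variogram(emp, "exponential")
        assert m.nugget == pytest.approx(c0, rel=0.01)
        assert m.partial_sill == pytest.approx(c, rel=0.01)
        assert m.a0 == pytest.approx(a0, rel=0.01)

    def test_pure_nugget_truth_yields_small_sill(self, network_coords):
        """Spatially independent residuals should not produce spurious
        structured variance (c ≈ 0) in the vast majority of fits."""
        rng = np.random.default_rng(12)
        hits = 0
        for _ in range(100):
            vals = rng.normal(0.0, 1.0, len(network_coords))
            m = fit_variogram_ml(network_coords, vals)
            hits += m.partial_sill < 0.1 * max(m.nugget, 1e-12)
        assert hits >= 90

    def test_ml_fit_recovers_structure(self, network_coords):
        rng = np.random.default_rng(3)
        vals = simulate_gaussian_field(network_coords, 0.005, 0.1, 45_000.0,
                                       rng)
        m = fit_variogram_ml(network_coords, vals)
        assert m.partial_sill > 5 * m.nugget        # planted ratio is 20:1
        assert 10_000.0 < m.a0 < 200_000.0

    def test_ml_rejects_linear_family(self, network_coords, rng):
        with pytest.raises(ValueError, match="linear"):
            fit_variogram_ml(network_coords,
                             rng.standard_normal(len(network_coords)),
                             family="linear")

    def test_model_form_properties(self):
        m = VariogramModel("exponential", nugget=0.5, partial_sill=2.0,
                           a0=10_000.0)
        d = np.linspace(0, 100_000, 200)
        g = m(d)
        assert g[0] == 0.0
        assert (np.diff(g[1:]) >= -1e-12).all()
        assert g[-1] <= m.sill + 1e-9
        assert m.effective_range == pytest.approx(30_000.0)

    def test_all_families_fit_something(self, network_coords, rng):
        vals = simulate_gaussian_field(network_coords, 0.01, 0.1, 60_000.0,
                                       rng)
        emp = empirical_variogram(network_coords, vals)
        for fam in ("spherical", "circular", "exponential", "gaussian",
                    "linear"):
            m = fit_variogram(emp, fam)
            assert m.nugget >= 0 and m.partial_sill >= 0 and m.a0 > 0


class TestKrige:
    @staticmethod
    def _vgm(c0=0.0, c=1.0, a=50_000.0):
        return VariogramModel("exponential", c0, c, a)

    def test_exact_at_stations_when_no_nugget(self, rng):
        coords = rng.uniform(0, 1e5, (12, 2))
        vals = rng.standard_normal(12)
        est, var, w = krige(coords, vals, self._vgm(), coords,
                            return_weights=True)
        np.testing.assert_allclose(est, vals, atol=1e-8)
        np.testing.assert_allclose(var, 0.0, atol=1e-8)
        np.testing.assert_allclose(np.diag(w), 1.0, atol=1e-8)

    def test_weights_sum_to_one(self, rng):
        coords = rng.uniform(0, 2e5, (15, 2))
        vals = rng.standard_normal(15)
        targets = rng.uniform(0, 2e5, (40, 2))
        _, _, w = krige(coords, vals, self._vgm(c0=0.3), targets,
                        return_weights=True)
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-10)

    def test_symmetric_two_station_midpoint(self):
        coords = np.array([[0.0, 0.0], [100_000.0, 0.0]])
        vals = np.array([1.0, -1.0])
        est, _, w = krige(coords, vals, self._vgm(), [[50_000.0, 0.0]],
                          return_weights=True)
        np.testing.assert_allclose(w[0], [0.5, 0.5], atol=1e-12)
        assert est[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_augmented_solve(self, rng):
        """Oracle: independently assembled augmented system, lstsq-solved."""
        for trial in range(25):
            n = int(rng.integers(4, 21))
            coords = rng.uniform(0, 1e5, (n, 2))
            vals = rng.standard_normal(n)
            target = rng.uniform(0, 1e5, (1, 2))
            vgm = self._vgm(c0=float(rng.uniform(0, 0.5)),
                            c=float(rng.uniform(0.5, 2.0)),
                            a=float(rng.uniform(1e4, 8e4)))
            est, var = krige(coords, vals, vgm, target)

            A = np.zeros((n + 1, n + 1))
            A[:n, :n] = vgm(squareform(pdist(coords)))
            A[:n, n] = A[n, :n] = 1.0
            b = np.concatenate([vgm(cdist(coords, target)).ravel(), [1.0]])
            sol = np.linalg.lstsq(A, b, rcond=None)[0]
            assert est[0] == pytest.approx(float(sol[:n] @ vals), abs=1e-8)
            assert var[0] == pytest.approx(float(sol @ b), abs=1e-7)

    def test_positive_variance_away_from_data(self, rng):
        coords = rng.uniform(0, 1e5, (10, 2))
        vals = rng.standard_normal(10)
        _, var = krige(coords, vals, self._vgm(), [[-5e4, -5e4]])
        assert var[0] > 0

    def test_duplicate_stations_averaged(self):
        coords = np.array([[0.0, 0.0], [0.0, 0.0], [60_000.0, 0.0]])
        vals = np.array([1.0, 3.0, 0.0])
        est, _ = krige(coords, vals, self._vgm(c0=0.1), [[0.0, 0.0]])
        dd_est, _ = krige(np.array([[0.0, 0.0], [60_000.0, 0.0]]),
                          np.array([2.0, 0.0]), self._vgm(c0=0.1),
                          [[0.0, 0.0]])
        assert est[0] == pytest.approx(dd_est[0])

    def test_loo_matches_bruteforce(self, rng):
        coords = rng.uniform(0, 1e5, (14, 2))
        vals = rng.standard_normal(14)
        vgm = self._vgm(c0=0.2)
        fast = loo_krige(coords, vals, vgm)
        for i in range(14):
            rest = np.delete(np.arange(14), i)
            est, _ = krige(coords[rest], vals[rest], vgm, coords[i][None, :])
            assert fast[i] == pytest.approx(est[0], abs=1e-8)


class TestDailySurfacesAndBlocks:
    def test_parameter_table_covers_every_day(self, rng):
        coords = _grid_coords(5, 20_000.0)  # 25 stations
        n_days = 12
        resid = np.vstack([simulate_gaussian_field(coords, 0.01, 0.2,
                                                   40_000.0, rng,
                                                   n_draws=n_days)])
        table, models = daily_variograms(resid, coords,
                                         np.arange(1, n_days + 1))
        assert len(table) == n_days
        assert table["kriged"].all()

    def test_identical_days_give_identical_surfaces(self, rng):
        coords = _grid_coords(5, 20_000.0)
        one_day = simulate_gaussian_field(coords, 0.01, 0.2, 40_000.0, rng)
        resid = np.tile(one_day[:, None], (1, 3))
        grid = GridSpec(0, 0, 80_000, 80_000, 20_000)
        stack, table = daily_surfaces(resid, coords, np.arange(1, 4), grid)
        np.testing.assert_allclose(stack[0], stack[1])
        np.testing.assert_allclose(stack[0], stack[2])

    def test_sparse_day_produces_zero_surface(self, rng):
        coords = _grid_coords(5, 20_000.0)
        resid = np.full((25, 2), np.nan)
        resid[:, 0] = simulate_gaussian_field(coords, 0.01, 0.2, 40_000.0, rng)
        resid[:5, 1] = 1.0                      # only 5 stations report
        grid = GridSpec(0, 0, 80_000, 80_000, 20_000)
        stack, table = daily_surfaces(resid, coords, np.arange(1, 3), grid)
        assert not table.loc[1, "kriged"]
        np.testing.assert_allclose(stack[1], 0.0)

    def test_block_mean_of_constant_surface(self):
        grid = GridSpec(0, 0, 100_000, 100_000, 10_000)
        surface = np.full(grid.shape, 7.5)
        poly = box(20_000, 20_000, 70_000, 60_000)
        assert block_mean(surface, grid, poly) == pytest.approx(7.5)

    def test_block_mean_two_cells(self):
        grid = GridSpec(0, 0, 20_000, 10_000, 10_000)
        surface = np.array([[10.0, 20.0]])
        poly = box(0, 0, 20_000, 10_000)
        assert block_mean(surface, grid, poly) == pytest.approx(15.0)

    def test_block_mean_refinement_consistent(self, rng):
        grid = GridSpec(0, 0, 100_000, 100_000, 5_000)
        xx, yy = np.meshgrid(grid.xs, grid.ys)
        surface = np.sin(xx / 3e4) + np.cos(yy / 4e4)
        poly = box(10_000, 10_000, 90_000, 90_000)
        m1 = block_mean(surface, grid, poly, refine=1)
        m2 = block_mean(surface, grid, poly, refine=2)
        assert abs(m2 - m1) < 0.01 * max(abs(m1), 1.0)

    def test_empty_polygon_rejected(self):
        grid = GridSpec(0, 0, 10_000, 10_000, 1_000)
        with pytest.raises(ValueError, match="intersect"):
            block_mean(np.zeros(grid.shape), grid,
                       box(1e6, 1e6, 2e6, 2e6))


def test_day_of_year_surface_lookup(rng):
    from pm25ens import surface_for_day_of_year

    stack = rng.standard_normal((5, 3, 3))
    days = np.array([1, 90, 180, 270, 360])
    surf, extrapolated = surface_for_day_of_year(stack, days, 182)
    np.testing.assert_array_equal(surf, stack[2])
    assert extrapolated
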