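import numpy as np
import pytest
from scipy import stats

import mimevol as mv
from mimevol.spatial import InfeasibleThresholdError, haversine_km


def grid_coords(n_side, spacing_deg=0.5, lat0=0.0):
    xs, ys = np.meshgrid(
        np.arange(n_side) * spacing_deg - 60, np.arange(n_side) * spacing_deg + lat0
    )
    return np.column_stack([xs.ravel(), ys.ravel()])


class TestNeighborWeights:
    def test_two_cells_sole_neighbors(self):
        # ~100 km apart (0.9 degrees latitude)
        coords = np.array([[0.0, 0.0], [0.0, 0.9]])
        w = mv.build_neighbor_weights(coords, 150.0, "binary")
        np.testing.assert_allclose(w.W, [[0, 1], [1, 0]])

    def test_infeasible_threshold_names_cell(self):
        coords = np.array([[0.0, 0.0], [0.0, 0.9]])  # ~100 km apart
        with pytest.raises(InfeasibleThresholdError, match="cell"):
            mv.build_neighbor_weights(coords, 50.0)

    def test_inverse_distance_matches_haversine(self):
        coords = grid_coords(4)
        thr = mv.min_feasible_threshold(coords)
        w = mv.build_neighbor_weights(coords, thr, "inverse-distance")
        d = haversine_km(coords)
        nz = w.base > 0
        np.testing.assert_allclose(w.base[nz], 1.0 / d[nz], atol=1e-9)

    def test_rows_standardized_and_connectivity_symmetric(self):
        coords = grid_coords(5)
        thr = mv.min_feasible_threshold(coords)
        for style in ("binary", "distance", "inverse-distance"):
            w = mv.build_neighbor_weights(coords, thr, style)
            np.testing.assert_allclose(w.W.sum(axis=1), 1.0, atol=1e-12)
            assert np.all((w.base > 0) == (w.base.T > 0))
            assert np.all(np.diag(w.W) == 0)

    def test_min_feasible_threshold_is_a_step_multiple(self):
        coords = grid_coords(4)
        thr = mv.min_feasible_threshold(coords, step_km=50.0)
        assert thr % 50 == 0
        mv.build_neighbor_weights(coords, thr)  # must be feasible


class TestSARError:
    def test_perfect_fit_recovers_beta_exactly(self):
        coords = grid_coords(6)
        w = mv.build_neighbor_weights(coords, mv.min_feasible_threshold(coords))
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (len(coords), 2))
        beta = np.array([2.0, -1.0, 0.5])
        y = beta[0] + X @ beta[1:]
        fit = mv.fit_sar_error(y, X, w)
        np.testing.assert_allclose(fit.params, beta, atol=1e-8)

    def test_iid_data_close_to_ols(self):
        coords = grid_coords(12)
        w = mv.build_neighbor_weights(coords, mv.min_feasible_threshold(coords))
        rng = np.random.default_rng(2)
        n = len(coords)
        X = rng.normal(0, 1, (n, 2))
        Xf = np.column_stack([np.ones(n), X])
        y = Xf @ np.array([1.0, 2.0, -0.5]) + rng.normal(0, 1, n)
        fit = mv.fit_sar_error(y, X, w)
        bols, *_ = np.linalg.lstsq(Xf, y, rcond=None)
        assert np.abs(fit.params - bols).max() < 1e-2

    def test_aic_bookkeeping(self):
        coords = grid_coords(5)
        w = mv.build_neighbor_weights(coords, mv.min_feasible_threshold(coords))
        rng = np.random.default_rng(3)
        y = rng.normal(0, 1, len(coords))
        X = rng.normal(0, 1, (len(coords), 1))
        fit = mv.fit_sar_error(y, X, w)
        k = 2 + 2  # intercept + slope + lambda + sigma2
        assert fit.aic == pytest.approx(2 * k - 2 * fit.loglik, abs=1e-10)
        assert len(fit.residuals) == len(coords)

    def test_collinear_predictors_rejected(self):
        coords = grid_coords(4)
        w = mv.build_neighbor_weights(coords, mv.min_feasible_threshold(coords))
        x = np.arange(len(coords), dtype=float)
        with pytest.raises(ValueError):
            mv.fit_sar_error(x, np.column_stack([x, 2 * x]), w)


class TestSelectNeighborhood:
    def test_matches_exhaustive_enumeration(self):
        coords = grid_coords(6)
        rng = np.random.default_rng(4)
        n = len(coords)
        X = rng.normal(0, 1, (n, 1))
        y = 1.0 + 2.0 * X[:, 0] + rng.normal(0, 1, n)
        best, table = mv.select_neighborhood(y, X, coords, max_steps=3)
        ok = table.dropna(subset=["aic"])
        assert best.aic == pytest.approx(ok["aic"].min())
        assert len(table) == 3 * 3  # thresholds x styles

    def test_reproducible(self):
        coords = grid_coords(5)
        rng = np.random.default_rng(5)
        y = rng.normal(0, 1, len(coords))
        X = rng.normal(0, 1, (len(coords), 1))
        _, t1 = mv.select_neighborhood(y, X, coords, max_steps=2)
        _, t2 = mv.select_neighborhood(y, X, coords, max_steps=2)
        np.testing.assert_array_equal(t1["aic"].to_numpy(), t2["aic"].to_numpy())


class TestMoransI:
    def test_constant_variable_rejected(self):
        coords = grid_coords(4)
        w = mv.build_neighbor_weights(coords, mv.min_feasible_threshold(coords))
        with pytest.raises(ValueError):
            mv.morans_i(np.ones(len(coords)), w)

    def test_checkerboard_strongly_negative(self):
        xs, ys = np.meshgrid(np.arange(4.0), np.arange(4.0))
        coords = np.column_stack([xs.ravel(), ys.ravel()])
        w = mv.build_neighbor_weights(coords, 120.0, "binary")  # rook at 1 deg
        chk = ((-1.0) ** (xs + ys)).ravel()
        i_obs, _ = mv.morans_i(chk, w, n_perm=0)
        assert i_obs == pytest.approx(-1.0, abs=1e-12)

    def test_gradient_positive(self):
        coords = np.column_stack([np.arange(16) * 0.5 - 70, np.zeros(16)])
        w = mv.build_neighbor_weights(coords, 60.0, "binary")
        i_obs, _ = mv.morans_i(np.arange(16.0), w, n_perm=0)
        assert i_obs > 0

    def test_null_p_uniform(self):
        coords = grid_coords(5)
        w = mv.build_neighbor_weights(coords, mv.min_feasible_threshold(coords))
        rng = np.random.default_rng(6)
        ps = []
        for rep in range(200):
            x = rng.normal(0, 1, len(coords))
            _, p = mv.morans_i(x, w, n_perm=199, seed=rep)
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestPermutationTest:
    def test_null_preserves_totals_and_model_raster(self, small_biogeo):
        sim = small_biogeo
        spec = mv.GridSpec.covering(sim.continent.bounds, 2.0)
        onland = spec.onland_mask(sim.continent)
        pres = mv.rasterize_presence(sim.range_polygons(), spec, onland)
        species = sorted(pres)
        tags = np.array([sim.tags[sp] for sp in species])
        cols = np.stack([pres[sp][onland] for sp in species])
        model_counts = cols[tags == "model"].sum(axis=0)
        total_counts = cols.sum(axis=0)
        # shuffling non-model labels cannot change either quantity
        rng = np.random.default_rng(0)
        non_model = np.where(tags != "model")[0]
        for _ in range(20):
            perm = non_model[rng.permutation(len(non_model))]
            reordered = cols.copy()
            reordered[non_model] = cols[perm]
            np.testing.assert_array_equal(reordered.sum(axis=0), total_counts)
            np.testing.assert_array_equal(
                reordered[tags == "model"].sum(axis=0), model_counts
            )

    def test_p_counting_convention(self, small_biogeo):
        sim = small_biogeo
        spec = mv.GridSpec.covering(sim.continent.bounds, 2.0)
        onland = spec.onland_mask(sim.continent)
        pres = mv.rasterize_presence(sim.range_polygons(), spec, onland)
        res = mv.permutation_test(pres, sim.tags, onland, n_iter=99, seed=3)
        b = int((res.null_slopes >= res.observed_slope).sum())
        assert res.p == b / 99
        assert res.p_conservative == (b + 1) / 100
        assert 0 <= res.p <= 1

    def test_requires_both_tags(self, small_biogeo):
        sim = small_biogeo
        spec = mv.GridSpec.covering(sim.continent.bounds, 2.0)
        onland = spec.onland_mask(sim.continent)
        pres = mv.rasterize_presence(sim.range_polygons(), spec, onland)
        all_other = {sp: "other" for sp in sim.tags}
        with pytest.raises(ValueError):
            mv.permutation_test(pres, all_other, onland, n_iter=10, seed=0)


class TestResidualZ:
    @pytest.mark.parametrize("f,fbar,expected", [(12, 9, 1.0), (4, 4, 0.0), (0, 4, -2.0)])
    def test_direct_formula(self, f, fbar, expected):
        assert mv.residual_z(f, fbar) == pytest.approx(expected)

    def test_zero_null_mean_masked(self):
        z = mv.residual_z(np.array([3.0]), np.array([0.0]))
        assert np.isnan(z[0])

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            mv.residual_z(-1.0, 4.0)

    def test_null_sd_denominator_option(self):
        assert mv.residual_z(10.0, 6.0, null_sd=2.0) == pytest.approx(2.0)
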