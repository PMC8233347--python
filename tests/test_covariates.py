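import numpy as np
import pandas as pd
import pytest

import reefvuln as rv
from reefvuln.covariates import _gvif_from_design

from conftest import make_stack_from_arrays


def _sites_df(grid):
    centers = grid.sea_centers()
    return pd.DataFrame({"lat": centers[:, 0], "lon": centers[:, 1]})


class TestRugosity:
    def test_flat_seabed_has_zero_slope(self):
        slope = rv.derive_rugosity(np.full((5, 5), -30.0), cell_size=0.08)
        np.testing.assert_allclose(slope, 0.0, atol=1e-12)

    def test_inclined_plane_matches_analytic_slope(self):
        # depth falls by g per cell along columns -> slope arctan(g/cell)
        g, cell = 2.0, 0.5
        b = -np.tile(g * np.arange(7.0), (6, 1))
        slope = rv.derive_rugosity(b, cell_size=cell)
        expected = np.degrees(np.arctan(g / cell))
        np.testing.assert_allclose(slope[1:-1, 1:-1], expected, rtol=1e-10)

    def test_slope_is_nonnegative(self):
        rng = np.random.default_rng(0)
        slope = rv.derive_rugosity(rng.normal(-50, 10, (8, 8)), cell_size=1.0)
        assert np.nanmin(slope) >= 0

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            rv.derive_rugosity(np.full((4, 4), np.nan))

    def test_too_small_raster_rejected(self):
        with pytest.raises(ValueError, match="3x3"):
            rv.derive_rugosity(np.zeros((2, 5)))


class TestRegrid:
    def test_constant_raster_stays_constant(self):
        out = rv.regrid(np.full((6, 6), 4.2), 0.04, 0.08)
        np.testing.assert_allclose(out, 4.2)

    def test_block_mean_of_known_values(self):
        out = rv.regrid(np.array([[1.0, 2.0], [3.0, 4.0]]), 0.04, 0.08)
        assert out.shape == (1, 1)
        assert out[0, 0] == pytest.approx(2.5)

    def test_missing_aware_mean(self):
        out = rv.regrid(np.array([[1.0, 2.0], [3.0, np.nan]]), 0.04, 0.08)
        assert out[0, 0] == pytest.approx(2.0)

    def test_finer_target_rejected(self):
        with pytest.raises(ValueError, match="finer"):
            rv.regrid(np.zeros((4, 4)), 0.08, 0.04)

    def test_noninteger_factor_rejected(self):
        with pytest.raises(ValueError, match="whole number"):
            rv.regrid(np.zeros((4, 4)), 0.05, 0.08)

    def test_mean_conserved_when_blocks_divide_evenly(self):
        rng = np.random.default_rng(1)
        r = rng.normal(size=(8, 12))
        out = rv.regrid(r, 0.02, 0.08)
        assert out.mean() == pytest.approx(r.mean(), abs=1e-10)


class TestStandardize:
    def test_zscores_over_sea_cells(self, allsea_grid):
        stack = rv.simulate_covariates(allsea_grid, seed=1)
        std_stack, params = rv.standardize(stack)
        for name in std_stack.names:
            v = std_stack.sea_values(name)
            assert abs(v.mean()) < 1e-10
            assert abs(v.std() - 1) < 1e-10

    def test_future_shift_remains_visible(self, allsea_grid):
        stack = rv.simulate_covariates(allsea_grid, seed=1)
        _, params = rv.standardize(stack)
        fut = rv.make_future_covariates(stack, "end_century")
        std_fut = params.apply(fut)
        std_cur = params.apply(stack)
        shift = std_fut.sea_values("sst") - std_cur.sea_values("sst")
        np.testing.assert_allclose(shift, 3.0 / params.sds["sst"], rtol=1e-10)

    def test_constant_layer_rejected_by_name(self, allsea_grid):
        stack = make_stack_from_arrays(
            allsea_grid, flatvar=np.full(allsea_grid.n_sea, 2.0)
        )
        with pytest.raises(ValueError, match="flatvar"):
            rv.standardize(stack)


class TestRescaleCover:
    @pytest.mark.parametrize(
        "frac,total,expected", [(0.5, 40.0, 20.0), (1.0, 33.0, 33.0), (0.0, 80.0, 0.0)]
    )
    def test_product_rule(self, frac, total, expected):
        assert rv.rescale_cover(frac, total) == pytest.approx(expected)

    @pytest.mark.parametrize("frac,total", [(1.5, 50), (-0.1, 50), (0.5, 101), (0.5, -1)])
    def test_out_of_range_rejected(self, frac, total):
        with pytest.raises(ValueError):
            rv.rescale_cover(frac, total)


class TestPearson:
    def test_self_and_negated(self, allsea_grid):
        n = allsea_grid.n_sea
        rng = np.random.default_rng(2)
        x = rng.normal(size=n)
        stack = make_stack_from_arrays(allsea_grid, x=x, negx=-x)
        corr = rv.pearson_matrix(stack, _sites_df(allsea_grid))
        assert corr.loc["x", "x"] == pytest.approx(1.0)
        assert corr.loc["x", "negx"] == pytest.approx(-1.0)

    def test_independent_normals_are_uncorrelated(self):
        g = rv.make_grid((0, 8, 0, 8), 0.08, {"kind": "all_sea"}, seed=0)
        rng = np.random.default_rng(3)
        stack = make_stack_from_arrays(
            g, a=rng.normal(size=g.n_sea), b=rng.normal(size=g.n_sea)
        )
        corr = rv.pearson_matrix(stack, _sites_df(g))
        assert abs(corr.loc["a", "b"]) < 0.05

    def test_too_few_rows_rejected(self, allsea_grid):
        stack = make_stack_from_arrays(allsea_grid, a=np.arange(allsea_grid.n_sea, dtype=float))
        with pytest.raises(ValueError, match="at least 3"):
            rv.pearson_matrix(stack, _sites_df(allsea_grid).iloc[:2])


class TestGvif:
    def test_orthogonal_predictors_have_unit_vif(self, allsea_grid):
        n = allsea_grid.n_sea
        x = np.ones(n)
        x[: n // 2] = -1.0
        y = np.tile([1.0, -1.0], n // 2 + 1)[:n]
        y -= y.mean()
        y -= x * (x @ y) / (x @ x)  # exactly orthogonal
        stack = make_stack_from_arrays(allsea_grid, x=x, y=y)
        tab = rv.gvif(stack, _sites_df(allsea_grid))
        np.testing.assert_allclose(tab["gvif"], 1.0, atol=1e-10)

    def test_known_correlation_matches_closed_form(self, allsea_grid):
        # |r| = 0.9 -> VIF = 1/(1 - 0.81) = 5.2631...
        n = allsea_grid.n_sea
        rng = np.random.default_rng(4)
        # orthonormalize against the intercept so the sample r is exact
        q, _ = np.linalg.qr(np.column_stack([np.ones(n), rng.normal(size=(n, 2))]))
        x, w = q[:, 1], q[:, 2]
        y = 0.9 * x + np.sqrt(1 - 0.81) * w
        stack = make_stack_from_arrays(allsea_grid, x=x, y=y)
        tab = rv.gvif(stack, _sites_df(allsea_grid))
        np.testing.assert_allclose(tab["gvif"], 1.0 / (1.0 - 0.81), rtol=1e-8)
        np.testing.assert_allclose(
            tab["gvif_corrected"], np.sqrt(1.0 / (1.0 - 0.81)), rtol=1e-8
        )

    def test_exact_copy_is_infinite_not_an_exception(self, allsea_grid):
        rng = np.random.default_rng(5)
        x = rng.normal(size=allsea_grid.n_sea)
        stack = make_stack_from_arrays(allsea_grid, x=x, xcopy=x.copy())
        tab = rv.gvif(stack, _sites_df(allsea_grid))
        assert np.isinf(tab.loc["x", "gvif"])


class TestScreening:
    def test_independent_variables_all_retained(self, allsea_grid):
        rng = np.random.default_rng(6)
        n = allsea_grid.n_sea
        stack = make_stack_from_arrays(
            allsea_grid,
            a=rng.normal(size=n), b=rng.normal(size=n), c=rng.normal(size=n),
        )
        rep = rv.screen_covariates(stack, _sites_df(allsea_grid))
        assert rep.removed == []
        assert sorted(rep.retained) == ["a", "b", "c"]

    def test_exact_copy_forces_single_removal(self, allsea_grid):
        rng = np.random.default_rng(7)
        n = allsea_grid.n_sea
        x = rng.normal(size=n)
        stack = make_stack_from_arrays(allsea_grid, x=x, xcopy=x.copy(), w=rng.normal(size=n))
        rep = rv.screen_covariates(stack, _sites_df(allsea_grid))
        assert "w" in rep.retained
        assert len(rep.retained) == 2
        assert len(rep.removed) == 1
        assert rep.removed[0][0] in ("x", "xcopy")

    def test_postconditions_on_random_stacks(self, allsea_grid):
        # retained sets must satisfy both thresholds by brute-force recheck
        n = allsea_grid.n_sea
        for trial in range(20):
            rng = np.random.default_rng(100 + trial)
            base = rng.normal(size=(n, 3))
            layers = {
                "a": base[:, 0],
                "b": 0.9 * base[:, 0] + 0.4 * rng.normal(size=n),
                "c": base[:, 1],
                "d": base[:, 1] + base[:, 2] + 0.2 * rng.normal(size=n),
                "e": base[:, 2],
            }
            stack = make_stack_from_arrays(allsea_grid, **layers)
            rep = rv.screen_covariates(stack, _sites_df(allsea_grid))
            if len(rep.retained) >= 2:
                X = pd.DataFrame({k: layers[k] for k in rep.retained})
                corr = X.corr().abs().to_numpy()
                np.fill_diagonal(corr, 0)
                assert corr.max() <= 0.70 + 1e-12
                assert _gvif_from_design(X)["gvif_corrected"].max() <= 3.0 + 1e-12
            assert sorted(rep.retained + [r[0] for r in rep.removed]) == sorted(layers)

    def test_screening_is_idempotent(self, allsea_grid):
        rng = np.random.default_rng(8)
        n = allsea_grid.n_sea
        x = rng.normal(size=n)
        layers = {"x": x, "y": 0.95 * x + 0.1 * rng.normal(size=n), "w": rng.normal(size=n)}
        stack = make_stack_from_arrays(allsea_grid, **layers)
        rep1 = rv.screen_covariates(stack, _sites_df(allsea_grid))
        stack2 = make_stack_from_arrays(allsea_grid, **{k: layers[k] for k in rep1.retained})
        rep2 = rv.screen_covariates(stack2, _sites_df(allsea_grid))
        assert rep2.removed == []
        assert sorted(rep2.retained) == sorted(rep1.retained)
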