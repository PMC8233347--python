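import numpy as np
import pytest

import reefvuln as rv
from reefvuln.predict import ProbabilitySurface
from reefvuln.vulnerability import PAPER_THRESHOLDS, VulnerabilitySurface


def surface_from(grid, sea_vals, scenario="current", kind="occurrence"):
    v = np.full(grid.shape, np.nan)
    v[grid.mask] = sea_vals
    return ProbabilitySurface(
        grid=grid, scenario=scenario, response_kind=kind,
        values=v, uncertainty=np.zeros(grid.shape),
    )


@pytest.fixture
def grid4():
    return rv.make_grid((0.0, 0.16, 0.0, 0.16), 0.08, {"kind": "all_sea"}, seed=0)


class TestMaxStandardize:
    def test_division_by_maximum(self, grid4):
        s = surface_from(grid4, np.array([0.2, 0.4, 0.8, 0.8]))
        out = rv.max_standardize(s)
        np.testing.assert_allclose(out.values[grid4.mask], [0.25, 0.5, 1.0, 1.0])
        assert np.nanmax(out.values) == pytest.approx(1.0)

    def test_scale_invariance(self, grid4):
        vals = np.array([0.1, 0.5, 0.7, 0.9])
        a = rv.max_standardize(surface_from(grid4, vals))
        b = rv.max_standardize(surface_from(grid4, 7.3 * vals))
        np.testing.assert_allclose(a.values[grid4.mask], b.values[grid4.mask])

    def test_all_zero_rejected(self, grid4):
        with pytest.raises(ValueError, match="positive"):
            rv.max_standardize(surface_from(grid4, np.zeros(4)))


class TestOverlap:
    def test_product_values(self, grid4):
        one = surface_from(grid4, np.array([1.0, 1.0, 1.0, 1.0]))
        half = surface_from(grid4, np.array([0.5, 0.5, 0.5, 1.0]), kind="cover")
        zero = surface_from(grid4, np.array([0.0, 1.0, 0.5, 1.0]), kind="bleaching")
        v = rv.overlap(one, half, zero)
        np.testing.assert_allclose(v.values[grid4.mask], [0.0, 0.5, 0.25, 1.0])

    def test_annihilation_and_unit(self, grid4):
        ones = np.ones(4)
        s = surface_from(grid4, ones)
        v = rv.overlap(s, surface_from(grid4, ones), surface_from(grid4, ones))
        np.testing.assert_allclose(v.values[grid4.mask], 1.0)

    def test_unstandardized_input_rejected(self, grid4):
        good = surface_from(grid4, np.array([0.2, 0.5, 1.0, 0.7]))
        bad = surface_from(grid4, np.array([0.2, 0.5, 0.9, 0.7]))
        with pytest.raises(ValueError, match="max-standardized"):
            rv.overlap(good, bad, good)

    def test_scenario_mismatch_rejected(self, grid4):
        a = surface_from(grid4, np.ones(4))
        b = surface_from(grid4, np.ones(4), scenario="end_century")
        with pytest.raises(ValueError, match="scenario"):
            rv.overlap(a, b, a)

    def test_monotone_in_each_input(self, grid4):
        rng = np.random.default_rng(0)
        x = rng.uniform(0.1, 1, 4); x[-1] = 1.0
        y = rng.uniform(0.1, 1, 4); y[-1] = 1.0
        z = rng.uniform(0.1, 1, 4); z[-1] = 1.0
        base = rv.overlap(surface_from(grid4, x), surface_from(grid4, y),
                          surface_from(grid4, z))
        y2 = np.minimum(y * 1.1, 1.0)
        more = rv.overlap(surface_from(grid4, x), surface_from(grid4, y2),
                          surface_from(grid4, z))
        assert np.all(more.values[grid4.mask] >= base.values[grid4.mask] - 1e-12)


class TestThresholds:
    def test_linear_interpolation_quartiles(self, grid4):
        v = VulnerabilitySurface(grid4, "current",
                                 values=surface_from(grid4, np.array([0.1, 0.2, 0.3, 0.4])).values)
        q_low, q_high = rv.quartile_thresholds(v)
        assert q_low == pytest.approx(0.175)
        assert q_high == pytest.approx(0.325)

    def test_constant_surface_degenerates(self, grid4):
        v = VulnerabilitySurface(grid4, "current",
                                 values=surface_from(grid4, np.full(4, 0.3)).values)
        assert rv.quartile_thresholds(v) == (pytest.approx(0.3), pytest.approx(0.3))

    def test_override_returns_literature_bounds_verbatim(self, grid4):
        v = VulnerabilitySurface(grid4, "current",
                                 values=surface_from(grid4, np.array([0.1, 0.2, 0.3, 0.4])).values)
        assert rv.quartile_thresholds(v, override=PAPER_THRESHOLDS) == (0.21, 0.78)

    def test_too_few_cells_rejected(self):
        g = rv.make_grid((0, 0.16, 0, 0.08), 0.08, {"kind": "all_sea"}, seed=0)
        v = VulnerabilitySurface(g, "current",
                                 values=surface_from(g, np.array([0.1, 0.2])).values)
        with pytest.raises(ValueError, match="at least 4"):
            rv.quartile_thresholds(v)


class TestClassify:
    def test_boundary_values_with_literature_thresholds(self, grid4):
        v = VulnerabilitySurface(
            grid4, "current",
            values=surface_from(grid4, np.array([0.80, 0.10, 0.78, 0.205])).values,
        )
        classified, report = rv.classify(v, (0.21, 0.78))
        cls = classified.class_map[grid4.mask]
        assert cls[0] == 2  # 0.80 -> hotspot
        assert cls[1] == 0  # 0.10 -> low
        assert cls[2] == 2  # 0.78 on the bound -> hotspot (half-open)
        assert cls[3] == 0  # 0.205 < 0.21 -> low

    def test_worked_four_cell_example(self, grid4):
        v = VulnerabilitySurface(
            grid4, "current",
            values=surface_from(grid4, np.array([0.1, 0.3, 0.5, 0.9])).values,
        )
        _, report = rv.classify(v, (0.21, 0.78))
        assert report.percentages == {"low": 25.0, "intermediate": 50.0, "hotspot": 25.0}
        assert sum(report.percentages.values()) == pytest.approx(100.0, abs=1e-9)

    def test_inverted_thresholds_rejected(self, grid4):
        v = VulnerabilitySurface(grid4, "current",
                                 values=surface_from(grid4, np.full(4, 0.5)).values)
        with pytest.raises(ValueError, match="inverted"):
            rv.classify(v, (0.8, 0.2))


class TestAreaChange:
    def _report(self, grid4, vals, thresholds=(0.21, 0.78), scenario="current"):
        v = VulnerabilitySurface(grid4, scenario,
                                 values=surface_from(grid4, np.asarray(vals)).values)
        return rv.classify(v, thresholds)[1]

    def test_identical_reports_zero_change(self, grid4):
        r = self._report(grid4, [0.1, 0.3, 0.5, 0.9])
        ch = rv.class_area_change(r, r)
        np.testing.assert_allclose(ch["percent_change"], 0.0)

    def test_halved_low_class_is_minus_fifty(self):
        g = rv.make_grid((0, 0.16, 0, 0.32), 0.08, {"kind": "all_sea"}, seed=0)  # 8 cells
        cur = rv.classify(VulnerabilitySurface(
            g, "current", values=_vals(g, [0.1, 0.1, 0.1, 0.1, 0.5, 0.5, 0.9, 0.9])), (0.21, 0.78))[1]
        fut = rv.classify(VulnerabilitySurface(
            g, "end_century", values=_vals(g, [0.1, 0.1, 0.5, 0.5, 0.5, 0.5, 0.9, 0.9])), (0.21, 0.78))[1]
        ch = rv.class_area_change(cur, fut).set_index("class")
        assert ch.loc["low", "percent_change"] == pytest.approx(-50.0)

    def test_total_area_conserved(self, grid4):
        cur = self._report(grid4, [0.1, 0.3, 0.5, 0.9])
        fut = self._report(grid4, [0.3, 0.5, 0.9, 0.9], scenario="end_century")
        assert cur.total == fut.total == 4

    def test_empty_class_flagged_not_crashed(self, grid4):
        cur = self._report(grid4, [0.3, 0.4, 0.5, 0.6])  # no low, no hotspot
        fut = self._report(grid4, [0.1, 0.4, 0.5, 0.9], scenario="end_century")
        ch = rv.class_area_change(cur, fut).set_index("class")
        assert bool(ch.loc["low", "undefined"])
        assert np.isnan(ch.loc["low", "percent_change"])


def _vals(grid, sea_vals):
    v = np.full(grid.shape, np.nan)
    v[grid.mask] = np.asarray(sea_vals, dtype=float)
    return v


class TestKde:
    def _grid(self):
        return rv.make_grid((0, 1.6, 0, 1.6), 0.08, {"kind": "all_sea"}, seed=0)

    def test_identical_surfaces_zero_change(self):
        g = self._grid()
        rng = np.random.default_rng(1)
        vals = rng.uniform(0, 1, g.n_sea)
        a = surface_from(g, vals)
        b = surface_from(g, vals.copy(), scenario="end_century")
        out = rv.kde_compare([a, b], thresholds=(0.25, 0.75))
        row = out.summary.iloc[0]
        assert row["mean_percent_change"] == pytest.approx(0.0, abs=1e-12)
        assert row["hotspot_mass_change"] == pytest.approx(0.0, abs=1e-12)

    def test_densities_integrate_to_one(self):
        g = self._grid()
        rng = np.random.default_rng(2)
        a = surface_from(g, rng.beta(2, 5, g.n_sea))
        b = surface_from(g, rng.beta(5, 2, g.n_sea), scenario="end_century")
        out = rv.kde_compare([a, b])
        for d in out.densities.values():
            assert np.trapezoid(d, out.eval_grid) == pytest.approx(1.0, abs=1e-3)

    def test_shift_moves_the_mode(self):
        g = self._grid()
        rng = np.random.default_rng(3)
        vals = rng.normal(0.4, 0.05, g.n_sea)
        a = surface_from(g, vals)
        b = surface_from(g, vals + 0.1, scenario="end_century")
        out = rv.kde_compare([a, b])
        step = out.eval_grid[1] - out.eval_grid[0]
        mode_a = out.eval_grid[np.argmax(out.densities["current"])]
        mode_b = out.eval_grid[np.argmax(out.densities["end_century"])]
        assert abs((mode_b - mode_a) - 0.1) <= step + 1e-12

    def test_single_surface_rejected(self):
        g = self._grid()
        with pytest.raises(ValueError, match="at least 2"):
            rv.kde_compare([surface_from(g, np.ones(g.n_sea))])
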