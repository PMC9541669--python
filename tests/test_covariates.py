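"""Sighting rates, standardization, and the kriged snow index."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from mooseipm.covariates import (
    Variogram,
    fit_variogram,
    ordinary_kriging,
    per_day_rate,
    snow_index,
    standardize,
    station_season_sums,
)
from mooseipm.exceptions import (
    DegenerateCovariateError,
    InsufficientDataError,
    MissingEffortError,
)


class TestPerDayRate:
    @pytest.mark.parametrize("count, days, expected", [
        (0, 100, 0.0), (40, 160, 0.25)])
    def test_values(self, count, days, expected):
        assert per_day_rate(count, days) == pytest.approx(expected)

    def test_scale_invariance(self):
        for c in (2.0, 7.5):
            assert per_day_rate(c * 40, c * 160) == pytest.approx(0.25)

    def test_missing_effort(self):
        with pytest.raises(MissingEffortError):
            per_day_rate(10, 0)


class TestStandardize:
    def test_unit_variance(self):
        z, _ = standardize([1, 2, 3, 4, 5])
        assert np.std(z, ddof=1) == pytest.approx(1.0)
        assert np.mean(z) == pytest.approx(0.0)

    def test_scale_only_option(self):
        x = np.array([2.0, 4.0, 8.0])
        z, scale = standardize(x, center=False)
        assert np.std(z, ddof=1) == pytest.approx(1.0)
        assert scale.center == 0.0
        assert np.all(z > 0)

    def test_round_trip(self):
        rng = np.random.default_rng(0)
        x = rng.normal(10, 3, 50)
        z, scale = standardize(x)
        assert np.allclose(scale.invert(z), x, atol=1e-12)

    def test_constant_series_rejected(self):
        with pytest.raises(DegenerateCovariateError):
            standardize([3.0, 3.0, 3.0])


def _stations_frame(xy, totals):
    rows = []
    for i, ((x, y), v) in enumerate(zip(xy, totals)):
        rows.append({"station_id": f"S{i}", "x": x, "y": y,
                     "week": 45, "depth": v})
    return pd.DataFrame(rows)


class TestKriging:
    def test_exact_interpolation_at_stations(self):
        rng = np.random.default_rng(4)
        xy = rng.uniform(0, 100_000, (20, 2))
        vals = 200 + 30 * np.sin(xy[:, 0] / 2e4) + rng.normal(0, 5, 20)
        pred = ordinary_kriging(xy, vals, xy)
        assert np.allclose(pred, vals, atol=1e-6)

    def test_constant_field(self):
        xy = np.array([[0, 0], [1e4, 0], [0, 1e4], [1e4, 1e4]], float)
        vals = np.full(4, 250.0)
        targets = np.array([[5e3, 5e3], [2e3, 9e3]])
        pred = ordinary_kriging(xy, vals, targets,
                                Variogram(0.0, 1.0, 5e3))
        assert np.allclose(pred, 250.0, atol=1e-8)

    def test_weights_sum_preserves_mean_shift(self):
        # adding a constant to all station values shifts predictions by it
        rng = np.random.default_rng(5)
        xy = rng.uniform(0, 5e4, (12, 2))
        vals = rng.normal(100, 20, 12)
        targets = rng.uniform(0, 5e4, (7, 2))
        vg = fit_variogram(xy, vals)
        a = ordinary_kriging(xy, vals, targets, vg)
        b = ordinary_kriging(xy, vals + 55.0, targets, vg)
        assert np.allclose(b - a, 55.0, atol=1e-6)

    def test_too_few_stations(self):
        with pytest.raises(InsufficientDataError):
            ordinary_kriging(np.zeros((2, 2)), np.zeros(2), np.zeros((1, 2)))


class TestSnowIndex:
    UNITS = {"A": box(0, 0, 50_000, 50_000), "B": box(50_000, 0, 100_000, 50_000)}

    def test_constant_field_gives_constant_index(self):
        xy = [(10_000, 10_000), (60_000, 20_000), (40_000, 40_000),
              (90_000, 10_000)]
        st = _stations_frame(xy, [300.0] * 4)
        idx = snow_index(st, self.UNITS, grid_resolution=10_000)
        assert np.allclose(idx.to_numpy(), 300.0, atol=1e-6)

    def test_weekly_sums_respect_window(self):
        st = pd.DataFrame({
            "station_id": ["S0"] * 3, "x": [0.0] * 3, "y": [0.0] * 3,
            "week": [39, 45, 52], "depth": [99.0, 10.0, 20.0]})
        sums = station_season_sums(st)
        assert sums.loc[0, "total"] == pytest.approx(30.0)  # week 39 excluded

    def test_linear_trend_matches_polygon_mean(self):
        # plane v = 100 + 0.002 x + 0.001 y sampled on a dense station grid;
        # the unit mean must match the analytic mean of the plane over each
        # polygon (its centroid value) within 2%
        g = np.linspace(0, 100_000, 9)
        xy = [(x, y) for x in g for y in np.linspace(0, 50_000, 5)]
        vals = [100 + 0.002 * x + 0.001 * y for x, y in xy]
        st = _stations_frame(xy, vals)
        idx = snow_index(st, self.UNITS, grid_resolution=5_000)
        for name, poly in self.UNITS.items():
            c = poly.centroid
            expected = 100 + 0.002 * c.x + 0.001 * c.y
            assert idx[name] == pytest.approx(expected, rel=0.02)

    def test_insufficient_stations(self):
        st = _stations_frame([(0, 0), (1, 1)], [10, 20])
        with pytest.raises(InsufficientDataError):
            snow_index(st, self.UNITS)

    def test_geojson_polygon_round_trip(self, tmp_path):
        import json

        from shapely.geometry import mapping

        from mooseipm.covariates import load_unit_polygons

        gj = {"type": "FeatureCollection", "features": [
            {"type": "Feature", "properties": {"unit_id": name},
             "geometry": mapping(poly)} for name, poly in self.UNITS.items()]}
        path = tmp_path / "units.geojson"
        path.write_text(json.dumps(gj))
        polys = load_unit_polygons(str(path))
        assert set(polys) == set(self.UNITS)
        for name in self.UNITS:
            assert polys[name].equals(self.UNITS[name])
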