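"""Covariate construction: sighting rates, standardization, snow index.

Per-day sighting rates divide seasonal counts by total hunter-days.  All
predictors are standardized (default: centered and scaled to unit variance)
with the transform stored so fitted coefficients can be mapped back to the
natural scale.

The fall snow-depth index sums weekly station depths from October to late
December, interpolates the station sums across the study area by ordinary
kriging, and averages the interpolated surface over each management-unit
polygon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, spatial
from shapely.geometry import Point
from shapely.prepared import prep

from .exceptions import (
    DegenerateCovariateError,
    InsufficientDataError,
    MissingEffortError,
)

__all__ = ["per_day_rate", "StandardScale", "standardize", "Variogram",
           "fit_variogram", "ordinary_kriging", "snow_index"]


def per_day_rate(count: float, days: float) -> float:
    """Animals seen per hunter-day: count / days."""
    count_arr = np.asarray(count, float)
    days_arr = np.asarray(days, float)
    if np.any(days_arr <= 0):
        raise MissingEffortError("days hunted must be > 0 to form a rate")
    if np.any(count_arr < 0):
        raise MissingEffortError("count must be >= 0")
    out = count_arr / days_arr
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class StandardScale:
    """Stored standardization transform: x_std = (x - center) / scale."""

    center: float
    scale: float

    def apply(self, x):
        return (np.asarray(x, float) - self.center) / self.scale

    def invert(self, x_std):
        return np.asarray(x_std, float) * self.scale + self.center


def standardize(series, center: bool = True) -> tuple[np.ndarray, StandardScale]:
    """Scale a covariate series to unit sample variance.

    Default also centers (z-score), which conditions the sampler better; a
    scale-only option (`center=False`) matches a literal unit-variance
    reading.  Returns the transformed series and the stored transform.
    """
    x = np.asarray(series, float)
    valid = x[np.isfinite(x)]
    if valid.size < 2 or np.unique(valid).size < 2:
        raise DegenerateCovariateError("need >= 2 distinct values to standardize")
    sd = float(np.std(valid, ddof=1))
    if sd == 0.0:
        raise DegenerateCovariateError("zero-variance covariate")
    c = float(np.mean(valid)) if center else 0.0
    scale = StandardScale(center=c, scale=sd)
    return scale.apply(x), scale


@dataclass(frozen=True)
class Variogram:
    """Exponential semivariogram: gamma(h) = nugget + sill*(1 - exp(-h/range))."""

    nugget: float
    sill: float
    range_: float

    def __call__(self, h):
        h = np.asarray(h, float)
        g = self.nugget + self.sill * (1.0 - np.exp(-h / self.range_))
        return np.where(h == 0.0, 0.0, g)


def empirical_semivariogram(xy: np.ndarray, values: np.ndarray,
                            n_bins: int = 12) -> pd.DataFrame:
    """Binned empirical semivariance: mean of squared differences / 2."""
    d = spatial.distance.pdist(xy)
    iu = np.triu_indices(len(values), k=1)
    sq = 0.5 * (values[iu[0]] - values[iu[1]]) ** 2
    edges = np.linspace(0.0, d.max() * (1 + 1e-9), n_bins + 1)
    idx = np.digitize(d, edges) - 1
    rows = []
    for b in range(n_bins):
        mask = idx == b
        if mask.sum() > 0:
            rows.append({"lag": d[mask].mean(), "gamma": sq[mask].mean(),
                         "n_pairs": int(mask.sum())})
    return pd.DataFrame(rows)


def fit_variogram(xy: np.ndarray, values: np.ndarray,
                  n_bins: int = 12) -> Variogram:
    """Fit an exponential model to the empirical semivariogram by WLS.

    Weights are the pair counts per lag bin (Cressie-style); nugget is
    pinned at 0 so kriging interpolates the station sums exactly.  A
    (near-)constant field degenerates to a tiny-sill variogram, for which
    ordinary kriging still returns the constant.
    """
    emp = empirical_semivariogram(xy, values, n_bins=n_bins)
    var = float(np.var(values))
    max_lag = float(emp["lag"].max())
    if var <= 1e-12 or len(emp) < 3:
        return Variogram(nugget=0.0, sill=max(var, 1e-12), range_=max_lag or 1.0)

    def model(h, sill, rng):
        return sill * (1.0 - np.exp(-h / rng))

    try:
        popt, _ = optimize.curve_fit(
            model, emp["lag"], emp["gamma"],
            p0=[var, max_lag / 3.0],
            sigma=1.0 / np.sqrt(emp["n_pairs"]),
            bounds=([1e-12, 1e-9 * max_lag], [np.inf, 100.0 * max_lag]),
            maxfev=10000)
        sill, rng = popt
    except RuntimeError:
        sill, rng = var, max_lag / 3.0
    return Variogram(nugget=0.0, sill=float(sill), range_=float(rng))


def ordinary_kriging(xy: np.ndarray, values: np.ndarray, targets: np.ndarray,
                     variogram: Variogram | None = None) -> np.ndarray:
    """Ordinary kriging prediction at target points.

    Solves the standard OK system [[Gamma, 1], [1', 0]] [w; m] = [gamma0; 1]
    per target.  With a zero nugget the predictor is exact at the stations.
    """
    xy = np.asarray(xy, float)
    values = np.asarray(values, float)
    if xy.shape[0] < 3:
        raise InsufficientDataError("ordinary kriging needs >= 3 stations")
    if variogram is None:
        variogram = fit_variogram(xy, values)
    n = xy.shape[0]
    gamma_mat = variogram(spatial.distance.squareform(spatial.distance.pdist(xy)))
    a = np.empty((n + 1, n + 1))
    a[:n, :n] = gamma_mat
    a[:n, n] = 1.0
    a[n, :n] = 1.0
    a[n, n] = 0.0
    # tiny jitter keeps the system solvable for degenerate variograms
    a[:n, :n] += 1e-10 * np.eye(n)
    d0 = spatial.distance.cdist(np.asarray(targets, float), xy)
    rhs = np.empty((n + 1, d0.shape[0]))
    rhs[:n, :] = variogram(d0).T
    rhs[n, :] = 1.0
    sol = np.linalg.solve(a, rhs)
    return sol[:n, :].T @ values


def load_unit_polygons(path: str) -> dict:
    """Read unit polygons from a GeoJSON FeatureCollection.

    Features must carry a "unit_id" property; returns {unit_id: polygon}.
    """
    import json

    from shapely.geometry import shape

    with open(path) as fh:
        gj = json.load(fh)
    out = {}
    for feat in gj.get("features", []):
        uid = feat.get("properties", {}).get("unit_id")
        if uid is None:
            raise InsufficientDataError("GeoJSON feature without unit_id")
        out[uid] = shape(feat["geometry"])
    if not out:
        raise InsufficientDataError(f"no features in {path}")
    return out


def load_stations(path: str) -> pd.DataFrame:
    """Read a snow-station CSV (station_id, x, y, week, depth)."""
    df = pd.read_csv(path)
    missing = {"station_id", "x", "y", "week", "depth"} - set(df.columns)
    if missing:
        raise InsufficientDataError(
            f"stations file missing columns {sorted(missing)}")
    return df


def station_season_sums(stations: pd.DataFrame,
                        weeks: tuple[int, int] = (40, 52)) -> pd.DataFrame:
    """Sum weekly depths per station over the fall window (ISO weeks).

    Expects columns station_id, x, y, week, depth; returns one row per
    station with the seasonal sum and coordinates.  Stations with no
    non-missing weekly depth in the window are dropped.
    """
    w = stations[(stations["week"] >= weeks[0]) & (stations["week"] <= weeks[1])]
    w = w.dropna(subset=["depth"])
    agg = (w.groupby("station_id")
            .agg(x=("x", "first"), y=("y", "first"), total=("depth", "sum"))
            .reset_index())
    return agg


def snow_index(stations: pd.DataFrame, unit_polygons: dict,
               grid_resolution: float = 10_000.0,
               variogram: Variogram | None = None,
               weeks: tuple[int, int] = (40, 52)) -> pd.Series:
    """Per-unit fall snow index for one year.

    Pipeline: sum weekly depths Oct-Dec per station, krige the sums onto a
    regular grid covering the union of the unit polygons (default 10 km
    resolution), and average grid values inside each polygon.  Polygons too
    small to contain a grid point fall back to kriging at their centroid.
    """
    sums = station_season_sums(stations, weeks=weeks)
    if len(sums) < 3:
        raise InsufficientDataError(
            f"snow index needs >= 3 stations with data, got {len(sums)}")
    xy = sums[["x", "y"]].to_numpy()
    vals = sums["total"].to_numpy()
    if variogram is None:
        variogram = fit_variogram(xy, vals)

    minx = min(p.bounds[0] for p in unit_polygons.values())
    miny = min(p.bounds[1] for p in unit_polygons.values())
    maxx = max(p.bounds[2] for p in unit_polygons.values())
    maxy = max(p.bounds[3] for p in unit_polygons.values())
    gx = np.arange(minx + grid_resolution / 2, maxx, grid_resolution)
    gy = np.arange(miny + grid_resolution / 2, maxy, grid_resolution)
    if gx.size == 0 or gy.size == 0:
        gx, gy = np.array([(minx + maxx) / 2]), np.array([(miny + maxy) / 2])
    gxx, gyy = np.meshgrid(gx, gy)
    grid = np.column_stack([gxx.ravel(), gyy.ravel()])
    surface = ordinary_kriging(xy, vals, grid, variogram)

    out = {}
    for unit, poly in unit_polygons.items():
        prepared = prep(poly)
        inside = np.fromiter(
            (prepared.contains(Point(x, y)) for x, y in grid),
            dtype=bool, count=len(grid))
        if inside.any():
            out[unit] = float(surface[inside].mean())
        else:
            centroid = np.array([[poly.centroid.x, poly.centroid.y]])
            out[unit] = float(ordinary_kriging(xy, vals, centroid, variogram)[0])
    return pd.Series(out, name="snow_index")
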