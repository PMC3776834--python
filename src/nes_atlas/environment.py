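"""Environmental layer stack: slope, multi-scale topographic PCA, and
topography-aware rainfall interpolation.

Rainfall is interpolated from sparse weather stations in two steps, the
scheme used by operational orographic-precipitation mappers: (1) describe
the topography around every cell by the centred elevations in square
windows at several scales, reduce them by PCA, and regress station rainfall
on (x, y, leading components) by ordinary least squares; (2) fit an
empirical semivariogram to the regression residuals and interpolate them by
ordinary kriging.  The prediction is the regression surface plus the kriged
residual field, optionally truncated at a ceiling (linear regression can
overshoot on extreme terrain).  A leave-one-station-out jackknife compares
this against a trivariate thin-plate spline on (x, y, elevation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from scipy.interpolate import RBFInterpolator

from .grids import GridSpec, Raster

__all__ = [
    "EnvLayerStack",
    "GEOLOGY_CODES",
    "compute_slope",
    "TopoPCA",
    "topographic_pca",
    "AurelhyModel",
    "fit_aurelhy",
    "predict_aurelhy",
    "predict_at_stations",
    "thin_plate_spline_predict",
    "jackknife_compare",
    "extract_at_points",
]

# Substrate classes: ultramafic, volcano-sedimentary, limestone, riverbank/anthropic.
GEOLOGY_CODES = {"U": 1.0, "V": 2.0, "L": 3.0, "R": 4.0}
GEOLOGY_NAMES = {v: k for k, v in GEOLOGY_CODES.items()}

RAINFALL_CEILING_MM = 4900.0


@dataclass
class EnvLayerStack:
    """Co-registered single-band rasters on one grid spec."""

    elevation: Raster
    slope: Raster
    rainfall: Raster
    temperature: Raster
    geology: Raster

    def __post_init__(self) -> None:
        g = self.elevation.grid
        for name in ("slope", "rainfall", "temperature", "geology"):
            if getattr(self, name).grid != g:
                raise ValueError(f"layer {name!r} is not on the common grid spec")

    @property
    def grid(self) -> GridSpec:
        return self.elevation.grid

    def layers(self) -> dict[str, Raster]:
        return {
            "elevation": self.elevation,
            "slope": self.slope,
            "rainfall": self.rainfall,
            "temperature": self.temperature,
            "geology": self.geology,
        }


def _pad_linear(z: np.ndarray, pad: int) -> np.ndarray:
    """Pad by linear extrapolation so edge finite differences become one-sided."""
    out = np.pad(z, pad, mode="edge")
    for k in range(1, pad + 1):
        out[pad - k, :] = 2 * out[pad, :] - out[pad + k, :]
        out[-(pad - k) - 1, :] = 2 * out[-pad - 1, :] - out[-pad - 1 - k, :]
    for k in range(1, pad + 1):
        out[:, pad - k] = 2 * out[:, pad] - out[:, pad + k]
        out[:, -(pad - k) - 1] = 2 * out[:, -pad - 1] - out[:, -pad - 1 - k]
    return out


def compute_slope(dem: Raster) -> Raster:
    """Slope in degrees from Horn's 3x3 weighted central differences.

    The DEM is padded by linear extrapolation, which reduces the stencil to
    one-sided differences at edges (exact for planar terrain).
    """
    z = np.asarray(dem.values, dtype=float)
    if z.shape[0] < 3 or z.shape[1] < 3:
        raise ValueError("DEM must be at least 3x3")
    if not np.isfinite(z).all():
        raise ValueError("DEM contains non-finite elevations")
    zp = _pad_linear(z, 1)
    cell = dem.grid.cell
    kx = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float) / (8 * cell)
    ky = kx.T
    dzdx = ndimage.convolve(zp, kx[::-1, ::-1], mode="constant")[1:-1, 1:-1]
    dzdy = ndimage.convolve(zp, ky[::-1, ::-1], mode="constant")[1:-1, 1:-1]
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    return Raster(slope, dem.grid, nodata=dem.nodata)


def _window_offsets(radius: int):
    return [(dy, dx) for dy in range(-radius, radius + 1) for dx in range(-radius, radius + 1)]


def _topo_features(z: np.ndarray, scales: tuple[int, ...]) -> np.ndarray:
    """Feature matrix (n_cells, sum (2r+1)^2): per scale, the window
    elevations around each cell (PCA centres the columns over cells, so the
    components span both absolute elevation and multi-scale relief)."""
    blocks = []
    for r in scales:
        if r < 1:
            raise ValueError("window radii must be >= 1 cell")
        zp = _pad_linear(z, r)
        cols = []
        for dy, dx in _window_offsets(r):
            shifted = zp[r + dy : r + dy + z.shape[0], r + dx : r + dx + z.shape[1]]
            cols.append(shifted.ravel())
        blocks.append(np.column_stack(cols))
    return np.concatenate(blocks, axis=1)


@dataclass
class TopoPCA:
    """PCA of multi-scale centred-window elevations over all land cells."""

    scales: tuple[int, ...]
    mean_: np.ndarray
    components_: np.ndarray  # (n_keep, n_features)
    explained_variance_ratio_: np.ndarray
    n_keep: int
    grid: GridSpec
    _cache: tuple | None = field(default=None, repr=False, compare=False)

    def transform_dem(self, dem: Raster) -> np.ndarray:
        """Component scores for every cell, shape (ny, nx, n_keep).

        Scores for the most recent DEM are cached — leave-one-out loops call
        this with the same DEM once per fold.
        """
        if self._cache is not None and self._cache[0] is dem.values:
            return self._cache[1]
        feats = _topo_features(np.asarray(dem.values, dtype=float), self.scales)
        scores = (feats - self.mean_) @ self.components_.T
        scores = scores.reshape(dem.grid.ny, dem.grid.nx, self.n_keep)
        self._cache = (dem.values, scores)
        return scores

    def scores_at(self, dem: Raster, x, y) -> np.ndarray:
        scores = self.transform_dem(dem)
        ix, iy = dem.grid.cell_index(np.asarray(x), np.asarray(y))
        return scores[iy, ix, :]


def topographic_pca(
    dem: Raster, scales: tuple[int, ...] = (1, 2, 4, 8), kept_variance: float = 0.999
) -> tuple[np.ndarray, TopoPCA]:
    """PCA description of topography at a range of scales.

    Returns (score_rasters, model) where score_rasters has shape
    (ny, nx, n_keep).  Raises on a constant DEM (zero-variance features).
    """
    from sklearn.decomposition import PCA

    if not scales:
        raise ValueError("need at least one scale")
    z = np.asarray(dem.values, dtype=float)
    feats = _topo_features(z, tuple(scales))
    if np.allclose(feats.std(axis=0), 0):
        raise ValueError("constant DEM: topographic features have zero variance")
    pca = PCA()
    pca.fit(feats)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_keep = int(np.searchsorted(cum, kept_variance - 1e-12) + 1)
    model = TopoPCA(
        scales=tuple(scales),
        mean_=pca.mean_,
        components_=pca.components_[:n_keep],
        explained_variance_ratio_=pca.explained_variance_ratio_[:n_keep],
        n_keep=n_keep,
        grid=dem.grid,
    )
    return model.transform_dem(dem), model


# ---------------------------------------------------------------------------
# Variograms and ordinary kriging


def exponential_semivariogram(h, nugget, psill, range_):
    h = np.asarray(h, dtype=float)
    return nugget + psill * (1.0 - np.exp(-h / np.maximum(range_, 1e-12)))


def fit_variogram(
    coords: np.ndarray,
    residuals: np.ndarray,
    n_bins: int = 12,
    nugget: float | None = None,
) -> tuple[float, float, float]:
    """Weighted-least-squares fit of an exponential semivariogram.

    Empirical semivariances are computed on distance bins up to half the
    maximum pairwise distance and fit with Cressie weights N(h)/gamma^2.
    ``nugget=None`` estimates the nugget; pass 0.0 to force exact
    interpolation.  Returns (nugget, partial sill, range in metres).
    """
    from scipy.spatial.distance import pdist

    d = pdist(coords)
    dv = 0.5 * pdist(residuals[:, None], metric="sqeuclidean")
    hmax = d.max() / 2
    edges = np.linspace(0, hmax, n_bins + 1)
    hs, gs, ns = [], [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (d > lo) & (d <= hi)
        if sel.sum() >= 2:
            hs.append(d[sel].mean())
            gs.append(dv[sel].mean())
            ns.append(sel.sum())
    hs, gs, ns = np.array(hs), np.array(gs), np.array(ns)
    if len(hs) < 3:
        raise ValueError("too few stations for a variogram fit")
    var0 = max(residuals.var(), 1e-12)
    r0 = hmax / 3

    def resid(params):
        if nugget is None:
            c0, c1, a = params
        else:
            c0 = nugget
            c1, a = params
        g = exponential_semivariogram(hs, c0, c1, a)
        w = np.sqrt(ns) / np.maximum(g, 1e-12)
        return w * (g - gs)

    if nugget is None:
        x0 = [0.1 * var0, 0.9 * var0, r0]
        lb = [0.0, 1e-12, 1e-3]
        ub = [10 * var0, 100 * var0, 100 * hmax]
    else:
        x0 = [max(var0 - nugget, 1e-12), r0]
        lb = [1e-12, 1e-3]
        ub = [100 * var0, 100 * hmax]
    sol = optimize.least_squares(resid, x0, bounds=(lb, ub))
    if nugget is None:
        c0, c1, a = sol.x
    else:
        c0, (c1, a) = nugget, sol.x
    return float(c0), float(c1), float(a)


def ordinary_kriging_weights(
    station_coords: np.ndarray, target_coords: np.ndarray, vparams: tuple[float, float, float]
) -> np.ndarray:
    """Ordinary-kriging weight matrix, shape (n_targets, n_stations).

    Weights of each row sum to 1 (unbiasedness constraint of the kriging
    system).  With a zero nugget the prediction at a station reproduces the
    observed value exactly.
    """
    from scipy.spatial.distance import cdist

    n = len(station_coords)
    c0, c1, a = vparams
    gamma = exponential_semivariogram(cdist(station_coords, station_coords), c0, c1, a)
    np.fill_diagonal(gamma, 0.0)
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = gamma
    A[n, :n] = 1.0
    A[:n, n] = 1.0
    A[n, n] = 0.0
    b = np.empty((n + 1, len(target_coords)))
    b[:n, :] = exponential_semivariogram(cdist(station_coords, target_coords), c0, c1, a)
    b[n, :] = 1.0
    try:
        sol = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        sol = np.linalg.lstsq(A, b, rcond=None)[0]
    return sol[:n, :].T


@dataclass
class AurelhyModel:
    """Fitted two-step rainfall interpolator: linear trend + kriged residuals."""

    topo: TopoPCA
    coef_: np.ndarray  # intercept, x, y, PCs (on scaled predictors)
    xy_center_: np.ndarray
    xy_scale_: np.ndarray
    pc_scale_: np.ndarray
    variogram: tuple[float, float, float]  # nugget, partial sill, range (m)
    station_coords: np.ndarray
    station_residuals: np.ndarray
    ceiling_mm: float = RAINFALL_CEILING_MM

    def design(self, xy: np.ndarray, pcs: np.ndarray) -> np.ndarray:
        xs = (xy - self.xy_center_) / self.xy_scale_
        ps = pcs / self.pc_scale_
        return np.column_stack([np.ones(len(xy)), xs, ps])

    def trend(self, xy: np.ndarray, pcs: np.ndarray) -> np.ndarray:
        return self.design(xy, pcs) @ self.coef_


def fit_aurelhy(
    stations: pd.DataFrame,
    dem: Raster,
    topo: TopoPCA | None = None,
    scales: tuple[int, ...] = (1, 2, 4, 8),
    kept_variance: float = 0.999,
    nugget: float | None = None,
    variogram: tuple[float, float, float] | None = None,
    ceiling_mm: float = RAINFALL_CEILING_MM,
) -> AurelhyModel:
    """Fit the two-step interpolator on a station table (x, y, rainfall).

    Station rainfall is regressed by OLS on scaled (x, y) plus the leading
    topographic components at the station cells; the residual semivariogram
    is then fit for ordinary kriging.  Requires enough stations to determine
    the regression (n >= max(6, predictors + 2)).
    """
    if topo is None:
        _, topo = topographic_pca(dem, scales, kept_variance)
    xy = stations[["x", "y"]].to_numpy(dtype=float)
    rain = stations["rainfall"].to_numpy(dtype=float)
    n_pred = 3 + topo.n_keep
    if len(stations) < max(6, n_pred + 2):
        raise ValueError(f"need at least {max(6, n_pred + 2)} stations for {topo.n_keep} components")
    pcs = topo.scores_at(dem, xy[:, 0], xy[:, 1])
    xy_center = xy.mean(axis=0)
    xy_scale = np.maximum(xy.std(axis=0), 1e-9)
    pc_scale = np.maximum(pcs.std(axis=0), 1e-9)
    X = np.column_stack([np.ones(len(xy)), (xy - xy_center) / xy_scale, pcs / pc_scale])
    coef, _, rank, _ = np.linalg.lstsq(X, rain, rcond=None)
    if rank < X.shape[1]:
        raise ValueError("singular regression design; reduce the number of components")
    resid = rain - X @ coef
    if variogram is not None:
        vparams = variogram
    elif np.allclose(resid, 0, atol=1e-8 * max(1.0, np.abs(rain).max())):
        vparams = (0.0, 1e-12, max(float(np.ptp(xy, axis=0).max()), 1.0))
    else:
        vparams = fit_variogram(xy, resid, nugget=nugget)
    return AurelhyModel(
        topo=topo,
        coef_=coef,
        xy_center_=xy_center,
        xy_scale_=xy_scale,
        pc_scale_=pc_scale,
        variogram=vparams,
        station_coords=xy,
        station_residuals=resid,
        ceiling_mm=ceiling_mm,
    )


def _predict_points(model: AurelhyModel, dem: Raster, xy: np.ndarray) -> np.ndarray:
    pcs = model.topo.scores_at(dem, xy[:, 0], xy[:, 1])
    trend = model.trend(xy, pcs)
    w = ordinary_kriging_weights(model.station_coords, xy, model.variogram)
    return trend + w @ model.station_residuals


def predict_aurelhy(model: AurelhyModel, dem: Raster) -> tuple[Raster, float]:
    """Predict the rainfall surface on the DEM grid.

    Returns (raster, clamped_fraction); values above the ceiling are
    truncated to it, and negatives floored at zero.
    """
    if dem.grid != model.topo.grid:
        raise ValueError("DEM grid does not match the grid the topographic PCA was fit on")
    xs, ys = dem.grid.cell_centers()
    xy = np.column_stack([xs.ravel(), ys.ravel()])
    pred = _predict_points(model, dem, xy)
    n_over = int((pred > model.ceiling_mm).sum())
    pred = np.clip(pred, 0.0, model.ceiling_mm)
    frac = n_over / pred.size
    return Raster(pred.reshape(dem.grid.shape), dem.grid, nodata=dem.nodata), frac


def predict_at_stations(model: AurelhyModel, dem: Raster, xy: np.ndarray) -> np.ndarray:
    pred = _predict_points(model, dem, np.asarray(xy, dtype=float))
    return np.clip(pred, 0.0, model.ceiling_mm)


def thin_plate_spline_predict(
    train: pd.DataFrame, test_xyz: np.ndarray, smoothing: float = 0.0
) -> np.ndarray:
    """Trivariate thin-plate spline on (x, y, elevation), coordinates scaled
    to unit variance so the vertical axis actually participates."""
    pts = train[["x", "y", "elevation"]].to_numpy(dtype=float)
    center = pts.mean(axis=0)
    scale = np.maximum(pts.std(axis=0), 1e-9)
    rbf = RBFInterpolator(
        (pts - center) / scale,
        train["rainfall"].to_numpy(dtype=float),
        kernel="thin_plate_spline",
        smoothing=smoothing,
    )
    q = (np.asarray(test_xyz, dtype=float) - center) / scale
    return rbf(q)


def jackknife_compare(
    stations: pd.DataFrame,
    dem: Raster,
    methods: tuple[str, ...] = ("aurelhy", "thin_plate_spline"),
    topo: TopoPCA | None = None,
    scales: tuple[int, ...] = (1, 2, 4, 8),
    kept_variance: float = 0.999,
    nugget: float | None = None,
) -> pd.DataFrame:
    """Leave-one-station-out comparison of interpolation methods.

    Each station is predicted from the remaining ones; the table reports
    RMSE, MAE and mean bias per method.  The topographic PCA is fit once on
    the DEM (it does not involve station data, so no leakage).
    """
    if len(stations) < 10:
        raise ValueError("need at least 10 stations for a jackknife")
    known = {"aurelhy", "thin_plate_spline"}
    for m in methods:
        if m not in known:
            raise ValueError(f"unknown method {m!r}; expected subset of {sorted(known)}")
    if topo is None and "aurelhy" in methods:
        _, topo = topographic_pca(dem, scales, kept_variance)
    obs = stations["rainfall"].to_numpy(dtype=float)
    vparams = None
    if "aurelhy" in methods:
        # variogram estimated once from the full-data residuals; refitting it
        # inside every fold adds noise and cost without changing the verdict
        full = fit_aurelhy(stations, dem, topo=topo, nugget=nugget)
        vparams = full.variogram
    errors = {m: np.empty(len(stations)) for m in methods}
    for i in range(len(stations)):
        train = stations.drop(stations.index[i])
        held = stations.iloc[[i]]
        for m in methods:
            if m == "aurelhy":
                model = fit_aurelhy(train, dem, topo=topo, nugget=nugget, variogram=vparams)
                pred = predict_at_stations(model, dem, held[["x", "y"]].to_numpy(dtype=float))[0]
            else:
                pred = thin_plate_spline_predict(
                    train, held[["x", "y", "elevation"]].to_numpy(dtype=float)
                )[0]
            errors[m][i] = pred - obs[i]
    rows = []
    for m in methods:
        e = errors[m]
        rows.append(
            {"method": m, "rmse": float(np.sqrt(np.mean(e**2))),
             "mae": float(np.mean(np.abs(e))), "bias": float(np.mean(e))}
        )
    return pd.DataFrame(rows)


def extract_at_points(stack: EnvLayerStack, points: pd.DataFrame) -> pd.DataFrame:
    """Nearest-cell covariate extraction for projected points (columns x, y).

    Adds one column per layer plus a ``valid`` flag (False where any layer
    is nodata); raises if every point falls outside the stack extent.
    """
    x = points["x"].to_numpy(dtype=float)
    y = points["y"].to_numpy(dtype=float)
    inside = stack.grid.contains(x, y)
    if not inside.any():
        raise ValueError("all points outside the layer-stack extent")
    out = points.copy()
    valid = inside.copy()
    for name, layer in stack.layers().items():
        vals, ok = layer.sample(x, y, outside="nan")
        out[name] = vals
        valid &= ok
    out["valid"] = valid
    return out
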