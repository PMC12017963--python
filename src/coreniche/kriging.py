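"""Ordinary kriging of station-level fields (e.g. Shannon diversity).

The workflow mirrors automated variogram-based interpolation: an empirical
semivariogram (10 lags to half the maximum separation), weighted-least-squares
fits of spherical, exponential and gaussian models with Cressie weights
n(h)/h^2, model selection by WLS score, then the ordinary-kriging system with
a Lagrange multiplier per prediction node.  Leave-one-out re-prediction at the
stations yields the cross-validation Pearson r.

Coordinates in degrees are projected to local planar kilometres by
equirectangular scaling at the mean latitude, which is adequate over a small
coastal domain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.spatial.distance import cdist
from scipy.stats import pearsonr

__all__ = [
    "VariogramModel", "OrdinaryKriging", "KrigingResults",
    "empirical_variogram", "fit_variogram", "krige_surface", "project_lonlat",
]

EARTH_KM_PER_DEG = 111.32


def project_lonlat(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    """Equirectangular projection to kilometres at the mean latitude."""
    lon, lat = np.asarray(lon, float), np.asarray(lat, float)
    lat0 = np.deg2rad(lat.mean())
    x = lon * EARTH_KM_PER_DEG * np.cos(lat0)
    y = lat * EARTH_KM_PER_DEG
    return np.column_stack([x, y])


def _gamma_shape(model: str, h: np.ndarray, rng: float) -> np.ndarray:
    hr = np.asarray(h, float) / rng
    if model == "spherical":
        g = np.where(hr < 1.0, 1.5 * hr - 0.5 * hr**3, 1.0)
    elif model == "exponential":
        g = 1.0 - np.exp(-3.0 * hr)
    elif model == "gaussian":
        g = 1.0 - np.exp(-3.0 * hr**2)
    else:
        raise ValueError(f"unknown variogram model {model!r}")
    return g


@dataclass
class VariogramModel:
    """Fitted semivariogram: gamma(h) = nugget + psill * shape(h / range)."""

    model: str
    nugget: float
    psill: float
    range_: float
    wls_score: float = np.nan
    empirical: pd.DataFrame | None = None

    def __call__(self, h: np.ndarray) -> np.ndarray:
        h = np.asarray(h, float)
        # gamma(0) = nugget; the nugget acts for any h >= 0
        return self.nugget + self.psill * _gamma_shape(self.model, h, self.range_)


def empirical_variogram(coords: np.ndarray, values: np.ndarray,
                        n_lags: int = 10) -> pd.DataFrame:
    """Binned empirical semivariogram up to half the maximum separation."""
    coords = np.asarray(coords, float)
    values = np.asarray(values, float)
    d = cdist(coords, coords)
    iu = np.triu_indices(len(values), 1)
    h = d[iu]
    sv = 0.5 * (values[iu[0]] - values[iu[1]]) ** 2
    h_max = h.max() / 2.0
    edges = np.linspace(0.0, h_max, n_lags + 1)
    rows = []
    for i in range(n_lags):
        sel = (h > edges[i]) & (h <= edges[i + 1])
        if sel.sum() == 0:
            continue
        rows.append({
            "lag": float(h[sel].mean()),
            "semivariance": float(sv[sel].mean()),
            "pair_count": int(sel.sum()),
        })
    if not rows:
        raise ValueError("no pairs fall inside the variogram lags")
    return pd.DataFrame(rows)


def fit_variogram(coords: np.ndarray, values: np.ndarray, n_lags: int = 10,
                  models: tuple[str, ...] = ("spherical", "exponential", "gaussian"),
                  ) -> VariogramModel:
    """WLS variogram fit (Cressie weights n(h)/h^2), best of the candidates."""
    emp = empirical_variogram(coords, values, n_lags=n_lags)
    h = emp["lag"].to_numpy()
    g = emp["semivariance"].to_numpy()
    w = emp["pair_count"].to_numpy() / np.maximum(h, 1e-12) ** 2

    var = values.var() if np.asarray(values).var() > 0 else 1.0
    best: VariogramModel | None = None
    for model in models:
        def resid(theta, model=model):
            nugget, psill, rng = theta
            return np.sqrt(w) * (nugget + psill * _gamma_shape(model, h, rng) - g)

        x0 = np.array([max(g.min(), 1e-6 * var), max(g.max() - g.min(), 1e-6 * var),
                       h.max() / 2.0])
        try:
            res = optimize.least_squares(
                resid, x0,
                bounds=([0.0, 0.0, 1e-6], [np.inf, np.inf, 10 * h.max()]),
            )
        except Exception:
            continue
        score = float(np.sum(res.fun**2))
        cand = VariogramModel(model, float(res.x[0]), float(res.x[1]),
                              float(res.x[2]), wls_score=score, empirical=emp)
        if best is None or score < best.wls_score:
            best = cand
    if best is None:
        raise RuntimeError("variogram fitting failed for every candidate model")
    return best


class OrdinaryKriging:
    """Ordinary kriging with a fitted (or supplied) semivariogram.

    ``fit()`` solves nothing heavy up front beyond factorising the kriging
    matrix; predictions solve the ordinary-kriging system (weights constrained
    to sum to one via a Lagrange multiplier) per node.
    """

    def __init__(self, coords: np.ndarray, values: np.ndarray,
                 variogram: VariogramModel | None = None, n_lags: int = 10):
        self.coords = np.asarray(coords, float)
        self.values = np.asarray(values, float)
        if len(self.coords) < 5:
            raise ValueError("need >= 5 stations")
        d = cdist(self.coords, self.coords)
        dup = np.argwhere((d < 1e-12) & ~np.eye(len(d), dtype=bool))
        if len(dup):
            i, j = dup[0]
            raise ValueError(f"duplicate coordinates at stations {i} and {j}")
        self.variogram = variogram or fit_variogram(self.coords, self.values,
                                                    n_lags=n_lags)

    def _system(self, coords, values):
        n = len(values)
        d = cdist(coords, coords)
        a = np.empty((n + 1, n + 1))
        a[:n, :n] = self.variogram(d)
        np.fill_diagonal(a[:n, :n], self.variogram(0.0))
        a[n, :n] = 1.0
        a[:n, n] = 1.0
        a[n, n] = 0.0
        return a

    def predict(self, targets: np.ndarray, coords=None, values=None):
        """Predict at target coordinates; returns (predictions, variances, weights)."""
        coords = self.coords if coords is None else np.asarray(coords, float)
        values = self.values if values is None else np.asarray(values, float)
        targets = np.atleast_2d(np.asarray(targets, float))
        n = len(values)
        a = self._system(coords, values)
        # the gaussian model with a tiny nugget is notoriously ill-conditioned;
        # fall back to the pseudo-inverse when the plain solve is unreliable
        if np.linalg.cond(a) > 1e10:
            lu = np.linalg.pinv(a, rcond=1e-12)
        else:
            lu = np.linalg.inv(a)
        g0 = self.variogram(cdist(coords, targets))       # n x m
        rhs = np.vstack([g0, np.ones(targets.shape[0])])  # (n+1) x m
        sol = lu @ rhs
        wts = sol[:n]
        mu = sol[n]
        # enforce the unbiasedness constraint exactly (guards the pinv path)
        wts /= wts.sum(axis=0, keepdims=True)
        preds = wts.T @ values
        variances = np.einsum("im,im->m", wts, g0) + mu
        return preds, np.maximum(variances, 0.0), wts.T

    def loo_cv(self) -> tuple[np.ndarray, float]:
        """Leave-one-out re-prediction at stations and its Pearson r."""
        n = len(self.values)
        preds = np.empty(n)
        for i in range(n):
            keep = np.arange(n) != i
            p, _, _ = self.predict(self.coords[i][None, :],
                                   coords=self.coords[keep],
                                   values=self.values[keep])
            preds[i] = p[0]
        # a (near-)constant field has no defined correlation
        if np.ptp(preds) > 1e-12 * max(1.0, np.abs(preds).max()) and np.ptp(self.values) > 0:
            r = pearsonr(preds, self.values)[0]
        else:
            r = np.nan
        return preds, float(r)

    def fit(self, grid_lon=None, grid_lat=None, resolution: int = 50,
            lonlat: np.ndarray | None = None) -> "KrigingResults":
        """Predict over a regular grid and run leave-one-out validation.

        ``lonlat``: original (lon, lat) in degrees for grid construction;
        defaults to interpreting ``coords`` directly as planar.
        """
        if lonlat is not None:
            lon = np.linspace(lonlat[:, 0].min(), lonlat[:, 0].max(), resolution)
            lat = np.linspace(lonlat[:, 1].min(), lonlat[:, 1].max(), resolution)
            glon, glat = np.meshgrid(lon, lat)
            targets = project_lonlat(glon.ravel(), glat.ravel())
            out_lon, out_lat = glon.ravel(), glat.ravel()
        else:
            gx = np.linspace(self.coords[:, 0].min(), self.coords[:, 0].max(), resolution)
            gy = np.linspace(self.coords[:, 1].min(), self.coords[:, 1].max(), resolution)
            mx, my = np.meshgrid(gx, gy)
            targets = np.column_stack([mx.ravel(), my.ravel()])
            out_lon, out_lat = mx.ravel(), my.ravel()
        preds, variances, wts = self.predict(targets)
        loo_pred, cv_r = self.loo_cv()
        grid = pd.DataFrame({
            "lon": out_lon, "lat": out_lat,
            "predicted": preds, "kriging_variance": variances,
        })
        return KrigingResults(model=self, grid=grid, weights=wts,
                              loo_predictions=loo_pred, cv_pearson_r=cv_r)


@dataclass
class KrigingResults:
    model: OrdinaryKriging
    grid: pd.DataFrame
    weights: np.ndarray
    loo_predictions: np.ndarray
    cv_pearson_r: float

    def summary(self) -> str:
        v = self.model.variogram
        return "\n".join([
            "Ordinary kriging",
            "-" * 30,
            f"variogram model       {v.model}",
            f"nugget                {v.nugget:.5g}",
            f"partial sill          {v.psill:.5g}",
            f"range                 {v.range_:.5g}",
            f"grid nodes            {len(self.grid)}",
            f"LOO Pearson r         {self.cv_pearson_r:.4f}",
        ])


def krige_surface(lon, lat, values, resolution: int = 50,
                  variogram: VariogramModel | None = None) -> KrigingResults:
    """Convenience wrapper: project, fit variogram, krige a lon/lat grid."""
    lonlat = np.column_stack([np.asarray(lon, float), np.asarray(lat, float)])
    coords = project_lonlat(lonlat[:, 0], lonlat[:, 1])
    ok = OrdinaryKriging(coords, np.asarray(values, float), variogram=variogram)
    return ok.fit(lonlat=lonlat, resolution=resolution)
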