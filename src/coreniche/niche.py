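"""Stressor-response fits and the hierarchical GAMM ladder locating the
multi-stressor niche optimum of core mixoplankton.

Workflow: the response (a relative proportion or trophic ratio) is
log10-transformed with a 1e-4 pseudocount, outliers beyond |z| > 3 on the
transformed scale are dropped, predictors are screened for collinearity by
VIF, then four nested additive models are fitted:

* M1: s(temperature) + s(DO) + s(NO3-N) + random station intercept
* M2: M1 + ti(temperature, DO)
* M3: M2 + ti(temperature, NO3-N)
* M4: M3 + ti(DO, NO3-N)

The lowest-AIC model is selected and the optimum is the argmax of its
population-level prediction over a grid spanning the central (2nd–98th
percentile) range of each stressor.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gam import GAMModel, GAMResults, Smooth, TensorSmooth

logger = logging.getLogger(__name__)

__all__ = [
    "clean_response", "vif_screen", "univariate_response", "UnivariateFit",
    "NicheLadder", "NicheFitResults", "fit_ladder", "locate_optimum",
]

STRESSORS = ("temperature", "DO", "NO3-N")
EPSILON = 1e-4


def clean_response(data: pd.DataFrame, response: str,
                   min_samples: int = 30) -> pd.DataFrame:
    """log10(x + 1e-4) transform plus |z| > 3 outlier removal.

    z-scores are computed on the transformed response (after, not before, the
    log, which avoids spurious removals from right skew).  A constant
    transformed response removes nothing (no z is defined).  Returns a copy
    with a ``log_response`` column; raises if fewer than ``min_samples``
    samples survive.
    """
    df = data.dropna(subset=[response]).copy()
    if (df[response] < 0).any():
        raise ValueError("response must be non-negative")
    df["log_response"] = np.log10(df[response] + EPSILON)
    sd = df["log_response"].std(ddof=0)
    if sd > 0:
        z = (df["log_response"] - df["log_response"].mean()) / sd
        dropped = df.index[z.abs() > 3]
        if len(dropped):
            logger.info("clean_response removed %d outliers", len(dropped))
        df = df.loc[z.abs() <= 3]
    if len(df) < min_samples:
        raise ValueError(
            f"only {len(df)} samples remain after cleaning (< {min_samples})"
        )
    return df


def vif_screen(predictors: pd.DataFrame, warn_above: float = 5.0) -> pd.Series:
    """Variance inflation factor 1/(1-R2_j) per predictor.

    Perfect collinearity yields +inf (flagged via warning); VIF above
    ``warn_above`` raises a warning but nothing is dropped.
    """
    cols = list(predictors.columns)
    if len(cols) < 2:
        raise ValueError("need >= 2 predictors")
    x = predictors.to_numpy(float)
    out = {}
    for j, name in enumerate(cols):
        others = np.column_stack([np.ones(len(x)), np.delete(x, j, axis=1)])
        yj = x[:, j]
        beta, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ beta
        sst = np.sum((yj - yj.mean()) ** 2)
        r2 = 1.0 - resid @ resid / sst if sst > 0 else 0.0
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    vifs = pd.Series(out, name="vif")
    flagged = vifs[(vifs > warn_above) | ~np.isfinite(vifs)]
    if len(flagged):
        warnings.warn(f"high collinearity (VIF > {warn_above}): "
                      f"{flagged.round(2).to_dict()}", stacklevel=2)
    return vifs


@dataclass
class UnivariateFit:
    """Best-of-AIC polynomial (degree 1 vs 2) stressor-response fit."""

    predictor: str
    response: str
    model: str              # "linear" or "quadratic"
    coefficients: np.ndarray  # highest degree first (numpy polyfit order)
    r_squared: float
    p_value: float
    aic_linear: float
    aic_quadratic: float

    @property
    def equation(self) -> str:
        c = self.coefficients
        if self.model == "linear":
            return f"y = {c[0]:+.4g}x {c[1]:+.4g}"
        return f"y = {c[0]:+.4g}x^2 {c[1]:+.4g}x {c[2]:+.4g}"

    def predict(self, x) -> np.ndarray:
        return np.polyval(self.coefficients, np.asarray(x, float))


def _poly_aic(x, y, degree):
    coef = np.polyfit(x, y, degree)
    resid = y - np.polyval(coef, x)
    n = len(y)
    rss = float(resid @ resid)
    aic = n * np.log(max(rss, 1e-300) / n) + 2 * (degree + 2)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / sst if sst > 0 else 1.0
    # overall F test of the polynomial regression
    p_terms = degree
    if sst > rss and n - p_terms - 1 > 0 and rss > 0:
        f_stat = (sst - rss) / p_terms / (rss / (n - p_terms - 1))
        p = float(stats.f.sf(f_stat, p_terms, n - p_terms - 1))
    else:
        p = 0.0 if rss == 0 and sst > 0 else 1.0
    return coef, aic, r2, p


def univariate_response(x, y, predictor: str = "x",
                        response: str = "y") -> UnivariateFit:
    """Fit degree-1 and degree-2 polynomials by least squares; select by AIC."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 10:
        raise ValueError("need >= 10 points")
    if np.std(x) == 0:
        raise ValueError("constant predictor")
    c1, aic1, r2_1, p1 = _poly_aic(x, y, 1)
    c2, aic2, r2_2, p2 = _poly_aic(x, y, 2)
    if aic2 < aic1:
        return UnivariateFit(predictor, response, "quadratic", c2, r2_2, p2,
                             aic1, aic2)
    return UnivariateFit(predictor, response, "linear", c1, r2_1, p1, aic1, aic2)


# ------------------------------------------------------------- the ladder

LADDER_INTERACTIONS = {
    "M1": (),
    "M2": (("temperature", "DO"),),
    "M3": (("temperature", "DO"), ("temperature", "NO3-N")),
    "M4": (("temperature", "DO"), ("temperature", "NO3-N"), ("DO", "NO3-N")),
}


@dataclass
class NicheLadder:
    """Model object for the four-model hierarchical GAMM ladder.

    ``data`` needs the stressor columns, a station column and the cleaned
    ``response`` column (typically ``log_response`` from
    :func:`clean_response`).
    """

    data: pd.DataFrame
    response: str = "log_response"
    stressors: tuple[str, str, str] = STRESSORS
    station: str = "station"
    n_basis: int = 9
    tensor_basis: int = 5
    specs: tuple[str, ...] = ("M1", "M2", "M3", "M4")

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response: str,
                       **kwargs) -> "NicheLadder":
        cleaned = clean_response(data, response)
        return cls(data=cleaned, **kwargs)

    def _terms(self, spec: str):
        terms = [Smooth(v, n_basis=self.n_basis) for v in self.stressors]
        for v1, v2 in LADDER_INTERACTIONS[spec]:
            terms.append(TensorSmooth(v1, v2, n_basis=self.tensor_basis))
        return terms

    def fit(self, maxiter: int = 200) -> "NicheFitResults":
        fits: dict[str, GAMResults] = {}
        failures: dict[str, str] = {}
        for spec in self.specs:
            try:
                model = GAMModel(self.data, self.data[self.response].to_numpy(),
                                 self._terms(spec),
                                 random_intercept=self.station)
                res = model.fit(maxiter=maxiter)
                if not res.converged or not np.isfinite(res.aic):
                    raise RuntimeError("non-finite fit")
                fits[spec] = res
            except Exception as err:  # noqa: BLE001 - flagged, not fatal
                logger.warning("spec %s failed: %s", spec, err)
                failures[spec] = str(err)
        if not fits:
            raise RuntimeError(f"every ladder spec failed: {failures}")
        selected = min(fits, key=lambda s: fits[s].aic)
        return NicheFitResults(ladder=self, fits=fits, failures=failures,
                               selected=selected)


@dataclass
class NicheFitResults:
    """Fitted ladder: per-spec AIC/edf, the selected model and the optimum."""

    ladder: NicheLadder
    fits: dict[str, GAMResults]
    failures: dict[str, str]
    selected: str

    @property
    def best(self) -> GAMResults:
        return self.fits[self.selected]

    def aic_table(self) -> pd.DataFrame:
        rows = []
        for spec in self.ladder.specs:
            if spec in self.fits:
                r = self.fits[spec]
                rows.append({"spec": spec, "aic": r.aic, "edf": r.edf,
                             "gcv": r.gcv, "converged": True,
                             "selected": spec == self.selected})
            else:
                rows.append({"spec": spec, "aic": np.nan, "edf": np.nan,
                             "gcv": np.nan, "converged": False,
                             "selected": False})
        return pd.DataFrame(rows).set_index("spec")

    def evaluation_box(self, lower_pct: float = 2.0,
                       upper_pct: float = 98.0) -> dict[str, tuple[float, float]]:
        box = {}
        for v in self.ladder.stressors:
            x = self.ladder.data[v].to_numpy(float)
            box[v] = (float(np.percentile(x, lower_pct)),
                      float(np.percentile(x, upper_pct)))
        return box

    def locate_optimum(self, box: dict | None = None, resolution: int = 50):
        return locate_optimum(self, box=box, resolution=resolution)

    def pairwise_surfaces(self, resolution: int = 50) -> dict[tuple[str, str], pd.DataFrame]:
        """2-D prediction surfaces per stressor pair, third at its median."""
        box = self.evaluation_box()
        med = {v: float(self.ladder.data[v].median()) for v in self.ladder.stressors}
        out = {}
        for v1, v2 in itertools.combinations(self.ladder.stressors, 2):
            g1 = np.linspace(*box[v1], resolution)
            g2 = np.linspace(*box[v2], resolution)
            m1, m2 = np.meshgrid(g1, g2)
            other = [v for v in self.ladder.stressors if v not in (v1, v2)][0]
            grid = pd.DataFrame({v1: m1.ravel(), v2: m2.ravel(),
                                 other: med[other]})
            grid["predicted"] = self.best.predict(grid, include_random=False)
            out[(v1, v2)] = grid
        return out

    def summary(self) -> str:
        lines = ["Hierarchical GAMM ladder", "=" * 40, ""]
        lines.append(self.aic_table().round(3).to_string())
        lines.append("")
        lines.append(f"selected: {self.selected}")
        lines.append("")
        lines.append(self.best.summary())
        return "\n".join(lines)


def fit_ladder(data: pd.DataFrame, response: str = "log_response",
               **kwargs) -> NicheFitResults:
    """Fit the M1..M4 ladder on already-cleaned data."""
    return NicheLadder(data=data, response=response, **kwargs).fit()


def locate_optimum(fit: NicheFitResults, box: dict | None = None,
                   resolution: int = 50):
    """Grid argmax of the selected model's population-level prediction.

    The grid spans ``box`` (default: 2nd–98th percentile per stressor) at
    ``resolution`` points per axis; the station random effect is set to its
    zero mean.  Ties break to the lowest grid index.  Returns
    ``(optimum dict, predicted value at optimum, boundary_flags dict)``;
    an optimum on a box edge is flagged (possible monotone response).
    """
    stressors = fit.ladder.stressors
    box = box or fit.evaluation_box()
    axes = {v: np.linspace(box[v][0], box[v][1], resolution) for v in stressors}
    mesh = np.meshgrid(*[axes[v] for v in stressors], indexing="ij")
    grid = pd.DataFrame({v: m.ravel() for v, m in zip(stressors, mesh)})
    pred = fit.best.predict(grid, include_random=False)
    i_max = int(np.argmax(pred))  # argmax takes the first (lowest) index on ties
    optimum = {v: float(grid[v].iloc[i_max]) for v in stressors}
    boundary = {}
    idx = np.unravel_index(i_max, (resolution,) * len(stressors))
    for axis_i, v in enumerate(stressors):
        boundary[v] = idx[axis_i] in (0, resolution - 1)
    if any(boundary.values()):
        warnings.warn(
            f"optimum lies on the evaluation-box boundary for "
            f"{[v for v, b in boundary.items() if b]} (possible monotone response)",
            stacklevel=2,
        )
    return optimum, float(pred[i_max]), boundary
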