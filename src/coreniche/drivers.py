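"""Environmental driver screening.

Three complementary screens:

* variance partitioning (VPA): unique and shared adjusted-R2 fractions of the
  Nutrient / Physicochemistry / Geography categories in partial redundancy
  analysis on Hellinger-transformed counts;
* partial Mantel tests of community dissimilarity against single-variable
  environmental distances, controlling (by default) for geographic distance,
  plus the pairwise Spearman matrix of the environmental variables;
* random-forest permutation importance (%IncMSE) of the 14 variables for a
  response such as the core-mixoplankton relative proportion, with
  significance from a response-permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.tree import DecisionTreeRegressor
from statsmodels.stats.multitest import multipletests

from .config import ENV_CATEGORIES
from .io import CommunityMatrix, relative_abundance

__all__ = [
    "hellinger", "vpa", "VpaResult", "partial_mantel", "MantelResult",
    "rf_importance", "spearman_matrix", "env_distance", "geographic_distance",
]


def hellinger(counts: pd.DataFrame) -> np.ndarray:
    """Hellinger transform: square root of relative abundances."""
    return np.sqrt(relative_abundance(counts).to_numpy())


# ---------------------------------------------------------------- VPA

def _adjusted_r2(y: np.ndarray, x: np.ndarray) -> float:
    """Adjusted RDA R2 (Ezekiel) of multivariate y on predictor block x."""
    n = y.shape[0]
    yc = y - y.mean(axis=0)
    xc = x - x.mean(axis=0)
    p = np.linalg.matrix_rank(xc)
    beta, *_ = np.linalg.lstsq(xc, yc, rcond=None)
    fitted = xc @ beta
    sst = float((yc**2).sum())
    r2 = float((fitted**2).sum()) / sst if sst > 0 else 0.0
    if n - p - 1 <= 0:
        raise ValueError("too few samples for the predictor block")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


@dataclass
class VpaResult:
    """Venn fractions of a three-category variance partitioning.

    ``fractions`` holds the raw (possibly negative) adjusted-R2 fractions with
    keys like ``unique[Nutrient]``, ``shared[Nutrient&Geography]``,
    ``shared[all]`` and ``residual``; ``clamped`` is the display version with
    negatives set to zero.  Raw fractions + residual sum to 1 by construction.
    """

    categories: tuple[str, str, str]
    fractions: dict[str, float]
    clamped: dict[str, float]
    marginal_adjusted_r2: dict[str, float]

    def summary(self) -> str:
        lines = ["Variance partitioning (adjusted R2 fractions)", "-" * 46]
        for k, v in self.fractions.items():
            lines.append(f"{k:<40s} {v:+.4f}")
        return "\n".join(lines)


def vpa(community: CommunityMatrix | pd.DataFrame, predictors: pd.DataFrame,
        categories: dict[str, list[str]] | None = None) -> VpaResult:
    """Three-way variance partitioning of the Hellinger-transformed community.

    ``predictors`` must carry every column named in ``categories``; the
    default categories are the Nutrient / Physicochemistry split of the 14
    environmental variables plus Geography = (longitude, latitude), which are
    expected among the predictor columns.
    """
    counts = community.counts if isinstance(community, CommunityMatrix) else community
    if categories is None:
        categories = {
            "Nutrient": [v for v, c in ENV_CATEGORIES.items() if c == "Nutrient"],
            "Physicochemistry": [v for v, c in ENV_CATEGORIES.items() if c == "Physicochemistry"],
            "Geography": ["longitude", "latitude"],
        }
    if len(categories) != 3:
        raise ValueError("vpa requires exactly three categories")
    names = tuple(categories)
    for name, cols in categories.items():
        if not cols:
            raise ValueError(f"category {name!r} has no variables")
        missing = [c for c in cols if c not in predictors.columns]
        if missing:
            raise ValueError(f"category {name!r} missing predictors: {missing}")
        block = predictors[cols].to_numpy(float)
        bc = block - block.mean(axis=0)
        if np.linalg.matrix_rank(bc) < bc.shape[1]:
            raise ValueError(f"rank-deficient predictor block in {name!r}: {cols}")

    y = hellinger(counts)
    n = y.shape[0]
    total_p = sum(len(c) for c in categories.values())
    if n <= total_p + 2:
        raise ValueError("need n samples > total predictors + 2")

    def block(*names_):
        cols = [c for nm in names_ for c in categories[nm]]
        return predictors[cols].to_numpy(float)

    A, B, C = names
    adj = {
        A: _adjusted_r2(y, block(A)),
        B: _adjusted_r2(y, block(B)),
        C: _adjusted_r2(y, block(C)),
        A + B: _adjusted_r2(y, block(A, B)),
        A + C: _adjusted_r2(y, block(A, C)),
        B + C: _adjusted_r2(y, block(B, C)),
        A + B + C: _adjusted_r2(y, block(A, B, C)),
    }
    abc = adj[A + B + C]
    a = abc - adj[B + C]
    b = abc - adj[A + C]
    c = abc - adj[A + B]
    d = abc - adj[C] - a - b          # shared A&B (not C)
    e = abc - adj[A] - b - c          # shared B&C (not A)
    f = abc - adj[B] - a - c          # shared A&C (not B)
    g = abc - (a + b + c + d + e + f)  # shared by all three
    residual = 1.0 - abc
    fractions = {
        f"unique[{A}]": a,
        f"unique[{B}]": b,
        f"unique[{C}]": c,
        f"shared[{A}&{B}]": d,
        f"shared[{B}&{C}]": e,
        f"shared[{A}&{C}]": f,
        "shared[all]": g,
        "residual": residual,
    }
    clamped = {k: max(v, 0.0) for k, v in fractions.items()}
    return VpaResult(categories=names, fractions=fractions, clamped=clamped,
                     marginal_adjusted_r2=adj)


# ---------------------------------------------------------- Mantel tests

def env_distance(values) -> np.ndarray:
    """Euclidean distance on the z-scored variable."""
    v = np.asarray(values, float)
    sd = v.std()
    z = (v - v.mean()) / (sd if sd > 0 else 1.0)
    return np.abs(z[:, None] - z[None, :])


def geographic_distance(lon, lat) -> np.ndarray:
    """Great-circle (haversine) distance matrix in kilometres."""
    lon, lat = np.deg2rad(np.asarray(lon, float)), np.deg2rad(np.asarray(lat, float))
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    return 2 * 6371.0 * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    controlled: str = "none"


def _offdiag(mat: np.ndarray, iu) -> np.ndarray:
    return mat[iu]


def partial_mantel(community_dist: np.ndarray, env_dist: np.ndarray,
                   control_dist: np.ndarray | None = None, n_perm: int = 999,
                   seed: int = 0, controlled: str = "control") -> MantelResult:
    """Partial Mantel correlation of two distance matrices given a third.

    The statistic is the Pearson correlation of the off-diagonal vectors of
    ``community_dist`` and ``env_dist`` after both are residualised on
    ``control_dist``.  Significance permutes rows/columns of the community
    matrix jointly; p = (1 + #{|r_perm| >= |r_obs|}) / (1 + n_perm).
    With ``control_dist=None`` this is the simple Mantel test.
    """
    dc = np.asarray(community_dist, float)
    de = np.asarray(env_dist, float)
    n = dc.shape[0]
    if dc.shape != de.shape or dc.shape[0] != dc.shape[1]:
        raise ValueError("distance matrices must be square and equally sized")
    if control_dist is not None and np.asarray(control_dist).shape != dc.shape:
        raise ValueError("control matrix size mismatch")
    iu = np.triu_indices(n, 1)

    def resid(vec, ctrl):
        if ctrl is None or np.std(ctrl) == 0:
            return vec - vec.mean()
        x = np.column_stack([np.ones_like(ctrl), ctrl])
        beta, *_ = np.linalg.lstsq(x, vec, rcond=None)
        return vec - x @ beta

    ctrl = _offdiag(np.asarray(control_dist, float), iu) if control_dist is not None else None
    ev = resid(_offdiag(de, iu), ctrl)

    def corr_with(cv):
        cvr = resid(cv, ctrl)
        denom = np.linalg.norm(cvr) * np.linalg.norm(ev)
        return float(cvr @ ev / denom) if denom > 0 else 0.0

    r_obs = corr_with(_offdiag(dc, iu))
    rng = np.random.default_rng(seed)
    ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        ge += abs(corr_with(_offdiag(dc[np.ix_(perm, perm)], iu))) >= abs(r_obs) - 1e-15
    p = (1 + ge) / (1 + n_perm)
    return MantelResult(r=r_obs, p_value=float(p), n_permutations=n_perm,
                        controlled=controlled if control_dist is not None else "none")


# --------------------------------------------- random-forest importance

def _forest_incmse(x: np.ndarray, y: np.ndarray, n_trees: int, mtry: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Mean per-tree percent OOB-MSE increase under predictor permutation."""
    n, p = x.shape
    inc = np.zeros(p)
    used = np.zeros(p)
    for _ in range(n_trees):
        boot = rng.integers(0, n, n)
        oob = np.setdiff1d(np.arange(n), boot, assume_unique=False)
        if len(oob) < 2:
            continue
        tree = DecisionTreeRegressor(max_features=mtry,
                                     random_state=int(rng.integers(0, 2**31 - 1)))
        tree.fit(x[boot], y[boot])
        x_oob = x[oob]
        base_mse = float(np.mean((tree.predict(x_oob) - y[oob]) ** 2))
        if base_mse <= 0:
            continue
        # one stacked predict for all p permuted copies
        stacked = np.tile(x_oob, (p, 1))
        m = len(oob)
        for j in range(p):
            stacked[j * m:(j + 1) * m, j] = x_oob[rng.permutation(m), j]
        perm_pred = tree.predict(stacked).reshape(p, m)
        perm_mse = np.mean((perm_pred - y[oob]) ** 2, axis=1)
        inc += (perm_mse - base_mse) / base_mse * 100.0
        used += 1
    if not used.any():
        raise RuntimeError("no tree produced an out-of-bag sample")
    return inc / np.maximum(used, 1)


def rf_importance(X: pd.DataFrame, y, n_trees: int = 1000, n_null: int = 100,
                  seed: int = 0, mtry: int | None = None) -> pd.DataFrame:
    """Permutation importance (%IncMSE) of each predictor with a
    response-permutation significance test.

    A regression forest (``n_trees`` trees, ``mtry = floor(p/3)`` features per
    split) is grown on bootstrap samples; %IncMSE is the percent increase in
    out-of-bag MSE when the predictor is permuted, averaged over trees.  The
    null distribution comes from ``n_null`` refits with permuted response;
    p = (1 + #{null >= observed}) / (1 + n_null).  Output is ranked by
    importance, descending.
    """
    x = np.asarray(X, float)
    yv = np.asarray(y, float)
    if np.isnan(x).any() or np.isnan(yv).any():
        raise ValueError("missing values in predictors or response")
    if x.shape[0] < 30:
        raise ValueError("need >= 30 samples")
    if np.std(yv) == 0:
        raise ValueError("degenerate response: y is constant")
    p = x.shape[1]
    mtry = mtry if mtry is not None else max(1, p // 3)

    rng = np.random.default_rng(seed)
    observed = _forest_incmse(x, yv, n_trees, mtry, rng)
    null = np.empty((n_null, p))
    for k in range(n_null):
        null[k] = _forest_incmse(x, rng.permutation(yv), n_trees, mtry, rng)
    p_values = (1 + (null >= observed[None, :]).sum(axis=0)) / (1 + n_null)

    out = pd.DataFrame({
        "inc_mse_pct": observed,
        "p_value": p_values,
    }, index=pd.Index(list(X.columns), name="predictor"))
    out = out.sort_values("inc_mse_pct", ascending=False)
    out["rank"] = np.arange(1, p + 1)
    return out


# ------------------------------------------------------ Spearman matrix

def spearman_matrix(env: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman rho (tie-corrected) with BH-adjusted p over pairs.

    Constant columns yield NaN rho/p for their pairs.
    Returns (rho matrix, adjusted-p matrix).
    """
    if len(env) < 3:
        raise ValueError("need >= 3 samples")
    cols = list(env.columns)
    k = len(cols)
    rho = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    praw = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    pairs, pvals = [], []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = env.iloc[:, i], env.iloc[:, j]
            if a.std() == 0 or b.std() == 0:
                r, pv = np.nan, np.nan
            else:
                r, pv = stats.spearmanr(a, b)
            rho.iloc[i, j] = rho.iloc[j, i] = r
            praw.iloc[i, j] = praw.iloc[j, i] = pv
            pairs.append((i, j))
            pvals.append(pv)
    pvals = np.asarray(pvals, float)
    ok = ~np.isnan(pvals)
    adj = np.full_like(pvals, np.nan)
    if ok.any():
        adj[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
    padj = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    for (i, j), q in zip(pairs, adj):
        padj.iloc[i, j] = padj.iloc[j, i] = q
    np.fill_diagonal(padj.values, 0.0)
    return rho, padj
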