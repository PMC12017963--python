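"""Alpha diversity with seasonal tests, and Bray–Curtis beta diversity
(PCoA with Lingoes correction + PERMANOVA).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .io import CommunityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "alpha_diversity", "seasonal_test", "pcoa_lingoes", "pcoa_permanova",
    "bray_curtis", "stars",
]


def stars(p: float) -> str:
    """Significance stars: *** P<.001, ** P<.01, * P<.05, else ''."""
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def alpha_diversity(m: CommunityMatrix, taxa: list[str] | None = None) -> pd.DataFrame:
    """Richness and Shannon entropy (nats) per sample over a taxon subset.

    All-zero rows get NaN diversity and ``flagged=True``.
    """
    counts = m.counts if taxa is None else m.counts[list(taxa)]
    if counts.shape[1] == 0:
        raise ValueError("taxon subset is empty")
    x = counts.to_numpy(dtype=float)
    totals = x.sum(axis=1)
    richness = (x > 0).sum(axis=1)
    shannon = np.full(len(x), np.nan)
    ok = totals > 0
    p = x[ok] / totals[ok, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        shannon[ok] = -np.nansum(np.where(p > 0, p * np.log(p), 0.0), axis=1)
    return pd.DataFrame({
        "richness": richness,
        "shannon": shannon,
        "flagged": ~ok,
    }, index=counts.index)


def seasonal_test(values: pd.Series, seasons: pd.Series) -> dict:
    """Kruskal–Wallis omnibus + pairwise Wilcoxon rank-sum with BH adjustment.

    Seasons with fewer than 2 samples are excluded (logged).  Returns
    ``{"omnibus_p", "pairwise"}`` where ``pairwise`` is a DataFrame with
    raw p, BH-adjusted p and the star encoding.
    """
    df = pd.DataFrame({"value": values, "season": seasons}).dropna()
    sizes = df.groupby("season").size()
    keep = sizes[sizes >= 2].index
    if len(keep) < len(sizes):
        logger.warning("excluding seasons with <2 samples: %s",
                       sorted(set(sizes.index) - set(keep)))
    df = df[df["season"].isin(keep)]
    if df["season"].nunique() < 2:
        raise ValueError("need >= 2 seasons with >= 2 samples each")

    groups = {s: g["value"].to_numpy() for s, g in df.groupby("season")}
    omnibus = stats.kruskal(*groups.values())

    rows = []
    for a, b in combinations(sorted(groups), 2):
        res = stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
        rows.append({"group_a": a, "group_b": b, "p_raw": res.pvalue})
    pairwise = pd.DataFrame(rows)
    pairwise["p_adj"] = multipletests(pairwise["p_raw"], method="fdr_bh")[1]
    pairwise["stars"] = [stars(p) for p in pairwise["p_adj"]]
    return {"omnibus_p": float(omnibus.pvalue), "pairwise": pairwise}


def bray_curtis(counts: pd.DataFrame | np.ndarray) -> np.ndarray:
    x = counts.to_numpy(float) if isinstance(counts, pd.DataFrame) else np.asarray(counts, float)
    return squareform(pdist(x, metric="braycurtis"))


def pcoa_lingoes(dissim: np.ndarray, n_axes: int = 2):
    """Principal coordinates with the Lingoes correction for negative
    eigenvalues (adds the constant ``-2*lambda_min`` to squared
    dissimilarities off the diagonal when needed).

    Returns (coordinates n x n_axes, eigenvalues, proportion explained,
    correction constant).
    """
    d = np.asarray(dissim, float)
    n = d.shape[0]

    j = np.eye(n) - np.ones((n, n)) / n

    def gower_from_d2(d2):
        return j @ (-0.5 * d2) @ j

    eigval, eigvec = np.linalg.eigh(gower_from_d2(d**2))
    c = 0.0
    if eigval.min() < -1e-8 * max(1.0, eigval.max()):
        c = -eigval.min()
        d2 = d**2 + 2.0 * c
        np.fill_diagonal(d2, 0.0)
        eigval, eigvec = np.linalg.eigh(gower_from_d2(d2))
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = np.clip(eigval, 0.0, None)
    coords = eigvec[:, :n_axes] * np.sqrt(pos[:n_axes])
    total = pos.sum()
    explained = pos / total if total > 0 else pos
    return coords, eigval, explained, c


def _permanova_f(d2: np.ndarray, labels: np.ndarray) -> float:
    """Pseudo-F from the standard partition of squared dissimilarities."""
    n = len(labels)
    sst = d2[np.triu_indices(n, 1)].sum() / n
    ssw = 0.0
    groups, counts = np.unique(labels, return_counts=True)
    for g, ng in zip(groups, counts):
        idx = np.flatnonzero(labels == g)
        sub = d2[np.ix_(idx, idx)]
        ssw += sub[np.triu_indices(ng, 1)].sum() / ng
    ssa = sst - ssw
    a = len(groups)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssa / (a - 1)) / (ssw / (n - a))
    return float(np.nan_to_num(f, nan=0.0, posinf=np.inf))


def pcoa_permanova(m: CommunityMatrix, labels: pd.Series | None = None,
                   n_perm: int = 999, seed: int = 0, n_axes: int = 2) -> dict:
    """Bray–Curtis PCoA (Lingoes-corrected) plus PERMANOVA on ``labels``.

    The permutation p-value is ``(1 + #{F_perm >= F_obs}) / (1 + n_perm)``;
    when the group arrangement count is below ``n_perm`` the exact
    permutation distribution is enumerated instead.
    """
    if labels is None:
        labels = m.metadata["season"]
    labels = pd.Series(labels).loc[m.counts.index]
    lab = labels.to_numpy()
    if len(np.unique(lab)) < 2:
        raise ValueError("need >= 2 groups")

    d = bray_curtis(m.counts)
    d2 = d**2
    f_obs = _permanova_f(d2, lab)

    from math import factorial
    n = len(lab)
    _, counts = np.unique(lab, return_counts=True)
    n_arrangements = factorial(n) // int(np.prod([factorial(int(c)) for c in counts]))
    rng = np.random.default_rng(seed)
    if n_arrangements <= n_perm:
        from itertools import permutations as iperm
        seen = set()
        f_null = []
        for perm in iperm(range(n)):
            key = tuple(lab[list(perm)])
            if key in seen:
                continue
            seen.add(key)
            f_null.append(_permanova_f(d2, np.asarray(key)))
        f_null = np.asarray(f_null)
        p = float((f_null >= f_obs - 1e-12).mean())
    else:
        ge = 0
        for _ in range(n_perm):
            ge += _permanova_f(d2, rng.permutation(lab)) >= f_obs
        p = (1 + ge) / (1 + n_perm)

    coords, eigval, explained, c = pcoa_lingoes(d, n_axes=n_axes)
    ordination = pd.DataFrame(
        coords, index=m.counts.index,
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )
    return {
        "ordination": ordination,
        "eigenvalues": eigval,
        "proportion_explained": explained,
        "lingoes_constant": c,
        "pseudo_F": float(f_obs),
        "p_value": float(p),
        "n_permutations": n_perm,
    }
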