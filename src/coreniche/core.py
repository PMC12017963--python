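"""Core-taxa prioritisation by spatiotemporal occupancy and the Bray–Curtis
contribution curve.

Taxa are ranked by a blend of overall occupancy (fraction of all samples in
which the taxon is detected) and temporal occupancy (mean over months of the
fraction of stations detected within the month).  The contribution curve
C(k) gives the fraction of total pairwise Bray–Curtis similarity explained by
the top-k ranked taxa; the core is cut at the last rank whose relative gain
in explained similarity is at least ``gain`` (default 1%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .io import CommunityMatrix, relative_abundance

__all__ = [
    "compute_occupancy", "contribution_curve", "select_core",
    "core_fraction", "ContributionCurve",
]


def compute_occupancy(m: CommunityMatrix) -> pd.DataFrame:
    """Per-taxon occupancy statistics and the blended rank.

    Returns a DataFrame indexed by taxon id, sorted by rank (1 = most core),
    with columns ``overall_occupancy``, ``temporal_occupancy``,
    ``mean_relabund``, ``rank_index`` and ``rank``.

    ``rank_index`` is the mean of the two scaled occupancy ranks (higher is
    better); ties are broken by mean relative abundance (descending), then by
    taxon id (lexicographic).
    """
    if m.n_samples == 0 or m.n_taxa == 0:
        raise ValueError("community matrix is empty")
    from scipy.stats import rankdata

    present = m.counts.to_numpy() > 0
    overall = present.mean(axis=0)

    months = m.metadata["month"].to_numpy()
    monthly = []
    for mo in np.unique(months):
        monthly.append(present[months == mo].mean(axis=0))
    temporal = np.mean(monthly, axis=0)

    relab = relative_abundance(m).to_numpy().mean(axis=0)
    n = m.n_taxa
    rank_index = (rankdata(overall) / n + rankdata(temporal) / n) / 2.0

    df = pd.DataFrame(
        {
            "overall_occupancy": overall,
            "temporal_occupancy": temporal,
            "mean_relabund": relab,
            "rank_index": rank_index,
        },
        index=pd.Index(m.taxon_ids, name="taxon_id"),
    )
    df = df.sort_values(
        ["rank_index", "mean_relabund", "taxon_id"],
        ascending=[False, False, True],
        kind="mergesort",
    )
    df["rank"] = np.arange(1, n + 1)
    return df


@dataclass
class ContributionCurve:
    """Cumulative Bray–Curtis similarity contribution of the top-k taxa."""

    ranking: list[str]
    contribution: np.ndarray  # C(k), k = 1..n
    gains: np.ndarray         # relative gain g(k) = (C(k)-C(k-1))/C(k-1); g(1)=nan

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "rank": np.arange(1, len(self.ranking) + 1),
            "taxon_id": self.ranking,
            "contribution": self.contribution,
            "relative_gain": self.gains,
        })


def contribution_curve(m: CommunityMatrix, ranking: list[str]) -> ContributionCurve:
    """Fraction of total pairwise Bray–Curtis similarity explained by top-k sets.

    For samples i, j the similarity restricted to a taxon set S is
    ``2 * sum_{t in S} min(x_it, x_jt) / (total_i + total_j)`` with totals over
    all taxa, so per-taxon contributions are additive and
    C(k) = cumsum(S_t over ranking) / total similarity.
    """
    if m.n_samples < 2:
        raise ValueError("need >=2 samples to compute pairwise similarity")
    if sorted(ranking) != sorted(m.taxon_ids):
        raise ValueError("ranking must be a permutation of the matrix taxa")

    x = m.counts[ranking].to_numpy(dtype=np.float64)
    totals = x.sum(axis=1)
    n = x.shape[0]
    shares = np.zeros(x.shape[1])
    for i in range(n - 1):
        pair_w = 2.0 / (totals[i] + totals[i + 1:])          # (n-i-1,)
        mins = np.minimum(x[i], x[i + 1:])                    # (n-i-1, t)
        shares += pair_w @ mins
    total = shares.sum()
    if total <= 0:
        raise ValueError("total Bray–Curtis similarity is zero")
    c = np.cumsum(shares) / total
    gains = np.full_like(c, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        gains[1:] = np.diff(c) / c[:-1]
    return ContributionCurve(list(ranking), c, gains)


def select_core(curve: ContributionCurve, gain: float = 0.01,
                mode: str = "relative") -> list[str]:
    """Select the core as the top-k* taxa, k* = last rank with gain >= ``gain``.

    ``mode='relative'`` (default) uses the relative gain
    (C(k)-C(k-1))/C(k-1); ``mode='absolute'`` uses C(k)-C(k-1).  A step
    qualifies when its gain strictly exceeds the threshold (an exact-tie gain
    is not an "increase by more than" the threshold; a 1e-9 relative guard
    absorbs float noise).  If no rank k >= 2 qualifies, the top-1 taxon is
    returned with a warning.
    """
    if gain <= 0:
        raise ValueError("gain must be > 0")
    if mode == "relative":
        g = curve.gains
    elif mode == "absolute":
        g = np.concatenate([[np.nan], np.diff(curve.contribution)])
    else:
        raise ValueError(f"mode must be relative|absolute, got {mode!r}")
    qualifying = np.flatnonzero(np.nan_to_num(g, nan=-np.inf) > gain * (1 + 1e-9))
    if len(qualifying) == 0:
        warnings.warn(
            "no rank reaches the gain threshold; falling back to top-1",
            stacklevel=2,
        )
        return curve.ranking[:1]
    k_star = int(qualifying[-1]) + 1  # ranks are 1-based
    return curve.ranking[:k_star]


def core_fraction(core_size: int, total: int) -> float:
    """Core share of all taxa as a percentage, rounded half-up to one decimal."""
    if total <= 0:
        raise ValueError("total must be > 0")
    if not 0 < core_size <= total:
        raise ValueError("core_size must lie in (0, total]")
    pct = Decimal(100 * core_size) / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
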