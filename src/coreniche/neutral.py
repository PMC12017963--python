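"""Sloan neutral community model for abundance–occupancy distributions.

Under neutral dispersal with migration parameter ``m`` and local community
size ``Nt`` (the rarefaction depth), the expected occupancy of a taxon with
mean relative abundance ``p`` is

    occ(p) = 1 - BetaCDF(d / Nt; Nt*m*p, Nt*m*(1 - p))

where ``d`` is the detection limit in reads (default 1).  ``m`` is estimated
by least squares on observed occupancy against ``p``; taxa are classified as
above/within/below a 95% Wilson binomial band around the fitted curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import beta as beta_dist
from statsmodels.stats.proportion import proportion_confint

__all__ = ["NeutralCommunityModel", "NeutralFitResults", "fit_neutral"]


def sloan_occupancy(p: np.ndarray, m: float, Nt: float, d: float = 1.0) -> np.ndarray:
    """Predicted occupancy under the neutral model (nondecreasing in p)."""
    p = np.clip(np.asarray(p, dtype=float), 1e-12, 1 - 1e-12)
    return 1.0 - beta_dist.cdf(d / Nt, Nt * m * p, Nt * m * (1.0 - p))


@dataclass
class NeutralCommunityModel:
    """Model object: mean relative abundances + observed occupancies.

    Parameters
    ----------
    mean_relabund : per-taxon mean relative abundance p.
    occupancy : per-taxon observed occupancy in [0, 1].
    Nt : community size (reads per sample after rarefaction).
    n_samples : number of samples behind the occupancy estimates (for the
        Wilson confidence band).
    d : detection limit in reads (default 1).
    """

    mean_relabund: np.ndarray
    occupancy: np.ndarray
    Nt: int
    n_samples: int
    d: int = 1
    taxon_ids: list | None = None

    @classmethod
    def from_community(cls, m, d: int = 1) -> "NeutralCommunityModel":
        """Build from a CommunityMatrix (rows must share a common depth)."""
        from .io import relative_abundance

        totals = m.counts.sum(axis=1)
        relab = relative_abundance(m)
        return cls(
            mean_relabund=relab.to_numpy().mean(axis=0),
            occupancy=(m.counts.to_numpy() > 0).mean(axis=0),
            Nt=int(round(float(totals.mean()))),
            n_samples=m.n_samples,
            d=d,
            taxon_ids=m.taxon_ids,
        )

    def fit(self) -> "NeutralFitResults":
        p = np.asarray(self.mean_relabund, dtype=float)
        occ = np.asarray(self.occupancy, dtype=float)
        keep = p > 0
        if keep.sum() < 10:
            raise ValueError("need >= 10 taxa with nonzero abundance")
        p_fit, occ_fit = p[keep], occ[keep]

        def ssr(log_m: float) -> float:
            pred = sloan_occupancy(p_fit, np.exp(log_m), self.Nt, self.d)
            return float(np.sum((occ_fit - pred) ** 2))

        res = optimize.minimize_scalar(ssr, bounds=(np.log(1e-6), np.log(10.0)),
                                       method="bounded",
                                       options={"xatol": 1e-8})
        if not res.success:
            raise RuntimeError(f"neutral-model fit did not converge: {res}")
        m_hat = float(np.exp(res.x))

        pred = sloan_occupancy(p, m_hat, self.Nt, self.d)
        sst = float(np.sum((occ_fit - occ_fit.mean()) ** 2))
        r2 = 1.0 - res.fun / sst if sst > 0 else np.nan

        k = np.clip(np.round(pred * self.n_samples), 0, self.n_samples)
        lo, hi = proportion_confint(k, self.n_samples, alpha=0.05, method="wilson")
        classes = np.where(occ > hi, "above", np.where(occ < lo, "below", "within"))

        table = pd.DataFrame({
            "mean_relabund": p,
            "occupancy": occ,
            "predicted": pred,
            "ci_lower": lo,
            "ci_upper": hi,
            "neutral_class": classes,
        }, index=self.taxon_ids if self.taxon_ids is not None else None)
        return NeutralFitResults(model=self, m=m_hat, r_squared=float(r2),
                                 table=table)


@dataclass
class NeutralFitResults:
    """Fitted neutral model: migration rate, fit quality and per-taxon band."""

    model: NeutralCommunityModel
    m: float
    r_squared: float
    table: pd.DataFrame

    def predict(self, p) -> np.ndarray:
        return sloan_occupancy(np.asarray(p, float), self.m, self.model.Nt,
                               self.model.d)

    def summary(self) -> str:
        counts = self.table["neutral_class"].value_counts()
        lines = [
            "Sloan neutral community model",
            "-" * 34,
            f"migration rate m      {self.m:.5f}",
            f"community size Nt     {self.model.Nt}",
            f"detection limit d     {self.model.d}",
            f"R-squared             {self.r_squared:.4f}",
            f"taxa above band       {counts.get('above', 0)}",
            f"taxa within band      {counts.get('within', 0)}",
            f"taxa below band       {counts.get('below', 0)}",
        ]
        return "\n".join(lines)


def fit_neutral(records: pd.DataFrame, Nt: int, n_samples: int,
                d: int = 1) -> NeutralFitResults:
    """Functional wrapper over :class:`NeutralCommunityModel`.

    ``records`` must carry ``mean_relabund`` and ``overall_occupancy`` (the
    output of :func:`coreniche.core.compute_occupancy`).
    """
    model = NeutralCommunityModel(
        mean_relabund=records["mean_relabund"].to_numpy(),
        occupancy=records["overall_occupancy"].to_numpy(),
        Nt=Nt, n_samples=n_samples, d=d,
        taxon_ids=records.index.tolist(),
    )
    return model.fit()
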