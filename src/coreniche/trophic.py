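"""Trophic-mode annotation and per-sample/seasonal trophic profiles.

Each taxon is assigned one of {autotroph, heterotroph, mixotroph} by merging
the database trophic column (PR2-style) with a manual-override table.  Manual
evidence beats the database; among overrides matching the same taxon, the
most specific lineage rank wins (species > genus > ... > domain).  Taxa with
neither source are "unknown" and excluded from profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import TROPHIC_MODES
from .io import CommunityMatrix
from .simulate import LINEAGE_RANKS

logger = logging.getLogger(__name__)

__all__ = ["annotate_trophic", "trophic_profile", "TrophicProfile"]

_RANK_LEVEL = {rank: i for i, rank in enumerate(LINEAGE_RANKS)}


def _parse_lineage(lineage: str) -> dict[str, str]:
    parts = [p.strip() for p in str(lineage).split(";")]
    return {rank: parts[i] for i, rank in enumerate(LINEAGE_RANKS) if i < len(parts)}


def annotate_trophic(taxonomy: pd.DataFrame,
                     overrides: pd.DataFrame | None = None) -> pd.DataFrame:
    """Assign a trophic mode per taxon.

    Parameters
    ----------
    taxonomy
        Indexed by taxon id; needs ``lineage`` (8-rank, ';'-separated) and
        ``db_trophic`` (mode or NA).
    overrides
        Optional manual table with columns ``lineage_name``, ``rank``,
        ``mode`` (and optionally ``source_citation``).  A row applies to every
        taxon whose lineage carries ``lineage_name`` at ``rank``.

    Returns
    -------
    DataFrame indexed by taxon id with ``mode`` in
    {autotroph, heterotroph, mixotroph, unknown} and ``provenance`` in
    {db, manual, unknown}.  Idempotent and independent of override row order.
    """
    valid = set(TROPHIC_MODES)
    if overrides is not None and len(overrides):
        bad = set(overrides["mode"]) - valid
        if bad:
            raise ValueError(f"override modes outside the vocabulary: {sorted(bad)}")
        bad_ranks = set(overrides["rank"]) - set(LINEAGE_RANKS)
        if bad_ranks:
            raise ValueError(f"override ranks unknown: {sorted(bad_ranks)}")

    modes, provenance = [], []
    for tid, row in taxonomy.iterrows():
        lineage = _parse_lineage(row.get("lineage", ""))
        best = None  # (rank_level, mode)
        if overrides is not None:
            for _, o in overrides.iterrows():
                if lineage.get(o["rank"]) == o["lineage_name"]:
                    level = _RANK_LEVEL[o["rank"]]
                    if best is None or level > best[0]:
                        best = (level, o["mode"])
        if best is not None:
            modes.append(best[1])
            provenance.append("manual")
            continue
        db = row.get("db_trophic")
        if isinstance(db, str) and db in valid:
            modes.append(db)
            provenance.append("db")
        else:
            modes.append("unknown")
            provenance.append("unknown")
    return pd.DataFrame({"mode": modes, "provenance": provenance},
                        index=taxonomy.index.copy())


@dataclass
class TrophicProfile:
    """Per-sample, monthly and seasonal reads/proportions of the three modes."""

    per_sample: pd.DataFrame   # reads_* , prop_*, ratio_auto_mixo, ratio_hete_mixo, flagged
    monthly: pd.DataFrame      # pooled reads then proportions, per month
    seasonal: pd.DataFrame     # pooled reads then proportions, per season


def _pooled(reads: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    pooled = reads.groupby(groups.to_numpy()).sum()
    props = pooled.div(pooled.sum(axis=1), axis=0)
    props.columns = [c.replace("reads_", "prop_") for c in props.columns]
    return pd.concat([pooled, props], axis=1)


def trophic_profile(m: CommunityMatrix, modes: pd.DataFrame | pd.Series,
                    core: list[str] | set[str] | None = None) -> TrophicProfile:
    """Build trophic profiles over the (core) annotated taxa.

    Sums are restricted to ``core`` (if given) intersected with annotated
    taxa; proportions renormalise over the three modes (unknowns excluded
    first).  Monthly/seasonal aggregates pool reads, then take proportions.
    Trophic ratios Auto:Mixo and Hete:Mixo are NaN (flagged) when the sample
    has no mixoplankton reads.
    """
    mode_series = modes["mode"] if isinstance(modes, pd.DataFrame) else modes
    taxa = set(m.taxon_ids)
    if core is not None:
        missing = set(core) - taxa
        if missing:
            raise ValueError(f"core taxa absent from the matrix: {sorted(missing)[:5]}")
        taxa &= set(core)

    reads = {}
    for mode in TROPHIC_MODES:
        cols = [t for t in m.taxon_ids
                if t in taxa and mode_series.get(t) == mode]
        reads[f"reads_{mode}"] = m.counts[cols].sum(axis=1) if cols else pd.Series(0, index=m.counts.index)
    reads = pd.DataFrame(reads)

    total = reads.sum(axis=1)
    flagged = total == 0
    if flagged.any():
        logger.warning("%d samples have zero annotated core reads", int(flagged.sum()))
    props = reads.div(total.where(total > 0), axis=0)
    props.columns = [c.replace("reads_", "prop_") for c in props.columns]

    mixo = reads["reads_mixotroph"].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio_auto = reads["reads_autotroph"] / mixo.where(mixo > 0)
        ratio_hete = reads["reads_heterotroph"] / mixo.where(mixo > 0)

    per_sample = pd.concat([reads, props], axis=1)
    per_sample["ratio_auto_mixo"] = ratio_auto
    per_sample["ratio_hete_mixo"] = ratio_hete
    per_sample["flagged"] = flagged | (mixo == 0)

    monthly = _pooled(reads, m.metadata["month"])
    seasonal = _pooled(reads, m.metadata["season"])
    return TrophicProfile(per_sample=per_sample, monthly=monthly, seasonal=seasonal)
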