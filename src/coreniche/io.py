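"""Reading, validation, filtering, rarefaction and normalisation of
community tables and their companion metadata/environment tables.

The canonical in-memory container is :class:`CommunityMatrix`: an integer
samples x taxa count table plus per-sample metadata (station, month, season,
latitude, longitude).  ASV tables are accepted as TSV with either taxa or
samples as rows (auto-detected against the metadata) and, read-only, as
BIOM 2.x HDF5.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ENV_VARIABLES
from .simulate import season_from_month

logger = logging.getLogger(__name__)

__all__ = [
    "CommunityMatrix", "read_tables", "read_counts", "read_env",
    "filter_min_count", "rarefy", "relative_abundance",
]

METADATA_COLUMNS = ("station", "month", "season", "latitude", "longitude")


@dataclass
class CommunityMatrix:
    """Samples x taxa count matrix with per-sample metadata."""

    counts: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dupes = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        if self.counts.columns.duplicated().any():
            dupes = self.counts.columns[self.counts.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate taxon ids: {dupes}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = self.counts.index.difference(self.metadata.index)
        if len(missing):
            raise ValueError(
                f"samples present in counts but absent from metadata: {missing.tolist()}"
            )
        self.metadata = self.metadata.loc[self.counts.index].copy()
        if "season" not in self.metadata.columns and "month" in self.metadata.columns:
            self.metadata["season"] = [
                season_from_month(int(m)) for m in self.metadata["month"]
            ]

    @property
    def sample_ids(self) -> list[str]:
        return self.counts.index.tolist()

    @property
    def taxon_ids(self) -> list[str]:
        return self.counts.columns.tolist()

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def subset_taxa(self, taxa) -> "CommunityMatrix":
        taxa = [t for t in self.taxon_ids if t in set(taxa)]
        return CommunityMatrix(self.counts[taxa].copy(), self.metadata.copy())

    def copy(self) -> "CommunityMatrix":
        return CommunityMatrix(self.counts.copy(), self.metadata.copy())


def _read_biom(path: Path) -> pd.DataFrame:
    """Minimal BIOM 2.1 (HDF5) reader; returns a samples x taxa DataFrame."""
    import h5py
    from scipy import sparse

    with h5py.File(path, "r") as f:
        obs_ids = [x.decode() if isinstance(x, bytes) else str(x) for x in f["observation/ids"][:]]
        sample_ids = [x.decode() if isinstance(x, bytes) else str(x) for x in f["sample/ids"][:]]
        g = f["observation/matrix"]
        mat = sparse.csr_matrix(
            (g["data"][:], g["indices"][:], g["indptr"][:]),
            shape=(len(obs_ids), len(sample_ids)),
        )
    dense = np.asarray(mat.todense())
    return pd.DataFrame(dense.T, index=sample_ids, columns=obs_ids)


def read_counts(path: str | Path, orientation: str = "auto",
                sample_ids=None) -> pd.DataFrame:
    """Read an ASV table (TSV, or BIOM 2.x HDF5) as samples x taxa.

    ``orientation`` is one of ``auto | samples | taxa`` (rows).  Auto-detection
    compares row labels against ``sample_ids`` when given, else assumes taxa
    rows (the common deposition layout).
    """
    path = Path(path)
    if path.suffix == ".biom":
        return _read_biom(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if orientation == "auto":
        if sample_ids is not None and len(set(df.index) & set(sample_ids)) >= max(
            1, len(set(df.index)) // 2
        ):
            orientation = "samples"
        else:
            orientation = "taxa"
    if orientation == "taxa":
        df = df.T
    elif orientation != "samples":
        raise ValueError(f"orientation must be auto|samples|taxa, got {orientation!r}")
    return df


def read_env(path: str | Path) -> pd.DataFrame:
    """Read and validate the 14-variable environment table (CSV)."""
    env = pd.read_csv(path, index_col=0)
    missing = [v for v in ENV_VARIABLES if v not in env.columns]
    if missing:
        raise ValueError(f"environment table missing columns: {missing}")
    n_missing = int(env[list(ENV_VARIABLES)].isna().sum().sum())
    if n_missing:
        logger.warning("environment table has %d missing cells", n_missing)
    return env


def read_tables(
    counts_path: str | Path,
    taxonomy_path: str | Path,
    metadata_path: str | Path,
    env_path: str | Path,
    orientation: str = "auto",
) -> tuple[CommunityMatrix, pd.DataFrame, pd.DataFrame]:
    """Read the standard input quartet and enforce cross-file consistency."""
    metadata = pd.read_csv(metadata_path, index_col=0)
    counts = read_counts(counts_path, orientation, sample_ids=metadata.index)
    counts = counts.astype(np.int64)
    m = CommunityMatrix(counts, metadata)

    taxonomy = pd.read_csv(taxonomy_path, sep="\t", index_col=0)
    unknown_taxa = set(m.taxon_ids) - set(taxonomy.index)
    if unknown_taxa:
        logger.warning("%d taxa lack taxonomy rows", len(unknown_taxa))

    env = read_env(env_path)
    missing_env = set(m.sample_ids) - set(env.index)
    if missing_env:
        raise ValueError(
            f"samples missing from environment table: {sorted(missing_env)[:5]}"
        )
    return m, taxonomy, env.loc[m.sample_ids]


def filter_min_count(m: CommunityMatrix, min_reads: int = 8) -> CommunityMatrix:
    """Drop taxa whose total count across samples is below ``min_reads``.

    Column order of survivors is preserved.  The default mirrors the common
    denoising practice of removing ASVs with fewer than 8 reads overall.
    """
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    totals = m.counts.sum(axis=0)
    keep = totals[totals >= min_reads].index
    if len(keep) == 0:
        warnings.warn("filter_min_count removed every taxon", stacklevel=2)
    return CommunityMatrix(m.counts[keep].copy(), m.metadata.copy())


def rarefy(m: CommunityMatrix, depth: int, seed: int) -> CommunityMatrix:
    """Subsample each sample to ``depth`` reads without replacement.

    Samples whose total is already exactly ``depth`` pass through unchanged;
    samples below ``depth`` are dropped (and logged).  Subsampling is
    hypergeometric (without replacement), so absent taxa stay absent.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = m.counts.sum(axis=1)
    keep_rows = totals[totals >= depth].index
    dropped = totals.index.difference(keep_rows)
    if len(keep_rows) == 0:
        raise ValueError(f"all samples have fewer than {depth} reads")
    if len(dropped):
        logger.warning("rarefy dropped %d samples below depth %d: %s",
                       len(dropped), depth, dropped.tolist()[:5])
    out = np.empty((len(keep_rows), m.n_taxa), dtype=np.int64)
    for i, sid in enumerate(keep_rows):
        row = m.counts.loc[sid].to_numpy()
        if row.sum() == depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, depth, method="marginals")
    counts = pd.DataFrame(out, index=keep_rows, columns=m.counts.columns)
    return CommunityMatrix(counts, m.metadata.loc[keep_rows].copy())


def relative_abundance(m: CommunityMatrix | pd.DataFrame) -> pd.DataFrame:
    """Row-normalise counts to relative abundances (rows sum to 1)."""
    counts = m.counts if isinstance(m, CommunityMatrix) else m
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        bad = totals.index[totals == 0].tolist()
        raise ValueError(f"zero-sum sample rows: {bad}")
    return counts.div(totals, axis=0)
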