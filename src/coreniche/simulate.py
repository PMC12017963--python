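"""Synthetic survey generator with planted, recorded ground truth.

The generator emits the four standard pipeline inputs (ASV counts, taxonomy,
sample metadata, environment) for a ``n_stations x n_months`` coastal survey,
plus a :class:`~coreniche.config.GroundTruth` record of everything planted:

* core membership — core ASVs occur in each sample with probability
  ``core_occupancy``, the rest with ``noncore_occupancy``;
* a lognormal abundance field with a small bloom-scale "dominant" tail among
  the core, mirroring the strong dominance structure of coastal plankton;
* three trophic modes, with the per-sample mixoplankton share following
  ``peak * exp(-sum(((x - opt)/width)^2) + noise)`` in (temperature, DO,
  NO3-N); the heterotroph share moves oppositely and autotrophs absorb the
  remainder;
* seasonally structured environmental covariates (sinusoidal temperature with
  fixed station offsets, DO anti-correlated with temperature, wet/dry-season
  nutrients) and fixed station coordinates.

Counts are drawn by multinomial allocation of a fixed per-sample depth, so
the emitted matrix is already rarefied.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .config import ENV_VARIABLES, TROPHIC_MODES, GroundTruth, SimConfig

__all__ = ["generate_environment", "generate_community", "simulate_survey", "write_inputs"]

#: months of the local wet season (sub-tropical coastal: June–September)
WET_MONTHS = frozenset({6, 7, 8, 9})

# PR2-style 8-rank lineage used for the synthetic taxonomy
LINEAGE_RANKS = (
    "domain", "supergroup", "division", "class",
    "order", "family", "genus", "species",
)


def season_from_month(month: int) -> str:
    """Dec–Feb winter, Mar–May spring, Jun–Aug summer, Sep–Nov autumn."""
    if month in (12, 1, 2):
        return "winter"
    if month in (3, 4, 5):
        return "spring"
    if month in (6, 7, 8):
        return "summer"
    if month in (9, 10, 11):
        return "autumn"
    raise ValueError(f"month must be 1..12, got {month}")


def _station_layout(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Fixed station coordinates inside a small coastal bounding box."""
    lon = rng.uniform(113.9, 114.45, cfg.n_stations)
    lat = rng.uniform(22.15, 22.55, cfg.n_stations)
    ids = [f"ST{i + 1:02d}" for i in range(cfg.n_stations)]
    return pd.DataFrame({"station": ids, "longitude": lon, "latitude": lat})


def generate_environment(cfg: SimConfig) -> pd.DataFrame:
    """Generate one environment row per station x month.

    Returns a DataFrame indexed by sample id with sample metadata columns
    (station, month, season, latitude, longitude) followed by the 14
    environmental variables.  Deterministic given ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    stations = _station_layout(cfg, rng)
    station_temp_offset = rng.normal(0.0, cfg.station_sd, cfg.n_stations)
    station_nutrient = np.exp(rng.normal(0.0, 0.25 * (cfg.station_sd / 0.8 if cfg.station_sd else 0.0), cfg.n_stations))

    rows = []
    for m in range(1, cfg.n_months + 1):
        month = ((m - 1) % 12) + 1
        # annual sinusoid peaking in early August
        t_season = 19.0 + 9.0 * np.cos(2 * np.pi * (month - 7.5) / 12.0)
        wet = month in WET_MONTHS
        for s in range(cfg.n_stations):
            e = rng.normal(0.0, cfg.env_noise_sd, 12)
            temperature = t_season + station_temp_offset[s] + e[0]
            do = max(12.5 - 0.35 * temperature + 4.0 * e[1], 0.2)
            no3 = (0.35 + 0.75 * wet) * station_nutrient[s] * np.exp(0.6 * e[2])
            nh4 = (0.10 + 0.12 * wet) * station_nutrient[s] * np.exp(0.6 * e[3])
            tp = (0.05 + 0.04 * wet) * station_nutrient[s] * np.exp(0.5 * e[4])
            po4 = 0.6 * tp * np.exp(0.3 * e[5])
            tn = (no3 + nh4) * 1.4 * np.exp(0.2 * e[6])
            turbidity = (6.0 + 4.0 * wet) * np.exp(0.5 * e[7])
            rows.append({
                "sample_id": f"ST{s + 1:02d}_M{m:02d}",
                "station": stations["station"].iloc[s],
                "month": month,
                "season": season_from_month(month),
                "latitude": stations["latitude"].iloc[s],
                "longitude": stations["longitude"].iloc[s],
                "TN": tn,
                "NO3-N": no3,
                "NH4-N": nh4,
                "TP": tp,
                "PO4-P": po4,
                "NP ratio": tn / tp,
                "temperature": temperature,
                "salinity": 32.0 - 2.5 * wet - 0.8 * e[8] ** 2 + 0.6 * e[8],
                "turbidity": turbidity,
                "pH": 8.1 - 0.01 * (temperature - 19.0) + 0.06 * e[9],
                "chlorophyll-a": 3.0 * np.exp(0.12 * (temperature - 19.0) + 0.5 * e[10]),
                "DO": do,
                "SS": 1.8 * turbidity * np.exp(0.3 * e[11]),
                "Secchi depth": 4.0 / (1.0 + 0.12 * turbidity),
            })
    env = pd.DataFrame(rows).set_index("sample_id")
    return env


def _synthetic_taxonomy(taxon_ids: list[str], labels: np.ndarray) -> pd.DataFrame:
    """PR2-style taxonomy with a trophic-mode column matching planted labels."""
    lineages = []
    for tid, mode in zip(taxon_ids, labels):
        idx = int(tid.split("_")[1])
        lineage = ";".join([
            "Eukaryota",
            f"Supergroup{idx % 5 + 1}",
            f"Division{idx % 17 + 1}",
            f"Class{idx % 53 + 1}",
            f"Order{idx % 131 + 1}",
            f"Family{idx % 311 + 1}",
            f"Genus{idx % 977 + 1}",
            f"Genus{idx % 977 + 1}_sp{idx}",
        ])
        lineages.append(lineage)
    return pd.DataFrame({
        "taxon_id": taxon_ids,
        "lineage": lineages,
        "db_trophic": labels,
        "annotation_rank": "species",
    }).set_index("taxon_id")


def generate_community(
    cfg: SimConfig, env: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate the counts matrix, taxonomy table and ground-truth record.

    Parameters
    ----------
    cfg
        Validated simulation configuration.
    env
        Output of :func:`generate_environment` (one row per station x month;
        must contain temperature, DO and NO3-N).

    Returns
    -------
    counts : DataFrame, samples x taxa, non-negative integers, rows sum to
        ``cfg.depth``.
    taxonomy : DataFrame indexed by taxon id with lineage and db_trophic.
    truth : GroundTruth with the planted core set, labels and optimum.
    """
    cfg.validate()
    t0, d0, n0 = cfg.optimum
    for name, value, col in (("temperature", t0, "temperature"), ("DO", d0, "DO"), ("NO3-N", n0, "NO3-N")):
        lo, hi = env[col].min(), env[col].max()
        if not lo <= value <= hi:
            raise ValueError(
                f"optimum not coverable: planted {name} optimum {value} outside "
                f"generated range [{lo:.3g}, {hi:.3g}]"
            )

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7**5]))
    n, t = len(env), cfg.n_taxa
    taxon_ids = [f"ASV_{i + 1:05d}" for i in range(t)]

    core_idx = rng.choice(t, size=cfg.n_core, replace=False)
    is_core = np.zeros(t, dtype=bool)
    is_core[core_idx] = True

    labels = rng.choice(TROPHIC_MODES, size=t, p=list(cfg.trophic_fractions))

    # Bloom-scale dominants live among the obligate (auto/hetero) core:
    # the planted mixoplankton response rescales mixotroph reads per sample,
    # which would otherwise couple dominance to the response surface.
    dominant_pool = core_idx[labels[core_idx] != "mixotroph"]
    n_dom = min(cfg.n_dominant_core, len(dominant_pool))
    dominant_idx = rng.choice(dominant_pool, size=n_dom, replace=False)

    weight = rng.lognormal(cfg.abundance_lognormal_mu, cfg.abundance_lognormal_sigma, t)
    weight[dominant_idx] *= cfg.dominant_factor * rng.lognormal(0.0, cfg.dominant_sigma, n_dom)
    weight[~is_core] *= cfg.noncore_abundance_factor

    occ = np.where(is_core, cfg.core_occupancy, cfg.noncore_occupancy)
    presence = rng.random((n, t)) < occ  # n x t

    # planted per-sample trophic shares
    x = env[["temperature", "DO", "NO3-N"]].to_numpy(float)
    bowl = (
        ((x[:, 0] - t0) / cfg.response_widths[0]) ** 2
        + ((x[:, 1] - d0) / cfg.response_widths[1]) ** 2
        + ((x[:, 2] - n0) / cfg.response_widths[2]) ** 2
    )
    log_mix = np.log(cfg.peak_mixotroph_share) - bowl
    if cfg.noise_sd > 0:
        log_mix = log_mix + rng.normal(0.0, cfg.noise_sd, n)
    mix_share = np.clip(np.exp(log_mix), 1e-6, 0.9)
    het_share = cfg.heterotroph_fraction * (1.0 - mix_share)
    auto_share = 1.0 - mix_share - het_share
    target = {"autotroph": auto_share, "heterotroph": het_share, "mixotroph": mix_share}

    w = presence * weight  # n x t raw weights
    alloc = np.zeros_like(w)
    for mode in TROPHIC_MODES:
        cols = labels == mode
        group_sum = w[:, cols].sum(axis=1)
        scale = np.divide(target[mode], group_sum, out=np.zeros(n), where=group_sum > 0)
        alloc[:, cols] = w[:, cols] * scale[:, None]
    # renormalise (a sample could lack one group entirely)
    alloc_sum = alloc.sum(axis=1)
    if np.any(alloc_sum <= 0):
        raise ValueError("a sample has no present taxa; increase occupancy or n_taxa")
    alloc /= alloc_sum[:, None]

    counts = np.empty((n, t), dtype=np.int64)
    for i in range(n):
        counts[i] = rng.multinomial(cfg.depth, alloc[i])

    counts_df = pd.DataFrame(counts, index=env.index.copy(), columns=taxon_ids)
    taxonomy = _synthetic_taxonomy(taxon_ids, labels)
    truth = GroundTruth(
        core_members=[taxon_ids[i] for i in sorted(core_idx)],
        dominant_members=[taxon_ids[i] for i in sorted(dominant_idx)],
        trophic_labels={tid: str(lab) for tid, lab in zip(taxon_ids, labels)},
        optimum=cfg.optimum,
        response_widths=cfg.response_widths,
        peak_mixotroph_share=cfg.peak_mixotroph_share,
        heterotroph_fraction=cfg.heterotroph_fraction,
        noise_sd=cfg.noise_sd,
    )
    return counts_df, taxonomy, truth


def simulate_survey(cfg: SimConfig):
    """Convenience wrapper: environment + community in one call."""
    env = generate_environment(cfg)
    counts, taxonomy, truth = generate_community(cfg, env)
    return counts, taxonomy, env, truth


def write_inputs(cfg: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Write the four standard input files plus the ground-truth JSON.

    Layout: ASV table as taxa-rows TSV, taxonomy TSV, metadata CSV,
    environment CSV and ground_truth.json.  Returns the path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts, taxonomy, env, truth = simulate_survey(cfg)

    meta_cols = ["station", "month", "season", "latitude", "longitude"]
    paths = {
        "counts": outdir / "asv_table.tsv",
        "taxonomy": outdir / "taxonomy.tsv",
        "metadata": outdir / "metadata.csv",
        "environment": outdir / "environment.csv",
        "ground_truth": outdir / "ground_truth.json",
    }
    counts.T.rename_axis("taxon_id").to_csv(paths["counts"], sep="\t")
    taxonomy.to_csv(paths["taxonomy"], sep="\t")
    env[meta_cols].rename_axis("sample_id").to_csv(paths["metadata"])
    env[list(ENV_VARIABLES)].rename_axis("sample_id").to_csv(paths["environment"])
    truth.to_json(paths["ground_truth"])
    return paths
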