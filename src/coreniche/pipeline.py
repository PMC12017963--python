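"""Configuration-driven orchestration of the full analysis chain.

Stage order: simulate/read -> filter -> rarefy -> core selection -> trophic
annotation -> profiles -> diversity & kriging -> driver screening -> niche
model.  Every stage writes its artifacts under the run directory and the run
ends with a machine-readable report (``run_report.json``) plus a manifest
sufficient to re-run the identical pipeline.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import ENV_VARIABLES, ConfigError, SimConfig, derive_seed
from .core import compute_occupancy, contribution_curve, core_fraction, select_core
from .diversity import alpha_diversity, pcoa_permanova, seasonal_test
from .drivers import (geographic_distance, env_distance, partial_mantel,
                      rf_importance, spearman_matrix, vpa)
from .io import CommunityMatrix, filter_min_count, rarefy, read_tables, relative_abundance
from .kriging import krige_surface
from .neutral import fit_neutral
from .niche import NicheLadder, clean_response, univariate_response, vif_screen
from .simulate import simulate_survey
from .trophic import annotate_trophic, trophic_profile

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "run_pipeline"]


@dataclass
class RunConfig:
    """Pipeline configuration: either input paths or a simulate block."""

    outdir: str = "coreniche_run"
    seed: int = 0
    # exactly one of the two input modes
    inputs: dict | None = None          # counts/taxonomy/metadata/environment paths
    simulate: dict | None = None        # SimConfig fields
    # stage parameters
    min_reads: int = 8
    rarefaction_depth: int | None = None   # None: keep depths as-is if equal
    gain: float = 0.01
    neutral_detection_limit: int = 1
    n_trees: int = 1000
    n_null: int = 100
    n_perm: int = 999
    resolution: int = 50
    grid_resolution: int = 50
    # stage toggles
    run_kriging: bool = True
    run_drivers: bool = True
    run_niche: bool = True
    overrides_path: str | None = None

    def validate(self) -> "RunConfig":
        if (self.inputs is None) == (self.simulate is None):
            raise ConfigError(
                "exactly one of 'inputs' and 'simulate' must be provided"
            )
        if self.inputs is not None:
            required = {"counts", "taxonomy", "metadata", "environment"}
            missing = required - set(self.inputs)
            if missing:
                raise ConfigError(f"inputs block missing paths: {sorted(missing)}")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        d = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d).validate()


@dataclass
class RunReport:
    """Per-stage status plus the headline numbers of the run."""

    stages: dict = field(default_factory=dict)
    numbers: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    version: str = __version__
    wall_seconds: float = 0.0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "stages": self.stages,
            "numbers": self.numbers,
            "seeds": self.seeds,
            "version": self.version,
            "wall_seconds": self.wall_seconds,
        }, indent=1, default=_jsonable))


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serialisable: {type(x)}")


class _StageRunner:
    def __init__(self, report: RunReport, outdir: Path):
        self.report = report
        self.outdir = outdir

    def run(self, name: str, fn):
        t0 = time.time()
        try:
            out = fn()
        except Exception as err:
            self.report.stages[name] = {"status": "error", "error": str(err),
                                        "seconds": round(time.time() - t0, 2)}
            self.report.to_json(self.outdir / "run_report.json")
            raise RuntimeError(f"stage {name!r} failed: {err}") from err
        self.report.stages[name] = {"status": "ok",
                                    "seconds": round(time.time() - t0, 2)}
        return out


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Run every configured stage, write all artifacts, return the report."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport()
    stage = _StageRunner(report, outdir)
    seeds = {name: derive_seed(cfg.seed, name)
             for name in ("simulate", "rarefy", "permanova", "mantel", "rf", "niche")}
    report.seeds = {"global": cfg.seed, **seeds}

    # ---- input ---------------------------------------------------------
    truth = None

    def _load():
        nonlocal truth
        if cfg.simulate is not None:
            sim_cfg = SimConfig.from_dict({**cfg.simulate, "seed": seeds["simulate"]})
            counts, taxonomy, env, truth_ = simulate_survey(sim_cfg)
            truth = truth_
            truth.to_json(outdir / "ground_truth.json")
            meta = env[["station", "month", "season", "latitude", "longitude"]]
            return CommunityMatrix(counts, meta), taxonomy, env
        return read_tables(cfg.inputs["counts"], cfg.inputs["taxonomy"],
                           cfg.inputs["metadata"], cfg.inputs["environment"])

    m, taxonomy, env = stage.run("load", _load)

    # ---- filter + rarefy ----------------------------------------------
    m = stage.run("filter", lambda: filter_min_count(m, cfg.min_reads))

    def _rarefy():
        totals = m.counts.sum(axis=1)
        depth = cfg.rarefaction_depth
        if depth is None:
            if totals.nunique() == 1:
                return m  # already even depth
            depth = int(totals.min())
        return rarefy(m, depth, seeds["rarefy"])

    m = stage.run("rarefy", _rarefy)
    env = env.loc[m.sample_ids]

    # ---- core selection ------------------------------------------------
    def _core():
        occ = compute_occupancy(m)
        curve = contribution_curve(m, occ.index.tolist())
        members = select_core(curve, gain=cfg.gain)
        occ["core"] = occ.index.isin(members)
        occ.to_csv(outdir / "occupancy.tsv", sep="\t")
        curve.to_frame().to_csv(outdir / "contribution_curve.tsv", sep="\t",
                                index=False)
        nt = int(m.counts.sum(axis=1).iloc[0])
        neutral = fit_neutral(occ, Nt=nt, n_samples=m.n_samples,
                              d=cfg.neutral_detection_limit)
        neutral.table.to_csv(outdir / "neutral_fit.tsv", sep="\t")
        (outdir / "neutral_fit.json").write_text(json.dumps(
            {"m": neutral.m, "r_squared": neutral.r_squared, "Nt": nt},
            indent=1))
        return occ, curve, members, neutral

    occ, curve, core_members, neutral = stage.run("core", _core)
    report.numbers["core_size"] = len(core_members)
    report.numbers["n_taxa_after_filter"] = m.n_taxa
    report.numbers["core_fraction_pct"] = core_fraction(len(core_members), m.n_taxa)
    report.numbers["neutral_m"] = neutral.m
    report.numbers["neutral_r_squared"] = neutral.r_squared
    if truth is not None:
        planted = set(truth.core_members) & set(m.taxon_ids)
        sel = set(core_members)
        report.numbers["core_precision"] = len(sel & planted) / len(sel)
        report.numbers["core_recall"] = len(sel & planted) / len(planted)

    # ---- trophic annotation and profiles -------------------------------
    def _trophic():
        overrides = None
        if cfg.overrides_path:
            overrides = pd.read_csv(cfg.overrides_path, sep="\t")
        modes = annotate_trophic(taxonomy.loc[taxonomy.index.intersection(m.taxon_ids)],
                                 overrides)
        modes.to_csv(outdir / "trophic_annotation.tsv", sep="\t")
        profile = trophic_profile(m, modes, core_members)
        profile.per_sample.to_csv(outdir / "trophic_profile_samples.tsv", sep="\t")
        profile.monthly.to_csv(outdir / "trophic_profile_monthly.tsv", sep="\t")
        profile.seasonal.to_csv(outdir / "trophic_profile_seasonal.tsv", sep="\t")
        return modes, profile

    modes, profile = stage.run("trophic", _trophic)

    core_modes = modes.loc[[t for t in core_members if t in modes.index]]
    groups = {mode: core_modes.index[core_modes["mode"] == mode].tolist()
              for mode in ("autotroph", "heterotroph", "mixotroph")}

    # ---- diversity ------------------------------------------------------
    def _diversity():
        records = {}
        tests = {}
        for mode, taxa in groups.items():
            if not taxa:
                continue
            div = alpha_diversity(m, taxa)
            div.to_csv(outdir / f"alpha_{mode}.tsv", sep="\t")
            records[mode] = div
            try:
                tests[mode] = seasonal_test(div["shannon"], m.metadata["season"])
            except ValueError:
                tests[mode] = None
        core_m = m.subset_taxa(core_members)
        beta = pcoa_permanova(core_m, m.metadata["season"], n_perm=cfg.n_perm,
                              seed=seeds["permanova"])
        beta["ordination"].to_csv(outdir / "pcoa.csv")
        return records, tests, beta

    alpha_records, alpha_tests, beta = stage.run("diversity", _diversity)
    report.numbers["permanova_pseudo_F"] = beta["pseudo_F"]
    report.numbers["permanova_p"] = beta["p_value"]

    if cfg.run_kriging:
        def _kriging():
            out = {}
            station_meta = m.metadata.groupby("station")[["longitude", "latitude"]].first()
            for mode, div in alpha_records.items():
                by_station = div["shannon"].groupby(m.metadata["station"]).mean()
                by_station = by_station.loc[station_meta.index]
                res = krige_surface(station_meta["longitude"], station_meta["latitude"],
                                    by_station.to_numpy(),
                                    resolution=cfg.grid_resolution)
                res.grid.to_csv(outdir / f"kriging_{mode}.csv", index=False)
                out[mode] = res
            return out

        kriging_results = stage.run("kriging", _kriging)
        report.numbers["kriging_cv_r"] = {
            mode: res.cv_pearson_r for mode, res in kriging_results.items()}

    # ---- response used by drivers and the niche model -------------------
    response = profile.per_sample["prop_mixotroph"]

    if cfg.run_drivers:
        def _drivers():
            predictors = pd.concat(
                [env[list(ENV_VARIABLES)],
                 m.metadata[["longitude", "latitude"]]], axis=1)
            vpa_res = vpa(m.subset_taxa(core_members), predictors)
            (outdir / "vpa.json").write_text(json.dumps(
                {"fractions": vpa_res.fractions, "clamped": vpa_res.clamped},
                indent=1, default=_jsonable))

            from .diversity import bray_curtis
            rows = []
            geo = geographic_distance(m.metadata["longitude"], m.metadata["latitude"])
            for mode, taxa in groups.items():
                if not taxa:
                    continue
                dcomm = bray_curtis(m.counts[taxa])
                for var in ENV_VARIABLES:
                    res = partial_mantel(dcomm, env_distance(env[var]), geo,
                                         n_perm=cfg.n_perm, seed=seeds["mantel"],
                                         controlled="geography")
                    rows.append({"group": mode, "variable": var,
                                 "r": res.r, "p": res.p_value})
            mantel_df = pd.DataFrame(rows)
            mantel_df.to_csv(outdir / "partial_mantel.tsv", sep="\t", index=False)

            rho, padj = spearman_matrix(env[list(ENV_VARIABLES)])
            rho.to_csv(outdir / "spearman_rho.tsv", sep="\t")
            padj.to_csv(outdir / "spearman_p_adj.tsv", sep="\t")

            rf = rf_importance(env[list(ENV_VARIABLES)], response.to_numpy(),
                               n_trees=cfg.n_trees, n_null=cfg.n_null,
                               seed=seeds["rf"])
            rf.to_csv(outdir / "rf_importance.tsv", sep="\t")
            return vpa_res, mantel_df, rf

        vpa_res, mantel_df, rf = stage.run("drivers", _drivers)
        report.numbers["rf_top3"] = rf.index[:3].tolist()
        report.numbers["vpa_fractions"] = vpa_res.fractions

    if cfg.run_niche:
        def _niche():
            data = pd.DataFrame({
                "response": response,
                "temperature": env["temperature"],
                "DO": env["DO"],
                "NO3-N": env["NO3-N"],
                "station": m.metadata["station"],
            })
            cleaned = clean_response(data, "response")
            vifs = vif_screen(cleaned[["temperature", "DO", "NO3-N"]])
            uni = {}
            for var in ("temperature", "DO", "NO3-N"):
                uni[var] = univariate_response(
                    cleaned[var], cleaned["log_response"], predictor=var,
                    response="log10 mixotroph proportion")
            fit = NicheLadder(data=cleaned).fit()
            fit.aic_table().to_csv(outdir / "ladder_aic.tsv", sep="\t")
            optimum, value, boundary = fit.locate_optimum(
                resolution=cfg.resolution)
            (outdir / "optimum.json").write_text(json.dumps(
                {"optimum": optimum, "predicted_log10_response": value,
                 "boundary": boundary, "selected": fit.selected,
                 "vif": vifs.to_dict()}, indent=1, default=_jsonable))
            for (v1, v2), surface in fit.pairwise_surfaces(
                    resolution=cfg.resolution).items():
                name = f"surface_{v1}_{v2}".replace("NO3-N", "NO3")
                surface.to_csv(outdir / f"{name}.csv", index=False)
            return fit, optimum, boundary, uni, vifs

        fit, optimum, boundary, uni, vifs = stage.run("niche", _niche)
        report.numbers["selected_spec"] = fit.selected
        report.numbers["optimum"] = optimum
        report.numbers["optimum_on_boundary"] = any(boundary.values())

    report.wall_seconds = round(sum(s.get("seconds", 0.0)
                                    for s in report.stages.values()), 2)
    report.to_json(outdir / "run_report.json")
    manifest = {"config": dataclasses.asdict(cfg), "version": __version__}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return report
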