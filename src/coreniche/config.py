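"""Configuration objects for the synthetic generator and the pipeline.

The synthetic generator emulates a monthly coastal plankton survey: a fixed
station grid sampled every month for a year, ~5000 ASVs of which a planted
subset is "core" (high occupancy), three trophic modes, and a mixoplankton
relative-proportion surface with a known (temperature, DO, nitrate) optimum.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence


#: The 14 environmental variables, by the names used throughout.
ENV_VARIABLES: tuple[str, ...] = (
    "TN", "NO3-N", "NH4-N", "TP", "PO4-P", "NP ratio",
    "temperature", "salinity", "turbidity", "pH",
    "chlorophyll-a", "DO", "SS", "Secchi depth",
)

#: Category map: every environmental variable is either a Nutrient or a
#: Physicochemistry variable; latitude/longitude form the Geography category
#: and live in the sample metadata, not the environment table.
ENV_CATEGORIES: dict[str, str] = {
    "TN": "Nutrient", "NO3-N": "Nutrient", "NH4-N": "Nutrient",
    "TP": "Nutrient", "PO4-P": "Nutrient", "NP ratio": "Nutrient",
    "temperature": "Physicochemistry", "salinity": "Physicochemistry",
    "turbidity": "Physicochemistry", "pH": "Physicochemistry",
    "chlorophyll-a": "Physicochemistry", "DO": "Physicochemistry",
    "SS": "Physicochemistry", "Secchi depth": "Physicochemistry",
}

TROPHIC_MODES: tuple[str, str, str] = ("autotroph", "heterotroph", "mixotroph")


class ConfigError(ValueError):
    """Raised when a configuration fails validation."""


@dataclass
class SimConfig:
    """Parameters of the synthetic survey generator.

    Defaults describe a 24-station x 12-month design with 5000 ASVs, a
    900-ASV planted core (occupancy 0.9 vs 0.1 for the remainder), a fixed
    per-sample depth of 20,000 reads (the matrix is born rarefied) and a
    mixoplankton log-proportion surface that is a quadratic bowl centred on
    ``optimum`` = (temperature degC, DO mg/L, NO3-N mg/L).
    """

    n_stations: int = 24
    n_months: int = 12
    n_taxa: int = 5000
    n_core: int = 900
    core_occupancy: float = 0.9
    noncore_occupancy: float = 0.1
    abundance_lognormal_mu: float = 0.0
    abundance_lognormal_sigma: float = 0.2
    trophic_fractions: tuple[float, float, float] = (0.54, 0.246, 0.214)
    optimum: tuple[float, float, float] = (18.0, 3.5, 0.64)
    response_widths: tuple[float, float, float] = (10.0, 6.0, 1.0)
    noise_sd: float = 0.1
    seed: int = 0
    # sampling depth; counts are allocated multinomially at this fixed depth
    depth: int = 20000
    # dominance tail: a few core ASVs carry bloom-scale abundance
    n_dominant_core: int = 50
    dominant_factor: float = 33.0
    dominant_sigma: float = 0.1
    # transient (non-core) taxa are also low-abundance taxa, per the
    # abundance-occupancy relationship
    noncore_abundance_factor: float = 0.4
    # mixoplankton share at the optimum, and heterotroph share of the rest
    peak_mixotroph_share: float = 0.45
    heterotroph_fraction: float = 0.35
    # environment-generator noise scales
    env_noise_sd: float = 0.5
    station_sd: float = 0.8

    def validate(self) -> "SimConfig":
        if min(self.n_stations, self.n_months, self.n_taxa) < 1:
            raise ConfigError("n_stations, n_months and n_taxa must be >= 1")
        if not 0 < self.n_core <= self.n_taxa:
            raise ConfigError("n_core must lie in (0, n_taxa]")
        for name in ("core_occupancy", "noncore_occupancy"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if abs(sum(self.trophic_fractions) - 1.0) > 1e-9:
            raise ConfigError("trophic_fractions must sum to 1")
        if any(w <= 0 for w in self.response_widths):
            raise ConfigError("response_widths must be positive")
        if self.noise_sd < 0 or self.env_noise_sd < 0 or self.station_sd < 0:
            raise ConfigError("noise scales must be non-negative")
        if self.depth < 1:
            raise ConfigError("depth must be >= 1")
        if not 0 <= self.n_dominant_core <= self.n_core:
            raise ConfigError("n_dominant_core must lie in [0, n_core]")
        if not 0 < self.peak_mixotroph_share < 1:
            raise ConfigError("peak_mixotroph_share must lie in (0, 1)")
        if not 0 < self.heterotroph_fraction < 1:
            raise ConfigError("heterotroph_fraction must lie in (0, 1)")
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown SimConfig fields: {sorted(unknown)}")
        cfg = cls(**{k: _tupled(k, v) for k, v in d.items()})
        return cfg.validate()


def _tupled(key: str, value):
    if key in ("trophic_fractions", "optimum", "response_widths") and isinstance(value, list):
        return tuple(value)
    return value


@dataclass
class GroundTruth:
    """Everything the generator planted, for downstream parameter recovery."""

    core_members: list[str]
    dominant_members: list[str]
    trophic_labels: dict[str, str]
    optimum: tuple[float, float, float]
    response_widths: tuple[float, float, float]
    peak_mixotroph_share: float
    heterotroph_fraction: float
    noise_sd: float

    def mixotroph_share(self, temperature, do, no3) -> "object":
        """Planted (noise-free) mixoplankton share at given conditions."""
        import numpy as np

        t0, d0, n0 = self.optimum
        wt, wd, wn = self.response_widths
        bowl = (
            ((np.asarray(temperature) - t0) / wt) ** 2
            + ((np.asarray(do) - d0) / wd) ** 2
            + ((np.asarray(no3) - n0) / wn) ** 2
        )
        return self.peak_mixotroph_share * np.exp(-bowl)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        for key in ("optimum", "response_widths"):
            d[key] = tuple(d[key])
        return cls(**d)


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 (stage-name hashing)."""
    import zlib

    return (int(global_seed) * 1000003 + zlib.crc32(stage.encode())) % (2**31 - 1)
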