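"""Configuration objects for the synthetic world and the pipeline run."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

from .errors import ConfigError

#: Mean occurrences per species for the log-normal occurrence-count model.
DEFAULT_OCC_MEAN = 30.0


@dataclass
class WorldConfig:
    """Free parameters of the synthetic biogeographic world.

    The defaults encode the study conditions the generator is meant to
    emulate: 27.3% of naturalized species threatened in at least one
    native-range country, a right-skewed per-species fraction of native
    range threatened (mean 13.6%, median ~4.6%), and a log10–log10
    allometry of slope 0.35 between threatened native AOO and naturalized
    AOO with residual scatter of 0.5 log10 units.

    Parameters
    ----------
    n_species : int
        Number of accepted species in the world.
    n_countries : int
        Number of rectangular countries tiling the region.
    n_families : int
        Number of plant families; species are assigned with a skewed
        size distribution so that small families exist.
    paradox_target : float
        Fraction of naturalized species that are threatened in >= 1
        native-range country (exact-count assignment, see docs).
    pct_threat_shape : tuple[float, float]
        Beta(a, b) shape of the per-species fraction of its native range
        (countries and AOO alike) that is threatened.
    allometry_slope : float
        log10 threatened AOO ~ slope * log10 naturalized AOO + intercept.
    allometry_noise_sd : float
        SD of the log10 residual scatter around that line.
    occ_per_species_mean : float
        Mean of the log-normal occurrence-count distribution used for
        species outside the allometry construction.
    naturalized_fraction : float
        Fraction of species with >= 1 naturalized country.
    threat_rate_non_naturalized : float
        Fraction of non-naturalized species threatened somewhere native
        (the net-loss pool).
    nt_only_rate : float
        Fraction of naturalized species that are merely Near Threatened
        (never VU or worse) in some native country; raises prevalence
        only when NT counts as threatened.
    global_threat_share : float
        Fraction of paradox species that are also globally threatened.
    seed : int
        Master seed; every table draws from a sub-stream derived from it.
    """

    n_species: int = 5000
    n_countries: int = 20
    n_families: int = 60
    paradox_target: float = 0.273
    pct_threat_shape: tuple = (0.3, 1.906)
    allometry_slope: float = 0.35
    allometry_noise_sd: float = 0.5
    occ_per_species_mean: float = DEFAULT_OCC_MEAN
    naturalized_fraction: float = 0.15
    threat_rate_non_naturalized: float = 0.44
    nt_only_rate: float = 0.052
    global_threat_share: float = 0.077
    region_lon: tuple = (-30.0, 30.0)
    region_lat: tuple = (-20.0, 20.0)
    seed: int = 0

    def __post_init__(self):
        counts = {"n_species": self.n_species, "n_countries": self.n_countries,
                  "n_families": self.n_families}
        for name, v in counts.items():
            if not isinstance(v, (int,)) or v < 1:
                raise ConfigError(f"{name} must be an integer >= 1, got {v!r}")
        props = {"paradox_target": self.paradox_target,
                 "naturalized_fraction": self.naturalized_fraction,
                 "threat_rate_non_naturalized": self.threat_rate_non_naturalized,
                 "nt_only_rate": self.nt_only_rate,
                 "global_threat_share": self.global_threat_share}
        for name, v in props.items():
            if not (0.0 <= float(v) <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1], got {v!r}")
        a, b = self.pct_threat_shape
        if not (a > 0 and b > 0):
            raise ConfigError(f"pct_threat_shape must be two positive reals, got {self.pct_threat_shape!r}")
        if not self.allometry_slope > 0:
            raise ConfigError(f"allometry_slope must be positive, got {self.allometry_slope!r}")
        if self.allometry_noise_sd < 0:
            raise ConfigError(f"allometry_noise_sd must be >= 0, got {self.allometry_noise_sd!r}")
        if not self.occ_per_species_mean > 0:
            raise ConfigError(f"occ_per_species_mean must be positive, got {self.occ_per_species_mean!r}")
        lon0, lon1 = self.region_lon
        lat0, lat1 = self.region_lat
        if not (lon0 < lon1 and lat0 < lat1 and abs(lat0) <= 90 and abs(lat1) <= 90):
            raise ConfigError("region_lon/region_lat must describe a valid lon/lat rectangle")
        if not isinstance(self.seed, int):
            raise ConfigError(f"seed must be an integer, got {self.seed!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pct_threat_shape"] = list(self.pct_threat_shape)
        d["region_lon"] = list(self.region_lon)
        d["region_lat"] = list(self.region_lat)
        return d


@dataclass
class GridSpec:
    """Longitude/latitude occupancy grid with latitude-corrected cell areas.

    The default 0.7 degree cell is (111.195 * 0.7)^2 ~ 6058 km^2 at the
    equator; cell area shrinks poleward with cos(latitude of cell center).
    """

    cell_size_deg: float = 0.7
    origin: tuple = (-180.0, -90.0)

    KM_PER_DEG = 111.195

    def __post_init__(self):
        if not self.cell_size_deg > 0:
            raise ConfigError(f"cell_size_deg must be positive, got {self.cell_size_deg!r}")

    def cell_area_km2(self, row):
        """Area of a cell in the given row (row index counted from origin lat)."""
        import numpy as np

        lat_center = self.origin[1] + (np.asarray(row) + 0.5) * self.cell_size_deg
        return (self.KM_PER_DEG * self.cell_size_deg) ** 2 * np.cos(np.radians(lat_center))


@dataclass
class StatsOptions:
    ci_level: float = 0.95
    n_permutations: int = 999
    bootstrap_ci: bool = False
    n_bootstrap: int = 2000
    zero_method: str = "wilcox"

    def __post_init__(self):
        if not (0.0 < self.ci_level < 1.0):
            raise ConfigError(f"ci_level must lie in (0, 1), got {self.ci_level!r}")
        if self.n_permutations < 99:
            raise ConfigError(f"n_permutations must be >= 99, got {self.n_permutations!r}")
        if self.zero_method not in ("wilcox", "pratt"):
            raise ConfigError(f"zero_method must be 'wilcox' or 'pratt', got {self.zero_method!r}")


@dataclass
class RunConfig:
    """Full pipeline configuration: either real input paths or a synthetic block."""

    synthetic: Optional[WorldConfig] = None
    inputs: Optional[dict] = None  # paths: checklist, naturalizations, national_statuses,
    #                                global_statuses, occurrences, countries, family_tree
    include_nt: bool = False
    grid: GridSpec = field(default_factory=GridSpec)
    stats: StatsOptions = field(default_factory=StatsOptions)
    synonym_rate: float = 0.0
    hybrid_rate: float = 0.0
    out_dir: str = "paradoxflora_out"
    overwrite: bool = False
    seed: int = 0

    REQUIRED_INPUTS = ("checklist", "naturalizations", "national_statuses",
                       "global_statuses", "occurrences", "countries", "family_tree")

    def __post_init__(self):
        if (self.synthetic is None) == (self.inputs is None):
            raise ConfigError("exactly one of 'synthetic' and 'inputs' must be present")
        if self.inputs is not None:
            missing = [k for k in self.REQUIRED_INPUTS if k not in self.inputs]
            if missing:
                raise ConfigError(f"inputs block missing paths: {', '.join(missing)}")
        for rate in ("synonym_rate", "hybrid_rate"):
            v = getattr(self, rate)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{rate} must lie in [0, 1], got {v!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kw = dict(raw)
        if "synthetic" in kw and kw["synthetic"] is not None:
            syn = dict(kw["synthetic"])
            for tup in ("pct_threat_shape", "region_lon", "region_lat"):
                if tup in syn:
                    syn[tup] = tuple(syn[tup])
            kw["synthetic"] = WorldConfig(**syn)
        if "grid" in kw and kw["grid"] is not None:
            g = dict(kw["grid"])
            if "origin" in g:
                g["origin"] = tuple(g["origin"])
            kw["grid"] = GridSpec(**g)
        else:
            kw.pop("grid", None)
        if "stats" in kw and kw["stats"] is not None:
            kw["stats"] = StatsOptions(**kw["stats"])
        else:
            kw.pop("stats", None)
        try:
            return cls(**kw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def to_dict(self) -> dict:
        d = {
            "include_nt": self.include_nt,
            "grid": {"cell_size_deg": self.grid.cell_size_deg, "origin": list(self.grid.origin)},
            "stats": asdict(self.stats),
            "synonym_rate": self.synonym_rate,
            "hybrid_rate": self.hybrid_rate,
            "out_dir": str(self.out_dir),
            "overwrite": self.overwrite,
            "seed": self.seed,
        }
        d["synthetic"] = self.synthetic.to_dict() if self.synthetic else None
        d["inputs"] = dict(self.inputs) if self.inputs else None
        return d
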