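"""Simulation and run configuration.

:class:`SimulationConfig` holds every ground-truth parameter of the synthetic
forest study: plot geometry, community size, point-process and trait-evolution
rates, terrain/soil structure, and the true survival-model coefficients
(the generator draws survival from the same logistic mixed model the
inference side fits).  The config round-trips through YAML so a written study
carries an exact echo of its truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import yaml

from .errors import InvalidArgumentError

#: Fixed-effect columns of the survival design, in canonical order.
#: ``log_height`` is the log-transformed initial height covariate; the six
#: neighborhood metrics follow; ``canopy`` is canopy openness; ``pca1``-``pca3``
#: are the topography+soil principal components; ``rainfall`` is the seasonal
#: rainfall total of the census interval.
PREDICTORS = [
    "log_height",
    "s_con",
    "a_con",
    "s_totpd",
    "a_totpd",
    "s_totfd",
    "a_totfd",
    "canopy",
    "pca1",
    "pca2",
    "pca3",
    "rainfall",
]

#: Default grouping of predictors used for relative-importance partitioning.
PREDICTOR_GROUPS = {
    "height": ["log_height"],
    "biotic": ["s_con", "a_con", "s_totpd", "a_totpd", "s_totfd", "a_totfd"],
    "habitat": ["canopy", "pca1", "pca2", "pca3"],
    "rainfall": ["rainfall"],
}

SEASONS = ("dry", "rainy")

#: Ten soil variables measured per quadrat.
SOIL_VARIABLES = ["temperature", "moisture", "ph", "ec", "omc", "ap", "ak", "tn", "tp", "tk"]

#: Topographic variables entering the habitat PCA alongside soil.
TOPO_VARIABLES = ["elevation_m", "slope_deg", "convexity_m"]


def _default_true_betas() -> dict:
    # Seasonal fixed-effect truth: significant community-level effects are
    # canopy openness in the dry season and seedling phylogenetic crowding,
    # adult functional crowding and rainfall in the rainy season; all other
    # terms are null.
    return {
        "log_height": 0.0,
        "s_con": 0.0,
        "a_con": 0.0,
        "s_totpd": {"dry": 0.0, "rainy": 0.939},
        "a_totpd": 0.0,
        "s_totfd": 0.0,
        "a_totfd": {"dry": 0.0, "rainy": 0.681},
        "canopy": {"dry": 0.315, "rainy": 0.0},
        "pca1": 0.0,
        "pca2": 0.0,
        "pca3": 0.0,
        "rainfall": {"dry": 0.0, "rainy": -0.412},
    }


@dataclass
class SimulationConfig:
    """Ground truth for one synthetic study.

    Defaults reproduce the study conditions: a 4-ha (200 m x 200 m) plot cut
    into 100 subplots of 20 m x 20 m, each nesting one 2 m x 2 m seedling
    quadrat; 56 species; ~936 seedlings followed over five censuses (four
    seasonal survival intervals, alternating dry/rainy from late 2020).
    """

    plot_size_m: tuple[float, float] = (200.0, 200.0)
    subplot_size_m: float = 20.0
    quadrat_size_m: float = 2.0
    n_species: int = 56
    n_intervals: int = 4
    first_season: str = "dry"
    start_year: int = 2020
    birth_rate: float = 1.0
    trait_sigma2: float = 1.0
    n_traits: int = 9
    stem_intensity: float = 0.25          # stems / m^2, DBH >= 1 cm
    cluster_scale_m: float = 10.0         # Thomas-process offspring dispersion
    mean_offspring: float = 20.0          # mean stems per cluster parent
    terrain_amplitude_m: float = 15.0
    soil_spatial_range_m: float = 40.0
    seedling_mean_per_quadrat: float = 9.36
    scale: float = 1.0                    # multiplies seedling density only
    recruitment_rate: float = 0.0         # Poisson mean per quadrat-interval
    height_lognorm: tuple[float, float] = (3.4, 0.5)   # log-mean, log-sd (cm)
    min_height_cm: float = 20.0
    dbh_lognorm: tuple[float, float] = (1.3, 0.9)      # left-truncated at 1 cm
    abundance_decay: float = 0.08         # geometric rank-abundance slope
    intercept: float = 2.2
    true_betas: dict = field(default_factory=_default_true_betas)
    re_sd: dict = field(default_factory=lambda: {"species": 0.5, "quadrat": 0.3, "year": 0.2})
    slope_sd: dict = field(default_factory=dict)   # predictor -> per-species slope SD
    rainfall_by_interval: Sequence[float] = (230.0, 990.0, 210.0, 950.0)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        counts = {
            "n_species": self.n_species,
            "n_intervals": self.n_intervals,
            "n_traits": self.n_traits,
        }
        for name, value in counts.items():
            if int(value) != value or value <= 0:
                raise InvalidArgumentError(f"{name} must be a positive integer, got {value!r}")
        if self.n_species < 2:
            raise InvalidArgumentError("n_species must be >= 2")
        if self.birth_rate <= 0:
            raise InvalidArgumentError("birth_rate must be > 0")
        if self.trait_sigma2 < 0:
            raise InvalidArgumentError("trait_sigma2 must be >= 0")
        if self.first_season not in SEASONS:
            raise InvalidArgumentError(f"first_season must be one of {SEASONS}")
        for key, sd in self.re_sd.items():
            if key not in ("species", "quadrat", "year"):
                raise InvalidArgumentError(f"unknown re_sd entry {key!r}")
            if sd < 0:
                raise InvalidArgumentError(f"re_sd[{key!r}] must be >= 0")
        for key, sd in self.slope_sd.items():
            if key not in PREDICTORS:
                raise InvalidArgumentError(f"unknown slope_sd predictor {key!r}")
            if sd < 0:
                raise InvalidArgumentError(f"slope_sd[{key!r}] must be >= 0")
        for key in self.true_betas:
            if key not in PREDICTORS:
                raise InvalidArgumentError(f"unknown true_betas predictor {key!r}")
        lx, ly = self.plot_size_m
        for L in (lx, ly):
            ratio = L / self.subplot_size_m
            if abs(ratio - round(ratio)) > 1e-9:
                raise InvalidArgumentError(
                    "subplot grid must divide the plot evenly: "
                    f"plot {L} m is not a multiple of subplot {self.subplot_size_m} m"
                )
        if self.quadrat_size_m <= 0 or self.quadrat_size_m > self.subplot_size_m:
            raise InvalidArgumentError("quadrat_size_m must lie in (0, subplot_size_m]")
        if len(self.rainfall_by_interval) < self.n_intervals:
            raise InvalidArgumentError(
                f"rainfall_by_interval needs >= n_intervals={self.n_intervals} entries"
            )
        if any(r < 0 for r in self.rainfall_by_interval):
            raise InvalidArgumentError("rainfall_by_interval entries must be >= 0")

    # -- derived geometry ----------------------------------------------------
    @property
    def n_subplots(self) -> tuple[int, int]:
        lx, ly = self.plot_size_m
        return int(round(lx / self.subplot_size_m)), int(round(ly / self.subplot_size_m))

    @property
    def n_quadrats(self) -> int:
        nx, ny = self.n_subplots
        return nx * ny

    # -- seasonal truth ------------------------------------------------------
    def beta(self, predictor: str, season: str) -> float:
        """True coefficient of *predictor* in *season* (scalar betas apply to both)."""
        value = self.true_betas.get(predictor, 0.0)
        if isinstance(value, Mapping):
            return float(value.get(season, 0.0))
        return float(value)

    def interval_labels(self) -> list[tuple[str, str, int]]:
        """``(interval_id, season, year)`` for each census interval, in time order.

        A dry interval spans November--April and is labelled by its starting
        year; intervals alternate starting from ``first_season``.
        """
        out = []
        season = self.first_season
        year = self.start_year
        for _ in range(self.n_intervals):
            out.append((f"{season}-{year}", season, year))
            if season == "dry":
                season, year = "rainy", year + 1
            else:
                season, year = "dry", year
        return out

    # -- (de)serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["plot_size_m"] = list(self.plot_size_m)
        d["height_lognorm"] = list(self.height_lognorm)
        d["dbh_lognorm"] = list(self.dbh_lognorm)
        d["rainfall_by_interval"] = list(self.rainfall_by_interval)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        for key in ("plot_size_m", "height_lognorm", "dbh_lognorm"):
            if key in d:
                d[key] = tuple(d[key])
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise InvalidArgumentError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))
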