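"""Shared fixtures: small synthetic studies generated once per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from seedlingndd import SimulationConfig, simulate_study
from seedlingndd.survival import ModelDesign, standardize_columns


def tiny_config(**overrides) -> SimulationConfig:
    """A 80 m x 80 m, 12-species study that simulates in well under a second."""
    base = dict(
        plot_size_m=(80.0, 80.0),
        n_species=12,
        n_intervals=4,
        stem_intensity=0.15,
        seedling_mean_per_quadrat=6.0,
        terrain_amplitude_m=10.0,
        seed=42,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_study():
    return simulate_study(tiny_config())


def toy_design(X: pd.DataFrame, y: np.ndarray, rng: np.random.Generator,
               n_species: int = 8, n_quadrats: int = 6, season: str = "rainy") -> ModelDesign:
    """Wrap an arbitrary predictor matrix in a minimal ModelDesign."""
    n = len(y)
    Xs, scaling = standardize_columns(X, list(X.columns))
    groups = pd.DataFrame(
        {
            "species": rng.integers(0, n_species, n).astype(str),
            "quadrat_id": rng.integers(0, n_quadrats, n).astype(str),
            "year": rng.integers(0, 2, n).astype(str),
        }
    )
    ids = pd.DataFrame({"seedling_id": [f"q{i}" for i in range(n)], "interval_id": "iv1"})
    return ModelDesign(season=season, y=np.asarray(y, float), X=Xs, groups=groups,
                       scaling=scaling, ids=ids)
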