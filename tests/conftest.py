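"""Shared fixtures: small simulated bundles and hand-built record tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from fieldmargins.simulate import (GuildSpec, PlantSpec, SimulationConfig,
                                   simulate_bundle)

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


def small_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A compact two-zone study used by most integration-level tests."""
    defaults = dict(
        sites_per_zone={"malawi_mid": 3, "tz_low": 3},
        n_points_per_transect=3,
        stages=("seedling", "flowering", "podding"),
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_bundle():
    bundle, truth = simulate_bundle(small_config(seed=11))
    return bundle, truth


@pytest.fixture()
def quadrat_rows():
    """Three valid hand-written quadrat records."""
    return pd.DataFrame({
        "site_id": ["s1", "s1", "s1"],
        "zone": ["tz_low"] * 3,
        "transect": ["margin", "margin", "into_crop"],
        "point_index": [1, 1, 2],
        "quadrat_index": [1, 2, 1],
        "stage": ["flowering"] * 3,
        "plant_species": ["bidens_pilosa", "euphorbia_sp", "bidens_pilosa"],
        "cover_pct": [12.5, 3.0, 40.0],
        "in_flower": [True, False, True],
        "origin": ["native", "introduced", "native"],
        "growth_form": ["herb", "herb", "herb"],
    })


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)
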