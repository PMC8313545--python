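"""Generator behaviour: determinism, limit cases, statistical calibration."""

import numpy as np
import pandas as pd
import pytest

from fieldmargins.errors import ConfigError
from fieldmargins.simulate import (GuildSpec, PlantSpec, SimulationConfig,
                                   simulate_bundle, simulate_flora,
                                   simulate_traps, simulate_visits,
                                   simulate_yield)

from conftest import small_config


def _one_site_cfg(**over):
    base = dict(sites_per_zone={"tz_low": 1}, n_points_per_transect=5,
                stages=("flowering",), prop_low_diversity={"tz_low": 0.0})
    base.update(over)
    return SimulationConfig(**base)


def test_identical_config_gives_bit_identical_bundle():
    cfg = small_config(seed=42)
    b1, _ = simulate_bundle(cfg)
    b2, _ = simulate_bundle(small_config(seed=42))
    for name in ("quadrats", "traps", "visits", "yields"):
        pd.testing.assert_frame_equal(getattr(b1, name), getattr(b2, name))


def test_occupancy_limits():
    pool = [PlantSpec("always", occupancy_prob=1.0),
            PlantSpec("never", occupancy_prob=0.0)]
    cfg = _one_site_cfg(plant_pool=pool, association={}, visitation={},
                        seed=3)
    flora = simulate_flora(cfg)
    n_events = 1 * 2 * 5 * 2 * 1   # site x transects x points x quadrats x stages
    assert (flora["plant_species"] == "always").sum() == n_events
    assert (flora["plant_species"] == "never").sum() == 0


def test_occupancy_frequency_matches_probability():
    # law of large numbers: 10,000 quadrat events at p = 0.3
    pool = [PlantSpec("x", occupancy_prob=0.3)]
    cfg = _one_site_cfg(sites_per_zone={"tz_low": 500}, plant_pool=pool,
                        association={}, visitation={}, seed=9)
    flora = simulate_flora(cfg)
    n_events = 500 * 2 * 5 * 2
    freq = len(flora) / n_events
    assert freq == pytest.approx(0.3, abs=0.01)


def test_cover_positive_and_bounded(small_bundle):
    bundle, _ = small_bundle
    assert (bundle.quadrats["cover_pct"] > 0).all()
    totals = bundle.quadrats.groupby(
        ["site_id", "transect", "point_index", "quadrat_index", "stage"]
    )["cover_pct"].sum()
    assert (totals <= 100.0 + 1e-9).all()


def test_guild_presence_matches_baseline_without_associations():
    pool = [PlantSpec("x", occupancy_prob=0.5)]
    guilds = [GuildSpec("wasp", "natural_enemy", 0.35, 2.0)]
    cfg = _one_site_cfg(sites_per_zone={"tz_low": 500}, plant_pool=pool,
                        guild_pool=guilds, association={}, visitation={},
                        seed=4)
    flora = simulate_flora(cfg)
    traps = simulate_traps(cfg, flora)
    n_points = 500 * 2 * 5
    assert len(traps) / n_points == pytest.approx(0.35, abs=0.02)


def test_zero_baseline_gives_no_trap_records():
    guilds = [GuildSpec("wasp", "natural_enemy", 0.0, 2.0)]
    cfg = _one_site_cfg(guild_pool=guilds, association={}, visitation={},
                        seed=1)
    traps = simulate_traps(cfg, simulate_flora(cfg))
    assert len(traps) == 0


def test_huge_association_tracks_plant_presence():
    pool = [PlantSpec("magnet", occupancy_prob=0.5)]
    guilds = [GuildSpec("bee", "pollinator", 0.05, 2.0)]
    cfg = _one_site_cfg(sites_per_zone={"tz_low": 50}, plant_pool=pool,
                        guild_pool=guilds,
                        association={("magnet", "bee"): 1e9}, visitation={},
                        seed=6)
    flora = simulate_flora(cfg)
    traps = simulate_traps(cfg, flora)
    plant_pts = set(map(tuple, flora[["site_id", "transect", "point_index",
                                      "stage"]].drop_duplicates().to_numpy()))
    trap_pts = set(map(tuple, traps[["site_id", "transect", "point_index",
                                     "stage"]].to_numpy()))
    assert plant_pts <= trap_pts


def test_association_with_unknown_species_rejected():
    cfg = _one_site_cfg(association={("not_a_plant", "honeybee"): 2.0})
    with pytest.raises(ConfigError, match="not_a_plant"):
        simulate_flora(cfg)


def test_zero_visit_preference_silences_the_pair():
    pool = [PlantSpec("flower", occupancy_prob=0.9,
                      flowering_stages=("flowering",))]
    guilds = [GuildSpec("bee", "pollinator", 0.3, 2.0, visit_rate=3.0)]
    cfg = _one_site_cfg(plant_pool=pool, guild_pool=guilds, association={},
                        visitation={("bee", "flower"): 0.0}, seed=2)
    visits = simulate_visits(cfg, simulate_flora(cfg))
    assert len(visits) == 0


def test_nonflowering_plants_receive_no_visits():
    pool = [PlantSpec("leafy", occupancy_prob=0.9,
                      flowering_stages=("podding",))]
    guilds = [GuildSpec("bee", "pollinator", 0.3, 2.0, visit_rate=5.0)]
    cfg = _one_site_cfg(plant_pool=pool, guild_pool=guilds, association={},
                        visitation={}, stages=("flowering",), seed=2)
    visits = simulate_visits(cfg, simulate_flora(cfg))
    assert len(visits) == 0


def test_yield_effect_zero_gives_equal_group_means():
    cfg = SimulationConfig(beta_tree=0.0, yield_sigma=0.5,
                           n_plants_per_site=100, seed=13)
    cats = {f"s{i}": ("high" if i % 2 else "low") for i in range(10)}
    y = simulate_yield(cfg, cats)
    y["bp"] = y["pods_per_plant"] * y["beans_per_pod"]
    y["cat"] = y["site_id"].map(cats)
    means = np.log(y.groupby("cat")["bp"].mean())
    # 1,000 plants total: Monte-Carlo error on log mean ~ sigma/sqrt(500)
    assert abs(means["high"] - means["low"]) < 4 * 0.5 / np.sqrt(500)


def test_yield_product_recovers_log_normal_target():
    cfg = SimulationConfig(seed=8, n_plants_per_site=50)
    y = simulate_yield(cfg, {"a": "high", "b": "low"})
    bp = y["pods_per_plant"] * y["beans_per_pod"]
    assert (bp > 0).all()
    assert y["pods_per_plant"].min() >= 1


def test_ground_truth_records_planted_parameters(small_bundle):
    bundle, truth = small_bundle
    gt = truth.to_frame()
    assert (gt["kind"] == "association").sum() == len(truth.association)
    assert truth.beta_tree == pytest.approx(0.4)
    assert set(truth.sites["yield_category"].unique()) >= {"high", "low"}


def test_empty_plant_pool_rejected():
    with pytest.raises(ConfigError, match="plant_pool"):
        simulate_flora(SimulationConfig(plant_pool=[]))
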