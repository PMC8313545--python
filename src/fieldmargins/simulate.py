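"""Synthetic survey generator with known ground truth.

Emulates the study's sampling design — sites spread over four agro-ecological
zones, two transects per site (margin, into-crop) with five pan-trap points
each, two 1x1 m quadrats flanking every trap, and up to five cropping stages
(pre-plough, seedling, flowering, podding, post-harvest) — while planting
known parameters that downstream analyses must recover:

* an **association matrix** ``A`` of plant x guild odds multipliers acting on
  guild presence at a trap point (the estimand of the co-occurrence stage);
* a **visitation preference** ``V`` of guild x plant rate multipliers behind
  the flower-visitor networks;
* an additive **tree-richness effect** ``beta_tree`` on log beans per plant
  behind the yield ANOVA.

Plant occupancy is Bernoulli per quadrat survey event; percent cover is
truncated lognormal (right-skewed, as in real vegetation surveys); guild
presence follows a logistic odds model so the association ground truth maps
directly onto the presence-based co-occurrence statistic; trap counts are
shifted Poisson (1 + Poisson) so presence and count are consistent; visits
are Poisson on flowering plants only. A fixed seed reproduces the bundle
bit-for-bit.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .survey import (STAGES, SurveyBundle, default_guild_roles)


@dataclasses.dataclass(frozen=True)
class PlantSpec:
    """One species in the regional plant pool."""

    species: str
    origin: str = "unclassified"          # native | introduced | unclassified
    growth_form: str = "herb"             # tree | shrub | herb | crop
    occupancy_prob: float = 0.3           # per quadrat survey event
    mean_cover: float = 10.0              # percent of quadrat area
    flowering_stages: tuple[str, ...] = ("flowering", "podding")


@dataclasses.dataclass(frozen=True)
class GuildSpec:
    """One insect functional group."""

    guild: str
    role: str = "pollinator"              # pollinator | natural_enemy | both
    baseline_presence_prob: float = 0.3   # per trap point and stage
    baseline_count_mean: float = 3.0      # mean catch given presence (>= 1)
    visit_rate: float = 0.0               # mean visits per flowering plant per walk


def default_plant_pool() -> list[PlantSpec]:
    """A pool of 18 species typical of East/Southern African bean-field margins.

    Occupancies and covers are set to realistic survey magnitudes: common
    weedy herbs at 0.3-0.55 per-quadrat occupancy, trees sparser, the bean
    crop near-ubiquitous in cropped quadrats.
    """
    P = PlantSpec
    return [
        # trees (only on margin-rich sites; see SimulationConfig)
        P("grevillea_robusta", "introduced", "tree", 0.35, 12.0, ("flowering", "podding")),
        P("albizia_schimperiana", "native", "tree", 0.30, 15.0, ("podding",)),
        P("vachellia_tortilis", "native", "tree", 0.25, 10.0, ("flowering",)),
        P("persea_americana", "introduced", "tree", 0.20, 14.0, ("pre_plough", "seedling")),
        P("parinari_curatellifolia", "native", "tree", 0.15, 12.0, ("podding",)),
        # crops
        P("phaseolus_vulgaris", "introduced", "crop", 0.9, 40.0, ("flowering",)),
        P("manihot_esculenta", "introduced", "crop", 0.35, 20.0, ("podding", "post_harvest")),
        # shrubs and herbs
        P("tithonia_diversifolia", "introduced", "shrub", 0.30, 18.0, ("flowering", "podding")),
        P("acalypha_fruticosa", "native", "shrub", 0.25, 12.0, ("flowering",)),
        P("acanthospermum_hispidum", "introduced", "herb", 0.50, 8.0, ("flowering", "podding")),
        P("euphorbia_sp", "introduced", "herb", 0.45, 6.0, ("seedling", "flowering", "podding")),
        P("ageratum_conyzoides", "introduced", "herb", 0.40, 7.0, ("flowering", "podding", "post_harvest")),
        P("bidens_pilosa", "native", "herb", 0.45, 8.0, ("flowering", "podding")),
        P("commelina_diffusa", "native", "herb", 0.35, 9.0, ("seedling", "flowering")),
        P("leucas_martinicensis", "introduced", "herb", 0.30, 5.0, ("podding",)),
        P("oxygonum_sinuatum", "native", "herb", 0.35, 6.0, ("flowering", "podding")),
        P("indigofera_spicata", "native", "herb", 0.30, 5.0, ("podding",)),
        P("tridax_procumbens", "unclassified", "herb", 0.25, 4.0, ("flowering", "podding", "post_harvest")),
    ]


def default_guild_pool() -> list[GuildSpec]:
    G = GuildSpec
    return [
        G("honeybee", "pollinator", 0.40, 4.0, 3.0),
        G("carpenter_bee", "pollinator", 0.25, 2.0, 1.2),
        G("beefly", "pollinator", 0.20, 2.0, 0.6),
        G("small_bee", "pollinator", 0.35, 3.0, 1.5),
        G("wasp", "natural_enemy", 0.35, 3.5, 0.0),
        G("predatory_beetle", "natural_enemy", 0.25, 2.0, 0.0),
        G("hoverfly", "both", 0.30, 2.5, 0.8),
        G("spider", "natural_enemy", 0.30, 2.0, 0.0),
        G("dolichopodidae", "natural_enemy", 0.35, 3.0, 0.0),
    ]


def default_association() -> dict[tuple[str, str], float]:
    """Planted plant->guild presence-odds multipliers (the recovery targets)."""
    return {
        ("grevillea_robusta", "honeybee"): 6.0,
        ("grevillea_robusta", "carpenter_bee"): 6.0,
        ("acanthospermum_hispidum", "wasp"): 6.0,
        ("albizia_schimperiana", "hoverfly"): 6.0,
        ("euphorbia_sp", "small_bee"): 6.0,
        ("manihot_esculenta", "predatory_beetle"): 6.0,
    }


def default_visitation() -> dict[tuple[str, str], float]:
    """Guild x plant visit-rate multipliers (1 everywhere else)."""
    return {
        ("carpenter_bee", "phaseolus_vulgaris"): 4.0,
        ("honeybee", "phaseolus_vulgaris"): 2.0,
        ("honeybee", "ageratum_conyzoides"): 2.0,
        ("honeybee", "tithonia_diversifolia"): 2.0,
        ("carpenter_bee", "oxygonum_sinuatum"): 2.0,
        ("beefly", "bidens_pilosa"): 2.0,
    }


@dataclasses.dataclass
class SimulationConfig:
    """Full description of one simulated study.

    Defaults mirror the study design: 32 sites in four zones (8 per zone),
    2 transects x 5 trap points x 2 quadrats, 5 cropping stages. Half the
    Malawi sites and a quarter of the Tanzanian sites have low-diversity
    margins (no trees, thinned margin vegetation, ``has_margin=False``);
    yields are simulated for the Malawi zone only, as in the study, with an
    additive tree-richness effect on log beans per plant.
    """

    sites_per_zone: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: {"malawi_mid": 8, "tz_low": 8, "tz_mid": 8,
                                 "tz_high": 8})
    n_points_per_transect: int = 5
    n_quadrats_per_point: int = 2
    stages: tuple[str, ...] = STAGES
    plant_pool: list[PlantSpec] = dataclasses.field(
        default_factory=default_plant_pool)
    guild_pool: list[GuildSpec] = dataclasses.field(
        default_factory=default_guild_pool)
    association: dict[tuple[str, str], float] = dataclasses.field(
        default_factory=default_association)
    visitation: dict[tuple[str, str], float] = dataclasses.field(
        default_factory=default_visitation)
    prop_low_diversity: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"malawi_mid": 0.5, "tz_low": 0.25,
                                 "tz_mid": 0.25, "tz_high": 0.25})
    margin_thinning: float = 0.4      # occupancy multiplier on low-diversity sites
    tree_crop_thinning: float = 0.3   # tree occupancy multiplier on into-crop transects
    cover_sigma_log: float = 0.6      # lognormal shape of percent cover
    # yield model: log(beans/plant) = intercept + beta_tree * 1[tree-rich] + N(0, sigma)
    yield_zones: tuple[str, ...] = ("malawi_mid",)
    n_plants_per_site: int = 12
    yield_intercept: float = 3.0
    beta_tree: float = 0.4
    yield_sigma: float = 0.5
    beans_per_pod_mean: float = 4.0
    seed: int = 0

    def validate(self) -> None:
        if not self.plant_pool:
            raise ConfigError("plant_pool is empty")
        if not self.guild_pool:
            raise ConfigError("guild_pool is empty")
        species = {p.species for p in self.plant_pool}
        guilds = {g.guild for g in self.guild_pool}
        for p in self.plant_pool:
            if not 0.0 <= p.occupancy_prob <= 1.0:
                raise ConfigError(f"occupancy_prob for {p.species} not in [0, 1]")
            if p.mean_cover <= 0:
                raise ConfigError(f"mean_cover for {p.species} must be > 0")
        for g in self.guild_pool:
            if not 0.0 <= g.baseline_presence_prob <= 1.0:
                raise ConfigError(
                    f"baseline_presence_prob for {g.guild} not in [0, 1]")
            if g.baseline_count_mean < 1.0:
                raise ConfigError(
                    f"baseline_count_mean for {g.guild} must be >= 1")
        for (sp, gu), mult in self.association.items():
            if sp not in species or gu not in guilds:
                raise ConfigError(
                    f"association references unknown pair ({sp}, {gu})")
            if mult <= 0:
                raise ConfigError("association multipliers must be > 0")
        for (gu, sp), mult in self.visitation.items():
            if sp not in species or gu not in guilds:
                raise ConfigError(
                    f"visitation references unknown pair ({gu}, {sp})")
            if mult < 0:
                raise ConfigError("visitation multipliers must be >= 0")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic stream per simulation stage."""
        return np.random.default_rng([int(self.seed) % (2**31), stream])


@dataclasses.dataclass
class GroundTruth:
    """Planted parameters recorded alongside a simulated bundle."""

    association: dict[tuple[str, str], float]
    visitation: dict[tuple[str, str], float]
    beta_tree: float
    sites: pd.DataFrame  # site_id, zone, rich_margin, has_margin, yield_category

    def to_frame(self) -> pd.DataFrame:
        rows = [("association", p, g, v) for (p, g), v in
                sorted(self.association.items())]
        rows += [("visitation", g, p, v) for (g, p), v in
                 sorted(self.visitation.items())]
        rows.append(("yield_beta_tree", "", "", self.beta_tree))
        rows += [("site_category", r.site_id, r.yield_category,
                  float(r.rich_margin))
                 for r in self.sites.itertuples()]
        return pd.DataFrame(rows, columns=["kind", "key1", "key2", "value"])


# Generation ---------------------------------------------------------------

def site_table(cfg: SimulationConfig,
               rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Assign sites to zones and margin-richness classes."""
    rng = rng or cfg.rng(0)
    rows = []
    for zone in sorted(cfg.sites_per_zone):
        n = int(cfg.sites_per_zone[zone])
        n_low = int(round(cfg.prop_low_diversity.get(zone, 0.0) * n))
        low = np.zeros(n, bool)
        low[rng.choice(n, size=n_low, replace=False)] = True
        for i in range(n):
            rows.append((f"{zone}_s{i + 1:02d}", zone, not low[i]))
    df = pd.DataFrame(rows, columns=["site_id", "zone", "rich_margin"])
    df["has_margin"] = df["rich_margin"]
    return df


def _event_grid(cfg: SimulationConfig, sites: pd.DataFrame) -> pd.DataFrame:
    """One row per quadrat survey event (site x transect x point x quadrat x stage)."""
    grid = pd.MultiIndex.from_product(
        [sites["site_id"], ("margin", "into_crop"),
         range(1, cfg.n_points_per_transect + 1),
         range(1, cfg.n_quadrats_per_point + 1), cfg.stages],
        names=["site_id", "transect", "point_index", "quadrat_index", "stage"],
    ).to_frame(index=False)
    return grid.merge(sites[["site_id", "zone", "rich_margin"]], on="site_id")


def simulate_flora(cfg: SimulationConfig,
                   rng: np.random.Generator | None = None,
                   sites: pd.DataFrame | None = None) -> pd.DataFrame:
    """Generate the quadrat table.

    Per quadrat survey event each species is present with its (site- and
    transect-adjusted) occupancy probability; cover is lognormal with the
    configured mean, truncated to (0, 100]; quadrats whose summed cover
    exceeds 100% are rescaled to a planar total of 100%.
    """
    cfg.validate()
    rng = rng or cfg.rng(1)
    sites = sites if sites is not None else site_table(cfg, cfg.rng(0))
    grid = _event_grid(cfg, sites)
    n_ev = len(grid)
    rich = grid["rich_margin"].to_numpy()
    on_margin = (grid["transect"] == "margin").to_numpy()

    frames = []
    for p in cfg.plant_pool:
        occ = np.full(n_ev, p.occupancy_prob)
        if p.growth_form == "tree":
            occ = np.where(rich, occ, 0.0)           # poor sites have no trees
            occ = np.where(on_margin, occ, occ * cfg.tree_crop_thinning)
        else:
            # low-diversity sites have thinned (weedy-edge) vegetation
            occ = np.where(rich, occ, occ * cfg.margin_thinning)
        present = rng.random(n_ev) < occ
        k = int(present.sum())
        if k == 0:
            continue
        mu = np.log(p.mean_cover) - cfg.cover_sigma_log ** 2 / 2.0
        cover = np.minimum(rng.lognormal(mu, cfg.cover_sigma_log, k), 100.0)
        sub = grid.loc[present, ["site_id", "zone", "transect", "point_index",
                                 "quadrat_index", "stage"]].copy()
        sub["plant_species"] = p.species
        sub["cover_pct"] = cover
        sub["in_flower"] = sub["stage"].isin(p.flowering_stages)
        sub["origin"] = p.origin
        sub["growth_form"] = p.growth_form
        frames.append(sub)
    if not frames:
        return pd.DataFrame(columns=["site_id", "zone", "transect",
                                     "point_index", "quadrat_index", "stage",
                                     "plant_species", "cover_pct", "in_flower",
                                     "origin", "growth_form"])
    flora = pd.concat(frames, ignore_index=True)
    # rescale overfull quadrats so planar cover sums to at most 100%
    key = ["site_id", "transect", "point_index", "quadrat_index", "stage"]
    totals = flora.groupby(key)["cover_pct"].transform("sum")
    scale = np.where(totals > 100.0, 100.0 / totals, 1.0)
    flora["cover_pct"] = flora["cover_pct"] * scale
    flora = flora.sort_values(key + ["plant_species"], ignore_index=True)
    cols = ["site_id", "zone", "transect", "point_index", "quadrat_index",
            "stage", "plant_species", "cover_pct", "in_flower", "origin",
            "growth_form"]
    return flora[cols]


def simulate_traps(cfg: SimulationConfig, flora: pd.DataFrame,
                   rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Generate pan-trap records conditional on the generated flora.

    Guild presence at a trap point follows a logistic odds model: baseline
    odds multiplied by ``A[p, g]`` for every plant ``p`` present at that
    point and stage (both flanking quadrats pooled). Catch size given
    presence is 1 + Poisson(mean - 1). Records are emitted only for caught
    guilds.
    """
    cfg.validate()
    rng = rng or cfg.rng(2)
    # trap-event grid: every designed point x stage, whether or not plants grew
    sites = flora[["site_id"]].drop_duplicates()
    grid = pd.MultiIndex.from_product(
        [sites["site_id"], ("margin", "into_crop"),
         range(1, cfg.n_points_per_transect + 1), cfg.stages],
        names=["site_id", "transect", "point_index", "stage"],
    ).to_frame(index=False)
    n_ev = len(grid)

    # pooled plant presence per trap event, only for species that enter A
    assoc_species = sorted({sp for sp, _ in cfg.association})
    log_mult = np.zeros((n_ev, len(cfg.guild_pool)))
    if assoc_species:
        present = (flora[flora["plant_species"].isin(assoc_species)]
                   [["site_id", "transect", "point_index", "stage",
                     "plant_species"]].drop_duplicates())
        pmat = (present.assign(v=1)
                .pivot_table(index=["site_id", "transect", "point_index",
                                    "stage"],
                             columns="plant_species", values="v",
                             fill_value=0))
        pmat = pmat.reindex(columns=assoc_species, fill_value=0)
        key = pd.MultiIndex.from_frame(
            grid[["site_id", "transect", "point_index", "stage"]])
        pmat = pmat.reindex(key, fill_value=0).to_numpy()
        for j, g in enumerate(cfg.guild_pool):
            logA = np.array([np.log(cfg.association.get((sp, g.guild), 1.0))
                             for sp in assoc_species])
            log_mult[:, j] = pmat @ logA

    frames = []
    for j, g in enumerate(cfg.guild_pool):
        p0 = g.baseline_presence_prob
        if p0 <= 0.0:
            continue
        if p0 >= 1.0:
            prob = np.ones(n_ev)
        else:
            logit = np.log(p0 / (1.0 - p0)) + log_mult[:, j]
            prob = 1.0 / (1.0 + np.exp(-logit))
        caught = rng.random(n_ev) < prob
        k = int(caught.sum())
        if k == 0:
            continue
        counts = 1 + rng.poisson(g.baseline_count_mean - 1.0, k)
        sub = grid.loc[caught].copy()
        sub["guild"] = g.guild
        sub["count"] = counts
        frames.append(sub)
    if not frames:
        return pd.DataFrame(columns=["site_id", "transect", "point_index",
                                     "stage", "guild", "count"])
    traps = pd.concat(frames, ignore_index=True)
    traps = traps.sort_values(["site_id", "transect", "point_index", "stage",
                               "guild"], ignore_index=True)
    return traps[["site_id", "transect", "point_index", "stage", "guild",
                  "count"]]


def simulate_visits(cfg: SimulationConfig, flora: pd.DataFrame,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Generate transect-walk visitation records.

    For each site x stage, every plant recorded in flower at that site and
    stage can receive visits from each guild with a positive visit rate:
    visits ~ Poisson(visit_rate x V[guild, plant]). Zero-visit draws produce
    no record (only observed interactions are recorded in the field).
    """
    cfg.validate()
    rng = rng or cfg.rng(3)
    flowering = (flora.loc[flora["in_flower"],
                           ["site_id", "stage", "plant_species"]]
                 .drop_duplicates())
    empty = pd.DataFrame(columns=["site_id", "stage", "visitor_guild",
                                  "plant_species", "visits"])
    if len(flowering) == 0:
        return empty
    frames = []
    for g in cfg.guild_pool:
        if g.visit_rate <= 0:
            continue
        lam = flowering["plant_species"].map(
            lambda sp, gu=g.guild: cfg.visitation.get((gu, sp), 1.0)
        ).to_numpy(dtype=float) * g.visit_rate
        visits = rng.poisson(lam)
        seen = visits >= 1
        if not seen.any():
            continue
        sub = flowering.loc[seen].copy()
        sub["visitor_guild"] = g.guild
        sub["visits"] = visits[seen]
        frames.append(sub)
    if not frames:
        return empty
    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values(["site_id", "stage", "visitor_guild",
                           "plant_species"], ignore_index=True)
    return out[["site_id", "stage", "visitor_guild", "plant_species",
                "visits"]]


def simulate_yield(cfg: SimulationConfig,
                   site_tree_richness: Mapping[str, str],
                   rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Generate per-plant yield records for sites in ``site_tree_richness``.

    log(beans/plant) = intercept + beta_tree * 1[category == "high"] +
    Normal(0, sigma). The target is mapped exactly onto integer pods per
    plant and real-valued mean beans per pod (their product recovers the
    target), so the planted effect is the exact ANOVA estimand.
    """
    rng = rng or cfg.rng(4)
    rows = []
    for site in sorted(site_tree_richness):
        high = site_tree_richness[site] == "high"
        n = cfg.n_plants_per_site
        log_y = (cfg.yield_intercept + cfg.beta_tree * float(high)
                 + rng.normal(0.0, cfg.yield_sigma, n))
        beans_plant = np.exp(log_y)
        pods = np.maximum(1, np.rint(beans_plant / cfg.beans_per_pod_mean)
                          ).astype(int)
        bpp = beans_plant / pods
        positions = np.where(rng.random(n) < 0.5, "edge", "middle")
        for j in range(n):
            rows.append((site, f"{site}_p{j + 1:02d}", positions[j],
                         int(pods[j]), float(bpp[j])))
    return pd.DataFrame(rows, columns=["site_id", "plant_id", "position",
                                       "pods_per_plant", "beans_per_pod"])


def simulate_bundle(cfg: SimulationConfig) -> tuple[SurveyBundle, GroundTruth]:
    """Generate a full survey bundle plus its ground truth.

    Deterministic: identical config (including seed) reproduces the bundle
    exactly. Stage-specific random streams are derived from the single seed,
    so e.g. regenerating only the yield table does not perturb the flora.
    """
    cfg.validate()
    sites = site_table(cfg, cfg.rng(0))
    flora = simulate_flora(cfg, cfg.rng(1), sites=sites)
    traps = simulate_traps(cfg, flora, cfg.rng(2))
    visits = simulate_visits(cfg, flora, cfg.rng(3))
    yield_sites = sites[sites["zone"].isin(cfg.yield_zones)]
    categories = {r.site_id: ("high" if r.rich_margin else "low")
                  for r in yield_sites.itertuples()}
    yields = simulate_yield(cfg, categories, cfg.rng(4))
    truth_sites = sites.copy()
    truth_sites["yield_category"] = truth_sites["site_id"].map(
        lambda s: categories.get(s, ""))
    bundle = SurveyBundle(
        quadrats=flora, traps=traps, visits=visits, yields=yields,
        sites=sites[["site_id", "zone", "has_margin"]].reset_index(drop=True),
        guild_roles=pd.DataFrame(
            [(g.guild, g.role) for g in cfg.guild_pool],
            columns=["guild", "role"]),
    )
    truth = GroundTruth(association=dict(cfg.association),
                        visitation=dict(cfg.visitation),
                        beta_tree=cfg.beta_tree, sites=truth_sites)
    return bundle, truth


def simulate_feature_response(n_sites: int = 100, n_features: int = 8,
                              active: Sequence[int] = (0, 1),
                              beta: float = 1.0, sigma: float = 0.5,
                              seed: int | None = None) -> pd.DataFrame:
    """Site-feature table with a response built from a known feature subset.

    Features are independent standard normals ``x1..xk``; the response is
    ``beta * sum(x_a for a in active) + Normal(0, sigma)``. Used to test
    variable-importance recovery.
    """
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n_sites, n_features))
    y = beta * X[:, list(active)].sum(axis=1) + rng.normal(0.0, sigma, n_sites)
    df = pd.DataFrame(X, columns=[f"x{i + 1}" for i in range(n_features)])
    df["response"] = y
    return df
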