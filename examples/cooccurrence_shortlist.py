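"""Recover planted plant-guild associations with the co-occurrence statistic.

For every plant x guild pair, presence frequencies over trap points give
P_plant and P_ins; the observed co-occurrence P_c is compared with the
random expectation P_pred = P_plant * P_ins. Plants seen only once or at
every point are excluded, and the top 5% of retained plants per guild
(ranked by excess P_c - P_pred) form the shortlist.
"""

from fieldmargins import SimulationConfig, associate, shortlist, simulate_bundle
from fieldmargins.simulate import GuildSpec, PlantSpec

# one flowering-stage survey of 20 sites with 2 planted associations
pool = [PlantSpec(f"herb{i:02d}", occupancy_prob=0.2 + 0.02 * i)
        for i in range(12)]
guilds = [GuildSpec("honeybee", "pollinator", 0.3, 2.0),
          GuildSpec("wasp", "natural_enemy", 0.3, 2.0)]
cfg = SimulationConfig(
    sites_per_zone={"tz_low": 20}, n_points_per_transect=20,
    stages=("flowering",), plant_pool=pool, guild_pool=guilds,
    association={("herb03", "honeybee"): 6.0, ("herb08", "wasp"): 6.0},
    visitation={}, prop_low_diversity={"tz_low": 0.0}, seed=1)
bundle, truth = simulate_bundle(cfg)

table = associate(bundle, fraction=0.05, rank_by="excess")
print("planted pairs:", sorted(truth.association))
print()
print("top-5% shortlist per guild (rank 1 = most strongly associated):")
print(shortlist(table).round(4).to_string(index=False))

# A correct recovery puts herb03 at rank 1 for honeybee and herb08 at
# rank 1 for wasp; 'excess' is the co-occurrence surplus over the random
# expectation and is ~0 for unplanted pairs.
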