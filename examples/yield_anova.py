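"""Test whether tree-rich margins are associated with higher bean yields.

Beans per plant (pods x beans/pod) is log-transformed and decomposed by a
sequential two-way ANOVA with site tree-richness category (low: bare
margin, <= 1 tree species per transect; high: vegetated margin, >= 2) and
field position (edge/middle) as factors.
"""

from fieldmargins import (SimulationConfig, categorize_richness, group_means,
                          simulate_bundle, site_features, yield_anova)

bundle, truth = simulate_bundle(SimulationConfig(seed=42))
features = site_features(bundle)
categories = categorize_richness(features)

print("site categories (from margin flag + transect tree richness):")
print(categories.value_counts().to_string())
print()
print("beans per plant by category:")
print(group_means(bundle.yields, categories).round(2).to_string(index=False))
print()
table = yield_anova(bundle.yields, categories)
print(f"ANOVA on {table.attrs['transform']} (Type {table.attrs['ss_type']}):")
print(table.round(4).to_string())

# The generator plants an additive effect of 0.4 on log beans/plant for
# tree-rich sites; a significant richness term (p < 0.05) with a higher
# 'high' group mean recovers it. Position carries no planted effect.
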