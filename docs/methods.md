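# Methods

This note documents the models, conventions and design choices behind each
stage, what the synthetic generator does and does not emulate, and the
numerical details a user should know before trusting the outputs.

## Sampling units and data model

The unit of the co-occurrence analysis is the **trap point** (site x
transect x point index). The two 1x1 m quadrats flanking a trap are pooled
to that point: a plant is "present" at a point if it was recorded with
positive cover in either quadrat. Trap catches are presence at the point
when the count is positive. Cropping stages are pooled by default (a
species or guild recorded at a point during any stage counts as present
there); per-stage tables are available (`by_stage`), and margin and
into-crop transect points enter as separate sampling points unless a
single transect is selected. Stage pooling trades power for simplicity:
with five stages, pooled presence frequencies saturate towards 1 and
association signals shrink, so single-stage or per-stage analyses are
preferable when occupancy is high.

Schemas are validated on ingest: enum membership (zones, transects,
stages, origins, growth forms, positions), ranges (cover in [0, 100],
non-negative counts), and key uniqueness. Total cover within a quadrat may
exceed 100% only with `layered_cover=true` (tree canopy over herbs); the
default is planar cover, with a small (1e-4) tolerance for CSV rounding.
Point indices are validated only as positive integers: the field design
uses 1–5 per transect, but longer transects are legitimate inputs and the
generator's recovery experiments use them.

## Co-occurrence statistic

For plant p and guild g over n shared points: `P_plant` and `P_ins` are
marginal presence frequencies, `P_c` the fraction of points where both are
present, and `P_pred = P_plant * P_ins` the expectation if presences
assort independently — the only parameter-free null consistent with
"random co-occurrence". `excess = P_c - P_pred` is the default ranking
statistic: it is null-centred (exactly unbiased under independence) and
comparable across plants; `ratio` and raw `observed` rankings are
available. Exclusions: a plant with exactly one presence point
(`single_occurrence`) or presence at every point (`ubiquitous`) carries no
information and is removed before ranking. Per guild, the shortlist holds
the top `k = max(1, round_half_up(0.05 * n_retained))` retained plants;
ties break on higher `P_c`, then species name, so output is deterministic.

## Diversity covariates

Shannon–Weaver `H` is computed per quadrat survey event (one quadrat at
one stage), cover-weighted, in nats; presence weighting is available via
config since surveys differ in whether cover is trusted. Effective plant
richness is the mean of `exp(H)` over a site's quadrat events — averaging
on the effective-number (Hill) scale, which keeps the value interpretable
as "equivalent equally-abundant species"; `exp(mean H)` is available via
`avg_scale="index"`. Site covariates follow the predictor-table
convention: `PlantQuad` and `Trees` are quadrat-event means;
`TreesTransect` is the mean count of distinct tree species per transect,
the scale on which the yield categorisation rule is stated; `Ratio` is
native/introduced species counts and is reported missing (and dropped
listwise by models) when no introduced species occur. Quadrat events with
no recorded species do not enter the means (field data contain no explicit
empty-quadrat rows).

## Networks

Site networks are weighted plant x visitor-guild matrices of summed visit
counts; visitors stay at guild resolution as recorded. Metrics:

* connectance `L / (I*J)`;
* interaction evenness `(-sum q ln q) / ln(I*J)`, `q = W / sum(W)`,
  undefined (missing) for single-cell webs;
* **NODF** on the binary incidence: for each pair of rows (and of
  columns), taking the denser line first, the contribution is
  `100 * overlap / fill_sparser` when fills differ strictly, else 0; the
  mean over all row and column pairs equals NODF of the packed matrix
  (the conventional reported form) and is invariant to input ordering.
  Weighted variants are out of scope; NODF is fixed as the de-facto
  standard among the nestedness family.
* **robustness**: species of one level are removed in uniformly random
  order; after each removal, species of the other level with no remaining
  links go secondarily extinct. The survival curve includes the endpoints
  (0, 1) and (1, 0) and is integrated by the trapezoid rule — stated
  explicitly because area conventions differ between implementations. The
  default is 2,000 seeded Monte-Carlo orders, which is within 0.01 of the
  exhaustive-order value on small webs; the n-specialist one-to-one web
  gives exactly 0.5 under this convention.

Median-split comparisons assign sites at or below the median to the
"below" group (deterministic tie rule) and use the one-way case of the
ANOVA engine; groups smaller than 2 are skipped with a warning.

## Random-forest importance

Forests are scikit-learn regression forests (bootstrap trees, `mtry`
candidate variables per split, default `round(p/3)`, 500 trees). Percent
variance explained is `100 * (1 - MSE_oob / var(y))` with out-of-bag
predictions, falling back to 5-fold cross-validation if OOB coverage is
incomplete. %IncMSE is computed in-package by explicit column permutation:
`100 * mean(MSE_perm - MSE_base) / MSE_base` over `n_perm` independent
shuffles (default 10), evaluated on out-of-bag predictions reconstructed
from the per-tree bootstrap indices, with a Monte-Carlo standard error
over permutations. The unscaled percent-increase form is used (no division
by the permutation s.d.), since the scaled variant conflates effect size
with permutation noise. Follow-up linear and quadratic OLS fits report
adjusted R² and flag relationships above 0.24 for display; generalised
additive fits are out of scope.

## Yield ANOVA

Beans/plant = pods x beans/pod. The response is `log(beans_plant + 1)`:
the offset keeps zero-pod plants in the analysis and is configurable. The
ANOVA engine computes sequential (Type I) sums of squares from incremental
least-squares fits, factor order (richness, position), no interaction —
matching the two separate single-degree-of-freedom F tests this design
reports; Type II is available for unbalanced data. Sums of squares below
1e-10 of the total are snapped to zero so degenerate inputs (constant
response) yield F = 0 rather than floating-point noise. Normality is
reported as a skewness value in the table attributes, not enforced as a
gate. Site categories follow the margin rule — low: no vegetated margin
and <= 1 tree species per transect; high: margin present and >= 2 — with
the gap between definitions left unclassified and excluded with a warning.

## Synthetic generator

The generator emulates the study design: 32 sites in four zones (8 each),
two transects x five points x two quadrats, five stages; yield records for
the Malawi zone only (8 sites, 12 plants each, within the study's 8–18
per-farm range). Half the Malawi sites and a quarter of the Tanzanian
sites have low-diversity margins: no trees, thinned margin vegetation
(occupancy x 0.4), `has_margin = False` — mirroring the bare road-edge
margins typical of the Malawian sites. Components:

* **Flora**: Bernoulli occupancy per quadrat event per species; percent
  cover lognormal (shape 0.6) truncated to (0, 100], with overfull
  quadrats rescaled to a planar 100% total; flowering is a deterministic
  function of stage. Tree occupancy falls to 0.3x inside the crop.
* **Traps**: guild presence at a point follows logistic odds — baseline
  odds times the product of association multipliers `A[p, g]` over plants
  present at that point — so the planted ground truth acts directly on
  the presence scale the co-occurrence statistic estimates. Counts are
  1 + Poisson(mean - 1), keeping presence and count consistent. Records
  are emitted only for caught guilds, as in field data; analyses
  therefore take an explicit trap-point universe.
* **Visits**: Poisson with rate = guild visit rate x preference
  `V[g, p]`, on flowering plants only.
* **Yield**: `log(beans/plant) = 3.0 + 0.4 * 1[tree-rich] + N(0, 0.5)`,
  mapped exactly onto integer pods and real beans/pod so the planted
  effect is the exact ANOVA estimand. The intercept (~20 beans/plant) and
  spread are realistic magnitudes for smallholder common bean.

Default association multipliers of 6 on six plant–guild pairs (trees and
common weeds favouring particular pollinator and natural-enemy guilds)
are the recovery targets. One seed drives independent per-stage random
streams, so a fixed config reproduces the bundle bit for bit and
regenerating one table does not perturb the others.

The generator does **not** emulate: spatial structure within or between
sites (no distance decay, no landscape context), inter-annual or weather
variation, observation error in identification, guild-level abundance
correlations beyond the planted associations, secondary sites with
reduced trap effort, or phenology beyond per-stage flowering flags.
Passing recovery tests therefore show the estimators are correct and well
calibrated under the design's sampling structure — not that field data
meet these assumptions.

## Problem sizes and runtime choices

Recovery and calibration experiments run at: 200 replicates of 20 sites x
40 points for association recovery; 1,000 replicates for null centring;
100 replicates of 100 sites (300 trees, 5 permutations) for importance
rank recovery; 2,000 null and 200 effect replicates of 60 plants for the
ANOVA calibration; 2,000 Monte-Carlo removal orders for robustness. These
sizes give Monte-Carlo errors well below the decision margins of each
check while keeping a full run in a few minutes on one core.

## Known limitations

* With all five stages pooled, common species approach ubiquity and the
  exclusion rule plus shrinking excess reduce sensitivity; use per-stage
  analysis for high-occupancy communities.
* `%IncMSE` values depend on forest hyperparameters and are comparable
  within a model, not across studies or toolkits.
* The in-package ANOVA assumes independent observations; plants within a
  site are treated as independent (no site random effect), as in the
  design it mirrors.
* Network metrics are computed on observed webs without null-model
  correction; NODF in particular correlates with fill and matrix size.
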