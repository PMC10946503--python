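# Methods

This note documents the models, conventions and design choices behind
`guildshift`, in the spirit of a statistical package's model documentation:
what is assumed, what is tunable, and what passing the test suite does and
does not demonstrate.

## The modelling unit

The atom is the **species-guild**: one species' run of size classes
assigned to one feeding guild. Size classes are taxon-specific intervals
derived from length at maturity and maximum length — `[0, 3)` larvae,
`[3, Lmat/2)`, `[Lmat/2, Lmat)`, `[Lmat, Lmax/2)`, `[Lmax/2, ∞)` cm.
Intervals are lower-inclusive/upper-exclusive, so a boundary length belongs
to the larger class; this convention is arbitrary but fixed and tested.
When life-history estimates give `Lmat > Lmax/2` the natural breakpoint
order is violated; breakpoints are sorted ascending before interval
construction and the taxon logged, so every positive length still maps to
exactly one class. A species may sit in different guilds at different
sizes (ontogenetic guild shifts), which is why indicators can count either
distinct species (default) or species-guild units.

## Trophic quantities

Diet matrices hold the % contribution of each prey functional group
(zooplankton / benthos / fish) to the **prey biomass** of a species-size
class; rows sum to 100 by construction. Guilds are obtained by hierarchical
clustering of diet rows with Bray–Curtis dissimilarity and average linkage
— the standard choice for composition data — cut at k = 3 and labelled by
each cluster's dominant mean prey group. Metric, linkage and k are
arguments, not constants. If two clusters share a dominant group the labels
are suffixed and a warning raised rather than silently merged: label
ambiguity is a data property the user should see.

Stomach-level PPMR is the prey-biomass-weighted mean of individual
predator/prey mass ratios, algebraically `M·Σcᵢ / Σcᵢmᵢ`; species-guild
PPMR is the unweighted mean over stomachs. Missing predator masses come
from `m = a·L^b` (coefficients are a required input table; the synthetic
default is a = 0.01 g·cm⁻³, b = 3, a generic isometric fish); missing fish
prey masses chain the typical-prey-length relation
`0.2057·L_pred + 1.618` cm through the prey's length–mass relation; missing
non-fish prey masses come from a mean-mass lookup per taxon or functional
group. Stomachs whose prey cannot be resolved are dropped and logged, never
silently imputed.

## Predictors

Dynamic layers are reduced to annual means plus, for the heterogeneity
variables (temperature, salinity, oxygen), the SD of the 12 monthly means
pooled over all cells within 75 km. The SD uses the **sample** convention
(ddof = 1) over the pooled neighbourhood-month values; neighbourhoods are
Euclidean disks on the projected 10-km grid, truncated at the domain edge.
A radius below one cell degrades to the within-cell SD with a warning.

Planktivores (largely pelagic) are modelled on surface variables,
benthivores and piscivores (largely demersal) on seabed variables; both
sets include the static layers (depth, distance to coast, substrate
fractions), surface productivity proxies and stratification (bottom −
surface temperature), the latter offered to all guilds (switchable).
Collinearity is pruned greedily per guild: while any pair exceeds
|r| = 0.7, the member of the worst pair with the larger mean |r| against
the remaining columns is dropped (ties: lower priority in the guild's
candidate ordering, then lexicographically later name). Constant columns
are dropped first. The retained set is therefore reproducible given the
input and priority order.

## The habitat model and its engine

Each species-guild gets a probabilistic presence/absence classifier.
Presence is defined at the cell-year level: present if ≥ 1 haul recorded
the species-guild, absent if ≥ 1 haul of the *same gear* sampled the
cell-year without recording it, missing otherwise. Gears are never mixed,
so catchability differences need no correction. Models require ≥ 40
presences; smaller species-guilds are listed as skipped, not fitted.

The pipeline is engine-agnostic: any ensemble-of-trees classifier exposing
per-draw probabilities and per-variable split counts satisfies the
contract. The default engine is a seeded bagged ensemble of 80 CART trees
(all features considered at each split, ≥ 8 samples per leaf). Predictions
are the ensemble-mean probability; the uncertainty width is the 95%
interpercentile range of the per-tree probabilities; variable importance is
the proportion of all split decisions using each variable, normalised to
sum 1. A Bayesian tree ensemble can be substituted wherever available
without touching the pipeline — the tests run the deterministic default.

## Validation

Spatial transfer is assessed by eightfold block cross validation. The
block edge is the empirical autocorrelation range of the dynamic predictors
in a reference year (nearest to 2000): the first lag at which the
correlogram drops below 1/e, median across predictors, rounded up to whole
cells. On small domains the latitudinal temperature gradient can push this
range so wide that fewer than eight blocks exist; the edge is then shrunk
to the largest value leaving eight non-empty folds, with a warning — the
design keeps its invariant (every cell in exactly one fold, eight non-empty
folds) at the cost of slightly optimistic independence. Blocks are dealt to
folds by a seeded permutation, round-robin for balance. Each fold is
predicted by a refit that never saw it; single-class training splits skip
the fold with a logged coverage gap.

Temporal transfer holds out the years from 2015 onward; if fewer than ten
validation presences exist the split year drops one year at a time, and a
species-guild with no feasible split is marked untestable (and cannot pass
the gate).

Metrics: ROC AUC (Mann–Whitney normalisation, ties half), PR AUC
(trapezoid over recall after collapsing duplicate recalls to their best
precision), and the Miller slope — the coefficient of a logistic regression
of outcome on logit(prediction), probabilities clipped to
[10⁻⁶, 1 − 10⁻⁶]; non-convergence yields NaN with a warning. A model passes
when both ROC AUCs reach 0.65. The presence threshold maximises
sensitivity + specificity over the pooled spatial-CV predictions; the
candidate set is the observed predicted values plus {0, 1}, and ties
resolve to the smallest maximiser.

## Indicators and change detection

Thresholded (probability ≥ threshold) presence grids give, per cell:
species richness (distinct species by default; species-guild counting is a
flag), mean maximum length over species present, and mean PPMR over
species-guild members present; empty cells are masked (NaN), never zero.
Range descriptors are occupied-cell counts (× 100 km²) and unweighted
centroid latitude/longitude. Percent change from a zero baseline is
undefined: such cells are flagged as colonisations and excluded from %
maps rather than mapped as infinities.

Study-area change is a Kruskal–Wallis rank test (tie-corrected, χ² with
1 df) between cell values at the endpoint years, reported with the sign of
the median difference since H is directionless. Per-cell trends use
Kendall τ-b (tie-corrected — indicator series are integer-valued and tied)
against year with the asymptotic two-sided p-value; a direction is assigned
only when p < α = 0.05. No multiplicity correction is applied across cells
by default, matching the mapped-significance convention of the approach;
Benjamini–Hochberg is available as an option.

## The synthetic generator

The generator emulates the *structure* of the study inputs, not their
geography or physics. The grid is abstract (10-km cells, linear lat/lon,
coast at the western edge). Temperature follows a south–north gradient, a
seasonal cycle and the scenario's warming rate (°C/decade, default 0.3
"moderate" and 0.55 "high", the contrast between a stabilisation and a
no-mitigation trajectory); salinity, oxygen, chlorophyll and zooplankton
carry their own spatial structure, with zooplankton deliberately collinear
with chlorophyll so the pruning path is always exercised. Spatial noise
fields are drawn once per variable and held fixed across years, so a
zero-trend scenario is bit-identical across years and the warming signal
is exactly the configured rate; optional interannual noise can be added.
Species niches are products of independent Gaussians over annual-mean
predictors, times a detectability in [0, 1]; surveys place seeded hauls
with an otter/beam gear split and record beam-designated taxa only in beam
hauls. Diet profiles are per-item probabilities; because item counts and
masses differ by orders of magnitude across prey groups (hundreds of ~2-mg
zooplankton versus single multi-gram fish), the archetype probabilities
are set sharply (0.95/0.90/0.70 dominance) so that *biomass* composition
matches the intended guild. All randomness flows from one explicit seed;
same seed, bit-identical tables and grids.

What the generator does **not** emulate: real bathymetry and coastline,
multi-variable climate trends (only temperature is trended by default),
species interactions, fishing pressure, observation effort gradients, and
abundance/biomass (presence only). Passing tests therefore demonstrate
that the pipeline recovers known structure under its own assumptions —
monotone Gaussian niches, independent hauls — not that it would achieve
the same skill on survey data.

## Problem sizes and runtime choices

The shipped experiment sizes are chosen to keep a full run on one CPU in
minutes: demonstration pipelines use 6–12 species on 18–30-cell grids with
~1000–3000 hauls; the recovery benchmark uses one species, 2000 hauls, a
30 × 30 grid and eightfold CV; the shift harness uses 24 × 24 grids with
16 projection years (2020–2095 in 5-year steps, as in the full design) and
20 seeded replicates. Larger runs are a matter of configuration, not code.

## Known limitations

- The bagged-trees default engine approximates, but is not, a Bayesian
  tree ensemble; its uncertainty width is ensemble spread, not a posterior
  credible interval.
- Block CV on small domains can require shrinking blocks below the
  autocorrelation range (see above), making spatial validation mildly
  optimistic there.
- Synthetic PPMR magnitudes span wider ranges across guilds than typically
  reported for real assemblages, because prey-group masses are stylised;
  PPMR *contrasts* between guilds, not absolute values, are the meaningful
  output.
- Kruskal–Wallis treats cells as independent replicates; spatial
  autocorrelation inflates its significance, which is why the per-cell
  Kendall maps accompany it.
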