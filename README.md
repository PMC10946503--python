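# guildshift

Climate change redistributes marine fish not species-by-species at random
but along the food web: species and size classes that share prey — feeding
guilds — respond together, shifting where planktivores, benthivores and
piscivores can live and thereby reshaping community size structure and
energy flux. `guildshift` is a tested, reusable pipeline for making and
validating that kind of prediction:

1. **Trophic structure from stomach contents.** Fish are split into five
   taxon-specific size classes from length at maturity (*L*<sub>mat</sub>)
   and maximum length (*L*<sub>max</sub>): `[0, 3)` cm larvae,
   `[3, L_mat/2)` small juveniles, `[L_mat/2, L_mat)` juvenile-medium,
   `[L_mat, L_max/2)` medium, and `[L_max/2, ∞)` large. Diet matrices
   (% prey biomass per functional group) are clustered (Bray–Curtis,
   average linkage) into feeding guilds, and each stomach yields a
   biomass-weighted predator–prey mass ratio

   PPMR = Σᵢ wᵢ (M/mᵢ) / Σᵢ wᵢ,  wᵢ = countᵢ · mᵢ,

   with missing masses filled by length–mass allometry *m* = *a·L^b* and the
   typical-fish-prey-length relation
   *prey length* = 0.2057 × *predator length* + 1.618 (cm).

2. **Habitat suitability per species-guild.** One probabilistic
   presence/absence model per species-guild (an ensemble-of-trees
   classifier with per-draw probabilities, posterior-style uncertainty
   widths and split-count variable importance), trained on single-gear
   survey data with ≥ 40 presences, on collinearity-pruned
   (|r| ≤ 0.7) annual-mean + 75-km monthly-SD predictors, surface
   variables for planktivores and seabed variables for demersal guilds.

3. **Validation in space and time.** Eightfold spatial-block cross
   validation (block size from the predictors' autocorrelation range) and a
   post-2015 temporal holdout; ROC AUC, precision–recall AUC and the Miller
   calibration slope; models must reach ROC AUC ≥ 0.65 in *both* tests;
   presence thresholds maximise sensitivity + specificity.

4. **Indicators and change detection.** Thresholded presence surfaces are
   aggregated into species richness, mean maximum length (MML) and mean
   PPMR per guild and community-wide; change is tested at the study-area
   scale (Kruskal–Wallis, 2020 vs 2095) and per 100-km² cell (Kendall τ-b
   over 5-year steps).

A first-class synthetic-data module generates virtual species with Gaussian
environmental niches, gear-structured trawl surveys, stomach contents and
multi-decadal warming scenarios, so the full pipeline runs and is testable
with no external data.

## Worked example

```python
from guildshift import pipeline

cfg = pipeline.RunConfig(
    seed=5, n_species=6, grid_shape=(18, 18), n_hauls=900,
    survey_years=tuple(range(2006, 2020)),
    projection_years=(2020, 2035, 2050, 2065, 2080, 2095),
    scenarios=(("moderate", 0.3), ("high", 0.55)),   # °C per decade
    n_stomachs_per_class=20, n_folds=4, min_presences=25)
res = pipeline.run_pipeline(cfg)

print("fitted:", res.manifest["n_models_fitted"],
      "passed gate:", res.manifest["n_models_passed"])
print(res.models[("sp00_plan", "planktivore")].summary())
```

prints (abridged):

```
fitted: 7 passed gate: 6
Habitat suitability model (bagged tree ensemble)
====================================================
species-guild: sp00_plan / planktivore   gear: beam
observations:  253   presences: 92
threshold:     0.3112472263391387
spatial  ROC AUC 0.766  PR AUC 0.583  Miller slope 0.740
temporal ROC AUC 0.788  PR AUC 0.650  Miller slope 0.625  (split year 2015)
passed 0.65 ROC gate: True
variable importance (proportion of splits):
  temperature_surface_sd75     0.217
  salinity_surface_sd75        0.170
  ...
```

Seven species-guild models had enough presences to train; six cleared the
0.65 dual-AUC gate and enter the indicator surfaces. The summary gives the
model's out-of-block and out-of-period discrimination (ROC/PR AUC), its
calibration (Miller slope, 1 = perfect), the presence threshold chosen on
the spatial-CV predictions, and which predictors the trees actually split
on. Downstream, `res.kw_tests` holds the endpoint Kruskal–Wallis table — in
this run, e.g. benthivore richness increases significantly under the
moderate scenario (H = 211.3, p < 0.001) while community MML declines —
and `res.trend_tables` the per-cell Kendall τ maps.

The same experiment is available from the shell:

```bash
guildshift run --seed 5 --out runs/demo
guildshift trends --warming 0.3 --seed 0     # single-species recovery harness
```

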