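"""End-to-end orchestration: synthetic inputs -> guilds & PPMR -> habitat
models -> validation gate -> projections -> indicators -> change detection.

`run_pipeline` executes the whole experiment from a :class:`RunConfig` and
returns a :class:`PipelineResult`; with an output directory it also writes
the tables, surfaces and a manifest (config, seeds, gate outcomes, skipped
species-guilds) from which the run can be regenerated.  Models failing the
0.65 ROC gate in either validation are excluded from every indicator
surface and listed in a machine-readable exclusions table.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from . import habitat, indicators, predictors, synthetic, trends, trophic, validation

logger = logging.getLogger(__name__)

INDICATOR_FUNS = ("richness", "mml", "ppmr")


@dataclass
class RunConfig:
    """Configuration for one synthetic end-to-end experiment."""

    seed: int = 0
    n_species: int = 12
    grid_shape: tuple[int, int] = (30, 30)
    survey_years: tuple[int, ...] = tuple(range(1995, 2020))
    projection_years: tuple[int, ...] = tuple(range(2020, 2096, 5))
    scenarios: tuple[tuple[str, float], ...] = (("moderate", 0.3), ("high", 0.55))
    n_hauls: int = 3000
    n_stomachs_per_class: int = 30
    k_guilds: int = 3
    n_folds: int = 8
    min_presences: int = habitat.MIN_PRESENCES
    auc_gate: float = validation.AUC_GATE
    split_year: int = validation.DEFAULT_SPLIT_YEAR
    alpha: float = trends.DEFAULT_ALPHA
    richness_mode: str = "species"

    def __post_init__(self):
        if not (0 < self.auc_gate < 1) or not (0 < self.alpha < 1):
            raise ValueError("auc_gate and alpha must lie in (0, 1)")
        if self.n_folds < 2 or self.min_presences < 1 or self.k_guilds < 2:
            raise ValueError("n_folds, min_presences and k_guilds out of range")

    @property
    def all_years(self) -> tuple[int, ...]:
        return tuple(sorted(set(self.survey_years) | set(self.projection_years)))


@dataclass
class PipelineResult:
    config: RunConfig
    species: list
    guild_map: pd.DataFrame
    diet_matrix: pd.DataFrame
    ppmr_table: pd.DataFrame
    models: dict = field(default_factory=dict)       # (taxon, guild) -> results
    skipped: list = field(default_factory=list)
    reports: dict = field(default_factory=dict)      # (taxon, guild) -> ValidationReport
    excluded: list = field(default_factory=list)     # gate failures
    surfaces: dict = field(default_factory=dict)     # (indicator, scope, scenario, year) -> grid
    presence: dict = field(default_factory=dict)     # (scenario, year) -> {(taxon, guild): grid}
    range_table: pd.DataFrame | None = None
    kw_tests: pd.DataFrame | None = None
    trend_tables: dict = field(default_factory=dict)  # (indicator, scope, scenario) -> frame
    trend_summaries: pd.DataFrame | None = None
    lat: np.ndarray | None = None
    lon: np.ndarray | None = None
    manifest: dict = field(default_factory=dict)


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> PipelineResult:
    rng_seed = int(config.seed)

    # -- synthetic inputs ---------------------------------------------------
    species = synthetic.make_species_pool(config.n_species, seed=rng_seed)
    life_history = synthetic.life_history_table(species)
    envs = {}
    for label, rate in config.scenarios:
        envs[label] = synthetic.generate_env_grids(synthetic.ScenarioConfig(
            years=config.all_years, warming_rate=rate, scenario_label=label,
            grid_shape=config.grid_shape, seed=rng_seed))
    base_label = config.scenarios[0][0]
    hauls, obs = synthetic.generate_survey(
        species, envs[base_label], n_hauls=config.n_hauls, seed=rng_seed + 1,
        years=list(config.survey_years))

    # -- trophic stage ------------------------------------------------------
    lw = synthetic.default_length_mass_params(species)
    stomachs = synthetic.generate_stomachs(
        species, n_per_class=config.n_stomachs_per_class, seed=rng_seed + 2,
        lw_params=lw, withheld_predator_mass_frac=0.1, withheld_fish_prey_mass_frac=0.2)
    stomachs = trophic.impute_masses(stomachs, lw, synthetic.NONFISH_MASS_LOOKUP)
    diet = trophic.build_diet_matrix(stomachs)
    ppmr_table = trophic.species_guild_ppmr(stomachs)
    guild_map = trophic.build_guild_map(diet, ppmr=ppmr_table, life_history=life_history,
                                        k=config.k_guilds)
    sg_ppmr = (guild_map.groupby(["taxon", "guild"], as_index=False)["ppmr"].mean())

    result = PipelineResult(config, species, guild_map, diet, ppmr_table)

    # -- habitat models + validation gate ----------------------------------
    fields = {label: predictors.annual_predictor_fields(env) for label, env in envs.items()}
    base_fields = fields[base_label]
    models, skipped = habitat.fit_species_guild_models(
        hauls, obs, guild_map, life_history, base_fields,
        min_presences=config.min_presences, random_state=rng_seed)
    result.models, result.skipped = models, skipped

    design = validation.build_blocks(base_fields, n_folds=config.n_folds, seed=rng_seed)
    passed = {}
    for key, res in models.items():
        report = res.validate(design=design, split_year=config.split_year, seed=rng_seed)
        result.reports[key] = report
        ok = (not report.temporal_untestable
              and report.spatial_roc_auc >= config.auc_gate
              and report.temporal_roc_auc >= config.auc_gate)
        if ok:
            passed[key] = res
        else:
            result.excluded.append({"taxon": key[0], "guild": key[1],
                                    "spatial_roc_auc": report.spatial_roc_auc,
                                    "temporal_roc_auc": report.temporal_roc_auc})
    logger.info("%d of %d models passed the %.2f ROC gate",
                len(passed), len(models), config.auc_gate)

    # -- projections + indicators ------------------------------------------
    env0 = envs[base_label]
    result.lat, result.lon = env0.lat.values, env0.lon.values
    lmax = dict(zip(life_history["taxon"], life_history["max_length_cm"]))
    ppmr_by_key = {(r.taxon, r.guild): r.ppmr for r in sg_ppmr.itertuples()}
    guilds = sorted(guild_map["guild"].unique())
    range_rows = []

    for label, _ in config.scenarios:
        for year in config.projection_years:
            pres = {}
            for key, res in passed.items():
                prob = res.predict_surface(fields[label], year)
                pres[key] = indicators.presence_surface(prob, res.threshold)
                range_rows.append({"taxon": key[0], "guild": key[1], "scenario": label,
                                   "year": year,
                                   **indicators.range_summary(pres[key], result.lat, result.lon)})
            result.presence[(label, year)] = pres
            for scope in guilds + ["community"]:
                sub = {k: g for k, g in pres.items() if scope == "community" or k[1] == scope}
                if not sub:
                    continue
                result.surfaces[("richness", scope, label, year)] = indicators.richness(
                    sub, mode=config.richness_mode)
                result.surfaces[("mml", scope, label, year)] = indicators.mml(sub, lmax)
                result.surfaces[("ppmr", scope, label, year)] = indicators.ppmr_surface(
                    sub, ppmr_by_key)
    result.range_table = pd.DataFrame(range_rows)

    # -- change detection ---------------------------------------------------
    y0, y1 = config.projection_years[0], config.projection_years[-1]
    kw_rows, ts_rows = [], []
    for label, _ in config.scenarios:
        for ind in INDICATOR_FUNS:
            for scope in guilds + ["community"]:
                key0, key1 = (ind, scope, label, y0), (ind, scope, label, y1)
                if key0 not in result.surfaces:
                    continue
                t = trends.kruskal_wallis_change(result.surfaces[key0].ravel(),
                                                 result.surfaces[key1].ravel(),
                                                 indicator=ind, scope=scope)
                kw_rows.append({"scenario": label, "indicator": ind, "scope": scope,
                                "H": t.h_statistic, "df": t.df, "p": t.p_value,
                                "median_change": t.median_change, "direction": t.direction})
                stack = np.stack([result.surfaces[(ind, scope, label, y)]
                                  for y in config.projection_years]).astype(float)
                tmap = trends.trend_map(stack, years=config.projection_years,
                                        alpha=config.alpha)
                result.trend_tables[(ind, scope, label)] = tmap
                ts_rows.append({"scenario": label, "indicator": ind, "scope": scope,
                                **trends.trend_summary(tmap)})
    result.kw_tests = pd.DataFrame(kw_rows)
    result.trend_summaries = pd.DataFrame(ts_rows)

    result.manifest = {
        "package": "guildshift",
        "config": dataclasses.asdict(config),
        "n_models_fitted": len(models),
        "n_models_passed": len(passed),
        "gate": config.auc_gate,
        "excluded": result.excluded,
        "skipped": [dataclasses.asdict(s) for s in skipped],
        "guilds": guilds,
    }
    if outdir is not None:
        _write_artifacts(result, Path(outdir), hauls, obs, stomachs, life_history)
    return result


def _write_artifacts(result: PipelineResult, outdir: Path, hauls, obs, stomachs,
                     life_history) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    synthetic.write_tables(outdir / "inputs", hauls, obs, stomachs, life_history)
    result.guild_map.to_csv(outdir / "guild_map.tsv", sep="\t", index=False)
    result.diet_matrix.to_csv(outdir / "diet_matrix.csv")
    result.ppmr_table.to_csv(outdir / "ppmr.tsv", sep="\t", index=False)
    pd.DataFrame(result.excluded).to_csv(outdir / "exclusions.csv", index=False)
    if result.range_table is not None:
        result.range_table.to_csv(outdir / "range_summary.csv", index=False)
    if result.kw_tests is not None:
        result.kw_tests.to_csv(outdir / "kruskal_wallis.csv", index=False)
    if result.trend_summaries is not None:
        result.trend_summaries.to_csv(outdir / "trend_summaries.csv", index=False)
    indicators.indicator_table(result.surfaces, result.lat, result.lon).to_csv(
        outdir / "indicator_surfaces.csv", index=False)
    reports = {f"{k[0]}|{k[1]}": v.to_dict() for k, v in result.reports.items()}
    (outdir / "validation_reports.json").write_text(json.dumps(reports, indent=2))
    (outdir / "manifest.json").write_text(json.dumps(result.manifest, indent=2, default=str))


def compare_scenarios(result: PipelineResult, scenario_a: str, scenario_b: str
                      ) -> tuple[dict, pd.DataFrame]:
    """Endpoint-change difference maps between two scenarios of one run.

    For each indicator/scope the endpoint change (last minus first projection
    year) is computed per scenario; returned are per-cell difference grids
    (change under B minus change under A) and a summary table of the median
    absolute endpoint change per scenario.
    """
    y0, y1 = result.config.projection_years[0], result.config.projection_years[-1]
    diffs, rows = {}, []
    for (ind, scope, scen, year) in list(result.surfaces):
        if scen != scenario_a or year != y0:
            continue
        try:
            a0, a1 = result.surfaces[(ind, scope, scenario_a, y0)], \
                result.surfaces[(ind, scope, scenario_a, y1)]
            b0, b1 = result.surfaces[(ind, scope, scenario_b, y0)], \
                result.surfaces[(ind, scope, scenario_b, y1)]
        except KeyError as e:
            raise ValueError(f"scenario surfaces missing: {e}") from e
        if a0.shape != b0.shape:
            raise ValueError("mismatched grids between scenarios")
        change_a = np.asarray(a1, float) - np.asarray(a0, float)
        change_b = np.asarray(b1, float) - np.asarray(b0, float)
        diffs[(ind, scope)] = change_b - change_a
        rows.append({"indicator": ind, "scope": scope,
                     f"median_abs_change_{scenario_a}": float(np.nanmedian(np.abs(change_a))),
                     f"median_abs_change_{scenario_b}": float(np.nanmedian(np.abs(change_b))),
                     "median_difference": float(np.nanmedian(change_b - change_a))})
    return diffs, pd.DataFrame(rows)


def model_recovery_benchmark(seed: int = 0, n_hauls: int = 2000,
                             grid_shape: tuple[int, int] = (30, 30),
                             niche_breadth: float = 0.5,
                             warming_rate: float = 0.2,
                             survey_years: tuple[int, ...] = tuple(range(2000, 2020)),
                             n_folds: int = 8) -> dict:
    """Can the habitat model recover a steep single-predictor niche?

    One demersal virtual species responds only to bottom temperature
    (Gaussian niche, SD ``niche_breadth`` deg C, detectability 1); a survey
    of ``n_hauls`` hauls is simulated, the model fitted and spatially
    block-cross-validated.  Returns the pooled spatial-CV ROC AUC, the
    importance rank of the informative temperature predictor, and the median
    predicted probability inside versus outside the generating niche band
    (+/- 2 SD) over the training cells.
    """
    env = synthetic.generate_env_grids(synthetic.ScenarioConfig(
        years=tuple(survey_years), warming_rate=warming_rate,
        scenario_label="benchmark", grid_shape=grid_shape, seed=seed))
    t0 = synthetic.annual_mean(env, "temperature_bottom", survey_years[0])
    centre = float(np.quantile(t0, 0.6))
    sp = synthetic.VirtualSpecies(
        taxon_id="steep", length_at_maturity=20.0, max_length=60.0,
        niche_center={"temperature_bottom": centre},
        niche_breadth={"temperature_bottom": niche_breadth},
        diet_profile={}, detectability=1.0, gear="otter")
    hauls, obs = synthetic.generate_survey([sp], env, n_hauls=n_hauls, seed=seed + 1,
                                           beam_fraction=0.0)
    fields = predictors.annual_predictor_fields(env)
    sg_obs = obs.assign(guild="benthivore")
    pa = habitat.presence_absence_table(hauls, sg_obs, "steep", "benthivore", "otter")
    cols = habitat.pruned_columns_for_guild(fields, "benthivore")
    table = predictors.predictor_table(fields, pa, cols)
    data = pd.concat([pa.reset_index(drop=True), table.reset_index(drop=True)], axis=1)
    model = habitat.HabitatModel.from_dataframe(data, cols, species="steep",
                                                guild="benthivore")
    res = model.fit(random_state=seed)
    design = validation.build_blocks(fields, n_folds=n_folds, seed=seed)
    pooled = validation.spatial_cv(model, design, random_state=seed)

    pred = res.predict(data[cols])
    temp = data["temperature_bottom_mean"].to_numpy()
    inside = np.abs(temp - centre) <= 2 * niche_breadth
    return {
        "spatial_cv_roc_auc": validation.roc_auc(pooled["obs"], pooled["pred"]),
        "temperature_importance_rank": int(
            res.variable_importance.rank(ascending=False)["temperature_bottom_mean"]),
        "median_prob_inside_niche": float(np.median(pred[inside])),
        "median_prob_outside_niche": float(np.median(pred[~inside])),
        "n_presences": int(pa["presence"].sum()),
    }


def recover_known_trend(warming_rate: float = 0.3, seed: int = 0,
                        grid_shape: tuple[int, int] = (24, 24),
                        n_hauls: int = 1200,
                        survey_years: tuple[int, ...] = tuple(range(2000, 2020)),
                        projection_years: tuple[int, ...] = tuple(range(2020, 2096, 5)),
                        n_folds: int = 8) -> dict:
    """End-to-end recovery harness: does a warming-driven northward niche
    shift come out of the full pipeline with the right sign?

    One virtual demersal species is given a temperature niche centred in the
    southern half of the domain; under warming the suitable isotherm moves
    north.  A habitat model is fitted to a simulated survey, validated and
    thresholded via spatial-block CV, then projected to the endpoint years.
    Returns the mean-latitude change of the occupied range, occupied-cell
    counts, and the mean richness Kendall tau in the northern (expanding)
    and southern (trailing) thirds of the domain.
    """
    years = tuple(sorted(set(survey_years) | set(projection_years)))
    env = synthetic.generate_env_grids(synthetic.ScenarioConfig(
        years=years, warming_rate=warming_rate, scenario_label="harness",
        grid_shape=grid_shape, seed=seed))
    t0 = synthetic.annual_mean(env, "temperature_bottom", years[0])
    centre = float(np.quantile(t0, 0.7))  # suitable band in the warm (southern) half
    sp = synthetic.VirtualSpecies(
        taxon_id="shifter", length_at_maturity=20.0, max_length=60.0,
        niche_center={"temperature_bottom": centre},
        niche_breadth={"temperature_bottom": 0.8},
        diet_profile={sc: {"zooplankton": 0.1, "benthos": 0.8, "fish": 0.1}
                      for sc in trophic.SIZE_CLASSES},
        detectability=0.9, gear="otter")
    hauls, obs = synthetic.generate_survey([sp], env, n_hauls=n_hauls, seed=seed + 1,
                                           years=list(survey_years), beam_fraction=0.0)
    fields = predictors.annual_predictor_fields(env)
    sg_obs = obs.assign(guild="benthivore", taxon=sp.taxon_id)
    pa = habitat.presence_absence_table(hauls, sg_obs, sp.taxon_id, "benthivore", "otter")
    cols = habitat.pruned_columns_for_guild(fields, "benthivore")
    table = predictors.predictor_table(fields, pa, cols)
    data = pd.concat([pa.reset_index(drop=True), table.reset_index(drop=True)], axis=1)
    model = habitat.HabitatModel.from_dataframe(data, cols, species=sp.taxon_id,
                                                guild="benthivore")
    res = model.fit(random_state=seed)
    design = validation.build_blocks(fields, n_folds=n_folds, seed=seed)
    pooled = validation.spatial_cv(model, design, random_state=seed)
    res.threshold = validation.choose_threshold(pooled["obs"], pooled["pred"])
    roc = validation.roc_auc(pooled["obs"], pooled["pred"])

    y0, y1 = projection_years[0], projection_years[-1]
    pres = {y: indicators.presence_surface(res.predict_surface(fields, y), res.threshold)
            for y in projection_years}
    r0 = indicators.range_summary(pres[y0], env.lat.values, env.lon.values)
    r1 = indicators.range_summary(pres[y1], env.lat.values, env.lon.values)
    stack = np.stack([pres[y].astype(float) for y in projection_years])
    tmap = trends.trend_map(stack, years=projection_years)
    ny = grid_shape[0]
    north = tmap[tmap["y"] >= 2 * ny // 3]["tau"].dropna()
    south = tmap[tmap["y"] < ny // 3]["tau"].dropna()
    return {
        "spatial_roc_auc": roc,
        "threshold": res.threshold,
        "mean_lat_change": r1["mean_lat"] - r0["mean_lat"],
        "cells_start": r0["cells_occupied"], "cells_end": r1["cells_occupied"],
        "tau_north_mean": float(north.mean()) if len(north) else float("nan"),
        "tau_south_mean": float(south.mean()) if len(south) else float("nan"),
        "temperature_importance_rank": int(
            (res.variable_importance.rank(ascending=False)["temperature_bottom_mean"])),
    }
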