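"""Presence/absence habitat suitability models per species-guild.

The modelling atom is the species-guild: one species' size-class range
assigned to one feeding guild.  A species-guild is *present* in a grid
cell-year if at least one haul there recorded it, and *absent* if at least
one haul of the same gear sampled the cell-year without recording it;
unsurveyed cell-years are missing, not absent.  Data from different gears
are never combined, so gear-specific catchability needs no correction.

The model itself follows the statsmodels convention: build a
:class:`HabitatModel` from data, call :meth:`~HabitatModel.fit` and work
with the returned :class:`HabitatModelResults` (probability surfaces,
uncertainty widths, variable importance, validation, threshold, summary).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from . import predictors, trophic
from .engines import BaggedTreesEngine, TreeEnsembleEngine

logger = logging.getLogger(__name__)

MIN_PRESENCES = 40


def species_guild_observations(
    obs: pd.DataFrame, life_history: pd.DataFrame, guild_map: pd.DataFrame
) -> pd.DataFrame:
    """Attach size-class and guild labels to individual length records.

    Lengths are classified with each taxon's Lmat/Lmax, then joined to the
    (taxon, size_class) -> guild map; records of unclassified taxa or size
    classes are dropped.
    """
    lh = life_history.set_index("taxon")
    rows = obs.merge(life_history[["taxon"]], on="taxon")
    rows["size_class"] = [
        trophic.assign_size_class(L, lh.at[t, "length_at_maturity_cm"], lh.at[t, "max_length_cm"])
        for t, L in zip(rows["taxon"], rows["length_cm"])
    ]
    return rows.merge(guild_map[["taxon", "size_class", "guild"]], on=["taxon", "size_class"])


def presence_absence_table(
    hauls: pd.DataFrame, sg_obs: pd.DataFrame, taxon: str, guild: str, gear: str
) -> pd.DataFrame:
    """Cell-year presence/absence for one species-guild from one gear's hauls.

    Returns one row per surveyed (y, x, year) with columns ``presence`` and
    the cell coordinates; presences are cell-years with >=1 observation.
    """
    gh = hauls[hauls["gear"] == gear]
    surveyed = gh.groupby(["y", "x", "year"], as_index=False).agg(lat=("lat", "first"),
                                                                  lon=("lon", "first"))
    hits = sg_obs[(sg_obs["taxon"] == taxon) & (sg_obs["guild"] == guild)]
    hit_hauls = gh[gh["haul_id"].isin(hits["haul_id"])]
    present = set(map(tuple, hit_hauls[["y", "x", "year"]].to_numpy()))
    surveyed["presence"] = [
        int((y, x, yr) in present) for y, x, yr in surveyed[["y", "x", "year"]].to_numpy()
    ]
    return surveyed


def pruned_columns_for_guild(
    fields: xr.Dataset, guild: str, threshold: float = predictors.COLLINEARITY_THRESHOLD
) -> list[str]:
    """Retained predictor columns for a guild after collinearity pruning.

    The candidate set (surface for planktivores, seabed otherwise) is
    evaluated over every cell-year of the predictor stack; pairs with
    |Pearson r| above the threshold are pruned once per guild and the same
    retained set reused by all of the guild's species models.
    """
    cols = predictors.select_depth_variables(guild)
    ny, nx = fields.sizes["y"], fields.sizes["x"]
    yy, xx = np.mgrid[0:ny, 0:nx]
    cells = pd.concat(
        [pd.DataFrame({"y": yy.ravel(), "x": xx.ravel(), "year": int(yr)})
         for yr in fields.year.values[:: max(1, len(fields.year) // 4)]],
        ignore_index=True,
    )
    table = predictors.predictor_table(fields, cells, cols)
    return list(predictors.prune_collinear(table, threshold=threshold, priority=cols).columns)


class HabitatModel:
    """Probabilistic presence/absence habitat model for one species-guild.

    Parameters
    ----------
    presence : array of 0/1 outcomes, one per surveyed cell-year (or haul).
    exog : DataFrame of predictor columns aligned with ``presence``.
    meta : optional DataFrame with ``y, x, year`` (and lat/lon) per row,
        required for spatial-block CV and temporal holdout.
    species, guild, gear : identification of the species-guild.
    engine : any :class:`~guildshift.engines.TreeEnsembleEngine`;
        defaults to seeded bagged CART trees.
    min_presences : species-guilds with fewer presences are refused (fit
        raises ``InsufficientPresences``), mirroring the >=40 training rule.
    """

    def __init__(self, presence, exog: pd.DataFrame, meta: pd.DataFrame | None = None,
                 species: str = "", guild: str = "", gear: str = "otter",
                 engine: TreeEnsembleEngine | None = None,
                 min_presences: int = MIN_PRESENCES):
        self.presence = np.asarray(presence, dtype=int)
        if self.presence.ndim != 1 or len(self.presence) != len(exog):
            raise ValueError("presence and exog must align")
        if exog.isna().any().any():
            raise ValueError("exog contains missing values")
        self.exog = exog.reset_index(drop=True)
        self.meta = meta.reset_index(drop=True) if meta is not None else None
        self.species, self.guild, self.gear = species, guild, gear
        self.engine = engine if engine is not None else BaggedTreesEngine()
        self.min_presences = min_presences

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, predictor_cols: list[str],
                       presence_col: str = "presence", **kw) -> "HabitatModel":
        meta_cols = [c for c in ("y", "x", "year", "lat", "lon") if c in data.columns]
        return cls(data[presence_col].to_numpy(), data[predictor_cols],
                   meta=data[meta_cols] if meta_cols else None, **kw)

    @property
    def n_presences(self) -> int:
        return int(self.presence.sum())

    def fit(self, random_state: int = 0) -> "HabitatModelResults":
        if self.n_presences < self.min_presences:
            raise InsufficientPresences(
                f"{self.species}-{self.guild}: {self.n_presences} presences "
                f"< required {self.min_presences}")
        if self.n_presences == len(self.presence):
            raise ValueError("training data contain a single class (all presences)")
        engine = self.engine.clone(random_state)
        engine.fit(self.exog.to_numpy(dtype=float), self.presence)
        return HabitatModelResults(self, engine)


class InsufficientPresences(ValueError):
    """Raised when a species-guild has too few presences to train on."""


class HabitatModelResults:
    """Fitted habitat model: predictive surfaces, importance, validation.

    ``predict`` returns the ensemble-mean presence probability;
    ``uncertainty`` the 95% interpercentile width of the ensemble draws.
    ``threshold`` is populated by :meth:`validate` (sensitivity+specificity
    maximiser on the pooled spatial-CV predictions) or can be set directly.
    """

    def __init__(self, model: HabitatModel, engine: TreeEnsembleEngine):
        self.model = model
        self.engine = engine
        counts = engine.split_counts()
        total = counts.sum()
        self.variable_importance = pd.Series(
            counts / total if total > 0 else counts, index=model.exog.columns,
            name="importance")
        self.threshold: float | None = None
        self.validation = None  # ValidationReport, set by validate()

    # -- prediction ---------------------------------------------------------
    def predict(self, exog: pd.DataFrame | np.ndarray) -> np.ndarray:
        X = exog[self.model.exog.columns].to_numpy(dtype=float) \
            if isinstance(exog, pd.DataFrame) else np.asarray(exog, dtype=float)
        return self.engine.predict_draws(X).mean(axis=0)

    def uncertainty(self, exog: pd.DataFrame | np.ndarray) -> np.ndarray:
        X = exog[self.model.exog.columns].to_numpy(dtype=float) \
            if isinstance(exog, pd.DataFrame) else np.asarray(exog, dtype=float)
        draws = self.engine.predict_draws(X)
        lo, hi = np.percentile(draws, [2.5, 97.5], axis=0)
        return hi - lo

    def predict_surface(self, fields: xr.Dataset, year: int,
                        with_uncertainty: bool = False):
        """Presence-probability grid (and optionally uncertainty-width grid)
        for one projection year."""
        if int(year) not in [int(y) for y in fields.year.values]:
            raise ValueError(f"year {year} not in predictor stack")
        ny, nx = fields.sizes["y"], fields.sizes["x"]
        yy, xx = np.mgrid[0:ny, 0:nx]
        cells = pd.DataFrame({"y": yy.ravel(), "x": xx.ravel(), "year": int(year)})
        table = predictors.predictor_table(fields, cells, list(self.model.exog.columns))
        prob = self.predict(table).reshape(ny, nx)
        if not with_uncertainty:
            return prob
        return prob, self.uncertainty(table).reshape(ny, nx)

    # -- validation ---------------------------------------------------------
    def validate(self, design=None, split_year: int = 2015, n_folds: int = 8,
                 seed: int = 0, min_val_presences: int = 10,
                 fields: xr.Dataset | None = None):
        """Spatial eightfold block CV plus temporal holdout; stores the
        report and the spatial-CV threshold on this results object."""
        from . import validation as val

        report, thr = val.validate_model(self.model, design=design, fields=fields,
                                         split_year=split_year, n_folds=n_folds,
                                         seed=seed, min_val_presences=min_val_presences)
        self.validation = report
        self.threshold = thr
        return report

    # -- reporting ----------------------------------------------------------
    def summary(self) -> str:
        m = self.model
        lines = [
            "Habitat suitability model (bagged tree ensemble)",
            "=" * 52,
            f"species-guild: {m.species} / {m.guild}   gear: {m.gear}",
            f"observations:  {len(m.presence)}   presences: {m.n_presences}",
            f"threshold:     {self.threshold if self.threshold is not None else 'not set'}",
        ]
        if self.validation is not None:
            v = self.validation
            lines += [
                f"spatial  ROC AUC {v.spatial_roc_auc:.3f}  PR AUC {v.spatial_pr_auc:.3f} "
                f" Miller slope {v.spatial_miller_slope:.3f}",
                f"temporal ROC AUC {v.temporal_roc_auc:.3f}  PR AUC {v.temporal_pr_auc:.3f} "
                f" Miller slope {v.temporal_miller_slope:.3f}  (split year {v.split_year})",
                f"passed 0.65 ROC gate: {v.passed}",
            ]
        lines.append("variable importance (proportion of splits):")
        for name, v in self.variable_importance.sort_values(ascending=False).items():
            lines.append(f"  {name:<28s} {v:.3f}")
        return "\n".join(lines)

    def plot_surface(self, fields: xr.Dataset, year: int, ax=None):
        """QC map of the predicted probability surface."""
        import matplotlib.pyplot as plt

        prob = self.predict_surface(fields, year)
        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(prob, origin="lower", vmin=0, vmax=1, cmap="viridis")
        ax.set_title(f"{self.model.species}/{self.model.guild} {year}")
        plt.colorbar(im, ax=ax, label="P(presence)")
        return ax


@dataclass
class SkippedModel:
    species: str
    guild: str
    gear: str
    n_presences: int
    reason: str


def fit_species_guild_models(
    hauls: pd.DataFrame,
    obs: pd.DataFrame,
    guild_map: pd.DataFrame,
    life_history: pd.DataFrame,
    fields: xr.Dataset,
    engine: TreeEnsembleEngine | None = None,
    min_presences: int = MIN_PRESENCES,
    random_state: int = 0,
) -> tuple[dict[tuple[str, str], HabitatModelResults], list[SkippedModel]]:
    """Fit one habitat model per species-guild with enough presences.

    Assembles cell-year presence/absence per species-guild from its gear's
    hauls, extracts the guild's collinearity-pruned predictor set, and fits.
    Species-guilds under ``min_presences`` (or with degenerate outcomes) are
    skipped and listed with reasons rather than fitted.
    """
    sg_obs = species_guild_observations(obs, life_history, guild_map)
    gear_by_taxon = dict(zip(life_history["taxon"], life_history["gear"]))
    cols_by_guild = {g: pruned_columns_for_guild(fields, g)
                     for g in guild_map["guild"].unique()}

    results: dict[tuple[str, str], HabitatModelResults] = {}
    skipped: list[SkippedModel] = []
    for (taxon, guild), _ in guild_map.groupby(["taxon", "guild"]):
        gear = gear_by_taxon.get(taxon, "otter")
        pa = presence_absence_table(hauls, sg_obs, taxon, guild, gear)
        table = predictors.predictor_table(fields, pa, cols_by_guild[guild])
        data = pd.concat([pa.reset_index(drop=True), table.reset_index(drop=True)], axis=1)
        model = HabitatModel.from_dataframe(
            data, cols_by_guild[guild], species=taxon, guild=guild, gear=gear,
            engine=engine, min_presences=min_presences)
        try:
            results[(taxon, guild)] = model.fit(random_state=random_state)
        except (InsufficientPresences, ValueError) as e:
            skipped.append(SkippedModel(taxon, guild, gear, model.n_presences, str(e)))
            logger.info("skipping %s-%s: %s", taxon, guild, e)
    return results, skipped


def guild_variable_importance(
    results_by_guild: dict[str, list[HabitatModelResults]]
) -> pd.DataFrame:
    """Mean variable importance per feeding guild, renormalised to sum 1.

    Models within a guild may use different predictor columns (pruning can
    differ); importances are aligned on the union and missing entries treated
    as zero before averaging.
    """
    out = {}
    for guild, results in results_by_guild.items():
        if not results:
            continue
        imp = pd.concat([r.variable_importance for r in results], axis=1).fillna(0.0)
        mean = imp.mean(axis=1)
        out[guild] = mean / mean.sum()
    return pd.DataFrame(out)
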