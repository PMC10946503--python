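"""Feeding-guild allocation and predator–prey mass ratios from stomach contents.

Fish are partitioned into five taxon-specific size classes from length at
maturity (Lmat) and maximum (asymptotic) length (Lmax).  Stomach records —
one row per prey item — are completed with allometric length–mass
conversions where masses are missing, summarised into a diet matrix
(% biomass per prey functional group), clustered into feeding guilds
(planktivore / benthivore / piscivore), and reduced to one biomass-weighted
predator–prey mass ratio (PPMR) per species-guild.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)

SIZE_CLASSES = ("larva", "small_juvenile", "juvenile_medium", "medium", "large")

#: canonical prey functional groups used for guild naming
PREY_GROUPS = ("zooplankton", "benthos", "fish")

#: dominant prey group -> guild label
GUILD_BY_PREY = {"zooplankton": "planktivore", "benthos": "benthivore", "fish": "piscivore"}

# typical fish prey length as a linear function of predator length (cm)
PREY_LENGTH_SLOPE = 0.2057
PREY_LENGTH_INTERCEPT = 1.618


@dataclass(frozen=True)
class SizeClassRule:
    """Five size classes: larvae below ``larva_cutoff``, then breakpoints at
    Lmat/2, Lmat and Lmax/2.  Intervals are lower-inclusive, upper-exclusive
    and partition (0, inf)."""

    larva_cutoff: float = 3.0


def size_class_breakpoints(lmat: float, lmax: float, rule: SizeClassRule = SizeClassRule()) -> np.ndarray:
    """Interior breakpoints (cm) separating the five classes.

    If Lmat > Lmax/2 the natural breakpoint ordering is violated (possible
    with real life-history estimates); breakpoints are then sorted ascending
    and a warning logged so affected taxa can be audited.
    """
    if lmat <= 0 or lmax <= 0:
        raise ValueError(f"Lmat and Lmax must be positive, got {lmat}, {lmax}")
    bps = np.array([rule.larva_cutoff, lmat / 2.0, lmat, lmax / 2.0])
    if not np.all(np.diff(bps) >= 0):
        logger.warning(
            "size-class breakpoints out of order (Lmat=%.3g > Lmax/2=%.3g); sorting ascending",
            lmat, lmax / 2.0,
        )
        bps = np.sort(bps)
    return bps


def assign_size_class(
    length: float, lmat: float, lmax: float, rule: SizeClassRule = SizeClassRule()
) -> str:
    """Size-class label for a fish of ``length`` cm given its life history.

    Classes: [0, 3) larva; [3, Lmat/2) small juvenile; [Lmat/2, Lmat)
    juvenile-medium; [Lmat, Lmax/2) medium; [Lmax/2, inf) large.
    Boundary lengths belong to the upper class (lower-inclusive).
    """
    if length <= 0:
        raise ValueError(f"length must be positive, got {length}")
    bps = size_class_breakpoints(lmat, lmax, rule)
    return SIZE_CLASSES[int(np.searchsorted(bps, length, side="right"))]


def size_class_bounds(lmat: float, lmax: float, rule: SizeClassRule = SizeClassRule()) -> dict[str, tuple[float, float]]:
    """(lower, upper) length interval per size class; upper of 'large' is inf."""
    bps = size_class_breakpoints(lmat, lmax, rule)
    edges = np.concatenate([[0.0], bps, [np.inf]])
    return {c: (edges[i], edges[i + 1]) for i, c in enumerate(SIZE_CLASSES)}


def predict_fish_prey_length(predator_length: float | np.ndarray) -> float | np.ndarray:
    """Typical fish prey length (cm) from predator length via the empirical
    linear relation prey = 0.2057 * predator + 1.618."""
    predator_length = np.asarray(predator_length, dtype=float)
    if np.any(predator_length < 0):
        raise ValueError("predator length must be non-negative")
    out = PREY_LENGTH_SLOPE * predator_length + PREY_LENGTH_INTERCEPT
    return float(out) if out.ndim == 0 else out


@dataclass
class LengthMassParams:
    """Per-taxon allometric coefficients of mass = a * length**b (a in g·cm^-b).

    ``default_a``/``default_b`` are documented synthetic fallbacks applied to
    taxa absent from the table when ``allow_default`` is set.
    """

    table: pd.DataFrame  # columns: taxon, a, b
    default_a: float = 0.01
    default_b: float = 3.0
    allow_default: bool = True
    _by_taxon: dict = field(init=False, repr=False)

    def __post_init__(self):
        t = self.table
        if (t["a"] <= 0).any() or (t["b"] <= 0).any():
            raise ValueError("length-mass coefficients must be positive")
        self._by_taxon = {r.taxon: (r.a, r.b) for r in t.itertuples()}

    def coefficients(self, taxon: str) -> tuple[float, float]:
        if taxon in self._by_taxon:
            return self._by_taxon[taxon]
        if self.allow_default:
            return self.default_a, self.default_b
        raise KeyError(taxon)

    def mass(self, taxon: str, length_cm: float) -> float:
        a, b = self.coefficients(taxon)
        return a * length_cm**b


def impute_masses(
    records: pd.DataFrame,
    params: LengthMassParams,
    nonfish_mass_lookup: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Complete missing predator and prey masses in a stomach table.

    One row per prey item with columns ``stomach_id, taxon,
    predator_length_cm, predator_mass_g, prey_taxon, prey_group, count,
    prey_mass_g`` (prey_length_cm optional).  Missing predator mass comes
    from the taxon's length–mass relation; missing fish-prey mass from the
    typical-prey-length relation chained through the prey taxon's length–mass
    relation; missing non-fish prey mass from a mean-mass lookup per prey
    taxon (falling back to prey functional group).  Stomachs whose prey taxa
    resolve to no mass source are dropped with a log entry.
    """
    out = records.copy()
    nonfish_mass_lookup = nonfish_mass_lookup or {}

    miss_pred = out["predator_mass_g"].isna()
    if miss_pred.any():
        out.loc[miss_pred, "predator_mass_g"] = [
            params.mass(t, l)
            for t, l in zip(out.loc[miss_pred, "taxon"], out.loc[miss_pred, "predator_length_cm"])
        ]

    miss_prey = out["prey_mass_g"].isna()
    is_fish = out["prey_group"] == "fish"

    fish_fix = miss_prey & is_fish
    if fish_fix.any():
        prey_len = predict_fish_prey_length(out.loc[fish_fix, "predator_length_cm"].to_numpy())
        out.loc[fish_fix, "prey_mass_g"] = [
            params.mass(t, l) for t, l in zip(out.loc[fish_fix, "prey_taxon"], prey_len)
        ]
        if "prey_length_cm" in out.columns:
            out.loc[fish_fix, "prey_length_cm"] = prey_len

    nonfish_fix = miss_prey & ~is_fish
    if nonfish_fix.any():
        looked = [
            nonfish_mass_lookup.get(t, nonfish_mass_lookup.get(g, np.nan))
            for t, g in zip(out.loc[nonfish_fix, "prey_taxon"], out.loc[nonfish_fix, "prey_group"])
        ]
        out.loc[nonfish_fix, "prey_mass_g"] = looked

    bad = out["prey_mass_g"].isna()
    if bad.any():
        dropped = out.loc[bad, "stomach_id"].unique()
        logger.warning(
            "%d stomach(s) dropped: prey taxa with no mass source: %s",
            len(dropped), sorted(set(out.loc[bad, "prey_taxon"]))[:10],
        )
        out = out[~out["stomach_id"].isin(dropped)]
    return out.reset_index(drop=True)


def stomach_ppmr(record: pd.DataFrame) -> float:
    """Biomass-weighted mean predator–prey mass ratio for one stomach.

    With predator mass M and prey items (count_i, mass_i), each item's ratio
    M/m_i is weighted by its prey biomass w_i = count_i * m_i:
    PPMR = sum_i w_i (M/m_i) / sum_i w_i = M * sum_i count_i / sum_i w_i.
    """
    m = record["prey_mass_g"].to_numpy(dtype=float)
    c = record["count"].to_numpy(dtype=float)
    M = float(record["predator_mass_g"].iloc[0])
    if np.any(m <= 0) or np.any(c <= 0) or M <= 0:
        raise ValueError("masses and counts must be positive")
    biomass = c * m
    total = biomass.sum()
    if total == 0:
        raise ValueError("zero total prey biomass")
    return float(np.sum(biomass * (M / m)) / total)


def species_guild_ppmr(
    records: pd.DataFrame, guild_map: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Mean PPMR per species-guild: an unweighted arithmetic mean of
    stomach-level biomass-weighted PPMRs across unique predator samples.

    ``guild_map`` (taxon, size_class, guild) attaches guild labels; without it
    the grouping is (taxon, size_class).  Stomachs with zero prey biomass are
    skipped with a log entry.  Returns columns group cols + ``ppmr, n_stomachs``.
    """
    recs = records
    keys = ["taxon", "size_class"]
    if guild_map is not None:
        recs = recs.merge(guild_map[["taxon", "size_class", "guild"]], on=["taxon", "size_class"])
        keys = ["taxon", "guild"]

    rows = []
    for (sid,), rec in recs.groupby(["stomach_id"]):
        try:
            p = stomach_ppmr(rec)
        except ValueError:
            logger.warning("stomach %s skipped (degenerate prey biomass)", sid)
            continue
        rows.append({**{k: rec[k].iloc[0] for k in keys}, "stomach_id": sid, "ppmr": p})
    if not rows:
        return pd.DataFrame(columns=keys + ["ppmr", "n_stomachs"])
    per_stomach = pd.DataFrame(rows)
    out = (
        per_stomach.groupby(keys, as_index=False)
        .agg(ppmr=("ppmr", "mean"), n_stomachs=("stomach_id", "nunique"))
    )
    return out


def build_diet_matrix(records: pd.DataFrame, groups: tuple[str, ...] = PREY_GROUPS) -> pd.DataFrame:
    """% biomass contribution of each prey functional group to the diet of
    each (taxon, size_class).  Rows sum to 100."""
    recs = records.copy()
    recs["biomass"] = recs["count"] * recs["prey_mass_g"]
    wide = (
        recs.pivot_table(
            index=["taxon", "size_class"], columns="prey_group", values="biomass", aggfunc="sum"
        )
        .reindex(columns=list(groups))
        .fillna(0.0)
    )
    wide.columns.name = None
    totals = wide.sum(axis=1)
    return wide.div(totals, axis=0) * 100.0


def cluster_guilds(
    diet: pd.DataFrame,
    k: int = 3,
    metric: str = "braycurtis",
    method: str = "average",
) -> pd.DataFrame:
    """Cluster species-size-classes into ``k`` feeding guilds from their diet
    composition (hierarchical clustering on Bray–Curtis dissimilarity,
    average linkage) and label each cluster by its dominant mean prey group.

    Returns a frame indexed like ``diet`` with columns ``cluster`` and
    ``guild``.  When two clusters share a dominant prey group the labels are
    suffixed (_1, _2, ...) and a warning raised rather than silently merged.
    """
    if len(diet) < k:
        raise ValueError(f"need at least k={k} rows, got {len(diet)}")
    d = pdist(diet.to_numpy(dtype=float), metric=metric)
    z = linkage(d, method=method)
    clusters = fcluster(z, t=k, criterion="maxclust")

    labels = {}
    seen: dict[str, int] = {}
    for c in np.unique(clusters):
        mean_diet = diet[clusters == c].mean(axis=0)
        dominant = mean_diet.idxmax()
        guild = GUILD_BY_PREY.get(dominant, dominant)
        seen[guild] = seen.get(guild, 0) + 1
        labels[c] = guild
    for guild, n in seen.items():
        if n > 1:
            warnings.warn(
                f"{n} clusters share dominant prey group for guild '{guild}'; suffixing labels",
                stacklevel=2,
            )
            i = 0
            for c, g in labels.items():
                if g == guild:
                    i += 1
                    labels[c] = f"{guild}_{i}"

    out = pd.DataFrame(index=diet.index)
    out["cluster"] = clusters
    out["guild"] = [labels[c] for c in clusters]
    return out


def build_guild_map(
    diet: pd.DataFrame,
    ppmr: pd.DataFrame | None = None,
    life_history: pd.DataFrame | None = None,
    k: int = 3,
    **cluster_kw,
) -> pd.DataFrame:
    """Tidy species-guild table: taxon, size_class, guild (+ ppmr, lmax when
    the corresponding tables are supplied)."""
    gm = cluster_guilds(diet, k=k, **cluster_kw).reset_index()[["taxon", "size_class", "guild"]]
    if ppmr is not None:
        sp = ppmr if "guild" not in ppmr.columns else ppmr.drop(columns="guild")
        gm = gm.merge(sp, on=[c for c in ("taxon", "size_class") if c in sp.columns], how="left")
    if life_history is not None:
        gm = gm.merge(life_history[["taxon", "max_length_cm"]], on="taxon", how="left")
    return gm
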