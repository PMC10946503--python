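"""Seeded synthetic stand-ins for the study's survey and climate inputs.

Generates (a) virtual fish species with Gaussian environmental niches and
size-class-specific diets, (b) multi-decadal gridded environmental layers
under configurable warming scenarios on an abstract 10x10 km grid,
(c) trawl-survey haul/observation tables with an otter/beam gear split and
(d) stomach-content tables.  Everything is driven by one explicit seed; the
same seed reproduces bit-identical tables and grids.

The grid is abstract: latitude/longitude are assigned linearly, the
"coast" is the western edge, and only temperature carries a secular trend
by default (other variables may be trended via ``ScenarioConfig.extra_trends``).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import xarray as xr

from . import trophic

CELL_KM = 10.0
#: variables generated at monthly resolution (so neighbourhood SDs are computable)
MONTHLY_VARS = ("temperature_surface", "temperature_bottom", "salinity_surface",
                "salinity_bottom", "oxygen_bottom")
ANNUAL_VARS = ("chlorophyll_surface", "zooplankton_surface")
STATIC_VARS = ("depth", "dist_coast", "substrate_mud", "substrate_sand", "substrate_gravel")


@dataclass
class VirtualSpecies:
    """A simulated fish species: life history, environmental niche, diet and
    observability.

    ``niche_center``/``niche_breadth`` map annual-mean predictor names (e.g.
    ``temperature_surface``) to the mean and SD of a Gaussian suitability
    response; suitability is the product over predictors, times
    ``detectability``, and gives the per-haul presence probability.
    ``diet_profile`` maps size-class -> {prey group -> proportion}.
    """

    taxon_id: str
    length_at_maturity: float
    max_length: float
    niche_center: dict[str, float]
    niche_breadth: dict[str, float]
    habitat_domain: str = "demersal"  # pelagic | demersal
    diet_profile: dict[str, dict[str, float]] = dc_field(default_factory=dict)
    detectability: float = 1.0
    gear: str = "otter"  # otter | beam

    def __post_init__(self):
        if not (0 < self.length_at_maturity <= self.max_length):
            raise ValueError("require 0 < Lmat <= Lmax")
        if not (0.0 <= self.detectability <= 1.0):
            raise ValueError("detectability must lie in [0, 1]")
        if self.habitat_domain not in ("pelagic", "demersal"):
            raise ValueError(f"unknown habitat domain {self.habitat_domain!r}")
        if self.gear not in ("otter", "beam"):
            raise ValueError(f"unknown gear {self.gear!r}")
        for sc, profile in self.diet_profile.items():
            s = sum(profile.values())
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"diet profile for {sc!r} sums to {s}, not 1")
        if set(self.niche_breadth) != set(self.niche_center):
            raise ValueError("niche_center and niche_breadth must share keys")


@dataclass
class ScenarioConfig:
    """One emission scenario for the synthetic climate generator.

    ``warming_rate`` is degrees C per decade applied to surface and bottom
    temperature relative to the first year.  ``extra_trends`` optionally
    trends other variables (units per decade).  Noise fields are drawn once
    per variable from ``seed`` and held fixed across years, so a zero-trend
    scenario yields bit-identical fields in every year; ``interannual_sd``
    adds optional year-specific noise on top.
    """

    years: tuple[int, ...]
    warming_rate: float = 0.3
    scenario_label: str = "moderate"
    grid_shape: tuple[int, int] = (30, 30)
    seed: int = 0
    noise_sd: float = 0.4
    interannual_sd: float = 0.0
    extra_trends: dict[str, float] = dc_field(default_factory=dict)

    def __post_init__(self):
        self.years = tuple(int(y) for y in self.years)
        if any(b <= a for a, b in zip(self.years, self.years[1:])):
            raise ValueError("years must be strictly increasing")
        if self.grid_shape[0] <= 0 or self.grid_shape[1] <= 0:
            raise ValueError("grid_shape must be positive")


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sd: float) -> np.ndarray:
    """Spatially smooth noise: white noise blurred with a small moving-average
    kernel, rescaled to the requested SD."""
    from scipy.ndimage import uniform_filter

    raw = rng.standard_normal(shape)
    sm = uniform_filter(raw, size=3, mode="nearest")
    s = sm.std()
    return sm * (sd / s) if s > 0 else sm


def generate_env_grids(config: ScenarioConfig) -> xr.Dataset:
    """Gridded environmental layers for every year of a scenario.

    Returns a dataset with monthly variables on (year, month, y, x), annual
    variables on (year, y, x) and static layers on (y, x); substrate
    fractions sum to 100 at every cell.  Surface temperature follows a
    south-to-north gradient plus a seasonal cycle, the scenario's warming
    trend and fixed spatial noise.
    """
    ny, nx = config.grid_shape
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    years = np.array(config.years)
    months = np.arange(1, 13)
    y0 = years[0]

    lat = 50.0 + np.arange(ny) * (CELL_KM / 111.0)          # degrees, south at row 0
    lon = -4.0 + np.arange(nx) * (CELL_KM / 70.0)
    southness = 1.0 - (np.arange(ny) / max(ny - 1, 1))[:, None] * np.ones((1, nx))

    depth = 20.0 + 140.0 * np.clip(_smooth_field(rng, (ny, nx), 0.25) + 0.5, 0.05, 1.0)
    dist_coast = (np.arange(nx)[None, :] + 0.5) * CELL_KM * np.ones((ny, 1))
    substrate = rng.dirichlet((2.0, 2.0, 1.0), size=(ny, nx)) * 100.0

    noise_scale = {"temperature_surface": 1.0, "temperature_bottom": 1.0,
                   "salinity_surface": 0.5, "salinity_bottom": 0.5,
                   "oxygen_bottom": 20.0, "chlorophyll_surface": 1.0,
                   "zooplankton_surface": 0.25}
    noise = {v: _smooth_field(rng, (ny, nx), config.noise_sd * noise_scale[v])
             for v in MONTHLY_VARS + ANNUAL_VARS}
    seasonal = {  # amplitude of the monthly cycle, peak in August
        "temperature_surface": 3.0, "temperature_bottom": 1.0,
        "salinity_surface": 0.15, "salinity_bottom": 0.05, "oxygen_bottom": 8.0,
    }
    cyc = -np.cos(2.0 * np.pi * (months - 2) / 12.0)  # min in Feb, max in Aug

    base = {
        "temperature_surface": 8.0 + 6.0 * southness,
        "temperature_bottom": 6.5 + 4.0 * southness - 0.004 * depth,
        "salinity_surface": 33.0 + 0.004 * dist_coast,
        "salinity_bottom": 33.5 + 0.004 * dist_coast,
        "oxygen_bottom": 290.0 - 0.15 * depth,
        "chlorophyll_surface": 1.0 + 2.0 * np.exp(-dist_coast / 120.0),
        "zooplankton_surface": None,  # tightly coupled to chlorophyll (collinear on purpose)
    }
    warming = {"temperature_surface": config.warming_rate, "temperature_bottom": config.warming_rate}

    # build in dependency order (zooplankton follows chlorophyll)
    order = ["temperature_surface", "temperature_bottom", "salinity_surface",
             "salinity_bottom", "chlorophyll_surface", "oxygen_bottom",
             "zooplankton_surface"]
    raw: dict[str, list[np.ndarray]] = {}
    for v in order:
        trend = warming.get(v, 0.0) + config.extra_trends.get(v, 0.0)
        per_year = []
        for i, yr in enumerate(years):
            if base[v] is None:  # zooplankton tracks chlorophyll
                fld = 0.6 * (raw["chlorophyll_surface"][i] - noise["chlorophyll_surface"]) + 0.2
            else:
                fld = base[v] + trend * (yr - y0) / 10.0
            fld = fld + noise[v]
            if config.interannual_sd > 0:
                fld = fld + _smooth_field(
                    np.random.default_rng(np.random.SeedSequence(
                        [config.seed, 211, int(yr), order.index(v)])),
                    (ny, nx), config.interannual_sd,
                )
            if v in MONTHLY_VARS:
                amp = seasonal.get(v, 0.0)
                fld = fld[None, :, :] + amp * cyc[:, None, None]
            per_year.append(fld)
        raw[v] = per_year
    data = {}
    for v in order:
        dims = ("year", "month", "y", "x") if v in MONTHLY_VARS else ("year", "y", "x")
        data[v] = xr.DataArray(np.stack(raw[v]), dims=dims)

    ds = xr.Dataset(
        data,
        coords={"year": years, "month": months, "y": np.arange(ny), "x": np.arange(nx),
                "lat": ("y", lat), "lon": ("x", lon)},
    )
    ds["depth"] = (("y", "x"), depth)
    ds["dist_coast"] = (("y", "x"), dist_coast)
    ds["substrate_mud"] = (("y", "x"), substrate[..., 0])
    ds["substrate_sand"] = (("y", "x"), substrate[..., 1])
    ds["substrate_gravel"] = (("y", "x"), substrate[..., 2])
    ds.attrs.update(cell_km=CELL_KM, scenario=config.scenario_label, seed=config.seed,
                    warming_rate=config.warming_rate)
    return ds


def annual_mean(env: xr.Dataset, var: str, year: int) -> np.ndarray:
    """Annual-mean 2-D field of ``var`` (mean over months where monthly)."""
    da = env[var]
    if "year" in da.dims:
        da = da.sel(year=year)
    if "month" in da.dims:
        da = da.mean("month")
    return da.values


def niche_probability(species: VirtualSpecies, env: xr.Dataset, year: int) -> np.ndarray:
    """Presence probability surface for one species-year: product of
    independent Gaussian responses over its niche predictors, times
    detectability."""
    ny, nx = env.sizes["y"], env.sizes["x"]
    p = np.ones((ny, nx)) * species.detectability
    for var, mu in species.niche_center.items():
        sigma = species.niche_breadth[var]
        x = annual_mean(env, var, year)
        p = p * np.exp(-0.5 * ((x - mu) / sigma) ** 2)
    return p


def generate_survey(
    species: list[VirtualSpecies],
    env: xr.Dataset,
    n_hauls: int,
    seed: int,
    years: list[int] | None = None,
    beam_fraction: float = 0.3,
    max_individuals: int = 4,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a trawl survey over the environmental grids.

    Hauls are placed at seeded uniform cells and years, each with gear otter
    or beam; a species can only be recorded in hauls of its designated gear
    (mirroring how beam-trawl taxa are excluded from otter-trawl data).
    Within a compatible haul, presence is Bernoulli with the species'
    niche-times-detectability probability at that cell-year; present species
    contribute 1..max_individuals length records spanning their size range.

    Returns (hauls, observations):  hauls has haul_id, year, quarter, gear,
    y, x, lat, lon;  observations has haul_id, taxon, length_cm, count.
    """
    if not species:
        raise ValueError("species list must not be empty")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 331]))
    years = list(years) if years is not None else [int(v) for v in env.year.values]
    ny, nx = env.sizes["y"], env.sizes["x"]

    hauls = pd.DataFrame({
        "haul_id": np.arange(n_hauls),
        "year": rng.choice(years, size=n_hauls),
        "quarter": rng.choice([1, 3], size=n_hauls),
        "gear": np.where(rng.random(n_hauls) < beam_fraction, "beam", "otter"),
        "y": rng.integers(0, ny, size=n_hauls),
        "x": rng.integers(0, nx, size=n_hauls),
    })
    hauls["lat"] = env.lat.values[hauls["y"]]
    hauls["lon"] = env.lon.values[hauls["x"]]

    prob = {
        (sp.taxon_id, yr): niche_probability(sp, env, yr) for sp in species for yr in years
    }
    obs_rows = []
    for h in hauls.itertuples():
        for sp in species:
            if sp.gear != h.gear:
                continue
            p = prob[(sp.taxon_id, h.year)][h.y, h.x]
            if rng.random() < p:
                n_ind = int(rng.integers(1, max_individuals + 1))
                lengths = rng.uniform(1.0, sp.max_length, size=n_ind)
                for L in lengths:
                    obs_rows.append((h.haul_id, sp.taxon_id, round(float(L), 1), 1))
    obs = pd.DataFrame(obs_rows, columns=["haul_id", "taxon", "length_cm", "count"])
    return hauls, obs


#: lognormal mean individual mass (g) by prey functional group
PREY_MASS_MEANLOG = {"zooplankton": np.log(0.002), "benthos": np.log(0.5)}
PREY_MASS_SDLOG = 0.4


def generate_stomachs(
    species: list[VirtualSpecies],
    n_per_class: int,
    seed: int,
    lw_params: trophic.LengthMassParams | None = None,
    withheld_predator_mass_frac: float = 0.0,
    withheld_fish_prey_mass_frac: float = 0.0,
    size_classes: tuple[str, ...] = trophic.SIZE_CLASSES,
) -> pd.DataFrame:
    """Simulate stomach-content samples, one row per prey item.

    For each species and size class with a diet profile, ``n_per_class``
    stomachs are drawn: predator length uniform within the size-class length
    interval, prey functional groups multinomial from the diet profile, prey
    item masses lognormal with group-specific means (fish prey mass from the
    typical-prey-length allometry).  ``withheld_*`` fractions blank out
    masses to exercise the downstream imputation path.
    """
    if lw_params is None:
        lw_params = default_length_mass_params(species)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 443]))
    rows = []
    sid = 0
    for sp in species:
        bounds = trophic.size_class_bounds(sp.length_at_maturity, sp.max_length)
        for sc in size_classes:
            if sc not in sp.diet_profile:
                continue
            lo, hi = bounds[sc]
            if hi == np.inf:
                hi = sp.max_length
            lo = max(lo, 0.5)
            if hi <= lo:
                raise ValueError(f"size class {sc!r} degenerate for {sp.taxon_id}")
            groups = list(sp.diet_profile[sc])
            probs = np.array([sp.diet_profile[sc][g] for g in groups])
            for _ in range(n_per_class):
                plen = float(rng.uniform(lo, hi))
                pmass = lw_params.mass(sp.taxon_id, plen)
                if rng.random() < withheld_predator_mass_frac:
                    pmass = np.nan
                n_items = int(rng.integers(1, 5))
                for g in rng.choice(groups, size=n_items, p=probs):
                    if g == "fish":
                        prey_len = trophic.predict_fish_prey_length(plen) * float(
                            np.exp(rng.normal(0, 0.15)))
                        prey_mass = lw_params.mass("prey_fish", prey_len)
                        count = 1
                        if rng.random() < withheld_fish_prey_mass_frac:
                            prey_mass = np.nan
                        prey_taxon = "prey_fish"
                    else:
                        prey_len = np.nan
                        prey_mass = float(np.exp(rng.normal(PREY_MASS_MEANLOG[g], PREY_MASS_SDLOG)))
                        count = int(rng.integers(50, 501)) if g == "zooplankton" \
                            else int(rng.integers(1, 9))
                        prey_taxon = f"prey_{g}"
                    rows.append((sid, sp.taxon_id, sc, round(plen, 2), pmass,
                                 prey_taxon, g, count, prey_mass, prey_len))
                sid += 1
    return pd.DataFrame(rows, columns=[
        "stomach_id", "taxon", "size_class", "predator_length_cm", "predator_mass_g",
        "prey_taxon", "prey_group", "count", "prey_mass_g", "prey_length_cm",
    ])


#: per-item probabilities by guild archetype; item counts differ by orders of
#: magnitude across groups, so these are sharper than the biomass shares
DIET_ARCHETYPES = {
    "planktivore": {"zooplankton": 0.95, "benthos": 0.04, "fish": 0.01},
    "benthivore": {"zooplankton": 0.08, "benthos": 0.90, "fish": 0.02},
    "piscivore": {"zooplankton": 0.05, "benthos": 0.25, "fish": 0.70},
}


def _perturbed_profile(rng: np.random.Generator, archetype: str, conc: float = 120.0) -> dict[str, float]:
    base = DIET_ARCHETYPES[archetype]
    draw = rng.dirichlet(np.array(list(base.values())) * conc)
    return dict(zip(base, (draw / draw.sum()).tolist()))


def make_species_pool(
    n_species: int,
    seed: int,
    temp_range: tuple[float, float] = (9.0, 14.0),
    niche_breadth: float = 1.2,
    beam_taxa: int = 2,
    detectability: tuple[float, float] = (0.6, 0.95),
) -> list[VirtualSpecies]:
    """A seeded pool of virtual species spanning the three diet archetypes.

    Adults follow their archetype's diet; larvae and small juveniles are
    shifted toward zooplankton so species can change guild through ontogeny.
    Pelagic (planktivorous) species take surface-temperature niches, demersal
    species bottom-temperature niches; centres are spread over ``temp_range``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 557]))
    archetypes = ["planktivore", "benthivore", "piscivore"]
    pool = []
    for i in range(n_species):
        arch = archetypes[i % 3]
        pelagic = arch == "planktivore"
        lmax = float(rng.uniform(25, 120))
        lmat = float(rng.uniform(0.2, 0.5)) * lmax  # keeps Lmat <= Lmax/2
        var = "temperature_surface" if pelagic else "temperature_bottom"
        centre = float(rng.uniform(*temp_range))
        diet = {}
        for sc in trophic.SIZE_CLASSES:
            sc_arch = "planktivore" if sc in ("larva", "small_juvenile") else arch
            diet[sc] = _perturbed_profile(rng, sc_arch)
        pool.append(VirtualSpecies(
            taxon_id=f"sp{i:02d}_{arch[:4]}",
            length_at_maturity=round(lmat, 1),
            max_length=round(lmax, 1),
            niche_center={var: centre},
            niche_breadth={var: niche_breadth},
            habitat_domain="pelagic" if pelagic else "demersal",
            diet_profile=diet,
            detectability=float(rng.uniform(*detectability)),
            gear="beam" if i < beam_taxa else "otter",
        ))
    return pool


def life_history_table(species: list[VirtualSpecies]) -> pd.DataFrame:
    return pd.DataFrame({
        "taxon": [s.taxon_id for s in species],
        "length_at_maturity_cm": [s.length_at_maturity for s in species],
        "max_length_cm": [s.max_length for s in species],
        "habitat_domain": [s.habitat_domain for s in species],
        "gear": [s.gear for s in species],
    })


def default_length_mass_params(species: list[VirtualSpecies] | None = None) -> trophic.LengthMassParams:
    """Synthetic length-mass coefficient table (documented defaults a=0.01, b=3)."""
    taxa = [s.taxon_id for s in species] if species else []
    taxa += ["prey_fish"]
    return trophic.LengthMassParams(
        table=pd.DataFrame({"taxon": taxa, "a": 0.01, "b": 3.0})
    )


#: mean individual mass (g) for non-fish prey, by functional group
NONFISH_MASS_LOOKUP = {"zooplankton": 0.002, "benthos": 0.5}


def write_tables(outdir, hauls: pd.DataFrame, obs: pd.DataFrame,
                 stomachs: pd.DataFrame, life_history: pd.DataFrame,
                 env: xr.Dataset | None = None) -> None:
    """Write survey/stomach/life-history tables as TSV (and the environmental
    stack as NetCDF when an engine is available, else per-variable CSV)."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    hauls.to_csv(outdir / "hauls.tsv", sep="\t", index=False)
    obs.to_csv(outdir / "observations.tsv", sep="\t", index=False)
    stomachs.to_csv(outdir / "stomachs.tsv", sep="\t", index=False)
    life_history.to_csv(outdir / "life_history.tsv", sep="\t", index=False)
    if env is not None:
        try:
            env.to_netcdf(outdir / "env.nc")
        except (ValueError, ModuleNotFoundError):
            for v in env.data_vars:
                env[v].to_dataframe().to_csv(outdir / f"env_{v}.csv")
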