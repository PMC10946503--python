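"""Environmental predictor assembly for the habitat models.

From monthly gridded layers this module derives annual means and a
spatio-temporal heterogeneity measure (the SD of the 12 monthly means pooled
over all cells within 75 km), selects surface versus seabed variables by
feeding guild (planktivores are largely pelagic, benthivores/piscivores
largely demersal), and prunes multicollinearity so that no retained pair of
predictors has |Pearson r| > 0.7.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import xarray as xr
from scipy.ndimage import convolve

logger = logging.getLogger(__name__)

DEFAULT_RADIUS_KM = 75.0
COLLINEARITY_THRESHOLD = 0.7

#: variables whose monthly SD is included as a heterogeneity predictor
SD_VARS = ("temperature_surface", "temperature_bottom", "salinity_surface",
           "salinity_bottom", "oxygen_bottom")

STATIC_SET = ["depth", "dist_coast", "substrate_mud", "substrate_sand", "substrate_gravel"]
SURFACE_SET = ["temperature_surface_mean", "temperature_surface_sd75",
               "salinity_surface_mean", "salinity_surface_sd75",
               "chlorophyll_surface_mean", "zooplankton_surface_mean", "stratification"]
BOTTOM_SET = ["temperature_bottom_mean", "temperature_bottom_sd75",
              "salinity_bottom_mean", "salinity_bottom_sd75", "oxygen_bottom_mean",
              "chlorophyll_surface_mean", "zooplankton_surface_mean", "stratification"]


def _disk_kernel(radius_cells: float) -> np.ndarray:
    r = int(np.floor(radius_cells))
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    return (yy**2 + xx**2 <= radius_cells**2).astype(float)


def neighbourhood_sd(monthly: np.ndarray, radius_km: float = DEFAULT_RADIUS_KM,
                     cell_km: float = 10.0) -> np.ndarray:
    """Per-cell SD of monthly means pooled over the surrounding neighbourhood.

    ``monthly`` has shape (12, ny, nx).  For each cell the 12 monthly values
    of every cell whose centre lies within ``radius_km`` are pooled and their
    sample SD (ddof=1) returned.  A radius smaller than one cell degrades to
    the within-cell SD of the 12 months, with a warning.
    """
    monthly = np.asarray(monthly, dtype=float)
    if monthly.ndim != 3:
        raise ValueError("monthly must have shape (n_months, ny, nx)")
    n_months = monthly.shape[0]
    radius_cells = radius_km / cell_km
    if radius_cells < 1.0:
        warnings.warn("radius below one cell; degenerating to within-cell SD", stacklevel=2)
        return monthly.std(axis=0, ddof=1)

    kernel = _disk_kernel(radius_cells)
    ones = np.ones(monthly.shape[1:])
    # edge handling: neighbourhood truncated at the domain boundary
    n_cells = convolve(ones, kernel, mode="constant", cval=0.0)
    s = sum(convolve(monthly[m], kernel, mode="constant", cval=0.0) for m in range(n_months))
    s2 = sum(convolve(monthly[m] ** 2, kernel, mode="constant", cval=0.0) for m in range(n_months))
    n = n_cells * n_months
    var = (s2 - s**2 / n) / (n - 1)
    return np.sqrt(np.clip(var, 0.0, None))


def select_depth_variables(guild: str) -> list[str]:
    """Predictor column names for a feeding guild.

    Planktivores (pelagic) get sea-surface variables; benthivores and
    piscivores (demersal) get seabed variables.  Both sets include the static
    layers (depth, distance to coast, substrate fractions), productivity
    proxies and stratification (bottom minus surface temperature).
    """
    if guild.startswith("planktivore"):
        return SURFACE_SET + STATIC_SET
    if guild.startswith(("benthivore", "piscivore")):
        return BOTTOM_SET + STATIC_SET
    raise ValueError(f"unknown guild label {guild!r}")


def annual_predictor_fields(env: xr.Dataset, radius_km: float = DEFAULT_RADIUS_KM) -> xr.Dataset:
    """Derive the full per-cell-per-year predictor stack from raw layers:
    annual means of every dynamic variable, 75-km monthly SDs for the
    heterogeneity variables, stratification, and the static layers."""
    cell_km = float(env.attrs.get("cell_km", 10.0))
    out = {}
    for v in env.data_vars:
        da = env[v]
        if "month" in da.dims:
            out[f"{v}_mean"] = da.mean("month")
        elif "year" in da.dims:
            out[f"{v}_mean"] = da
        else:
            out[v] = da
    for v in SD_VARS:
        if v not in env:
            continue
        sds = [neighbourhood_sd(env[v].sel(year=yr).values, radius_km, cell_km)
               for yr in env.year.values]
        out[f"{v}_sd75"] = xr.DataArray(np.stack(sds), dims=("year", "y", "x"))
    out["stratification"] = out["temperature_bottom_mean"] - out["temperature_surface_mean"]
    ds = xr.Dataset(out, coords=env.coords)
    ds.attrs.update(env.attrs)
    return ds


def predictor_table(fields: xr.Dataset, cells: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Extract predictor rows for (y, x, year) locations in ``cells``.

    Each haul or cell-year gets the annual predictor values of its grid cell
    and year; static layers are broadcast.
    """
    rows = {}
    yi = cells["y"].to_numpy()
    xi = cells["x"].to_numpy()
    years = cells["year"].to_numpy()
    year_index = {int(y): i for i, y in enumerate(fields.year.values)}
    ti = np.array([year_index[int(y)] for y in years])
    for c in columns:
        da = fields[c]
        if "year" in da.dims:
            rows[c] = da.values[ti, yi, xi]
        else:
            rows[c] = da.values[yi, xi]
    return pd.DataFrame(rows, index=cells.index)


def prune_collinear(
    table: pd.DataFrame,
    threshold: float = COLLINEARITY_THRESHOLD,
    priority: list[str] | None = None,
) -> pd.DataFrame:
    """Drop predictors until no pair has |Pearson r| above ``threshold``.

    Greedy rule: while an offending pair exists, remove the member of the
    worst pair with the larger mean |r| against all remaining columns; ties
    break by lower priority (later in or absent from ``priority``), then by
    dropping the lexicographically later name.
    Constant columns (undefined correlations) are dropped first with a warning.
    """
    cols = [c for c in table.columns]
    const = [c for c in cols if np.nanstd(table[c].to_numpy(dtype=float)) == 0]
    if const:
        warnings.warn(f"dropping constant predictor(s): {const}", stacklevel=2)
        cols = [c for c in cols if c not in const]
    priority = priority or []

    def rank(c: str) -> tuple:
        # higher tuple = preferred for removal
        pr = priority.index(c) if c in priority else -1
        return (pr if pr >= 0 else len(priority), c)

    while len(cols) > 1:
        corr = table[cols].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        if corr.max() <= threshold:
            break
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        mean_r = corr.sum(axis=0) / (len(cols) - 1)
        cand = [cols[i], cols[j]]
        scores = [mean_r[i], mean_r[j]]
        if np.isclose(scores[0], scores[1]):
            drop = max(cand, key=rank)
        else:
            drop = cand[int(np.argmax(scores))]
        logger.info("pruning collinear predictor %s (|r|=%.3f with %s)",
                    drop, corr[i, j], cand[0] if drop == cand[1] else cand[1])
        cols.remove(drop)
    return table[cols]
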