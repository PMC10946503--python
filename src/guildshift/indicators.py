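"""Cell-level diversity and size-structure indicators from thresholded
presence surfaces.

Each validated species-guild model yields a boolean presence grid per
scenario-year (probability >= its threshold).  These are aggregated into
species richness, mean maximum length (MML — the mean of species'
asymptotic maximum lengths over those present, a community size-structure
indicator) and mean PPMR, per feeding guild or community-wide, plus range
descriptors (occupied-cell counts and range centroids; each cell is
100 km^2).  By default a species occurring in a scope through two
size-class guild members counts once ("species" mode); "species_guild"
mode counts modelling units instead.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def presence_surface(prob: np.ndarray, threshold: float) -> np.ndarray:
    """Boolean presence grid: probability >= threshold (inclusive)."""
    if not (0 < threshold < 1):
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    return np.asarray(prob) >= threshold


def _species_of(key) -> str:
    # keys are (species, guild) tuples or plain species labels
    return key[0] if isinstance(key, tuple) else key


def _member_grids(presence: dict, mode: str) -> dict:
    """Collapse species-guild presence grids to the counting unit.

    In 'species' mode grids of the same species are OR-ed; in
    'species_guild' mode each (species, guild) member stays distinct.
    """
    if mode == "species_guild":
        return dict(presence)
    out: dict = {}
    for key, grid in presence.items():
        sp = _species_of(key)
        out[sp] = np.logical_or(out[sp], grid) if sp in out else np.asarray(grid, bool)
    return out


def richness(presence: dict, mode: str = "species") -> np.ndarray:
    """Per-cell count of distinct species (or species-guild units) present."""
    members = _member_grids(presence, mode)
    if not members:
        raise ValueError("no presence grids in scope")
    return np.sum([g.astype(int) for g in members.values()], axis=0)


def mml(presence: dict, lmax: dict[str, float], mode: str = "species") -> np.ndarray:
    """Mean maximum length (cm) over species present per cell; cells where
    nothing is present are NaN-masked.  Species missing from the Lmax table
    are excluded with a warning."""
    return _masked_mean(presence, {k: lmax.get(k) for k in lmax}, mode, "Lmax")


def ppmr_surface(presence: dict, ppmr: dict, mode: str = "species_guild") -> np.ndarray:
    """Mean species(-guild) PPMR over members present per cell; empty cells
    are NaN-masked.  PPMR is native to the species-guild unit, hence the
    default mode."""
    return _masked_mean(presence, ppmr, mode, "PPMR")


def _masked_mean(presence: dict, value: dict, mode: str, what: str) -> np.ndarray:
    members = _member_grids(presence, mode)
    lookup = {}
    for k in members:
        key = _species_of(k) if what == "Lmax" else k
        v = value.get(key, value.get(_species_of(k)))
        if v is None or (isinstance(v, float) and np.isnan(v)):
            logger.warning("%s missing for %s; member excluded", what, k)
            continue
        lookup[k] = float(v)
    if not lookup:
        raise ValueError(f"no members with known {what}")
    some = next(iter(members.values()))
    total = np.zeros(some.shape)
    count = np.zeros(some.shape)
    for k, v in lookup.items():
        g = members[k]
        total += g * v
        count += g
    with np.errstate(invalid="ignore"):
        out = total / count
    out[count == 0] = np.nan
    return out


def range_summary(presence_grid: np.ndarray, lat: np.ndarray, lon: np.ndarray) -> dict:
    """Occupied-cell count and unweighted mean latitude/longitude of the
    occupied cells (each cell is 100 km^2); an empty range has NaN centroid."""
    g = np.asarray(presence_grid, bool)
    n = int(g.sum())
    if n == 0:
        return {"cells_occupied": 0, "area_km2": 0.0,
                "mean_lat": float("nan"), "mean_lon": float("nan")}
    yy, xx = np.nonzero(g)
    return {"cells_occupied": n, "area_km2": n * 100.0,
            "mean_lat": float(np.mean(np.asarray(lat)[yy])),
            "mean_lon": float(np.mean(np.asarray(lon)[xx]))}


def percent_change(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell % change 100*(b-a)/a between two indicator surfaces.

    Cells with a=0 and b>0 are new colonisations: the percentage is
    undefined there, so they are NaN in the % grid and flagged True in the
    companion mask.  Cells with a=b=0 (or NaN inputs) are NaN, unflagged.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("mismatched grids")
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * (b - a) / a
    colonised = (a == 0) & (b > 0)
    pct[a == 0] = np.nan
    return pct, colonised


def indicator_table(surfaces: dict[tuple, np.ndarray], lat: np.ndarray,
                    lon: np.ndarray) -> pd.DataFrame:
    """Tidy long table (cell, year, scenario, scope, indicator, value) from
    a {(indicator, scope, scenario, year): grid} mapping."""
    rows = []
    for (ind, scope, scen, year), grid in surfaces.items():
        ny, nx = grid.shape
        yy, xx = np.mgrid[0:ny, 0:nx]
        rows.append(pd.DataFrame({
            "y": yy.ravel(), "x": xx.ravel(),
            "lat": np.asarray(lat)[yy.ravel()], "lon": np.asarray(lon)[xx.ravel()],
            "indicator": ind, "scope": scope, "scenario": scen, "year": year,
            "value": grid.ravel(),
        }))
    return pd.concat(rows, ignore_index=True)
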