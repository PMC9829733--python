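"""Continuous vagrancy index.

A record's vagrancy is the mean great-circle distance (km) from its capture
location to the k (default 10) nearest of n (default 10,000) points simulated
from that species-week's relative-abundance surface. One point cloud is drawn
per species-week and shared by all records of that species-week; records whose
location falls on a masked (out-of-modeled-range) or off-grid cell are flagged
and excluded from modeling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import AbundanceSurface

EARTH_RADIUS_KM = 6371.0


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray | float:
    """Great-circle distance in km on a sphere of radius 6371 km.

    Accepts scalars or broadcastable arrays of decimal degrees.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    if d.ndim == 0:
        return float(d)
    return d


def week_of_year(dates) -> np.ndarray:
    """Map dates to weeks 1..52 as (day_of_year - 1) // 7 + 1, capped at 52."""
    doy = pd.DatetimeIndex(dates).dayofyear.to_numpy()
    return np.minimum((doy - 1) // 7 + 1, 52)


def sample_abundance_points(
    surface: AbundanceSurface, n: int = 10_000, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Draw ``n`` (lon, lat) points with cell probability ∝ abundance.

    Cells are drawn multinomially over unmasked cells; each point is then
    jittered uniformly within its cell (adequate for cell sizes ≲ 0.25°; at
    the coarser grids used in synthetic worlds this is a stated approximation).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    weights = surface.masked_values().ravel()
    total = weights.sum()
    if total <= 0:
        raise ValueError(
            f"unusable species-week: {surface.species_code} week {surface.week} "
            "has no positive unmasked abundance"
        )
    p = weights / total
    cells = rng.choice(p.size, size=n, p=p)
    ii, jj = np.unravel_index(cells, surface.values.shape)
    half = surface.cell_deg / 2.0
    lons = surface.lons[jj] + rng.uniform(-half, half, size=n)
    lats = surface.lats[ii] + rng.uniform(-half, half, size=n)
    return np.column_stack([lons, lats])


def mean_knn_distance(lon: float, lat: float, points: np.ndarray, k: int = 10) -> float:
    """Mean of the k smallest haversine distances from (lon, lat) to ``points``."""
    points = np.asarray(points, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if points.shape[0] < k:
        raise ValueError(f"need at least k={k} points, got {points.shape[0]}")
    d = haversine_km(lon, lat, points[:, 0], points[:, 1])
    if k == points.shape[0]:
        return float(np.mean(d))
    nearest = np.partition(d, k - 1)[:k]
    return float(np.mean(nearest))


def _locate_cell(surface: AbundanceSurface, lon: float, lat: float) -> tuple[int, int] | None:
    """Index of the cell containing (lon, lat), or None when off-grid."""
    half = surface.cell_deg / 2.0
    if not (surface.lons[0] - half <= lon <= surface.lons[-1] + half):
        return None
    if not (surface.lats[0] - half <= lat <= surface.lats[-1] + half):
        return None
    j = int(np.argmin(np.abs(surface.lons - lon)))
    i = int(np.argmin(np.abs(surface.lats - lat)))
    return i, j


def record_on_modeled_range(surface: AbundanceSurface, lon: float, lat: float) -> bool:
    loc = _locate_cell(surface, lon, lat)
    if loc is None:
        return False
    return bool(surface.mask[loc])


def compute_vagrancy_table(
    records: pd.DataFrame,
    surfaces: dict[tuple[str, int], AbundanceSurface],
    n: int = 10_000,
    k: int = 10,
    seed: int = 0,
    floor_zeros: bool = True,
) -> pd.DataFrame:
    """Attach ``week``, ``vagrancy_km`` and ``excluded_out_of_range`` to records.

    One point cloud is simulated per species-week (deterministic in ``seed``)
    and shared across all of that species-week's records, so within a
    species-week the index depends only on a record's location. Exact zeros
    (a record sitting on ≥ k points) are floored to half the smallest positive
    index of that species so the gamma likelihood downstream is defined.
    """
    out = records.copy().reset_index(drop=True)
    out["week"] = week_of_year(out["date"])
    vagrancy = np.full(len(out), np.nan)
    excluded = np.zeros(len(out), dtype=bool)

    for (species, week), group in out.groupby(["species_code", "week"]):
        key = (str(species), int(week))
        if key not in surfaces:
            raise KeyError(f"no abundance surface for species {species} week {week}")
        surface = surfaces[key]
        # stream keyed on (seed, species, week): independent of record order
        # and of which other species-weeks are present
        cloud_rng = np.random.default_rng([int(seed), int(week)] + list(str(species).encode()))
        points = sample_abundance_points(surface, n=n, seed=cloud_rng)
        for idx in group.index:
            lon, lat = float(out.at[idx, "lon"]), float(out.at[idx, "lat"])
            if not record_on_modeled_range(surface, lon, lat):
                excluded[idx] = True
                continue
            vagrancy[idx] = mean_knn_distance(lon, lat, points, k=k)

    out["vagrancy_km"] = vagrancy
    out["excluded_out_of_range"] = excluded

    if floor_zeros:
        for species, group in out.groupby("species_code"):
            vals = group["vagrancy_km"].to_numpy()
            zeros = (vals == 0) & ~np.isnan(vals)
            if zeros.any():
                positive = vals[(vals > 0) & ~np.isnan(vals)]
                floor = positive.min() / 2.0 if positive.size else 1e-3
                out.loc[group.index[zeros], "vagrancy_km"] = floor
    return out
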