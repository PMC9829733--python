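"""Model covariates: 21-day rolling indices, z-standardization, and
abundance-derived species traits (seasonal centroids, migration length).

The rolling window is trailing and inclusive of the record day (days t-20..t);
this mirrors how a capture on day t integrates conditions over the preceding
three weeks. Standardization uses the population SD and is performed over the
values actually entering the model (record dates), with the transform
parameters retained so effects per SD can be mapped back to raw index units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import AbundanceSurface, DailyIndexSeries
from .vagrancy import haversine_km, sample_abundance_points

ROLLING_WINDOW_DAYS = 21


def rolling_mean_21(series: DailyIndexSeries, window: int = ROLLING_WINDOW_DAYS) -> DailyIndexSeries:
    """Trailing mean over days t-(window-1)..t; first window-1 days undefined (NaN)."""
    if len(series.values) < window:
        raise ValueError(
            f"{series.name}: series of length {len(series.values)} shorter than "
            f"{window}-day window"
        )
    rolled = (
        pd.Series(series.values).rolling(window=window, min_periods=window).mean().to_numpy()
    )
    return DailyIndexSeries(
        name=series.name, dates=series.dates, values=series.values, rolling_mean_21=rolled
    )


def join_covariates(
    records: pd.DataFrame, geomag: DailyIndexSeries, solar: DailyIndexSeries
) -> pd.DataFrame:
    """Exact date join of both 21-day rolling indices onto the record table.

    No interpolation: a record dated where either rolling value is undefined
    (including the first 20 days of a series) is a hard error.
    """
    out = records.copy()
    for series, col in ((geomag, "geomag_21d"), (solar, "solar_21d")):
        if series.rolling_mean_21 is None:
            series = rolling_mean_21(series)
        lookup = pd.Series(series.rolling_mean_21, index=series.dates)
        vals = lookup.reindex(pd.DatetimeIndex(out["date"])).to_numpy()
        if np.isnan(vals).any():
            bad = out.loc[np.isnan(vals), "record_id"].head(5).tolist()
            raise ValueError(
                f"records dated outside the defined {series.name} rolling coverage "
                f"(e.g. record_id {bad})"
            )
        out[col] = vals
    return out


@dataclass
class StandardizedCovariate:
    """z-scored values with the transform parameters retained."""

    raw: np.ndarray
    z: np.ndarray
    mean: float
    sd: float

    def transform(self, values) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.mean) / self.sd

    def inverse(self, z) -> np.ndarray:
        return np.asarray(z, dtype=float) * self.sd + self.mean


def standardize(values) -> StandardizedCovariate:
    """z = (x - mean) / SD with the population-SD convention (ddof=0)."""
    raw = np.asarray(values, dtype=float)
    if np.unique(raw).size < 2:
        raise ValueError("cannot standardize: fewer than 2 distinct values")
    mean = float(raw.mean())
    sd = float(raw.std(ddof=0))
    if sd == 0:
        raise ValueError("cannot standardize: zero variance")
    return StandardizedCovariate(raw=raw, z=(raw - mean) / sd, mean=mean, sd=sd)


def seasonal_centroid(
    surfaces: list[AbundanceSurface], n: int = 10_000, seed: int = 0
) -> tuple[float, float]:
    """Abundance-weighted seasonal centroid (lon, lat).

    Draws ``n`` points per usable week of the season, pools them, and returns
    the arithmetic centroid — adequate for mid-latitude, non-dateline-crossing
    ranges; dateline-spanning inputs are rejected.
    """
    usable = [s for s in surfaces if s.usable]
    if not usable:
        raise ValueError("no usable weeks in season")
    lons = np.concatenate([s.lons for s in usable])
    if lons.max() - lons.min() > 180:
        raise ValueError("dateline-crossing surfaces are not supported")
    points = []
    for idx, surface in enumerate(usable):
        rng = np.random.default_rng([int(seed), int(surface.week), idx])
        points.append(sample_abundance_points(surface, n=n, seed=rng))
    pooled = np.vstack(points)
    return float(pooled[:, 0].mean()), float(pooled[:, 1].mean())


def migration_length_km(breeding_centroid, nonbreeding_centroid) -> float:
    """Haversine distance (km) between the two seasonal centroids."""
    (lon1, lat1), (lon2, lat2) = breeding_centroid, nonbreeding_centroid
    return float(haversine_km(lon1, lat1, lon2, lat2))


def index_correlation(geomag: DailyIndexSeries, solar: DailyIndexSeries) -> tuple[float, float]:
    """Pearson correlation of the two 21-day rolling series (diagnostic)."""
    a = geomag if geomag.rolling_mean_21 is not None else rolling_mean_21(geomag)
    b = solar if solar.rolling_mean_21 is not None else rolling_mean_21(solar)
    joined = pd.DataFrame(
        {"a": pd.Series(a.rolling_mean_21, index=a.dates), "b": pd.Series(b.rolling_mean_21, index=b.dates)}
    ).dropna()
    r, p = stats.pearsonr(joined["a"], joined["b"])
    return float(r), float(p)


def attach_standardized_covariates(
    records: pd.DataFrame,
    traits: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict[str, StandardizedCovariate]]:
    """z-score the rolling indices over record dates, and species traits
    (migration length, breeding latitude) over the species set.

    Returns the augmented table and the fitted transforms, keyed by column.
    """
    out = records.copy()
    transforms: dict[str, StandardizedCovariate] = {}
    for col, zcol in (("geomag_21d", "geomag_z"), ("solar_21d", "solar_z")):
        if col in out.columns:
            sc = standardize(out[col].to_numpy())
            out[zcol] = sc.z
            transforms[col] = sc
    if traits is not None:
        tr = traits.set_index("species_code")
        for col, zcol in (
            ("migration_length_km", "migration_length_z"),
            ("breeding_latitude_deg", "breeding_latitude_z"),
        ):
            sc = standardize(tr[col].to_numpy())
            ztab = pd.Series(sc.z, index=tr.index)
            out[zcol] = out["species_code"].map(ztab).to_numpy()
            transforms[col] = sc
    return out, transforms
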