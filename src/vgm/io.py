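"""Readers and writers for the on-disk artifacts of the vagrancy pipeline.

All tabular files are comma-separated with ISO-8601 dates. Gridded weekly
abundance surfaces are stored as long tables (lon, lat, abundance, mask), one
file per species-week; coordinates are cell centers in decimal degrees.
Phylogenies are newick (parsed with dendropy). Generative ground truth and
world configuration round-trip through JSON.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

RECORD_COLUMNS = [
    "record_id",
    "species_code",
    "date",
    "lon",
    "lat",
    "precision_km",
    "age_class",
    "record_type",
    "banding_code",
]

AGE_CLASSES = {"adult", "young", "unknown"}
RECORD_TYPES = {"banding", "encounter", "recapture"}
DIEL_CLASSES = {"nocturnal", "diurnal", "both", "unknown"}


class SchemaError(ValueError):
    """A file does not match the expected schema."""


class RowValidationError(ValueError):
    """One or more rows violate field invariants; offending rows are listed."""

    def __init__(self, message: str, rows: list[int]):
        super().__init__(message)
        self.rows = rows


@dataclass
class AbundanceSurface:
    """Weekly relative-abundance grid for one species.

    ``values`` is a (n_lat, n_lon) array of nonnegative abundance; ``mask``
    marks cells inside the modeled range. ``lons``/``lats`` are cell centers.
    """

    species_code: str
    week: int
    lons: np.ndarray
    lats: np.ndarray
    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        self.lons = np.asarray(self.lons, dtype=float)
        self.lats = np.asarray(self.lats, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != (self.lats.size, self.lons.size):
            raise ValueError(
                f"surface shape {self.values.shape} does not match grid "
                f"({self.lats.size}, {self.lons.size})"
            )
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape does not match values")
        if (self.values < 0).any():
            raise ValueError("abundance values must be nonnegative")

    @property
    def cell_deg(self) -> float:
        if self.lons.size > 1:
            return float(self.lons[1] - self.lons[0])
        return float(self.lats[1] - self.lats[0])

    @property
    def usable(self) -> bool:
        """True when at least one unmasked cell carries positive abundance."""
        return bool((self.values[self.mask] > 0).any())

    def masked_values(self) -> np.ndarray:
        out = np.where(self.mask, self.values, 0.0)
        return out


@dataclass
class DailyIndexSeries:
    """A contiguous daily scalar series (geomagnetic Ap-like or sunspot-like).

    The 21-day trailing mean (undefined for the first 20 days) is attached
    lazily by :func:`vgm.covariates.rolling_mean_21`.
    """

    name: str
    dates: pd.DatetimeIndex
    values: np.ndarray
    rolling_mean_21: np.ndarray | None = field(default=None)

    def __post_init__(self):
        self.dates = pd.DatetimeIndex(self.dates)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.dates) != len(self.values):
            raise ValueError("dates and values differ in length")
        deltas = np.diff(self.dates.values).astype("timedelta64[D]").astype(int)
        if (deltas <= 0).any():
            raise ValueError(f"{self.name}: dates must be strictly increasing")
        gaps = np.nonzero(deltas != 1)[0]
        if gaps.size:
            first = self.dates[gaps[0]].date()
            raise ValueError(f"{self.name}: gap in daily series after {first}")
        if (self.values < 0).any():
            raise ValueError(f"{self.name}: index values must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"date": self.dates, "value": self.values})


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def read_records(path) -> pd.DataFrame:
    """Read and validate a banding-record table.

    Blank/NA age fields become ``unknown`` (unknown-age records are retained;
    they are common in banding data). Rows violating coordinate, precision,
    or categorical invariants are rejected with their row numbers.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"record_id": str, "species_code": str})
    _require_columns(df, RECORD_COLUMNS, path)
    df = df[RECORD_COLUMNS].copy()
    df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    df["age_class"] = df["age_class"].fillna("unknown").replace({"": "unknown"})
    df["banding_code"] = df["banding_code"].astype(int)

    bad: dict[int, str] = {}

    def flag(mask: pd.Series, reason: str) -> None:
        for idx in df.index[mask]:
            bad.setdefault(int(idx), reason)

    flag(~df["lon"].between(-180, 180) | df["lon"].isna(), "lon out of range")
    flag(~df["lat"].between(-90, 90) | df["lat"].isna(), "lat out of range")
    flag(df["precision_km"] < 0, "negative precision_km")
    flag(~df["age_class"].isin(AGE_CLASSES), "invalid age_class")
    flag(~df["record_type"].isin(RECORD_TYPES), "invalid record_type")
    if bad:
        listing = "; ".join(f"row {i}: {r}" for i, r in sorted(bad.items())[:20])
        raise RowValidationError(
            f"{path}: {len(bad)} invalid rows ({listing})", sorted(bad)
        )
    return df.reset_index(drop=True)


def write_records(records: pd.DataFrame, path) -> None:
    out = records.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_surface(path) -> AbundanceSurface:
    """Read one species-week abundance surface from a long-format CSV."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["species_code", "week", "lon", "lat", "abundance", "mask"], path)
    species = str(df["species_code"].iloc[0])
    week = int(df["week"].iloc[0])
    lons = np.sort(df["lon"].unique())
    lats = np.sort(df["lat"].unique())
    values = np.zeros((lats.size, lons.size))
    mask = np.zeros((lats.size, lons.size), dtype=bool)
    ii = np.searchsorted(lats, df["lat"].to_numpy())
    jj = np.searchsorted(lons, df["lon"].to_numpy())
    values[ii, jj] = df["abundance"].to_numpy()
    mask[ii, jj] = df["mask"].to_numpy().astype(bool)
    return AbundanceSurface(species, week, lons, lats, values, mask)


def write_surface(surface: AbundanceSurface, path) -> None:
    jj, ii = np.meshgrid(np.arange(surface.lons.size), np.arange(surface.lats.size))
    df = pd.DataFrame(
        {
            "species_code": surface.species_code,
            "week": surface.week,
            "lon": surface.lons[jj.ravel()],
            "lat": surface.lats[ii.ravel()],
            "abundance": surface.values.ravel(),
            "mask": surface.mask.ravel().astype(int),
        }
    )
    df.to_csv(path, index=False)


def read_index(path, name: str | None = None) -> DailyIndexSeries:
    """Read a daily index series; any calendar gap is a hard error."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["date", "value"], path)
    dates = pd.DatetimeIndex(pd.to_datetime(df["date"], format="ISO8601"))
    if name is None:
        name = path.stem
    return DailyIndexSeries(name=name, dates=dates, values=df["value"].to_numpy(float))


def write_index(series: DailyIndexSeries, path) -> None:
    df = series.to_frame()
    df["date"] = df["date"].dt.strftime("%Y-%m-%d")
    df.to_csv(path, index=False)


_WINDOW_RE = re.compile(r"^(\d{4}-\d{2}-\d{2})/(\d{4}-\d{2}-\d{2})$")


def _parse_windows(cell) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "":
        return []
    windows = []
    for token in str(cell).split(";"):
        m = _WINDOW_RE.match(token.strip())
        if not m:
            raise SchemaError(f"malformed date window {token!r}; expected YYYY-MM-DD/YYYY-MM-DD")
        start, end = pd.Timestamp(m.group(1)), pd.Timestamp(m.group(2))
        if start > end:
            raise SchemaError(f"window start after end in {token!r}")
        windows.append((start, end))
    return windows


def _format_windows(windows) -> str:
    return ";".join(
        f"{pd.Timestamp(a).strftime('%Y-%m-%d')}/{pd.Timestamp(b).strftime('%Y-%m-%d')}"
        for a, b in windows
    )


TRAIT_COLUMNS = [
    "species_code",
    "migration_length_km",
    "breeding_latitude_deg",
    "wintering_latitude_deg",
    "diel",
    "fall_window",
    "spring_window",
    "exclusion_windows",
]


def read_traits(path) -> pd.DataFrame:
    """Read the species-trait table.

    Seasonal windows are month-day ranges (``MM-DD/MM-DD``) applied to every
    study year; taxonomic exclusion windows are absolute date ranges.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"species_code": str})
    _require_columns(df, TRAIT_COLUMNS, path)
    if not df["diel"].isin(DIEL_CLASSES).all():
        bad = sorted(set(df["diel"]) - DIEL_CLASSES)
        raise SchemaError(f"{path}: invalid diel values {bad}")
    if (df["migration_length_km"] < 0).any():
        raise SchemaError(f"{path}: negative migration_length_km")
    df["exclusion_windows"] = df["exclusion_windows"].map(_parse_windows)
    return df


def write_traits(traits: pd.DataFrame, path) -> None:
    out = traits.copy()
    out["exclusion_windows"] = out["exclusion_windows"].map(
        lambda w: _format_windows(w) if isinstance(w, (list, tuple)) else (w or "")
    )
    out.to_csv(path, index=False)


def read_tree(path) -> dendropy.Tree:
    path = Path(path)
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick")
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"{path}: unparseable newick ({exc})") from exc
    return tree


def write_tree(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def read_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_json(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=float)
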