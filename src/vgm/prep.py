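"""Inclusion filters and density-aware thinning for banding-record tables.

Defaults follow standard banding-data hygiene: only ordinary captures of wild
birds (banding code 3), banding and encounter records (recaptures are
inconsistently reported and dropped), location precision of at most 10 km
(exactly 10 km is retained), capture date inside the species' seasonal
migration window and outside any taxonomic-indeterminacy window, at least 100
records per species per season, and a per-species cap of 20,000 records thinned
inversely to year density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class FilterConfig:
    allowed_banding_codes: frozenset = frozenset({3})
    max_precision_km: float = 10.0
    include_record_types: frozenset = frozenset({"banding", "encounter"})
    season: str = "fall"
    min_records_per_species: int = 100
    thin_cap: int = 20_000
    require_known_age: bool = False

    def __post_init__(self):
        if self.thin_cap <= 0:
            raise ValueError("thin_cap must be positive")
        if self.min_records_per_species <= 0:
            raise ValueError("min_records_per_species must be positive")
        if self.season not in {"fall", "spring"}:
            raise ValueError("season must be 'fall' or 'spring'")


def _in_season_window(dates: pd.Series, window: str) -> np.ndarray:
    """Inclusive month-day window 'MM-DD/MM-DD', applied to every year."""
    start_md, end_md = window.split("/")
    md = dates.dt.strftime("%m-%d")
    if start_md <= end_md:
        return ((md >= start_md) & (md <= end_md)).to_numpy()
    return ((md >= start_md) | (md <= end_md)).to_numpy()  # wraps the year end


def filter_records(
    records: pd.DataFrame, traits: pd.DataFrame, config: FilterConfig
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the inclusion rules; returns survivors and per-rule exclusion counts.

    Rules are evaluated independently on each row; a row excluded by several
    rules is counted once, attributed to the first failing rule in the order
    below, so the counts sum to (input - output).
    """
    missing = set(records["species_code"]) - set(traits["species_code"])
    if missing:
        raise ValueError(f"species missing from trait table: {sorted(missing)}")

    tr = traits.set_index("species_code")
    season_col = f"{config.season}_window"
    dates = pd.to_datetime(records["date"])

    ok_code = records["banding_code"].isin(config.allowed_banding_codes).to_numpy()
    ok_type = records["record_type"].isin(config.include_record_types).to_numpy()
    ok_precision = (records["precision_km"] <= config.max_precision_km).to_numpy()
    ok_age = (
        (records["age_class"] != "unknown").to_numpy()
        if config.require_known_age
        else np.ones(len(records), dtype=bool)
    )

    ok_season = np.zeros(len(records), dtype=bool)
    ok_taxo = np.ones(len(records), dtype=bool)
    for species, group in records.groupby("species_code"):
        gdates = dates.loc[group.index]
        ok_season[group.index] = _in_season_window(gdates, tr.at[species, season_col])
        for start, end in tr.at[species, "exclusion_windows"]:
            inside = ((gdates >= start) & (gdates <= end)).to_numpy()
            ok_taxo[group.index] &= ~inside

    rules = [
        ("banding_code", ok_code),
        ("record_type", ok_type),
        ("precision", ok_precision),
        ("season_window", ok_season),
        ("taxonomic_exclusion", ok_taxo),
        ("unknown_age", ok_age),
    ]
    counts: dict[str, int] = {}
    excluded = np.zeros(len(records), dtype=bool)
    for name, ok in rules:
        newly = ~ok & ~excluded
        counts[name] = int(newly.sum())
        excluded |= newly
    survivors = records.loc[~excluded].reset_index(drop=True)
    counts["total_excluded"] = int(excluded.sum())
    return survivors, counts


def species_season_inclusion(records: pd.DataFrame, config: FilterConfig) -> list[str]:
    """Species with at least ``min_records_per_species`` season records.

    Exactly the threshold count is retained (only strictly fewer are dropped).
    """
    counts = records.groupby("species_code").size()
    kept = counts[counts >= config.min_records_per_species].index.tolist()
    return sorted(kept)


def _capped_inclusion_probs(weights: np.ndarray, cap: int) -> np.ndarray:
    """Inclusion probabilities proportional to ``weights`` summing to ``cap``,
    iteratively clipped at 1 with the excess redistributed (standard pips
    capping)."""
    p = weights * (cap / weights.sum())
    while True:
        over = p >= 1.0
        if not (p > 1.0).any():
            return p
        p[over] = 1.0
        free = cap - over.sum()
        rest = p[~over].sum()
        if rest <= 0:
            return p
        p[~over] *= free / rest


def thin_records(records: pd.DataFrame, cap: int = 20_000, seed: int = 0) -> pd.DataFrame:
    """Cap each species at ``cap`` rows with per-record inclusion probability
    inversely proportional to that species-year's record count.

    A fixed-size probability-proportional-to-size draw (systematic sampling on
    a random permutation) realizes those inclusion probabilities exactly, so
    low-density years keep representation: with two years the expected sampled
    counts per year are equal regardless of how lopsided the raw counts are.
    Under-cap species pass through unchanged; deterministic under fixed seed.
    """
    if cap <= 0:
        raise ValueError("cap must be positive")
    rng = np.random.default_rng(seed)
    years = pd.to_datetime(records["date"]).dt.year
    pieces = []
    for species, group in records.groupby("species_code", sort=True):
        if len(group) <= cap:
            pieces.append(group)
            continue
        year_counts = years.loc[group.index].value_counts()
        weights = 1.0 / years.loc[group.index].map(year_counts).to_numpy(float)
        p = _capped_inclusion_probs(weights, cap)
        perm = rng.permutation(len(group))
        grid = np.cumsum(p[perm]) - rng.uniform()
        crossings = np.floor(grid)
        prev = np.concatenate([[-1.0], crossings[:-1]])
        keep = perm[crossings > prev]
        pieces.append(group.iloc[np.sort(keep)])
    out = pd.concat(pieces, ignore_index=True) if pieces else records.iloc[0:0].copy()
    return out
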