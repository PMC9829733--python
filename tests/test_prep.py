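import pandas as pd
import pytest

from vgm.prep import (
    FilterConfig,
    filter_records,
    species_season_inclusion,
    thin_records,
)


def _traits_for(species, fall="08-13/11-04", exclusion=()):
    return pd.DataFrame(
        {
            "species_code": species,
            "migration_length_km": 1000.0,
            "breeding_latitude_deg": 45.0,
            "wintering_latitude_deg": 30.0,
            "diel": "nocturnal",
            "fall_window": fall,
            "spring_window": "04-02/06-03",
            "exclusion_windows": [list(exclusion) for _ in species],
        }
    )


@pytest.fixture
def clean_records(toy_records):
    rec = toy_records.copy()
    rec["date"] = pd.to_datetime("2001-09-15")
    return rec


class TestFilterRules:
    def test_each_rule_excludes_its_violation(self, clean_records):
        rec = clean_records.copy()
        rec.loc[0, "banding_code"] = 4
        rec.loc[1, "record_type"] = "recapture"
        rec.loc[2, "precision_km"] = 11.0
        rec.loc[3, "date"] = pd.Timestamp("2001-01-05")  # outside fall window
        rec.loc[4, "date"] = pd.Timestamp("2001-09-20")  # inside exclusion window
        traits = _traits_for(
            ["SP000", "SP001"],
            exclusion=[(pd.Timestamp("2001-09-18"), pd.Timestamp("2001-09-25"))],
        )
        # the exclusion window hits rows 0-4 (SP000); row 4 is its clean victim
        out, counts = filter_records(rec, traits, FilterConfig())
        assert counts["banding_code"] == 1
        assert counts["record_type"] == 1
        assert counts["precision"] == 1
        assert counts["season_window"] == 1
        assert counts["taxonomic_exclusion"] == 1
        assert counts["total_excluded"] == 5
        assert set(out["record_id"]) == {"R5", "R6", "R7", "R8", "R9"}

    def test_precision_boundary_exactly_10km_retained(self, clean_records):
        rec = clean_records.copy()
        rec.loc[0, "precision_km"] = 10.0
        out, counts = filter_records(rec, _traits_for(["SP000", "SP001"]), FilterConfig())
        assert "R0" in set(out["record_id"])
        assert counts["precision"] == 0

    def test_species_missing_from_traits_is_hard_error(self, clean_records):
        with pytest.raises(ValueError, match="SP001"):
            filter_records(clean_records, _traits_for(["SP000"]), FilterConfig())

    def test_empty_input(self, clean_records):
        out, counts = filter_records(
            clean_records.iloc[0:0], _traits_for(["SP000"]), FilterConfig()
        )
        assert len(out) == 0
        assert counts["total_excluded"] == 0

    def test_filtering_is_idempotent(self, clean_records):
        rec = clean_records.copy()
        rec.loc[0, "precision_km"] = 99.0
        traits = _traits_for(["SP000", "SP001"])
        once, _ = filter_records(rec, traits, FilterConfig())
        twice, counts = filter_records(once, traits, FilterConfig())
        pd.testing.assert_frame_equal(once, twice)
        assert counts["total_excluded"] == 0

    def test_known_age_switch(self, clean_records):
        rec = clean_records.copy()
        rec.loc[0, "age_class"] = "unknown"
        traits = _traits_for(["SP000", "SP001"])
        cfg = FilterConfig(season="fall", require_known_age=True)
        out, counts = filter_records(rec, traits, cfg)
        assert counts["unknown_age"] == 1
        assert "R0" not in set(out["record_id"])


class TestSpeciesInclusion:
    def _records(self, counts):
        rows = []
        for code, k in counts.items():
            rows += [{"species_code": code}] * k
        return pd.DataFrame(rows)

    def test_threshold_boundary(self):
        rec = self._records({"A": 99, "B": 100, "C": 150})
        kept = species_season_inclusion(rec, FilterConfig(min_records_per_species=100))
        assert kept == ["B", "C"]

    def test_all_below_threshold(self):
        rec = self._records({"A": 5})
        assert species_season_inclusion(rec, FilterConfig()) == []


class TestThinning:
    def _two_year_records(self, n1, n2):
        dates = [f"2001-06-{1 + (i % 28):02d}" for i in range(n1)] + [
            f"2002-06-{1 + (i % 28):02d}" for i in range(n2)
        ]
        return pd.DataFrame(
            {"species_code": "SP000", "date": pd.to_datetime(dates)}
        )

    def test_under_cap_passthrough(self):
        rec = self._two_year_records(300, 200)
        out = thin_records(rec, cap=20_000, seed=0)
        pd.testing.assert_frame_equal(out, rec)

    def test_cap_one_boundary(self):
        rec = self._two_year_records(300, 100)
        out = thin_records(rec, cap=1, seed=0)
        assert len(out) == 1

    def test_deterministic_under_seed(self):
        rec = self._two_year_records(250, 150)
        pd.testing.assert_frame_equal(
            thin_records(rec, cap=200, seed=5), thin_records(rec, cap=200, seed=5)
        )

    def test_every_year_keeps_representation(self):
        dates = []
        for year in range(2001, 2006):
            dates += [f"{year}-06-{1 + (i % 28):02d}" for i in range(20 + 30 * (year - 2001))]
        rec = pd.DataFrame({"species_code": "SP000", "date": pd.to_datetime(dates)})
        for seed in range(20):
            out = thin_records(rec, cap=50, seed=seed)
            assert len(out) == 50
            assert pd.to_datetime(out["date"]).dt.year.nunique() == 5
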