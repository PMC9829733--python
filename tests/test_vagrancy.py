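import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vgm.io import AbundanceSurface
from vgm.vagrancy import (
    compute_vagrancy_table,
    haversine_km,
    mean_knn_distance,
    sample_abundance_points,
    week_of_year,
)


def _single_blob_surface(center=(-90.0, 40.0), width=21, cell=1.0):
    lons = center[0] + cell * (np.arange(width) - width // 2)
    lats = center[1] + cell * (np.arange(width) - width // 2)
    d2 = (lons[None, :] - center[0]) ** 2 + (lats[:, None] - center[1]) ** 2
    values = np.exp(-d2 / 8.0)
    mask = d2 <= 81.0
    values = np.where(mask, values, 0.0)
    return AbundanceSurface("SP000", 35, lons, lats, values / values.sum(), mask)


class TestHaversine:
    def test_identity(self):
        assert haversine_km(-100.0, 40.0, -100.0, 40.0) == 0.0

    def test_one_degree_equator_closed_form(self):
        expected = 6371.0 * np.pi / 180.0  # 111.195 km
        assert haversine_km(0.0, 0.0, 1.0, 0.0) == pytest.approx(expected, abs=1e-9)

    def test_symmetry_over_random_pairs(self):
        rng = np.random.default_rng(0)
        a = rng.uniform([-180, -89], [180, 89], size=(100, 2))
        b = rng.uniform([-180, -89], [180, 89], size=(100, 2))
        d1 = haversine_km(a[:, 0], a[:, 1], b[:, 0], b[:, 1])
        d2 = haversine_km(b[:, 0], b[:, 1], a[:, 0], a[:, 1])
        np.testing.assert_allclose(d1, d2)
        assert (d1 >= 0).all()


class TestAbundanceSampling:
    def test_all_mass_in_one_cell(self):
        surface = _single_blob_surface()
        values = np.zeros_like(surface.values)
        values[10, 10] = 1.0
        point_mass = AbundanceSurface(
            "SP000", 35, surface.lons, surface.lats, values, surface.mask
        )
        pts = sample_abundance_points(point_mass, n=500, seed=1)
        assert (np.abs(pts[:, 0] - surface.lons[10]) <= 0.5).all()
        assert (np.abs(pts[:, 1] - surface.lats[10]) <= 0.5).all()

    def test_three_to_one_cell_ratio(self):
        lons = np.array([-90.0, -89.0])
        lats = np.array([40.0])
        surface = AbundanceSurface(
            "SP000", 35, lons, lats, np.array([[3.0, 1.0]]), np.ones((1, 2), bool)
        )
        pts = sample_abundance_points(surface, n=4000, seed=2)
        in_first = (pts[:, 0] < -89.5).sum()
        assert stats.binomtest(in_first, 4000, 0.75).pvalue > 1e-3

    def test_unusable_surface_raises(self):
        surface = _single_blob_surface()
        dead = AbundanceSurface(
            "SP000", 35, surface.lons, surface.lats,
            np.zeros_like(surface.values), surface.mask,
        )
        with pytest.raises(ValueError, match="unusable"):
            sample_abundance_points(dead, n=10, seed=0)

    def test_deterministic_under_seed(self):
        surface = _single_blob_surface()
        a = sample_abundance_points(surface, n=50, seed=9)
        b = sample_abundance_points(surface, n=50, seed=9)
        np.testing.assert_array_equal(a, b)


class TestMeanKnn:
    def test_coincident_points_give_zero(self):
        pts = np.tile([[-90.0, 40.0]], (12, 1))
        assert mean_knn_distance(-90.0, 40.0, pts, k=10) == 0.0

    def test_k_one_is_nearest_neighbor(self):
        pts = np.array([[-90.0, 40.0], [-80.0, 40.0]])
        d = mean_knn_distance(-89.0, 40.0, pts, k=1)
        assert d == pytest.approx(haversine_km(-89.0, 40.0, -90.0, 40.0))

    def test_fewer_than_k_points_rejected(self):
        with pytest.raises(ValueError, match="k=10"):
            mean_knn_distance(0, 0, np.zeros((5, 2)), k=10)

    def test_matches_full_sort_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            pts = rng.uniform([-100, 30], [-80, 50], size=(40, 2))
            loc = rng.uniform([-100, 30], [-80, 50])
            expected = np.sort(haversine_km(loc[0], loc[1], pts[:, 0], pts[:, 1]))[:10].mean()
            assert mean_knn_distance(loc[0], loc[1], pts, k=10) == pytest.approx(expected)


class TestVagrancyTable:
    def _records_at(self, locations):
        return pd.DataFrame(
            {
                "record_id": [f"R{i}" for i in range(len(locations))],
                "species_code": "SP000",
                "date": pd.to_datetime("2001-09-01"),
                "lon": [p[0] for p in locations],
                "lat": [p[1] for p in locations],
                "precision_km": 0.0,
                "age_class": "adult",
                "record_type": "banding",
                "banding_code": 3,
            }
        )

    def test_monotone_in_displacement(self):
        surface = _single_blob_surface()
        surfaces = {("SP000", int(week_of_year(["2001-09-01"])[0])): surface}
        rec = self._records_at([(-90, 40), (-85, 40), (-82, 40)])
        out = compute_vagrancy_table(rec, surfaces, n=2000, k=10, seed=4)
        v = out["vagrancy_km"].to_numpy()
        assert v[0] < v[1] < v[2]

    def test_masked_record_excluded(self):
        surface = _single_blob_surface()
        surfaces = {("SP000", int(week_of_year(["2001-09-01"])[0])): surface}
        rec = self._records_at([(-90, 40), (-80, 49.9)])  # second is off-mask
        out = compute_vagrancy_table(rec, surfaces, n=500, k=10, seed=4)
        assert not out.loc[0, "excluded_out_of_range"]
        assert out.loc[1, "excluded_out_of_range"]
        assert np.isnan(out.loc[1, "vagrancy_km"])

    def test_deterministic_and_order_insensitive(self):
        surface = _single_blob_surface()
        surfaces = {("SP000", int(week_of_year(["2001-09-01"])[0])): surface}
        rec = self._records_at([(-90, 40), (-85, 42), (-88, 39)])
        out1 = compute_vagrancy_table(rec, surfaces, n=800, k=10, seed=5)
        out2 = compute_vagrancy_table(rec, surfaces, n=800, k=10, seed=5)
        pd.testing.assert_frame_equal(out1, out2)
        shuffled = rec.iloc[[2, 0, 1]].reset_index(drop=True)
        out3 = compute_vagrancy_table(shuffled, surfaces, n=800, k=10, seed=5)
        merged = out1.set_index("record_id")["vagrancy_km"]
        for rid in shuffled["record_id"]:
            assert out3.set_index("record_id").at[rid, "vagrancy_km"] == merged.at[rid]

    def test_missing_surface_is_hard_error(self):
        rec = self._records_at([(-90, 40)])
        with pytest.raises(KeyError, match="SP000"):
            compute_vagrancy_table(rec, {}, n=100, k=10, seed=0)


def test_week_of_year_convention():
    weeks = week_of_year(["2001-01-01", "2001-01-07", "2001-01-08", "2001-12-31"])
    np.testing.assert_array_equal(weeks, [1, 1, 2, 52])
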