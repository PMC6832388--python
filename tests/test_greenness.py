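"""NDVI-binned species statistics, variability coefficients, summary tables."""

import numpy as np
import numpy.ma as ma
import pytest

from greencities.cities import CityTable, city_size, extract_cities, size_spectrum
from greencities.greenness import (
    GLOBAL_VERTEBRATE_TABLE,
    StratumMask,
    bin_stats,
    city_percentage,
    coefficient_of_variability,
    ndvi_percentage,
    size_conditioned_stats,
    table1_summary,
    threatened_indicator,
)
from greencities.grid import GridRaster, TimeRaster, pixel_area_km2
from greencities.synthetic import gen_ndvi_clim, gen_species, make_equatorial_grid

from _oracles import sorted_quantile


def _raster(vals):
    vals = np.atleast_2d(np.asarray(vals, float))
    ny, nx = vals.shape
    return GridRaster(vals, np.linspace(0, ny, ny + 1), np.linspace(0, nx, nx + 1))


class TestThreatenedIndicator:
    def test_no_threats_gives_zero(self):
        assert threatened_indicator(0, 50) == 0.0

    def test_direct_ratio(self):
        assert threatened_indicator(5, 50) == pytest.approx(0.1)

    def test_global_totals_ratio(self):
        # ratio of the summed per-taxon global counts
        total_th = GLOBAL_VERTEBRATE_TABLE["threatened"].sum()
        total_ab = GLOBAL_VERTEBRATE_TABLE["abundance"].sum()
        assert threatened_indicator(total_th, total_ab) == pytest.approx(
            0.02448, abs=5e-5)

    def test_zero_abundance_masked_with_warning(self):
        with pytest.warns(UserWarning, match="zero abundance"):
            out = threatened_indicator(np.array([1.0, 1.0]),
                                       np.array([0.0, 10.0]))
        assert ma.getmaskarray(out).tolist() == [True, False]

    def test_scaling_both_layers_leaves_indicator_unchanged(self, rng):
        th = rng.integers(0, 10, 20).astype(float)
        ab = rng.integers(1, 100, 20).astype(float)
        base = threatened_indicator(th, ab)
        scaled = threatened_indicator(7.3 * th, 7.3 * ab)
        assert np.allclose(np.asarray(base), np.asarray(scaled))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            threatened_indicator(-1, 10)


class TestCoefficientOfVariability:
    def _series(self, stacks):
        layers = [_raster(s) for s in stacks]
        return TimeRaster(np.arange(2000, 2000 + len(stacks)), layers)

    def test_constant_series_has_zero_cv(self):
        cv = coefficient_of_variability(self._series([[[0.4]]] * 4))
        assert float(cv.values[0, 0]) == 0.0

    def test_two_year_population_sd_hand_value(self):
        # {0.2, 0.4}: population SD 0.1, mean 0.3
        cv = coefficient_of_variability(self._series([[[0.2]], [[0.4]]]),
                                        min_years=2)
        assert float(cv.values[0, 0]) == pytest.approx(0.1 / 0.3, rel=1e-12)

    def test_nonpositive_mean_masked(self):
        cv = coefficient_of_variability(self._series([[[-0.1]], [[0.0]],
                                                      [[0.1]]]))
        assert ma.getmaskarray(cv.values)[0, 0]

    def test_too_few_years_masked_with_warning(self):
        series = self._series([[[0.2]], [[0.3]]])
        with pytest.warns(UserWarning, match="fewer than"):
            cv = coefficient_of_variability(series)
        assert ma.getmaskarray(cv.values).all()


class TestBinStats:
    def test_single_pixel_lands_in_correct_bin(self):
        out = bin_stats(_raster([[0.25]]), _raster([[10.0]]), _raster([[1.0]]),
                        np.ones((1, 1), bool))
        row = out[out["n_pixels"] > 0]
        assert row["ndvi_lo"].tolist() == [0.2]
        assert row["abundance"].tolist() == [10.0]

    def test_indicator_is_ratio_of_sums_not_mean_of_ratios(self):
        ndvi = _raster([[0.32, 0.38]])
        out = bin_stats(ndvi, _raster([[10.0, 30.0]]), _raster([[1.0, 5.0]]),
                        np.ones((1, 2), bool))
        got = float(out.loc[out["ndvi_lo"] == 0.3, "indicator"].iloc[0])
        assert got == pytest.approx(6 / 40)   # not (0.1 + 5/30) / 2

    def test_planted_u_shape_argmin_recovered(self):
        lat, lon = make_equatorial_grid(120, 120)
        clim = gen_ndvi_clim(lat, lon, seed=5)
        ab, th, truth = gen_species(clim, seed=6, profile="u_shape",
                                    argmin_bin=0.3)
        out = bin_stats(clim, ab, th, np.ones(clim.shape, bool))
        argmin = out.loc[out["indicator"].idxmin(), "ndvi_lo"]
        assert argmin == pytest.approx(0.3)

    def test_city_plus_noncity_equals_land_sums(self, small_world):
        w = small_world
        strata = StratumMask(city=w["city_mask"], land=w["land_mask"])
        frames = {s: bin_stats(w["ndvi_clim"], w["abundance"], w["threatened"],
                               strata.stratum(s), areas=w["areas"], stratum=s)
                  for s in ("land", "city", "non_city")}
        for col in ("abundance", "threatened", "n_pixels", "area_km2"):
            assert np.allclose(frames["land"][col],
                               frames["city"][col] + frames["non_city"][col])

    def test_empty_bins_retained_with_masked_stats(self):
        out = bin_stats(_raster([[0.25]]), _raster([[10.0]]), _raster([[1.0]]),
                        np.ones((1, 1), bool))
        assert len(out) == 10
        assert out.loc[out["ndvi_lo"] == 0.7, "indicator"].isna().all()


class TestPercentageCurves:
    def test_uniform_region_fills_one_bin(self):
        out = ndvi_percentage(_raster([[0.35, 0.35]]), np.ones((1, 2), bool))
        assert float(out.loc[out["ndvi_lo"] == 0.3, "fraction"].iloc[0]) == 1.0

    def test_two_equal_halves(self):
        out = ndvi_percentage(_raster([[0.15, 0.45]]), np.ones((1, 2), bool))
        by = out.set_index("ndvi_lo")["fraction"]
        assert by[0.1] == pytest.approx(0.5)
        assert by[0.4] == pytest.approx(0.5)

    def test_fractions_plus_out_of_range_close_to_one(self, rng):
        vals = rng.uniform(-0.2, 1.0, (12, 12))
        out = ndvi_percentage(_raster(vals), np.ones((12, 12), bool))
        assert out["fraction"].sum() + out.attrs["out_of_range"] == \
            pytest.approx(1.0, abs=1e-12)

    def test_uniform_field_has_flat_profile(self):
        lat, lon = make_equatorial_grid(150, 150)
        clim = gen_ndvi_clim(lat, lon, seed=11)
        out = ndvi_percentage(clim, np.ones(clim.shape, bool))
        assert np.allclose(out["fraction"], 0.1, atol=0.02)

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ndvi_percentage(_raster([[0.5]]), np.zeros((1, 1), bool))

    def test_city_percentage_single_bin_and_halves(self):
        ndvi = _raster([[0.25, 0.25, 0.55, 0.55]])
        full = city_percentage(ndvi, np.array([[True, True, False, False]]))
        assert float(full.loc[full["ndvi_lo"] == 0.2, "fraction"].iloc[0]) == 1.0
        halves = city_percentage(ndvi, np.ones((1, 4), bool))
        by = halves.set_index("ndvi_lo")["fraction"]
        assert by[0.2] == pytest.approx(0.5) and by[0.5] == pytest.approx(0.5)

    def test_city_percentage_empty_city_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            city_percentage(_raster([[0.5]]), np.zeros((1, 1), bool))


class TestTable1Summary:
    def _fixture(self):
        # 1 x 4 world: two regions of two cells; city = cell 0 and cell 2
        ndvi = _raster([[0.2, 0.4, 0.6, 0.8]])
        areas = GridRaster(np.ones((1, 4)), ndvi.lat_edges, ndvi.lon_edges)
        ab = _raster([[100.0, 300.0, 200.0, 400.0]])
        th = _raster([[10.0, 30.0, 5.0, 15.0]])
        regions = {"west": np.array([[True, True, False, False]]),
                   "east": np.array([[False, False, True, True]])}
        strata = StratumMask(city=np.array([[True, False, True, False]]),
                             land=np.ones((1, 4), bool))
        return regions, {"verts": (ab, th)}, strata, areas

    def test_planted_counts_give_hand_computed_percentages(self):
        regions, taxa, strata, areas = self._fixture()
        out = table1_summary(regions, taxa, strata, areas)
        assert out.loc["west", "land_area_pct_of_global"] == pytest.approx(50.0)
        assert out.loc["west", "abundance_pct_verts"] == pytest.approx(
            100 * 400 / 1000)
        assert out.loc["east", "threatened_pct_verts"] == pytest.approx(
            100 * 20 / 60)
        # west: threatened in city = 10 of 40
        assert out.loc["west", "threatened_in_city_pct_verts"] == \
            pytest.approx(25.0)
        assert out.loc["west", "city_pct"] == pytest.approx(50.0)

    def test_in_and_out_of_city_sum_to_hundred(self):
        regions, taxa, strata, areas = self._fixture()
        out = table1_summary(regions, taxa, strata, areas)
        total = (out["threatened_in_city_pct_verts"]
                 + out["threatened_out_city_pct_verts"])
        assert np.allclose(total, 100.0, atol=1e-9)

    def test_all_species_in_cities_extreme(self):
        ndvi = _raster([[0.3, 0.5]])
        areas = GridRaster(np.ones((1, 2)), ndvi.lat_edges, ndvi.lon_edges)
        taxa = {"verts": (_raster([[50.0, 0.0]]), _raster([[5.0, 0.0]]))}
        strata = StratumMask(city=np.array([[True, False]]),
                             land=np.ones((1, 2), bool))
        out = table1_summary({"all": np.ones((1, 2), bool)}, taxa, strata, areas)
        assert out.loc["all", "threatened_in_city_pct_verts"] == 100.0
        assert out.loc["all", "threatened_out_city_pct_verts"] == 0.0


class TestSizeConditionedStats:
    def _world_with_monotone_indicator(self):
        # horizontal strip cities of growing length; threat fraction
        # decreases with city size
        ny, nx = 12, 40
        dn = np.zeros((ny, nx), int)
        ab = np.full((ny, nx), 100.0)
        th = np.zeros((ny, nx))
        lengths = [1, 2, 4, 8, 16, 32]
        for row, length in zip(range(0, ny, 2), lengths):
            dn[row, :length] = 30
            th[row, :length] = 100.0 * (0.5 / (1 + lengths.index(length)))
        light = GridRaster(dn, np.linspace(-0.06, 0.06, ny + 1),
                           np.linspace(-0.2, 0.2, nx + 1))
        areas = pixel_area_km2(light)
        table = city_size(extract_cities(light, connectivity=4), areas)
        ndvi = GridRaster(np.full((ny, nx), 0.5), light.lat_edges,
                          light.lon_edges)
        return table, areas, ndvi, _replace(light, ab), _replace(light, th)

    def test_monotone_planted_law_recovered(self):
        table, areas, ndvi, ab, th = self._world_with_monotone_indicator()
        spec = size_spectrum(table)
        out = size_conditioned_stats(table, spec, ndvi, ab, th, areas=areas)
        means = out["indicator_mean"].dropna().to_numpy()
        assert np.all(np.diff(means) <= 1e-12)

    def test_single_city_single_bin(self):
        dn = np.zeros((4, 4), int)
        dn[1, 1] = 40
        light = GridRaster(dn, np.linspace(0, 4, 5), np.linspace(0, 4, 5))
        areas = pixel_area_km2(light)
        table = city_size(extract_cities(light), areas)
        spec = size_spectrum(table)
        out = size_conditioned_stats(
            table, spec, _replace(light, np.full((4, 4), 0.3)),
            _replace(light, np.full((4, 4), 10.0)),
            _replace(light, np.ones((4, 4))), areas=areas)
        assert (out["n_cities"] > 0).sum() == 1
        row = out[out["n_cities"] > 0].iloc[0]
        assert row["indicator_mean"] == pytest.approx(0.1)
        assert row["ndvi_mean"] == pytest.approx(0.3)

    def test_quartiles_match_sort_oracle(self, rng):
        # 200 single-pixel cities with known per-city indicator values
        n = 200
        dn = np.zeros((1, 2 * n), int)
        dn[0, ::2] = 30
        light = GridRaster(dn, np.array([0.0, 0.01]),
                           np.linspace(0, 2 * n * 0.01, 2 * n + 1))
        areas = pixel_area_km2(light)
        table = city_size(extract_cities(light, connectivity=4), areas)
        ab = np.zeros((1, 2 * n))
        th = np.zeros((1, 2 * n))
        ab[0, ::2] = 1000.0
        th[0, ::2] = rng.integers(0, 1000, n)
        spec = size_spectrum(table)
        out = size_conditioned_stats(table, spec,
                                     _replace(light, np.full((1, 2 * n), 0.5)),
                                     _replace(light, ab), _replace(light, th),
                                     areas=areas)
        row = out[out["n_cities"] == n].iloc[0]
        vals = th[0, ::2] / 1000.0
        assert row["indicator_q25"] == pytest.approx(sorted_quantile(vals, 0.25))
        assert row["indicator_median"] == pytest.approx(sorted_quantile(vals, 0.5))
        assert row["indicator_q75"] == pytest.approx(sorted_quantile(vals, 0.75))


def _replace(template: GridRaster, values) -> GridRaster:
    return GridRaster(values, template.lat_edges, template.lon_edges)
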