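import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit
from scipy.stats import linregress

from lakebloom.drivers import N_CATEGORIES
from lakebloom.synthetic import (
    BloomModel,
    SimulationConfig,
    generate_lake_geometry,
    generate_met_series,
    generate_nutrient_series,
    generate_scene_series,
)


class TestConfigValidation:
    def test_grid_too_small(self):
        with pytest.raises(ValueError):
            SimulationConfig(grid_size=4)

    def test_single_year_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(year_start=2010, year_end=2010)

    def test_cloud_prob_out_of_range(self):
        with pytest.raises(ValueError):
            SimulationConfig(cloud_prob=1.5)


class TestGeometry:
    def test_all_water_mask_with_fringe(self, small_config):
        g = generate_lake_geometry(small_config, 3)
        assert g.lake_mask.all()
        interior = g.water_presence[2:-2, 2:-2]
        assert np.allclose(interior, 0.95)
        assert (g.water_presence < 0.5).any()

    def test_deterministic_regeneration(self, small_config):
        g1 = generate_lake_geometry(small_config, 2)
        g2 = generate_lake_geometry(small_config, 2)
        assert np.array_equal(g1.water_presence, g2.water_presence)
        assert g1.hemisphere == g2.hemisphere and g1.frozen == g2.frozen

    def test_fringe_count_matches_brute_force(self, small_config):
        g = generate_lake_geometry(small_config, 3)
        # direct enumeration of the width-2 perimeter strip on a 16x16 grid
        count = 0
        for y in range(16):
            for x in range(16):
                if y < 2 or y >= 14 or x < 2 or x >= 14:
                    count += 1
        assert int((g.water_presence < 0.5).sum()) == count
        assert count == 16 * 16 - 12 * 12

    def test_mask_at_least_25_pixels(self, small_config):
        g = generate_lake_geometry(small_config, 0)
        assert g.lake_mask.sum() >= 25

    def test_lake_index_out_of_range(self, small_config):
        with pytest.raises(ValueError):
            generate_lake_geometry(small_config, small_config.n_lakes)

    def test_hemisphere_and_ice_assignment(self):
        cfg = SimulationConfig(n_lakes=8, southern_fraction=0.25,
                               ice_fraction=0.25, seed=5)
        geoms = [generate_lake_geometry(cfg, i) for i in range(8)]
        assert sum(g.hemisphere == "S" for g in geoms) == 2
        assert sum(g.frozen for g in geoms) == 2
        for g in geoms:
            if g.frozen:
                assert g.ice_cover is not None


class TestMetSeries:
    def test_nh_peak_midyear(self, small_config):
        met = generate_met_series(small_config, 3)  # index 3 -> NH
        df = met.assign(doy=pd.to_datetime(met["date"]).dt.dayofyear)
        by_doy = df.groupby("doy")["air_temperature"].mean()
        assert 150 <= by_doy.idxmax() <= 250

    def test_sh_peak_near_new_year(self):
        cfg = SimulationConfig(n_lakes=4, southern_fraction=0.5, seed=2)
        met = generate_met_series(cfg, 0)  # index 0 -> SH
        df = met.assign(doy=pd.to_datetime(met["date"]).dt.dayofyear)
        by_doy = df.groupby("doy")["air_temperature"].mean()
        peak = by_doy.idxmax()
        assert peak <= 60 or peak >= 330

    def test_wind_precip_nonnegative(self, small_config):
        met = generate_met_series(small_config, 1)
        assert (met["wind_speed"] >= 0).all()
        assert (met["precipitation"] >= 0).all()

    def test_warming_trend_recovered(self):
        cfg = SimulationConfig(
            n_lakes=1, year_start=2003, year_end=2022,
            warming_trend_c_per_yr=0.05, seed=21, southern_fraction=0.0,
            ice_fraction=0.0,
        )
        met = generate_met_series(cfg, 0)
        annual = (
            met.assign(year=pd.to_datetime(met["date"]).dt.year)
            .groupby("year")["air_temperature"]
            .mean()
        )
        res = linregress(annual.index.values, annual.values)
        # noise sd 1.5 over 365 days -> annual-mean se ~0.08; slope se follows
        assert abs(res.slope - 0.05) < 2 * res.stderr + 1e-9
        assert res.slope == pytest.approx(0.05, abs=0.03)

    def test_deterministic(self, small_config):
        m1 = generate_met_series(small_config, 0)
        m2 = generate_met_series(small_config, 0)
        pd.testing.assert_frame_equal(m1, m2)


class TestSceneSeries:
    def test_zero_probability_no_blooms(self, small_config):
        cfg = SimulationConfig(
            n_lakes=4, year_start=2003, year_end=2004, seed=11,
            bloom_model=BloomModel(intercept=-1e9, temp_coef=0.0),
        )
        g = generate_lake_geometry(cfg, 3)
        met = generate_met_series(cfg, 3)
        _, truth = generate_scene_series(g, met, cfg, 3)
        assert not truth.true_bloom.any()

    def test_no_clouds_full_validity(self):
        cfg = SimulationConfig(n_lakes=2, year_start=2003, year_end=2004,
                               cloud_prob=0.0, ice_fraction=0.0,
                               southern_fraction=0.0, seed=7)
        g = generate_lake_geometry(cfg, 0)
        met = generate_met_series(cfg, 0)
        stack, _ = generate_scene_series(g, met, cfg, 0)
        assert stack.valid.all()

    def test_binomial_calibration(self):
        # constant p = 0.3 via temp_coef = 0
        p = 0.3
        cfg = SimulationConfig(
            n_lakes=1, year_start=2003, year_end=2005, seed=13,
            ice_fraction=0.0, southern_fraction=0.0,
            bloom_model=BloomModel(intercept=float(logit(p)), temp_coef=0.0),
        )
        g = generate_lake_geometry(cfg, 0)
        met = generate_met_series(cfg, 0)
        stack, truth = generate_scene_series(g, met, cfg, 0)
        n = len(stack)
        assert n >= 1000
        frac = truth.true_bloom.any(axis=(1, 2)).mean()
        se = np.sqrt(p * (1 - p) / n)
        assert abs(frac - p) < 3 * se

    def test_bloom_pixels_inside_lake_and_interior(self, small_config):
        cfg = SimulationConfig(
            n_lakes=1, year_start=2003, year_end=2004, seed=3,
            ice_fraction=0.0, southern_fraction=0.0,
            bloom_model=BloomModel(intercept=0.0, temp_coef=0.0),
        )
        g = generate_lake_geometry(cfg, 0)
        met = generate_met_series(cfg, 0)
        _, truth = generate_scene_series(g, met, cfg, 0)
        interior = g.lake_mask & (g.water_presence >= 0.9)
        assert truth.true_bloom.any()
        assert not (truth.true_bloom & ~interior[None]).any()

    def test_iced_days_invalid(self):
        cfg = SimulationConfig(n_lakes=2, year_start=2003, year_end=2004,
                               southern_fraction=0.0, ice_fraction=1.0,
                               cloud_prob=0.0, seed=9)
        g = generate_lake_geometry(cfg, 0)
        assert g.frozen
        met = generate_met_series(cfg, 0)
        stack, _ = generate_scene_series(g, met, cfg, 0)
        doy = stack.dates.dayofyear
        iced = ~((doy >= cfg.melt_doy) & (doy <= cfg.freeze_doy))
        assert not stack.valid[iced].any()
        assert stack.valid[~iced].all()

    def test_met_too_short_hard_error(self, small_config):
        g = generate_lake_geometry(small_config, 3)
        met = generate_met_series(small_config, 3).iloc[:100]
        with pytest.raises(ValueError):
            generate_scene_series(g, met, small_config, 3)

    def test_reproducible_bytes(self, small_config):
        g = generate_lake_geometry(small_config, 2)
        met = generate_met_series(small_config, 2)
        s1, t1 = generate_scene_series(g, met, small_config, 2)
        s2, t2 = generate_scene_series(g, met, small_config, 2)
        assert np.array_equal(s1.reflectance, s2.reflectance)
        assert np.array_equal(s1.valid, s2.valid)
        assert np.array_equal(t1.true_bloom, t2.true_bloom)

    def test_cloud_censoring_keeps_truth(self):
        cfg = SimulationConfig(
            n_lakes=1, year_start=2003, year_end=2004, cloud_prob=0.5,
            ice_fraction=0.0, southern_fraction=0.0, seed=17,
            bloom_model=BloomModel(intercept=2.0, temp_coef=0.0),
        )
        g = generate_lake_geometry(cfg, 0)
        met = generate_met_series(cfg, 0)
        stack, truth = generate_scene_series(g, met, cfg, 0)
        hidden = truth.true_bloom & ~stack.valid
        assert hidden.any()  # truth retained under cloud ...
        from lakebloom.synthetic import CLOUD_SPECTRUM

        d, y, x = np.argwhere(hidden)[0]
        # ... but the observable spectrum there is cloud, not bloom
        assert np.allclose(stack.reflectance[d, :, y, x], CLOUD_SPECTRUM)

    def test_designed_season_probabilities(self):
        cfg = SimulationConfig(
            n_lakes=1, year_start=2003, year_end=2012, seed=23,
            ice_fraction=0.0, southern_fraction=0.0,
            bloom_model=BloomModel(season=(150, 250), p_in_season=0.9),
        )
        g = generate_lake_geometry(cfg, 0)
        met = generate_met_series(cfg, 0)
        stack, truth = generate_scene_series(g, met, cfg, 0)
        doy = stack.dates.dayofyear.to_numpy()
        bloom_day = truth.true_bloom.any(axis=(1, 2))
        assert not bloom_day[(doy < 150) | (doy > 250)].any()
        in_season = bloom_day[(doy >= 150) & (doy <= 250)]
        assert abs(in_season.mean() - 0.9) < 0.05


class TestNutrients:
    def test_total_is_sum_of_categories(self, small_config, rng):
        nut = generate_nutrient_series(small_config, 1)
        assert np.allclose(
            nut["total_n_input"], nut[list(N_CATEGORIES)].sum(axis=1)
        )

    def test_nonnegative(self, small_config):
        nut = generate_nutrient_series(small_config, 0)
        assert (nut[list(N_CATEGORIES)] >= 0).all().all()
        assert (nut["fertilizer_N"] >= 0).all()
        assert (nut["fertilizer_P"] >= 0).all()

    def test_years_match_config(self, small_config):
        nut = generate_nutrient_series(small_config, 2)
        assert list(nut["year"]) == [2003, 2004]

    def test_deterministic(self, small_config):
        n1 = generate_nutrient_series(small_config, 1)
        n2 = generate_nutrient_series(small_config, 1)
        pd.testing.assert_frame_equal(n1, n2)


class TestCrossLakeIndependence:
    def test_streams_differ_across_lakes(self, small_config):
        m0 = generate_met_series(small_config, 0)
        m1 = generate_met_series(small_config, 1)
        assert not np.allclose(
            m0["air_temperature"].values, m1["air_temperature"].values
        )

    def test_seed_changes_output(self):
        c1 = SimulationConfig(n_lakes=2, year_start=2003, year_end=2004, seed=1)
        c2 = SimulationConfig(n_lakes=2, year_start=2003, year_end=2004, seed=2)
        m1 = generate_met_series(c1, 0)
        m2 = generate_met_series(c2, 0)
        assert not np.allclose(
            m1["air_temperature"].values, m2["air_temperature"].values
        )
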