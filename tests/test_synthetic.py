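"""Synthetic-world generators: determinism, distributional law, bias."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import statsmodels.api as sm

import urbantol as ut
from urbantol.exceptions import ConfigurationError


class TestAlanRaster:
    def test_no_cities_no_noise_gives_zero(self):
        cfg = ut.SyntheticConfig(n_cities=0, noise_sd=0.0, seed=1)
        r = ut.make_alan_raster(cfg)
        assert np.all(r.values == 0.0)

    def test_single_city_peak_at_city_pixel(self):
        cfg = ut.SyntheticConfig(n_cities=1, noise_sd=0.0, seed=3)
        r = ut.make_alan_raster(cfg)
        assert r.values.max() > 0
        # radiance decays monotonically with distance from the brightest pixel
        j, i = np.unravel_index(np.argmax(r.values), r.values.shape)
        assert r.values[j, i] >= r.values.max()

    def test_deterministic_given_seed(self):
        cfg = ut.SyntheticConfig(seed=11)
        a = ut.make_alan_raster(cfg)
        b = ut.make_alan_raster(cfg)
        assert np.array_equal(a.values, b.values)

    def test_noise_keeps_radiance_nonnegative(self):
        cfg = ut.SyntheticConfig(n_cities=0, noise_sd=1.0, seed=5)
        r = ut.make_alan_raster(cfg)
        assert np.all(r.values >= 0)

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            ut.SyntheticConfig(pixel_km=0.0)
        with pytest.raises(ConfigurationError):
            ut.SyntheticConfig(brightness_bias=-1.0)


class TestChecklists:
    def test_unbiased_placement_uniform_over_pixels(self):
        """brightness_bias = 0: checklist counts per pixel pass a two-sided
        chi-square uniformity test at alpha = 0.01."""
        cfg = ut.SyntheticConfig(
            extent_km=(20.0, 20.0), n_checklists=40_000, brightness_bias=0.0, seed=2
        )
        r = ut.make_alan_raster(cfg)
        cl = ut.simulate_checklists(cfg, r)
        ix = np.floor(cl["lon"] / cfg.pixel_km).astype(int)
        iy = np.floor(cl["lat"] / cfg.pixel_km).astype(int)
        counts = np.bincount(iy * 20 + ix, minlength=400)
        chi2 = np.sum((counts - 100.0) ** 2 / 100.0)
        p = stats.chi2.sf(chi2, 399)
        assert 0.005 < p  # not suspiciously clustered
        assert stats.chi2.cdf(chi2, 399) > 0.005  # nor suspiciously even

    def test_bright_bias_concentrates_effort(self):
        cfg = ut.SyntheticConfig(n_checklists=5000, brightness_bias=2.0, seed=4)
        r = ut.make_alan_raster(cfg)
        cl = ut.simulate_checklists(cfg, r)
        x = ut.median_radiance_at_points(
            r, cl["lon"].to_numpy(), cl["lat"].to_numpy(), 2.0
        )
        assert np.nanmean(x) > r.values.mean()

    def test_zero_violation_fractions_all_pass_filter(self):
        cfg = ut.SyntheticConfig(n_checklists=3000, seed=6)
        r = ut.make_alan_raster(cfg)
        cl = ut.simulate_checklists(cfg, r)
        _, rep = ut.filter_checklists(cl)
        assert rep.n_retained == 3000

    def test_violation_fractions_exercise_each_rule(self):
        cfg = ut.SyntheticConfig(
            n_checklists=4000,
            seed=6,
            violations=ut.ViolationFractions(
                incomplete=0.05, protocol=0.05, duration=0.05, distance=0.05, date=0.05
            ),
        )
        r = ut.make_alan_raster(cfg)
        cl = ut.simulate_checklists(cfg, r)
        _, rep = ut.filter_checklists(cl)
        for rule in ("incomplete", "protocol", "duration", "distance", "date_window"):
            assert rep.removed[rule] > 0
        assert rep.n_retained < 4000

    def test_deterministic_given_seed(self):
        cfg = ut.SyntheticConfig(n_checklists=500, seed=8)
        r = ut.make_alan_raster(cfg)
        a = ut.simulate_checklists(cfg, r)
        b = ut.simulate_checklists(cfg, r)
        pd.testing.assert_frame_equal(a, b)

    def test_stationary_checklists_have_zero_distance(self):
        cfg = ut.SyntheticConfig(n_checklists=2000, seed=9)
        r = ut.make_alan_raster(cfg)
        cl = ut.simulate_checklists(cfg, r)
        stationary = cl["protocol"] == "Stationary"
        assert (cl.loc[stationary, "distance_km"] == 0).all()


class TestSpeciesCounts:
    def test_no_effect_means_no_correlation(self):
        cfg = ut.SyntheticConfig(n_checklists=20_000, seed=12)
        r = ut.make_alan_raster(cfg)
        cl = ut.simulate_checklists(cfg, r)
        truth = ut.SpeciesTruth("null", beta0=0.7, beta_alan=0.0)
        ds = ut.simulate_species_counts(cl, r, truth, seed=cfg.seed)
        corr = np.corrcoef(ds["count"], ds["x_alan"])[0, 1]
        assert abs(corr) < 0.05

    def test_nb_moments(self):
        """Constant mu: sample variance matches mu + mu^2/theta within 5%."""
        cfg = ut.SyntheticConfig(
            extent_km=(10.0, 10.0), n_cities=0, noise_sd=0.0,
            n_checklists=100_000, brightness_bias=0.0, seed=13,
        )
        r = ut.make_alan_raster(cfg)
        cl = ut.simulate_checklists(cfg, r)
        mu, theta = 2.0, 2.0
        truth = ut.SpeciesTruth("m", beta0=np.log(mu), beta_alan=0.0, theta=theta)
        ds = ut.simulate_species_counts(cl, r, truth, buffer_radius_km=2.0, seed=cfg.seed)
        assert ds["count"].mean() == pytest.approx(mu, rel=0.02)
        expected_var = mu + mu**2 / theta
        assert ds["count"].var(ddof=1) == pytest.approx(expected_var, rel=0.05)

    def test_glm_recovers_slope_on_raw_data(self, small_world):
        """Independent oracle: statsmodels NB regression of count on the
        radiance covariate alone recovers the generating slope."""
        ds = small_world["dataset"]
        X = sm.add_constant(ds["x_alan"].to_numpy())
        fit = sm.NegativeBinomial(ds["count"].to_numpy(), X).fit(disp=0, maxiter=200)
        assert fit.params[1] == pytest.approx(small_world["truth"].beta_alan, abs=0.05)

    def test_bad_theta_rejected(self):
        with pytest.raises(ValueError):
            ut.SpeciesTruth("x", theta=0.0)

    def test_presence_markers_flag_only_detections(self, small_world):
        ds = ut.mark_presence_only(small_world["dataset"], 0.3, seed=1)
        assert ds.loc[ds["presence_only"], "detection"].all()
        assert 0.15 < ds.loc[ds["detection"], "presence_only"].mean() < 0.45


class TestTraitTable:
    def test_ranges_and_levels(self):
        traits, idx = ut.simulate_trait_table(40, seed=3)
        assert traits["nest_substrate_breadth"].between(1, 6).all()
        assert traits["habitat_breadth"].between(1, 30).all()
        assert traits["body_mass_g"].between(100, 4000).all()
        assert set(traits["feeding_guild"]) == {
            "generalist", "bird specialist", "mammal specialist", "fish specialist"
        }
        assert set(traits["migratory_status"]) == {"local dispersal", "partial migrant"}
        assert len(idx) == 40

    def test_noiseless_table_recovers_effect_exactly(self):
        traits, idx = ut.simulate_trait_table(24, mass_effect=-0.7, noise_sd=0.0, seed=4)
        summary = ut.fit_trait_model(idx, traits)
        est = summary.terms.set_index("term")["estimate"]
        assert est["body_mass_g"] == pytest.approx(-0.7, abs=1e-10)

    def test_minimum_species_count(self):
        with pytest.raises(ValueError):
            ut.simulate_trait_table(5, seed=1)

    def test_deterministic(self):
        a, ia = ut.simulate_trait_table(12, seed=9)
        b, ib = ut.simulate_trait_table(12, seed=9)
        pd.testing.assert_frame_equal(a, b)
        assert np.array_equal(ia.to_numpy(), ib.to_numpy())
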