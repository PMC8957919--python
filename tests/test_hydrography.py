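"""MLD, chlorophyll layer, season, and depth-integration behaviour."""

import numpy as np
import pandas as pd
import pytest

from domseason.hydrography import (
    DepthZone,
    ExtrapolationWarning,
    MLDCriterion,
    classify_seasons,
    compute_mld,
    detect_dcm_dcml,
    integrate_inventory,
    zone_mean,
)

SIGMA_MODE = MLDCriterion(mode="sigma", sigma_increment=0.03)


class TestComputeMLD:
    def test_analytic_linear_gradient_crossing(self):
        # sigma = 25 + 0.001 (z - 10): increment 0.03 crossed at z = 40 m.
        z = np.arange(0.0, 205.0, 5.0)
        sigma = 25.0 + 0.001 * np.clip(z - 10.0, 0, None)
        res = compute_mld(z, sigma=sigma, criterion=SIGMA_MODE)
        assert res.depth == pytest.approx(40.0, abs=0.1)
        assert not res.fully_mixed

    def test_step_profile_locates_the_step(self):
        z = np.arange(0.0, 300.0, 1.0)
        sigma = np.where(z < 150.0, 25.0, 26.0)
        res = compute_mld(
            z, sigma=sigma, criterion=MLDCriterion(mode="sigma", sigma_increment=0.05)
        )
        assert abs(res.depth - 150.0) <= 1.0  # within one sample spacing

    def test_uniform_profile_flagged_fully_mixed(self):
        z = np.arange(0.0, 505.0, 5.0)
        res = compute_mld(z, sigma=np.full_like(z, 26.0), criterion=SIGMA_MODE)
        assert res.fully_mixed and res.depth == z[-1]

    def test_invariant_to_constant_sigma_offset(self):
        z = np.arange(0.0, 205.0, 5.0)
        sigma = 25.0 + 0.002 * np.clip(z - 20.0, 0, None)
        a = compute_mld(z, sigma=sigma, criterion=SIGMA_MODE).depth
        b = compute_mld(z, sigma=sigma + 3.7, criterion=SIGMA_MODE).depth
        assert a == pytest.approx(b, abs=1e-9)

    def test_density_mode_threshold_uses_equation_of_state(self):
        # A temperature drop of exactly delta_T across the base must put the
        # crossing essentially at the base of the uniform layer.
        z = np.arange(0.0, 300.0, 1.0)
        t = np.where(z <= 100.0, 24.0, 24.0 - 3.0 * (1 - np.exp(-(z - 100.0) / 5.0)))
        s = np.full_like(z, 36.0)
        res = compute_mld(z, temperature=t, salinity=s)
        assert 100.0 < res.depth < 103.0

    def test_non_monotone_depths_rejected(self):
        with pytest.raises(ValueError):
            compute_mld(np.array([0.0, 10.0, 5.0]), sigma=np.array([25.0, 25.0, 25.1]))

    def test_profile_must_reach_reference_depth(self):
        with pytest.raises(ValueError):
            compute_mld(np.array([20.0, 30.0]), sigma=np.array([25.0, 25.5]),
                        criterion=SIGMA_MODE)


class TestChlorophyllLayer:
    def test_gaussian_boundaries_match_closed_form(self):
        z = np.arange(0.0, 300.0, 0.5)
        chl = np.exp(-((z - 90.0) ** 2) / (2 * 20.0**2))
        layer = detect_dcm_dcml(z, chl, boundary_fraction=0.35)
        half_width = 20.0 * np.sqrt(2.0 * np.log(1 / 0.35))
        assert layer.dcm_depth == pytest.approx(90.0, abs=0.5)
        assert layer.dcml_top == pytest.approx(90.0 - half_width, abs=0.1)
        assert layer.dcml_bottom == pytest.approx(90.0 + half_width, abs=0.1)

    def test_uniform_profile_clamps_to_ends(self):
        z = np.arange(0.0, 100.0, 10.0)
        layer = detect_dcm_dcml(z, np.full_like(z, 0.5))
        assert layer.dcm_depth == z[0]
        assert layer.clamped_top and layer.clamped_bottom
        assert (layer.dcml_top, layer.dcml_bottom) == (z[0], z[-1])

    def test_all_zero_profile_is_an_error(self):
        z = np.arange(0.0, 100.0, 10.0)
        with pytest.raises(ValueError):
            detect_dcm_dcml(z, np.zeros_like(z))


class TestSeasons:
    def _layers(self, index, dcm=95.0, top=66.0):
        return pd.DataFrame({"dcm_m": dcm, "dcml_top_m": top}, index=index)

    def test_shallow_mld_is_always_stratified(self):
        idx = pd.period_range("2016-07", periods=6, freq="M")
        mld = pd.Series(20.0, index=idx)
        out = classify_seasons(mld, self._layers(idx, dcm=95.0, top=80.0))
        assert (out == "Stratified").all()

    def test_canonical_cycle_order(self, config, dataset):
        from domseason.synthetic import simulate_seasonal_mld

        from itertools import groupby

        mld = simulate_seasonal_mld(config)
        out = classify_seasons(mld, self._layers(mld.index))
        seen = [k for k, _ in groupby(out)]
        assert seen == ["Stratified", "FallTransition", "Mixed",
                        "SpringTransition", "Stratified"]
        # every timestamp labelled exactly once
        assert len(out) == len(mld) and out.notna().all()

    def test_deep_winter_mld_is_mixed(self):
        idx = pd.period_range("2016-11", periods=3, freq="M")
        mld = pd.Series([20.0, 242.0, 242.0], index=idx)
        out = classify_seasons(mld, self._layers(idx, dcm=100.0, top=70.0))
        assert list(out) == ["Stratified", "Mixed", "Mixed"]

    def test_missing_layer_data_carries_label_forward(self):
        idx = pd.period_range("2016-07", periods=4, freq="M")
        mld = pd.Series([20.0, 20.0, 20.0, 20.0], index=idx)
        layers = self._layers(idx)
        layers.loc[idx[2], "dcm_m"] = np.nan
        with pytest.warns(UserWarning, match="carrying season forward"):
            out = classify_seasons(mld, layers)
        assert list(out) == ["Stratified"] * 4


class TestInventories:
    def test_uniform_concentration_times_thickness(self):
        z = np.arange(0.0, 505.0, 5.0)
        c = np.full_like(z, 2.5)
        assert integrate_inventory(z, c, 120.0, 300.0) == pytest.approx(2.5 * 180.0)
        assert integrate_inventory(z, np.zeros_like(z), 120.0, 300.0) == 0.0

    def test_linear_profile_matches_analytic_integral(self):
        z = np.arange(0.0, 505.0, 5.0)
        a, b = 3.0, 0.01
        c = a + b * z
        analytic = a * (300 - 120) + b / 2 * (300**2 - 120**2)
        assert integrate_inventory(z, c, 120.0, 300.0) == pytest.approx(analytic, rel=1e-12)

    def test_additive_over_adjacent_zones(self):
        rng = np.random.default_rng(3)
        z = np.sort(rng.uniform(0, 500, 40))
        z[0], z[-1] = 0.0, 500.0
        c = rng.uniform(1, 5, z.size)
        whole = integrate_inventory(z, c, 13.0, 477.0)
        split = integrate_inventory(z, c, 13.0, 200.0) + integrate_inventory(z, c, 200.0, 477.0)
        assert split == pytest.approx(whole, rel=1e-12)

    def test_extrapolation_beyond_samples_is_flagged(self):
        z = np.array([10.0, 100.0])
        c = np.array([1.0, 1.0])
        with pytest.warns(ExtrapolationWarning):
            inv = integrate_inventory(z, c, 0.0, 150.0)
        assert inv == pytest.approx(150.0)

    def test_zone_outside_samples_is_an_error(self):
        with pytest.raises(ValueError):
            integrate_inventory(np.array([0.0, 100.0]), np.array([1.0, 1.0]), 200.0, 300.0)

    def test_zone_mean_modes(self):
        z = np.arange(0.0, 505.0, 5.0)
        inv_zone = DepthZone("meso", 120.0, 300.0, "inventory")
        disc_zone = DepthZone("meso", 120.0, 300.0, "discrete")
        c_uniform = np.full_like(z, 4.2)
        assert zone_mean(z, c_uniform, inv_zone) == pytest.approx(4.2)
        assert zone_mean(z, c_uniform, disc_zone) == pytest.approx(4.2)
        # linear profile, inventory mode -> value at the zone midpoint
        c_lin = 1.0 + 0.02 * z
        assert zone_mean(z, c_lin, inv_zone) == pytest.approx(1.0 + 0.02 * 210.0)

    def test_discrete_mean_single_sample_and_empty_zone(self):
        z = np.array([0.0, 150.0, 400.0])
        c = np.array([1.0, 7.0, 2.0])
        assert zone_mean(z, c, DepthZone("m", 120.0, 300.0, "discrete")) == 7.0
        with pytest.raises(ValueError):
            zone_mean(z, c, DepthZone("m", 500.0, 600.0, "discrete"))
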