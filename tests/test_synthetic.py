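"""Ground-truth properties of the synthetic water-column generator."""

import numpy as np
import pandas as pd
import pytest

from domseason.hydrography import compute_mld
from domseason.synthetic import (
    EventSpec,
    ResponderSpec,
    SimulationConfig,
    apply_zone_trend,
    homogenize_mixed_layer,
    simulate_community,
    simulate_conservative_tracer,
    simulate_hydrography,
    simulate_seasonal_mld,
    synthetic_reference_table,
)


class TestConfigValidation:
    def test_bad_depth_grid_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(depth_grid=np.array([0.0, 10.0, 5.0]))

    def test_mld_bounds_checked(self):
        with pytest.raises(ValueError):
            SimulationConfig(mld_min=300.0, mld_max=242.0)

    def test_window_must_lie_inside_time_grid(self):
        with pytest.raises(ValueError):
            SimulationConfig(mixing_window=("2019-01", "2019-04"))

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(noise_cv=-0.1)


class TestSeasonalMLD:
    def test_maximum_equals_configured_max_inside_window(self, config):
        mld = simulate_seasonal_mld(config)
        assert mld.max() == config.mld_max
        start, end = config.window_periods
        assert start <= mld.idxmax() <= end

    def test_minimum_in_stratified_months(self, config):
        mld = simulate_seasonal_mld(config)
        start, end = config.window_periods
        outside = mld[(mld.index < start) | (mld.index > end)]
        assert np.allclose(outside, config.mld_min)

    def test_deterministic(self, config):
        a = simulate_seasonal_mld(config)
        b = simulate_seasonal_mld(SimulationConfig(seed=config.seed))
        pd.testing.assert_series_equal(a, b)


class TestHydrography:
    def test_density_stable_and_uniform_above_mld(self, config):
        mld = simulate_seasonal_mld(config)
        ds = simulate_hydrography(mld, config)
        sig = ds["sigma_theta"].values
        assert np.all(np.diff(sig, axis=0) >= -1e-12)
        for j, h in enumerate(mld):
            above = config.depth_grid <= h
            assert np.ptp(sig[above, j]) < 1e-9

    def test_mld_round_trip_within_one_grid_step(self, config):
        mld = simulate_seasonal_mld(config)
        ds = simulate_hydrography(mld, config)
        step = float(np.diff(config.depth_grid).max())
        hits = 0
        for j in range(len(config.times)):
            res = compute_mld(
                config.depth_grid,
                temperature=ds["temperature"].values[:, j],
                salinity=ds["salinity"].values[:, j],
            )
            hits += abs(res.depth - mld.iloc[j]) <= step
        assert hits / len(config.times) >= 0.95

    def test_chlorophyll_maximum_at_dcm_when_stratified(self, config):
        mld = simulate_seasonal_mld(config)
        ds = simulate_hydrography(mld, config)
        j = 0  # first month is stratified
        prof = ds["chlorophyll"].values[:, j]
        assert config.depth_grid[np.argmax(prof)] == pytest.approx(config.dcm_depth, abs=2.5)


class TestConservativeTracer:
    def _cfg(self, **kw):
        base = dict(seed=3, noise_cv=0.0, n_replicates=1)
        base.update(kw)
        return SimulationConfig(**base)

    def test_inventory_conserved_without_events(self, grid_mld):
        cfg = self._cfg()
        z = cfg.depth_grid
        grid = simulate_conservative_tracer(2 + np.exp(-z / 150), grid_mld, [], cfg)
        inv = [np.trapezoid(grid.values[:, j], z) for j in range(len(cfg.times))]
        assert max(abs(i - inv[0]) / inv[0] for i in inv) < 1e-9

    def test_two_layer_entrainment_mean_is_analytic(self):
        # MLD deepening from 100 m (uniform C1) into a C2 layer: the mixed
        # layer concentration is the two-layer volume-weighted mean.
        z = np.arange(0.0, 505.0, 5.0)
        c1, c2, h = 1.0, 2.0, 200.0
        c = np.where(z <= 95.0, c1, np.where(z >= 105.0, c2, (c1 + c2) / 2))
        out = homogenize_mixed_layer(c, z, int(h / 5))
        assert out[0] == pytest.approx((100 * c1 + (h - 100) * c2) / h, rel=1e-12)

    def test_homogenization_conserves_column_and_layer_integrals(self):
        rng = np.random.default_rng(0)
        z = np.arange(0.0, 505.0, 5.0)
        c = rng.uniform(1, 3, z.size)
        k = 30
        out = homogenize_mixed_layer(c, z, k)
        assert np.trapezoid(out, z) == pytest.approx(np.trapezoid(c, z), rel=1e-12)
        assert np.trapezoid(out[: k + 1], z[: k + 1]) == pytest.approx(
            np.trapezoid(c[: k + 1], z[: k + 1]), rel=1e-12
        )
        assert np.ptp(out[: k + 1]) == 0.0

    def test_event_changes_layer_inventory_by_its_magnitude(self, grid_mld):
        cfg = self._cfg()
        z = cfg.depth_grid
        t_event = cfg.window_periods[1]
        ev = EventSpec("tracer", t_event, 60.0)
        with_ev = simulate_conservative_tracer(np.full_like(z, 2.0), grid_mld, [ev], cfg)
        without = simulate_conservative_tracer(np.full_like(z, 2.0), grid_mld, [], cfg)
        j = list(cfg.times).index(t_event)
        h = float(grid_mld.iloc[j])
        sel = z <= h
        gain = np.trapezoid(with_ev.values[sel, j], z[sel]) - np.trapezoid(
            without.values[sel, j], z[sel]
        )
        assert gain == pytest.approx(60.0, rel=1e-9)

    def test_event_deeper_than_mixed_layer_rejected(self, grid_mld):
        cfg = self._cfg()
        ev = EventSpec("tracer", cfg.times[0], 10.0, z_bottom=400.0)
        with pytest.raises(ValueError, match="deeper than the mixed layer"):
            simulate_conservative_tracer(
                np.full_like(cfg.depth_grid, 2.0), grid_mld, [ev], cfg
            )

    def test_replicates_deterministic_given_seed(self, grid_mld):
        cfg = SimulationConfig(seed=9, noise_cv=0.15)
        z = cfg.depth_grid
        a = simulate_conservative_tracer(np.full_like(z, 2.0), grid_mld, [], cfg)
        b = simulate_conservative_tracer(np.full_like(z, 2.0), grid_mld, [], cfg)
        assert np.array_equal(a.replicates, b.replicates)
        assert a.replicates.shape == (cfg.n_replicates, z.size, len(cfg.times))

    def test_zone_trend_applies_only_in_zone_and_window(self, grid_mld):
        cfg = self._cfg()
        z = cfg.depth_grid
        grid = simulate_conservative_tracer(np.full_like(z, 10.0), grid_mld, [], cfg)
        start, end = cfg.window_periods
        trended = apply_zone_trend(grid, (120.0, 300.0), -0.03, (end, cfg.times[-1]))
        j_before = 0
        assert np.array_equal(trended.values[:, j_before], grid.values[:, j_before])
        j_after = len(cfg.times) - 1
        in_zone = (z >= 120.0) & (z < 300.0)
        assert np.all(trended.values[in_zone, j_after] < grid.values[in_zone, j_after])
        assert np.array_equal(
            trended.values[~in_zone, j_after], grid.values[~in_zone, j_after]
        )


class TestCommunity:
    def _doc(self, config):
        ramp = np.r_[np.full(6, 50.0), np.linspace(50, 55, 4), np.linspace(54, 51, 5)]
        return pd.Series(ramp[: len(config.times)], index=config.times)

    def test_sample_proportions_sum_to_one(self, config):
        counts, tax, meta = simulate_community(
            self._doc(config), [ResponderSpec("r1", -2, 0.02)], 5, config
        )
        totals = counts.sum(axis=0)
        assert (totals == totals.iloc[0]).all()  # fixed sequencing depth
        rel = counts / totals
        assert np.allclose(rel.sum(axis=0), 1.0, atol=1e-12)

    def test_planted_lag_recovered_by_ccf(self, config):
        from domseason.community import ccf_lagged, monthly_zone_series, relative_abundance, _asv_long
        from domseason.hydrography import MESOPELAGIC_ZONE

        doc = self._doc(config)
        counts, tax, meta = simulate_community(
            doc, [ResponderSpec("r1", -2, 0.05)], 5, config
        )
        rel = relative_abundance(counts, tax)
        s = monthly_zone_series(_asv_long(rel, meta, "r1"), MESOPELAGIC_ZONE)
        ccf = ccf_lagged(doc, s, max_lag=4)
        assert ccf.best_lag == -2

    def test_deterministic_given_seed(self, config):
        args = (self._doc(config), [ResponderSpec("r1", -1, 0.02)], 4, config)
        c1, _, _ = simulate_community(*args)
        c2, _, _ = simulate_community(*args)
        pd.testing.assert_frame_equal(c1, c2)

    def test_requires_at_least_one_null_taxon(self, config):
        with pytest.raises(ValueError):
            simulate_community(self._doc(config), [], 0, config)

    def test_responder_lag_bounds_enforced(self):
        with pytest.raises(ValueError):
            ResponderSpec("bad", -5, 0.02)
        with pytest.raises(ValueError):
            ResponderSpec("bad", 1, 0.02)


def test_synthetic_reference_table_is_well_formed():
    ref = synthetic_reference_table()
    assert (ref["std_molepct"] > 0).all()
    # fresh material must score higher than degraded material
    from domseason.dom_quality import degradation_index
    from domseason.synthetic import _DEGRADED, _FRESH

    di_fresh = degradation_index(pd.Series(_FRESH), ref)
    di_degraded = degradation_index(pd.Series(_DEGRADED), ref)
    assert di_fresh > 0 > di_degraded
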