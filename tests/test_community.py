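"""ASV filtering, lagged cross-correlation, and responder selection."""

import numpy as np
import pandas as pd
import pytest

from domseason.community import (
    ResponderCriteria,
    ccf_lagged,
    enrichment_filter,
    mixing_anomaly,
    monthly_zone_series,
    relative_abundance,
    select_responders,
)
from domseason.hydrography import MESOPELAGIC_ZONE


def _months(n=15, start="2016-07"):
    return pd.period_range(start, periods=n, freq="M")


class TestRelativeAbundance:
    def _table(self):
        counts = pd.DataFrame(
            {"s1": [10, 30, 60, 5], "s2": [1, 1, 2, 0]},
            index=["a", "b", "c", "chl"],
        )
        taxonomy = pd.Series(
            {
                "a": "Bacteria;P;ClassA;O1",
                "b": "Bacteria;P;ClassB;O2",
                "c": "Bacteria;P;ClassC;O3",
                "chl": "Bacteria;Cyanobacteria;Cyanobacteriia;Chloroplast",
            }
        )
        return counts, taxonomy

    def test_simple_proportions_and_column_sums(self):
        counts, tax = self._table()
        rel = relative_abundance(counts.drop(index="chl"), tax)
        assert np.allclose(rel["s1"], [0.1, 0.3, 0.6])
        assert np.allclose(rel.sum(axis=0), 1.0, atol=1e-12)

    def test_chloroplast_removed_then_renormalized(self):
        counts, tax = self._table()
        rel = relative_abundance(counts, tax)
        assert "chl" not in rel.index
        assert rel["s1"].sum() == pytest.approx(1.0, abs=1e-12)
        assert rel.loc["c", "s1"] == pytest.approx(0.6)

    def test_unclassified_at_class_level_removed(self):
        counts = pd.DataFrame({"s1": [5, 5]}, index=["ok", "nix"])
        tax = pd.Series({"ok": "Bacteria;P;ClassA", "nix": "Bacteria;P"})
        rel = relative_abundance(counts, tax)
        assert list(rel.index) == ["ok"]

    def test_rank_order_preserved_within_sample(self):
        counts, tax = self._table()
        rel = relative_abundance(counts, tax)
        raw = counts.drop(index="chl")["s1"]
        assert (rel["s1"].rank() == raw.rank()).all()


class TestMonthlyZoneSeries:
    def test_identity_for_one_sample_per_month(self):
        months = _months(4)
        df = pd.DataFrame(
            {
                "timestamp": months.to_timestamp() + pd.Timedelta(days=14),
                "depth_m": 150.0,
                "value": [1.0, 2.0, 3.0, 4.0],
            }
        )
        s = monthly_zone_series(df, MESOPELAGIC_ZONE)
        assert np.allclose(s.to_numpy(), [1, 2, 3, 4])

    def test_two_casts_in_one_month_are_averaged(self):
        ts = pd.to_datetime(["2017-04-05", "2017-04-20"])
        df = pd.DataFrame({"timestamp": ts, "depth_m": 150.0, "value": [1.0, 3.0]})
        s = monthly_zone_series(df, MESOPELAGIC_ZONE)
        assert s.loc[pd.Period("2017-04", "M")] == pytest.approx(2.0)

    def test_half_open_zone_boundary(self):
        ts = pd.to_datetime(["2017-04-05", "2017-04-05"])
        df = pd.DataFrame({"timestamp": ts, "depth_m": [119.9, 120.0], "value": [99.0, 1.0]})
        s = monthly_zone_series(df, MESOPELAGIC_ZONE)
        assert s.iloc[0] == pytest.approx(1.0)  # 119.9 m sits above the zone

    def test_gap_months_are_absent_not_zero(self):
        ts = pd.to_datetime(["2017-01-15", "2017-03-15"])
        df = pd.DataFrame({"timestamp": ts, "depth_m": 150.0, "value": [1.0, 2.0]})
        s = monthly_zone_series(df, MESOPELAGIC_ZONE)
        assert pd.Period("2017-02", "M") not in s.index


class TestEnrichmentFilter:
    def _criteria(self):
        return ResponderCriteria()

    def _meso(self, peak_month, months=None):
        months = months if months is not None else _months()
        vals = np.full(len(months), 0.01)
        vals[list(months).index(pd.Period(peak_month, "M"))] = 0.05
        return pd.DataFrame([vals], index=["x"], columns=months)

    def test_in_window_peak_with_ml_increase_passes(self):
        out = enrichment_filter(
            self._meso("2017-05"), pd.Series({"x": 0.02}), pd.Series({"x": 0.01}),
            self._criteria(),
        )
        assert out["x"]

    def test_out_of_window_peak_fails(self):
        out = enrichment_filter(
            self._meso("2016-09"), pd.Series({"x": 0.02}), pd.Series({"x": 0.01}),
            self._criteria(),
        )
        assert not out["x"]

    def test_equal_mixed_layer_means_fail_strict_comparison(self):
        out = enrichment_filter(
            self._meso("2017-05"), pd.Series({"x": 0.02}), pd.Series({"x": 0.02}),
            self._criteria(),
        )
        assert not out["x"]

    def test_missing_reference_data_is_unevaluable(self):
        out = enrichment_filter(
            self._meso("2017-05"), pd.Series({"x": np.nan}), pd.Series({"x": 0.01}),
            self._criteria(),
        )
        assert not out["x"]

    def test_invariant_to_scaling_one_samples_counts(self):
        # Relative abundance is compositional: multiplying one sample's
        # counts by a constant leaves the filter inputs unchanged.
        counts = pd.DataFrame(
            {"s1": [10, 90], "s2": [20, 80]}, index=["a", "b"]
        )
        tax = pd.Series({"a": "B;P;C1", "b": "B;P;C2"})
        rel1 = relative_abundance(counts, tax)
        scaled = counts.copy()
        scaled["s1"] *= 7
        rel2 = relative_abundance(scaled, tax)
        assert np.allclose(rel1, rel2)


class TestCCF:
    def _driver(self, n=15):
        rng = np.random.default_rng(0)
        return pd.Series(rng.normal(size=n).cumsum(), index=_months(n))

    def test_identity_peaks_at_lag_zero(self):
        x = self._driver()
        ccf = ccf_lagged(x, x, max_lag=4)
        assert ccf.best_lag == 0 and ccf.best_r == pytest.approx(1.0)

    @pytest.mark.parametrize("k", [0, 1, 2, 3, 4])
    def test_exact_shift_recovered_at_negative_lag(self, k):
        x = self._driver(20)
        y = x.copy()
        y.index = y.index + k  # y(t) = x(t - k)
        ccf = ccf_lagged(x, y, max_lag=4)
        assert ccf.best_lag == -k
        assert ccf.best_r == pytest.approx(1.0)

    def test_constant_series_rejected(self):
        x = self._driver()
        with pytest.raises(ValueError):
            ccf_lagged(x, pd.Series(1.0, index=x.index), max_lag=4)

    def test_insufficient_overlap_rejected(self):
        x = self._driver(5)
        with pytest.raises(ValueError):
            ccf_lagged(x, x, max_lag=4)

    def test_significance_bound_shrinks_with_overlap(self):
        x = self._driver(24)
        ccf = ccf_lagged(x, x, max_lag=4)
        assert ccf.bounds[4] < ccf.bounds[0]  # lag 0 uses more pairs than lag -4


class TestSelectResponders:
    def test_synthetic_community_recovered_exactly(self, dataset):
        counts, taxonomy, metadata = dataset["community"]
        res = select_responders(
            counts, taxonomy, metadata, dataset["doc_meso_series"], None,
            dataset["mld"], ResponderCriteria(),
        )
        want = sorted(r.asv_id for r in dataset["responders"])
        assert sorted(res["asv_id"]) == want
        assert not res["taxonomy"].str.contains("Cyanobacteria").any()
        by_asv = res.set_index("asv_id")
        for r in dataset["responders"]:
            assert by_asv.loc[r.asv_id, "best_lag"] == r.lag_months
            assert by_asv.loc[r.asv_id, "r"] > 0

    def test_positive_lag_only_responder_excluded(self, dataset):
        # An ASV tracking the driver's *future* passes enrichment screens
        # but must not be selected (the driver does not lead it).
        counts, taxonomy, metadata = dataset["community"]
        doc = dataset["doc_meso_series"]
        delayed = doc.copy()
        delayed.index = delayed.index + 4  # delayed(t) = doc(t - 4)
        # Planted lag -1/-2 responders now only correlate with this driver
        # at positive lags (they lead it), so nothing may be selected.
        res = select_responders(
            counts, taxonomy, metadata, delayed, None,
            dataset["mld"], ResponderCriteria(),
        )
        assert res.empty

    def test_either_driver_suffices(self, dataset):
        # Responders correlated with the TDAA-C series alone must still be
        # selected when DOC is replaced by uninformative noise.
        counts, taxonomy, metadata = dataset["community"]
        rng = np.random.default_rng(0)
        noise = pd.Series(rng.normal(50, 0.01, len(dataset["mld"])), index=dataset["mld"].index)
        res = select_responders(
            counts, taxonomy, metadata, noise, dataset["doc_meso_series"],
            dataset["mld"], ResponderCriteria(),
        )
        assert sorted(res["asv_id"]) == sorted(r.asv_id for r in dataset["responders"])
        assert (res["driver"] == "TDAA-C").all()


class TestMixingAnomaly:
    def test_constant_series_has_zero_anomaly(self):
        s = pd.Series(0.5, index=_months())
        anomaly, sd, enriched = mixing_anomaly(s, ("2017-04", "2017-07"))
        assert anomaly == 0.0 and not enriched

    def test_window_shift_algebra(self):
        months = _months()
        s = pd.Series(1.0, index=months, dtype=float)
        win = (pd.Period("2017-04", "M"), pd.Period("2017-07", "M"))
        in_win = (months >= win[0]) & (months <= win[1])
        delta = 0.3
        s[in_win] += delta
        w, n = int(in_win.sum()), len(months)
        anomaly, _, _ = mixing_anomaly(s, win)
        assert anomaly == pytest.approx(delta * (1 - w / n), rel=1e-12)

    def test_empty_window_is_an_error(self):
        s = pd.Series(1.0, index=_months())
        with pytest.raises(ValueError):
            mixing_anomaly(s, ("2020-01", "2020-03"))

    def test_planted_responders_exceed_band_null_taxa_do_not(self, dataset):
        from domseason.community import _asv_long, relative_abundance, monthly_zone_series

        counts, taxonomy, metadata = dataset["community"]
        rel = relative_abundance(counts, taxonomy)
        win = ("2017-04", "2017-07")
        for r in dataset["responders"]:
            s = monthly_zone_series(_asv_long(rel, metadata, r.asv_id), MESOPELAGIC_ZONE)
            _, _, enriched = mixing_anomaly(s, win)
            assert enriched
        s = monthly_zone_series(_asv_long(rel, metadata, "ASV_null_000"), MESOPELAGIC_ZONE)
        _, _, enriched = mixing_anomaly(s, win)
        assert not enriched
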