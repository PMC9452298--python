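"""Day/night splits, Savitzky-Golay smoothing, diel cycles, proxies."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.signal import savgol_coeffs

import chiraflux as cf
from chiraflux.diel import DielCycle, _moving_median


def _hourly(values, start="2019-09-09"):
    t = pd.date_range(start, periods=len(values), freq="h")
    return pd.Series(np.asarray(values, dtype=float), index=t)


class TestSplitDayNight:
    def test_all_dark_is_all_night(self):
        s = _hourly(np.arange(10.0))
        day, night = cf.split_day_night(s, np.zeros(10))
        assert len(day) == 0 and len(night) == 10

    def test_threshold_boundary_counts_as_night(self):
        s = _hourly([1.0, 2.0])
        day, night = cf.split_day_night(s, np.array([0.1, 0.2]))
        assert len(day) == 1 and len(night) == 1
        assert night.iloc[0] == 1.0  # PAR exactly 0.1 is night

    def test_partition_with_missing_par(self):
        s = _hourly(np.arange(6.0))
        par = np.array([0.0, 5.0, np.nan, 3.0, 0.05, np.nan])
        day, night = cf.split_day_night(s, par)
        assert len(day) + len(night) == 4  # 2 excluded

    def test_day_fraction_matches_photoperiod(self, predrought_forcing):
        f = predrought_forcing
        day, night = cf.split_day_night(f["par"], f["par"].to_numpy())
        frac = len(day) / (len(day) + len(night))
        photoperiod = 12.0 / 24.0
        assert abs(frac - photoperiod) < 1.0 / 24.0


class TestSmoothTrend:
    def test_low_order_polynomial_reproduced_exactly(self):
        x = np.arange(200.0)
        y = 1.0 + 0.5 * x - 0.01 * x ** 2 + 1e-4 * x ** 3
        out = cf.smooth_trend(y, window=25, polyorder=3)
        assert np.allclose(out, y, rtol=1e-8, atol=1e-6)

    def test_constant_series_unchanged(self):
        out = cf.smooth_trend(np.full(100, 7.0), window=11, polyorder=2)
        assert np.allclose(out, 7.0)

    @given(st.floats(-5, 5), st.floats(-5, 5))
    def test_filter_is_linear(self, a, b):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=80), rng.normal(size=80)
        lhs = cf.smooth_trend(a * x + b * y, window=11, polyorder=3)
        rhs = (a * np.asarray(cf.smooth_trend(x, window=11, polyorder=3))
               + b * np.asarray(cf.smooth_trend(y, window=11, polyorder=3)))
        assert np.allclose(lhs, rhs, atol=1e-9)

    def test_white_noise_variance_scales_with_weight_norm(self):
        rng = np.random.default_rng(1)
        n, window, order = 40000, 25, 3
        y = rng.normal(0.0, 1.0, n)
        out = cf.smooth_trend(y, window=window, polyorder=order)
        w = savgol_coeffs(window, order)
        interior = out[window:-window]
        assert np.var(interior) == pytest.approx(np.sum(w ** 2), rel=0.05)

    def test_uncertainty_propagates_through_squared_weights(self):
        sigma = np.full(100, 2.0)
        _, sig_out = cf.smooth_trend(np.zeros(100), sigma, window=25,
                                     polyorder=3)
        w = savgol_coeffs(25, 3)
        want = 2.0 * np.sqrt(np.sum(w ** 2))
        assert sig_out[50] == pytest.approx(want, rel=1e-9)
        assert np.all(sig_out > 0)

    def test_window_validation(self):
        with pytest.raises(ValueError):
            cf.smooth_trend(np.zeros(10), window=11, polyorder=3)
        with pytest.raises(ValueError):
            cf.smooth_trend(np.zeros(100), window=4, polyorder=3)


class TestDielCycle:
    def test_constant_series_normalizes_to_one(self):
        s = _hourly(np.full(96, 5.0))
        cycles = cf.diel_cycle(s, np.full(96, "PD", dtype=object))
        assert np.allclose(cycles["PD"].normalized, 1.0)

    def test_moving_median_suppresses_isolated_spike(self):
        base = np.full(24, 1.0)
        base[10] = 50.0
        smoothed = _moving_median(base, 5)
        assert smoothed[10] == pytest.approx(1.0)

    def test_normalization_max_is_exactly_one(self, default_campaign):
        v = default_campaign.vmr["(-)-a-pinene"]
        stages = cf.stage_of_doy(v["doy"])
        cycles = cf.diel_cycle(v["vmr"], stages)
        top = max(np.nanmax(c.normalized) for c in cycles.values())
        assert top == 1.0

    def test_predrought_group2_peaks_late_morning(self, default_campaign):
        v = default_campaign.vmr["(-)-a-pinene"]
        cycles = cf.diel_cycle(v["vmr"], cf.stage_of_doy(v["doy"]))
        hour, _ = cf.peak_hour(cycles["PD"])
        assert hour in (11, 12)

    def test_drought_shifts_group2_peak_later(self, default_campaign):
        v = default_campaign.vmr["(-)-a-pinene"]
        cycles = cf.diel_cycle(v["vmr"], cf.stage_of_doy(v["doy"]))
        pd_hour, _ = cf.peak_hour(cycles["PD"])
        sd_hour, _ = cf.peak_hour(cycles["SD"])
        assert sd_hour > pd_hour

    def test_empty_stage_flagged(self):
        s = _hourly(np.ones(24))
        labels = np.full(24, "PD", dtype=object)
        cycles = cf.diel_cycle(s, labels)
        assert "PD" in cycles and "SD" not in cycles


class TestPeakHour:
    def _cycle(self, values):
        v = np.asarray(values, dtype=float)
        return DielCycle("x", "PD", v, v, np.ones(24), np.zeros(24), v)

    def test_unique_maximum(self):
        v = np.zeros(24)
        v[14] = 2.0
        hour, flags = cf.peak_hour(self._cycle(v))
        assert hour == 14 and not flags

    def test_tie_breaks_to_earliest_and_flags(self):
        v = np.zeros(24)
        v[11] = v[12] = 1.0
        hour, flags = cf.peak_hour(self._cycle(v))
        assert hour == 11
        assert any("tie" in f for f in flags)

    def test_all_equal_flagged_degenerate(self):
        hour, flags = cf.peak_hour(self._cycle(np.ones(24)))
        assert any("degenerate" in f for f in flags)


class TestDroughtProxies:
    def _equal_vmr(self):
        idx = pd.date_range("2019-09-09", periods=48, freq="h")
        return {c: pd.Series(10.0, index=idx) for c in cf.config.MONOTERPENES}

    def test_equal_constants(self):
        vmr = self._equal_vmr()
        stages = np.full(48, "PD", dtype=object)
        out = cf.drought_proxies(vmr, stages)
        assert out.loc["PD", "plus_a_over_minus_b"] == pytest.approx(1.0)
        assert out.loc["PD", "beta_pinene_fraction"] == pytest.approx(1 / 8)

    def test_symmetric_diel_cycle_has_unit_afternoon_morning_ratio(self):
        idx = pd.date_range("2019-09-09", periods=96, freq="h")
        hour = idx.hour.to_numpy()
        sym = np.cos(2 * np.pi * (hour - 12.0) / 24.0) + 2.0
        vmr = {c: pd.Series(sym, index=idx) for c in cf.config.MONOTERPENES}
        out = cf.drought_proxies(vmr, np.full(96, "PD", dtype=object))
        # window centres 9.5 and 14.5 mirror around noon
        assert out.loc["PD", "afternoon_morning_ratio"] == pytest.approx(
            1.0, rel=1e-6)

    def test_beta_pinene_fraction_triples_under_drought(self, default_campaign):
        vmr = {name: df["vmr"] for name, df in default_campaign.vmr.items()
               if name != "isoprene"}
        stages = cf.stage_of_doy(default_campaign.vmr["(-)-a-pinene"]["doy"])
        out = cf.drought_proxies(vmr, stages)
        ratio = (out.loc["SD", "beta_pinene_fraction"]
                 / out.loc["PD", "beta_pinene_fraction"])
        assert 2.0 < ratio < 4.5

    def test_missing_compound_rejected(self):
        vmr = self._equal_vmr()
        del vmr["(-)-b-pinene"]
        with pytest.raises(ValueError, match="b-pinene"):
            cf.drought_proxies(vmr, np.full(48, "PD", dtype=object))


class TestCorrelationMatrix:
    def test_self_correlation_is_one(self, default_campaign):
        vmr = {name: df["vmr"] for name, df in default_campaign.vmr.items()
               if name != "isoprene"}
        doy = default_campaign.vmr["(-)-a-pinene"]["doy"]
        stages = cf.stage_of_doy(doy)
        par = default_campaign.forcing["par"].reindex(
            default_campaign.vmr["(-)-a-pinene"].index).to_numpy()
        corr = cf.correlation_matrix(vmr, stages, "PD", par, day=True)
        assert np.allclose(np.diag(corr), 1.0)

    def test_predrought_enantiomer_correlation_structure(
            self, default_campaign):
        """(-)-a-pinene tracks its biosynthetic sibling (-)-b-pinene more
        closely than its mirror image (+)-a-pinene in pre-drought daytime."""
        vmr = {name: df["vmr"] for name, df in default_campaign.vmr.items()
               if name != "isoprene"}
        doy = default_campaign.vmr["(-)-a-pinene"]["doy"]
        stages = cf.stage_of_doy(doy)
        par = default_campaign.forcing["par"].reindex(
            default_campaign.vmr["(-)-a-pinene"].index).to_numpy()
        corr = cf.correlation_matrix(vmr, stages, "PD", par, day=True)
        assert (corr.loc["(-)-a-pinene", "(-)-b-pinene"]
                > corr.loc["(-)-a-pinene", "(+)-a-pinene"])

    def test_anticorrelated_pair_negative(self):
        idx = pd.date_range("2019-09-09", periods=30, freq="h")
        x = np.linspace(0, 1, 30)
        vmr = {"a": pd.Series(x, index=idx), "b": pd.Series(-x, index=idx)}
        corr = cf.correlation_matrix(
            vmr, np.full(30, "PD", dtype=object), "PD", np.full(30, 500.0))
        assert corr.loc["a", "b"] < 0

    def test_insufficient_overlap_is_nan(self):
        idx = pd.date_range("2019-09-09", periods=4, freq="h")
        vmr = {"a": pd.Series([1.0, np.nan, np.nan, 2.0], index=idx),
               "b": pd.Series([1.0, 1.0, 1.0, 2.0], index=idx)}
        corr = cf.correlation_matrix(
            vmr, np.full(4, "PD", dtype=object), "PD", np.full(4, 500.0))
        assert np.isnan(corr.loc["a", "b"])
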