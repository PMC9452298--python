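"""Two-reservoir emission model: forward dynamics, fitting, G93 baseline."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import chiraflux as cf
from chiraflux.config import G93Params, GroupParams, R_GAS
from chiraflux.reservoir import hourly_diel, simulate_group


def _flat_forcing(n=200, temp=30.0, dt_h=0.25):
    return np.full(n, temp), dt_h


class TestForwardDynamics:
    def test_phi_zero_has_no_storage_emission(self, predrought_model):
        m = predrought_model
        gp = GroupParams(epsilon=5.0, phi=0.0)
        sim = simulate_group(gp, m.dt_h, m.temp, m.assimilation / 20.0, m.vpd)
        assert np.allclose(sim["E_store"], 0.0)
        assert np.allclose(sim["E_total"], sim["P"])

    def test_constant_forcing_steady_state_fixed_point(self):
        temp, dt = _flat_forcing(n=4000)
        gp = GroupParams(epsilon=2.0, light_activated=False, phi=0.4,
                         k0=0.1, beta=0.09)
        sim = simulate_group(gp, dt, temp, None, None, s0=0.0)
        k = gp.k0 * np.exp(gp.beta * (temp[0] - 30.0))
        assert sim["S"][-1] == pytest.approx(gp.phi * gp.epsilon / k, rel=1e-6)
        assert sim["E_store"][-1] == pytest.approx(gp.phi * gp.epsilon,
                                                   rel=1e-6)

    def test_predrought_peak_separation(self, predrought_model):
        """De novo group peaks by noon; storage group peaks mid-afternoon."""
        sim = predrought_model.simulate()
        g2 = int(np.argmax(hourly_diel(sim["E_total_2"], sim.index)))
        g3 = int(np.argmax(hourly_diel(sim["E_store_3"], sim.index)))
        assert g2 <= 12
        assert g3 >= 14

    def test_mass_conservation_every_group(self, predrought_model):
        sim = predrought_model.simulate()
        dt = predrought_model.dt_h
        for g in (1, 2, 3):
            p = sim[f"P_{g}"].to_numpy()
            e = (sim[f"E_dn_{g}"] + sim[f"E_store_{g}"]).to_numpy()
            s = sim[f"S_{g}"].to_numpy()
            synth = np.trapezoid(p, dx=dt)
            emitted = np.trapezoid(e, dx=dt) + (s[-1] - s[0])
            if synth > 0:
                assert emitted == pytest.approx(synth, rel=1e-3)

    def test_peak_lag_increases_for_slower_pools(self, predrought_model):
        """Slower pools release later in the day.  The shift is monotone
        while the pool timescale is comparable to the diel cycle; for very
        slow pools it saturates at the temperature-response peak."""
        m = predrought_model
        peaks = []
        for k0 in (5.0, 1.0, 0.3, 0.1):
            gp = GroupParams(epsilon=1.0, phi=1.0, k0=k0, light_activated=True)
            sim = simulate_group(gp, m.dt_h, m.temp, m.assimilation / 20.0,
                                 m.vpd)
            peaks.append(int(np.argmax(hourly_diel(sim["E_store"], m.time))))
        assert peaks == sorted(peaks)
        assert peaks[0] < peaks[-1]

    def test_phi_to_zero_converges_to_pure_light_model(self, predrought_model):
        m = predrought_model
        pure = simulate_group(GroupParams(epsilon=1.0, phi=0.0), m.dt_h,
                              m.temp, m.assimilation / 20.0, m.vpd)
        near = simulate_group(GroupParams(epsilon=1.0, phi=1e-4), m.dt_h,
                              m.temp, m.assimilation / 20.0, m.vpd)
        assert np.allclose(near["E_total"], pure["E_total"], rtol=5e-4,
                           atol=1e-4 * pure["E_total"].max())

    def test_negative_forcing_rejected(self, predrought_forcing):
        bad = predrought_forcing.copy()
        bad.loc[bad.index[3], "par"] = -1.0
        with pytest.raises(ValueError, match="PAR"):
            cf.ReservoirModel(bad[["par", "temp", "rh"]])


class TestFit:
    TRUE = GroupParams(epsilon=10.0, light_activated=True, phi=0.3,
                       k0=0.08, beta=0.09)

    def _observed(self, model, noise=0.0, seed=42):
        sim = simulate_group(self.TRUE, model.dt_h, model.temp,
                             model.assimilation / 20.0, model.vpd)
        obs = sim["E_total"]
        if noise:
            rng = np.random.default_rng(seed)
            obs = obs * rng.lognormal(0.0, noise, size=obs.shape)
        return obs

    def test_noise_free_parameter_recovery_within_1pct(self, predrought_model):
        res = predrought_model.fit(self._observed(predrought_model),
                                   light_activated=True, seed=0)
        for name, want in (("epsilon", 10.0), ("phi", 0.3),
                           ("k0", 0.08), ("beta", 0.09)):
            assert res.params[name] == pytest.approx(want, rel=0.01)

    def test_phi_fixed_zero_flags_unidentifiable_pool(self, predrought_model):
        gp = GroupParams(epsilon=3.0, phi=0.0)
        m = predrought_model
        obs = simulate_group(gp, m.dt_h, m.temp, m.assimilation / 20.0,
                             m.vpd)["E_total"]
        res = m.fit(obs, light_activated=True, fix_phi=0.0, seed=0)
        assert any("unidentifiable" in f for f in res.flags)
        assert res.params["epsilon"] == pytest.approx(3.0, rel=0.01)

    def test_flat_observations_flagged_degenerate(self, predrought_model):
        obs = np.full(len(predrought_model.time), 2.5)
        res = predrought_model.fit(obs, light_activated=False)
        assert any("degenerate" in f for f in res.flags)

    def test_noisy_fit_recovers_peak_hour_within_one_hour(
            self, predrought_model):
        m = predrought_model
        true_sim = simulate_group(self.TRUE, m.dt_h, m.temp,
                                  m.assimilation / 20.0, m.vpd)
        true_peak = int(np.argmax(hourly_diel(true_sim["E_total"], m.time)))
        obs = self._observed(m, noise=0.05, seed=7)
        res = m.fit(obs, light_activated=True, seed=0)
        assert abs(res.peak_hour() - true_peak) <= 1

    def test_summary_mentions_parameters(self, predrought_model):
        res = predrought_model.fit(self._observed(predrought_model), seed=0)
        text = res.summary()
        for name in ("epsilon", "phi", "k0", "beta"):
            assert name in text


class TestG93:
    def test_dark_emission_is_zero(self):
        assert cf.g93_emission(0.0, 30.0) == 0.0

    def test_direct_formula_oracle_at_standard_temperature(self):
        p = G93Params()
        t_k = p.t_s  # 303 K -> exponent 0 in C_T numerator
        par = 1000.0
        c_l = p.alpha * p.c_l1 * par / np.sqrt(1 + p.alpha ** 2 * par ** 2)
        c_t = 1.0 / (1.0 + np.exp(p.c_t2 * (t_k - p.t_m)
                                  / (R_GAS * p.t_s * t_k)))
        want = p.basal * c_l * c_t
        assert cf.g93_emission(par, t_k - 273.15, p) == pytest.approx(
            want, rel=1e-12)

    @given(st.floats(0.0, 2000.0), st.floats(1.0, 500.0))
    def test_light_response_monotone(self, par, dpar):
        lo = cf.g93_emission(par, 30.0)
        hi = cf.g93_emission(par + dpar, 30.0)
        assert hi > lo

    def test_negative_par_rejected(self):
        with pytest.raises(ValueError):
            cf.g93_emission(-1.0, 30.0)


class TestCompareToBaseline:
    def test_identical_series(self):
        t = pd.date_range("2019-09-09", periods=96, freq="15min")
        obs = np.sin(np.linspace(0, 4 * np.pi, 96)) + 2.0
        out = cf.compare_to_baseline(obs, obs, t)
        assert out.loc["all", "ratio"] == pytest.approx(1.0)
        assert out.loc["all", "peak_offset_h"] == 0.0

    def test_shifted_observation_reports_offset(self):
        t = pd.date_range("2019-09-09", periods=24 * 4 * 3, freq="15min")
        hour = t.hour + t.minute / 60.0
        pred = np.exp(-0.5 * ((hour - 12.0) / 2.0) ** 2)
        obs = np.exp(-0.5 * ((hour - 14.0) / 2.0) ** 2)
        out = cf.compare_to_baseline(obs, pred, t)
        assert out.loc["all", "peak_offset_h"] == 2.0

    def test_drought_emissions_exceed_light_temp_baseline(
            self, default_campaign):
        """Severe-drought storage-dominated emissions exceed a pooled
        light x temperature prediction calibrated on pre-drought data."""
        camp = default_campaign
        f = camp.forcing
        obs = camp.truth["emissions"]["(-)-a-pinene"]["E_total"]
        activity = cf.g93_emission(f["par"].to_numpy(), f["temp"].to_numpy())
        stages = f["stage"].to_numpy()
        pd_mask = stages == "PD"
        basal = obs[pd_mask].mean() / activity[pd_mask].mean()
        out = cf.compare_to_baseline(obs, basal * activity, f.index, stages)
        assert out.loc["PD", "ratio"] == pytest.approx(1.0, rel=0.15)
        assert out.loc["SD", "ratio"] > 1.0

    def test_zero_prediction_flagged(self):
        t = pd.date_range("2019-09-09", periods=8, freq="h")
        with pytest.warns(UserWarning, match="undefined"):
            out = cf.compare_to_baseline(np.ones(8), np.zeros(8), t)
        assert bool(out.loc["all", "flag_undefined_ratio"])
        assert np.isnan(out.loc["all", "ratio"])
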