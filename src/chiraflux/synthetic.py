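"""Synthetic mesocosm campaign generator.

Produces self-consistent observables for an enclosed, continually flushed
rainforest drought experiment — environmental forcing, SF6 tracer decay,
inside/outside CO2, per-enantiomer monoterpene and isoprene mixing ratios
and discrete 13C isotope samples — together with the ground truth needed
to test every downstream analysis stage (true exchange rate, true
emissions, true NEE/assimilation, true emission source class).

Physics emulated
----------------
* diel forcing: PAR a clipped sinusoid peaking at noon; temperature a
  sinusoid peaking mid-afternoon; RH anti-correlated with temperature with
  two depressed minima during the drought; topsoil moisture declining
  35% -> 15% and recovering after rewetting;
* chamber mass balance per trace gas, dC/dt = E/V - ER (C - C_out) - v_d C,
  integrated with explicit Euler at 1-min substeps;
* emissions from the three-enzyme-group / two-reservoir model, with de novo
  synthesis scaled by realised assimilation and storage release scaled by
  VPD, plus per-compound stage stress multipliers (the drought-modulation
  magnitudes that observations do not pin down; see docs/methods.md);
* CO2 drawn down by Michaelis-type assimilation (light- and CO2-limited)
  against constant ecosystem respiration; gas bookkeeping at a fixed
  reference temperature (no thermal-expansion fluxes);
* 13CO2 pulses that transiently enrich the isotope ratio of de novo
  emissions in proportion to their instantaneous de novo fraction, while
  storage-pool compounds keep ambient ratios.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .budget import vpd as vpd_formula
from .config import (
    CompoundSpec,
    ConfigurationError,
    R_GAS,
    ScenarioConfig,
    interp_points,
    stage_of_doy,
)
from .reservoir import simulate_group

_YEAR0 = pd.Timestamp("2019-01-01")


def time_grid(config: ScenarioConfig) -> tuple[pd.DatetimeIndex, np.ndarray]:
    """15-min (or configured) grid covering doy_start..doy_end inclusive."""
    steps_per_day = 24 * 60 // config.dt_minutes
    n = (config.doy_end - config.doy_start + 1) * steps_per_day
    doy = config.doy_start + np.arange(n) * (config.dt_minutes / (24 * 60.0))
    time = _YEAR0 + pd.to_timedelta((doy - 1) * 24.0, unit="h")
    return pd.DatetimeIndex(time.round("s")), doy


def _hour_of_day(doy: np.ndarray) -> np.ndarray:
    return (doy % 1.0) * 24.0


def gen_forcing(config: ScenarioConfig) -> pd.DataFrame:
    """Deterministic environmental forcing with stage labels.

    Columns: doy, par, temp, rh, pressure, soil_moisture, vpd, stage.
    """
    time, doy = time_grid(config)
    hour = _hour_of_day(doy)

    half = config.photoperiod_h / 2.0
    phase = (hour - config.par_peak_hour + 12.0) % 24.0 - 12.0
    par = config.par_max * np.cos(np.pi * phase / (2.0 * half))
    par[np.abs(phase) >= half] = 0.0
    par = np.clip(par, 0.0, None)

    t_mid = 0.5 * (config.temp_max + config.temp_min)
    t_amp = 0.5 * (config.temp_max - config.temp_min)
    temp = t_mid + t_amp * np.cos(2.0 * np.pi * (hour - config.temp_peak_hour) / 24.0)

    rh = (config.rh_base - config.rh_temp_slope * (temp - t_mid)
          - interp_points(doy, config.rh_depression_points))
    rh = np.clip(rh, 5.0, 100.0)

    sm = interp_points(doy, config.soil_moisture_points)
    df = pd.DataFrame(
        {
            "doy": doy,
            "par": par,
            "temp": temp,
            "rh": rh,
            "pressure": config.pressure,
            "soil_moisture": sm,
            "vpd": vpd_formula(temp, rh),
            "stage": stage_of_doy(doy, config.stage_bounds),
        },
        index=time,
    )
    df.index.name = "time"
    return df


def gen_tracer(config: ScenarioConfig, er_pct_h: np.ndarray,
               rng: np.random.Generator | None = None) -> pd.DataFrame:
    """SF6 series: exponential decay between injections.

    ``er_pct_h`` is the true exchange-rate series (%/h) on the forcing
    grid.  After each injection the concentration above background decays
    as exp(-integral ER dt); multiplicative lognormal noise of scale
    ``config.sf6_noise`` is applied above background (noise-free when 0).
    """
    time, doy = time_grid(config)
    er = np.asarray(er_pct_h, dtype=float)
    if er.shape != doy.shape:
        raise ValueError("exchange-rate series not aligned with grid")
    if np.any(er < 0):
        raise ValueError("exchange rate must be positive")
    dt_h = config.dt_minutes / 60.0
    bg = config.sf6_background_ppt
    peak_above = config.sf6_injection_peak_ppt - bg
    inj_doy = np.asarray(
        [d + config.sf6_injection_hour / 24.0 for d in config.sf6_injection_doys])
    inj_doy = inj_doy[(inj_doy >= doy[0]) & (inj_doy <= doy[-1])]
    inj_idx = np.searchsorted(doy, inj_doy)

    above = np.zeros_like(doy)
    flags = np.zeros(doy.shape, dtype=bool)
    flags[inj_idx] = True
    decay = np.exp(-0.5 * (er[:-1] + er[1:]) / 100.0 * dt_h)
    level = 0.0
    for i in range(doy.size):
        if i > 0:
            level *= decay[i - 1]
        if flags[i]:
            level = peak_above
        above[i] = level
    if config.sf6_noise > 0:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        sigma = config.sf6_noise
        above = above * rng.lognormal(-0.5 * sigma ** 2, sigma, size=above.shape)
    df = pd.DataFrame({"doy": doy, "sf6": bg + above, "injection": flags},
                      index=time)
    df.index.name = "time"
    return df


def enrichment_factor(config: ScenarioConfig) -> float:
    """Injection peak concentration over tracer background (dimensionless)."""
    return config.sf6_injection_peak_ppt / config.sf6_background_ppt


# --------------------------------------------------------------------------
def _euler_chamber(emis_ppt_h: np.ndarray, loss_h: np.ndarray, dt_h_grid: float,
                   substeps: int, c0: float) -> np.ndarray:
    """Explicit-Euler chamber balance dC/dt = E - loss*C at fine substeps.

    ``emis_ppt_h`` and ``loss_h`` live on the coarse grid and are linearly
    interpolated to substeps; returns C on the coarse grid.
    """
    n = emis_ppt_h.shape[0]
    h = dt_h_grid / substeps
    c = np.empty_like(emis_ppt_h)
    c[0] = c0
    cur = np.asarray(c0, dtype=float)
    for i in range(n - 1):
        for s in range(substeps):
            w = s / substeps
            e = emis_ppt_h[i] * (1 - w) + emis_ppt_h[i + 1] * w
            lam = loss_h[i] * (1 - w) + loss_h[i + 1] * w
            cur = cur + h * (e - lam * cur)
        c[i + 1] = cur
    return c


@dataclass
class Campaign:
    """All synthetic observables plus the ground-truth record."""

    config: ScenarioConfig
    forcing: pd.DataFrame
    tracer: pd.DataFrame
    vmr: dict[str, pd.DataFrame]
    co2: pd.DataFrame
    isotope_samples: pd.DataFrame
    truth: dict = field(default_factory=dict)


def _stage_mult(doy: np.ndarray, spec: CompoundSpec,
                config: ScenarioConfig) -> np.ndarray:
    """Per-compound synthesis stress multiplier, blended across stages."""
    pts = []
    bounds = config.stage_bounds
    order = [s for s in ("PD", "ED", "SD", "DRW", "RRW") if s in bounds]
    for st in order:
        lo, hi = bounds[st]
        m = spec.boost(st)
        pts.append(((lo + hi) / 2.0, m))
    pts = [(bounds[order[0]][0], spec.boost(order[0]))] + pts
    pts.append((bounds[order[-1]][1] + 1, spec.boost(order[-1])))
    return interp_points(doy, pts)


def gen_campaign(config: ScenarioConfig) -> Campaign:
    """Generate the full synthetic campaign (see module docstring)."""
    rng = np.random.default_rng(config.seed)
    streams = {name: np.random.default_rng(s) for name, s in zip(
        ("sf6", "co2", "vmr", "ratio"), rng.integers(0, 2 ** 31 - 1, size=4))}

    forcing = gen_forcing(config)
    time, doy = forcing.index, forcing["doy"].to_numpy()
    dt_h = config.dt_minutes / 60.0
    er = config.er_pct_h(doy)  # %/h on the grid
    er_h = er / 100.0

    # ----- CO2 and realised assimilation (1-min explicit Euler) -----------
    n_air = (config.volume_m3 * config.pressure
             / (R_GAS * (273.15 + config.t_ref_gas)))  # mol air, fixed T ref
    conv = config.area_m2 * 60.0 / n_air  # umol m-2 s-1 -> ppm min-1
    stomatal = 1.0 / (1.0 + config.vpd_stomatal_gamma * np.clip(
        forcing["vpd"].to_numpy() - config.vpd_stomatal_ref, 0.0, None))
    a_cap = (config.a_max
             * forcing["par"].to_numpy() / (forcing["par"].to_numpy() + config.k_par)
             * interp_points(doy, config.a_drought_points)
             * stomatal)
    substeps = config.dt_minutes  # 1-min substeps
    n = doy.size
    co2 = np.empty(n)
    a_real = np.empty(n)
    a_step = np.full(n, np.nan)  # mean over the step ending at each grid point
    c = config.co2_outside_ppm + config.r_eco * conv * 60.0 / max(er_h[0] * 60.0, 1e-9)
    c = min(c, 600.0)
    for i in range(n):
        a_real[i] = a_cap[i] * c / (c + config.k_co2)
        co2[i] = c
        if i == n - 1:
            break
        acc = 0.0
        for s in range(substeps):
            w = s / substeps
            cap = a_cap[i] * (1 - w) + a_cap[i + 1] * w
            lam = (er_h[i] * (1 - w) + er_h[i + 1] * w) / 60.0  # per minute
            a_now = cap * c / (c + config.k_co2)
            acc += a_now
            c = c + (config.r_eco - a_now) * conv + lam * (
                config.co2_outside_ppm - c)
        a_step[i + 1] = acc / substeps
    nee_true = a_real - config.r_eco  # uptake-positive, umol m-2 s-1
    nee_true_step = a_step - config.r_eco  # step-averaged counterpart

    co2_obs = co2.copy()
    co2_out_obs = np.full(n, config.co2_outside_ppm)
    if config.co2_noise_ppm > 0:
        co2_obs = co2_obs + streams["co2"].normal(0, config.co2_noise_ppm, n)
        co2_out_obs = co2_out_obs + streams["co2"].normal(
            0, config.co2_noise_ppm, n)
    co2_df = pd.DataFrame({"doy": doy, "co2_inside": co2_obs,
                           "co2_outside": co2_out_obs}, index=time)
    co2_df.index.name = "time"

    # ----- emissions per compound (two-reservoir model) --------------------
    res = config.reservoir
    a_norm = a_real / res.a_ref
    temp = forcing["temp"].to_numpy()
    vpd = forcing["vpd"].to_numpy()
    sm = forcing["soil_moisture"].to_numpy()
    phi2 = interp_points(doy, config.phi2_drought_points)
    emissions: dict[str, dict[str, np.ndarray]] = {}
    for spec in config.compounds:
        gp = res.groups[spec.group]
        gp = type(gp)(epsilon=spec.epsilon, light_activated=gp.light_activated,
                      phi=gp.phi, k0=gp.k0, beta=gp.beta,
                      gamma_vpd=gp.gamma_vpd, vpd_ref=gp.vpd_ref)
        emissions[spec.name] = simulate_group(
            gp, dt_h, temp, a_norm, vpd, _stage_mult(doy, spec, config),
            t_ref=res.t_ref,
            phi_override=phi2 if spec.group == 2 else None)

    # ----- chamber balance per compound, hourly instrument averages --------
    vmr_true_15: dict[str, np.ndarray] = {}
    vmr_hourly: dict[str, pd.DataFrame] = {}
    steps_per_hour = max(60 // config.dt_minutes, 1)
    for spec in config.compounds:
        e = emissions[spec.name]["E_total"]  # ppt h-1 (chamber-normalised)
        v_d = (config.isoprene_soil_uptake_h
               * np.clip((sm - 15.0) / 20.0, 0.0, 1.0)
               if spec.name == "isoprene"
               else np.full(n, config.soil_uptake_h))
        loss = er_h + v_d
        c0 = e[0] / max(loss[0], 1e-12)
        conc = _euler_chamber(e, loss, dt_h, config.dt_minutes, c0)
        vmr_true_15[spec.name] = conc
        m = (n // steps_per_hour) * steps_per_hour
        hourly = conc[:m].reshape(-1, steps_per_hour).mean(axis=1)
        h_time = time[:m:steps_per_hour]
        h_doy = doy[:m:steps_per_hour]
        obs = hourly.copy()
        if config.vmr_noise > 0:
            sig = config.vmr_noise
            obs = obs * streams["vmr"].lognormal(-0.5 * sig ** 2, sig,
                                                 size=obs.shape)
        unit = "ppb" if spec.name == "isoprene" else "ppt"
        scale = 1e-3 if unit == "ppb" else 1.0
        df = pd.DataFrame(
            {"doy": h_doy, "vmr": obs * scale,
             "uncertainty": hourly * config.vmr_noise * scale,
             "unit": unit, "compound": spec.name}, index=h_time)
        df.index.name = "time"
        vmr_hourly[spec.name] = df

    tracer = gen_tracer(config, er, streams["sf6"])

    # ----- isotope samples --------------------------------------------------
    iso = _gen_isotope_samples(config, doy, emissions, er_h, streams["ratio"])

    truth = {
        "seed": int(config.seed),
        "t_ref_gas_c": config.t_ref_gas,
        "n_air_mol": n_air,
        "r_eco": config.r_eco,
        "er_pct_h": er,
        "a_real": a_real,
        "nee_true": nee_true,
        "nee_true_step": nee_true_step,
        "co2_true": co2,
        "vmr_true": vmr_true_15,
        "emissions": emissions,
        "source_class": {
            spec.name: ("de_novo" if res.groups[spec.group].phi < 1.0
                        else "storage")
            for spec in config.compounds},
        "group": {spec.name: spec.group for spec in config.compounds},
    }
    return Campaign(config, forcing, tracer, vmr_hourly, co2_df, iso, truth)


def _pulse_washout(t_doy: np.ndarray, pulse, er_mean_h: float) -> np.ndarray:
    """Label availability: 1 during the pulse, exchange washout after."""
    start = pulse.doy + pulse.hour / 24.0
    end = start + pulse.duration_h / 24.0
    w = np.zeros_like(t_doy, dtype=float)
    during = (t_doy >= start) & (t_doy <= end)
    w[during] = 1.0
    after = t_doy > end
    w[after] = np.exp(-er_mean_h * (t_doy[after] - end) * 24.0)
    return w


def _gen_isotope_samples(config: ScenarioConfig, doy: np.ndarray,
                         emissions: dict, er_h: np.ndarray,
                         rng: np.random.Generator) -> pd.DataFrame:
    r_amb = config.r13_vpdb * (1.0 + config.delta13c_ambient_permil / 1000.0)
    if len(config.pulses) != 2:
        raise ConfigurationError("default schedule expects two pulses")
    p1, p2 = config.pulses
    n_amb, n_p1, n_post1, n_p2, n_post2 = config.isotope_sample_counts

    def times_in(day0, day1, count, hour0=10.0):
        days = np.linspace(day0, day1, count)
        return days + hour0 / 24.0 + 0.15 * np.cos(np.arange(count))

    schedule: list[tuple[str, float]] = []
    schedule += [("ambient", t) for t in times_in(p1.doy - 8, p1.doy - 2, n_amb)]
    start1 = p1.doy + p1.hour / 24.0
    schedule += [("pulse1", t) for t in np.linspace(
        start1 + 0.2 / 24, start1 + p1.duration_h / 24.0, n_p1)]
    schedule += [("post1", t) for t in times_in(p1.doy + 1, p1.doy + 12, n_post1)]
    start2 = p2.doy + p2.hour / 24.0
    schedule += [("pulse2", t) for t in np.linspace(
        start2 + 0.2 / 24, start2 + p2.duration_h / 24.0, n_p2)]
    schedule += [("post2", t) for t in times_in(p2.doy + 1, p2.doy + 8, n_post2)]

    er_mean = float(np.mean(er_h))
    rows = []
    for spec in config.compounds:
        e_dn = emissions[spec.name]["E_dn"]
        e_tot = emissions[spec.name]["E_total"]
        with np.errstate(invalid="ignore", divide="ignore"):
            f_dn_grid = np.where(e_tot > 0, e_dn / np.where(e_tot > 0, e_tot, 1.0), 0.0)
        for context, t in schedule:
            f_dn = float(np.interp(t, doy, f_dn_grid))
            w = 0.0
            for pulse, lbl in ((p1, ("pulse1", "post1")), (p2, ("pulse2", "post2"))):
                if context in lbl or context == "ambient":
                    w = max(w, float(_pulse_washout(
                        np.asarray([t]), pulse, er_mean)[0]))
            strength = (p1.label_strength if context in ("pulse1", "post1")
                        else p2.label_strength)
            if context == "ambient":
                w = 0.0
            ratio = r_amb * (1.0 + strength * f_dn * w)
            if config.ratio_noise > 0:
                sig = config.ratio_noise
                ratio *= rng.lognormal(-0.5 * sig ** 2, sig)
            rows.append({
                "compound": spec.name, "context": context, "doy": t,
                "time": _YEAR0 + pd.Timedelta(days=t - 1), "ratio_13_12": ratio})
    df = pd.DataFrame(rows)
    df["time"] = df["time"].dt.round("s")
    return df.sort_values(["compound", "doy"]).reset_index(drop=True)


# --------------------------------------------------------------------------
def write_campaign(campaign: Campaign, outdir: str | Path) -> dict[str, Path]:
    """Write the campaign as schema-checked CSV files plus truth.json."""
    from . import io as cio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["forcing"] = cio.write_forcing(campaign.forcing, outdir / "forcing.csv")
    paths["tracer"] = cio.write_tracer(campaign.tracer, outdir / "tracer.csv")
    paths["co2"] = cio.write_co2(campaign.co2, outdir / "co2.csv")
    for name, df in campaign.vmr.items():
        key = f"vmr_{cio.slug(name)}"
        paths[key] = cio.write_vmr(df, outdir / f"{key}.csv")
    paths["isotope_samples"] = cio.write_isotopes(
        campaign.isotope_samples, outdir / "isotope_samples.csv")

    truth = campaign.truth
    truth_small = {
        "seed": truth["seed"],
        "t_ref_gas_c": truth["t_ref_gas_c"],
        "n_air_mol": truth["n_air_mol"],
        "r_eco": truth["r_eco"],
        "source_class": truth["source_class"],
        "group": truth["group"],
        "er_pct_h_mean": float(np.mean(truth["er_pct_h"])),
    }
    p = outdir / "truth.json"
    p.write_text(json.dumps(truth_small, indent=2, sort_keys=True))
    paths["truth"] = p

    series = pd.DataFrame({
        "doy": campaign.forcing["doy"].to_numpy(),
        "er_pct_h": truth["er_pct_h"],
        "a_real": truth["a_real"],
        "nee_true": truth["nee_true"],
        "co2_true": truth["co2_true"],
    }, index=campaign.forcing.index)
    series.index.name = "time"
    paths["truth_series"] = cio.write_truth_series(
        series, outdir / "truth_series.csv")
    return paths
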