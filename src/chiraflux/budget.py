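"""Semi-enclosed chamber CO2 budget and derived ecophysiological fluxes.

Net ecosystem exchange (NEE) of the enclosure is computed every 15 min
from the change in moles of CO2 inside plus the moles lost or gained
through air exchange with the outside:

    NEE = -[(n_t - n_{t-1}) + f * (n_in - n_out)] / (Area * dt)

with n the moles of CO2 from the ideal gas law, f the fractional air
replacement over the step and the sign chosen so that net ecosystem
*uptake* is positive.  Assimilation follows A = NEE - R, with respiration
R taken from night-time NEE (PAR <= 0.1 umol m-2 s-1), assumed
representative of daytime respiration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PAR_DAY_THRESHOLD, R_GAS


def vpd(temp_c, rh):
    """Vapour pressure deficit (kPa) from temperature (degC) and RH (%).

    Tetens-type saturation curve: VPD = 0.6108 (1 - RH/100) e^(17.27T/(237.3+T)).
    """
    temp_c = np.asarray(temp_c, dtype=float)
    rh = np.asarray(rh, dtype=float)
    if np.any(rh < 0) or np.any(rh > 100):
        raise ValueError("RH must lie in [0, 100] %")
    out = 0.6108 * (1.0 - rh / 100.0) * np.exp(17.27 * temp_c / (237.3 + temp_c))
    return out if out.ndim else float(out)


def moles_co2(volume_m3, pressure_pa, temp_c, co2_ppm):
    """Moles of CO2 in a volume from the ideal gas law.

    n = V P / ((273.15 + T) R) * [CO2] / 1e6
    """
    volume_m3 = np.asarray(volume_m3, dtype=float)
    pressure_pa = np.asarray(pressure_pa, dtype=float)
    temp_c = np.asarray(temp_c, dtype=float)
    co2_ppm = np.asarray(co2_ppm, dtype=float)
    if np.any(volume_m3 <= 0) or np.any(pressure_pa <= 0):
        raise ValueError("volume and pressure must be positive")
    if np.any(temp_c <= -273.15):
        raise ValueError("temperature below absolute zero")
    out = (volume_m3 * pressure_pa) / ((273.15 + temp_c) * R_GAS) * co2_ppm / 1e6
    return out if out.ndim else float(out)


@dataclass
class CO2BudgetInputs:
    """Aligned inputs of the chamber CO2 mass balance.

    ``er_frac`` is the fractional air replacement per time step (already
    integrated over the step, dimensionless).  ``temp_ave`` may be a scalar
    (well-mixed, isothermal bookkeeping) or a per-step series.
    """

    time: pd.DatetimeIndex
    co2_inside_ppm: np.ndarray
    co2_outside_ppm: np.ndarray
    er_frac: np.ndarray
    temp_ave_c: np.ndarray | float
    pressure_pa: float
    volume_m3: float = 27700.0
    area_m2: float = 1950.0

    def __post_init__(self):
        n = len(self.time)
        if n < 2:
            raise ValueError("need at least 2 time steps")
        for name in ("co2_inside_ppm", "co2_outside_ppm", "er_frac"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} not aligned with time axis")
            setattr(self, name, arr)
        self.temp_ave_c = np.broadcast_to(
            np.asarray(self.temp_ave_c, dtype=float), (n,)
        ).copy()
        if self.volume_m3 <= 0 or self.area_m2 <= 0:
            raise ValueError("volume and area must be positive")


def nee_series(inputs: CO2BudgetInputs) -> pd.DataFrame:
    """Uptake-positive NEE (umol m-2 s-1) per time step.

    The exchange term uses the step-average (trapezoid) inside
    concentration; storage change is the exact mole difference.  The first
    step has no predecessor and is NaN.
    """
    t = inputs.time
    dt_s = np.diff(t.view("int64")) / 1e9
    if np.any(dt_s <= 0):
        raise ValueError("timestamps must be strictly increasing")
    n_in = moles_co2(inputs.volume_m3, inputs.pressure_pa,
                     inputs.temp_ave_c, inputs.co2_inside_ppm)
    n_out = moles_co2(inputs.volume_m3, inputs.pressure_pa,
                      inputs.temp_ave_c, inputs.co2_outside_ppm)
    storage = np.diff(n_in)
    n_in_mid = 0.5 * (n_in[1:] + n_in[:-1])
    n_out_mid = 0.5 * (n_out[1:] + n_out[:-1])
    exchange = inputs.er_frac[1:] * (n_in_mid - n_out_mid)
    nee = -(storage + exchange) / (inputs.area_m2 * dt_s) * 1e6
    out = np.concatenate([[np.nan], nee])
    return pd.DataFrame({"time": t, "nee": out}).set_index("time")


def assimilation(nee: pd.DataFrame, par, threshold: float = PAR_DAY_THRESHOLD,
                 resp_window: str = "date") -> pd.DataFrame:
    """Split NEE into respiration and assimilation.

    R is the mean night-time NEE (PAR <= threshold) of each calendar date
    (``resp_window="date"``) or of the whole record (``"campaign"``).
    A = NEE - R at day steps and NaN at night.
    """
    par = np.broadcast_to(np.asarray(par, dtype=float), (len(nee),))
    df = nee.copy()
    df["par"] = par
    df["day"] = df["par"] > threshold
    if resp_window == "campaign":
        night = df.loc[~df["day"], "nee"].mean()
        if np.isnan(night):
            raise ValueError("no night-time steps to estimate respiration")
        df["resp"] = night
    elif resp_window == "date":
        by_date = df.groupby(df.index.normalize()).apply(
            lambda g: g.loc[~g["day"], "nee"].mean()
        )
        if by_date.isna().any():
            bad = by_date.index[by_date.isna()][0].date()
            raise ValueError(f"no night-time steps on {bad}")
        df["resp"] = by_date.reindex(df.index.normalize()).to_numpy()
    else:
        raise ValueError(f"unknown resp_window {resp_window!r}")
    df["a"] = np.where(df["day"], df["nee"] - df["resp"], np.nan)
    return df[["nee", "resp", "a", "par", "day"]]


def normalize_flux(flux, area_m2: float, biomass_c_kg: float):
    """Scale a total flux to per-land-area and per-biomass-carbon units."""
    if area_m2 <= 0 or biomass_c_kg <= 0:
        raise ValueError("area and biomass carbon must be positive")
    flux = np.asarray(flux, dtype=float)
    per_area = flux / area_m2
    per_biomass = flux / biomass_c_kg
    return {"per_area": per_area if per_area.ndim else float(per_area),
            "per_biomass_c": per_biomass if per_biomass.ndim else float(per_biomass)}
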