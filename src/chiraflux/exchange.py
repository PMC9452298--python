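"""Air-exchange-rate estimation from SF6 tracer decay, VMR leakage
correction and soil-chamber fluxes.

The enclosure leaks: an inert tracer injected to ~125x background decays
exponentially at the air-exchange rate ER.  ER is estimated per decay
window by ordinary least squares on ln(SF6 - background) vs time (unbiased
under multiplicative noise), reported in % per hour, interpolated across
the campaign, and used to correct measured VMRs for the air replaced
during one sampling interval:

    VMR_c = VMR_u * (1 + ER_frac),   ER_frac = ER[%/h]/100 * dt[h].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .config import R_GAS


class DataError(ValueError):
    """Raised when input data violate an operation's preconditions."""


@dataclass(frozen=True)
class ExchangeRateEstimate:
    """One log-linear decay fit: window, ER (%/h), its standard error and
    the r^2 of the fit."""

    window: tuple[pd.Timestamp, pd.Timestamp]
    er: float  # % per hour
    stderr: float  # % per hour
    r2: float
    n: int

    @property
    def midpoint(self) -> pd.Timestamp:
        return self.window[0] + (self.window[1] - self.window[0]) / 2


@dataclass
class MixingRatioSeries:
    """A per-compound VMR time series with uncertainty and a unit tag."""

    time: pd.DatetimeIndex
    vmr: np.ndarray
    uncertainty: np.ndarray
    compound: str
    unit: str = "ppt"
    corrected: bool = False

    def __post_init__(self):
        self.vmr = np.asarray(self.vmr, dtype=float)
        self.uncertainty = np.asarray(self.uncertainty, dtype=float)
        if self.vmr.shape != (len(self.time),) or \
                self.uncertainty.shape != self.vmr.shape:
            raise DataError("vmr/uncertainty not aligned with time")
        if np.any(self.vmr < 0) or np.any(self.uncertainty < 0):
            raise DataError("vmr and uncertainty must be >= 0")
        if self.unit not in ("ppt", "ppb"):
            raise DataError(f"unknown unit {self.unit!r}")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, compound: str | None = None
                   ) -> "MixingRatioSeries":
        units = df["unit"].unique() if "unit" in df else ["ppt"]
        if len(units) != 1:
            raise DataError(f"mixed units in series: {sorted(units)}")
        name = compound or (df["compound"].iloc[0] if "compound" in df
                            else "unknown")
        return cls(pd.DatetimeIndex(df.index), df["vmr"].to_numpy(),
                   df["uncertainty"].to_numpy(), name, str(units[0]),
                   bool(df.attrs.get("corrected", False)))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"vmr": self.vmr, "uncertainty": self.uncertainty,
                           "unit": self.unit, "compound": self.compound},
                          index=self.time)
        df.index.name = "time"
        df.attrs["corrected"] = self.corrected
        return df


def fit_exchange_rate(tracer: pd.DataFrame,
                      window: tuple[pd.Timestamp, pd.Timestamp],
                      background: float = 8.0) -> ExchangeRateEstimate:
    """Exchange rate (%/h) from the SF6 decay inside ``window``.

    OLS on ln(sf6 - background) vs time; ER = -slope.  Requires at least 5
    points, all strictly above background.  A positive fitted slope
    (apparent growth) is clamped to ER = 0 with a warning — a semi-closed
    chamber cannot un-leak.
    """
    t0, t1 = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    sel = tracer.loc[(tracer.index >= t0) & (tracer.index <= t1)]
    if len(sel) < 5:
        raise DataError(f"insufficient data: {len(sel)} points in window (need 5)")
    above = sel["sf6"].to_numpy(dtype=float) - background
    if np.any(above <= 0):
        raise DataError("tracer at or below background inside window; "
                        "cannot take log")
    hours = (sel.index - t0).view("int64") / 3.6e12
    fit = linregress(hours, np.log(above))
    er = -fit.slope * 100.0
    if er < 0:
        warnings.warn("fitted SF6 growth; clamping exchange rate to 0 %/h")
        er = 0.0
    return ExchangeRateEstimate(
        (t0, t1), float(er), float(fit.stderr * 100.0),
        float(fit.rvalue ** 2), len(sel))


def interpolate_er(estimates: list[ExchangeRateEstimate],
                   grid: pd.DatetimeIndex) -> pd.Series:
    """ER (%/h) on ``grid``: linear between window midpoints, constant
    extrapolation outside."""
    if not estimates:
        raise DataError("no exchange-rate estimates to interpolate")
    ests = sorted(estimates, key=lambda e: e.midpoint)
    mids = np.array([e.midpoint.value for e in ests], dtype=float)
    vals = np.array([e.er for e in ests], dtype=float)
    x = pd.DatetimeIndex(grid).view("int64").astype(float)
    return pd.Series(np.interp(x, mids, vals), index=grid, name="er_pct_h")


def correct_vmr(series: MixingRatioSeries, er_pct_h,
                sampling_interval_h: float | None = None) -> MixingRatioSeries:
    """Leakage-corrected VMR series: VMR_c = VMR_u (1 + ER_frac).

    ER_frac is the dimensionless fraction of chamber air replaced during
    one sampling interval (ER[%/h]/100 * dt).  The uncertainty scales by
    the same factor; the ``corrected`` flag is set and double correction
    rejected.
    """
    if series.corrected:
        raise DataError("series is already corrected; refusing to correct twice")
    er = np.broadcast_to(np.asarray(er_pct_h, dtype=float), series.vmr.shape)
    if np.any(er < 0):
        raise DataError("exchange rate must be >= 0")
    if sampling_interval_h is None:
        steps = np.diff(series.time.view("int64")) / 3.6e12
        sampling_interval_h = float(np.median(steps)) if steps.size else 1.0
    factor = 1.0 + er / 100.0 * sampling_interval_h
    return replace(series, vmr=series.vmr * factor,
                   uncertainty=series.uncertainty * factor, corrected=True)


def soil_chamber_flux(mr_atm_ppt, mr_soil_ppt, flow_ml_min: float,
                      area_m2: float, temp_c: float = 25.0,
                      pressure_pa: float = 101325.0):
    """Signed soil-chamber flux (mol m-2 s-1) from inlet/outlet mixing
    ratios of a flow-through chamber; negative = soil uptake.

    flux = (MR_soil - MR_atm) * Q * n_molar / Area with n_molar = P/(R T).
    """
    if flow_ml_min <= 0 or area_m2 <= 0:
        raise DataError("flow and area must be positive")
    q_m3_s = flow_ml_min * 1e-6 / 60.0
    n_molar = pressure_pa / (R_GAS * (273.15 + temp_c))  # mol m-3
    diff = (np.asarray(mr_soil_ppt, dtype=float)
            - np.asarray(mr_atm_ppt, dtype=float)) * 1e-12
    out = diff * q_m3_s * n_molar / area_m2
    return out if out.ndim else float(out)
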