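"""Configuration types shared across the package.

The campaign coordinate system is day-of-year (doy).  Five experiment
stages partition the campaign window: pre-drought (PD), early drought (ED),
severe drought (SD), deep-water rewet (DRW) and rain rewet (RRW).  The DRW
band here runs until the first overhead rain so that the stages tile the
time axis without gaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np

R_GAS = 8.314  # J mol-1 K-1
PAR_DAY_THRESHOLD = 0.1  # umol m-2 s-1; strictly greater counts as day

STAGES = ("PD", "ED", "SD", "DRW", "RRW")

#: inclusive (start_doy, end_doy) bands; DRW extended to the first rain day
DEFAULT_STAGE_BOUNDS: dict[str, tuple[int, int]] = {
    "PD": (252, 280),
    "ED": (281, 305),
    "SD": (306, 336),
    "DRW": (337, 346),
    "RRW": (347, 356),
}


class ConfigurationError(ValueError):
    """Raised for inconsistent scenario or pipeline configuration."""


def validate_stage_bounds(bounds: Mapping[str, tuple[int, int]]) -> None:
    """Stage bands must be non-overlapping, increasing and gapless."""
    items = [bounds[s] for s in STAGES if s in bounds]
    if not items:
        raise ConfigurationError("no stage boundaries given")
    for (a0, a1), (b0, b1) in zip(items, items[1:]):
        if a1 >= b0:
            raise ConfigurationError(
                f"overlapping stage boundaries: ({a0},{a1}) vs ({b0},{b1})"
            )
        if b0 != a1 + 1:
            raise ConfigurationError(
                f"gap between stage boundaries: ({a0},{a1}) vs ({b0},{b1})"
            )
        if a0 > a1 or b0 > b1:
            raise ConfigurationError("stage boundaries must be increasing")


def stage_of_doy(doy, bounds: Mapping[str, tuple[int, int]] | None = None):
    """Stage label for (possibly fractional) day-of-year values.

    Timestamps outside every band get the empty string.
    """
    if bounds is None:
        bounds = DEFAULT_STAGE_BOUNDS
    doy = np.asarray(doy)
    day = np.floor(doy).astype(int)
    out = np.full(doy.shape, "", dtype=object)
    for name, (lo, hi) in bounds.items():
        out[(day >= lo) & (day <= hi)] = name
    return out


@dataclass(frozen=True)
class GroupParams:
    """Per-enzyme-group parameters of the two-reservoir emission model.

    epsilon
        synthesis capacity at reference conditions (mixing-ratio units per
        hour when used inside the chamber balance; arbitrary mass/time
        otherwise).
    light_activated
        synthesis scales with assimilation A/a_ref when True, constant
        otherwise (group 3).
    phi
        fraction of synthesis routed to the lipid storage pool (0..1);
        isoprene (group 1) has phi = 0.
    k0, beta
        first-order pool release constant at the reference temperature
        (h-1) and its exponential temperature sensitivity (K-1).
    gamma_vpd, vpd_ref
        storage release is multiplied by 1 + gamma_vpd * max(VPD - vpd_ref, 0)
        (kPa), the drought release modifier.
    """

    epsilon: float = 1.0
    light_activated: bool = True
    phi: float = 0.15
    k0: float = 0.02
    beta: float = 0.09
    gamma_vpd: float = 1.0
    vpd_ref: float = 1.5

    def __post_init__(self):
        if self.epsilon < 0 or self.k0 < 0 or self.beta < 0 or self.gamma_vpd < 0:
            raise ConfigurationError("reservoir rates must be >= 0")
        if not 0.0 <= self.phi <= 1.0:
            raise ConfigurationError("phi must lie in [0, 1]")


@dataclass(frozen=True)
class ReservoirParams:
    """Three enzyme groups: 1 isoprene, 2 (-)-pinenes (light-activated,
    partly stored), 3 (+)-alpha-pinene/(+)-limonene (light-independent,
    fully stored)."""

    groups: Mapping[int, GroupParams] = field(
        default_factory=lambda: {
            1: GroupParams(light_activated=True, phi=0.0),
            2: GroupParams(light_activated=True, phi=0.15),
            3: GroupParams(light_activated=False, phi=1.0),
        }
    )
    t_ref: float = 30.0  # deg C reference for k(T)
    a_ref: float = 20.0  # umol m-2 s-1 assimilation normalisation


@dataclass(frozen=True)
class G93Params:
    """Canonical light/temperature activity factors of MEGAN-style models.

    C_L = alpha * c_l1 * L / sqrt(1 + alpha^2 L^2)
    C_T = exp(c_t1 (T - T_s)/(R T_s T)) / (1 + exp(c_t2 (T - T_m)/(R T_s T)))
    with T in kelvin and R the molar gas constant.
    """

    basal: float = 1.0
    alpha: float = 0.0027
    c_l1: float = 1.066
    c_t1: float = 95000.0  # J mol-1
    c_t2: float = 230000.0  # J mol-1
    t_s: float = 303.0  # K
    t_m: float = 314.0  # K

    def __post_init__(self):
        if min(self.basal, self.alpha, self.c_l1, self.c_t1, self.c_t2,
               self.t_s, self.t_m) <= 0:
            raise ConfigurationError("G93 parameters must be positive")


@dataclass(frozen=True)
class CompoundSpec:
    """A quantified compound: enzyme group, synthesis capacity and the
    stage-dependent stress multiplier on synthesis (the drought-modulation
    magnitudes the source experiment does not constrain; see docs)."""

    name: str
    group: int
    epsilon: float  # ppt h-1 chamber-normalised emission capacity
    stage_boost: Mapping[str, float] = field(default_factory=dict)

    def boost(self, stage: str) -> float:
        return float(self.stage_boost.get(stage, 1.0))


_G2_OTHERS = {"ED": 1.5, "SD": 2.0, "DRW": 1.5, "RRW": 1.2}
_G3_BOOST = {"ED": 1.2, "SD": 1.5, "DRW": 1.2, "RRW": 1.0}

MONOTERPENES = (
    "(-)-a-pinene", "(+)-a-pinene", "(-)-b-pinene", "(-)-limonene",
    "(+)-limonene", "(-)-camphene", "(+)-camphene", "g-terpinene",
)

DEFAULT_COMPOUNDS: tuple[CompoundSpec, ...] = (
    CompoundSpec("isoprene", 1, 4.0e5),
    CompoundSpec("(-)-a-pinene", 2, 1100.0,
                 {"ED": 2.2, "SD": 3.5, "DRW": 2.0, "RRW": 1.3}),
    CompoundSpec("(-)-b-pinene", 2, 200.0,
                 {"ED": 3.0, "SD": 22.0, "DRW": 10.0, "RRW": 2.5}),
    CompoundSpec("(-)-limonene", 2, 200.0, _G2_OTHERS),
    CompoundSpec("(-)-camphene", 2, 120.0, _G2_OTHERS),
    CompoundSpec("g-terpinene", 2, 80.0, _G2_OTHERS),
    CompoundSpec("(+)-a-pinene", 3, 230.0, _G3_BOOST),
    CompoundSpec("(+)-limonene", 3, 80.0, _G3_BOOST),
    CompoundSpec("(+)-camphene", 3, 47.0, _G3_BOOST),
)


@dataclass(frozen=True)
class PulseSpec:
    """A 13CO2 labelling pulse: start (doy, hour), duration (h) and the
    isotope-ratio enhancement it imprints on fully de novo emissions."""

    doy: int
    hour: float
    duration_h: float
    label_strength: float


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything the synthetic mesocosm generator needs.

    Defaults emulate the 2019 enclosed-rainforest drought campaign: 15-min
    environmental cadence over doy 252-356, PAR peaking at noon,
    temperature at 14:30, topsoil moisture declining 35% -> 15% and
    recovering after rewetting, SF6 injections to ~1 ppb over an 8 ppt
    background, two morning 13CO2 pulses (one pre-drought, one in severe
    drought).
    """

    doy_start: int = 252
    doy_end: int = 356  # inclusive
    dt_minutes: int = 15
    stage_bounds: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_BOUNDS)
    )

    # forcing
    par_peak_hour: float = 12.0
    par_max: float = 1500.0  # umol m-2 s-1
    photoperiod_h: float = 12.0
    temp_peak_hour: float = 14.5
    temp_max: float = 32.0  # deg C (daytime 28-32, night 21-24 envelope)
    temp_min: float = 21.0
    rh_base: float = 85.0  # % at the mean temperature, pre-drought
    rh_temp_slope: float = 3.0  # % per K anticorrelation with temperature
    pressure: float = 92000.0  # Pa (site elevation ~1100 m)
    soil_moisture_points: tuple[tuple[float, float], ...] = (
        (252, 35.0), (281, 26.0), (306, 20.0), (337, 15.0),
        (340, 15.0), (347, 28.0), (356, 32.0),
    )
    # additional RH depression (%) during the drought, two minima
    rh_depression_points: tuple[tuple[float, float], ...] = (
        (281, 0.0), (295, 25.0), (303, 15.0), (325, 35.0),
        (337, 30.0), (340, 10.0), (347, 5.0), (350, 0.0),
    )

    # chamber / exchange
    volume_m3: float = 27700.0
    area_m2: float = 1950.0
    exchange_rate_pct_h: float = 150.0  # constant default; or profile below
    exchange_rate_profile: Callable[[np.ndarray], np.ndarray] | None = None

    # tracer
    sf6_background_ppt: float = 8.0
    sf6_injection_peak_ppt: float = 1000.0  # total concentration reached
    sf6_injection_doys: tuple[int, ...] = tuple(range(253, 356, 7))
    sf6_injection_hour: float = 10.0

    # CO2 / carbon budget truth
    co2_outside_ppm: float = 415.0
    a_max: float = 20.0  # umol m-2 s-1 potential assimilation capacity
    k_par: float = 600.0  # umol m-2 s-1 light half-saturation
    k_co2: float = 200.0  # ppm CO2 half-saturation (self-limits drawdown)
    r_eco: float = 4.0  # umol m-2 s-1 ecosystem respiration
    t_ref_gas: float = 26.5  # deg C molar-density reference (isothermal bookkeeping)
    # piecewise-linear drought scaling of assimilation capacity vs doy
    a_drought_points: tuple[tuple[float, float], ...] = (
        (252, 1.0), (281, 1.0), (296, 0.8), (321, 0.5), (337, 0.5),
        (342, 0.65), (352, 0.9), (356, 0.92),
    )
    # stomatal downscaling of assimilation under afternoon VPD:
    # factor = 1 / (1 + gamma * max(VPD - ref, 0)); shifts peak A to
    # late morning, ahead of the PAR maximum
    vpd_stomatal_gamma: float = 0.13
    vpd_stomatal_ref: float = 0.8  # kPa
    # drought drift of group-2 storage allocation phi (doy-interpolated):
    # under progressive drying the (-)-pinene source shifts from de novo
    # toward the lipid pool
    phi2_drought_points: tuple[tuple[float, float], ...] = (
        (252, 0.15), (281, 0.15), (306, 0.45), (321, 0.7), (337, 0.7),
        (342, 0.5), (352, 0.25), (356, 0.2),
    )

    # emissions
    compounds: tuple[CompoundSpec, ...] = DEFAULT_COMPOUNDS
    reservoir: ReservoirParams = field(default_factory=ReservoirParams)
    # first-order soil-uptake velocity per compound (h-1); "modest steady
    # uptake" for monoterpenes, moisture-weakening uptake for isoprene
    soil_uptake_h: float = 0.02
    isoprene_soil_uptake_h: float = 1.5

    # isotopes
    pulses: tuple[PulseSpec, ...] = (
        PulseSpec(278, 8.0, 4.0, 0.10),
        PulseSpec(327, 9.0, 5.2, 0.15),
    )
    delta13c_ambient_permil: float = -28.0
    r13_vpdb: float = 0.0111802
    isotope_sample_counts: tuple[int, ...] = (5, 16, 36, 11, 14)

    # noise (relative unless stated) and randomness
    vmr_noise: float = 0.05  # multiplicative lognormal on hourly VMRs
    co2_noise_ppm: float = 0.5  # additive gaussian
    sf6_noise: float = 0.02  # multiplicative lognormal above background
    ratio_noise: float = 0.003  # multiplicative lognormal on isotope ratios
    seed: int = 2019

    def __post_init__(self):
        validate_stage_bounds(self.stage_bounds)
        if self.doy_start >= self.doy_end:
            raise ConfigurationError("doy_start must precede doy_end")
        if self.exchange_rate_pct_h < 0 or self.soil_uptake_h < 0:
            raise ConfigurationError("rates must be >= 0")

    def with_(self, **kw) -> "ScenarioConfig":
        return replace(self, **kw)

    def er_pct_h(self, doy: np.ndarray) -> np.ndarray:
        """True exchange-rate series (%/h) on a fractional-doy grid."""
        doy = np.asarray(doy, dtype=float)
        if self.exchange_rate_profile is not None:
            er = np.asarray(self.exchange_rate_profile(doy), dtype=float)
            er = np.broadcast_to(er, doy.shape).astype(float)
        else:
            er = np.full(doy.shape, float(self.exchange_rate_pct_h))
        if np.any(er < 0):
            raise ConfigurationError("exchange rate profile must be >= 0")
        return er


def interp_points(doy, points: Sequence[tuple[float, float]]) -> np.ndarray:
    """Piecewise-linear interpolation with constant extrapolation."""
    pts = np.asarray(points, dtype=float)
    return np.interp(np.asarray(doy, dtype=float), pts[:, 0], pts[:, 1])
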