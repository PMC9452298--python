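import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import chiraflux as cf

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_campaign() -> cf.Campaign:
    """Full default campaign (doy 252-356, default noise, default seed)."""
    return cf.gen_campaign(cf.ScenarioConfig())


@pytest.fixture(scope="session")
def quiet_campaign() -> cf.Campaign:
    """Noise-free 20-day campaign for exact recovery checks."""
    cfg = cf.ScenarioConfig(doy_start=252, doy_end=271, vmr_noise=0.0,
                            co2_noise_ppm=0.0, sf6_noise=0.0, ratio_noise=0.0)
    return cf.gen_campaign(cfg)


@pytest.fixture(scope="session")
def predrought_forcing() -> pd.DataFrame:
    """Ten pre-drought days of default forcing (PAR peak 12:00, T peak 14:30)."""
    return cf.gen_forcing(cf.ScenarioConfig(doy_start=252, doy_end=261))


@pytest.fixture(scope="session")
def predrought_model(predrought_forcing) -> cf.ReservoirModel:
    """Reservoir model under pre-drought forcing with a light-saturating
    assimilation proxy peaking at noon."""
    par = predrought_forcing["par"].to_numpy()
    a = 20.0 * par / (par + 600.0)
    return cf.ReservoirModel(
        predrought_forcing[["par", "temp", "rh", "vpd"]], assimilation=a)


def budget_inputs(campaign: cf.Campaign) -> "cf.budget.CO2BudgetInputs":
    """CO2 budget inputs at the generator's gas-bookkeeping reference
    temperature, using the true exchange rate."""
    from chiraflux.budget import CO2BudgetInputs

    cfg = campaign.config
    f = campaign.forcing
    dt_h = cfg.dt_minutes / 60.0
    return CO2BudgetInputs(
        time=f.index,
        co2_inside_ppm=campaign.co2["co2_inside"].to_numpy(),
        co2_outside_ppm=campaign.co2["co2_outside"].to_numpy(),
        er_frac=campaign.truth["er_pct_h"] / 100.0 * dt_h,
        temp_ave_c=campaign.truth["t_ref_gas_c"],
        pressure_pa=cfg.pressure,
        volume_m3=cfg.volume_m3,
        area_m2=cfg.area_m2,
    )


def welch_one_tailed_oracle(a, b) -> float:
    """Independent Welch/Satterthwaite implementation (one-tailed)."""
    from scipy import stats

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
    return float(stats.t.sf(t, df))
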