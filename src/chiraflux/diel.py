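"""Trend smoothing, day/night and stage partitioning, diel cycles and
drought proxies.

The analysis pipeline mirrors standard chamber-campaign data management:
Savitzky-Golay smoothing for long-term trends (uncertainty propagated
through the same linear filter weights), a strict PAR > 0.1 umol m-2 s-1
day/night split, per-stage hourly diel cycles smoothed with a centred
five-point moving median and normalised by the maximum across all averaged
diel bins, and three drought proxies: the (+)-alpha-pinene/(-)-beta-pinene
ratio, the afternoon-to-morning ratio of (-)-alpha-pinene and the
fractional contribution of (-)-beta-pinene to the monoterpene sum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_coeffs, savgol_filter

from .config import MONOTERPENES, PAR_DAY_THRESHOLD

log = logging.getLogger(__name__)

MORNING_HOURS = (8, 12)  # [08:00, 12:00)
AFTERNOON_HOURS = (13, 17)  # [13:00, 17:00)


def split_day_night(series: pd.Series | pd.DataFrame, par,
                    threshold: float = PAR_DAY_THRESHOLD):
    """Partition a series into (day, night) by strict PAR > threshold.

    Points with missing PAR are excluded from both and logged.
    """
    par = np.asarray(par, dtype=float)
    if par.shape != (len(series),):
        raise ValueError("PAR not aligned with series")
    missing = ~np.isfinite(par)
    if missing.any():
        log.warning("split_day_night: excluding %d points with missing PAR",
                    int(missing.sum()))
    day = series[~missing & (par > threshold)]
    night = series[~missing & ~(par > threshold)]
    return day, night


def _savgol_edge_operator(window: int, polyorder: int) -> np.ndarray:
    """Hat matrix of the polynomial fit to one window (rows = weights)."""
    x = np.arange(window, dtype=float)
    a = np.vander(x, polyorder + 1, increasing=True)
    return a @ np.linalg.solve(a.T @ a, a.T)


def smooth_trend(values, uncertainty=None, window: int = 25,
                 polyorder: int = 3):
    """Savitzky-Golay smoothing with uncertainty propagation.

    The smoother is a linear filter, so uncertainties propagate through the
    squared filter weights: var_out = sum_j w_j^2 var_in.  Edges use the
    same polynomial-fit weights as ``savgol_filter(mode="interp")``.
    Returns the smoothed values, or ``(smoothed, propagated_sigma)`` when an
    uncertainty array is given.
    """
    y = np.asarray(values, dtype=float)
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and greater than polyorder")
    if window >= y.size:
        raise ValueError("window must be shorter than the series")
    smoothed = savgol_filter(y, window, polyorder, mode="interp")
    if uncertainty is None:
        return smoothed
    var = np.asarray(uncertainty, dtype=float) ** 2
    if var.shape != y.shape:
        raise ValueError("uncertainty not aligned with values")
    w = savgol_coeffs(window, polyorder)
    var_out = np.convolve(var, w ** 2, mode="same")
    half = window // 2
    hat2 = _savgol_edge_operator(window, polyorder) ** 2
    var_out[:half] = hat2[:half] @ var[:window]
    var_out[-half:] = hat2[-half:] @ var[-window:]
    return smoothed, np.sqrt(var_out)


@dataclass
class DielCycle:
    """24 hourly bins of a stage-average cycle for one compound."""

    compound: str
    stage: str
    mean: np.ndarray  # raw hourly means
    smoothed: np.ndarray  # after 5-point moving median
    n: np.ndarray
    uncertainty: np.ndarray  # sem of hourly bins
    normalized: np.ndarray  # smoothed / max over the stage set
    flags: list[str] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return bool(np.all(self.n == 0))


def _moving_median(x: np.ndarray, window: int) -> np.ndarray:
    return (pd.Series(x).rolling(window, center=True, min_periods=1)
            .median().to_numpy())


def diel_cycle(series: pd.Series, stages: Sequence[str],
               median_window: int = 5, compound: str = "",
               normalize_across: str = "all") -> dict[str, DielCycle]:
    """Per-stage hourly diel cycles of an hourly series.

    Bins by hour of day within each stage, averages, applies a centred
    moving median (window ``median_window``, truncated at the edges) and
    normalises by the maximum across all stage cycles (``"all"``) or within
    each stage (``"stage"``).  Empty stages yield an empty, flagged cycle.
    """
    if not isinstance(series.index, pd.DatetimeIndex):
        raise ValueError("series must be indexed by time")
    labels = np.asarray(stages, dtype=object)
    if labels.shape != (len(series),):
        raise ValueError("stage labels not aligned with series")
    hours = series.index.hour
    out: dict[str, DielCycle] = {}
    for stage in pd.unique(labels[labels != ""]):
        m = labels == stage
        sub = pd.DataFrame({"v": series.to_numpy()[m], "h": hours[m]})
        g = sub.groupby("h")["v"]
        mean = g.mean().reindex(range(24)).to_numpy()
        n = g.count().reindex(range(24), fill_value=0).to_numpy()
        sem = (g.std(ddof=1) / np.sqrt(g.count().clip(lower=1))).reindex(
            range(24)).to_numpy()
        smoothed = _moving_median(mean, median_window)
        flags = []
        if np.all(n == 0):
            flags.append("empty stage")
        out[stage] = DielCycle(compound, str(stage), mean, smoothed, n, sem,
                               smoothed.copy(), flags)
    norm_max = np.nanmax(np.concatenate(
        [c.smoothed for c in out.values()])) if out else np.nan
    for c in out.values():
        ref = (norm_max if normalize_across == "all"
               else np.nanmax(c.smoothed))
        if not np.isfinite(ref) or ref == 0:
            c.flags.append("normalization undefined")
            c.normalized = np.full(24, np.nan)
        else:
            c.normalized = c.smoothed / ref
    return out


def peak_hour(cycle: DielCycle) -> tuple[int, list[str]]:
    """Argmax hour of a diel cycle.

    The moving median can flatten the peak into an exact plateau; ties in
    the smoothed cycle are broken by the raw hourly mean within the tied
    bins, then to the earliest hour, and flagged either way.  An all-equal
    cycle is flagged degenerate.  Returns (hour, flags).
    """
    vals = cycle.smoothed
    if np.all(~np.isfinite(vals)):
        raise ValueError("empty diel cycle has no peak")
    flags = []
    finite = vals[np.isfinite(vals)]
    if np.allclose(finite, finite[0]):
        flags.append("degenerate: all bins equal")
    top = np.nanmax(vals)
    winners = np.flatnonzero(np.isclose(vals, top))
    hour = int(winners[0])
    if len(winners) > 1:
        flags.append(f"tie between hours {winners.tolist()}")
        raw = cycle.mean[winners]
        if np.any(np.isfinite(raw)) and not np.allclose(
                raw[np.isfinite(raw)], np.nanmax(raw)):
            hour = int(winners[np.nanargmax(raw)])
    return hour, flags


def _window_mean(series: pd.Series, hours: tuple[int, int]) -> float:
    h = series.index.hour
    sel = series[(h >= hours[0]) & (h < hours[1])]
    return float(sel.mean()) if len(sel) else np.nan


def drought_proxies(vmr: Mapping[str, pd.Series], stages: Sequence[str],
                    morning: tuple[int, int] = MORNING_HOURS,
                    afternoon: tuple[int, int] = AFTERNOON_HOURS,
                    day_hours: tuple[int, int] = (8, 17)) -> pd.DataFrame:
    """Stage-resolved drought proxies from hourly VMR series.

    * ``plus_a_over_minus_b`` — daytime mean (+)-a-pinene / (-)-b-pinene;
    * ``afternoon_morning_ratio`` — (-)-a-pinene afternoon (13-17) over
      morning (08-12) mean;
    * ``beta_pinene_fraction`` — (-)-b-pinene share of the summed
      quantified monoterpenes (daytime mean).

    All series must share a common hourly index and unit.  Zero
    denominators yield NaN with a flag column.
    """
    needed = ("(+)-a-pinene", "(-)-b-pinene", "(-)-a-pinene")
    for c in needed:
        if c not in vmr:
            raise ValueError(f"missing required compound {c!r}")
    idx = next(iter(vmr.values())).index
    for name, s in vmr.items():
        if not s.index.equals(idx):
            raise ValueError(f"{name}: index not aligned")
    labels = np.asarray(stages, dtype=object)
    if labels.shape != (len(idx),):
        raise ValueError("stage labels not aligned")
    terps = [c for c in MONOTERPENES if c in vmr]
    total = sum(vmr[c] for c in terps)
    rows = []
    for stage in pd.unique(labels[labels != ""]):
        m = labels == stage
        flags = []
        plus_a = _window_mean(vmr["(+)-a-pinene"][m], day_hours)
        minus_b = _window_mean(vmr["(-)-b-pinene"][m], day_hours)
        ratio_ab = plus_a / minus_b if minus_b else np.nan
        if not minus_b:
            flags.append("zero (-)-b-pinene denominator")
        morn = _window_mean(vmr["(-)-a-pinene"][m], morning)
        aft = _window_mean(vmr["(-)-a-pinene"][m], afternoon)
        ratio_am = aft / morn if morn else np.nan
        if not morn:
            flags.append("zero morning denominator")
        tot = _window_mean(total[m], day_hours)
        frac = minus_b / tot if tot else np.nan
        if not tot:
            flags.append("zero monoterpene sum")
        rows.append({"stage": stage, "plus_a_over_minus_b": ratio_ab,
                     "afternoon_morning_ratio": ratio_am,
                     "beta_pinene_fraction": frac,
                     "flags": "; ".join(flags)})
    return pd.DataFrame(rows).set_index("stage")


def correlation_matrix(vmr: Mapping[str, pd.Series], stages: Sequence[str],
                       stage: str, par, day: bool = True,
                       threshold: float = PAR_DAY_THRESHOLD,
                       min_overlap: int = 3) -> pd.DataFrame:
    """Pairwise Pearson correlations of compound VMRs within one stage and
    day/night subset (pairwise-complete; entries with fewer than
    ``min_overlap`` overlapping points are NaN)."""
    wide = pd.DataFrame(vmr)
    labels = np.asarray(stages, dtype=object)
    par = np.asarray(par, dtype=float)
    if labels.shape != (len(wide),) or par.shape != (len(wide),):
        raise ValueError("stages/par not aligned with series")
    is_day = np.isfinite(par) & (par > threshold)
    m = (labels == stage) & (is_day if day else ~is_day & np.isfinite(par))
    sub = wide[m]
    corr = sub.corr(method="pearson", min_periods=min_overlap)
    np.fill_diagonal(corr.values, 1.0)
    return corr
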