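"""13C pulse-chase source attribution.

During a 13CO2 pulse, compounds synthesised from freshly assimilated
carbon (de novo) become enriched in 13C while storage-pool emissions keep
ambient ratios.  Because absolute delta-13C of coeluting compounds is not
trustworthy, enrichment is expressed as a relative offset between pulse
and ambient isotope ratios,

    eps13C = R_pulse / R_ambient - 1,

computed on the 13C/12C ratio so enrichment is positive.  Significance is
a one-tailed two-sample unequal-variance (Welch) t-test at alpha = 0.05;
compounds significant in at least one pulse classify as de novo, never
significant as storage, borderline as ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

ALPHA = 0.05
#: natural-abundance probability that a carbon atom is 13C
P_13C = 0.011
N_CARBON_ISOPRENE = 5
#: linear n*p natural background of singly labelled isoprene (= 5.5%)
ISOPRENE_LABEL_BACKGROUND = N_CARBON_ISOPRENE * P_13C


def epsilon13c(ratio_pulse, ambient_mean_ratio: float,
               orientation: str = "13/12"):
    """Relative isotope-ratio offset eps = R_pulse/R_ambient - 1.

    ``orientation="13/12"`` (default) yields positive eps for 13C
    enrichment; ``"12/13"`` reproduces the inverted-ratio convention.
    """
    r = np.asarray(ratio_pulse, dtype=float)
    if np.any(r <= 0) or ambient_mean_ratio <= 0:
        raise ValueError("isotope ratios must be positive")
    if orientation == "13/12":
        out = r / ambient_mean_ratio - 1.0
    elif orientation == "12/13":
        out = ambient_mean_ratio / r - 1.0
    else:
        raise ValueError(f"unknown ratio orientation {orientation!r}")
    return out if out.ndim else float(out)


def isoprene_label_fraction(single_labeled, total,
                            n_carbon: int = N_CARBON_ISOPRENE,
                            p13: float = P_13C):
    """Background-corrected singly-13C-labelled isoprene fraction.

    fraction = single/total - n_carbon * p13 (linear natural-abundance
    approximation, 5 * 1.1% = 5.5%).  Negative values mean the signal is
    below the natural background.
    """
    single = np.asarray(single_labeled, dtype=float)
    total = np.asarray(total, dtype=float)
    if np.any(total <= 0):
        raise ValueError("total abundance must be positive")
    if np.any(single < 0) or np.any(single > total):
        raise ValueError("single-labelled abundance must lie in [0, total]")
    out = single / total - n_carbon * p13
    return out if out.ndim else float(out)


def enrichment_test(pulse_eps: Sequence[float],
                    ambient_eps: Sequence[float]) -> float:
    """One-tailed Welch t-test p-value for mean(pulse) > mean(ambient)."""
    pulse = np.asarray(pulse_eps, dtype=float)
    ambient = np.asarray(ambient_eps, dtype=float)
    if pulse.size < 2 or ambient.size < 2:
        raise ValueError("need at least 2 samples per group")
    res = stats.ttest_ind(pulse, ambient, equal_var=False,
                          alternative="greater")
    return float(res.pvalue)


def classify_source(p_values: Mapping[str, float] | Sequence[float],
                    alpha: float = ALPHA,
                    borderline: float = 0.10) -> tuple[str, str]:
    """Source class from per-pulse enrichment p-values.

    Significant (p <= alpha) in any pulse -> ``de_novo``; never significant
    and all p > ``borderline`` -> ``storage``; never significant but some p
    in (alpha, borderline] -> ``ambiguous``.  Returns (class, rationale).
    """
    if isinstance(p_values, Mapping):
        items = list(p_values.items())
    else:
        items = [(f"pulse{i + 1}", p) for i, p in enumerate(p_values)]
    if not items:
        raise ValueError("need at least one pulse result")
    sig = [name for name, p in items if p <= alpha]
    if sig:
        return "de_novo", f"significant 13C enrichment in {', '.join(sig)}"
    near = [name for name, p in items if alpha < p <= borderline]
    if near:
        return "ambiguous", (f"borderline enrichment (p in ({alpha}, "
                             f"{borderline}]) in {', '.join(near)}")
    return "storage", "no significant 13C enrichment in any pulse"


@dataclass(frozen=True)
class EnrichmentResult:
    compound: str
    pulse: str
    epsilon_mean: float
    p_value: float
    significant: bool
    source_class: str
    rationale: str


def analyze_enrichment(samples: pd.DataFrame, alpha: float = ALPHA,
                       ambient_contexts: Sequence[str] = ("ambient",),
                       pulse_contexts: Sequence[str] = ("pulse1", "pulse2"),
                       orientation: str = "13/12") -> pd.DataFrame:
    """Per-compound, per-pulse enrichment summary and source class.

    ``samples`` needs columns compound, context, ratio_13_12.  The ambient
    reference is the mean ratio over ``ambient_contexts`` per compound (the
    default pools only no-pulse samples).
    """
    required = {"compound", "context", "ratio_13_12"}
    if not required.issubset(samples.columns):
        raise ValueError(f"samples must have columns {sorted(required)}")
    rows: list[EnrichmentResult] = []
    for compound, grp in samples.groupby("compound", sort=True):
        amb = grp.loc[grp["context"].isin(ambient_contexts), "ratio_13_12"]
        if len(amb) < 2:
            raise ValueError(f"{compound}: fewer than 2 ambient samples")
        r_amb = float(amb.mean())
        amb_eps = epsilon13c(amb.to_numpy(), r_amb, orientation)
        p_by_pulse: dict[str, float] = {}
        stats_rows = []
        for pulse in pulse_contexts:
            sub = grp.loc[grp["context"] == pulse, "ratio_13_12"]
            if len(sub) < 2:
                raise ValueError(f"{compound}: fewer than 2 samples in {pulse}")
            eps = epsilon13c(sub.to_numpy(), r_amb, orientation)
            p = enrichment_test(eps, amb_eps)
            p_by_pulse[pulse] = p
            stats_rows.append((pulse, float(np.mean(eps)), p))
        cls, why = classify_source(p_by_pulse, alpha=alpha)
        for pulse, eps_mean, p in stats_rows:
            rows.append(EnrichmentResult(compound, pulse, eps_mean, p,
                                         p <= alpha, cls, why))
    return pd.DataFrame([r.__dict__ for r in rows])
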