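# Methods

`chiraflux` analyses enantiomer-resolved monoterpene and isoprene time
series from a semi-enclosed, continually flushed forest mesocosm subjected
to a controlled drought, and forward-simulates the emission mechanism that
explains them.  This note documents the models, the choices behind every
tunable default, what the synthetic-data generator does and does not
emulate, and the numerical details.

## The emission model

Chiral monoterpenes with identical physics can have distinct biosynthetic
sources.  The package groups terpene synthases into three enzyme groups by
observable behaviour and routes their products through up to two
reservoirs (direct emission vs a leaf lipid storage pool):

| group | products | synthesis | storage fraction φ |
|---|---|---|---|
| 1 | isoprene | light-activated (∝ A) | 0 |
| 2 | (−)-α-pinene, (−)-β-pinene (and other (−) forms) | light-activated (∝ A) | small (default 0.15) |
| 3 | (+)-α-pinene, (+)-limonene | constitutive | 1 |

Per group, with A the ecosystem assimilation and `a_ref` its
normalisation:

```
P(t)      = ε · L(t) · m(t),          L = A/a_ref (groups 1-2), 1 (group 3)
dS/dt     = φ P − k_eff S
k_eff(t)  = k0 · exp(β (T − T_ref)) · (1 + γ max(VPD − VPD_ref, 0))
E_de novo = (1 − φ) P
E_storage = k_eff S
```

Synthesis equals emission plus pool change at every instant (mass
conservation), and at constant forcing the pool settles at the fixed point
S* = φP/k_eff.

**Parameter defaults and why.**

* `k0 = 0.02 h⁻¹` at `T_ref = 30 °C`: a lipid-pool residence time of about
  two days.  Slow pools release in proportion to k(T), so storage emission
  peaks with temperature in the mid-afternoon (14:00–15:00) while de novo
  emission tracks assimilation and peaks by noon — the two observed diel
  modes.  Much faster pools (k0 ≳ 0.3 h⁻¹) would drag the storage peak
  back toward the synthesis peak and erase the separation.
* `β = 0.09 K⁻¹`: the standard exponential temperature sensitivity used
  for storage-driven terpene emission in light/temperature emission
  algorithms.
* `γ = 1 kPa⁻¹`, `VPD_ref = 1.5 kPa`: the drought release enhancement
  engages only above the pre-drought VPD envelope (pre-drought afternoons
  reach ≈1.5 kPa).  With a lower threshold the release modifier would
  already distort pre-drought diel cycles, which are observed to be
  de novo-shaped.
* `φ (group 2) = 0.15` pre-drought: (−)-pinene emissions are predominately
  de novo when water is plentiful, with a minor lipid-phase partition.
* `a_ref = 20 µmol m⁻² s⁻¹`: the pre-drought midday assimilation scale,
  so L ≈ 1 at the pre-drought peak.

Note one structural property: at quasi-steady state a first-order pool
emits φ·P̄ on average regardless of how fast it releases — a larger release
modifier changes the *phasing* of storage emission, not its daily total.
A drought-driven shift of a compound's emission from de novo toward
storage character therefore requires the allocation φ itself to move.
The simulator accepts a time-varying φ for exactly this purpose, and the
synthetic scenario drifts group-2 φ from 0.15 (pre-drought) to 0.7
(severe drought) and back after rewetting.

**Fitting.**  `ReservoirModel.fit` estimates (ε, φ, k0, β) per group by
nonlinear least squares on an observed emission series, parameterised as
(ln ε, logit φ, ln k0, ln β) to enforce positivity and the unit interval.
A seeded multi-start (default 5 starts jittered around a data-informed
initial guess) guards against local minima; `scipy.optimize.least_squares`
(Levenberg–Marquardt, ftol/xtol 1e-14) does the optimisation.  Standard
errors come from the Gauss–Newton covariance mapped back to natural units
by the delta method.  With φ fixed at 0 the pool parameters k0 and β do
not enter the likelihood and are flagged unidentifiable; flat observed
series are flagged degenerate and not fitted.

**Baseline.**  The pooled light × temperature baseline uses the canonical
G93 activity factors (as in MEGAN-class models): C_L = αc_L1·L/√(1+α²L²)
and C_T = exp(c_T1(T−T_s)/(R T_s T)) / (1+exp(c_T2(T−T_m)/(R T_s T))),
with α=0.0027, c_L1=1.066, c_T1=95, c_T2=230 kJ mol⁻¹, T_s=303 K,
T_m=314 K.  `compare_to_baseline` reports per-stage observed/predicted
mean ratios and diel peak-hour offsets; under severe drought the
storage-dominated emissions exceed a baseline calibrated on pre-drought
data and the baseline cannot shift its diel peak.

## Tracer exchange and VMR correction

The enclosure exchanges air with the outside.  SF6 injected to ~1 ppb
(125× the 8 ppt background) decays exponentially at the air-exchange rate
ER.  `fit_exchange_rate` subtracts the background, regresses
ln(SF6 − bg) on time by OLS and reports −slope in % h⁻¹ with its
regression standard error; the log-linear form is closed-form and
unbiased under multiplicative measurement noise.  Negative fitted slopes
(apparent growth, possible under noise) are clamped to 0 with a warning.
Window estimates are interpolated linearly between window midpoints with
constant extrapolation.

The leakage correction is `VMR_c = VMR_u (1 + ER_frac)` where `ER_frac`
is the dimensionless fraction of chamber air replaced during one VOC
sampling interval (ER[%/h]/100 × Δt).  At steady state the correction
increment equals exactly the emission-supported VMR added per sampling
interval.  Uncertainties scale by the same factor, and a corrected series
refuses a second correction.

## Carbon budget

VPD uses the Tetens-type form VPD = 0.6108(1 − RH/100)e^{17.27T/(237.3+T)}
(kPa).  Moles of CO2 follow the ideal gas law,
n = VP/((273.15+T)R)·[CO2]/10⁶.  NEE per 15-min step combines the change
in stored moles with the moles exchanged,

    NEE = −[(n_t − n_{t−1}) + f·(n_in − n_out)] / (Area · Δt),

**uptake-positive** by convention, so that A = NEE − R yields positive
daytime assimilation.  The exchange term evaluates the inside
concentration at the step endpoint average (trapezoid) — second-order
accurate where a pure endpoint rule leaves a few-percent residual at high
exchange rates.  Respiration R is the mean night-time NEE
(PAR ≤ 0.1 µmol m⁻² s⁻¹) of the same calendar date by default
(`resp_window="date"`, tracking drought-driven respiration change), or a
single campaign constant (`"campaign"`).

## Isotope source attribution

Enrichment is the relative offset ε¹³C = R_pulse/R_ambient − 1 computed on
the **13C/12C** ratio, so that ¹³C enrichment is positive (an inverted
12C/13C orientation is available as a switch).  The ambient reference is
the per-compound mean over no-pulse samples.  Significance is a
one-tailed, two-sample, unequal-variance (Welch) t-test at α = 0.05 for
mean(pulse) > mean(ambient).  Compounds significantly enriched in at
least one pulse classify as de novo (a compound may incorporate label in
only one pulse and still be de novo-capable); compounds never significant
with all p > 0.10 classify as storage; never-significant compounds with
some p in (0.05, 0.10] are flagged ambiguous with a rationale.

The singly-labelled isoprene fraction uses the linear natural-abundance
background n_C · p¹³ = 5 × 1.1% = 5.5%, subtracted from single/total;
values below background come out negative by design.  (The exact binomial
background, ≈5.26%, is not the default because the linear convention is
the one the field uses for this correction.)

## Diel analysis

Long-term trends use a Savitzky–Golay filter (default window 25 h, order
3 — long enough to suppress diel-scale fluctuation, short enough to keep
multi-day drought trends; both configurable).  Uncertainties propagate
through the same linear filter weights (σ_out² = Σw²σ²), with the edge
rows taken from the polynomial-fit hat matrix so edges match
`savgol_filter(mode="interp")`.

Day/night splits at strict PAR > 0.1 µmol m⁻² s⁻¹ (0.1 exactly is
night); missing-PAR points are excluded and logged.  Diel cycles bin each
stage's hourly data by hour of day, average, smooth with a centred
five-point moving median (truncated at the edges) and normalise by the
maximum across all stage cycles of that compound, so exactly one bin in
the stage set equals 1.  The moving median flattens peaks into exact-tie
plateaus; `peak_hour` therefore breaks ties by the raw bin mean and then
to the earliest hour, flagging the tie, and flags all-equal cycles as
degenerate.

Drought proxies (windows are a documented convention, the source data do
not pin them): afternoon = 13:00–17:00, morning = 08:00–12:00,
daytime = 08:00–17:00.  Proxies are the daytime (+)-α-pinene/(−)-β-pinene
ratio, the (−)-α-pinene afternoon/morning ratio and the (−)-β-pinene
fraction of the eight quantified monoterpenes.  Correlation matrices are
pairwise-complete Pearson within a stage and day/night subset, with a
3-point minimum overlap.

## The synthetic mesocosm generator

The generator produces a full self-consistent campaign so every analysis
stage can be tested against known truth.  Defaults encode the study
conditions: 15-min forcing over doy 252–356 with stages PD 252–280,
ED 281–305, SD 306–336, DRW 337–346, RRW 347–356 (the deep-water-rewet
band is extended to the first rain so the stages tile the axis; the ED/SD
split at doy 306 is a configurable convention anchored to the two RH
minima); PAR a clipped sinusoid peaking at 12:00 (max 1500 µmol m⁻² s⁻¹,
12-h photoperiod); temperature a 21–32 °C sinusoid peaking at 14:30; RH
anti-correlated with temperature with two depressed minima during the
drought; topsoil moisture declining 35% → 26% (pre-drought) → 15%
(severe drought) and recovering after rewetting; hourly VOC sampling;
SF6 injections every 7 days; two morning ¹³CO2 pulses (doy 278 and 327,
4 h and 5.2 h, the second stronger), with 5/16/36/11/14 samples in the
ambient/pulse1/post1/pulse2/post2 contexts.

Choices the source observations do not pin down, set once from
steady-state arithmetic (not adjusted afterwards):

* **Exchange rate 150 % h⁻¹** (air residence ≈ 40 min).  The VOC mixing
  ratio lags emission by ≈ arctan(ω/ER)/ω; at a few % h⁻¹ the diel VMR
  cycle of a noon-peaking emitter would be damped and shifted several
  hours into the afternoon, incompatible with observed late-morning
  (−)-α-pinene maxima in a continually flushed enclosure.  One to two air
  changes per hour is the regime in which the reported diel phenomenology
  exists at all.
* **CO2/assimilation truth**: A = A_max·PAR/(PAR+600)·d(doy)·g(VPD)·
  [CO2]/([CO2]+200) with A_max = 20 µmol m⁻² s⁻¹, a piecewise-linear
  drought factor d falling to 0.5 in severe drought, and a stomatal
  factor g = 1/(1+0.13·max(VPD−0.8,0)) that moves the assimilation peak
  into late morning, ahead of PAR.  Respiration is constant at
  4 µmol m⁻² s⁻¹.  Gas bookkeeping uses a fixed reference temperature
  (26.5 °C): thermal-expansion fluxes are deliberately not emulated, and
  budget-closure tests evaluate NEE at that reference.
* **Drought modulation magnitudes**: per-compound stage multipliers on
  synthesis (e.g. (−)-β-pinene ×3 in early and ×22 in severe drought,
  (−)-α-pinene ×2.2/×3.5, (+) compounds ×1.2/×1.5 plus the VPD release
  modifier), the group-2 φ drift (0.15 → 0.7 → 0.25) and base capacities
  ε sized so pre-drought daytime mixing ratios sit near 0.5 ppb
  (−)-α-pinene, 0.22 ppb (+)-α-pinene, ~0.1 ppb (−)-β-pinene and
  ~10² ppb isoprene.  Together these reproduce the qualitative campaign
  pattern: an early-drought concentration peak and a larger severe-drought
  peak, (−)-α-pinene daytime maxima higher in early than severe drought,
  a ≈3× rise of the (−)-β-pinene fraction from pre-drought to severe
  drought, diel peaks shifting from ~12:00 to ~14:00–15:00 under drought
  and returning after rain, and (−)-α-pinene correlating with
  (−)-β-pinene more strongly than with its own mirror image before the
  drought.
* **Noise**: multiplicative lognormal on hourly VMRs (5%) and on SF6
  above background (2%), additive Gaussian on CO2 (0.5 ppm),
  multiplicative lognormal on isotope ratios (0.3%).  All streams derive
  from a single seed; identical configs give bit-identical campaigns.
* **Isotopes**: ambient ¹³C/¹²C set by δ¹³C = −28‰ on VPDB.  During a
  pulse, a compound's ratio rises by (label strength) × (instantaneous
  de novo fraction of its emission); after the pulse the enhancement
  washes out with the chamber exchange rate.  Storage-pool compounds stay
  at ambient ratios by construction.
* **Soil sink**: first-order uptake of 0.02 h⁻¹ for monoterpenes (small
  next to the exchange rate — soil uptake does not drive enantiomeric
  fractionation) and a soil-moisture-weakening isoprene uptake of up to
  1.5 h⁻¹, which produces the pre-drought isoprene rise as the topsoil
  dries.

**What the generator does not emulate** — and hence what passing tests do
not show about real campaigns: canopy gradients and turbulence (the
chamber is a single well-mixed box), thermal-expansion gas fluxes,
chromatographic coelution and drift (isotope ratios arrive as clean
numbers; the analysis takes supplied ratios as-is), instrument downtime
and gaps, per-species plant variation (emissions are ecosystem
aggregates), weather variability (forcing is a clean sinusoid plus the
drought trajectory), and any atmospheric oxidation chemistry.

## Numerical choices

* Chamber trace-gas balances: explicit Euler at 1-min substeps — the
  stiffness ratio is mild at these rate constants (λΔt ≈ 0.03) and the
  scheme is transparent; the 15-min grid stores the result.
* Reservoir ODE: fixed-step RK4 at the forcing resolution with linear
  midpoint interpolation of the drivers; pool mass clipped at 0.
* Mass-conservation checks compare RK4 trajectories against trapezoid
  integrals of synthesis and emission; both are second-order, so the
  tests assert 1e-3 relative agreement rather than machine precision.
* Exchange-rate windows need ≥ 5 points strictly above background;
  tracer values at or below background are a data error (log undefined).
* Problem sizes: simulations in the test-suite and acceptance runs use
  10–20 day campaigns at the native 15-min cadence (the full 105-day
  default campaign runs in ~2 s); these sizes were chosen as the smallest
  that exercise multi-stage behaviour.

## Known limitations

* The enzyme-group model is deliberately minimal: first-order pool
  kinetics, exponential temperature response, one pool per group.  It is
  an explanatory mechanism, not a calibrated prediction tool.
* ER enters the VMR correction as a per-interval fraction; at high
  exchange rates (ER_frac ≳ 1) the linear correction is a crude
  inflation and the corrected values should be read as leak-adjusted
  indices rather than absolute chamber-free mixing ratios.
* Welch-test source classification inherits the usual multiple-testing
  caveat: with many truly storage-type compounds and two pulses, a ~10%
  family-wise false "de novo" rate per compound is expected at α = 0.05.
* Absolute δ¹³C values are out of scope by design; only relative offsets
  are meaningful for chromatographically unresolved compounds.
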