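# Methods

## The problem

Laccases oxidise phenolic substrates while reducing O₂ to water.  For
chromogenic substrates (ABTS, 2,6-dimethoxyphenol) their kinetics are read
out optically through Beer–Lambert absorbance of the coloured product.
Polymeric lignosulfonic acid offers no such handle, so its turnover is
measured calorimetrically instead: an isothermal titration calorimeter (ITC)
records the differential thermal power needed to keep the reaction cell
isothermal, and that power is itself proportional to the reaction rate.
This package implements both read-outs and a full synthetic instrument to
validate them.

## The calorimetric model

Two experiments, both in a fixed-volume overflow cell of volume V with
enzyme at concentration [E]₀:

1. **Single-injection (calibration).**  A substrate bolus small enough to be
   converted completely is injected; integrating the baseline-corrected
   power gives the heat per mole of substrate turned over, the apparent
   molar enthalpy

   ΔH_app = ∫(dQ/dt) dt / ([S]_total · V)   (cal/mol).

   Under the power-compensation sign convention an exothermic reaction
   deflects negative, so ΔH_app < 0 for an exothermic turnover.

2. **Multiple-injection (kinetics).**  Many small boluses raise the in-cell
   substrate stepwise.  Instantaneous power converts to reaction rate,

   rate = d[P]/dt = (1/(V·ΔH_app)) · dQ/dt,

   and cumulative heat to converted product, [P](t) = Q(t)/(ΔH_app·V), so
   the residual substrate is [S](t) = [S]_total(t) − [P](t).  Pairing
   ([S], rate) across the titration traces out the Michaelis–Menten
   hyperbola rate = V_max·S/(K_m+S), which is fitted by nonlinear least
   squares; k_cat = V_max/[E]₀ and the efficiency k_cat/K_m follow.

### Dilution bookkeeping

The overflow cell displaces liquid on each injection of volume v: every
resident species is scaled by (1 − v/V) and the injected species gains
c_syr·v/V (linear displacement; at v/V ≤ 2.5% this differs from the
exponential overflow model by < 0.04%).  Three consequences are handled
explicitly:

* [S]_total(t) is a step function maintained under this dilution, also
  diluting already-formed product.
* The **enzyme** is diluted too — ≈ 14% over a 30 × 1 μL titration — so
  measured rates are divided by the cumulative dilution factor before
  fitting; the fitted V_max then refers to [E]₀.  This is switchable in
  `ExclusionPolicy`.
* Converted moles per injection default to the full bolus c_syr·v,
  consistent with the dilution model above; `bolus_displacement`
  ("half"/"full") implements the alternative conventions in which part of
  the bolus itself is treated as displaced.

### Terminal self-calibration of the substrate axis

[S](t) is the difference of two nearly equal numbers near the end of a
titration, so it is extraordinarily sensitive to the ΔH_app scale: a 0.3%
calibration error shifts the whole substrate axis by 0.3% of the cumulative
input (≈ 0.4 μM here), which is fatal where the decay sweeps S through the
K_m-informative region — in simulation it biases K_m by ~20%.  When the
trace demonstrably runs to completion (terminal power at baseline, judged
by a median test robust to noise spikes), the conversion fraction is pinned
by the trace itself: the heat-to-concentration scale is refined so that
[S](end) = 0, equivalently [P](t) = [S]_total(end)·Q(t)/Q(end) up to
dilution bookkeeping.  The single-injection ΔH_app remains a required
input and a sanity reference (disagreement beyond 2× is an error, beyond
25% a warning); rates are rescaled consistently.  The behaviour is
controlled by `terminal_calibration` ("auto"/"never"/"require").

## The synthetic calorimeter

`simulate_cell` integrates dS/dt = −k_cat·E·S/(K_m+S) between injections
(LSODA, rtol 10⁻⁸) on a 0.5 s internal grid — fine enough that the 5 s
instrument sampling never limits accuracy — applying injections as
instantaneous displacement events.  `render_thermogram` then applies a
single-exponential (Tian) instrument response with time constant τ via the
exact zero-order-hold recursion starting from rest, resamples to the 5 s
instrument grid, and adds baseline offset, linear drift (default 0) and
white Gaussian noise from a seeded generator.  Real compensation
calorimeters are closer to second order, but a single τ is the standard
identifiable model; τ defaults to 6 s (a fast-response iTC-200), noise SD
to 0.01 μcal/s, baseline offset to 0.1 μcal/s.

The packaged default parameter set encodes the reference
laccase/lignosulfonic-acid system: k_cat = 0.234 s⁻¹, K_m = 56.7 μM,
[E]₀ = 1.39 μM, ΔH_app = −25,040 cal/mol, 200 μL cell at 30 °C, with the
two protocols `single_lsa` (2 × 5 μL of 100 μM, 1000 s spacing) and
`multi_lsa` (30 × 1 μL of 1000 μM, 60 s spacing), both preceded by 250 s of
equilibration.  The enzyme concentration of the multi-injection run reuses
the single-injection run's 1.39 μM — an assumption, as the protocol leaves
it unstated.  Simulations extend 2000 s (single), 1800 s (multi) past the
last injection so the final bolus converts essentially completely.

What the simulator deliberately omits: injection mixing-artifact spikes,
product inhibition, enzyme inactivation, reversible kinetics, second-order
instrument response, and 1/f baseline wander.  Passing round-trips therefore
demonstrate the correctness of the inference chain under the stated model,
not robustness to every instrumental pathology of real thermograms.

## Signal conditioning

* **Baseline**: constant or linear, fitted to the pre-first-injection span
  (≥ 30 s required).  By default the terminal span is *not* used: a
  first-order reaction approaches baseline only asymptotically, and a
  terminal window silently absorbs real tail heat (worth several percent of
  the total here).  Noise SD is the MAD-based residual spread.
* **Tian deconvolution**: P_true = P_meas + τ·dP/dt with the derivative
  from a local-quadratic Savitzky–Golay filter, default window 7 points —
  the smallest odd window that tames 0.01 μcal/s noise at 5 s sampling
  without flattening 60 s features.  The filter is applied segment-wise
  between injections so the window never straddles a known power
  discontinuity; without this the last ~3 samples of every interval inherit
  a spurious derivative from the upcoming jump (up to ~17% rate error).
* **Integration**: trapezoid.  Per-injection windows start 3 samples before
  the injection (the smoothed derivative spreads a little heat backwards)
  and run to the next injection; the final window spans one typical
  injection spacing.  A noise-aware auto-close rule (quiet for 5 samples
  under max(3×SD, 0.5% of peak, 10⁻⁶ μcal/s)) serves single-injection
  schedules.  The absolute floors exist because purely SD-based rules
  degenerate on noise-free data.

Completeness between injections is enforced: the median |power| of the ~10
samples before the next injection must sit under max(3×SD, 1% of peak);
otherwise `estimate_delta_h_app` raises rather than misattribute heat.

## Michaelis–Menten fitting

`MichaelisMenten.fit()` runs Levenberg–Marquardt (scipy `least_squares`,
analytic Jacobian) in log-parameter space, which enforces positivity without
constraints; relative tolerance 10⁻⁸, ≤ 200 iterations.  Starting values
come from an Eadie–Hofstee linearisation with Lineweaver–Burk fallback,
ties broken by RSS.  Standard errors come from the Jacobian at the optimum
(σ² = RSS/(n−2)).  A fit is flagged `reliable=False` when it fails to
converge, when an SE dwarfs its estimate, or when the fitted K_m falls more
than 5× outside the sampled substrate range (all-saturated or all-linear
designs cannot support it).  Least squares is unweighted by default; a
1/rate² option exists.  The Lineweaver–Burk double-reciprocal fit is
reported as a diagnostic only.  Reported efficiencies are rounded to 2
significant figures (1 below 0.01) in report output; full precision is kept
internally.

## Rate-curve exclusions

After every injection a settling window of max(5τ, 20 s) is dropped (the
restored step still carries ≈ e^(−t/τ) of un-deconvolved transient); the
pre-first-injection span, the trailing 3 derivative-edge samples, and
negative-rate samples (noise about zero) are likewise excluded, each with a
recorded reason code.  Residual-substrate values within a tolerance of
max(2% of peak [S]_total, 3×propagated noise) below zero are clipped to
zero and counted; larger negative excursions raise, since they signal a
wrong ΔH_app or sign convention.

## Spectrophotometric initial rates

A(t) = ε·l·[P](t); the initial rate is the least-squares slope over the
longest prefix (≥ 5 points) on which a quadratic fit's curvature term is
either statistically negligible at 2σ or contributes under 2% of the linear
change across the window — the second branch makes the rule meaningful on
noise-free traces, where any curvature is formally significant.  The slope
divided by ε·l gives μM/s.  One unit U is 1 μmol substrate oxidised per
minute; specific activity converts via k_cat·60·10³/MW (U/mg), and MW must
be supplied explicitly — it is never guessed.

## Validation problem sizes

The test-suite round trips use the two reference protocols noise-free
(~650 and ~760 samples) plus 50-seed noisy replicates of both the reference
titration and a higher-dose validation design (30 × 2 μL of 5 mM with a
matching 2 × 5 μL calibration at 2000 s spacing) that drives the cell well
past saturation.  The reference titration only reaches ≈ K_m/3 in
substrate, so K_m is weakly identified there — its noisy-median error is
checked against a wide 25% band, against 5% for the saturating design.
The Michaelis–Menten optimiser is cross-checked against a 400×400
log-grid search on 20 random noisy datasets, and the simulator against
zero-order and first-order closed forms deep in their respective limits.

## Known limitations

* The substrate's nominal molarity is taken as exact; for a polydisperse
  polymer like lignosulfonate the molar-mass basis is a convention, and
  K_m inherits it.
* With the reference single-injection protocol at 0.01 μcal/s noise, the
  ΔH_app estimate scatters by roughly ±10% seed-to-seed: the ~25 μcal of
  signal is integrated over ~2000 s, so the baseline estimate from 250 s of
  pre-injection data dominates the error budget.  Terminal self-calibration
  shields K_m and V_max from this, but reported ΔH_app values from noisy
  single runs carry that uncertainty.
* Temperature and pH are metadata only; no optimum-condition modelling.
* No blank-titration (dilution heat) workflow beyond subtracting a
  user-supplied blank thermogram, and no joint single-trace fitting of
  ΔH and kinetics.
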