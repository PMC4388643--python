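# itckinetics

Enzyme kinetics from isothermal titration calorimetry (ITC), plus the
classical spectrophotometric initial-rate workflow — built for substrates
like lignosulfonic acid that have no optical handle, where the heat of
reaction is the only universal activity signal.

## Who this is for

Enzymologists and biophysicists who run multiple-injection ITC enzyme
assays (e.g. laccase acting on lignosulfonates on a MicroCal iTC-200) and
want a tested, scriptable path from raw thermograms to Michaelis–Menten
parameters — and a synthetic calorimeter to validate that path end to end.

## The method

A power-compensation calorimeter records the differential thermal power
dQ/dt needed to hold the cell isothermal (exothermic reaction = negative
deflection).  Two experiments on a cell of volume V containing enzyme at
[E]₀:

* **Single-injection calibration** — a substrate bolus is converted
  completely; the apparent molar enthalpy is

  ΔH_app = ∫(dQ/dt)dt / ([S]_total·V)  (cal/mol).

* **Multiple-injection kinetics** — many small boluses; instantaneous power
  gives the rate and cumulative heat gives conversion:

  rate = d[P]/dt = (1/(V·ΔH_app))·dQ/dt,
  [S]_t = [S]_total − [P]_t = [S]_total − Q(t)/(ΔH_app·V).

Pairing ([S]_t, rate) across the titration and fitting
rate = V_max·S/(K_m + S) yields K_m, V_max, k_cat = V_max/[E]₀ and the
catalytic efficiency k_cat/K_m.  The pipeline in between — baseline fit,
Tian deconvolution of the instrument lag (P_true = P_meas + τ·dP/dt),
windowed heat integration, dilution bookkeeping, transient exclusion — is
what this package implements and tests.  Absorbance assays (A = ε·l·[P])
follow the standard initial-rate route.  See `docs/methods.md` for the full
model and numerical choices.

## Worked example

Simulate the packaged reference experiments (200 μL cell, 1.39 μM laccase,
lignosulfonic-acid kinetics k_cat = 0.234 s⁻¹, K_m = 56.7 μM,
ΔH_app = −25,040 cal/mol; calibration 2 × 5 μL of 0.1 mM with 1000 s
spacing, titration 30 × 1 μL of 1 mM with 60 s spacing, τ = 6 s, 5 s
sampling) and analyse them:

```python
import itckinetics as ik

analysis = ik.ITCKineticsAnalysis.from_simulation(noise_sd=0.0, seed=1)
res = analysis.fit()
res.mm = ik.derive_catalytic_constants(res.mm, enzyme_conc=1.39,
                                       molecular_weight=67700.0)
print(res.summary())
```

```
ITC enzyme-kinetics analysis
==============================================
dH_app (cal/mol)        -25161.8
per-injection dH        -25120, -25203
rate-curve points       526 retained / 759 total

Michaelis-Menten fit
==============================================
n observations          526
converged               True
reliable                True
iterations (nfev)       8
RSS                     1.73529e-06
----------------------------------------------
Vmax (uM/s)             0.323197 +/- 0.000285
Km (uM)                 56.1855 +/- 0.0647
kcat (1/s)              0.232516
kcat/Km (1/s/uM)        0.00413837  [reported: 0.004]
specific activity (U/mg)0.20607
==============================================
```

Reading it: the calibration run recovers the generating enthalpy
(−25,162 vs −25,040 cal/mol, +0.5%); the titration chain recovers
K_m = 56.19 μM (generating 56.7, −0.9%) and k_cat = 0.233 s⁻¹ (generating
0.234), so the efficiency reports as 0.004 s⁻¹μM⁻¹ and the specific
activity as 0.206 U/mg at MW 67.7 kDa.  526 of 759 thermogram samples
survive the exclusion rules (pre-injection span, 30 s post-injection
settling, trailing filter edge).

The same chain is available file-by-file from the shell:

```bash
itckin --seed 1 simulate --protocol multi_lsa --outdir sim
itckin report --simulate --noise-sd 0 --outdir out     # full chain + report
itckin deltaH sim/single_lsa_thermogram.csv sim/single_lsa_schedule.csv
```

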