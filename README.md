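# mibgdose

Dosimetry and efficacy analysis for preclinical studies that combine external
beam radiotherapy (EBRT) with ¹³¹I-mIBG molecular radiotherapy (MRT) in
neuroblastoma xenografts.

The package is aimed at radiopharmaceutical-dosimetry and preclinical-therapy
researchers who need the full computational chain behind such a study as
tested, reusable code:

* **Sphere dosimetry (MIRD schema).** Tumour absorbed dose is
  `D = Ã · S`, where the cumulated activity `Ã` (total decays in the tumour)
  comes from trapezoidal integration of the %ID/g time–activity curve with a
  physical-decay tail `A_last/λ` after the last sample, and the S-value
  (Gy per Bq·s) comes from an event-by-event Monte Carlo of the full ¹³¹I
  emission inventory (allowed-shape beta spectra, conversion/Auger electrons,
  gamma lines) in a unit-density water sphere of the tumour mass.  The MC is
  validated against a shipped independent chord-length-quadrature reference
  table (agreement well inside 10%).
* **DCE-MRI permeability quantification.** Baseline-normalised T1 enhancement
  `n(t) = (S(t) − S̄_pre)/S̄_pre`, post-injection summary statistics, and
  paired t-tests between imaging sessions (before vs 24 h vs 72 h after EBRT).
* **Growth and time-to-endpoint analysis.** Slice-summation tumour volumes,
  percent-change tables with one-way ANOVA, Kaplan–Meier product-limit
  estimation with right censoring, and a censored Weibull accelerated
  failure time model (`log T = μ + x'β + σW`) with treatment effects.
* **Synthetic cohort generator.** Per-animal biodistribution, growth and DCE
  datasets calibrated to the published group summaries, so the entire
  pipeline runs end to end with no external data.

## Worked example

Dose to a 0.5 g tumour from 20 MBq injected ¹³¹I-mIBG, using the published
group-mean uptake curves with and without EBRT 24 h before injection:

```python
from mibgdose import (load_i131_scheme, Sphere, simulate_sphere, s_value,
                      TimeActivityCurve, cumulated_activity, absorbed_dose, dose_ratio)
from mibgdose.pipeline import REPORTED_GROUP_UPTAKE as uptake

scheme = load_i131_scheme()
sphere = Sphere(mass_g=0.5)
mc = simulate_sphere(scheme, sphere, n_histories=100_000, seed=1, keep_per_history=True)
sv = s_value(mc, sphere)
print(f"S = {sv.value:.3e} +/- {sv.uncertainty:.1e} Gy/(Bq s)")

reports = {}
for group in ("mrt", "ebrt_mrt"):
    curve = TimeActivityCurve.from_arrays(
        uptake["times_h"], uptake[group]["means"], injected_activity_mbq=20.0, label=group)
    cum = cumulated_activity(curve, scheme)          # trapezoid + physical-decay tail
    reports[group] = absorbed_dose(cum, tumour_mass_g=0.5, s=sv, label=group)
    print(f"{group}: A_cum = {cum.value_mbq_h_per_g:.1f} MBq h/g, "
          f"dose = {reports[group].dose_gy:.2f} Gy")
print(f"fold change = {dose_ratio(reports['ebrt_mrt'], reports['mrt']):.2f}")
```

prints

```
S = 5.933e-11 +/- 1.4e-13 Gy/(Bq s)
mrt: A_cum = 97.0 MBq h/g, dose = 10.36 Gy
ebrt_mrt: A_cum = 428.1 MBq h/g, dose = 45.72 Gy
fold change = 4.41
```

The S-value says each decay in the 0.5 g sphere delivers ~59 pGy; the
cumulated activities say prior EBRT multiplies the number of retained decays
by >4 (driven by the much slower washout after irradiation), and the fold
change of the absorbed dose — which is independent of the S-value when the
sphere is the same — exceeds the two-fold enhancement the combination is
expected to provide.  Absolute doses depend on explicit conventions (tumour
mass, decay-correction of the counter data, start-of-curve rule), all of
which are recorded in each `DoseReport.assumptions`.

Everything is also available from the command line:

```bash
mibg synth --seed 1 --out-dir data/          # synthetic cohort CSVs
mibg svalue --mass-g 0.5 --n 100000 --seed 1 --out svalue.json
mibg dose --tac data/tac.csv --group mrt --svalue svalue.json
mibg dce --dce data/dce.csv
mibg efficacy --volumes data/volumes.csv --survival data/survival.csv
mibg all --seed 1 --out-dir out/             # all three studies + manifest
```

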