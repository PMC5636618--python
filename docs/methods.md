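# Methods

This note documents the models implemented in `mibgdose`, the assumptions
behind them, the defaults and why they were chosen, and the limitations a
user should keep in mind.  Units are fixed throughout the package: energies
in keV, biodistribution times in hours, transport lengths in cm, masses in
grams, activities in MBq, doses in Gy.

## ¹³¹I decay scheme (`mibgdose.decay`)

The emission inventory ships in `data/i131_decay.csv` (half-life 8.0252 d =
192.6048 h, transcribed with the line data from standard published decay
compilations).  Truncation policy: beta branches with intensity ≥ 0.1%,
discrete photon/electron lines with yield ≥ 0.5%; Auger and low-energy
conversion electrons below 10 keV are lumped into a single 3.4 keV line that
always deposits locally.  The omitted inventory carries well under 1% of the
emitted energy per decay, far below the 10% validation tolerance used for
the sphere dosimetry.

Beta spectra use the allowed shape — phase space `p·W·(Q−E)²` times a
nonrelativistic Fermi Coulomb factor `F = 2πη/(1−e^{−2πη})`, `η = Zα/β`
with Z = 54 (the Xe daughter) — evaluated on a 1 keV grid, normalised, and
sampled by inverse CDF with linear interpolation.  The resulting
intensity-weighted mean beta energy (computed, not assumed) falls in the
180–200 keV range of published ¹³¹I tables; tests assert this.  Discrete
lines are included per decay as independent Bernoulli trials with
probability equal to the yield.

## Sphere Monte Carlo (`mibgdose.transport`)

Self-dose geometry: source region = target region = a homogeneous water
sphere (ρ = 1 g/cm³ by default) of the tumour mass.  Decay sites are uniform
in the volume, emission directions isotropic, and every emission of a decay
is transported.

**Electrons.** Continuous slowing-down along a straight track with tabulated
collision stopping power (log-log interpolated on a fine grid, CSDA range by
cumulative quadrature).  A track cut by the surface escapes with its
residual energy, evaluated in closed form from the range table — no
stepping, which makes per-history energy conservation exact to floating
precision.  Termination below 1 keV deposits locally.  Neglected: radiative
losses (bremsstrahlung yield in water < 1% below 1 MeV), multiple-scattering
path detour.  The detour correction would slightly *increase* absorbed
fractions (shorter crow-flight penetration), so the straight-track model is
conservative; for spheres much larger than the electron range the boundary
term it affects is itself a small correction.

**Photons.** Analog transport: free paths from the total interaction
coefficient (tabulated photoelectric + Klein–Nishina incoherent evaluated
analytically with 3.3428·10²³ electrons/g); photoelectric events transfer
the full photon energy to a secondary electron (fluorescence neglected —
the O K-edge is 0.5 keV); Compton events sample the scattered energy from
the Klein–Nishina distribution by the standard composition/rejection
method, hand the recoil electron to the electron model at its kinematic
angle, and continue tracking the scattered photon; photons below 1 keV
deposit locally.  Rayleigh scattering is neglected (no energy transfer,
small angular effect at these energies).

**Scoring.** Deposits are accumulated per history and per source component
(beta continuum, discrete electrons, photons-with-secondaries).  Absorbed
fractions use the ratio estimator Σdep/Σemit with a ratio-estimator standard
error; the S-value is mean deposited energy per decay (J) divided by sphere
mass (kg), with uncertainty from the spread of per-history deposits.

**Randomness.** One seeded numpy PCG64 generator drives a fixed sequence of
vectorised draws, so a run is a pure function of (scheme, sphere,
n_histories, seed); tests assert bit-level reproducibility.  Seeds are
recorded in every S-value and report.

**Validation reference.** `data/sphere_svalue_reference_synthetic.csv`
(masses 0.1–10 g) is generated by `scripts/make_sphere_reference.py` using a
deterministic model that shares no code path with the event-by-event MC:
electron absorbed fractions by Gauss–Legendre quadrature of the closed-form
track deposit over the uniform-source/isotropic-direction chord-length
distribution of the sphere, and photon absorbed fractions from the mass
energy-absorption coefficient along the same chords,
`φ_p = E[1 − exp(−μ_en d)]`, which is exact to first order in the optical
thickness (spheres up to 10 g are ≤ 0.15 mean free paths across).  The
table is a synthetic, independently computed reference — not a published
data product — and the acceptance suite requires the MC sweep at 10⁵
histories per sphere to agree with it within 10%, the same tolerance used
for sphere-model cross-code comparisons in this field.  A caveat follows
from the construction: the electron part of the reference shares the
stopping-power *data* (though not the algorithm) with the MC, so the
comparison validates the transport and sampling machinery rather than the
underlying cross sections.

The large-sphere limit is an electron statement: the electron absorbed
fraction tends to 1 (tested within 2% at 10⁶ g).  No such limit holds for
photons at any practical sphere size — at 10⁶ g (r ≈ 62 cm) a substantial
fraction of the 364 keV photon energy still escapes, since the
energy-absorption length in water is ~30 cm.

## MIRD dosimetry (`mibgdose.dosimetry`)

Activity per gram is `A(t) = uptake(t)/100 × A_inj`; if the input %ID/g was
decay-corrected by the counter, physical activity is recovered with
`e^{−λt}`.  Cumulated activity integrates trapezoidally between samples
with a pure physical-decay tail `A_last/λ` after the last point.  Two
conventions the source data leave open are explicit flags, defaulted as
follows and recorded in every report:

* `decay_corrected` — default **False** (counter values taken as physical
  activity at measurement time).  The ambiguity must be visible, not silent.
* `start_convention` — default **"zero"** (linear rise from (0,0) to the
  first sample); `"flat"` extends the first sample back to injection.

Default tumour mass 0.5 g (mean xenograft volume ~500 mm³ at unit density);
per-group masses are arguments.  `DoseReport` stores the full segment
decomposition and all assumptions so any absolute-dose discrepancy can be
audited; the *fold change* between two groups with the same sphere is
independent of the S-value and of these conventions (tests sweep every
combination).  Absolute doses for the published curves are **not**
reproducible without knowing the per-group tumour masses, the counter's
decay-correction convention and the per-animal averaging scheme, none of
which are derivable from group-summary inputs; the package therefore treats
the fold-change claim as the reproducible quantity and exposes the
assumptions behind any absolute number it prints.

## DCE-MRI analysis (`mibgdose.imaging`)

Normalised enhancement is relative enhancement
`(S − S̄_pre)/S̄_pre` (mean of all pre-injection frames as baseline;
`S/S̄_pre` available by flag).  Relative enhancement is scale-free —
invariant to any positive rescaling of the raw signal — and makes the
zero-baseline invariant testable.  The session summary is the mean of the
normalised values from the injection frame to the end of the series
(peak available by flag); the mean was chosen over the peak because it uses
the whole washout plateau and is insensitive to single-frame noise.
Session contrasts use a paired two-sided t-test by default (the same
animals are imaged longitudinally; n = 3).  Tumour volume is
Σ(slice area) × slice thickness, matching the manual-delineation protocol
(0.33 mm slices in the emulated acquisition).

## Outcome statistics (`mibgdose.stats`, `mibgdose.survival`)

* Two-sample t-tests are computed from summary statistics (mean/SD/n);
  pooled Student by default, Welch by flag.  Degenerate convention: both
  SDs zero gives p = 1 for equal means, p = 0 otherwise.  No
  multiple-testing adjustment (unadjusted pairwise reporting).
* One-way ANOVA is the standard between/within decomposition (delegated to
  scipy), with degrees of freedom reported.
* Kaplan–Meier is implemented directly (the estimate object exposes the
  at-risk table, plateau, median and restricted mean); ties are handled by
  processing events before censorings at equal times.  lifelines serves as
  an independent cross-check in the tests, and log-rank comparisons in the
  pipeline use lifelines.
* The Weibull model is the accelerated failure time parameterisation
  `log T = μ + x'β + σW` (shape k = 1/σ, scale e^μ; treatment coefficients
  are log-time ratios).  The censored MLE uses an analytic gradient with
  BFGS followed by Newton polishing; convergence is declared at gradient
  norm < 10⁻⁸, and the covariance of the estimates is the inverse observed
  information (plain covariance-based standard errors; no quasi-variance
  presentation).  `fix_shape=1` reduces to the exponential model, whose
  closed-form MLE (total time / events) the tests verify to 10⁻⁸.
  One note on implementation choice: an in-package MLE was written because
  the fixed-shape constraint and the gradient-norm convergence contract are
  not available through the installed survival libraries; lifelines'
  unconstrained Weibull fitter is the independent oracle in the tests.

Survival time is measured from treatment start; censoring is at day 53.

## Synthetic cohort generator (`mibgdose.synth`)

The generator emulates the *statistical structure* of the emulated study,
not its biology:

* **Biodistribution** — per-timepoint truncated-normal draws around the
  published group means/SDs (2/4/24/48/72 h; n = 3 per time point, n = 2 at
  72 h), cross-sectional animals per time point as in a terminal-excision
  design.  No kinetic model links time points (only per-timepoint summaries
  exist to calibrate one), and uptake is generated independently of tumour
  size.
* **Growth** — per animal, `V(t)` is a deterministic profile (lognormal
  baseline around 500 mm³; optional pre-treatment drift; a kill factor
  ramping linearly to a lognormally dispersed surviving fraction; exponential
  regrowth at 0.095/day after a Gaussian per-animal delay) times mean-one
  lognormal measurement noise, sampled at the imaging days
  (0, 6, 7, 13, 17, 20, then weekly to 53).  The endpoint event is the first
  imaging day with measured volume ≥ 800 mm³; otherwise the animal is
  censored at day 53.  A per-animal Bernoulli "complete regression"
  branch (probability 0.2 for the EBRT-then-MRT schedule, 1/3 for
  MRT-then-EBRT) reproduces the observed fractions of animals that never
  regrew.  Surviving-fraction means are set so the expected day-6 percent
  change equals the published group values (−65% EBRT, −91% EBRT-then-MRT,
  −2% MRT-then-EBRT, ~+7% MRT).  One published pair of control summaries is
  internally inconsistent under exponential growth (a +52% day-6 mean from
  500 mm³ cannot put every animal past 800 mm³ by day 7); the generator
  prioritises the endpoint timing — every control tumour should reach
  800 mm³ by day 7 in ≥ 95% of seeds — which puts the simulated control
  day-6 change near +77%.
* **DCE** — 60 frames at 9 s, injection at frame 12, gamma-variate bolus on
  a constant baseline, Gaussian frame noise, lognormal animal- and
  session-level amplitude jitter.  The tumour bolus multiplier is 1.0 /
  2.0 / 1.8 at baseline / 24 h / 72 h; the muscle multiplier is fixed at 1
  across sessions.  The 24 h effect size was fixed, by simulation across
  seeds before freezing the defaults, so that the paired baseline-vs-24 h
  test at n = 3 is significant in ≥ 90% of seeds while the 24 h-vs-72 h
  contrast usually is not — matching the reported significance pattern.

All generators are pure functions of (config, seed) with substreams derived
from a single global seed; datasets regenerate byte-identically.  Passing
tests on these cohorts demonstrates that the analysis chain recovers the
structure the generator encodes — it says nothing about new animals, about
kinetic coupling between uptake and tumour size (absent by construction),
or about growth dynamics other than piecewise-exponential.

## Pipeline and reproducibility (`mibgdose.pipeline`)

`run_all` writes the synthetic CSVs, the three study reports and a manifest
(seed, package version, config snapshot, SHA-256 of every input CSV, output
paths); re-running with the same seed reproduces every report exactly.
The qualitative pattern check used for end-to-end evaluation requires
(i) significantly higher uptake in the pre-irradiated group at one or more
of the 24–72 h retention time points (pooled t-test; the enhancement claim
is about the retention phase, and tying it to a single fixed time point
would measure the power of one small-n test instead), and (ii) each
combined schedule superior to each monotherapy by log-rank test with a
larger restricted mean time-to-endpoint.

### File formats

* TAC CSV: `group, animal_id, time_h, pct_id_per_g`.
* Volumes CSV: `group, animal_id, day, volume_mm3`.
* Survival CSV: `group, animal_id, time_days, event` (1 = endpoint reached).
* DCE CSV: `animal_id, region, session, time_s, signal`, with a
  `# injection_index: <int>` comment header.
* Reports: JSON, with physical quantities carrying unit-suffixed keys and an
  assumptions block wherever a convention enters.

## Known limitations

* Dosimetry is self-dose to a uniform sphere: no voxel or non-spherical
  geometry, no cross-organ S-values, no biologically effective dose.
* The electron model omits angular multiple scattering; accuracy degrades
  for spheres comparable to or smaller than the electron range
  (≲ 0.01 g), outside the validated 0.1–10 g span.
* Photon physics omits coherent scattering, fluorescence and bremsstrahlung
  photons; adequate at the 10% level for 29–723 keV in water.
* No pharmacokinetic (Tofts-type) modelling of the DCE data, no image
  processing — inputs are already region-averaged signal series and
  delineated slice areas.
* The Weibull model has no frailty/random effects; group sizes of 3–6 give
  wide treatment-effect intervals, as the reported standard errors show.
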