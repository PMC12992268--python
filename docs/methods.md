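# Methods

This note documents the models, numerical choices and validation design of
`tdnirs`: what each stage assumes, which parameters matter, what the
synthetic cohorts do and do not emulate, and where the design was
genuinely open.

## Photon-migration model

Time-resolved diffuse reflectance of a semi-infinite homogeneous medium is
the closed-form diffusion-equation (DE) solution with image sources,

    R(ρ, t) = (1/2) (4πDv)^(−3/2) t^(−5/2) exp(−μ_a v t − ρ²/(4Dvt))
              × [ z₀ e^(−z₀²/4Dvt) + (z₀+2z_b) e^(−(z₀+2z_b)²/4Dvt) ],

with `D = 1/(3 μ_s')`, `z₀ = 1/μ_s'`, `v = c/n`, and the extrapolated-
boundary distance `z_b = 2AD` using the standard polynomial approximation
for the internal-reflection factor `A(n)`. A zero-boundary variant is
selectable. Two modelling commitments deserve emphasis:

* **`D` excludes absorption.** With `D = 1/(3 μ_s')` the solution
  factorizes as `R = M(t)·exp(−μ_a v t)` with `M` independent of `μ_a`.
  The entire ratio-family inversion rests on this factorization.
* **Scattering is fixed within a recording.** `μ_s'`, geometry and
  refractive index are per-subject inputs; only `μ_a(t)` follows the
  hemodynamics. Units: mm, ps, mm⁻¹, µM.

Asymptotics used as a numerical check: `d ln R/dt → −(μ_a v + 5/(2t))`
for `t ≫ ρ²/(4Dv)`; convergence is slow (the `ρ²/4Dvt²` correction is
still ~2% at 8 ns for ρ = 30 mm), so the tests evaluate it near 40 ns.

## Gating and inversions

Gates are three disjoint windows (defaults 500–1000, 1500–2000,
2500–3000 ps; the instrument's true gate timing is a free parameter of
the analysis). A gated value sums the counts of bins whose centers fall in
the window; partial bins are excluded.

**Per-gate ΔHbO (MBLL).** `ΔOD_i(λ,t) = −ln(I_i(λ,t)/⟨I_i(λ)⟩_rest)` and
`[ΔHbO, ΔHbR]` solves the 2×2 extinction system with per-delay pathlength
`L_i = v·t̄_i` (photon pathlength is proportional to arrival time in a
time-domain measurement; `t̄_i` is the gate-center time, chosen over the
count-weighted mean for simplicity). The shipped extinction table holds
the common literature compilation for 760/850 nm converted to
ln-based mm⁻¹µM⁻¹; it is configurable, and the synthetic generator uses
the same table, so round-trip validations are table-independent.

**Gate-pair μ_a and RHbO.** For a gate pair (a, b) the factorized model
gives `ln(I_a/I_b) = ln(M̄_a/M̄_b) + μ_a v (t̄_b − t̄_a)` up to gate-width
corrections. The default estimator inverts the *gate-integrated* forward
model exactly: the log intensity ratio is tabulated on a μ_a grid
(0–0.1 mm⁻¹, 512 points, 129-point quadrature per gate) and inverted by
monotone interpolation, making the inverse exact for any gate width up to
interpolation error (<0.01%). The closed-form midpoint estimator — solve
the displayed equation with `M` evaluated at gate centers — is available
as `method="midpoint"`; its bias grows smoothly with gate width (≈8% for
the first pair at 500 ps gates, where `M(t)` is steep) and vanishes as
width → 0, which the property tests pin. Estimates below a configurable
floor (10⁻⁴ mm⁻¹) are floored and counted; nonpositive intensities
propagate as missing frames, never interpolated. Absolute `[HbO](t)` then
solves `ε·C = μ_a` at the two wavelengths and `RHbO(t) = HbO(t)/⟨HbO⟩_rest`
(baseline mean 1 by construction). Any per-channel multiplicative gain
cancels twice — in the gate ratio and in the task/rest ratio — which is
the practical appeal of the ratio family.

Instrument-response-function deconvolution is outside the inverse path:
the gates are wide relative to typical IRFs. The generator can stress this
assumption only implicitly (via gate placement); convolving an explicit
IRF is future work.

## Task protocol and responses

The block design is rest 30 s / task 60 s / rest 70 s at 1 Hz
(configurable; typical VFT block designs). The task window is inclusive of
both endpoints so that uniform-grid closed forms (boxcar integral = h·T,
symmetric centroid = T/2) are exact. The baseline window is the pre-task
rest.

**Channel rejection** is deterministic given thresholds (the defaults are
the package's own choices; no canonical values exist): median gated counts
< 100/frame ("low_counts"), baseline CV > 15%, pre/post rest-level shift
> 15% ("drift"), > 5% burst frames, and for ratio series a baseline offset
> 0.2 from the reference. Burst detection uses robust z-scores of *second*
differences — first differences of smooth hemodynamic transitions are
indistinguishable from spikes on a noise-free recording — with the robust
scale floored at 2% of the signal SD so that zero-noise recordings are
never flagged.

**Response classification** is per channel and per parameter family: a
channel is *activated* iff its task-window mean deviation from the rest
reference (1 for ratios, 0 for changes) is strictly positive, otherwise
*suppressive* (a tie is a non-positive deflection). A channel with more
than half its task-window frames missing joins neither class. Class means
ignore missing frames pointwise; an empty class yields a constant
reference curve with an empty flag, and its features are emitted as
missing rather than zero. Whether channels should be classified once
globally or per family is genuinely open; per family was chosen because
each family is analyzed and plotted separately, and the choice is flagged
for sensitivity analysis.

## Features and statistics

Integral: trapezoidal area of (curve − reference) over the task window,
signed, so suppressive responses are negative. Centroid:
`Σ t·|x−ref| / Σ|x−ref|` relative to task onset; the absolute weight is
what gives a suppressive response a meaningful timing. Both are invariant
to frame-rate refinement to <1%.

Group selection uses Welch's unequal-variance two-tailed t-test per
feature at α = 0.05 (pooled-variance Student as option; the exact test
variant used in comparable studies is usually unstated). No multiplicity
correction by default — raw per-feature p-values mirror standard practice
in this literature — with Benjamini–Hochberg behind a flag. Samples are
subject × session rows treated as independent for group selection,
mirroring the two-session 54-vs-54 design; this is anticonservative under
nonzero between-subject variance, which is why the calibration studies
below use single-session cohorts. Test–retest comparison is a paired
two-tailed t-test across subjects per feature, with p = 1 by convention
for identically zero differences.

Classification: linear SVM (C = 1), LDA with equal priors, decision trees
capped at 3 splits (4 leaves), Gaussian naive Bayes. Stratified five-fold
CV with a fixed seed; rows are canonicalized by sample id before
splitting, so reports are invariant to row order. Train-fold z-scoring is
on for all models except trees. Same-subject sessions may land in
different folds — deliberately, to mirror the 108-sample design — and a
grouped-CV mode exists for leakage-aware analysis. Resubstitution accuracy
and fold mean ± SD (ddof = 1) are reported with integer confusion counts;
2-feature models export a dense decision-boundary grid spanning the
observed ranges ±10%.

## Synthetic cohorts: what they emulate, and what they don't

The generator's defaults are the study conditions: 27 subjects per group
× 2 sessions, 22 channels, per-channel corruption probability 0.34,
session effect 0. Response curves are differences of two gamma-variate
bumps on the ratio scale, rescaled so the peak deviation equals the
programmed amplitude exactly at onset + latency + time-to-peak, with a
12% undershoot. Between-subject variability is lognormal on amplitudes
(σ = 0.35) and Gaussian on timings (3–4 s); channels jitter around their
subject (20% amplitude, 1 s latency). Seeding is counter-based per
(group, subject, session), so enlarging a cohort never reshuffles
existing subjects.

Programmed group differences encode the depression-effect directions:
stronger early-pair suppression (more negative F3), stronger and earlier
late-pair activation (larger F7, earlier F8), earlier channel-average
timing (F6, F12). Magnitudes were calibrated once so that the full
pipeline reproduces the reported headline classification performance —
linear discriminant analysis on {F7, F8} lands at ≈76% mean five-fold CV
accuracy, inside the pre-registered 65–85% acceptance band. (Published
per-feature p-values in this design imply d ≈ 0.4–0.6, which under
Gaussian assumptions cannot produce 75% two-feature accuracy; reproducing
the classifier result was chosen as the binding constraint.)

Corruption draws one of three artifact archetypes per corrupted channel —
dead channel (gain collapse), drifting gain (±30–50% ramp), burst
outliers (≈8% of frames) — chosen to exercise every rejection rule.

Rendering modes: `hbo_direct` emits ratio series directly (fast; used for
replicated statistical studies); `tpsf` renders full photon histograms
(50 ps bins to 4 ns, default budget 10⁶ expected counts/frame/channel/
wavelength) as Poisson draws around the DE reflectance driven by the
programmed HbO trajectory through the extinction table, with
`ΔHbR = −0.25·ΔHbO` and baselines 60/25 µM. One physical trajectory
cannot carry family-specific effects, so TPSF mode renders the late-pair
family's parameters and serves as the physics-validation path; both modes
draw identical per-channel parameters for a given seed, which is what the
cross-mode parity test exploits.

Not emulated: systemic physiology (Mayer waves, respiration, superficial
contamination), motion beyond spike bursts, spatial channel topology,
education/medication confounds, and any non-Gaussian heterogeneity of
real clinical populations. Passing tests therefore demonstrate that the
*pipeline* is correct and calibrated under its stated model — not that
real recordings would yield these accuracies.

## Validation design

* Physics: independent re-implementation of the closed form; MBLL
  synthesis/inversion round trip at machine precision; gate-pair μ_a
  recovery within 2% (default inverse: <0.01%); end-to-end TPSF → RHbO
  recovery within 3×10⁻⁷ noise-free.
* Calibration: null-effect single-session cohorts give per-feature
  selection rates statistically compatible with 5% over 200 replicates;
  permuted labels give chance-level CV accuracy.
* Effects: the five programmed sign relations replicate in ≥95% of
  default cohorts; DA {F7, F8} CV accuracy falls in 65–85% in ≥80% of 25
  replicates.
* Determinism: a fixed seed makes the photon-level simulate→classify run
  byte-identical; the small-cohort end-to-end run completes in well under
  a minute on one CPU.

Monte-Carlo problem sizes in the test suite (cohort counts, subjects per
group) were scaled to keep the full suite around two minutes while leaving
every binomial check adequately powered; the acceptance script uses
15 replicate cohorts for the CV estimate and 120 null cohorts for the
calibration rate.

## Known limitations

* The ratio-family derivation assumes all absorption changes are
  hemoglobin; background chromophores would bias absolute concentrations
  (largely cancelling in the ratio, but not exactly).
* A single `μ_s'` serves both wavelengths; wavelength-dependent scattering
  would require per-wavelength optical property inputs.
* The midpoint μ_a estimator's first-pair bias at wide gates is
  documented rather than corrected; use the default interpolated inverse.
* Table-style resubstitution accuracies are reported as such; whether
  comparable published single-accuracy figures are resubstitution or
  held-out is ambiguous, and resubstitution was assumed.
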