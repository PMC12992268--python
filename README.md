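# tdnirs

Analysis pipeline for **time-domain functional near-infrared spectroscopy
(TD-fNIRS)** studies of prefrontal hemodynamics in depression, from raw
photon time-of-flight histograms to visualized two-feature classifiers.

TD-fNIRS instruments record, per channel and wavelength, the temporal
point spread function (TPSF) — the histogram of photon arrival times after
an ultrashort light pulse. Early-arriving photons sample shallow tissue;
late photons sample deeper cortex. This package implements the analysis
chain used to ask whether verbal-fluency-task (VFT) hemodynamics separate
people with major depressive disorder (MDD) from healthy controls (HC):

1. **Delay gating** — TPSF counts are integrated in three delay windows
   (defaults 500–1000, 1500–2000, 2500–3000 ps), giving per-gate intensity
   time series `I_i(t)`.
2. **Hemoglobin inversion** — two parameter families per recording:
   * `ΔHbO_i` (µM): per-gate modified Beer–Lambert law,
     `ΔOD_i = −ln(I_i/⟨I_i⟩_rest)`, solved through the 2×2 extinction
     system with a per-delay pathlength `L_i = v·t̄_i`;
   * `RHbO_i` (dimensionless): the task/rest HbO **ratio**. The
     diffusion-equation reflectance of a semi-infinite medium factorizes as
     `R(ρ,t) = M(t)·exp(−μ_a v t)`, so the log-ratio of two delay gates is
     an affine function of the absorption coefficient; inverting it per
     frame and wavelength yields absolute `[HbO](t)`, and
     `RHbO(t) = HbO(t)/⟨HbO⟩_rest`.
3. **Response separation** — after channel-quality rejection (poor
   optode–scalp coupling corrupts roughly a third of channels in speech
   tasks), retained channels are split into an *activated* class
   (task-window mean above the rest reference) and a *suppressive* class
   (below it), plus the channel-wise average.
4. **Features** — each response curve reduces to its task-window
   **integral** (signed response intensity, units·s) and **centroid**
   (|deviation|-weighted mean time, s after task onset). The twelve
   ratio-family features carry canonical names F1–F12 (e.g. F3 = integral
   of suppressive RHbO₁, F7/F8 = integral/centroid of activated RHbO₂,
   F12 = centroid of channel-averaged RHbO₂).
5. **Selection & classification** — two-tailed Welch t-tests at α = 0.05
   select discriminative features; linear SVM, linear discriminant
   analysis (DA), shallow decision trees (≤3 splits) and Gaussian naive
   Bayes are scored by resubstitution accuracy and stratified five-fold
   cross-validation, with exportable 2-D decision-boundary grids.

Because subject-level recordings from such studies are generally not
redistributable, the package ships a first-class **synthetic cohort
generator** (`tdnirs.synthetic`) that emulates the full study design —
two groups × two sessions × 22 channels, block-design VFT timing,
activated/suppressive hemodynamic response curves with programmable group
effects, Poisson photon noise, and a configurable fraction of corrupted
channels — either directly at the ratio level or as full TPSF photon
histograms rendered through the diffusion model. Every downstream stage is
validated against this generator's ground truth.

## Worked example

Run the full pipeline on a default synthetic cohort (27 subjects per
group, 2 sessions each, 34% channel-corruption probability):

```python
from tdnirs import RunConfig, run_pipeline
out = run_pipeline(RunConfig(seed=1), "demo_run")
```

or from the shell: `tdnirs all --out demo_run --seed 1`.

The run directory contains `features.csv` (108 samples × F1–F12),
`selection.csv`, `reports/*.json`, and optional boundary figures. With
seed 1 the feature-selection stage prints (excerpt):

```
feature         t            p  selected
     F3  5.037966 2.061001e-06      True
     F6  4.445174 2.199352e-05      True
     F7 -4.873100 5.199967e-06      True
     F8  3.231971 1.640146e-03      True
```

i.e. the suppressive early-pair integral (F3), the channel-average timing
(F6) and the activated late-pair integral/centroid (F7, F8) separate the
groups, with the programmed directions: the depression group shows a
stronger suppressive deflection, a larger activation integral and earlier
response timing. The DA classifier on {F7, F8} reports

```
{"accuracy": 75.0, "sensitivity": 74.1, "specificity": 75.9}
cv: mean 71.2% ± 7.3% over 5 folds
```

and the channel-rejection log shows `7.4 ± 2.4` of 22 channels rejected
per recording (34%), matching the programmed corruption rate.

## Layout

```
src/tdnirs/
  protocol.py    rest/task/rest block timing on the frame grid
  physics.py     DE reflectance, gating, MBLL, gate-pair mua, RHbO
  synthetic.py   cohort generator with ground truth
  responses.py   channel rejection, activation/suppression separation
  features.py    integral/centroid features, t-test selection, test-retest
  classify.py    four classifiers, 5-fold CV, boundary grids
  pipeline.py    RunConfig + end-to-end orchestration
  io.py          HDF5 TPSF container, CSV/JSON artifacts
  cli.py         `tdnirs` command-line interface
```
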