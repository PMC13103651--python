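# Methods

This note documents the models, conventions and numerical choices behind
`thalatarget`, and what the synthetic studies do and do not demonstrate.

## Problem setting

Seed-based functional connectivity (FC) maps correlate every brain location's
BOLD time series with the mean signal of a seed region — here a bilateral
thalamic seed (label indices 231–246 of a volumetric atlas). Candidate
cortical targets for non-invasive brain stimulation (NIBS) are taken to be
the extrema of such maps: a *normative* analysis finds the positive and
negative peaks of a cohort-average map once and evaluates those fixed sites
in every patient, while an *individual* analysis finds each patient's own
peaks. A virtual-stimulation step places a coil over a site, masks the
cortical patch receiving the strongest field, and asks whether
treatment-induced FC changes inside that patch track symptom changes
(Chalder 14-item fatigue totals, FS14).

The clinical datasets this design was developed on are not public, so the
package is built synthetic-first: every analysis runs against generated
cohorts whose connectivity–fatigue structure is planted and therefore
recoverable, and correctness is judged by parameter recovery rather than by
reproducing any particular clinical value.

## Synthetic cohort model

**Geometry.** The cortical stand-in is an icosphere (default subdivision 4,
2562 vertices, radius 50 mm — between-vertex spacing ≈ 3.3 mm, comparable to
a downsampled template surface), with a coarser 60 mm scalp icosphere and a
16³ volume grid of 7 mm voxels whose 16 central voxels carry the thalamic
seed labels.

**Connectivity field.** The group-level field is defined in Fisher-z units
as two Gaussian bumps on the sphere: a negative bump (amplitude 0.5, angular
σ 0.25 rad) centred on the mesh vertex nearest the left-lateral-occipital
direction and a positive bump (same size) toward the anterior midline.
Correlations are obtained as ρ = tanh(z), so they remain in (−1, 1) for any
jitter. Per-subject fields add a smooth random field: real spherical
harmonics of degree 1–4 with i.i.d. coefficients, scaled so the per-vertex
SD is exactly `jitter_sd` (default 0.4 z) everywhere (the addition theorem
makes the basis's sum of squares direction-independent). The source study
does not report between-subject FC variance; 0.4 was chosen once so that
(a) individual peak locations scatter widely (low cross-subject overlap, the
phenomenon the individual analysis exhibits) while (b) a 100-subject average
still pins the group peaks, and it is documented here rather than presented
as data-derived.

**BOLD synthesis.** Location v's series is
`y_v = ρ_v·s + sqrt(1 − ρ_v²)·η_v` with the seed signal `s` and noises `η_v`
independent, unit-variance and band-limited to 0.01–0.08 Hz (white noise
shaped by the squared-magnitude response of a 4th-order Butterworth, i.e.
the zero-phase filter gain, applied spectrally). The expected Pearson
correlation of `y_v` with `s` is then exactly ρ_v, and the analysis
band-pass (0.01–0.1 Hz) leaves the planted correlations intact. Band
limitation matters statistically: the null sampling variance of a Pearson
correlation between two such series is κ/n rather than 1/n, with
κ = Σ_k ρ(k)² ≈ 3.6 at TR = 2 s and 230 frames. All tests that reason about
sampling spread use this autocorrelation-corrected value (computed from the
filter response, not fitted).

**Confound structure.** Motion is a small random-walk drift plus sustained
translation steps ("spikes", Poisson rate 3/run, 0.7 mm) that exceed the
0.5 mm censoring threshold; three tissue series (global, WM, CSF) are
band-limited noise. Contamination is injected as a random linear combination
of the full 36-parameter regressor family (columns standardized, amplitude
0.7), so it lies exactly in the span the nuisance regression removes — a
deliberate design that makes denoising provably sufficient rather than
approximately so.

**Phenotypes.** FS14 totals are generated on the 0–14 binary-scored scale:
`FS14_i = clip(round(a + b·z_i(peak) + ε_i), 0, 14)` where `z_i(peak)` is
the subject's *true* Fisher z at the planted negative vertex. Group means/SDs
(patients 10.35 ± 2.90, controls 4.73 ± 3.96; HAMD analogues likewise)
follow the reference demographics as study conditions. When a target
coupling r is specified (patients: −0.3), the noise is orthogonalized
against `z_i(peak)` in-sample (Gram–Schmidt), so the planted correlation is
exact before rounding/clipping; rounding and ceiling clipping attenuate the
realized magnitude by roughly 1–3%. "Planted r" in this package always means
this exact in-sample construction.

**Longitudinal arm.** Treatment shifts each patient's field by
`δ_i·g(u)` inside a Gaussian region g (angular σ 0.4 rad) centred on the
negative peak, with `δ_i ~ N(0.15, 0.20)` z. The FS14 change is planted
against δ_i (equivalently the region-mean true Δz, which is proportional)
with target r = −0.4, SD 2.5 and mean −3 (symptomatic improvement). The δ
spread 0.20 was set so that between-subject variation in the true regional
change dominates the common-mode measurement noise of masked means; with the
original smaller spread the planted coupling would be attenuated to ≈0.65 of
its value before it ever reached the statistics, which would test the
generator's noise floor rather than the analysis.

## Preprocessing conventions

Order: drop the first 10 frames → framewise displacement (FD) → censor →
36-parameter regression on retained frames → linear interpolation of
residuals across censored frames → zero-phase band-pass → re-apply the
censoring mask → spatial smoothing. Specific choices, fixed because
published pipelines differ:

- **FD** is the backward-difference sum over the six rigid-body parameters,
  rotations converted to arc length at a 50 mm head radius; FD₀ = 0.
- **Censoring** is strict (`FD > threshold`), so a frame at exactly 0.5 mm
  is retained; censoring only edits the retained-frame mask.
- **Regression** always adds an intercept (37 design columns); collinear
  columns are dropped via pivoted QR with a logged warning. Residuals are
  orthogonal to the confounds to < 1e-8 and regression is idempotent.
- **Band-pass** is the squared-magnitude (forward–backward) response of a
  4th-order Butterworth applied in the frequency domain, so the realized
  gain equals the documented response exactly at the DFT frequencies; DC is
  removed entirely, 0.05 Hz is retained ≥ 80%, 0.2 Hz attenuated ≥ 80% at
  TR = 2 s. Censored rows are interpolated beforehand and never re-enter
  statistics.
- **Smoothing** uses σ = FWHM/(2√(2 ln 2)) per axis in voxel units
  (volume; nearest-edge padding so constants are preserved) or calibrated
  iterative neighbour averaging (surface — an extension; the reference
  chain smooths in volume space only).
- Two denoising recipes exist and are deliberately not harmonized: "36p"
  (in-house cohorts) and "gsr" (motion + global signal family, 28 columns,
  normative cohorts), mirroring the asymmetry in how normative datasets are
  typically preprocessed.

## Targeting conventions

- Volume→surface transfer is plain trilinear sampling at vertex
  coordinates; vertices outside the grid take the nearest in-grid value and
  are flagged.
- Peaks are the global argmax/argmin over non-excluded vertices; ties break
  to the lowest vertex index for determinism. Individual-mode peaks are
  unrestricted (whole-mesh extrema).
- A "surface-based sphere" is a geodesic disc: vertices within the given
  edge-graph shortest-path distance (Euclidean edge weights, Dijkstra).
  Graph distance slightly overestimates true polyhedral geodesics; the
  oracle tests use the same metric, and no exact-geodesic algorithm is
  attempted.
- Sphere-level FC is the unweighted mean over member vertices (chosen over
  the median for linearity with map averaging).
- The cross-subject overlap rate is not a standard quantity; the default
  reading is max vertex coverage (the maximum over vertices of the fraction
  of subjects whose sphere contains it), with mean pairwise Jaccard
  available as an alternative. Neither is presented as the reference
  definition, which is unstated.

## Stimulation-field surrogate

The finite-element E-field stage (tissue conductivities, coil model) is out
of scope. What downstream logic needs is a field that peaks under the coil
and decays with distance, so the surrogate is isotropic Gaussian decay
`exp(−d²/(2σ²))` from the coil position (the scalp vertex nearest the
cortical target, nearest-neighbour projection with lowest-index
tie-breaking), with σ = 20 mm chosen so the top-30% mask is a contiguous
patch at head scale. The mask is by vertex count — `ceil(fraction·N)`
highest-field vertices, ties admitted lowest-index-first — because the
top-30% rule's base set is otherwise ambiguous. Field units are arbitrary;
no V/m calibration is claimed.

## Statistics

Independent two-sample t tests default to pooled variance (Welch
available), two-tailed, α = 0.05; Pearson correlations report two-tailed p
and a Fisher-transform 95% CI (`z ± 1.96/√(n−3)`). The Δ–Δ analysis is a
Pearson test on paired differences. No multiple-testing correction is
applied anywhere; reports state the number of tests performed. Of the
demographic summary rows used as anchors, only the age row reproduces its
printed t (1.37) from the printed means/SDs under standard formulas; the
BMI, HAMD, FS14 and gender-χ² entries do not, under either pooled or Welch
variants, and are therefore not asserted — the inconsistency is noted, not
repaired.

## Problem sizes and calibration checks

The recovery studies run at the study's own sample sizes on desk-scale
geometry: 20 generator seeds × 100 patients (240 frames, volume mode,
contamination on) for peak and coupling recovery; 20 seeds × 35 patients
(surface mode) for the longitudinal Δ–Δ sign; 1000 replicates × 12+12
subjects on a 42-vertex mesh for type-I calibration (the t test's size does
not depend on n, so small replicates calibrate the same quantity). Expected
outcomes, all computed by the tests and `scripts/acceptance.py` rather than
asserted from memory: negative peak within 6 mm geodesic of the planted
vertex in ≥ 90% of seeds; planted coupling recovered within its analytic
95% band in ≥ 90% of seeds and detected (r < 0, p < 0.05) at the recovered
vertex in ≥ 80%; Δ–Δ sign correct in ≥ 90%; rejection rate 5 ± 2%.

The detection (power) check deserves a caveat: with measurement attenuation
the effective coupling is ≈ −0.29, whose analytic power at n = 100 is
≈ 0.85, so the ≥ 80%-of-20-seeds bar sits close to its own expectation and
a fixed seed set can land near the boundary; the test seed was fixed before
the studies were first run and is not tuned.

## What passing does and does not show

The generator realizes exactly the statistical structure the analysis
assumes: stationary band-limited Gaussian noise, contamination inside the
regression span, spatially smooth between-subject variation, a coupling
that is linear in true peak FC. Passing therefore demonstrates that the
pipeline recovers planted structure under its own assumptions at realistic
sample sizes — not that real BOLD (with spatially correlated, non-Gaussian,
non-stationary noise, imperfect registration, and confounds outside the
36P span) would behave as well. Scanner artifacts, multi-site effects,
anatomical variability and item-level questionnaire structure are
deliberately not simulated.

## Known limitations

- Graph geodesics on an icosphere overestimate surface distance by a few
  percent; at 6 mm radius this changes sphere membership only at the rim.
- The surrogate field ignores tissue anisotropy and coil geometry; only the
  masking logic downstream of a field map is exercised.
- Surface-mode smoothing is an approximate FWHM calibration (iterative
  averaging), adequate for the constant-preservation and monotone-smoothing
  contracts it is tested against, not for quantitative FWHM matching.
- Directory-based (non-synthetic) cohort ingestion is provided at the
  per-subject level (`thalatarget.io`); full on-disk cohort orchestration
  is intentionally minimal since no compatible public dataset accompanies
  the package.
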