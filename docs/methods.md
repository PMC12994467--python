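# Methods

## The conversion problem

A surface ECG lead is, to first order, the scalar projection of the
cardiac dipole **v**(t) ∈ ℝ³ onto a fixed lead vector: ℓ(t) = **c**ᵀ**v**(t).
The dipole trajectory is a property of the myocardium and does not change
with body position; the lead vectors do, because turning a patient prone
moves the precordial electrodes onto the back. Prone-to-standard
conversion is therefore a change of basis: estimate something equivalent
to **v**(t) (explicitly, as in the VCG route, or implicitly, as in the
regression/tree routes) from the prone lead set and re-project it onto
the supine lead vectors.

## Synthetic cohort generator

The generator makes that physics literal. Per subject it builds one
dipole loop as a sum of Gaussian kernels — one 3-vector kernel each for
P, Q, R, S, T (plus an optional ST-offset kernel), with centre and width
in seconds — and projects the same loop through two 12×3 lead-field
matrices:

* **Supine field**: the classic Dower lead vectors for the eight
  independent leads; III/aVR/aVL/aVF rows derived from I and II so the
  Einthoven/Goldberger identities hold by construction.
* **Prone field**: limb rows identical (limb electrodes do not move);
  precordial rows mirrored — prone V1 = −(supine V4 row), prone V2 =
  −(supine V2 row), prone V4 = −(supine V1 row), prone V3/V5 the means of
  their neighbours, prone V6 unchanged (same anatomical site). This is a
  stylised stand-in: no quantitative prone electrode geometry is
  published, so the field is the simplest matrix consistent with the
  inverse-pairing observation, and it is config-replaceable.

Diagnosis classes perturb the kernels: ST elevation/depression add a
broad ST-offset kernel along (±) the anterior direction; old anterior MI
scales the R kernel to 20% and amplifies Q and S (QS patterns); bundle
branch blocks widen the QRS kernels and add a terminal-delay kernel
(leftward-posterior for LBBB, rightward-anterior for RBBB, giving RsR′ in
V1); left anterior hemiblock rotates the QRS vectors −0.9 rad in the
frontal plane. Subject-level variability multiplies kernel vectors by
clipped Gaussian factors (±18%), rotates the frontal axis (σ = 0.12 rad)
and jitters widths (±10%).

Study-condition defaults: 70 subjects, 590 prone cycles total (7–10
beats per subject, adjusted to the exact total), 10 s records at 500 Hz,
class mix matching the development cohort counts (24 normal, 7 ST
elevation, 8 old MI, 11 ST depression, 4 CLBBB, 11 CRBBB/RBBB, 5 LAH),
covariates from truncated normals around the cohort medians (age 58 y,
height 168 cm, weight 67 kg, chest 90.3 cm, waist 86.4 cm, 58.6% male).
Default measurement noise is 0.02 mV white Gaussian per lead; the
recovery oracles run at noise 0.

What the generator does *not* emulate: respiratory and motion artefacts,
baseline wander, beat-to-beat variability within a subject, non-dipolar
(higher-order) potentials, and any true torso volume-conductor geometry.
Consequently, passing the exact-recovery and floor tests shows the
implementation is correct and self-consistent — not that clinical
accuracy at the published level would be achieved on real recordings.

## Delineation

R peaks: 5–25 Hz band-pass, squared-derivative energy envelope (150 ms
moving RMS), candidate peaks ≥ 200 ms apart, adaptive threshold at 40% of
the largest candidate, snap to the local raw-signal extremum. QRS bounds:
slope activity |dx/dt| on the 60 Hz low-passed signal falling below 2% of
the local maximum slope for a sustained 30 ms, searched ≤140 ms left /
≤130 ms right of R — slope, unlike amplitude, is blind to ST-segment
deviation, and the quiet-run requirement bridges the gaps between QRS
deflections while stopping in the isoelectric segments. T offset: the
tangent rule (steepest post-peak slope of the ≤15 Hz-filtered T,
intersected with the baseline), which for a Gaussian T lands analytically
at μ_T + 2σ_T; the generator's ground truth uses the same analytic
definition while wave onsets/offsets use the 2.5σ points (≈4% of kernel
peak, the conventional visible-departure level). P onset: largest
baseline deviation in [R−300 ms, QRS onset), flat below 0.05 mV, onset at
the 8% down-crossing. Baseline: median of the diastolic stretch
[R−290 ms, R−220 ms]. Fiducials are detected once per beat on lead II
(fallback V2) and shared by all leads.

ST level is read at J+60 ms relative to the P-R baseline (clinical
convention; the measurement point is not otherwise specified). Amplitudes
are measured per cycle, with P and T reported as bidirectional extrema.

## The three routes and the hybrid

*Direct*: pooled OLS per target lead over all time points of the eligible
(default healthy) subjects; predictors are the paired prone lead, sex and
age. *VCG route*: pooled OLS of X, Y, Z on the 12 prone leads + Male,
Age, Height, Weight. On noise-free cohorts the 12 prone-lead columns have
rank 3 (all are projections of one dipole), so the design is rank
deficient; the fit returns the minimum-norm least-squares solution with a
warning — predictions, and hence R², are unaffected. The published
coefficient table is packaged as a read-only fixture flagged
``scale-unknown`` (its predictor scaling and intercepts are unreported)
and excluded from amplitude claims. The Dower matrix uses the classic
published values; the Uijen matrix is a clearly labelled synthetic
stand-in (the original table was not available when the fixture was
assembled) and both are config-replaceable.

*Tree route*: segment windows are piecewise-linearly time-normalised to
fixed lengths (PR 50, QRS 60, ST-T 200 points at 500 Hz) so feature and
target rows align between the non-simultaneous prone and standard beats;
each prone beat pairs with the subject's representative (median-index)
standard beat. mtry = 6 is the regression default p/3 at p = 18 features.
nrounds for boosting is config-exposed (default 500; the reproduction
protocol uses 1000). Reconstructed beats map per-segment predictions back
to the native windows, with a 10 ms decaying correction at each window
onset that removes the prediction step at the boundary without touching
the neighbouring window; outside [P onset, T offset) baseline 0 is
emitted.

*Hybrid*: per lead and segment, the forest beat is rescaled to the
VCG-route amplitude as out = base + s·(rf − base), where s is the ratio
of segment peak-to-peak amplitudes clamped to [0.2, 5], forced to 1 when
either peak-to-peak is under 0.05 mV, and base is the forest beat's P-R
window mean. Scaling around the baseline (rather than raw zero) makes the
baseline-referenced QRS lobe ratios exactly scale-invariant, which is the
point of using the forest's morphology. The combination granularity (per
segment, not per wave or per beat) is a design choice; the source
procedure is described only as a "scaled combination". Note the limits of
morphology preservation: classes defined by *absolute* thresholds can
legitimately change when amplification lifts a sub-threshold deflection
across the 0.05 mV visibility level or an ST level across the
elevation/depression bounds — that is the amplitude correction working,
not a morphology error. Pattern structure (letter order and case) is
invariant away from those crossing bands.

## Morphology nomenclature

QRS deflections are zero-crossing-separated lobes exceeding 0.05 mV
(0.5 mm at standard gain); letters by polarity and order (Q/q before the
first positive, R/r positive with ′ for repeats, S/s after), upper case
iff the lobe exceeds half the largest lobe (strict inequality, so a lobe
at exactly half stays lower case: "RsR′" for +0.5/−0.3/+0.6), a single
all-negative deflection is "QS". P/T classes: flat below 0.05 mV,
biphasic when both polarities exceed it, else upright/inverted. ST:
elevated ≥ +0.10 mV, depressed ≤ −0.05 mV at J+60 ms. An absent P
(undetected) is its own class, distinct from flat. Similarity is the
proportion of index-aligned descriptor pairs agreeing on all four fields;
per-lead and per-field breakdowns are both exposed since the source's
aggregation level is ambiguous.

## Evaluation

RMSE, MAE and R² = 1 − SS_res/SS_tot (a constant observed series raises
``DegenerateTarget`` rather than returning an undefined R²). Bland–Altman
uses differences converted − original, bias ± 1.96·sd (sample sd, n−1).
Diagnostic metrics are one-vs-rest per class; AUC is rank-based for
scores and the single-threshold trapezoid (sens + spec)/2 for hard expert
labels; confidence intervals are percentile bootstrap over subjects
(respecting within-subject correlation), n_boot default 1000.

## Reproduction protocols and problem sizes

`scripts/acceptance.py` and the acceptance tests share the protocols in
`pronecg.studies`, all at the study scale of 70 subjects / 590 cycles /
500 Hz with noise 0: (a) the VCG regression refitted on targets generated
by a fixed random 16×3 map (pooled n = 350 000 time points); (b) the
direct route fitted on healthy subjects and scored on everyone (same
pooled n); (c) forest and boosted-tree QRS models for lead V1 trained on
the 56-subject side of the 8:2 participant split and scored on the
14-subject side (≈6 900 held-out rows). These sizes run in about a
minute on one CPU. Unit tests use smaller cohorts (6–30 subjects) chosen
to keep the default suite fast while preserving the properties under
test; the tree-generalisation tests need ≥ 30 subjects so held-out
amplitude ranges fall inside the training support — with only a handful
of subjects, axis-aligned trees extrapolate flat and scores collapse,
which is expected behaviour, not a defect.

## Known limitations

* The prone lead field is stylised; real prone geometry varies with
  habitus, and the covariates' role in the synthetic cohort is weaker
  than in reality (targets are exact functions of the prone leads alone
  at noise 0).
* The Uijen matrix fixture is a synthetic stand-in, and the packaged
  cohort coefficient table cannot be used for amplitude predictions
  (scale-unknown).
* Delineation is tuned for sinus-rhythm morphologies of the generator's
  kernel family; ectopy, pre-excitation and pacing are out of scope.
* Morphology thresholds follow clinical convention (0.05 mV flat, half
  for case, +0.10/−0.05 mV ST) because the source names the label sets
  but no thresholds.
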