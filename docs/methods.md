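# Methods

`mcgkit` implements a magnetocardiography (MCG) rule-out analysis as a
reusable, fully synthetic-testable pipeline: waveform simulation from a
current-dipole forward model, preprocessing of unshielded multichannel
recordings into an R-centered averaged beat, extraction of the 10
magnetic-field-map (MFM) predictors of ventricular depolarization, and
diagnostic evaluation of elastic-net rule-out models with repeated
stratified cross-validation and prevalence-adjusted negative predictive
value.  This note records the models, the defaults and why, and what the
synthetic data can and cannot establish.

## Forward model

Ventricular depolarization is modelled as a single point current dipole in
free space.  The normal field component over a planar array is

    Bz(r) = (mu0 / 4pi) (Q x (r - r0)) . z / |r - r0|^3,

with moment Q in A·m at position r0.  Torso volume currents are ignored.
This is deliberate: the free-space dipole shares the two-pole map topology
of a real QRS field map and admits closed-form oracles — pole separation
sqrt(2)·depth, pole axis perpendicular to the moment, exact antisymmetry
(MMR = 1) — against which the whole feature-extraction chain is verified.
It is *not* a physiological torso model, and simulated absolute field
values should not be read as patient-accurate.

A beat is a time-varying dipole defined by a `BeatTemplate`: Gaussian
deflections at the Q, R and S fiducials (defaults tQ = −40 ms,
tS = +42 ms, widths 8/10/8 ms, amplitudes −0.3/+1.0/−0.4 × 10 µA·m) plus
optional orientation keyframes that rotate the moment across the beat.
10 µA·m at 6–9 cm depth yields tens of pT at the sensors — both numbers in
the physiological range for the peak QRS dipole and for chest-surface MCG.
Default fiducials realize QR/RS intervals of 40/42 ms, the adult scale.

## Sensor array

Default geometry is an 8 × 8 planar grid at 2.5 cm pitch (64 channels,
17.5 cm span), the footprint of clinical 64-channel MCG systems.  The span
matters: typical map pole distances are 9.5–11.5 cm, i.e. source depths of
~7–8 cm, putting the poles ±5.7 cm from center.  Both poles must fall well
inside the sensor hull for interpolation-based pole localization to meet
its accuracy contract (pole distance to ±0.5 cm, angle to ±5°, MMR to
±5 %); numerically, sparse 16-channel layouts miss that contract by a
factor of ~5 at these depths, which is why the denser array is the
default.  Any `SensorGeometry` can be supplied instead.

## Interference and preprocessing

The unshielded-room `NoiseModel` has three parts: independent per-channel
white sensor noise (default SD 2 pT), baseline drift (Gaussian noise
low-passed at 0.1 Hz, rescaled to 30 pT RMS) and 50 Hz powerline pickup
(20 pT amplitude, random phase).  Drift and powerline originate far from
the array and are therefore simulated as common-mode — identical on every
channel — which is exactly the component virtual gradiometry removes.
Real interference has spatial gradients and transient artifacts that this
model does not attempt.

Preprocessing defaults:

- **Baseline correction** — per-channel least-squares polynomial
  (Legendre, order 3) over the record; a 0.5 Hz zero-phase high-pass is
  the alternative.
- **Virtual gradiometry** — per-time-sample orthogonal projection of the
  channel vector off a spatial background basis.  Order 0 (spatial mean;
  default) nulls any uniform field exactly and leaves a centered dipolar
  map essentially intact, since an antisymmetric map has near-zero spatial
  mean.  Order 1 also removes a fitted plane a + bx + cy — it nulls
  spatially linear interferents exactly but projects out part of the
  dipole pattern itself (the map's net tilt), so it is not the default.
- **Filtering** — zero-phase 4th-order Butterworth band-pass 0.5–40 Hz
  plus a Q = 30 notch at 50 Hz.  With the default R width (σ = 10 ms) the
  band attenuates the R apex by < 5 %; narrower deflections would lose
  more, which is the reason the template default is not sharper.
- **R-peak detection** — rectified maximal-amplitude channel thresholded
  at 0.6 × its running block maximum (10 s blocks), 300 ms refractory.
  An optional absolute floor (`min_height_pt`) rejects records with no
  cardiac signal at all, where a purely relative threshold would fire on
  noise.
- **Ensemble averaging** — beats aligned at R over a −150…+400 ms window,
  edge-truncated beats dropped; beats whose maximal-channel trace
  correlates < 0.8 with the median beat are rejected before averaging.
  Residual white noise falls as 1/sqrt(N) (verified over N = 4…256).
- **Quality control** — SNR = R amplitude on the maximal channel / SD of
  the pre-Q baseline window (−150…−80 ms); scans below the configurable
  threshold (default 5) fail QC.  Noiseless input yields an infinite SNR
  by convention.

## Field maps and the 10 predictors

Channel values at one instant are interpolated onto a 0.25 cm grid over
the sensor bounding box with a thin-plate-spline radial basis function
(exact at the sensors; kernel configurable).  Poles are the grid
argmax/argmin refined by a quadratic fit over the 3 × 3 neighborhood,
clamped to one cell — without sub-grid refinement the pole-distance
estimate is quantized at the grid step and fails the analytic oracle.

Coordinates: origin at the array center, x from the subject's right to
left, y from feet to head, angles counterclockwise from +x in
(−180°, 180°].  The four map features are the angle of the line from the
negative to the positive pole, the Euclidean pole distance (cm), the
maximum magnetic field ratio MMR = B⁺/|B⁻|, and the positive peak field
(pT).

Fiducials: on the maximal channel, Q is the extremum of polarity opposite
to R in (−80, −10) ms and S likewise in (10, 80) ms; QR/RS intervals are
−tQ and tS.  A window with no opposite-polarity deflection is an error,
not a guess.

**Section-peak instants.**  The QR- and RS-section features are measured
at the instant of maximal aggregate field magnitude (RMS across channels)
inside each section.  The R apex belongs to both sections, so taken
literally both sections would select the same sample and the two maps
could never differ; a guard of ±10 ms around R is therefore excluded, and
the QR instant is the argmax over [tQ, −10 ms], the RS instant over
[+10 ms, tS].  This keeps the instants on each section's own flank of the
R wave, where a rotating source expresses the section's own map
orientation.  The rule is isolated behind `section_peak_instants` so an
alternative operationalization (e.g. maximal |dB/dt|) can be swapped in
without touching the rest of the extractor.

## Cohort generators

Two generators serve different purposes:

- **Feature-level** (`sample_feature_cohort`): per-subject predictor
  vectors drawn from group-conditional normals.  The packaged scenario
  carries the published group means ± SD for the three study groups at
  their analysis sizes (70 ischemic patients / 69 controls / 37 young
  healthy volunteers).  Predictors are independent within group by
  default — no inter-predictor correlations are published — and a common
  correlation matrix can be supplied.  Draws are not truncated, so sample
  moments are unbiased; the far-tail probability of a nonpositive
  ratio-valued draw (< 0.3 %) is accepted.
- **Waveform-level** (pipeline `source='waveform'`): per-subject dipole
  beats with group-conditioned depth (pole distance / sqrt(2)), moment
  magnitude, map orientations and intervals, run through the full
  simulate → preprocess → extract chain.  Default 6 subjects per group at
  60 s per recording; it demonstrates end-to-end consistency, not
  study-scale statistics.

Because the feature-level generator uses independent normals, model
discrimination on synthetic cohorts is *not* expected to match published
cohort values — with all ten predictors independently informative, the
patient vs young-volunteer model separates almost perfectly
(cross-validated AUC ≈ 1.0 vs a real-data 0.94).  What synthetic cohorts
do establish is behavioural: chance-level cross-validated AUC when labels
are independent of features, optimism of apparent over cross-validated
performance, the ordering of the control-group separations, and exact
internal consistency of the NPV arithmetic.  Conclusions about real
patients require real recordings.

## Diagnostic evaluation

- **Group comparison** — per-predictor one-way ANOVA across groups, plus
  pairwise Welch t-tests.  Pairwise significance marks (\* p < 0.05,
  \*\* p < 0.01) are Fisher-protected: only issued when the omnibus F is
  significant, keeping the per-predictor false-flag rate near nominal.
- **Model** — logistic regression of patient vs control on the 10
  standardized predictors with the elastic-net objective
  (1/n)·log-loss + λ[(1−α)/2‖β‖² + α‖β‖₁], α = 0.3.  The solver is
  scikit-learn's saga under the glmnet parameterization C = 1/(nλ);
  λ ≥ the L1 path entry point returns the exact null model analytically
  (saga converges poorly there).  Correctness is cross-checked in the
  test suite against an independently hand-coded IRLS + coordinate-descent
  solver (agreement to 1e-4 relative).
- **λ selection** — deviance-minimizing value by stratified 10-fold CV
  over a 40-point geometric path from the path entry point down 3 decades.
  In repeated cross-validation λ is selected once on the full table and
  held fixed across outer folds (`lambda_select='once'`, the default);
  per-fold re-selection is available at ~10× the cost.  At n ≈ 176,
  p = 10 the optimism induced by the shared λ is negligible next to the
  fold-to-fold variance.
- **Cross-validation** — stratified 5-fold, 10 repeats (both
  configurable; class ratio preserved within one subject per fold).
  Sensitivity, specificity and AUC are averaged over all folds × repeats.
- **Operating point** — fixed a-priori probability cut-offs (0.20 for the
  pooled-control model, 0.30 otherwise), classifying positive at
  probability ≥ cut-off; alternatively the cut-off is selected as the
  largest value whose sensitivity strictly exceeds a floor (default 90 %),
  i.e. specificity-maximal subject to the sensitivity constraint.
- **NPV** — from Bayes' theorem at an assumed disease prevalence
  (default 15 %): NPV = spec(1−prev) / [(1−sens)prev + spec(1−prev)],
  computed from the *averaged* sensitivity/specificity, never averaged
  per fold.  A degenerate operating point at which nobody tests negative
  has no NPV and is reported as NaN.

## Eligibility filtering

The roster module reproduces a CONSORT-style flow: each enrolled subject
has a candidate group and boolean exclusion flags (device malfunction,
low SNR, missing/corrupted data, prior IHD history in a volunteer); any
set flag excludes the subject, and the remainder pool into groups A/B/C.
The packaged roster encodes the combined study flow (202 enrolled →
70/69/37 analyzed) and is a plain CSV, so alternative flows are trivial
to construct.  Filtering is a pure row filter and hence order-independent.

## Numerical choices and degenerate inputs

- Interpolation grid step 0.25 cm; pole refinement clamped to ±1 cell.
- Single-signed maps, coincident poles, missing deflections, empty
  passbands, sub-Nyquist violations, non-PSD correlation matrices and
  undersized classes all raise informative errors rather than degrade.
- Sampling rate default 500 Hz; one sample = 2 ms bounds the interval
  resolution quoted by the recovery tests.
- All generators take explicit seeds; identical seeds give bit-identical
  recordings, cohorts and cross-validation splits.

## Problem sizes

Default statistical runs use the study-scale cohort (176 subjects) with
10 × 5-fold CV; the multi-seed behavioural checks use 20 seeds.  Waveform
demonstrations use 60 s recordings at 500 Hz on the 64-channel array
(2-minute and 10-minute runs appear where beat-count accounting is the
point).  These sizes were chosen to make every claim checkable in minutes
on a single core while keeping each estimate's Monte-Carlo error well
inside the asserted tolerance.

## Known limitations

- No torso conduction model, no repolarization (T wave) — the predictor
  set is depolarization-only by design.
- Feature-level cohorts ignore inter-predictor correlation unless one is
  supplied; discrimination metrics on them overstate real-data
  separability.
- The common-mode interference model cannot exercise gradient-order
  trade-offs of real gradiometer arrays.
- Gender/age subgroup effects are out of scope.
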