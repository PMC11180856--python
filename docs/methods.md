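# Methods

This note records the models implemented in `svdquant`, the defaults and
why they were chosen, what the digital phantom does and does not emulate,
and the numerical decisions a maintainer would otherwise have to reverse-
engineer from the code.

## Scope and design

The package reproduces the quantitative chain of a two-arm imaging trial
in cerebral small vessel disease: dynamic contrast-enhanced (DCE) MRI →
Patlak influx-rate (K_i) maps; dynamic TSPO PET → simplified-reference-
tissue-model (SRTM) binding-potential (BP_ND) maps; both summarised as
percentile "hotspot" endpoints in eroded normal-appearing white matter
(NAWM); and the trial statistics on those endpoints. Everything upstream
of quantification (reconstruction, registration, segmentation, lesion
contouring) is out of scope: the phantom supplies aligned volumes and
masks directly.

Model fits follow the estimator/results convention: `VFAT1`, `Patlak`,
`SRTM` and `TreatmentEffect` are model objects whose `fit()` returns a
results object carrying estimates, uncertainty or validity flags, and a
`summary()`. Map-level wrappers (`ki_map`, `bp_map`) vectorise the same
fits across a mask.

## Variable-flip-angle T1 mapping

Signal model: S = M0 sin α (1 − E1)/(1 − E1 cos α), E1 = exp(−TR/T1).
Default estimator is the DESPOT1 linearisation (S/sin α on S/tan α, OLS),
chosen because it is standard, fast enough for per-cycle whole-volume
fitting, and exactly inverts noise-free data; `fit(refine=True)` adds
Levenberg–Marquardt polish on the full signal equation. A voxel whose
regression slope falls outside (0, 1) has no physical T1; it is flagged
invalid with a reason code and propagates as missing downstream — never
silently zeroed. No B1+ correction is modelled. Default angles
{2, 5, 10, 15, 20, 25}° and TR = 5 ms are declared acquisition defaults,
not inferences.

## DCE-MRI and Patlak analysis

- Concentration: C_t = (1/T1(t) − 1/T1(0))/r1, with r1 = 3.5 s⁻¹mM⁻¹
  (literature relaxivity of gadoterate at 3 T; configurable and recorded
  in outputs). Water exchange and T2* effects are ignored — standard at
  the low dose (0.025 mmol/kg) this protocol uses.
- Input function: the superior-sagittal-sinus ROI average concentration,
  divided by (1 − Hct). ROI averaging precedes the division.
- Patlak fit: OLS of C_t/C_p on (∫₀ᵗC_p dτ)/C_p, integral by trapezoid on
  the sampling grid. All 8 post-contrast cycles are used by default
  (window start configurable): at this dose and ~1-minute cycles the
  pseudo-equilibrium assumption is applied from the first cycle.
- Units: tissue density is taken as 1 g/mL, so the slope in min⁻¹ is
  reported as mL/g/min.
- Negative K_i values are retained (a near-zero true influx yields
  negative estimates under noise; clamping would bias NAWM means). A
  clamp option exists but defaults off.

The phantom's forward DCE model computes the plasma integral with the
same trapezoid rule on the same grid as the fit, which makes the
noise-free simulation an exact fixed point of the quantification chain
(round-trip error ~1e−12 relative). The bi-exponential bolus AIF was
chosen precisely because its running integral has a closed form, which
serves as the independent oracle for that quadrature.

## PET kinetics

- Basis-function SRTM: θ3 (= k2a) scanned over 100 log-spaced values in
  [0.006, 0.6] min⁻¹ (the conventional basis range); per θ3 the model is
  linear and solved in closed form; smallest-RSS θ3 wins, ties to the
  smallest θ3. BP_ND = θ2/θ3 + θ1 − 1 and k2 = θ2 + θ1·θ3 hold exactly
  for every fit by construction. Noise-free recovery error is bounded by
  the grid spacing and halves when the grid is refined.
- Vascular correction: fitted curve (1 − v_b)·SRTM + v_b·C_wb with v_b
  box-constrained to [0, 1] (boundary handled by re-solving the reduced
  system). The whole-blood curve is the blood class of the control
  library — no arterial sampling exists in this setting.
- Convolution: curves are interpolated from frame midpoints to a fine
  uniform grid (anchored at t = 0 by clipped linear extrapolation),
  convolved with exp(−λt) by the exact piecewise-linear recursion, and
  integrated back over frame durations. Accuracy vs. the closed form for
  exponential inputs is ~0.1% at the default 1 s grid.
- k2 is reported but flagged non-identifiable when θ2 ≈ 0 (the
  tac-equals-reference degeneracy).
- Decay correction is assumed already applied (reconstruction is out of
  scope); the flag is carried on the data object.

### Supervised cluster reference

Each voxel curve is normalised to unit area and decomposed by
non-negative least squares onto four normalised healthy-control class
curves (gray, white, blood, high-binding); voxels whose white-class
weight share exceeds 0.9 form the reference set. Two constructions are
provided:

- `mode="mean"` (default): the white-weight-weighted mean of member
  voxels' raw curves. Faithful to the classical construction, but the
  members' vascular admixture (~5% blood) and their mean tissue BP leak
  into the reference; on the noise-free phantom this produces a
  systematic BP bias of about +0.03.
- `mode="projected"` (used by the pipeline): each member is regressed on
  the white and blood class curves; the reference is the white class
  curve scaled by the vascular-corrected amplitude mean c/(1 − d). This
  removes intravascular activity from the reference and recovers the
  phantom's v_b exactly, leaving a residual BP bias of ~+0.01.

Reference-region bias of this kind is intrinsic to same-brain
pseudo-reference extraction, which is also why negative NAWM BP_ND values
are expected and preserved.

## Hotspot endpoints

NAWM = white matter minus the WMH lesion mask, eroded by a 3 mm
Euclidean-ball structuring element built in world units (so anisotropic
voxels are handled); out-of-volume counts as background. The hotspot
threshold is the 95th percentile of the pooled control-cohort voxel
distribution, computed with the Hazen / R type-7 convention
(h = 1 + (n − 1)q/100) and pinned — changing the convention changes
thresholds, so it is part of the reproducibility contract. Strict ">" at
the threshold; ties are non-hotspot. Invalid-fit voxels leave both the
numerator and denominator. Pooling is voxelwise across control subjects;
a per-subject-mean alternative sits behind a flag. An uneroded-NAWM
sensitivity mode is computed alongside the primary endpoints.

In the end-to-end pipeline the control distributions are obtained by
pushing lesion-free control phantoms through the *same* quantification
chain as the patients, so control and patient null voxels share the
measurement-noise distribution — the exchangeability on which the
95th-percentile calibration rests. (Thresholds computed from the
noise-free control distribution would mis-calibrate as soon as map noise
dominates the biological spread, which is the realistic regime for K_i.)

## Trial statistics

- Baseline tables: two-sample t-tests (continuous), χ² without continuity
  correction (binary), Fisher's exact test when any observed cell count
  is below five, median (τ = 0.5 quantile) regression for ordinal traits
  with a permutation-bootstrap fallback. The test actually used is
  reported with each p-value.
- Treatment effects: OLS of log(follow-up) on an arm indicator and
  log(baseline), optionally age; RR = exp(arm coefficient) with Wald 95%
  CI. This log-outcome operationalisation is the package's reading of
  ratio-scale effects with near-unity RRs and tight CIs; a
  ratio-of-changes alternative (`fit_ratio_of_changes`) is provided and
  labelled, and neither is claimed to replicate any particular study's
  code. Zeros: ε = half the smallest positive observed value, added only
  when zeros are present and recorded in the result. Values still
  non-positive after ε (genuinely negative outcomes) have no ratio-scale
  representation and drop pairwise. Mean-BP endpoints are therefore
  shifted to the strictly positive 1 + BP scale (BP > −1 by model
  definition) before the ratio model; the output labels this scale.
- Populations: ITT = all randomized subjects with available data,
  missing follow-up dropped pairwise; per-protocol = treatment
  completers.
- Biomarkers: per-protein treatment effects with Bonferroni threshold
  0.05/m (m = 92); PCA by SVD of the z-scored panel, sign convention
  "largest-|loading| element positive", per-component effects on the
  difference scale (scores are already centred; a ratio there would be
  meaningless).
- Power: smallest per-arm n such that a two-sided two-sample t-test at
  level α reaches the target power, exact noncentral-t iteration. With a
  20% reduction at a standardized effect of 1.0 this gives 17 per arm;
  at 0.9 it gives 21.

## The phantom

Geometry: concentric spherical GM shell / WM core with a small central
CSF cavity on a 32³ grid at 1 mm isotropic (configurable); spherical WMH
lesions (radii U(2, 4) mm) placed wholly inside WM by rejection sampling;
a superior-sagittal-sinus tube along the posterior edge. Hotspot truth is
assigned as contiguous blobs covering a configurable fraction (default
0.10) of NAWM — focal clusters, not i.i.d. voxels.

Ground truth defaults reproduce the published order of magnitude for this
population: NAWM K_i ~ N(0.0002, 0.0003²) mL/g/min, hotspot K_i
~ N(0.007, 0.001²); NAWM BP_ND ~ N(−0.03, 0.025²), hotspot BP_ND
~ N(0.19, 0.018²); v_p = 0.01, v_b = 0.05, R1 = 1 (1.3 in GM),
k2 = 0.10 min⁻¹. The control library draws its K_i/BP voxel samples from
the same Gaussian nulls, making control and patient null voxels
exchangeable by construction.

Acquisition defaults: 1 pre- + 8 post-contrast T1-mapping cycles at 60 s
(cycle timing is a declared default — not stated by any acquisition
protocol this emulates), six flip angles; PET histogrammed into 55 frames
of geometrically increasing duration over 75 min. Dose 0.025 mmol/kg,
target activity 500 MBq, Hct 0.45.

Noise is Gaussian: DCE noise sd = 1% of the mean baseline signal; PET
frame noise sd = 5% of the peak activity scaled by 1/√(frame duration).
Gaussian (rather than Rician/Poisson) noise is a simplification
appropriate at phantom SNR; with it, measured voxel K_i noise exceeds the
biological spread (realistic for low-dose BBB mapping — permeability maps
are noisy) while BP maps sit at ~2.7× the biological spread.

Cohort: permuted-block randomization (blocks of 2 and 4, 1:1), per-arm
demographics drawn from the trial-population summaries coded in
`TABLE_PARAMS` (Gaussian for age/BMI, log-normal moment-matched for WMH
volume and time since stroke, Bernoulli prevalences for comorbidities).
A 12-subject lumbar-puncture subgroup receives albumin values whose
CSF/serum ratio correlates with the subject's true mean K_i at ρ = 0.6
(Qalb ~ 5.39 ± 1.71 mg/g). The 92-protein panel follows a 3-factor model
with loadings scaled so the factors carry 45% of total variance in
expectation; follow-up shares factor scores with baseline at ρ = 0.7, and
an optional per-protein multiplicative effect in the active arm provides
a known non-null.

What the phantom does **not** emulate — and hence what passing tests do
not establish about real data: motion, partial-volume effects, B1/coil
inhomogeneity, reconstruction artefacts, Rician/Poisson noise statistics,
spatially correlated noise, deviations from SRTM/Patlak kinetics
(e.g. water exchange, reversible leakage), and longitudinal biological
drift other than the injected treatment effect.

## Numerical choices and degenerate inputs

- All randomness flows from one seed through spawned `SeedSequence`
  children; identical config + seed is bit-reproducible end to end.
- Normal-equation solves flag voxels with condition number > 1e12 as
  invalid rather than returning garbage.
- θ3 ties break to the smallest grid value; the basis scan keeps the
  first (smallest-θ3) minimiser under exact RSS ties.
- Percentile thresholds refuse samples smaller than 20 values at q = 95.
- Empty eroded NAWM, empty SSS ROI, empty reference set and
  constant-variable baseline tests all raise (or flag) with messages
  naming the violated constraint.
- Pipeline problem sizes (32³ grid, 44 subjects, 2 timepoints, 3 control
  subjects) were chosen as a demonstration scale that completes in
  minutes on a single CPU; tests use smaller grids/cohorts with the same
  code paths.

## Known limitations

- The SVCA reference inherits bias from the member voxels (see above);
  both constructions are provided and the residual is documented rather
  than hidden.
- The RR operationalisation of "linear regression" effects is a declared
  design choice; the alternative estimator is shipped alongside.
- K_i measurement noise at default settings dominates the biological
  NAWM spread, so subject-level K_i endpoints are noisy by design — the
  phantom mirrors the known fragility of low-dose DCE permeability
  mapping rather than an idealised modality.
- No cluster-size filtering or smoothing of hotspot masks is applied.
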