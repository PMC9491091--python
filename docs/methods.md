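# Methods

`neuropet` implements the quantitative chain of a reference-region dynamic
TSPO-PET group study: synthetic cohort generation, Logan graphical DVR
estimation, voxelwise permutation inference with TFCE, ROI extraction, and
regression of regional DVR against cognitive assessments. This note records
the models, the defaults and why they were chosen, and what the synthetic
data do and do not establish.

## Study design being emulated

Four diagnostic groups — cognitively healthy (CH, n=7), delirium (n=4),
dementia (n=4), and delirium superimposed on dementia (DSD, n=4) — each with
a 22-frame, 60-minute dynamic acquisition (4×30 s + 4×60 s + 4×120 s +
4×240 s + 6×300 s). The scientific claim under test is that microglial
activation, indexed by the distribution volume ratio (DVR) of a TSPO tracer,
differs between groups in the choroid plexus but not in gray or white
matter, and that choroid-plexus DVR tracks global cognition (MoCA).

## Forward model (synthetic cohorts)

Voxel time-activity curves come from the simplified reference tissue model
(SRTM):

C_T(t) = R1·C_R(t) + (k2 − R1·k2a)·[C_R ⊛ e^(−k2a·t)](t), k2a = k2/(1+BP),

with reference input C_R(t) = A·t·e^(−t/τ). SRTM is the minimal generator
consistent with a reference-region analysis: the estimand (DVR = 1 + BP)
appears as an explicit parameter, and the Logan estimator is not used to
build the data it is later asked to recover. The convolution is evaluated by
an exponential-integrator recursion that is exact for piecewise-linear
C_R on a 0.5-s grid, then averaged over frames; the BP=0, R1=1 identity
C_T ≡ C_R holds to ~3·10⁻⁶ relative, and the noiseless Logan round-trip
recovers DVR to <0.02% over BP ∈ [−0.5, 1].

Fixed defaults and rationale:

| parameter | default | meaning / why |
|---|---|---|
| R1 | 1 | delivery ratio; group differences confined to binding |
| k2 | 0.4 /min | reference efflux; mid-range for reversible tracers, fast enough to equilibrate before t* |
| A, τ | 1 (a.u.), 15 min | bolus amplitude and time-to-peak of the gamma-variate input |
| noise_scale | 0.05 | per-voxel Gaussian SD = noise_scale·√(signal/frame-min); variance ∝ signal, ∝ 1/duration (counting statistics after reconstruction) |
| grid | 32³ (tests run much at 16³) | desk-scale; grid is a config knob, not part of the model |
| group DVR (choroid plexus) | CH 0.856, delirium 0.601, dementia 0.614, DSD 0.559 | study-condition group levels; all other regions 1.0 in every group |
| MoCA (mean, SD) | CH 19.9/4.62, delirium 6.5/4.95, dementia 6.0/1.73, DSD 5.3/2.01 | group score moments; draws clipped to the 0–30 range |

The toy atlas is a deterministic labeled phantom (reference block,
gray-matter shell, white-matter core, subcortical slab, choroid-plexus block
inside it — 216 choroid-plexus voxels at 32³). It preserves the topology the
pipeline needs (disjoint roles, a reference region, a small target nested in
a larger tissue mask) and nothing else: no anatomy, no partial volume, no
inter-subject variability in geometry.

Among the nine assessments, the drawn MoCA score is carried by the
MoCA-attention column and the remaining eight are independent noise, so
exactly one regression in the battery has a true association — matching the
reported pattern of one significant assessment out of nine.

What the simulator deliberately omits: arterial input variability, scanner
PSF and partial-volume effects, motion, registration error, reference-region
contamination, and spatially correlated noise. Passing tests therefore show
that the estimators and the inference chain are correct and calibrated under
their own assumptions, not that the pipeline is robust to real-data
artifacts.

## Logan reference-region estimation

The Logan plot regresses y_i = ∫₀^{t_i}C_T/C_T(t_i) on
x_i = (∫₀^{t_i}C_R + C_R(t_i)/k2′)/C_T(t_i); the asymptotic slope is DVR.
Conventions, chosen once and applied consistently: cumulative integrals are
evaluated at frame end times (exact for frame-averaged data), instantaneous
values are the frame averages, and frames enter the fit when their mid-time
≥ t*.

- **t\* = 30 min** by default (the final six frames of the schedule). With
  k2 = 0.4 /min and DVR ≥ 0.5, k2a ≥ 0.27 /min, so the plot is linear well
  before 30 min; an `auto_tstar` helper picks the earliest candidate whose
  max relative residual is ≤ 10% when a data-driven choice is wanted.
- **k2′ omitted** by default (classic simplified formulation); supplying it
  adds the C_R/k2′ term. At these kinetics the two agree to well under 2%.
- Voxels with any non-positive activity in the fit window are returned as
  NaN and excluded from every downstream statistic — no imputation, no
  division blow-ups.
- The slope/intercept come from a closed-form least-squares kernel that
  broadcasts over voxels; it matches a normal-equations solve to 1e-10.

## Voxelwise inference

Unpaired pooled-variance t maps are enhanced with TFCE
(Σ_h extent(h,v)^E · h^H · dh with E=0.5, H=2, 26-connectivity, dh adaptive
at max/100; all configurable) and tested against the permutation
distribution of the image-wide maximum TFCE. Each direction is its own
one-sided run with its own correction. Implementation notes:

- Threshold membership uses stat ≥ h − ε with ε = 10⁻⁹·max, so a voxel
  exactly at a threshold is included despite floating-point rounding.
- Exhaustive mode enumerates all C(n, n_A) relabelings (observed included)
  and p = #{null ≥ obs}/N. Sampled mode draws n_perm uniformly random
  relabelings and adds the observed labeling as the "+1":
  p = (1 + #{null ≥ obs})/(n_perm + 1), so p ≥ 1/(n_perm+1) and p > 0
  always. Sampling falls back to exhaustive enumeration when the distinct
  count does not exceed n_perm, which also makes the two modes agree
  exactly on small instances.
- Computation is cropped to the mask bounding box, making TFCE equivariant
  under translation and insensitive to values outside the mask.
- The three tissue-mask analyses are independent runs; no correction is
  applied across masks, and no variance or spatial smoothing is used.

Under a true null (all groups at the same DVR), the family-wise rejection
rate of the full simulate→Logan→permutation stack is checked to sit at the
nominal 5% within binomial error over 200 reduced runs. Note that a
multi-contrast pipeline performs many such FWE tests; with ~9–18 runs per
cohort, *some* null run rejects in a sizable fraction of cohorts even though
each individual run is calibrated. Pipeline-level claims are therefore
stated as rates over runs, not as "nothing anywhere is significant".

## ROI extraction and overlap

ROI means exclude NaN voxels and report n_voxels/n_defined separately.
"Highest overlap" between a significance mask and the atlas is a plain voxel
count (not normalized by region size — the plain reading of the procedure),
background is never eligible, and ties break to the smallest label id with a
warning.

## Regression battery

Each of the nine assessments is regressed on the chosen region's mean DVR
over QC-passing subjects with pairwise-complete data. Outlier screening
removes points > 3 SD from the full-sample mean of either variable in a
single pass (no re-screening). Two-sided p comes from the t distribution
with n−2 df; adjusted R² = 1 − (1−r²)(n−1)/(n−2), which reproduces the
analytic value 0.40 at r = 0.66, n = 19. The Bonferroni divisor is fixed at
9 — the size of the battery — even when some assessments are skipped for
missing data. At n = 5 the exact permutation null of r is discrete (120
relabelings), so the t-based p is only expected to agree with a permutation
p to within that grid; the test suite compares against exact enumeration.

## Problem sizes and reproducibility

Default test and pipeline scale is a 16³ grid with 200–500 permutations;
32³ with 5000 permutations (`full_scale`) reproduces the full-size setting.
Group-level DVR recovery is assessed at 32³ (216 choroid-plexus voxels,
noise_scale 0.05), where ROI means land within ±0.01 of truth and the ±0.03
acceptance band is comfortably met. All randomness flows from one master
seed through `numpy.random.SeedSequence` spawning (per subject, per
permutation run), so identical configs give identical outputs.

## Known limitations

- The simulator treats DVR < 1 as a true binding deficit relative to the
  reference; whether such values in real data reflect signal below the
  reference or reference contamination cannot be resolved here.
- The Logan estimator's well-known noise-dependent underestimation bias is
  negligible at the default noise level but is not corrected; at much higher
  noise, recovered DVR will drift low.
- Pooled-variance t assumes equal group variances; with the simulator's
  homogeneous noise this holds by construction.
- Permutation exchangeability assumes no confounding covariates; no GLM
  nuisance scheme is provided.
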