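# Methods

## The measurement model

### Diffusion tensor fit

Signals follow the single-tensor model S = S₀ exp(−b gᵀDg). The fit is
unweighted log-linear least squares over all volumes per voxel (a weighted
refinement with one reweighting pass is available behind
`fit_tensor(..., weighted=True)`). Non-positive signal samples (possible
under Rician noise at low SNR) are dropped from that voxel's fit; a voxel
needs at least 7 usable samples, one b = 0 volume and 6 independent
directions, otherwise it is flagged invalid and excluded from every ROI
mean downstream. Eigenvalues are floored at 10⁻⁶ mm²/s when computing FA
and MD so noise cannot produce negative diffusivities; together with the
guard on the ALPS denominator this keeps the index finite and positive.
FA uses the standard closed form √(3/2)·‖λ − λ̄‖/‖λ‖; MD is the eigenvalue
mean. Tensor axes are the image axes: the acquisition is assumed axial
with x = left–right, y = anterior–posterior, z = superior–inferior, so the
ALPS formula reads the tensor's diagonal elements directly.

### ALPS index

Sphere ROIs are rasterised boundary-inclusively (voxel center within
diameter/2 of the ROI center); at 5 mm diameter on a 1 mm grid this gives
81 voxels, matching brute-force lattice enumeration. Template ROIs are
projected into subject space by nearest-neighbour resampling through a
user-supplied affine — registration *estimation* is out of scope; in
synthetic mode the exact generator transform (identity) is used, so ROI
placement error is zero by construction and measurement error isolates
noise and fitting effects. ROI aggregation is the arithmetic mean of the
relevant tensor element over valid voxels.

The source protocol labels the positive-x ROIs "left", which is opposite
to the usual right-positive template convention; the default follows the
printed labels and `AlpsRoiSpec(laterality="radiological")` swaps sides.
Swapping relabels left/right but never changes the subject-level mean.

### EPVS morphometrics

Lesions are maximal 26-connected components. Lesion length is the spread
of member voxel centers projected on the first principal axis of their
world-coordinate covariance, plus one voxel edge: for a straight tube this
is the end-to-end extent; a single voxel has length one edge rather than
zero. The published exclusion rule "length < 2 mm" is applied strictly:
exactly 2.0 mm is retained. Regional volume fractions divide the EPVS
volume assigned to BG or CSO (majority vote of member voxels over the
atlas) by whole-brain volume. A raw ratio is O(10⁻⁴) and incompatible
with the ~0.2 magnitudes conventionally tabulated, so fractions are
reported per mille (scale 10³); the scale is a parameter
(`fraction_scale`) and is stated in every output header.

### Segmentation agreement

TP/FP/FN are voxel counts; DSC, recall and precision follow the standard
formulas. Conventions for degenerate inputs: both masks empty → all three
metrics 1 (perfect agreement on absence); exactly one empty → all three 0.
With two raters, the reference may be a single rater, their voxelwise
union, or their intersection. The rater simulator flips only boundary
voxels (each eligible voxel independently with the given rate), never
creates voxels outside the brain label, and in add-only mode produces a
superset of its input — which is why precision of the original mask
against an add-only reference is exactly 1, reproducing the behaviour of
expert correction workflows that mostly extend automated masks.

The rule-based segmenter (T1 below a threshold AND T2 above a threshold
AND inside brain, with an optional 3 mm maximum-diameter component veto)
is a transparent stand-in used to exercise the evaluation machinery; it is
not a learned model and no claim is made that it matches one on real data.

## The phantom

The template grid is 64×64×40 voxels at 1.5 mm isotropic spacing with the
world origin at the grid center, so the published ROI millimetre
coordinates fall inside the fiber slabs with no extra offset. The atlas
labels are 0 background, 1 brain, 2 BG, 3 CSO, 4 midbrain; BG, CSO and
midbrain are disjoint boxes inside the brain box. The association-fiber
slab spans the full peritrigonal band and the projection-fiber slab sits
inside it with precedence, so the medial ROI pair samples projection
tensors and the lateral pair association tensors.

Tensors are diagonal: isotropic 0.8×10⁻³ mm²/s in background brain;
in the projection slab diag(g·0.4, 0.4, 1.4)×10⁻³ (principal axis z) and
in the association slab diag(g·0.4, 1.4, 0.4)×10⁻³ (principal axis y),
where g is the subject's true ALPS. The two denominator terms equal
0.4×10⁻³, so the ALPS formula returns g identically — the noiseless
pipeline recovers it to < 10⁻⁶ relative error, and the measured index at
SNR 30 scatters around g with per-subject SD ≈ 0.01.

DWI uses one b = 0 volume plus 25 directions (b = 1000 s/mm²) on a
spherical Fibonacci lattice. Noise is Rician on the complex-signal
magnitude, σ = S₀/SNR per quadrature channel (`noise_model="gaussian"`
falls back to additive noise). Structural T1/T2 images carry Gaussian
noise with σ = 1/SNR on their unit-scale intensities.

Lesions are digital tubes: voxels within one voxel of a random line,
taken in order along the axis — one to two voxel diameters (≤ 3 mm),
random orientation for short lesions, biased along the host region's long
axis for long ones (penetrating vessels run the length of the structure).
Every lesion has ≥ 2 voxels, so it survives the 2 mm filter; lesions are
kept 26-disconnected from each other by a one-voxel exclusion halo, so
labeling returns exactly the planted count and exactly the planted volume.

### Cohort calibration

Per-subject truths are drawn as:

* ALPS g ~ Normal(group mean, between-subject SD). Group means 1.308 /
  1.450 / 1.570 for AD / aMCI / NC. The tabulated "±" values are treated
  as SEMs of group means, so between-subject SD = SEM·√n: 0.1415, 0.1960,
  0.1527. This makes cohort-mean recovery a well-posed target.
* Lesion count ~ round(Lognormal), floored at 1, and per-subject total
  lesion volume ~ Lognormal, with log-medians at the published medians
  (19/14/12 lesions; 457.5/330.9/320.6 mm³) and σ = ln(Q3/median)/0.6745
  from the published upper quartiles. The two draws share a latent factor
  (ρ = 0.6): subjects with more lesions carry more volume. The
  correlation leaves both marginals — hence the calibrated medians and
  quartiles — unchanged, while avoiding physically impossible
  few-huge-lesion combinations. Single lesions are capped at 40 voxels
  (135 mm³); the cap truncates only the extreme upper tail and does not
  move cohort medians. Total volume is split across lesions by largest
  remainder over lognormal weights, so planted voxel counts sum exactly
  to the voxelised target.
* 80% of lesions are placed in BG (the tabulated CSO fractions are near
  zero while BG fractions dominate); when a region cannot host another
  lesion without contact, placement falls back to the other region rather
  than failing the subject.
* MMSE/MoCA = per-group intercept + shared slope × g + noise, clamped to
  [0, 30]. The shared slope is the least-squares line through the three
  (group ALPS mean, group score mean) points; per-group intercepts
  re-center each group's mean exactly. The residual noise SD absorbs
  whatever score variance the ALPS link does not explain, floored at
  zero — at this calibration the link explains more variance than the
  published score SDs contain, so scores are effectively deterministic in
  g. This preserves the sign and ordering of the published
  cognition–imaging correlations without claiming their effect sizes.
* Age, sex, education match the published group summaries and are
  independent of the imaging metrics (no group differences were found in
  them); a synthetic total brain volume ~ Normal(1.45×10⁶, 1.3×10⁵) mm³
  serves as the covariate the correlation analyses control for (the
  phantom's geometric brain volume is constant across subjects and would
  be collinear with the intercept).

Per-subject seeds derive from the master seed via `SeedSequence`; each
subject uses independent substreams for truth scalars, lesion geometry,
DWI noise and structural noise, so regenerating a subject without DWI
does not perturb its lesions or truths. Identical configuration and seed
give bit-identical outputs.

### What the phantom does not emulate

Bias fields, skull, partial-volume effects, crossing fibers, realistic
anatomy, registration error (transforms are exact), eddy-current or
motion artifacts, and any spatial correlation of noise. Passing tests
therefore demonstrate the correctness of the measurement and statistics
code under the stated model — not robustness to real-world acquisition
artifacts, which real-data users must establish separately. Real-data
inputs are expected pre-processed (bias-corrected, skull-stripped,
co-registered), per the documented I/O contract.

## Statistics

Routing: Shapiro–Wilk per group at α = 0.05; ANCOVA (value ~ group +
age + sex + education by default; brain volume joins the covariate list
only in the partial correlations, mirroring common reporting practice)
when every group passes, otherwise Kruskal–Wallis. Constant-valued groups
route to nonparametric rather than erroring. Post hoc: pairwise contrasts
on adjusted means with Bonferroni (parametric) or Dunn's tie-corrected
z-tests with Bonferroni over the pairs (nonparametric). The
Kruskal–Wallis overall p uses the χ² approximation except at total
n ≤ 10, where it is computed exactly by enumerating all group
assignments — the asymptotic p deviates from the exact one by up to ~0.08
at n = 7, which matters for small-sample method checks. Partial
correlation residualises both variables on [1, covariates] and reports
the Pearson r of residuals with p from t on n − 2 − k df. Sex enters
linear models as a 0/1 covariate. Chi-square uses no continuity
correction.

## Problem sizes and runtime

The default phantom (64×64×40 at 1.5 mm, 26 DWI volumes) makes one
full-pipeline subject ≈ 1–1.5 s on one CPU, so the calibrated 145-subject
cohort runs in ≈ 3–4 minutes; mask-only cohorts (for EPVS targets) run in
seconds. The recovery tests use the study's own group sizes (89/24/32);
EPVS median recovery aggregates 12 replicate cohorts per group so the
check has a controlled false-failure rate; detection-rate checks use 100
seeds of the scalar truth generator (the imaging stages add only
zero-mean per-subject noise to the quantities those checks aggregate).

## Known limitations

* The EPVS-volume group effect at the published calibration gives
  Kruskal–Wallis power of only ≈ 0.75 at the published group sizes
  (aMCI and NC medians nearly coincide; the AD shift is modest against a
  σ ≈ 0.6–0.7 lognormal). A requirement that this effect be detected in
  > 95% of seeds is not attainable under these study conditions, and the
  corresponding test documents the shortfall rather than weakening it.
* The stand-in segmenter's thresholds default to the phantom's
  construction contrasts; on real data they are user configuration, and
  no learned model is reproduced.
* The "volume fraction" per-mille scale is an inference from the
  magnitudes conventionally tabulated, not a published definition.
* Published Table values for lesion volume carry no explicit units;
  mm³ is assumed.
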