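# Methods

## Problem and read-outs

Neuromelanin (NM) is lost from the substantia nigra pars compacta (SNc)
and locus coeruleus (LC) as Parkinson's disease progresses, while iron
accumulates in the substantia nigra (SN); the red nucleus (RN) is an
iron-rich reference structure. On NM-sensitive T1 turbo-spin-echo MRI the
NM-rich nuclei are hyperintense; on susceptibility-weighted imaging (SWI)
the iron-rich nuclei are hypointense. The pipeline quantifies both signals
per structure, side and sequence with two dimensionless read-outs:

* **Contrast ratio.** `CR = (μ_S − μ_BS) / μ_BS`, where `μ_S` is the mean
  intensity over the structure's signal voxels and `μ_BS` the mean over a
  brainstem reference region. Iron CRs are sign-inverted so that a larger
  CR always means more pigment or iron.
* **Normalized volume.** `nVol = V_S / V_GM`: the structure's signal
  volume (voxel count × voxel volume, mm³) over the subject's total
  gray-matter volume. GM volume is an input scalar per subject.

Signal voxels are selected by thresholding the segmented structure at
`μ_BS + k·σ_BS` (hyperintense, NM) or `μ_BS − k·σ_BS` (hypointense,
iron), with `k = 2` by default and configurable. Two readings of the
brainstem reference were possible; we exclude the labelled nuclei from the
reference region so that a bright or dark structure does not drag its own
normalizer, which also makes the phantom ground truth exact (see below).
Undefined measures (a structure that vanishes after thresholding) are NaN
with a flag, never zero.

## Segmentation

Structures are segmented by multi-atlas label fusion, one static atlas per
sequence (brainstem, SNc, LC on NM; brainstem, SN iron deposit, RN on
iron). Each atlas member is registered to the target with a
multiresolution three-step scheme — rigid, affine, then B-spline free-form
deformation, three pyramid levels (shrink 4/2/1) for the linear stages and
the two coarser levels for the B-spline — using negated normalized
cross-correlation within a sequence. Labels are propagated with
nearest-neighbour interpolation and fused by simple majority voting; an
exact tie votes background, the conservative choice for segmentation.
Registration quality is monitored per atlas member (metric value, flat or
worsening metrics flag non-convergence; failed members drop out of the
vote), and the atlas itself is scored by leave-one-out Dice against the
manual annotations.

Cross-sequence (NM–iron) alignment is rigid only, with Mattes mutual
information since the contrasts differ; its QC score is the brainstem Dice
after alignment (flag threshold 0.85, configurable). The aligned SNc mask
from the NM image splits the SN iron deposit exactly into an SNc
compartment (SN ∩ SNc) and the SNr remainder. The partition is computed on
the NM grid, where the SNc was drawn and which is finer along the slice
axis.

## SNc topography

The SNc's long axis is the first principal component of its voxel world
coordinates; the two in-plane principal axes split the structure into four
quadrants forming an elliptical-section cylinder (per-slice ellipse
parameters from the in-plane covariance). Quadrants are named
anatomically — Q1 ventral, Q2 (mostly) lateral, Q3 medial-rostral, Q4
medial-caudal — by scoring each sign-combination's *direction vector*
against the world axes (ventral = anterior +y, lateral = away from the
midline, rostral = superior). Assigning by direction rather than by
quadrant centroid keeps the labels stable under small mask perturbations;
for structures only a few voxels thick the voxel-level labels near the
quadrant boundaries remain sensitive to single-voxel changes (a
resolution, not algorithm, limitation). Per-quadrant and per-axial-slice
CR and nVol reuse the quantification operators restricted to quadrant
masks, so quadrant nVols are additive to the whole-structure nVol by
construction. All quantitative measures are computed in subject space;
the common (reference) space — the healthy control with the highest SNc
QC Dice, ties broken by lowest subject id — is used only for probabilistic
maps (voxelwise mean of binary masks) and display (in-plane bicubic ×4
upsampling, clipped to [0, 1], never fed back into quantification).

## Statistics

CR/nVol distributions are skewed and heteroscedastic, so group comparisons
use 20%-trimmed means with winsorized variances:

* one-way heteroscedastic ANOVA on trimmed means (Welch-type F with
  fractional error df); at trimming 0 it reduces exactly to Welch's ANOVA
  (validated against an independent implementation to 1e-8);
* two-way mixed designs (group × side/region/sequence) via Johansen's
  approximation on the stacked trimmed means with per-group winsorized
  covariance blocks;
* post hoc pairs by percentile bootstrap of the trimmed-mean difference
  (500 resamples by default, explicit seed), Hochberg-adjusted within a
  measure family; effect sizes as the AKP robust d — trimmed-mean
  difference over pooled winsorized SD rescaled by the normal
  winsorization constant (0.642 at 20%), so it estimates the classical d
  under normality;
* categorical clinical variables: Pearson chi-square without continuity
  correction for two groups, tie-corrected Kruskal–Wallis for three (for
  binary data H ≡ (N−1)/N times the chi-square, asserted in tests);
* associations with clinical covariates: Huber M-regression (tuning
  1.345·σ̂, MAD scale) with sandwich-covariance Wald tests, preceded by
  all-relevant feature selection against permuted shadow features. The
  selector scores held-out permutation importance (fit on a random half,
  score on the other half) against the best of two shadow copies per
  feature; hit counts are tested against Binomial(n, ½) at a
  Bonferroni-adjusted α, and features still tentative at the iteration cap
  are resolved by the median-importance rough fix. Out-of-sample
  importance keeps in-sample chance correlations of noise features from
  accumulating systematic hits.

Diagnostic performance uses binary logistic regression over nested feature
sets (LC NM → + RN iron → + SNc NM → + SNc iron) and single-structure
models, per pairwise group contrast. AUC is the Mann–Whitney statistic
with half-weight ties; CIs are stratified case-bootstrap percentiles
(1000 resamples). AUCs are in-sample by default: the ladder quantifies separation on the
cohort itself. At very small cohort sizes in-sample scores are degenerate
(any feature pair separates a 4-vs-4 contrast perfectly), so the
orchestrated pipeline switches to leave-one-out scoring whenever the
smallest group has fewer than 10 subjects — only out-of-fold AUCs can
rank models there. Features are z-scored inside the fit (CR is O(0.1),
nVol O(1e-4); on raw scales a penalized fit would ignore the small-scale
features). (Quasi-)separation is flagged and the fit falls back to a weak
ridge penalty so the score function stays defined.

## The synthetic cohort

No imaging data are publicly deposited for this problem, so every stage is
exercised on a parametric brainstem phantom whose ground truth is exact by
construction. Geometry is analytic — an ellipsoidal brainstem (semi-axes
13×14×22 mm), a crescent SNc (ellipsoid minus an offset ellipsoid) inside
a larger SN ellipsoid, spherical RN disjoint from SN, and a cylindrical
LC (radius 1.4 mm) in the pons — voxelized on an NM grid of
0.6×0.6×1.0 mm and an iron grid of 0.7×0.7×2.0 mm. Only the relative
topology (SNc ⊂ SN ⊂ brainstem, RN ∩ SN = ∅) matters for testing; no
anatomical realism is claimed.

Generative conditions (the defaults *are* the study conditions):

* **Contrast.** Brainstem baseline 100, background 60, uniform intensity
  offsets inside each structure equal to the prescribed CR; additive
  Gaussian noise (SD 2.0 intensity units by default). Per-subject CRs
  jitter around the group value (SD 0.02).
* **Volume.** Group effects are depth-ordered erosion of the template
  mask (surface voxels first, deterministic tie-breaks), optionally
  apportioned over SNc quadrants, so the true nVol is the eroded voxel
  count exactly. Group signatures mirror the reported patterns: both PD
  groups lose ~25% (iPD) and ~21% (LRRK2) of SNc NM volume relative to
  HC, concentrated in the ventral/lateral quadrants; iPD loses LC volume
  and contrast while LRRK2 preserves the LC; both PD groups carry more SN
  iron, and RN iron contrast is elevated only in LRRK2. Left/right volume
  asymmetry is 1.10 everywhere.
* **Effect size.** The per-subject SNc volume scale is Beta-distributed
  with a spread solved (delta method, including GM-volume variance and
  the between-subgroup mean gap) so the standardized HC-vs-PD difference
  of true SNc NM nVol equals the planning effect size, 1.20 by default;
  verified by Monte Carlo.
* **Anatomy.** Subjects are individualized by a smooth random sinusoidal
  displacement field constructed as the curl of a vector potential, hence
  divergence-free: anatomy varies but structure volumes are preserved to
  first order (RMS displacement 0.5 mm by default). The NM and iron grids
  are related by a known small rigid transform (≤2°, ≤1.5 mm), recorded
  with the subject. GM volume is log-normal (mean 620 cm³, SD 45 cm³).
* **Clinical covariates** are simulated with simple documented
  distributions (age N(64, 9²) years; PD duration 2 + Gamma(2, 3.3)
  years; binary comorbidity rates per subgroup, e.g. RBD 0.60 in iPD vs
  0.25 in LRRK2).

Everything flows from one seed through `numpy.random.SeedSequence`;
identical (seed, spec) reproduce a cohort bit for bit.

**What the phantom does not emulate** — and hence what passing tests do
not show about real data: MR physics (bias fields, susceptibility
artifacts, partial-volume profiles at structure borders), real anatomical
shape variation beyond smooth warps, intensity inhomogeneity within
structures (real NM loss is graded, not piecewise-constant), and realistic
atlas-to-patient anatomical distance. Registration accuracy and Dice
scores on the phantom are optimistic relative to patient data.

## Numerical choices and scale

Dice of two empty masks is defined as 1 (QC on structures that can vanish
on coarse grids must not report failure). Volumes are stored float32;
contrast recovery is therefore exact only to ~1e-7. The default study
sizes keep a full run practical on one CPU: a 6-member atlas (leave-one-out
SNc Dice ≈ 0.88 on the phantom), 12-subject cohorts for end-to-end runs,
40 optimizer iterations per linear registration level and 20 L-BFGS-B
iterations for the B-spline stage on the two coarser pyramid levels; these
are package defaults, and larger values are plain configuration. The
statistical battery itself is cheap (the 2000-replicate null calibration
of the trimmed ANOVA runs in seconds).

## Known limitations

* The label-fusion rule (majority voting) and registration metrics stand
  in for unpublished implementation details of the original pipeline;
  they are the stated-family defaults, surfaced as parameters.
* In-sample AUCs overstate out-of-sample discrimination, especially at
  phantom cohort sizes; use the cross-validated mode for honest
  generalization estimates.
* The phantom SNc spans only a few voxels in its thin direction, so
  voxel-level quadrant labels near boundaries are sensitive to single-voxel
  mask changes even though the fitted frame and the quadrant centroids are
  stable.
* Iron quantification is relative (CR), not absolute iron concentration;
  SWI contrast is orientation-dependent in real acquisitions.
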