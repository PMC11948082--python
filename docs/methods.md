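# Methods

This note documents the models, numerical choices, and synthetic study
conditions behind `habitatomics`, and what the test suite does and does not
demonstrate about real data.

## Preprocessing

Volumes pass through a fixed order: N4 bias-field correction → B-spline
resampling to isotropic voxels → piecewise-linear histogram standardization.

* **N4** is backed by SimpleITK. The multiplicative field is estimated on the
  tumor mask dilated by 3 voxels (bias varies slowly, so a neighbourhood
  suffices), normalized to unit geometric mean over that region so correction
  never rescales the volume, and applied everywhere. A near-constant fit
  region skips correction: N4's histogram sharpening is degenerate on a delta
  histogram. Defaults: shrink factor 2, three fitting levels of 20 iterations.
* **Resampling** targets 1.0 mm isotropic spacing, degree-3 B-spline for
  intensities and nearest-neighbour (re-binarized, largest component kept)
  for masks. Anisotropy ratios above 20 warn but proceed.
* **Histogram standardization** maps the volume's intensity landmarks —
  percentiles {1, 10, 20, …, 90, 99} computed *inside the tumor mask* — onto
  reference landmarks by monotone piecewise-linear interpolation with linear
  end extrapolation. The step is idempotent (re-running moves landmarks by
  < 1e-6) and exactly undoes affine intensity distortions. Whether tumor-only
  or whole-breast intensities should define the landmarks is not knowable
  from the source study; tumor-only is used, which is the stronger
  normalization.

## Habitat delineation

Each tumor is over-segmented into SLIC supervoxels (target 150, compactness
0.1, intensity min-max normalized over the mask, computed on the mask
bounding box). Per supervoxel, three summaries feed the clustering:

* median intensity (location),
* log of the IQR-derived robust SD (dispersion; the log makes the estimate's
  sampling noise scale-free so heterogeneous and homogeneous habitats form
  equally tight clusters),
* fixed-bin-width histogram entropy (1/32 of the central 99% tumor range).

Quantile statistics are deliberate: supervoxels that straddle habitat
boundaries contain a few voxels of a neighbouring habitat, and because
inter-habitat contrast far exceeds within-habitat noise, even a 2% impurity
would dominate a moment-based SD (mixture variance grows with p(1−p)Δμ²).

Cluster count: k-means (k-means++ init, 10 restarts, tol 1e-6) for each
candidate K ∈ {2..6} on column-standardized features; chosen K maximizes the
Calinski-Harabasz index, with silhouette scores reported alongside for
validation. K is then fixed (default 3) and applied to both timepoints of a
patient — the longitudinal contract. Clusters are relabelled by descending
voxel-weighted mean intensity (ties broken by larger volume), so label 1 is
always the high-enhancement habitat; the labelling is canonical and
permutation-invariant. Masks under 200 voxels cluster voxels directly
(supervoxel step skipped). The cohort-wide vs per-patient clustering mode is
exposed through the same functions; per-patient with fixed K = 3 is the
default.

## Feature panel

Per region: 14 shape features (marching-cubes mesh of the region smoothed
with a σ = 1 voxel Gaussian to suppress staircase artefacts in surface
estimates; principal-axis lengths from the voxel point cloud) plus 93
intensity/texture features — 18 first-order, 24 GLCM, 16 GLRLM, 16 GLSZM,
14 GLDM, 5 NGTDM — on each of 13 channels: original, 8 single-level
stationary-wavelet sub-bands (coif1; undecimated so sub-bands stay
voxel-aligned), and Laplacian-of-Gaussian at σ = 2, 3, 4, 5 mm. That yields
14 + 93×13 = 1223 features per region, 3×1223 = 3669 per timepoint for the
habitat panel, and 2×(1223+3669) = 9784 per patient — the published
accounting this panel was reverse-engineered to match; the wavelet/LoG
channel split and the σ values are configuration, since no source lists them.

Texture conventions: fixed bin width 25 intensity units (post-
standardization); GLCM distance 1, 13 unique 3D directions, symmetric,
features averaged over directions; GLRLM likewise direction-averaged; GLSZM
zones and GLDM dependencies use 26-connectivity; GLDM dependence = 1 + the
number of neighbours within α = 0 grey levels. Regions under 8 voxels yield
an explicitly flagged all-NaN vector rather than being dropped; single-grey-
level regions produce the defined degenerate values (never NaN). The
matrices are validated against brute-force enumeration oracles (pair
counting, line walking) in the test suite.

## Selection cascade

Fixed order, counts non-increasing, every dropped feature keeps a reason:

1. **Reliability**: ICC(2,1) — two-way random effects, absolute agreement,
   single measurement — must exceed 0.8 for both intra-reader (re-reads) and
   inter-reader (different readers) tables. Zero-variance features get
   ICC 0. Below 5 patients the estimate is refused as unstable.
2. **Redundancy**: variance floor 1e-8, then greedy Spearman pruning —
   features visited in decreasing univariate rank |U − n₁n₂/2| (name as
   deterministic tie-break); a feature survives only if |ρ| ≤ 0.9 with all
   previously kept features.
3. **Univariate**: two-sided Mann-Whitney U, p < 0.05, *no* multiplicity
   correction — a deliberately liberal stage mirrored from practice; BH
   correction is reported downstream in the expression analyses instead.
4. **Sparse selection**: L1-penalized logistic regression on standardized
   features; λ chosen by stratified k-fold (default 10) cross-validated
   log-loss at the minimum (a 1-SE rule is not used).

## Response models

`ResponseModel(table, labels, clinical=None).fit()` returns a
`ResponseResults` carrying a frozen `ModelBundle` (feature list,
standardization statistics, decision threshold, learner). The learner is a
gradient-boosted tree ensemble (depth 3, learning rate 0.1, 200 trees, 80%
row subsampling, fixed seed) — modest settings for cohorts of tens to
hundreds of patients. Fusion models concatenate selected pre- and
mid-treatment features with one-hot clinical covariates (cT stage 4 levels,
ER, HER2) into a single learner; score-stacking was considered and rejected
for simplicity. The decision threshold is Youden's J on training
predictions, frozen into the bundle; applying a bundle never refits and
reproduces training predictions bit-for-bit.

Evaluation: AUC via the Mann-Whitney (midrank) formulation with DeLong
variance and normal CIs; Wilson CIs for sensitivity/specificity; quantile-
binned calibration with a logistic recalibration intercept/slope; decision
curves NB(t) = TP/n − (FP/n)·t/(1−t) against treat-all/treat-none; subgroup
evaluation without refitting, flagging subgroups under 10 patients or with a
single class.

## Immune association

* TPM: TPM_g = 10⁶·(c_g/L_g)/Σ_j(c_j/L_j); columns sum to 10⁶ exactly.
* Differential expression: per-gene two-sample moderated t on log2(TPM+1).
  The scaled-inverse-chi-square variance prior (d₀, s₀²) is fitted by moment
  matching of the sample variances against their scaled-F marginal
  (d₀ = (2d − 4 + 4vd)/(vd − 2) with v the squared coefficient of variation
  of s²; v·d ≤ 2 collapses to no shrinkage). BH-adjusted p-values are
  reported alongside raw ones.
* Preranked GSEA: weighted KS running sum (weight exponent 1); the null is
  gene-label permutation (random same-size sets); NES divides ES by the mean
  |ES| of same-sign permutations; p is the same-sign tail with the +1
  correction.
* ssGSEA: per-sample rank weights rank^0.25, running-difference sum between
  the weighted in-set and unweighted out-set ECDFs, min-max normalized
  across the cohort.
* Marker indices: mean log2(TPM+1) over compact marker panels shipped as a
  JSON data file (B, T, cytotoxic lymphocyte, myeloid, endothelial,
  fibroblast); the B panel combines lineage markers (CD19, CD79A, MS4A1)
  with immunoglobulin genes (IGHM, IGHG1, IGHG2).
* Ro/e: observed over expected cell counts under row/column independence;
  margin conservation is exact.
* Group comparisons: Wilcoxon rank-sum, exact for ≤ 10 untied observations
  per group, normal approximation with tie correction otherwise. High/low
  model-score groups are formed by median split.

## Synthetic study conditions

The generator emulates the data-generating structure the pipeline assumes —
not MR physics. Tumors are smoothly perturbed ellipsoids (≈ 4800 voxels at
the default 32³ grid; 28³ in cohort runs) containing three latent perfusion
classes grown from seeds by quota-repaired competitive assignment, so each
class is a spatially coherent blob whose volume fraction matches its target
exactly. Class intensity models differ in mean *and* dispersion
(μ = 300/200/100 at SD = 20/8/14 by default, noise SD 10): vascular tissue
is texturally heterogeneous, the transitional rim uniform, necrotic cores
intermediate — which makes habitats separable in (median, log-spread,
entropy) space rather than along a single intensity axis. The class-1
habitat's *arrangement* is a free parameter from compact core (0) to
peripheral rim (1).

Cohorts draw clinical covariates (cT stage, ER, HER2 at realistic marginal
frequencies), per-patient compositions (Dirichlet), contrasts, dispersion
jitters, and arrangements; the outcome follows a logistic model

    b0 + effect·(z(f1_mid) + 0.5·z(rim_mid) + 0.25·z(contrast_mid)) + clinical

with b0 solved so the cohort prevalence matches the target pCR rate (0.396,
the published pooled rate). Three constructions keep this signal strictly
subregional: per-patient class means are solved so every tumor has the same
whole-tumor mean (200) *and* variance (10⁴) — moment pinning — and the
arrangement term changes habitat geometry without touching the histogram at
all. Whole-tumor first- and second-moment summaries therefore carry no
outcome signal by construction, which is the premise habitat analysis
tests. The default effect size of 2.5 places the subregional oracle AUC in
the high-0.8s, the discrimination regime of interest for neoadjuvant
response models; effect sizes in real data are unknown and the parameter is
free.

Reader variation is simulated by thresholding the mask's signed Euclidean
distance against a smooth Gaussian random field (correlation length ≈ 4
voxels, amplitude = magnitude in mm): magnitude 0 is the identity and Dice
decreases monotonically in expectation with magnitude.

Expression matrices are negative-binomial (lognormal gene baselines,
dispersion 0.15) with designated marker genes multiplied by 2^shift in the
high group and lognormal gene lengths for TPM; cell-type tables are
per-patient multinomials over 7 types with the B-cell probability scaled in
the high group.

**What passing tests show — and don't.** Parameter-recovery results (K = 3
selection ≥ 90%, habitat ARI ≥ 0.8, Clin-SHR > Clin-TR by ≥ 0.05 held-out
AUC) demonstrate that the *pipeline* recovers planted structure under its
own assumptions; they are not evidence about real DCE-MR data, where habitat
boundaries are not crisp, class counts are not known, intensity
distributions are not Gaussian mixtures, and scanner effects exceed what
histogram standardization removes. Published real-data figures (external
AUCs, NES values, selected-feature counts) depend on undeposited patient
data and are deliberately not targeted.

## Simulation scale

Chosen so the full suite and the acceptance script each run in minutes on
one core: K-selection consistency uses 50 phantoms at 36³ (≈ 7·10³ tumor
voxels, a ~2.4 cm tumor at 1 mm isotropic); habitat recovery 20 phantoms at
32³; the fusion benchmark 20 seeded cohorts of 80 patients at 28³
with a reduced panel (shape + first-order on the original channel, plus
habitat composition fractions — geometry must stay in the panel because the
arrangement signal is geometric); the full 1223-feature panel is exercised
on single phantoms where exact accounting is the point.

## Known limitations

* GAN-based resolution enhancement, DICOM ingestion, scRNA clustering/
  annotation, RECIST/interobserver analyses, and survival endpoints are out
  of scope.
* The 1223-feature decomposition (8 wavelet + 4 LoG channels, family sizes)
  is the only one consistent with standard family sizes, but remains an
  inference; σ values and bin width are configuration.
* GLDM has no canonical standardized definition; the dependence convention
  used here (centre counted, α = 0) is documented above and frozen by tests.
* The moderated-t prior is moment-matched, not marginal-likelihood fitted;
  for thousands of genes the difference is negligible, for tens it is not.
* Ro/e and the rank-sum comparisons treat patients as exchangeable; no
  per-patient random effects.
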