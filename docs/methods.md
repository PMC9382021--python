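# Methods

This note records the models, conventions and design choices behind
`habitomics`, in the spirit of a package methods appendix. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Habitat partition

**Local entropy.** For each axial slice, intensities of the ROI are binned
into `n_bins = 32` equal-width bins spanning the slice's ROI intensity
range; for every ROI pixel the Shannon entropy (bits) of the bin-occupancy
histogram inside a 9 × 9 window is computed, with the window clipped at the
image edge. By default only in-mask neighbors contribute, so the map
measures intratumoral texture rather than the tumor/background step edge;
`restrict_to_mask=False` restores plain windowing. 32 bins keeps an 81-pixel
window from saturating (entropy is bounded by log2 32 = 5 bits) while still
resolving compartments whose intensity spread differs by a factor of a few.
Entropy is affine-invariant by construction (bins track the ROI range), and
zero on constant ROIs.

**Patient-level superpixels.** Within each slice, k-means (k-means++ init,
10 restarts, tol 1e-6, seeded) clusters the 2-D points (z-scored intensity,
z-scored entropy). The superpixel count is density-based:
`ceil(ROI pixels / 1000)`, clamped to [2, 20]. The density matters: a
superpixel's (mean intensity, mean entropy) descriptor should estimate a
compartment-level phenotype, which requires averaging over enough pixels
that pixel noise cancels. At a few tens of pixels per superpixel, k-means
simply tiles the per-pixel noise distribution into intensity bands, the
population descriptor cloud becomes a continuum, and dispersion-ratio
criteria then prefer many small clusters. At ~1000 pixels per superpixel a
sub-millimetre-resolution tumor cross-section still yields several
superpixels per slice and tens per patient. Superpixels are clusters in
feature space and may be spatially disconnected; this is accepted, matching
the habitat-clustering methodology.

**Population clustering and k selection.** All superpixels from all patients
are pooled; their (mean intensity, mean entropy) descriptors are z-scored
over the population and clustered by Ward-linkage agglomerative clustering
for k = 2 … 10. The Calinski–Harabasz index, evaluated on the same z-scored
descriptors, selects k (ties, including ties among +inf values in the
degenerate zero-within-variance case, resolve to the smaller k —
parsimony). Cluster labels map back to member pixels; subregions are named
S1, S2, … by decreasing pixel-weighted mean entropy, making S1 the most
heterogeneous (marginal) habitat deterministically.

Known behavior at small sample sizes: with only a few dozen superpixel
records, Ward can isolate near-coincident descriptor pairs, the
within-cluster dispersion of tiny clusters approaches zero, and CH spikes at
large k. Cohorts of ~15+ multi-slice cases are comfortably beyond this
regime; the tests cover both the stable regime and the exactly-separable
single-slice limit.

## Synthetic phantoms

Each phantom is an axis-aligned ellipsoid (default radius 8 mm) on a
constant background, sampled on a grid with 0.359 × 0.359 mm in-plane
spacing and 5 mm slices — a typical contrast-enhanced T1 acquisition
geometry. The shell ("rim", relative thickness 0.3) is drawn i.i.d. from
N(200, 30²), the interior ("core") from N(100, 5²). Gaussian i.i.d. noise is
a deliberate simplification: local entropy responds to local dispersion, so
a higher rim SD plants exactly the marginal high-intensity/high-entropy,
inner low-intensity/low-entropy dichotomy the partition should recover,
with analytically controllable ground truth.

Cohorts jitter per-case geometry and intensity parameters (radius ±15%,
rim fraction ±20%, means ±5–10%, SDs ±10–20%) to emulate between-patient
variability; without it, between-case feature variance would be dominated
by segmentation-perturbation variance and ICC would be uninformative.
Class 1 cases shift rim mean and rim SD by `effect_size × core_sd`.
Second-observer and repeat segmentations are simulated by a randomized
in-plane morphological perturbation of the mask boundary (a smoothed random
field chooses voxel-wise between the slice-wise dilation and erosion by
≤ magnitude voxels), mimicking manual re-contouring without a human.

What the phantoms do **not** model: MR physics (bias fields, Rician noise,
partial volume), spatially correlated texture, multifocality, and
anatomical context. Passing tests therefore demonstrate that the pipeline
recovers planted dispersion/intensity structure and that its statistics
behave as specified — not that it segments real metastases correctly.

## Handcrafted features

Filters: one-level stationary (undecimated) 3-D wavelet decomposition
(coiflet-1; sub-bands LLL … HHH, L = approximation, H = detail per axis);
Laplacian of Gaussian with sigma in millimetres converted per-axis through
the voxel spacing (kernel truncated at 8σ so a constant input maps to zero
to float precision); square and signed square-root maps rescaled to the
original maximum absolute intensity; and 3-D local-binary-pattern maps
(42-direction icosphere sampling at radius 1 voxel; m1/m2 = first/second
moments of the binary pattern, k = excess kurtosis of the sampled
neighborhood). The LBP maps are a moment-map formulation; tests pin their
determinism and shape, not specific values.

Texture families follow IBSI definitions: GLCM (symmetric co-occurrence
over all distance-1 directions, features averaged over directions;
InverseVariance, Imc1 with the 0 convention when max(HX, HY) = 0,
Contrast), GLRLM (direction-averaged run-length features), GLSZM
(26-connected 3-D / 8-connected 2-D equal-level zones), NGTDM
(full-neighborhood averaging excluding the center, edge-clipped,
mask-restricted; single-gray-level ROIs give Contrast = Busyness = 0).
Masks confined to one slice automatically use the 2-D direction/
connectivity sets. Every family is verified against an independent
brute-force oracle (explicit pair/run/zone/neighborhood enumeration) to
1e-9 in the test suite.

Discretization defaults: fixed bin width 25 on the original image, fixed
bin count 32 on filtered images (filtered intensities have no stable
physical scale). Both are configurable on `FeatureConfig`; the original
acquisition-specific preprocessing of the source models is not public, so
these defaults are declared rather than inferred.

First-order statistics use linearly interpolated percentiles, population
(biased) variance and skewness (0 for constant samples), and mean absolute
deviation about the mean.

## Deep features

The contract is backbone → global average pooling → 512-unit fully
connected layer; the 512 post-ReLU activations are the features (recording
after the nonlinearity is the common transfer-learning convention and keeps
features nonnegative; a softmax head exists but is unused in feature mode).
Inputs are the largest axial slice of the chosen subregion, zeroed outside
the subregion, cropped to its bounding box, zero-padded to a square and
bilinearly resized to 224 × 224, then min-max normalized and replicated to
three channels.

The built-in `tiny-test-cnn` backbone (two conv-ReLU-avgpool blocks, 8 and
16 maps, seeded Glorot-style random weights, pure numpy) makes the full
image → feature path deterministic and verifiable against hand-constructed
weights. Random-projection convolutional features are texture-sensitive but
carry no semantic claim. A standard ResNet50 backbone is available as a
plug-in when torch and a weight file are supplied; no test or default path
requires it.

## Selection chain

Applied identically to handcrafted and deep features, in order:

1. **ICC filter.** Two-way random-effects, absolute-agreement,
   single-measurement ICC, computed from the two-way ANOVA decomposition.
   Inter-observer ICC uses a second observer's segmentation; intra-observer
   ICC uses a repeat segmentation by the first observer. Keep threshold
   0.75 ("good" reproducibility), configurable. Zero-variance features are
   undefined and dropped at this stage.
2. **Mann-Whitney screening** at two-sided P < 0.05 on the training split.
   Exact enumeration for combined n ≤ 12 (tie-aware), tie-corrected normal
   approximation otherwise. No multiplicity correction — the conventional
   radiomics practice, deliberately retained and noted as permissive.
3. **Standardization.** z-scores fitted on the training split only and
   applied to validation; model coefficients therefore act on z-scored
   features and the intercept is the log-odds at feature means.
4. **LASSO-logistic** over a 40-point log-spaced penalty grid, stratified
   10-fold CV, lambda* at the minimum held-out deviance (ties resolve to
   the stronger penalty); features with nonzero coefficients pass. The
   CV-minimum rule (not 1-SE) is the default and exposed in config.
5. **Stepwise logistic regression**, bidirectional, information-criterion
   driven. BIC is the default: with cohorts of one or two hundred cases,
   AIC's fixed 2-point penalty admits a chance feature roughly every third
   run under the null (P(χ²₁ > 2) ≈ 0.16 per candidate), while BIC's log(n)
   penalty keeps null data at the intercept-only model; AIC remains
   available via `SelectionConfig(stepwise_criterion="aic")`. Perfect
   separation falls back to a lightly ridge-penalized fit with a warning.

## Evaluation

AUC is the pairwise concordance probability (ties ½); every call
cross-checks it against the rank-sum identity U/(n₁n₀). Confidence
intervals: DeLong placement-value variance by default (matching the
symmetric CIs usual in radiomics reports), stratified bootstrap (2000
seeded replicates) optionally. The operating threshold maximizes Youden's J
on the training scores and is frozen for validation; accuracy, specificity
and sensitivity are reported at that threshold.

## Pipeline and problem sizes

`run_pipeline` chains phantom generation → partition → handcrafted + deep
feature extraction under three segmentation sets (primary, second observer,
repeat) → selection → stepwise model → train/validation summaries, with
every stage seeded from one SeedSequence; identical configurations yield
byte-identical JSON. The default synthetic cohort is 40 cases (stratified
2:1 train/validation split — a common radiomics protocol when the true
split of a source study is unreported), 64 × 64 × 12 grids with ~8 mm
tumors. These sizes were chosen so the planted two-habitat structure and
class effect are comfortably detectable while a full run stays in the
couple-of-minutes range on one CPU; the acceptance script uses 10 cohorts
of 20 phantoms for the cluster-count experiment for the same reason.

## Known limitations

- Only the synthetic path is wired into `run_pipeline`; external NIfTI
  cohorts go through the library functions (`read_volume`, `read_mask`,
  `build_partition`, `extract_all`, …) and the `phantom`/`partition` CLI.
- The partition treats slices independently within a patient (per-slice
  clustering), consistent with slice-wise habitat methodology; no 3-D
  superpixels.
- ICC under alternative segmentations intersects the *fixed* partition
  labels with each mask rather than re-running the partition per observer;
  this isolates segmentation variability from clustering variability and
  keeps the chain O(cohort) rather than O(cohort × observers).
- The LBP-3D maps are a documented moment-map formulation, not a verbatim
  reimplementation of any specific package's spherical-harmonic variant.
- CH-based k selection is unreliable below a few dozen superpixel records
  (see above).
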