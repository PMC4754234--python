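# Methods

This note documents the models, numerical choices and known limitations of
the package. It is written for users who want to understand what each stage
computes and what the synthetic validation does — and does not — establish.

## Pipeline overview

A DaT-SPECT volume passes through five stages:

1. **Spatial normalization.** Every subject is rigidly registered (6 DOF)
   to a template built by averaging co-registered control scans and
   symmetrizing across the mid-sagittal plane, `T ← (T + reflect(T))/2`.
   Rigid-only alignment is deliberate: the pipeline needs a common overall
   position, not voxel-perfect anatomy, and rigid transforms cannot distort
   the striatal shape features extracted later.
2. **Intensity normalization.** The in-brain intensity histogram is
   summarized by a skewed α-stable law (α stability, β skewness, γ
   dispersion, μ location). Each image is mapped by `Y = aᵢX − bᵢ` with
   `aᵢ = γ*/γᵢ`, `bᵢ = aᵢμᵢ − μ*`, the unique linear map sending every
   fitted `(γᵢ, μᵢ)` to the pooled means `(γ*, μ*)`.
3. **Striatal segmentation.** Per hemisphere, voxels inside the brain mask
   become 4-vectors (intensity, i, j, k); a two-component full-covariance
   Gaussian mixture is fitted by EM, each voxel is labeled by the larger
   normalized component likelihood `exp(−½ mahal²)/|Σ|^{1/2}` (unweighted;
   MAP with mixture weights is available as an option), and the largest
   26-connected component of the higher-mean-intensity class becomes that
   side's striatal mask.
4. **Ellipsoid fitting.** The mask's surface voxels (those with a
   6-connected background neighbour) are fitted with the ellipsoid
   `(X−U)ᵀRᵀDR(X−U) = 1` minimizing the summed squared Euclidean
   point-to-surface distances `Σ Lᵢ²` by Levenberg–Marquardt over centre,
   axis-angle rotation and log-semi-axes.
5. **Features, classification, correlation.** Per side: MEU (mean intensity
   inside the fitted-ellipsoid ROI), DI = 1 − Π|Eᵢ^S·Eᵢ^T| over rank-paired
   unit eigenvectors of subject and template ellipsoids, SMU = MEU·(1−DI),
   and optionally SBR = (C_str−C_occ)/C_occ against an occipital reference
   box. A linear-kernel SVM with per-fold standardization and leave-one-out
   cross-validation separates patients from controls; SMU is related to
   motor scores by Spearman rank correlation plus linear and exponential
   (`y = a·e^{bx}`) least-squares fits with adjusted R² at df = n − 2.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| registration levels | 4, 2, 1 | multiresolution block-mean factors |
| registration max_iter | 40 | Powell iterations per level |
| brain-mask fraction | 0.05 | threshold at q01 + 0.05·(q99.5 − q01) |
| GMM components M | 2 | striatum vs background, per hemisphere |
| EM tolerance | 1e−6 (relative) | convergence of the log-likelihood |
| EM max iterations | 500 | hard cap |
| segmentation seed | 17 | drives any seeded initialization |
| ellipsoid optimizer | LM, ftol 1e−10, ≤2000 evals | surface-distance least squares |
| SVM | linear kernel, C = 1 | standardized features, LOO |

## The α-stable estimator

Parameters are estimated by quantile matching in the spirit of McCulloch's
estimator: the location/scale-free ratios
ν_α = (x₉₅−x₀₅)/(x₇₅−x₂₅) and ν_β = (x₉₅+x₀₅−2x₅₀)/(x₉₅−x₀₅) are matched
against a precomputed grid of standard stable quantiles (S0
parameterization, α ∈ [0.6, 2], β ∈ [−1, 1] by mirror symmetry), then γ
scales the interquartile range and μ shifts the median. The estimator is
closed-form fast, deterministic, and exactly location/scale equivariant —
which makes the normalization a true fixed point: renormalizing normalized
data returns aᵢ ≈ 1, bᵢ ≈ 0 to float precision of the quantiles. At the
Gaussian boundary (α → 2) skewness is unidentifiable and β is pinned to 0.
The brain-mask threshold is quantile-anchored rather than a fraction of the
robust maximum alone, so the mask itself is invariant under the linear
normalization map; without this the fixed-point property fails through
mask drift at the partial-volume rim.

## Segmentation: initialization and masks

Two deliberate choices depart from a naive reading of the method:

* **EM initialization.** With spatial coordinates in the feature vector,
  the globally best two-component mixture on a brain-shaped support is
  often a *spatial* split of the hemisphere (one Gaussian fits a uniform
  half-ellipsoid of coordinates poorly, so splitting space buys more
  likelihood than isolating the small striatal cluster). That optimum is
  useless for uptake segmentation. EM is therefore started from a
  top-0.5%-intensity quantile split, which steers it to the uptake-relevant
  local maximum — the solution the labeling step ("the component with the
  highest uptake") presupposes. Monotone likelihood and determinism are
  unaffected. A seeded k-means++ start remains the generic default of
  `fit_gmm_em` for data without this pathology.
* **Rim exclusion.** The segmentation-stage brain mask keeps voxels above
  half the median in-brain template intensity. The partial-volume rim of
  the brain (intensities ramping from background to zero) otherwise forms
  a better two-cluster structure than background-vs-striatum at patient
  contrast, and the mixture latches onto it.

Degenerate inputs: a constant volume yields an empty brain mask and raises
an empty-segmentation error naming the side. A *noisy* but featureless
brain is not detected as empty — the hot component then covers a diffuse
region; downstream features (low MEU, unstable orientation) carry the
"no focal uptake" signal instead. Covariance collapse during EM is guarded
by a trace-scaled ridge (1e−6·tr(Σ)/d) with a logged warning.

## Ellipsoid distance and fit

The point-to-surface distance is computed in the principal frame from the
Lagrange condition: the unique root t of
`F(t) = Σ (aᵢyᵢ/(t+aᵢ²))² − 1` on (−a_min², ∞), found by safeguarded
bracketing bisection (120 iterations, relative error ≪1e−9); the centre is
handled exactly (distance = smallest semi-axis) and exact zeros in
principal coordinates are nudged by ~1e−9·a_min, which perturbs the
distance by no more than the same amount (the distance is 1-Lipschitz).
The fit is initialized from moments (centroid, covariance eigenvectors,
axes ∝ √eigenvalues rescaled to the RMS normalized radius) and never
returns an energy above the initializer's. Fitting the surface voxels of a
*voxelized* solid biases axes inward by roughly half a voxel (surface-voxel
centres lie strictly inside the continuous surface); grid-aligned centres
are the worst case for this staircase bias.

The dysmorphic index pairs eigenvectors by semi-axis rank. When adjacent
semi-axes are within 2% of each other the pairing is unstable and a warning
is emitted; DI is still returned (it is continuous in the inputs even if
the pairing is not).

## The phantom generator

The generator emulates a DaT-SPECT study at desk scale: 64×64×48 voxels at
2.95 mm, a brain-shaped background ellipsoid (baseline 1.0 with ±10%
smooth heterogeneity, correlation length 15 mm), and per side a comma-
shaped striatum — a 10×20×8 mm half-axis "body" (caudate-like) plus a
6×11×6 mm posterior "tail" (putamen-like) — at 3× background uptake.
Degradation is scaled-Poisson count noise (50 counts per unit intensity)
followed by a 10 mm FWHM Gaussian point-spread blur.

Disease severity is one number per side, damage ∈ [0, 1]:
tail uptake fades by (1 − 0.95·damage) and the tail shrinks linearly to
nothing (comma → dot), body uptake fades by (1 − 0.45·damage) — the
posterior-to-anterior progression of dopaminergic loss, which keeps the
caudate remnant conspicuous at cohort-maximal severity as in real scans —
and the body rotates about the axial direction by 45°·damage unless an
explicit rotation is given. Cohorts draw control damage from U(0, 0.1) and
patient dominant-side damage from U(0.5, 0.9) with the other side at
0.3–0.8× the dominant (unilateral onset). Motor scores follow the monotone
link UPDRS = 69 − 21·mean(true SMU) + N(0, 7), clipped at zero, with the
clinically most affected side contralateral to the dominant striatal
damage; the constants are calibrated so a default 31-patient group shows
scores near 29 ± 8.5 points and a rank correlation with SMU around −0.5.

What the phantoms do *not* model: projection-space physics (sinograms,
attenuation, scatter, reconstruction filters), anatomical detail beyond
two-lobe striata, and inter-subject anatomical variability beyond pose and
noise. Passing the synthetic suite therefore demonstrates that the
algorithmic chain is correct and discriminates the programmed effects; it
does not by itself establish clinical accuracy on patient data.

## Known limitations

* **Partial-volume shell vs geometric masks.** At 10 mm PSF (3.4 voxels)
  the maximum-likelihood decision boundary between the two mixture
  components lies about one to two voxels *outside* the geometric striatal
  surface, so segmented masks contain the true striatum almost entirely
  (recall ≈ 1) but run 2–3× its volume; Dice against the geometric mask
  plateaus near 0.5–0.65 for anatomically sized, elongated striata. A
  fixed-contrast threshold at 30–40% would score Dice ≈ 0.9 but is not the
  mixture-model method. Downstream features are robust to this: the MEU is
  computed over the fitted-ellipsoid ROI (diluted for every subject
  equally), and DI depends only on orientation.
* **Severe disease.** At damage ≳ 0.9 and 3× baseline contrast the faint
  striatum occasionally loses the mixture competition to background
  heterogeneity and the mask goes diffuse. The resulting features (MEU near
  background, large DI) still classify such subjects correctly, but their
  masks are not anatomically meaningful.
* Ellipsoid fitting and ROIs work in voxel-index coordinates; with
  anisotropic spacing the fitted shape is distorted accordingly. All
  defaults here use isotropic grids.
* The exponential severity fit requires strictly positive scores and is
  fitted on the original scale (log-linear start); its adjusted R² uses
  df = n − 2, stated in the output metadata. No multiple-testing correction
  is applied across the clinical-score family, and this is flagged in the
  report metadata.

## Problem sizes in the shipped validation

The validation suite runs the full pipeline once on a 31-patient /
12-control cohort at 64×64×48 (the cohort-level classification check),
plus per-stage checks on single phantoms, 5–10-phantom batches, and
small synthetic datasets (n ≤ 5000 for mixture recovery, n = 31 for the
correlation machinery). These sizes mirror the emulated study's cohort
while keeping a complete run in minutes on one CPU.
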