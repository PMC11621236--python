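# Methods

This note documents the models, estimators and numerical conventions the
package implements, the design of the synthetic data generator, and the
choices made where the design was genuinely open.

## Track-weighted dynamic functional connectivity

The BOLD series of length *T* timepoints is segmented into rectangular
sliding windows of `length_tp` timepoints advanced by `stride_tp`
(default 1); the number of windows is `floor((T − L)/stride) + 1` and the
last window lies fully inside the series.  For streamline *i*, FC_i(t) is
the Pearson correlation of the two endpoint-voxel BOLD signals within
window *t*; the tw-dFC value of voxel *v* is the mean of FC_i(t) over the
N_v streamlines traversing *v*.  Implementation notes:

* Endpoint sampling uses the single voxel containing each terminal point
  (partial-volume effects are expected to be handled by smoothing the BOLD
  beforehand; `smooth_bold` provides the Gaussian kernel, default analog
  6 mm FWHM for real data).
* Windows in which an endpoint series has zero variance yield an undefined
  correlation; undefined values are *excluded* from the voxel average (NaN
  propagation), never treated as 0 — zero is a data value, not a missing
  one.  A voxel-window with no defined contribution is NaN.
* Voxels traversed by exactly one streamline copy that streamline's FC
  series without arithmetic, so the propagation property is bit-exact.
* Correlations are computed in float64 with explicit within-window
  centering; agreement with a naive per-window `corrcoef` loop is at the
  1e-12 level.
* Output spatial resolution equals the BOLD resolution (no track-weighted
  super-resolution).

### Streamline geometry

World (mm, RAS) points map to voxels by `floor(A⁻¹p + 0.5)` — voxel-centre
cells with half-open boundaries resolved upward.  Voxel traversal of a
polyline is computed *exactly* by an Amanatides–Woo grid walk per segment
(rather than supersampled point sampling, which can skip thin corner
clips); the dense-sampling oracle in the tests confirms agreement.
Streamlines with either terminal point outside the grid are excluded from
the traversal index and counted.  TCK I/O goes through
`nibabel.streamlines` and preserves coordinates to float32.

## Parcellation

* **WM analysis mask**: mean of subject WM probability maps thresholded at
  ≥ 0.5, minus the seed ROIs dilated by 4 mm (Euclidean distance transform
  with physical voxel sizes), so neither seed signal nor its partial-volume
  surround enters the feature space.
* **Series extraction**: WM tw-dFC is block-mean downsampled by an integer
  factor (default 2, i.e. 2 mm → 4 mm) over defined (traversed, non-NaN)
  entries only; the seed stays at native resolution.
* **Fingerprints**: Pearson correlation between every seed-voxel and every
  WM-voxel series over the jointly defined windows, Fisher r-to-z with the
  argument clamped to ±(1 − 1e−7); zero-variance series give z = 0 (logged).
* **k-means**: Euclidean distance on z-profile rows; centroids initialized
  at k randomly chosen data rows; best of `n_init` (default 100) restarts
  by within-cluster sum of squares; deterministic given a seed.
  scikit-learn's Lloyd implementation (`init="random"`) provides exactly
  this scheme; its empty-cluster relocation (re-seeding at the points
  farthest from their centroids) keeps k fixed.
* **Consensus**: subject-level binary co-assignment matrices q_ij
  (1 iff voxels i, j share a cluster) are averaged across subjects and
  k-means is applied to the rows of the group matrix.  Hemispheres are
  parcellated independently.

## Validity metrics

* **Silhouette**: mean of (b − a)/max(a, b) in Euclidean feature space;
  singleton clusters and 0/0 degeneracies score 0.  Individual-level
  scores use the Fisher-z fingerprint rows; a group-level score can be
  computed on the group co-assignment rows (the feature space of the group
  clustering).
* **nVI**: VI = H(p₁) + H(p₂) − 2I(p₁,p₂) in nats, normalized by ln N so
  that one-cluster-vs-all-singletons equals exactly 1; partitions equal up
  to relabelling return exactly 0 (detected from the contingency table).
  Split-half stability draws disjoint random halves of the cohort (the
  first half receives the extra subject when the count is odd), recomputes
  the consensus per half, and records the nVI between the two half
  solutions; 100 resamples by default.
* **ANOVA/Tukey**: `scipy.stats.f_oneway` plus statsmodels
  `pairwise_tukeyhsd` over the per-k score samples.
* **Dice matching**: greedy matching on descending pairwise Dice, each
  cluster used once, ties to the lower index pair.  On structured random
  cases the greedy match coincides with the exhaustive optimal assignment
  ≥ 95% of the time (tested); greedy is the documented choice.
  Empty-vs-empty Dice is defined as 1.

## Characterization and inference

* Cluster time courses are across-voxel means of the cluster's defined
  tw-dFC values per window; whole-brain correlation maps are Fisher-z of
  the Pearson correlation with every traversed voxel's series.
* Winner-takes-all assigns each voxel to the cluster with the highest
  group-mean z (ties to the lowest index; voxels with no positive z stay
  background), and subject z maps masked to each territory undergo the
  permutation test.
* **Permutation one-sample test**: voxelwise t across subjects; the null is
  built by random sign-flipping of whole subject maps, with the unpermuted
  labelling included so p ≥ 1/(n_perm + 1); the FWE-adjusted p of a voxel
  is the fraction of null iterations whose maximum |t| over the analysis
  mask reaches that voxel's |t|.  Zero-variance voxels are excluded.
  Default 5000 permutations at α = 0.001 for real-scale use; the test
  suite uses 300–500 permutations at α = 0.05, which preserves calibration
  (verified empirically: run-level type-I error 0.05 over 200 null
  datasets).
* **Lateralization**: LI = (Z_left − Z_right)/(Z_left + Z_right), guarded
  where |Z_left + Z_right| ≤ ε (default 1e−3).  Homotopic correspondence
  is established by reflecting the right-seed maps along the left-right
  axis (in a symmetric standard space this is the homotopic-flip
  convention); left and right clusters are paired by Dice of their
  (reflected) WTA territories.  LI is evaluated only where both
  hemispheres' group preferential maps are FWE-significant: outside that
  bilateral support the ratio degenerates to ±1 wherever one map is near
  zero, which would manufacture spurious lateralization.  Inference is a
  single joint sign-flip test with the max statistic taken over all
  cluster pairs' supports (shared subject flips), so family-wise error is
  controlled over the entire LI analysis rather than per cluster.

## Decoding

Term maps are optionally masked to grey matter, track-weighted (mean of
the scalar sampled at each streamline's points, averaged per voxel over
traversing streamlines), and ranked by Pearson correlation with a
connectivity map over in-mask voxels; ranking is invariant to positive
affine rescaling of term maps, ties break by name.  In the synthetic
experiment the connectivity input is the bilaterally averaged group
cluster map and the ranking mask is the WM analysis mask — seed voxels
carry near-saturated self-correlation z values that would otherwise
dominate the spatial correlation.

## Synthetic scenes

The generator plants the statistical structure the analysis assumes, at
workstation scale.  Defaults (the study conditions): 24³ grid, 2 mm
voxels, TR 1 s, T = 440 timepoints, 20 subjects, k_true = 4 clusters,
150 streamlines per cluster per hemisphere, coupling amplitude 0.9, base
coupling period 200 s, voxel noise SD 0.3, planned window 40 timepoints.

Geometry: a 4×6×6-voxel seed block per hemisphere (mirror images),
partitioned into k_true planted clusters by contiguous chunks of the
(y,z,x)-sorted voxel list; one 3×6×6 ipsilateral target territory per
cluster per hemisphere at distinct peripheral locations, the right
territories exact x-reflections of the left; a second, differently
oriented partition of the seed serves as synthetic "atlas nuclei" so
overlap tables are non-trivial.  Streamlines leave the seed along x
within their own (y,z) column — so each seed voxel is traversed only by
its own cluster's bundle — then bridge to the target face nearest the
seed and descend into the territory along per-target-voxel tails;
right-hemisphere streamlines are bit-exact mirror images of the left
ones.  Every seed voxel and every target voxel is covered by at least one
endpoint, so the whole network has defined tw-dFC.

Dynamics: per cluster c and hemisphere, a standard-normal latent x(t)
drives the seed voxels, and the target voxels receive
u(t) = r_c(t)·x(t) + √(1 − r_c(t)²)·η(t) with
r_c(t) = amplitude · ½(1 + sin(2π t/P_c + φ_c)), so the instantaneous
seed–target correlation is exactly r_c(t).  The cluster periods P_c are
chosen so cluster c completes an integer number of cycles (2, 3, 4, …)
over the span covered by the window centres of the planned window;
distinct integer cycle counts make the cluster waveforms mutually
orthogonal, which is what makes k clusters × 2 hemispheres identifiable
from windowed correlations (a single shared period with distinct phases
provably leaves some pair of waveforms collinear or ambiguous).  The two
hemispheres of a cluster share the identical waveform but independent
latents: under equal amplitudes the mirrored systems are exactly
exchangeable — the basis of the lateralization null — and
`right_coupling_scale` scales the right-hemisphere r(t) for power
studies (amplitude × scale must stay ≤ 1).  Gaussian voxel noise of SD
`noise_sd` is added everywhere.

What the generator does *not* emulate: hemodynamic response convolution,
scanner/physiological noise spectra, head motion, partial-volume mixtures,
geometric distortion, or tractography errors (false-positive/negative
streamlines).  Passing tests therefore demonstrate the correctness and
calibration of the estimators and inference under the assumed data model,
not robustness to acquisition artefacts.

### Detectability and problem sizes

Windowed-correlation estimates carry irreducible sampling noise of
variance ≈ (1 − r²)²/L per window, so how faithfully FC_i(t) tracks the
planted r_c(t) is bounded by the window length relative to the coupling
period.  The tracking property (Pearson ≥ 0.9 between FC series and
window-averaged r) is demonstrated on a dedicated noise-free long-scan
configuration (16³ grid, T = 1200, window 100, base period 1100 s,
amplitude 1.0); at the default analysis scale the tracking is weaker but
parcellation does not require it — cluster identity is carried by the
orthogonal waveforms.

Test-suite and acceptance-script problem sizes are chosen for
workstation-scale runs: permutation tests use 300–500 permutations at
α = 0.05 instead of 5000 at 0.001 (calibration is permutation-count
invariant), lateralization null rates use 20 runs of 10-subject scenes,
power and recovery use the full 20-subject default, and split-half nVI
uses the full 100 resamples.

## Known limitations

* The file-based `run_pipeline` driver covers simulation-backed and
  file-backed inputs but characterization/decoding beyond the overlap
  table are exposed through the library API rather than the driver.
* Greedy Dice matching can be suboptimal on highly confusable partitions
  (it is never better than the exhaustive optimum; discrepancies are
  possible and the greedy rule is the documented behaviour).
* The lateralization analysis assumes a mirror-symmetric grid (even
  first-axis dimension with a symmetric affine) for the homotopic flip.
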