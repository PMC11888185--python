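# Methods

This document records the scientific model the `toibn` package implements, the
numerical choices it makes, and the rationale behind its default parameters.

## 1. Problem setting

Subject-level intrinsic brain network estimation starts from a 4D fMRI scan
`Ys` (T timepoints × V masked voxels) and a set of K group-level reference
spatial maps `theta_G` (K × V). The standard two-stage regression (dual
regression) estimates per-subject network timecourses and spatial maps by
ordinary least squares:

1. timecourses: `TCs = Ys @ pinv(theta_G)` (T × K),
2. spatial maps: `theta = pinv(TCs) @ Ys` (K × V).

OLS maps are noisy: thresholded subject maps routinely show spurious
components and holes that the reference networks do not have. The method
implemented here regularizes each subject map toward the *topology* of its
reference network, without forcing voxel-wise agreement.

## 2. Topology of a voxel map

### 2.1 Filtration and complex

A spatial map is analyzed through its superlevel sets `{v : map(v) > t}` as
the threshold `t` decreases from +∞. Connected components (H0) appear at
local maxima and merge at saddles; loops (H1) appear when a ring of
high-valued voxels closes around a low-valued center. Cavities (H2) are
omitted: at realistic map resolutions they are rare and noise-dominated.

The voxel grid is triangulated with the Freudenthal (Kuhn) construction
restricted to the brain mask: vertices are masked voxels; edges connect voxel
pairs whose coordinate offset is a nonzero 0/1 vector (up to 7 forward
neighbors); triangles are monotone chains `p, p+d1, p+d1+d2` with `d1, d2`
nonzero 0/1 vectors of disjoint support (12 per base vertex). H1 of this
2-skeleton equals H1 of the full triangulation, because 3-cells only affect
H2 and above.

### 2.2 Persistence computation

Cell values are the minimum of their vertex values (superlevel convention);
cells are ordered by a deterministic total order on their determining vertex:
higher intensity first, ties broken by lower linear voxel index (x fastest,
then y, then z). H0 pairs come from union–find over edges in filtration
order with the elder rule (the higher-born component survives; ties to the
lower voxel index). H1 pairs come from GF(2) column reduction of the
triangle boundary matrix. Zero-persistence pairs are discarded. Each masked
connected component contributes one essential class whose death is pinned at
the minimum masked intensity. Every retained point carries the voxel that
determines its birth and the voxel (edge vertex) that determines its death;
this is what makes the loss differentiable.

Both kernels are numba-compiled, and the complex for a given mask is cached,
so a 2048-voxel diagram costs well under 10 ms — the correction loop below
computes ~18,000 diagrams in a full cohort run.

The implementation is verified exactly (dims, births, deaths) against an
independent full boundary-matrix reduction on structured fixtures and
batches of random masked grids, and the Euler characteristic routine is
verified against Betti numbers of the vertex-cubical complex (including
3-cells) via the Euler–Poincaré formula.

## 3. Topological loss

### 3.1 Matching

Subject and reference diagrams are compared per homology dimension. Both
point sets are sorted by descending persistence (ties: higher birth, then
lower birth voxel) and paired rank for rank. Surplus subject points — more
features than the reference has — are paired with a *zero target*: their own
birth with zero persistence (default), or the diagram origin (configurable).
Surplus reference points are left unmatched and unpenalized; the loss pulls
spurious subject features down but does not manufacture missing ones, which
gradient steps on at most two voxels could not do meaningfully anyway.

The loss is the squared-Wasserstein-style sum over matched pairs:

```
L_top = Σ (b_subj − b_target)² + (d_subj − d_target)²
```

### 3.2 Gradient

For an ordinary pair the target is constant, so the gradient is
`2(b − b_target)` at the birth voxel and `2(d − d_target)` at the death
voxel (essential points route their death term to the global-minimum voxel,
whose intensity *is* the essential death value). For a zero-persistence
target the target birth equals the subject birth, so the pair's loss is
`(d − b)²` and the exact derivative is `−2(d − b)` at the birth voxel and
`+2(d − b)` at the death voxel. Using the exact derivative (rather than
treating the target as constant) makes the analytic gradient agree with
central finite differences of the recomputed loss to ~1e−10 relative error.

The gradient is exact only locally: it is the derivative of the loss holding
the matching and the critical cells fixed, which is valid between
critical-value crossings. Descent therefore re-computes the diagram and the
matching at every iteration.

### 3.3 Known limitation: rank matching has no spatial awareness

The matcher pairs by persistence rank only. If a spurious component is *more
persistent* than the genuine one, it inherits the reference target and the
genuine component gets the zero target — descent then amplifies the impostor
and erases the real feature. This is intrinsic to diagram-space matching; at
the operating point (spurious features weaker than genuine ones) it does not
arise, but it bounds how large a perturbation the correction can fix.

## 4. Correction loop

Each network map `theta_k` is refined independently by gradient descent on

```
L_full = λ · L_top + (1 − λ) · L_mse
```

with the other networks frozen at their OLS fit, so the MSE term is
`mean((R_k − tc_k ⊗ theta_k)²)` with `R_k` the scan residual after removing
the frozen networks, and its gradient is `(−2/(T·V)) · tc_k @ resid`.

Before each diagram computation the map is z-scored within the mask, so
subject and reference intensities share a scale regardless of the OLS fit's
amplitude; the mean and SD are treated as constants in the gradient
(stop-gradient), i.e. the topological gradient is divided by the current SD.

Defaults: `λ = 0.5` (equal weight), `learning_rate = 0.01` on z-scored
intensities, `n_iterations = 150`. The fixed iteration count acts as early
stopping: run long enough, the topology term will overfit the subject map
onto the reference diagram exactly. Descent aborts with a diagnostic if the
loss turns non-finite or exceeds 10× its initial value (divergence, usually
a too-large learning rate). With λ = 0 and an OLS initialization the map is
a stationary point of the loss and does not move (verified to machine
tolerance).

## 5. Synthetic cohort

The generator produces the study the estimator expects, with known ground
truth. Its defaults are fixed study conditions.

- **Geometry**: 16 × 16 × 8 grid; brain mask is the inscribed ellipsoid with
  semi-axes `n/2 − 1` (640 voxels); a small interior sphere
  (`csf_radius = 1.6`) is the CSF region.
- **References** (`K = 3`): each network is a sum of two Gaussian bumps
  (`blob_sigma = 1.4`) placed around the ellipsoid at 0.68 radius,
  z-scored within the mask, then zeroed at CSF voxels — reference networks
  carry no CSF signal, which is what makes CSF a pure-noise floor for CNR.
  Construction rejects blob centers within 2σ of the CSF region.
- **Subject truth**: reference + smooth Gaussian perturbation
  (`perturb_sd = 0.15` z-units, smoothed at 2 voxels) per subject/network,
  zeroed at CSF.
- **Planted effect**: patients receive, in `effect_networks = (0,)`, either
  an `extra_component` (a remote bump of amplitude 3.0 placed diametrically
  opposite the network's blobs) or an `extra_hole` (a cylindrical depression
  through a blob, turning its superlevel sets into an annulus).
- **Scans**: `Ys = TC @ truth + noise`. Timecourses are stationary
  unit-variance AR(1) with `tc_autocorr = 0.4` (typical serial correlation
  at a ~2 s repetition time). Noise is Gaussian with `noise_sd = 2.0`
  against reference peaks of ~4 z-units (BOLD-like low contrast-to-noise),
  spatially smoothed at `noise_smooth = 0.85` voxels (≈ 6 mm FWHM at 3 mm
  voxels, the standard preprocessing smoothing) and rescaled to keep the
  marginal per-voxel SD at 1. Spatially correlated noise matters: with iid
  voxel noise the binarized maps are dominated by one-voxel speckle whose
  near-zero persistence the topological loss cannot act on, a regime real
  smoothed fMRI is never in.
- **Determinism**: all per-subject randomness derives from
  `SeedSequence((seed, subject_index, group_code[, stream]))`, so any
  subject is reproducible in isolation and `ground_truth_timecourses`
  can regenerate the exact generating series.

Generator realism limits: no scanner drift, motion, physiological noise, or
site effects; noise is Gaussian and stationary; networks do not overlap
temporally beyond chance AR(1) correlation. These are deliberate — the
cohort is an instrument for validating the estimator, not a simulator of
fMRI physics.

## 6. Evaluation battery

All metrics are computed per network for both the OLS-only and the corrected
stacks:

- **Topological similarity**: Euler characteristic (vertex-cubical
  alternating cell count) of the z-scored map binarized at z > 0, minus the
  reference's.
- **Voxel-wise similarity**: mean absolute error between z-scored maps
  (z-scoring both because raw OLS and corrected maps live on different
  scales).
- **Subject variability**: all pairwise Pearson correlations between subject
  maps, and the across-subject SD at *relevant* voxels — the highest-valued
  cluster of a k-means (k = 3) on the **reference** map's values.
- **Image quality**: contrast-to-noise ratio
  `(μ_high − μ_center) / σ_CSF`, where the high/center clusters come from a
  k-means (k = 3) on the **subject** map's own non-CSF values and the noise
  floor is the map's SD over CSF voxels.
- **Group test**: per-network two-sample t-test (or Kruskal–Wallis) on
  per-subject Euler-characteristic differences, Benjamini–Hochberg corrected
  across networks, significance at adjusted p < 0.05.

K-means uses 10 restarts at a fixed seed with up to 3 reseeds on degenerate
(empty-cluster) solutions, after which the metric is reported missing; cluster
identities are assigned by ascending cluster mean. Degenerate inputs
(constant maps, all-NaN networks) are isolated per metric as NaN rather than
failing the report.

## 7. Resolved design questions

- **Freudenthal vs cubical**: persistence runs on the Freudenthal 2-skeleton
  (simplicial, 26-ish connectivity via diagonal edges); the Euler
  characteristic runs on the vertex-cubical complex (6-connectivity). The
  two serve different purposes — the first feeds the differentiable loss,
  the second is the evaluation statistic — and each is validated against its
  own oracle.
- **Zero-target default**: surplus subject points are pulled to zero
  persistence at their own birth level, not to the origin. Pulling to the
  origin also drags the birth *value* toward 0, which distorts map intensity
  without topological justification; zero persistence removes the feature
  while leaving its level alone. The origin mode remains available.
- **Surplus reference points unpenalized**: see §3.1.
- **Z-score stop-gradient**: differentiating through the mean/SD would
  spread a dense correction over every voxel, defeating the sparse critical-
  voxel structure of the topological gradient; the normalization is treated
  as a frozen preprocessing step per iteration.
- **MAE z-scoring**: both maps are z-scored before MAE since the corrected
  and OLS maps are on different intensity scales (flagged in config by the
  same `zscore_before_pd` convention).

## 8. Known scale limitations

At desk scale the correction's voxel changes (~0.05–0.08 SD on 13–17 % of
voxels) are small relative to between-subject map differences (truth maps of
different subjects already correlate at ~0.98). Consequently the correction
reliably improves topological agreement, MAE, relevant-voxel SD, CNR, and
group-effect detection, but it does not *decrease* mean pairwise subject
correlation — mild denoising slightly raises it. Decorrelation effects
reported at clinical scale require corrections that are large relative to
inter-subject variability.
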