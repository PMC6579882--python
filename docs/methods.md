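# Methods

`somatoseg` studies how fMRI acquisition protocol (voxel size, encoding
scheme, timing) affects the measurable segregation of motor somatotopy maps
in cortical and deep-brain regions. Because no suitable public dataset pairs
the same motor task across 1.5 mm, 2 mm and 3 mm EPI protocols, the package
ships a synthetic-study generator whose defaults encode the experimental
conditions of interest, and every analysis stage is validated against that
programmed ground truth.

## The pattern component model

For one region of interest (ROI), let `Y` be the `n x v` matrix of GLM
regression coefficients (conditions x voxels). The model is

    Y = Z U + E,    U[:, j] ~ N(0, G),    E[i, j] ~ N(0, sigma2) iid,

with `Z` the `n x p` design over hypothesized pattern components, `U` the
latent `p x v` patterns and `G` the `p x p` pattern covariance. Marginally
each voxel column is `N(0, V)` with `V = Z G Z' + sigma2 I`, so the
likelihood depends on the data only through the sample second moment
`S = Y Y' / v`:

    loglik = -(v/2) [ n log 2pi + log|V| + tr(V^-1 S) ].

Here the `n = 9` rows are the cells of the MOVEMENT (foot, hand, face) x
RESOLUTION (1.5, 2, 3 mm) factorial in resolution-major order, `Z = I9`
(the "free" model: no constraints on G), and voxels are the random effect.

### Estimation

`fit_pcm_em` maximizes the marginal likelihood by EM over the latent `U`.
The E-step uses the inversion-free form `E[u_j] = G Z' V^-1 y_j`,
`Cov[u_j] = G - G Z' V^-1 Z G`, valid for singular `G`. The M-step is the
parameter-expanded (PX-EM) update: the model is embedded in
`Y = Z A U* + E`, the auxiliary mixing matrix `A` is estimated by least
squares and folded back into `G = A E[u u'] A'`. PX-EM preserves the
monotone-ascent guarantee of EM while eliminating the slow crawl plain EM
exhibits near variance boundaries; the plain update remains available
(`expand=False`). Iteration stops when the relative log-likelihood change
drops below `tol = 1e-6` (default) or at `max_iter = 1000`. `G` is
projected onto the PSD cone (eigenvalue clipping) at exit only. Initial
values: `G0 = diag` of the second moment of `pinv(Z) Y`, `sigma2_0` from
half the residual variance after projecting onto `col(Z)`, floored away
from zero.

`fit_pcm_direct` maximizes the same likelihood by L-BFGS over a Cholesky
parameterization of `G` plus `log sigma2`. It is used purely as an
independent oracle: the test suite demands agreement with EM to `1e-3` in
log-likelihood and `1e-2` sup-norm in `G` on seeded instances.

### Identifiability caveat

With `Z = I` the decomposition `V = G + sigma2 I` does not identify the
split between `G`'s diagonal and `sigma2`; the EM typically lands near
`sigma2 ~ 0`, so estimated correlations are mildly attenuated toward zero
(by a factor `G_ii / (G_ii + sigma2_true)`). The attenuation is uniform
across cells and therefore preserves every ordering the package reports.
Recovery tests that assert entrywise `G` accuracy either pin the noise
variance (`fix_sigma2`) or use a replicated design (`Z` with repeated rows
per cell), where `sigma2` is identified. The identified quantity under the
free 9-cell fit is `V` itself, and is tested as such.

## Index of Similarity and inference

`G` is normalized to correlations `r_ij = G_ij / sqrt(G_ii G_jj)`
(clipped to +/-(1 - 1e-12)); the Index of Similarity of a condition pair is
the absolute Fisher transform `IoS = |atanh(r)|`. Low IoS = well segregated
representations. Two per-ROI families are reported: the 9 within-resolution
movement pairs (how segregated are body parts under one protocol) and the 9
within-movement resolution pairs (how consistent is one body part's map
across protocols). Differences use the two-correlation Fisher statistic
`Z = (z_a - z_b) / sqrt(2/(n_eff - 3))` on *signed* Fisher-z values (the
absolute value is a reporting convention; differencing absolute values has
no standard null), with Benjamini-Hochberg FDR applied within each family.
`n_eff` defaults to the ROI voxel count; spatial smoothing inflates
inter-voxel dependence, so this overstates the effective sample size — a
documented caveat, not corrected, and overridable by the caller.

## Subject-level GLM

Condition regressors are 16 s boxcars convolved with the canonical
double-gamma HRF (response gamma shape 6, undershoot shape 16 weighted 1/6,
unit scale, 32 s support, unit peak) on a 0.1 s grid and sampled at volume
onsets. Nuisance columns: one pooled preparation-period regressor, six
rigid-body motion parameters, an intercept; optional cosine drift columns
(off by default — the generator produces no drift). Estimation is ordinary
least squares per voxel; no prewhitening (the AR(1) noise mildly inflates
the variance of t-statistics but leaves betas unbiased, which is what the
PCM consumes). Contrast t-maps use `t = c'b / sqrt(s2 c'(X'X)^-1 c)` with
`dof = n - rank(X)`.

## Sensitivity metrics

* tSNR per voxel = mean of the raw series / SD of residuals after
  regressing out the full design (`dof`-corrected). The raw mean is used in
  the numerator because the residual mean is ~0 by construction.
* Weighted variants: `tSNR / sqrt(TR_volume in s)`, `tSNR / sqrt(N)`, and
  `tSNR_s = tSNR * sqrt(N (1 - phi) / (1 + phi))` — the AR(1)
  effective-sample-size scaling, with `phi` the residual lag-1
  autocorrelation. The closed form is isolated in one function
  (`weighted_tsnr`) so an alternative scaling can be swapped in.
* Top-5% t-scores: mean of the `ceil(0.05 |ROI|)` largest t-values per ROI.
* Motion: frame-to-frame translation norms (mean, max, count > 0.5 mm) and
  mean frame-to-frame rotation magnitude in degrees. Frame-to-frame rather
  than cumulative position, since transient movements are what corrupt
  volumes.
* Scaled variance: mean squared intensity difference of consecutive volumes
  divided by the squared global mean — scale-invariant by construction.

## Somatotopy geometry

Group t-maps (one-sample t over subjects of the contrast effect maps) are
thresholded one-sided at `p < 0.05` uncorrected. Centers of mass are
unweighted means of suprathreshold voxel world coordinates (a t-weighted
option exists); activation maxima break ties by lowest linear voxel index;
activation volumes are divided by ROI size. Axis semantics are MNI-like
(+X lateral-right, +Y anterior, +Z dorsal); medial/lateral comparisons use
|X|; all ordering checks are strict (ties fail). Ordering checks: is the
hand center strictly between foot and face on at least one axis, and does
the foot-face difference have the expected sign on the structure's gradient
axis (dorsoventral in M1/putamen/pallidum, posterior-anterior in SMA,
mediolateral in thalamus). Per ROI, the 9 centers of mass (3 body parts x 3
resolutions) are centered and projected onto their SVD right-singular
vectors (sign-fixed so the largest-magnitude loading is positive), giving
scale- and orientation-free coordinates for the MANOVA.

## Group statistics

Pearson and Spearman correlations relate mean within-resolution IoS to mean
tSNR over ROI x resolution rows (30 rows under the default ROI set).
The ANCOVA fits `IoS ~ tSNR * resolution` (treatment coding, lowest
resolution as reference) with Type-II F tests, a nested model comparison
against `IoS ~ tSNR`, and per-level simple slopes as planned post hocs.
MANOVA on the projected center-of-mass coordinates uses Pillai's trace with
the standard F approximation. One-/two-way ANOVAs (Type-II) with
Bonferroni-Holm pairwise post hocs cover activation volumes, motion metrics
and scaled variance. All F statistics are cross-checked in the tests
against explicit projection-matrix residual-sum-of-squares oracles.

## The synthetic study

What the generator emulates:

* **Paradigm** — 18 active blocks of 16 s (3 per body part x side), rest
  blocks of equal duration, a 3 s cued preparation before each block, 1 Hz
  pacing, pseudo-random order with no immediate condition repeats.
* **Protocols** — 1.5 mm/TR 4.032 s/176 vols (3D), 2 mm/2.704 s/263 vols
  (3D), 3 mm/1.980 s/359 vols (2D), all covering a common 90 mm head-foot
  slab (retained-slice counts 60/45/30). All protocols are simulated on one
  common 1.5 mm grid, standing in for resampling to a common standard
  space; protocol identity enters through TR, volume count, and tSNR.
* **ROIs** — 10 axis-aligned boxes (M1, SMA, putamen, pallidum, thalamus x
  hemisphere), mirrored across the midline. Boxes make centers of mass
  hand-computable. Each box splits into dorsal/middle/ventral thirds along
  z: the foot/hand/face slabs (the classical dorsoventral gradient).
* **Responses** — a movement condition drives the contralateral slabs at a
  structure-specific percent-of-baseline amplitude, multiplicatively
  modulated by a group-level pattern component `U` drawn once per study
  from the scenario's 9 x 9 covariance `G_true`. The slab indicator is
  shared across resolutions and movements' slabs are disjoint, so the
  *between-movement* correlation is governed by `G_true` (attenuated by a
  constant factor from the slab variance — ordering is preserved).
* **Scenarios** — `G_true` is built from a factor-loading decomposition
  (movement + resolution + common + cell-unique factors), hence PSD by
  construction, with unit cell variances. `cortical_invariant` programs a
  between-movement correlation of 0.10 at every resolution;
  `subcortical_protocol_dependent` programs 0.10 / 0.50 / 0.10 at
  1.5 / 2 / 3 mm — the intermediate resolution least segregated. In the
  pipeline, cortical ROI voxels always follow the invariant covariance and
  subcortical voxels follow the configured scenario, so one run exercises
  both outcomes. Same-movement cross-resolution correlation is 0.40
  (consistent localization across protocols).
* **Noise** — per-voxel AR(1) Gaussian (`phi = 0.3` by default), stationary
  SD set to baseline / tSNR-target with targets 20 / 30 / 40 for
  1.5 / 2 / 3 mm (higher sensitivity at coarser resolution, roughly 2:1
  between 3 mm and 1.5 mm). AR(1) is the minimal temporally autocorrelated
  model and supplies the lag-1 coefficient that `tSNR_s` exercises.
* **Motion** — a seeded random walk with step SDs chosen so frame-to-frame
  displacements average ~0.4 mm with excursions past 0.5 mm and mean
  frame-to-frame rotations of a few thousandths of a degree, the regime
  typical of motor-task runs.

What it does **not** emulate: physiological (cardiac/respiratory) noise and
its differential impact on 2D vs 3D encoding, scanner physics (GRAPPA,
bandwidth, flip angle are metadata only), k-space readout and distortion,
anatomical variability, drift. Consequently, passing tests demonstrate the
*analysis machinery* is correct and that programmed effects are recovered
faithfully; they do not certify how real acquisitions rank.

## Numerical and design choices

* Smoothing: separable Gaussian, FWHM in mm converted per axis through the
  affine scales; sheared affines are rejected. "Kernel proportional to
  resolution" defaults to FWHM = 1 x voxel size: the synthetic ROI boxes
  are only ~9 mm wide, so larger kernels would be comparable to the
  structures themselves and dominate the pattern structure. The constant
  is configurable.
* PCM rows: subject-averaged group betas (default). Stacking subjects as
  repeated rows is supported at the estimator level via a replicated `Z`.
* Correlation clipping at +/-(1 - 1e-12) before `atanh`.
* Degenerate inputs: zero-residual voxels give NaN tSNR (logged); empty
  suprathreshold masks give NaN centers of mass (warned); empty ROIs are
  skipped in `fit_per_roi` (warned); activation-maximum ties take the
  lowest linear index.
* Problem sizes: the default `RunConfig` is the full study (15 subjects,
  40 x 48 x 40 grid at 1.5 mm, 8 x 8 x 9 boxes; ~6 min on one core). Tests
  and the acceptance script use reduced sizes (3-6 subjects, 28 x 36 x 28
  grid, 6 x 6 x 6 boxes) — the package's own desk-scale choice; every
  qualitative conclusion is size-stable between these settings.
* All generators are pure functions of (parameters, seed); pipeline outputs
  embed the config hash and seed, and reruns are byte-identical.

## Known limitations

* `n_eff` for the Fisher Z-tests equals the ROI voxel count; smoothing and
  intrinsic spatial correlation make the true effective sample size
  smaller, so reported p-values are anti-conservative in absolute terms
  (comparisons between pairs are unaffected).
* No cross-validated similarity estimator: IoS from a single fit inherits
  the attenuation noted above.
* OLS without prewhitening leaves t-maps mildly miscalibrated under strong
  autocorrelation; the thresholding step is used for geometry, not for
  inference claims.
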