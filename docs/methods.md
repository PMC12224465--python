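# Methods

This note records the models, numerical choices, and limitations behind
`gstopo`.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The generative model

Each subject's 4D run on the synthetic atlas grid follows, voxel-wise,

```
y_v(t) = w_r(a) · g(t) + u_r(t) + Σ_k b_kv · n_k(t) + ε_v(t)
```

* **Global latent g(t).**  Gaussian noise ideally filtered to 0.01–0.1 Hz and
  scaled to unit variance.  Power outside the band is numerically zero (the
  spectral test bounds it below 5 %).  White and CSF voxels carry no g.
* **Age coupling w_r(a) = w0 + w1·z(a) + w2·z(a)².**  z(a) is age standardized
  over the simulated cohort (each `Phenotype` carries its cohort `age_z`, so
  the generator's centering matches the group GLM's).  Default coefficients
  (units of g's SD): thalamus (1, +0.35, 0), putamen (1, −0.35, 0),
  sensorimotor (1, −0.25, 0), nucleus basalis / frontoparietal /
  dorsal-attention (1, 0, +0.3), medial-prefrontal–caudate–visual
  (1, 0, −0.3), generic gray background (1, 0, 0).  Magnitudes were chosen
  once so that a 120–150-subject desk-scale cohort recovers every sign at the
  p < 0.001 voxel threshold with comfortable margin; they are config values,
  not fitted quantities.
* **Region geometry.**  Invented connected blobs (spheres plus a dorsal cap)
  inside a spherical brain on a configurable grid (default 24³ voxels at
  3 mm; tests use 16³–18³, and every extent must be ≥ 16).  Only the coupling
  signs, not the shapes, carry scientific meaning.
* **Local signals u_r(t).**  Independent band-limited series per region
  (SD 0.5; 0.6× that in white/CSF), giving each region coherent non-GS
  variance.
* **Structured noise n_k(t)** with deterministic spatial loadings so that
  classification features are testable:
  * *respiratory-like*: 0.15–0.3 Hz series, loading a smooth spatial gradient
    over the whole brain (white/CSF included) — spatially varying because a
    spatially uniform loading is invisible to a spatial ICA after centering;
  * *brain-stem-like*: 0.03–0.15 Hz series, Gaussian blob at the inferior
    pole with a weak (−0.05) anti-correlated loading elsewhere in the brain;
  * *striped motion banding*: amplitude 5·FD(t) mm⁻¹-scaled white noise on
    alternating 2-slice bands across the whole field of view.  Two-slice
    bands survive 6 mm smoothing; the amplitude tracks absolute FD so that
    high-motion subjects carry proportionally stronger artifact, which is
    what gives the behavioral PLS a motion pattern distinct from the age
    pattern.
* **Voxel noise ε.**  Two parts: spatially smooth (6 mm), temporally in-band
  "spontaneous background" fluctuations (SD 2.5) plus iid thermal noise
  (SD 0.5).  The in-band, spatially correlated part is what keeps
  single-subject GS-coupling z statistics off the ±8.2 ceiling after analysis
  smoothing — iid noise alone would be annihilated by the smoother and every
  gray voxel would saturate.
* **Spikes.**  Frames with FD > 0.5 mm receive an additive spatial pattern
  scaled by 3.0.

### Phenotypes

Ages are uniform on [6, 85]; sex is Bernoulli(0.4).  Mean FD is
`0.2 + 0.07·(β·z + √(1−β²)·e)` mm clipped to [0.03, 0.49], with β = 0.35 by
default and e standard normal *orthogonalized against z in-sample*, so every
simulated cohort realizes the requested standardized FD–age slope essentially
exactly (clipping contributes < 0.01); the Monte-Carlo mean over 50 seeds is
within ±0.02 of the request.  FD traces are a two-part mixture — |N(0.18,
0.08)| mm frames with spikes of 0.55 + |N(0, 0.25)| mm at per-frame
probability 0.015 scaled by the subject's relative FD — rescaled to match the
subject mean exactly.  Scrub counts therefore inherit the FD–age gradient.
Scan start time (uniform 08:00–18:00) and the sleep score (Poisson mean 5)
are independent of age by construction.

## Preprocessing dialects

* **Bandpass** is an ideal frequency-domain filter (bins with f < low or
  f > high zeroed; temporal mean removed and restored).  It is bit-reproducible
  and exactly idempotent — a deliberate dialect difference from IIR
  (Butterworth) implementations.
* **Scrubbing** (FD > 0.5 mm, strict inequality) removes frames from
  *regression estimation only*; residuals are evaluated at all frames and
  censored frames are never interpolated.  Changing data at censored frames
  leaves estimated coefficients bit-identical.
* **Friston-24**: per parameter [m(t), m(t−1), m(t)², m(t−1)²]; the lag at
  t = 0 is zero-padded (a documented constant — the convention is not
  universal).
* **WM/CSF nuisance series** are means over atlas tissue labels taken from
  the *unsmoothed* run: at desk-scale grids the 6 mm smoother bleeds
  gray-matter signal into the small white/CSF cores, and a contaminated
  regressor would remove the global latent itself.
* **Smoothing** is a separable Gaussian (σ = FWHM/2.355/voxel) with
  reflective boundaries; volume means are preserved to 1e-6.
* Pipeline orders are fixed: MP = smooth → bandpass; CR = smooth → nuisance
  (Friston-24 + WM/CSF + detrend) → bandpass; tICA = smooth → ICA cascade →
  per-subject cleanup (noise TCs + Friston-24 + detrend) → bandpass.
* `BoldRun` volumes are stored float32 (memory); the estimator classes
  compute in float64, and the 1e-8…1e-10 numerical contracts apply to them.

## ICA cascade

Group spatial ICA runs FastICA on the temporally concatenated, brain-masked
runs with voxels as samples; dimensionality reduction to k components happens
inside FastICA's whitening step (we do not run a separate variance-retention
PCA — the k requested components are the retained subspace).  Convergence
uses tol 1e-3 with two fresh-seed retries and a final attempt at tol 5e-2:
rotations within a near-Gaussian residual subspace are statistically
unidentifiable, so demanding fine tolerance there is meaningless.  If even
the coarse attempt oscillates, the last decomposition — still an exact
orthogonal factorization of the whitened subspace — is kept with a warning
(`strict` mode raises instead); the temporal stage hits this routinely
because the cleaned band-limited channels are themselves near-Gaussian.  Component signs are fixed by
positive skewness (spatial maps for sICA, time-courses for tICA).

Noise classification is rule-based over four features — spatial energy
outside gray matter (> 0.35), time-course power above 0.1 Hz (> 0.5), maximum
|z| of time-course increments (> 5), and negative lag-1/2 spatial
autocorrelation along z (> 0.5) — with a ground-truth override path that
matches component time-courses against the generator's planted noise series
(mean |r| > 0.4) *unless* the noise match fails to dominate the component's
global-latent match by at least 1.5×: mixed components are kept as signal so
aggressive cleanup never strips the global latent itself (the
signal-preservation principle trained ICA cleanup classifiers follow).  The override path is the authoritative one in
tests; full-scale defaults are 125 spatial / 75 temporal components, with a
12 / 8 desk profile for synthetic grids (the temporal count is clamped to the
number of cleaned channels).  Group temporal-ICA maps are defined as
mixing-weighted sums of the non-noise spatial maps — the rendering of group
maps is genuinely ambiguous and this choice is recorded here.  The "overall
cortical negativity as noise" toggle is a config flag.

## GS topography

The GS is the unweighted mean over the gray-matter probability mask
(strictly > 0.2).  Per-voxel coupling is the OLS slope on [1, GS] over
retained frames; z is the slope's t statistic mapped through the t CDF to a
normal quantile (df = retained − 2), the Fisher-z-of-correlation alternative
being a config dialect.  Infinite or overflowing z values are capped at
±8.2.  All mask and censoring boundaries are strict inequalities.

## Group GLM and cluster inference

Design: [intercept, z(age), (z(age)² − mean) if quadratic, centered FD,
centered sex]; age is standardized *before* squaring and the quadratic column
centered, which makes the two age columns orthogonal for age distributions
symmetric about their mean.  Sex is coded 0/1 then centered.  Rank deficiency
is an error that names the collinear columns.

Residual smoothness: residuals standardized per voxel, per-axis λ estimated
as the variance of spatial first differences, FWHM = √(4 ln 2 / λ) voxels
(λ clipped to (1e-3, 4)); resels = mask voxels / Π FWHM.  On white noise this
yields ≈ 1.18 voxels, within the estimator's expected discretization bias.

Cluster correction thresholds the signed z map one-sided at Φ⁻¹(1 − voxel_p)
(default voxel_p = 0.001, exposed in config since the exact printed threshold
convention varies), labels clusters at 26-connectivity (6 available), and
computes corrected p from the standard 3D Gaussian-field machinery: expected
cluster count from EC densities ρ₁…ρ₃ on an equivalent-box resel geometry,
expected cluster size S·Φ(−z)/E[m], size tail P(n ≥ k) = exp(−β k^{2/3}) with
β = (Γ(5/2)/E[n])^{2/3}, and p = 1 − exp(−E[m]·P(n ≥ k)).  A Freedman–Lane
permutation of reduced-model residuals provides the assumption-free check;
on calibration simulations the GRF familywise error sits near, and slightly
below, the nominal 0.05, and its corrected p ranks agree with the
permutation p (ρ > 0.9) over graded planted clusters.

## QC analyses

Behavioral PLS uses the cross-covariance of centered FD with centered voxel
values (one latent variable for one behavior): salience = unit-norm
covariance pattern, singular value = its norm, significance by FD
permutation, voxel stability by bootstrap ratios over subject resamples
(sign-aligned before averaging), brain score = map projection on the
salience, sign-aligned so r(brain score, FD) ≥ 0.  A zero-variance brain
score passed to the adjusted GLM is dropped, reducing to the base model.
Parcels for the distance-dependence analysis come from gridding the gray
mask into contiguous blocks (default 6 voxels per side).  Cross-pipeline
within-subject correlations are averaged on the Fisher-z scale and
back-transformed.  Phenotype-age p-values are two-sided Pearson tests with
no multiple-testing correction.

## Determinism

All randomness flows from one master seed through
`SeedSequence([seed, crc32(stage), index])`; identical configs reproduce
cohorts, cascades, and GS series bit-for-bit.  Scikit-learn seeds are derived
the same way, reduced mod 2³¹.

## Problem sizes

Desk-scale defaults used throughout the tests were chosen as the smallest
sizes at which every effect is comfortably detectable: 16³–18³ grids at 3 mm,
120 frames at TR 1.4 s, cohorts of 20 (cascade), 120 (topography/GLM
fixtures), 150 × 10 seeds (sign recovery), 600 (phenotype regression);
500 null simulations for FWER calibration; 200-permutation /
100–200-bootstrap resampling in PLS and cluster nulls.  All counts are
config-scalable to the full-scale values (24³ grids, 200+ frames,
125/75 components, 5000 resamples).

## What the generator does and does not emulate

It emulates the statistical structure the analysis assumes: a band-limited
global latent with region-specific age-dependent coupling, motion-linked
artifacts and scrubbing counts that rise with age, structured physiological
noise separable by spatial/temporal ICA, and confounds independent of age.
It does not emulate hemodynamic response shapes, anatomically realistic
geometry, multi-band acquisition physics, susceptibility artifacts, or
between-site heterogeneity.  Passing tests therefore show the *pipeline*
recovers what was injected under the assumed model — not that real data meet
those assumptions.  Real-data headline statistics (cross-pipeline r values,
cluster tables, FD averages) are cohort-dependent and are not reproduction
targets; the qualitative analogues asserted in tests (sign patterns,
orderings, minimum correlations) are.

## Known limitations

* The GRF equivalent-box correction is approximate for non-box masks; the
  permutation engine is the authoritative inference at desk scale.
* The brain-stem noise component is only partially removed by the cascade
  (its diffuse anti-correlated part mixes with other brain-wide components);
  the ≥ 80 % attenuation criterion is met by total planted-noise energy.
* Spatial ICA on strongly Gaussian backgrounds is unidentifiable in the
  residual subspace; the loose final FastICA tolerance accepts this rather
  than masking it.
* The z cap at ±8.2 ties extreme voxels; rank-identity of β and z maps is
  asserted only below the cap on an equal-residual-variance fixture.
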