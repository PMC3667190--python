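# Methods

This note documents the models, numerical choices and limitations of
the `natisc` pipeline: what each stage computes, which parameters
matter, what the synthetic cohorts do and do not emulate, and where the
design was genuinely open.

## Stimulus regressors (`stimreg`)

The audio-to-regressor chain is: full-wave rectification → low-pass
filter → decimation → HRF convolution → anti-aliased resampling to the
scanner rate → truncation to the retained volume range.

* **Envelope filter.** The low-pass stage is a 4th-order Butterworth
  with an 8 Hz cut-off, applied forward–backward (`sosfiltfilt`), so
  the envelope is zero-phase. Only the filter family ("IIR, 8 Hz") is
  canonical; order and phase handling are our choices — zero phase
  avoids introducing a systematic latency into regressors that are later
  compared against haemodynamic signals. Decimation by 16 takes a
  48 kHz track to 3 kHz. The intermediate rate is a computational
  convenience, not semantics: a property test verifies the final
  regressor is invariant (< 1% RMS) to decimation factors {8, 16, 32}
  for band-limited inputs.
* **HRF.** Canonical double-gamma: response peak at 6 s, undershoot at
  16 s, peak/undershoot amplitude ratio 6, 32 s support
  (`HRFSpec`, all parameters exposed). The kernel is normalised to unit
  sum so the regressor scale does not depend on the envelope sampling
  rate.
* **Resampling.** Polyphase FIR with a Hamming-windowed sinc
  anti-aliasing filter (`scipy.signal.resample_poly`), honouring the
  linear-phase FIR convention; 0.4 Hz output at TR = 2.5 s. Length
  matching to the retained volume count mirrors the EPI trimming
  (3 volumes cut at the start, 2 at the end: 456 → 451).
* **RMS statistics.** Presence/loudness statistics use 100 ms
  non-overlapping windows and a silence threshold of −40 dB relative to
  each track's own maximum window RMS; loudness ties split 50/50.
  These three constants have no canonical values and are configurable;
  the statistics are descriptive and feed no downstream decision.

## Preprocessing (`prep`)

The pipeline starts from registered, masked voxel × time matrices.
Volume trimming removes onset/offset transients. Nuisance regression
projects out, per subject: a constant, a normalised linear drift term,
the six motion parameters, and (optionally, default on) the global mean
over the mask. Columns that are effectively zero or collinear are
pruned with a warning; the projection is idempotent, and residuals are
orthogonal to every retained column by construction (QR projection).
The global mean is computed over the supplied analysis mask; no tissue
segmentation is attempted. Whether the ICA input should also be
nuisance-cleaned is a flag (`ica_on_cleaned`, default on).

## Intersubject correlation (`isc`)

Pairwise voxelwise Pearson correlations over all unordered subject
pairs; r is clipped to |r| ≤ 1 − 1e−7 before the Fisher transform (the
clip changes z by < 1e−6 for |r| ≤ 0.999). The group statistic is a
one-sample t over pair z values with df = n_pairs − 1 (78 pairs, 77 df
at 13 subjects). Zero-variance voxels are excluded per pair; a voxel
needs ≥ 90% of pairs valid to enter the group test.

Thresholding combines a voxelwise criterion with a cluster-extent rule
(components with ≥ `extent` voxels are kept). Cluster connectivity is
6-neighbour (face) by default, with 18 and 26 available. Three
family-wise error modes:

* `fixed_t` — the replication mode (t > 5.1, extent 20);
* `bonferroni` — α divided by the voxel count;
* `monte_carlo` — a max-statistic null built by circularly shifting
  every subject's series by an independent random offset of ≥ 10 TRs
  and recomputing the max-voxel group t per permutation. Circular
  shifts preserve each series' autocorrelation while destroying
  inter-subject alignment. Because standardisation is shift-invariant,
  the shifted correlation equals the circular cross-correlation of the
  standardised series at the relative lag, which is evaluated for all
  lags at once by FFT — permutations then cost an indexing operation
  per pair, making a 100-permutation null on a cohort sub-second.
  Random-field-theory corrections are deliberately not implemented.

On null cohorts the α = 0.01 Monte-Carlo threshold yields an empirical
family-wise false-positive rate consistent with 1% (binomial check over
200 replicate experiments in the acceptance suite).

## Group spatial ICA (`gica`)

* **Order selection.** MDL on the eigenvalues of each subject's
  temporal covariance, treating voxels as samples; the cohort order is
  the rounded mean of per-subject argmin values. Eigenvalues below
  1e−10 of the largest are clamped to a common floor so an exactly
  rank-deficient covariance gives a flat likelihood term beyond the true
  rank. The full-scale ("paper") profile targets order 55; the desk
  profile uses 12 on the synthetic cohort, whose cleaned data have true
  order 8.
* **Reduction.** Subject PCA to k1 = ⌈1.5 k⌉ temporal dimensions,
  concatenation across subjects, group PCA to k, then whitening of the
  k rows. The 1.5 k rule is a pragmatic default; toolbox conventions
  vary.
* **Infomax.** Natural-gradient ascent with the logistic nonlinearity;
  learning rate 0.01, annealed ×0.9 on weight blow-up and ×0.98 when
  the epoch-to-epoch weight change oscillates; block size ⌈√V⌉;
  convergence when the max weight change falls below 1e−6, capped at
  500 epochs. Voxel time series are variance-normalised before ICA by
  default (flag `zscore_voxels`; disable for noiseless data, where
  zero-variance voxels make the normalisation degenerate).
* **Stability.** n_runs random-initialisation restarts (150 in the
  full-scale profile, ~10 at desk scale; no bootstrap). Components from
  all runs are clustered by absolute spatial correlation with average
  linkage, cut at k clusters. Iq = mean intra-cluster similarity −
  mean extra-cluster similarity, clipped to [0, 1]; the cluster
  centrotype (member with maximal within-cluster similarity sum) is the
  representative component. Components with Iq < 0.9 are not retained.
  The anatomical "not in gray matter" exclusion is replaced by a
  mask-coverage QC flag, since synthetic data have no tissue classes.
  Note that Iq is sensitive to true inter-map correlations: boxcar
  blob maps are weakly negatively correlated by construction, which
  caps noiseless Iq near 0.97; exactly orthogonal sources reach 1.0.
* **Sign and order.** Each aggregate map is flipped to positive skew,
  and components are ordered by descending Iq, making the output
  deterministic given the seed set.
* **GICA3 back-reconstruction.** With X = A S the aggregate mixing of
  the group-reduced data, F_i the subject PCA basis, G_i the i-th row
  block of the group PCA basis and R_i = F_iᵀ (preprocessed data), the
  subject map is S_i = A⁻¹ G_i⁺ R_i and the subject time-course matrix
  is T_i = F_i G_i A. Two identities follow: the mean of S_i over
  subjects equals S, and T_i S_i reconstructs the preprocessed data —
  both exact (machine precision) on noiseless data of exact rank, and
  verified to 1e−6 in the acceptance suite. With noise the mean
  identity holds approximately (the group-PCA residual enters through
  G_i⁺). Aggregate maps are stored with unit-variance rows; the spatial
  mean is deliberately **not** removed, because mean removal is an
  affine shift that would break the reconstruction identity. A true
  z-map is a one-line transform for display.
* **Component t-maps.** Voxelwise one-sample t across subject maps,
  df = n_subjects − 1 (12 at cohort scale); zero-variance voxels are
  capped at ±1e6.

## Classification, FNC, stimulus regression (`classify`)

* **Extrinsic rule.** spatial_r is the Pearson correlation between the
  *unthresholded* IC group t-map and the binary ISC mask (the common
  spatial-sorting convention; a thresholded-vs-thresholded variant is
  behind a flag). overlap_pct uses the IC's own suprathreshold voxel
  count as denominator. A component is extrinsic iff retained AND
  spatial_r > 0.3 AND overlap > 50%. Components whose thresholded map
  is empty have undefined overlap and are forced intrinsic with a
  warning. IC maps are thresholded with the same cluster rule as the
  ISC map, at the model's own df.
* **FNC.** Within each subject, Pearson correlations between every
  (extrinsic, non-extrinsic) retained pair of time-courses; Fisher z;
  two-tailed one-sample t across subjects (df = n_subjects − 1);
  Bonferroni over n_extrinsic × n_non_extrinsic tests (160 tests in
  the full-scale configuration of 4 extrinsic among 44 retained).
  The reported mean r is tanh of the mean z (averaging in z space);
  the averaging domain is a convention choice.
* **Stimulus regression.** Each IC time-course is regressed per subject
  on [speech, non-speech, linear drift, constant]; group one-sample
  t-tests on the betas (per-subject statistics, not concatenated data).
  Partial correlations residualise both sides against the remaining
  columns. Regressors with |r| > 0.99 are rejected as collinear; the
  speech/non-speech correlation is reported but the regressors are not
  orthogonalised.

## GLM (`glm`)

First level: OLS on [stimulus regressors, drift, constant, global,
motion], then a single pooled AR(1) coefficient from the lag-1
autocorrelation of the OLS residuals (pooled over voxels, one value per
subject — the approximate global AR model, not voxelwise), then a refit
after exact AR(1) whitening (Prais–Winsten, which equals GLS for known
ρ; verified against the closed form to 1e−8). ρ is capped at ±0.99
with a warning; ρ = 0 reduces exactly to OLS. Second level: voxelwise
one-sample t on per-subject contrast values, thresholded at FWE p <
0.05 with a 10-voxel extent by default.

## Synthetic cohorts (`synthdata`)

Defaults emulate the acquisition the pipeline targets: 13 subjects,
451 volumes at TR = 2.5 s, a 20×20×5 grid (2000 voxels — the smallest
geometry that comfortably exercises 20-voxel cluster extents).

* Spatial maps are boxcar blobs (5×5×2 = 50 voxels, unit loading) on
  pairwise-disjoint supports by default.
* Extrinsic time-courses are shared across subjects; when stimulus
  regressors are supplied they become the leading extrinsic
  time-courses (standardised), mirroring stimulus-driven activity.
* Intrinsic time-courses are subject-specific Gaussian noise band-passed
  to 0.01–0.1 Hz (resting-state-like spectra without extra parameters).
  Optional coupling to an extrinsic time-course at target correlation ρ
  is constructed by exact Gram–Schmidt mixing, so the per-subject sample
  correlation equals ρ to machine precision. Coupling is **off by
  default**: with shared extrinsic time-courses, a coupling ρ induces a
  cross-subject correlation ρ²·a²/(a²+1) at the intrinsic support
  (a = spatial amplitude), and at a = 1, ρ = 0.5 that is 0.125 — large
  enough for the 78-pair t > 5.1 rule to (correctly) flag the support
  as stimulus-correlated. The FNC-recovery scenario therefore uses
  a = 0.3, keeping the coupled component's ISC below threshold while
  the within-subject coupling remains ρ = 0.5.
* Nuisance: per-subject linear drift with per-voxel gain (uniform
  0.5–1.5; a spatially uniform drift would be collinear with the global
  signal), a band-limited global signal, and a 6-column random-walk
  motion table injected through random spatial weights and also
  provided as the confound table, so confound regression has something
  real to remove.
* Noise: AR(1) (default φ = 0.3) plus white innovation, marginal SD
  `noise_sd` = 1, making extrinsic SNR 1 at support voxels — which
  yields pairwise ISC ≈ 0.5, comfortably detectable at 78 pairs.
* Determinism: all randomness flows from one `SeedSequence`; the same
  seed reproduces bit-identical cohorts.

What the generator does **not** emulate: anatomical geometry, tissue
classes, spatial smoothness of the noise, EPI artifacts or
susceptibility dropout, physiological (cardiac/respiratory)
confounds, and inter-subject spatial misalignment. Passing tests
therefore demonstrate the correctness and calibration of the
*computations*, not robustness to every property of real fMRI data.
In particular, the MDL order estimate is exact here because the noise
is spatially white; on smoothed real data MDL is known to return much
larger orders (the full-scale profile's 55).

## Problem sizes and profiles

The `paper` profile keeps the full-scale settings (order 55, 150
stability runs). Tests and the acceptance script use the `desk` profile
and cohort-scale syntheses (orders 8–20, 4–10 runs, grids of 400–2000
voxels, 100–200 Monte-Carlo replicates), chosen so the full suite runs
in a few minutes on a single CPU while every statistical rule (pair
counts, df, thresholds, Bonferroni divisors) is identical to the
full-scale configuration.

## Known limitations

* The Monte-Carlo null design (circular shifts) is one reasonable
  choice among several; block permutations or phase randomisation would
  also preserve autocorrelation.
* The pooled (not voxelwise) AR(1) model is an approximation; voxels
  with atypical autocorrelation are mis-whitened.
* Iq is computed over random-restart variability only; bootstrap
  resampling would add sampling variability to the stability estimate.
* The GICA3 mean identity is exact only up to the group-PCA residual on
  noisy data.
* `estimate_order`'s MDL assumes i.i.d. samples across voxels; spatial
  smoothing violates this and inflates the estimate.
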