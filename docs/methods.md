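# Methods

This note documents the models, conventions and design choices behind
`cardioconn`, and what the synthetic-data experiments do and do not
demonstrate.

## Cardiac chain

**Protocol.** Recordings are assumed to be ~10-minute seated resting
sessions from a wrist PPG device sampling at 64 Hz. The first 60 s are
discarded (device stabilization); retention is half-open, so a beat at
exactly 60.0 s is kept. All interval indexing treats interval *k* as the
gap ending at beat *k+1*.

**Beat detection** (optional front end) band-passes 0.5-8 Hz, tracks a
2-s rolling amplitude envelope, and picks maxima above half the local
envelope with a 300 ms refractory period. It is a deliberately simple
stand-in for commercial detectors and is validated only on synthetic
pulse trains (>= 99% of beats within 50 ms at SNR 10).

**Artifact flagging.** Interval *k* is flagged iff
`|IBI_k - med_k| > max(rel_thr * med_k, abs_thr_ms)` with a running
median over 11 intervals (edge-replicated), `rel_thr = 0.30`,
`abs_thr_ms = 250`. The reference software's defaults are proprietary;
these thresholds recover >= 95% of injected halved/doubled intervals on
synthetic series and are fully configurable. With both thresholds at
zero every interval off its running median is flagged (degenerate
limit).

**Segmentation.** Within each maximal flag-free span (after widening
every flag by a 2-interval buffer on each side), windows are packed
greedily from the span start: intervals accumulate while total duration
stays <= 60 s; a terminal remainder >= 40 s is kept. No interval is
used twice; a subject may end with zero segments, in which case the
profile is returned marked unusable rather than dropped silently.

**Metrics.** Mean HR defaults to the mean of instantaneous 60000/IBI
(the convention consistent with group tables in which mean HR exceeds
60000/mean IBI, as Jensen's inequality requires); the interval-mean
variant is selectable. SDNN uses the n-1 denominator. The tachogram for
spectral analysis stamps each interval at its ending beat time, resamples
by cubic spline at 4 Hz, and removes a linear trend.

**AR spectrum.** Coefficients come from Burg's method (order 16, the
common default at 4 Hz resampling; reduced automatically on segments too
short to support it). Two numerical choices matter:

1. *Line-adaptive integration.* On near-noise-free segments the AR poles
   approach the unit circle and spectral lines become narrower than any
   uniform frequency grid. Band powers are therefore integrated on a
   grid augmented, around each pole frequency f0 with half-width d, by
   the substitution f = f0 + d tan(v) sampled uniformly in v, which
   resolves arbitrarily sharp Lorentzian lines. A planted sinusoid of
   amplitude a recovers its analytic band power a^2/2 to ~1%.
2. *Variance-matching normalization.* The Burg innovation variance does
   not guarantee that the model spectrum integrates to the sample
   variance (it can be ~20% off with near-unit poles), so the density is
   rescaled so its integral over (0, 2 Hz] equals the tachogram
   variance (Parseval).

The HF peak is searched over 0.10-2.0 Hz so a respiratory peak that has
drifted below the band bounds renders the profile's plausibility flag
(power-weighted mean peak inside 0.15-0.40 Hz) informative.

**Aggregation** is an unweighted mean across segments
(duration-weighted optional); HF is averaged on the absolute ms^2 scale
and then log-transformed.

## Connectivity chain

Processing order per run: drop 4 equilibration volumes -> 6-mm FWHM
Gaussian smoothing -> grand-mean scaling to 10,000 -> zero-phase
2nd-order Butterworth band-pass 0.01-0.08 Hz. Runs are concatenated,
volumes with framewise displacement > 0.5 mm (Power convention: sum of
absolute translation increments plus 50 mm times absolute rotation
increments; FD[0] = 0) are scrubbed, and the first 120 usable volumes
retained (a hard error otherwise, naming the subject). The confound
design holds an intercept, linear and quadratic trends, the 6 rigid-body
parameters and their backward differences, and the top 5 principal
components each of the white-matter and CSF voxel series.

*Confound filtering.* Nuisance regressors are band-pass filtered
identically to the data before regression (the unfiltered variant is
available behind `filter_confounds=False`). Regressing unfiltered
confounds from filtered data removes only part of the band-limited
nuisance signal and effectively reintroduces broadband regressor noise;
in simulation this leaves a subject-level global component in the
weighted-degree maps (first principal component up to ~46% of
between-subject variance, whole-map z-shifts of +-1.5 under the null)
that destroys the calibration of any stationarity-based cluster
correction. Filtering the regressors is the standard remedy and is the
package default.

Weighted degree clips correlations at |r| <= 1 - 1e-7 before atanh
(which diverges at 1), excludes the diagonal, zeroes negative weights,
and accumulates over voxel-row blocks so the full voxel-by-voxel matrix
never exists in memory; results are bit-identical across block sizes.
Zero-variance voxels are removed from the shared mask with a warning at
extraction time and are a hard error if they reach the degree
computation. The grey-matter mask is strict (partial volume > 0.2),
voxel-indexed and 0-based, with world coordinates carried by the NIfTI
affine, and the identical mask is reused for every subject. Cohort-level
quality control flags subjects whose mean whole-mask WD leaves
[Q1 - 1.5 IQR, Q3 + 1.5 IQR].

## Inference chain

Voxel-wise OLS gives the metric's t with df = n - p (14 under the
primary covariate set and 12 under the post-hoc set at n = 20);
conversion to z composes the exact t tail probability with the normal
quantile in log space (`ndtri_exp`), so |t| of any size maps to a
finite, strictly monotone |z| without saturating at the double-precision
probability floor.

**Smoothness.** For each residual map the empirical spatial
autocorrelation is computed by zero-padded FFT, divided by the mask's
own autocorrelation (pair counts), and radially binned to lags <= 8
voxels. Two conventions matter and both were settled by calibration
experiments on zero-coupling cohorts:

1. The residual maps' autocorrelation is computed *about zero*, not
   about each map's in-mask mean. Residual maps are mean-zero across
   subjects by construction, so a map-level offset (the subject's
   overall connectivity level) is part of the random structure; it
   appears as a long-lag plateau that the cluster null must reproduce.
   Centering each map hides it and leaves the chain anticonservative.
2. The empirical ACFs are averaged across residual maps and the mixed
   model `ACF(r) = a exp(-r^2/(2 b^2)) + (1-a) exp(-r/c)` is fit once
   to the average, by weighted least squares (Gaussian-only fallback if
   the mixture fit fails). Fitting per map and averaging the parameters
   is upward-biased: the non-negative mixture weight rectifies per-map
   tail noise, inflating the fitted plateau and the resulting
   cluster-size threshold several-fold.

The reported effective FWHM is the width of the Gaussian
kernel that would produce the model's half-height radius on white noise
(kernel FWHM = sqrt(2) x ACF half-height radius); applied widths of 2-4
voxels are recovered within ~3%.

**Cluster-size null.** Null fields with the fitted ACF are produced by
Fourier spectral shaping of white noise (spectrum = FFT of the model ACF
on the periodic grid, clipped at zero) and normalized to unit voxel
variance *analytically* (Parseval), not re-standardized per field: each
realized field keeps the natural sampling fluctuation of its in-mask
mean and variance, exactly as a real z-map does. Per-field empirical
z-scoring was tried first and thins the null's upper tail (every field
forced to mean 0, SD 1), which made the procedure anticonservative by a
factor ~3 on realistic cohorts. k_alpha is the smallest cluster size
whose null exceedance probability is <= 0.05; under the default
"bisided" rule positive and negative clusters are formed separately
(the pooled |z| variant is selectable), with faces-only connectivity
(edge/corner variants selectable). With a fixed seed the chain is
bit-reproducible.

The between-model intersection mask (voxels significant under both the
primary and extended covariate sets) implements the "remains significant
after additional adjustment" logic used for reporting.

## Synthetic cohort

The generator's purpose is verification, not biophysics.

*Beats* are built by direct interval modulation -- mean IBI 800 ms plus
HF (0.25 Hz, 30 ms) and LF (0.10 Hz, 40 ms) sinusoids plus 5 ms Gaussian
jitter, validity requiring `hf + lf + 4*noise < mean` -- rather than an
integrate-and-fire model, because the planted band power is then
analytically a^2/2. Artifacts are isolated interval halvings/doublings
(ectopic-like) at 0.5/min by default, with injected indices retained as
ground truth.

*Brains* are 16^3 grids of 3-mm voxels, 128 volumes at TR 3 s: a
grey-matter shell (~1300 voxels; partial-volume map values 0.9/0.1/0.05
for GM/WM/CSF), a white-matter ring and CSF core carrying their own
shared fluctuations plus a strong (0.5 sd) loading of the global signal
-- as physiological noise does in real tissue compartments, which is
what makes anatomical-noise regression effective -- and a weak (0.1 sd)
global signal in all brain voxels so negative correlations remain
common. A contiguous hub (~148 voxels, an outer-shell cap kept > 1.7
voxels clear of the white-matter ring so its smoothed signal does not
leak into the nuisance masks) shares a latent time series with loading
g = base + beta * covariate; with base 1.25 and beta 0.375 the
constructed pairwise hub correlation g^2/(1+g^2) spans ~0.2-0.8 over a
+-2 SD covariate range. Volumes are smoothed to 6-mm FWHM; motion is a
bounded Gaussian random walk calibrated so scrubbing is rare. Fixed
seeds give bit-identical outputs, including the JSON manifest.

What these simulations do **not** emulate: hemodynamic response shapes,
scanner drift and spike artifacts, registration error, physiological
(cardiac/respiratory) aliasing in the BOLD band, non-stationary
smoothness across the brain, and heavy-tailed motion. Passing the
calibration and recovery experiments therefore shows the *inference
machinery* is correct and calibrated under its own assumptions, not that
those assumptions hold on any particular real dataset.

## Verification experiments (problem sizes)

- Family-wise error of the cluster threshold: 16^3-grid mask, k_alpha
  from 1,000 Monte-Carlo fields, FWER over 500 fresh fields (target
  0.05, accepted 0.03-0.08).
- Zero-coupling calibration of the *full* chain: 200 cohorts of n = 20
  subjects, per-cohort smoothness estimation and 1,000-field null; the
  any-cluster rate is compared with the binomial 95% interval around
  0.05. "Zero coupling" means the hub construct is absent entirely --
  the stationary-field regime the cluster-size null models. Keeping a
  *metric-independent* coherent hub in the brains (constant loading,
  zero coupling slope) raises the observed rate to ~0.12-0.14: ~150
  voxels sharing one latent time series act as a single degree of
  freedom, which stationary-ACF nulls cannot represent. This reproduces
  the well-documented anticonservativeness of cluster-extent inference
  under non-stationary correlation structure and is deliberately left
  visible rather than patched by ad-hoc map normalization.
- Planted-coupling recovery: 25 cohorts, n = 20; the primary/post-hoc
  intersection must cover >= 50% of the hub in >= 80% of cohorts.
- Smoothness recovery: applied FWHM 2, 3, 4 voxels on 24^3 white-noise
  maps, tolerance 10%.

The 1,000-iteration null (rather than the 10,000 default used for real
analyses) and the 16^3 grid are the package's chosen experiment sizes;
they keep the complete verification run to minutes on one CPU while
leaving the Monte-Carlo error on k_alpha well below the acceptance
margins.

## Known limitations

- The artifact detector and beat detector are documented simplifications;
  neither reproduces any proprietary algorithm.
- The clinical-table continuous-variable statistics cannot be recomputed
  without subject-level data; only the categorical rows (determined by
  printed counts) and the FDR adjustment across the printed 12-row
  family are reproduced. Under every standard chi-square convention the
  SSRI/SNRI row computes to 0.64 versus a printed 0.65; this is logged
  as a rounding-level discrepancy and not chased.
- Whether group HF averaging happened in the absolute or log domain, and
  whether mean HR is instantaneous- or interval-mean, is not stated in
  the source material; both variants are implemented and the defaults
  documented above.
- Cluster-extent correction assumes stationary smoothness; strongly
  structured between-subject modes (e.g. global connectivity level)
  violate it. The package mitigates the largest synthetic source
  (confound filtering, above) but real data may need global-mode
  modeling that is out of scope here.
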