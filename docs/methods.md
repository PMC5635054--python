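# Methods

This note records the models, parameter choices and numerical conventions
behind `alphabold`, and what the synthetic validation does and does not
establish about real recordings.

## Synthetic simultaneous EEG-fMRI generator

The generator emulates the acquisition the pipeline targets: 32-channel
EEG at 5 kHz recorded during ~7.5 min of eyes-closed rest inside a 3 T
scanner acquiring one volume every 2.6 s. The default duration is 468 s =
180 × 2.6 s, so the default 180 volumes exactly fill the recording; volume
markers stop at the end of the EEG recording if it is shorter.

**Alpha source.** The amplitude envelope is a rectified AR(1) Gaussian
process: at 20 Hz, lag-1 coefficient 0.98 (time constant ≈ 2.5 s), mean
20 µV, SD 10 µV. The coefficient of variation of 0.5 matches the
Rayleigh-like variability (CV ≈ 0.52) of a narrowband Gaussian process's
envelope, and the mean amplitude is typical of occipital alpha. The
envelope modulates a 10 Hz carrier with phase diffusion of 2 rad/√s
(Lorentzian linewidth ≈ 0.6 Hz). The diffusion matters: a perfectly
coherent 10 Hz carrier completes exactly 26 cycles per 2.6 s volume and is
therefore phase-locked to the TR grid, so trigger-locked artifact
averaging would coherently absorb (and subtract) the mean-envelope alpha —
a degeneracy real alpha does not exhibit. The source projects to the scalp
through a fixed occipital-dominant topography (O1/O2/Oz weight 1.0,
parieto-occipital 0.7, parietal 0.4, centro-parietal 0.2, elsewhere 0.05).

**Noise and artifacts.** Each channel receives independent white and pink
(1/f-amplitude) noise, 5 µV SD each. The gradient artifact is a fixed
sawtooth-plus-harmonic template of amplitude 1000 µV repeated exactly at
every volume onset (optional per-epoch amplitude jitter, default 0), so
its spectrum peaks at multiples of 1/TR, including inside the alpha band.
The BCG is a damped 7 Hz oscillation (0.5 s, 50 µV peak scale, smooth
front-to-back channel weighting) starting 0.21 s after each R-peak; RR
intervals come from a 60 bpm heart with 3% multiplicative jitter. A
stylized PQRST trace plus noise forms the ECG channel.

**BOLD.** Voxel time courses are
`baseline · (1 + c_v · z(t)) + drift + noise`, where `z` is the
standardized HRF-convolved envelope sampled at the volume onsets, `c_v` a
per-voxel signed coupling fraction (group-specific map), drift a 1%
cosine of period 300 s with random phase per voxel, and noise i.i.d.
Gaussian with SD 1% of baseline. The grid is a 20³ "already normalized"
common space with 3.5 mm voxels — spatial registration is out of scope, so
simulation happens directly in common space.

**Demonstration cohort.** 8 controls with coupling +0.02 in region A
(voxels 4:9 on each axis, 125 voxels) and −0.02 in region B (12:17),
8 patients with zero coupling. Covariates are drawn per group from normal
distributions matching the target cohort's demographics (age 75.3 ± 5.7 /
73.4 ± 3.1 years, education 14.4 ± 2.7 / 13.6 ± 2.8 years, 10/14 male,
hippocampus/TIV 0.0042 vs 0.0048 ± 0.0008 — the latter chosen so the
group difference is of borderline significance, as in mild disease).

**What the generator does not emulate:** slice-wise acquisition, head
motion, physiological noise structure beyond the BCG, spatially
heterogeneous anatomy, ocular artifacts, non-stationary alpha slowing, or
amplitude differences between groups (both groups share the same alpha
statistics, so scalar power comparisons are null by construction). Passing
tests therefore demonstrate algorithmic correctness and calibration under
these idealized conditions, not robustness to every failure mode of
clinical data.

## EEG cleaning

Order: decimate → gradient AAS → BCG AAS → filters → ICA proxy →
re-reference → pool → artifact marking. Decimation (5 kHz → 250 Hz) comes
first, matching the processing order the pipeline models; both AAS stages
operate identically at either rate because TR is an integer number of
samples at 250 Hz.

- **Decimation**: staged FIR anti-alias decimation (factors ≤ 13),
  zero-phase.
- **AAS**: per channel, each trigger-locked epoch has the mean of its
  `n_avg = 21` nearest epochs (centered window, truncated at the ends)
  subtracted. 21 epochs ≈ 55 s of gradient history balances template
  accuracy (noise in the template falls as 1/√n) against drift tracking.
  With identical epochs and `n_avg` ≥ the epoch count, removal is exact to
  machine precision — the average of identical epochs is the epoch.
- **R-peak detection**: band-pass 5–20 Hz, squared energy smoothed over
  80 ms, adaptive threshold at 30% of the 99th percentile, 0.3 s
  refractory period, peak refinement to the local extremum. A flat ECG
  warns and returns no peaks rather than raising.
- **BCG**: heartbeat-locked AAS with epoch `[R + 0.21 s, R + 0.21 s +
  0.7 s)`; 0.21 s is the conventional pulse-artifact delay, and the
  template must be shorter than the median RR interval (enforced).
- **Filters**: 4th-order Butterworth high-pass (0.5 Hz) and low-pass
  (70 Hz) and a 2 Hz-wide 2nd-order band-stop at 50 Hz, all applied
  forward-backward (zero phase; effective order doubles).
- **ICA proxy**: full-rank FastICA on the scalp channels; a component is
  removed when |r| with the ECG exceeds 0.3 or more than 60% of its Welch
  power lies below 2 Hz. These thresholds stand in for the manual
  component selection a human operator would perform. The unmixing matrix
  is fit on a temporally strided subsample (default every 2nd sample in
  the library, every 4th in the full pipeline) purely for throughput; the
  mixing matrix is square, so reconstruction is exact and a no-removal
  pass returns the input to ~1e-6 relative. Decomposition failure skips
  the stage with a warning.
- **Artifact marking**: moving RMS over 0.2 s, standardized by
  median/MAD (a large burst must not inflate its own detection
  threshold), suprathreshold when robust z > 4 *and* RMS > 1.5× the
  median (guards against false alarms on homogeneous signals); runs
  closer than 0.5 s merge; runs ≥ 1 s are flagged for the nuisance
  regressor, shorter runs still invalidate power segments.

## Band power

Complex demodulation at band center `f_c`, 4th-order zero-phase low-pass
at half the bandwidth, power = `2|·|²` so a pure in-band sinusoid of
amplitude A has mean power A²/2. The first and last 2 s are marked
edge-invalid (filter transients). One-second power values are
non-overlapping means; a segment is invalid when it intersects any marked
artifact interval or the edge margins. Relative alpha power divides the
per-segment periodogram band power by the 1–40 Hz total (the reference
band is a convention of this package; it is configurable) and averages
over 1-s rectangular-window segments. The sub-band filters overlap
slightly at the 10 Hz boundary, so lower + upper ≈ total holds to ~5% for
band-confined signals; the 4th-order low-pass has ≈ 90% of the brick-wall
noise bandwidth, approaching the band integral as the order grows.

## Regressors and GLM

The canonical HRF is the difference of two gamma densities (shapes 6 and
16, unit scales, undershoot ratio 1/6, 32 s support), peak-normalized;
it peaks near 5 s with a smaller undershoot near 15.7 s. Invalid power
seconds are linearly interpolated from the nearest valid neighbors before
mean-centering and convolution at 1 Hz; the convolved course is sampled at
each retained volume onset by linear interpolation (1 s does not divide
2.6 s). The artifact regressor — the fraction of each volume window
covered by flagged intervals — is deliberately *not* convolved: it is a
nuisance indicator, not a hypothesized hemodynamic response. Both
regressors drop the same 6 initial volumes as the image series.

The first-level model is OLS on `[alpha, artifact, constant]` with
centered predictors; an all-zero artifact column is dropped with a
warning, exact collinearity is an error naming the column. No prewhitening
is applied: the synthetic noise is temporally white, OLS keeps the
estimator deterministic and exactly calibrated there, and a whitening
stage can be inserted before fitting if the pipeline is pointed at data
with appreciable serial correlation. Zero-residual voxels (relative to the
data scale) yield NaN t-values with a logged count.

Demographic covariates are second-level-only: within a subject they are
constant and therefore collinear with the first-level mean term.

The 128 s high-pass is a projection onto the orthogonal complement of a
drift basis (constant, linear ramp, and DCT-II components with period ≥
cutoff) — idempotent by construction. The ramp is included because a
truncated cosine set only approximates a linear trend. The same filter is
applied to the data and to the alpha/artifact regressors. The first-level
df is reported as volumes − design rank (171 in the default geometry); the
dimensions absorbed by the high-pass are not subtracted, which biases the
nominal p = 0.01 voxel-wise false-positive rate to a measured ≈ 0.012 —
inside the ±0.005 calibration band the validation enforces, and the
second level (where inference actually happens) is exactly calibrated.

## Group level

Second-level inference uses the summary-statistics approach on the
per-subject alpha beta maps: one-sample (intercept) and two-sample
(HC − AD indicator) regressions with mean-centered covariates and pooled
residual variance; df = n − 1 − n_cov and n − 2 − n_cov. Zero-variance
voxels carry signed infinity sentinels rather than NaN so a degenerate but
consistent effect still thresholds correctly. Positive and negative
associations are separate one-sided tests at p < 0.01; suprathreshold
voxels inside the gray-matter mask (tissue probability ≥ 0.3, read
inclusively) are labeled at 18-connectivity (6/26 available) and clusters
under 50 voxels are discarded. Cluster tables sort by size, then peak t,
then lexicographic peak index. Atlas comparison is quantitative (overlap
fraction and Dice) rather than visual. The scalar comparison helper also
accepts printed summary moments, so group tests can be reproduced from
published tables.

## Validation design and problem sizes

- **Oracle equivalence**: both GLM levels against an independent
  normal-equations solver on random 20-volume / 12-subject fixtures
  (agreement ~1e-14).
- **Artifact recovery**: measured against the *known* injected artifact
  component, not just total power: noiseless removal to < 1e-9 relative
  RMS; ≥ 20 dB at TR harmonics for the gradient (measured ≈ 78 dB),
  ≥ 15 dB in 1–12 Hz for the BCG with 3% RR jitter (measured ≈ 45 dB).
- **Calibration**: 20 null cohorts (zero coupling) of 16 subjects on the
  20³ grid, full volume-domain pipeline; pooled voxel-wise exceedance of
  the p = 0.01 threshold at both levels (≈ 2.6 M first-level draws) and
  the fraction of replicates with no cluster ≥ 50 voxels.
- **Recovery**: the 8 + 8 demonstration cohort end to end at full
  acquisition scale (5 kHz EEG, 180 volumes); the HC > AD positive
  contrast must overlap region A with Dice ≥ 0.3. The Dice ceiling is
  ≈ 0.35 here because 8 mm smoothing spreads a 125-voxel seed region into
  a ~600-voxel cluster.
- **Labeling**: 1000 random 8³ binary arrays against a flood-fill labeler
  at all three connectivities.

These sizes keep the complete validation run within a few minutes on one
CPU while leaving every measured quantity comfortably inside its band.

## Known limitations

- No prewhitening, motion correction, slice timing, spatial normalization
  or multiple-comparison correction beyond the cluster-extent rule — by
  scope.
- The marker-driven AAS assumes reliable volume triggers; the
  autocorrelation fallback for marker-less files is not implemented
  (synthetic recordings always carry markers).
- Channel interpolation by topographic triangulation is omitted; the ICA
  proxy replaces, but cannot fully emulate, expert component review.
- Relative alpha power of the synthetic cohort (~0.77) is higher than
  typical empirical values because the simulated background spectrum is
  simpler than real EEG; group comparisons of that scalar are null by
  construction.
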