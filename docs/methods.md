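# Methods

This note documents the models, numerical choices and known limitations of
`efpcouple`. It complements the API docstrings; nothing here states a result
that the test suite or `scripts/acceptance.py` does not itself compute.

## The EFP signal model

The EFP (EEG-fMRI pattern) predicts the BOLD activity of a deep target
region from a single bipolar EEG derivation (Pz referenced to FCz). For an
output sample at time *t*, the trailing 12-s raw segment is:

1. notch-filtered for 50-Hz line interference (zero-phase 4th-order
   Butterworth band-stop, default width 2 Hz; skipped when above Nyquist);
2. Stockwell-transformed at one frequency per model band;
3. mean-pooled into ¼-s time bins and 10 frequency bands (48 × 10 for a
   12-s segment);
4. contracted with the model's weight table and intercept:
   `EFP = b + Σ P·W`.

**Discrete Stockwell transform.** The S-transform localizes each frequency
*f* with a Gaussian window of σ = 1/f (amplitude f/√2π), equivalently a
frequency-domain Gaussian `exp(−2π²ν²/f²)` applied to the shifted spectrum.
We implement the frequency-domain form on the circular (DFT) signal domain,
summing the Gaussian over ±1 spectral aliases so the FFT path agrees with a
direct time-domain Gaussian-windowed sum to machine precision (the test
suite asserts < 1e−6 relative agreement against an independent O(N²)
oracle; measured error is ~1e−14). Requested frequencies are mapped to the
nearest DFT bin; the f = 0 row is excluded. Phase is referenced to t = 0
(the classic S-transform convention); downstream analyses use only |S|².

**Band definition.** The published models reduce the frequency axis to 10
frequencies, but the band edges and weights are not public. The package
default is 10 contiguous log-spaced bands spanning 1–40 Hz, stored inside
every `EFPModel`, so any result is read relative to a declared model file.
The bundled `demo_model()` is a *synthetic* model (uniform positive weight
on the bands covering a chosen carrier range, zero elsewhere); it is a
stand-in for the proprietary trained weights, not a reproduction of them.
User-supplied weight tables load from JSON.

**Output sampling.** One value is emitted per stride (default 1.5 s = one
TR), timestamped at the *end* of its 12-s segment; output therefore starts
at t = 12 s and the 7 earlier stride slots are warm-up, never emitted as
values. Because stride < segment, consecutive values share 87.5% of their
input and the EFP time-course is strongly autocorrelated; its effective lag
relative to the underlying drive is ≈ half a segment (6 s), which is
comparable to the hemodynamic delay of BOLD. Alignment to the volume grid
uses nearest-sample matching with warm-up volumes dropped from both sides.

**Fused batch path.** `compute_efp_timecourse` evaluates voice-by-voice and
pools each voice's power into ¼-s bins before computing the next, so the
full complex time × frequency × segment cube is never materialized. A test
asserts this fused path is numerically identical to composing the public
`stockwell_transform` and `bin_time_frequency` operations.

## EEG preprocessing

Only the filter stages are implemented: a zero-phase 4th-order Butterworth
band-pass (default 0.75–70 Hz) and zero-phase band-stop notches (default a
4-Hz-wide notch at 33 Hz for periodic scanner-related interference).
MR-artifact removal (gradient, ballistocardiogram, ocular ICA) is upstream
of this package.

## Voxel-wise GLM

Per voxel, the prepared signal is regressed on `[EFP, intercept]` by
ordinary least squares; `dof = volumes − 2`. Preparation order is detrend →
high-pass → demean. The high-pass is realized as discrete-cosine drift
regression: all DCT-II columns with frequency ≤ the cutoff (default
0.001 Hz) are projected out. The EFP regressor is z-scored by default so
betas are comparable across models; a raw-scale option is retained. The
regressor is *not* HRF-convolved by default (the EFP's built-in ~6-s lag
already roughly matches the hemodynamic delay); `efp_convolve_hrf` enables
convolution with the canonical HRF.

Group level: voxel-wise two-tailed one-sample *t* (betas against zero) or
paired *t* (contrasting two EFP models), Benjamini–Hochberg FDR at α = 0.05
across all voxels or a supplied subset (e.g. an anatomical mask). Voxels
with zero across-subject variance are flagged and set to p = 1 (never
significant). Paired contrasts also report directional masks thresholded at
α/2 per direction (p < 0.025 when α = 0.05), matching the usual one-sided
display convention.

## ROI selection

Seed coactivation is the Pearson correlation of each target-mask voxel with
the mean time-course of all voxels whose centers lie within the seed sphere
(default 4-mm radius; boundary inclusive; center-distance criterion; on a
fully occupied 2.2-mm lattice such a sphere holds 27 voxel centers).
Percentiles use linear interpolation over valid (non-missing) correlations;
both the percentile rule and the 0.2 floor/ceiling are strict inequalities,
so ties at the threshold are excluded and the clusters are disjoint on every
input. "At least below 0.2" is read as r < 0.2 (not r < −0.2); this is the
`low_ceiling` config field. Selection and coupling testing are meant to run
on different task runs; the pipeline enforces this by generating a separate
selection run.

## Sliding-window permutation test

Real distribution: per-voxel mean of Pearson correlations over all full
windows of w TRs in 1-TR steps (T − w + 1 windows). Null: the BOLD windows
stay in place while the *intact* EFP windows are reassigned by a seeded
random permutation (without replacement) of window start positions, shared
across voxels within a permutation; 100 permutations pool a null of size
100 × n. Decision: real median > 95th percentile of the null (linear
interpolation percentile, standard median, strict inequality). Degenerate
zero-variance windows contribute r = 0 with a warning, identically in the
real and null branches. The ×100 scaling of real-distribution frequencies
is display-only and never enters the decision.

**Calibration caveat (measured, by design of the published rule).** Aligned
overlapping windows are strongly serially dependent — consecutive windows
share w − 1 samples in *both* series — while shuffled pairings share them in
only one. The real per-voxel window-mean r therefore has a substantially
larger spread than the null values (SD ≈ 0.055 vs ≈ 0.009 at T = 400,
w = 30), so the rule's empirical false-positive rate rises as ROIs shrink:
with white-noise inputs we measure ≈ 28% / 11% / 7.5% at 10 / 25 / 40
voxels. The calibration suite uses 40-voxel ROIs (the default synthetic
target-mask size), where the empirical rate is within 1–10%. Exchangeability
of the machinery itself is verified in the regime where it holds exactly —
non-overlapping windows (step = w), where the identity pairing is one of the
permutations and a KS test cannot distinguish real from null. Decisions on
small clusters should be read as liberal, consistently for signal and null
clusters alike.

## Emotional reactivity

Ratings on the 1–7 scale (4 = neutral) are step-resampled to a uniform grid
(continuous ratings hold their last value between samples), centered at the
neutral anchor 4 (not the subject mean), converted to absolute deviations
and averaged — the reactivity index. Scene differences follow the
high-intensity-minus-low-intensity convention (snakes − farewell). EFP
amplitude per scene is the raw mean over the scene window (absolute-mean
option available). Cohort-level: paired two-tailed *t*-tests per measure and
the Pearson correlation between the two difference vectors; subjects missing
a scene are dropped with a warning without affecting the others.

## Synthetic cohort generator

The generator produces the statistical structure the analyses assume, with
ground truth attached. What it emulates, and what it does not:

- **Latent drive**: low-pass-filtered Gaussian noise (4th-order zero-phase
  Butterworth, default cutoff 0.1 Hz), demeaned, unit SD — a slow smooth
  arousal proxy. Scene blocks add per-subject step levels (defaults: snakes
  1.0, farewell 0.5, between-subject SD 0.3, fixation 0, within-run
  fluctuation scale 0.5), so scenes differ in mean arousal across subjects
  and the reactivity and EFP-amplitude scene differences co-vary.
- **EEG** (250 Hz): the carrier is a constant-modulus frequency-modulated
  sinusoid wandering inside the carrier band (default 4–8 Hz, restricted to
  the flat center of the band), amplitude-modulated by
  `clip(1 + 0.5·latent, 0.05, ∞)`, plus white noise (SD 1) on both
  electrodes of the Pz/FCz pair. A constant-modulus carrier was chosen over
  amplitude-modulated band noise because a stochastic carrier adds
  chi-squared estimation noise (~2 dof per ¼-s bin) to any short-window
  power readout, swamping the envelope signal; with the FM carrier the
  measured amplitude envelope tracks the latent at r > 0.99 (power envelope
  ≈ 0.88) at zero noise. Real EEG background (1/f spectrum, rhythms,
  artifacts) is not modeled, so passing tests demonstrate correct analysis
  behavior given the assumed band-power coding, not robustness to real EEG.
- **BOLD** (TR 1.5 s): coupled voxels are β · (latent ⊛ HRF, resampled to
  volume times, z-scored) + AR(1) noise (stationary SD `noise_sd`, lag-1
  coefficient φ, default 0.3); remaining voxels are pure AR(1). The HRF is
  the canonical double-gamma (peak 6 s, undershoot 16 s, ratio 1/6, 32-s
  support, unit peak), exposed as a config object. Voxels sit on a 2.2-mm
  isotropic lattice with an explicit origin so mm seed spheres are well
  defined. A 7-voxel seed sphere carries a seed signal mixing the BOLD
  drive with an independent smooth component (r ≈ 0.7 with the drive);
  salience-truth target voxels are built as
  `r·seed + √(1−r²)·AR(1)` with r = `seed_coupling_r` (default 0.6, 15% of
  the 40-voxel target mask); the rest of the target mask is AR(1) noise.
  No spatial smoothness, motion, or physiological noise is simulated.
- **Ratings**: `clip(4 + slope·latent + N(0, σ), 1, 7)` every 0.5 s —
  saturation, not rejection.

Every generator is a pure function of its arguments including the seed;
each subject component (levels, latent, EEG, BOLD, ratings) draws from an
independent seeded substream, so disabling one component for speed leaves
the others bit-identical. Between-subject variation applies to `beta_bold`
(normal around the template, clipped at 0); inter-subject variability of
EFP-BOLD coupling is not characterized empirically anywhere we know of, so
the default SD (0.1) is an arbitrary, documented choice.

## Problem sizes used by the validation suites

- Oracle equivalence: signals ≤ 512 samples (Stockwell), ≤ 120 volumes
  (sliding window), 60-volume OLS instances, 1000 randomized ROI-selection
  vectors.
- Null calibration: 200 white-noise ROIs, 40 voxels × 400 volumes, w = 30,
  100 permutations.
- Coupled-cohort recovery: 20 subjects on the full 867-s movie run
  (578 volumes; 120 brain + 7 seed + 40 target voxels), template β = 0.5,
  noise SD 1, full EEG → EFP → GLM → sliding-window chain.
- Reactivity chain: 100 cohorts × 60 subjects on a compact two-scene run
  (45-s scenes) through the full EEG → EFP chain; scene durations were
  shortened from the cinema-length originals to keep the Monte-Carlo sweep
  tractable while leaving ≈ 90 rating samples and ≈ 30 EFP values per
  scene.
- GLM null calibration: 200 cohorts × 20 subjects × 500 voxels at 120
  volumes.

## Known limitations

- The bundled demo EFP model is synthetic; results obtained with it
  characterize the pipeline, not the published trained models.
- The sliding-window decision rule is anti-conservative for small ROIs (see
  the calibration caveat above); the package reports it faithfully rather
  than recalibrating it.
- The generator's EEG and BOLD noise models are deliberately minimal;
  recovery results bound what the analyses can do under their own
  assumptions, not under real-data artifact regimes.
- MR-artifact EEG cleaning, fMRI preprocessing/registration, and atlas
  handling are out of scope; masks and preprocessed inputs are supplied by
  the user (or the generator).
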