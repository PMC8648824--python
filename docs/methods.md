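# Methods

`pceeg` implements the statistical analysis of a probabilistically cued
affective-stimulation EEG experiment, together with a synthetic-data
generator that makes every stage verifiable without access to recordings.
This note documents the model, the defaults and the design choices that were
genuinely open.

## Experimental design and factor model

Each trial presents a cue (modality colour + intensity digit), a jittered
blank, a two-second stimulus, and a 1–4 aversiveness rating.  The cue is
valid in modality on 70% of trials and in intensity on 60%; the two wrong
intensities split the remaining mass equally, and modality and intensity
validity are treated as independent, so per cue the joint cell probabilities
are 0.42 / 0.14 / 0.14 (congruent modality) and 0.18 / 0.06 / 0.06
(incongruent).  `build_trial_schedule` realizes these proportions *exactly*
and therefore requires trials-per-cue counts that make every cell integral
(multiples of 50).  The desk-scale default is `n_per_cue = 50`, i.e. 21
congruent-cell and 7 incongruent-cell picture trials per condition cell per
subject.  Pseudorandomization is a uniform seeded shuffle; no run-length
constraints are imposed.

Only trials where a picture was cued *and* shown enter the analysis.  The
nine cue × stimulus cells carry three within-subject factors:

* `INT` — stimulus intensity, coded −1 / 0 / +1,
* `EXP` — cued intensity, coded the same way,
* `PE`  — absolute prediction error, `|EXP − INT|` ∈ {0, 1, 2}.

Under equal cell weighting the three code vectors are mutually orthogonal
(Σ INT·PE = Σ EXP·PE = Σ INT·EXP = 0), which is what makes separate
single-factor trend tests meaningful.

## Synthetic EEG generator

Each trial is the sum of

1. **1/f background noise**, independent per channel: spectrally shaped
   white noise with power ∝ 1/f (exponent configurable), normalized to unit
   SD and scaled by `noise_scale` (default 1);
2. **three band-limited oscillations** (alpha 10 ± 2 Hz, beta 20 ± 4 Hz,
   gamma 55 ± 10 Hz), each a sinusoid with per-trial uniform random phase
   and per-trial frequency drawn uniformly within the band — induced,
   non-phase-locked activity; evoked components are not modelled.  Each band
   is spatially weighted by a smooth, strictly positive Gaussian topography
   over the montage grid.

During 0–2000 ms post-stimulus the alpha and beta amplitudes are multiplied
by `1 + g_pe_low·PE − g_int·INT − g_exp·EXP` and the gamma amplitude by
`1 + g_pe_gamma·PE`, with 100 ms raised-cosine ramps at the window edges to
avoid spectral splatter.  Because the modulation is multiplicative on
amplitude, band power scales as `(1+m)²` — the closed form used as the
Monte-Carlo oracle in the tests.  Validation requires `|m| < 1` over all
nine cells so amplitudes stay positive.

Default scale: 12 subjects, a 4 × 4 grid montage (16 channels, 4-connected
neighbours), 250 Hz sampling, epochs −2750…+2200 ms around stimulus onset —
minutes-scale runs that preserve the inference problem.  The default gains
(`g_int = 0.25`, `g_exp = 0.22`, `g_pe_low = 0.15`, `g_pe_gamma = 0.45`;
amplitudes alpha 2.5, beta 2.0, gamma 1.2) were fixed once in a design-phase
power check so that the injected effects are reliably recoverable at this
scale; no published effect magnitudes exist in raw-signal units, so the
defaults target recoverability, not a specific empirical SNR.

What the generator does *not* emulate: head-model forward projection (the
topographies are abstract weights, not dipole fields), eye-blink/EMG
artifacts, evoked (phase-locked) responses, between-subject heterogeneity in
effect size, and pain-modality trials (schedule rows exist, but no EEG is
synthesized for them).  Passing tests therefore demonstrate the statistical
machinery — calibration, recovery, exactness — on clean data; they say
nothing about robustness to artifacts or realistic inter-subject variance.

### Ratings

Ratings follow a latent linear model `u = β₀ + β_INT·INT + β_PE·PE +
N(0, σ)`, rounded half-up and clipped to [1, 4]; EXP does not enter.
Defaults: `β₀ = 2.5`, `β_INT = 0.6`, `β_PE = 0.25`, `σ = 0.5`.  The betas
centre the latent cell means on the scale midpoint and keep them clear of
the bounds: clipping extreme cells is asymmetric across the EXP = ±1 columns
and, with homogeneous simulated subjects, even a ~0.03-point systematic bias
becomes a significant spurious EXP trend.  (Real rating data are strongly
clipped at the scale floor, but real subjects also vary between themselves,
which hides biases of this size; the generator has no subject heterogeneity,
so its betas must avoid the bias at source.)

## Spectral analysis

* Preprocessing: per trial-channel mean removal and linear detrend (closed
  form, residuals orthogonal to (1, t)); zero-phase 4th-order Butterworth
  band-pass 1–100 Hz (`sosfiltfilt`); common-average re-reference.
* Time axes: the generator produces stimulus-locked epochs; `timelock`
  re-expresses them cue-locked by shifting each trial by its cue→stimulus
  interval (`soa_ms`, 1500–1900 ms, validated) rounded to whole samples,
  cropping to the common range.
* **Low band (1–30 Hz, 1 Hz steps):** sliding Hann window, 300 ms length,
  50 ms steps.  **High band (31–100 Hz):** sliding multitaper window,
  200 ms, 50 ms steps, ±15 Hz spectral smoothing.  The taper count follows
  the time–bandwidth rule K = ⌊2·T·W⌋ − 1 = 5 Slepian tapers (T = 0.2 s,
  W = 15 Hz).  Power is evaluated at exactly the requested integer
  frequencies via windowed inner products with complex exponentials, so the
  1 Hz grid does not depend on the window length; windows that would need
  data outside the epoch are dropped (no padding).  Window centers lie on
  the 50 ms grid with t = 0 always on-grid; at 250 Hz a center is evaluated
  at the nearest sample (≤ 2 ms off).  Power units are arbitrary; all
  statistics operate on z-baselined values.
* Trial power is averaged per condition cell (arithmetic mean, counts
  recorded); an empty cell is an error.
* **z-baseline:** per subject-channel-frequency, the mean and sample SD
  (N − 1) of the *all-trial* average power (trial-count-weighted mean over
  the nine cells) over the baseline window are computed, and every data
  point is transformed (x − mean)/SD.  Baseline statistics are pooled over
  conditions rather than computed per condition — a condition-specific
  baseline would re-introduce condition differences through the divisor.
  Cue-locked baseline: (−650, −150) ms (150 ms guard = half the 300 ms
  window).  Stimulus-locked baseline: the same window shifted by the
  maximum cue-to-stimulus interval (500 ms cue + 1400 ms blank = 1900 ms),
  i.e. (−2550, −2050) ms.  After baselining, the pooled average restricted
  to the baseline window has mean 0 and SD 1 exactly (tested to 1e−10).

## Statistics

**Per-sample statistic.** For each (channel, frequency, time) sample the
nine cell values collapse to the three level means of the tested factor
(equal cell weights: 3/3/3 for INT and EXP; 3/4/2 for PE levels 0/1/2).  Per
subject an OLS slope over the level codes is fit; the group statistic is
F = t² with t the one-sample t of the subject slopes, df = (1, n − 1).  This
single-df linear trend test matches the reported df structure of a
three-level repeated-measures factor tested for its linear component; the
omnibus F(2, 2(n−1)) variant is intentionally not implemented.  The F is
invariant to affine rescaling of the level codes.

**Cluster formation.** Samples with F strictly greater than the
cluster-forming threshold (upper-α F quantile; F(1, 28) = 4.196 at the
study's n) are split by the sign of the group-mean slope.  Each sign's mask
is pruned by the spatial-neighbour rule — a sample survives only if at least
one neighbouring channel is supra-threshold at the same (frequency, time) —
then grouped into connected components under orthogonal adjacency: ±1
frequency step, ±1 time step, or a neighbouring channel.  A cluster's value
is the sum of its member F values.  The implementation labels each
channel's (frequency, time) plane with 4-connectivity and merges labels
across montage edges with union-find; a naive flood-fill oracle in the test
suite verifies exact equivalence on hundreds of random instances.

**Permutation inference.** Each of `n_perm` Monte-Carlo permutations
independently re-assigns, per subject, the three level means to the level
codes (uniform over the 6 label permutations), recomputes the F map and
re-applies the identical threshold, filter and clustering; the maximum
same-sign cluster value is recorded.  A cluster's p is the plain proportion
of same-sign permutation maxima at or above its value (it can be 0; an
`add_one` option gives (b+1)/(n+1)).

**Tail handling.** The test is two-sided over positive and negative
clusters.  The default `tail_mode="split"` judges each tail at α/2, so the
overall two-sided family-wise error is controlled at α; this is the
convention under which the package's own calibration tests centre on the
nominal rate.  `per_tail` (each tail at full α, which roughly doubles the
per-analysis false-alarm rate) is available for comparison.  The
cluster-forming threshold always uses the full α.

**Post-hoc tests.** For significant clusters, per-subject values are
averaged over all cluster members, collapsed to factor levels, and the three
level pairs are compared with paired t-tests, Bonferroni-corrected (×3).
Zero-variance differences are reported as t = 0 / p = 1 when the difference
is identically zero and raised as degenerate otherwise.

**Test matrix.** Stimulus-locked data (test window 0–2000 ms) are tested
for INT, EXP and PE in both bands; cue-locked data (0–1500 ms) for EXP only
— eight analyses per run.  Windows clip TFR samples by window-center time,
closed intervals.  Display summaries partial out the other two factors per
subject (OLS residuals plus the subject grand mean).

## Numerical choices

* Sliding-window projections run as two real GEMMs (real and imaginary
  parts) on float32 segments; power is accumulated in float64.  The noise
  synthesis FFT uses a padded fast length.
* Supra-threshold membership is strict (`F > threshold`).
* Degenerate inputs (zero slope variability, zero baseline SD, empty
  condition cells, non-integral schedule counts) raise errors that name the
  offending unit rather than propagating NaNs.
* Seeds: every stochastic stage takes an explicit seed; per-subject streams
  derive from `numpy.random.SeedSequence`.  Identical configs are
  byte-identical end to end.

## Scaled-down validation sizes

The calibration and recovery checks run at sizes chosen for desk-scale
turnaround, as the package's own validation design:

* Type-I calibration: 200 null datasets (12 subjects, 16 channels, 250 Hz,
  all gains 0), low-band 8–12 Hz grid, test window 0–1000 ms, 200
  permutations, detrend-only preprocessing (band-pass and re-referencing are
  linear channel-wise maps that cannot break label exchangeability under
  the null).  The fraction of datasets with any significant cluster is
  compared to the 99% binomial interval around the nominal 0.05.
* Effect recovery: 10 seeds with default injected gains and 10 with all
  gains zero; low band 1–30 Hz, high band 40–70 Hz, 200 permutations,
  stimulus-locked INT/EXP (low band) and PE (high band).  Recovery requires
  a significant cluster of the injected sign covering ≥ 50% of the injected
  time–frequency extent.
* Ratings pattern: 50 simulations of 12 subjects each; the INT and PE
  trends must be significant and EXP not.

## Known limitations

* The generator's homogeneous subjects make group tests more powerful than
  real data would allow; recovered effect sizes are not calibrated to any
  empirical SNR.
* Delta/theta (< ~3 Hz) estimates from a 300 ms window are poorly resolved;
  the low-band grid includes them for completeness, as in the analysis the
  package mirrors.
* The multitaper's ±15 Hz smoothing spreads narrow-band gamma over ~30 Hz;
  injected-extent coverage is therefore evaluated against the generator's
  band definition, not the smoothed appearance.
* Artifact handling (ICA, trial rejection, EOG/EMG) is out of scope; the
  synthetic data are clean by construction.
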