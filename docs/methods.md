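# Methods

This note documents the models, the measurement conventions, the
synthetic-data generator, and the numerical and design choices behind
`speecherp`. It states how quantities are computed; every empirical
number it refers to is produced by the test suite or by
`scripts/acceptance.py`, not asserted here.

## The dual-locking problem

Averaging EEG time-locked to stimulus presentation sharpens activity tied
to perception and smears activity tied to the act of responding, and vice
versa: a source that fires a fixed interval before vocal onset is
attenuated in the stimulus-locked average by the reaction-time jitter
(here ~72 ms SD), while it survives intact in the response-locked
average. The pipeline therefore runs every analysis twice, epoching to
stimulus onset (window −200…700 ms, baseline −200…0 ms) and to vocal
onset (window −500…200 ms, baseline −500…−300 ms). Response-locked
analysis of overt speech is only possible after dealing with articulation
EMG, which contaminates precisely the interval of interest.

## Preprocessing

**High-pass filter.** Zero-phase (forward–backward) Butterworth, order 2
before doubling, cutoff 0.16 Hz. The zero-phase choice avoids phase
distortion of the slow pre-response ramps; the low cutoff removes
electrode drift only.

**Ocular correction.** Regression of EEG on the EOG channels. When an
event table is available, the stimulus-locked average is subtracted from
both EEG and EOG before estimating the propagation factors, so genuine
event-related activity does not leak into them; the correction itself is
applied to the raw signals. A single factor matrix (n_EOG × n_EEG) is
used for the whole recording — per-blink/saccade factor splitting is not
implemented.

**Trial selection.** Only correct trials with a registered vocal onset
enter the averages; error, no-response and voice-key-failure trials are
coded in the events table and dropped.

**Artifact rejection.** The original workflow's trial-by-trial visual
inspection is replaced by a reproducible automated surrogate with three
rules on scalp channels: global peak-to-peak above 150 µV; all-channel
peak-to-peak below a flatness floor (0.5 µV); and a *local* rule flagging
trials in which a single channel's peak-to-peak is a robust outlier
across trials (median/MAD z > 5, with the scale floored at 10% of the
channel's median so that small-sample MAD noise does not reject ordinary
variation). The local rule exists because the surface Laplacian is very
sensitive to single-electrode artifacts. A robust z is used rather than
a classical one because a gross trial inflates the classical SD enough to
mask itself. These thresholds are configuration values, and the surrogate
makes no claim to reproduce any particular human rejection rate.

## EMG removal by BSS-CCA

The decomposition solves the canonical correlation problem between the
multichannel window X(t) and its one-sample delay X(t−1); the canonical
correlations equal the lag-1 autocorrelations of the extracted
components, so brain activity (smooth, autocorrelated) and muscle
activity (broadband, weakly autocorrelated) separate along the component
order. Windows are non-overlapping, 1.5 s long (the maximum trial
length), so that local articulation bursts — as opposed to tonic muscle
tone — dominate single windows. A trailing partial window is processed
on its own when it has more samples than channels, otherwise merged into
the preceding window.

Components are classified by the ratio of Welch band power (Hann, 1 s
segments, 50% overlap) in the EMG band [15, 30] Hz to the EEG band
[0, 15) Hz; the label is EMG when the ratio reaches 1/5, and every
flagged component in a window is subtracted (no cap). Subtraction of the
flagged components is algebraically identical to back-projecting the kept
ones in the full-rank case, and is exactly the identity when nothing is
flagged.

**Covariance shrinkage.** With 68 channels in a 768-sample window the
sample covariance is noisy, and unregularized CCA manufactures spurious
low-autocorrelation directions out of estimation noise; these look
broadband, get flagged, and their removal through the oblique
back-projection measurably degrades clean signal. The covariance
diagonals therefore always carry a shrinkage ridge of 1e−3 × trace/n
(upgraded, with a logged warning, when the covariance is numerically rank
deficient). This is an estimation-stability choice, not a rank repair.

## Surface Laplacian (CSD)

Scalp potential is interpolated with spherical splines: the interpolant
is `U(E) = c0 + Σ c_i g(cos(E, E_i))` with

    g(x) = (1/4π) Σ_{n=1..n_max} (2n+1) / (n(n+1))^m · P_n(x),

m = 3 (spline degree), n_max = 15 Legendre terms. The surface Laplacian
follows analytically from the eigenfunction property of spherical
harmonics via the companion kernel h (each term multiplied by n(n+1)).
The reported CSD is the *negative* surface Laplacian,
`(1/r²) Σ c_i h(cos(E, E_i))`, so a focal source under an electrode
appears positive; units µV/cm² on a 10 cm head sphere, whose radius
affects only the 1/r² scale. A Tikhonov term (1e−5) on the spline-system
diagonal is standard smoothing at 64 channels. The transform is linear
and reference-free, so its order relative to baseline subtraction is
immaterial; both properties are tested. Electrode coordinates are
idealized spherical 10–20 positions.

## Component statistics

* **GFP** is the per-sample spatial standard deviation across scalp
  channels; analysis windows are placed where the GFP increases fastest:
  a sliding window (default 25 ms) is scored by the OLS slope of the GFP
  inside it, and the k highest-scoring positive-slope, mutually
  non-overlapping windows are returned (ties to the earlier window). The
  slope scoring is a concrete reading of "fastest increase"; no formula
  is prescribed by convention.
* **Slope statistics.** Per subject, the OLS slope of the waveform inside
  a window; a one-sample t test (one- or two-tailed) compares the slopes
  to zero. Slopes are invariant to per-subject constant offsets, hence
  baseline-independent.
* **Peak latencies.** The grand-average extremum defines a fixed 100 ms
  window; per subject, the waveform is smoothed with a centered 40 ms
  moving average (shrinking symmetric windows at epoch edges) and the
  extremum latency inside the window is taken, earliest sample on ties.
  Window-edge extrema are flagged, flat windows are reported at the
  window center with a degenerate flag. The grand-average window is
  computed per lock condition.
* **Peak-to-peak surface amplitude.** On the *unsmoothed* data, the
  signed trapezoidal area between curve and zero line over 40 ms windows
  centered on two consecutive peak latencies; the measure is
  area(second) − area(first).
* **Latency–RT relation.** Pearson correlation per electrode (t test with
  df = n − 2) plus one multiple regression of mean RT on all electrode
  latencies (statsmodels OLS).
* **Repeated-measures ANOVA** helper with the subject × factor
  interaction as error term; cross-checked against pingouin in the tests.

## Distributed source estimate

Sources sit on a deterministic Fibonacci lattice of 800 free-orientation
dipoles over a spherical cap (z ≥ −0.35 of the sphere at 0.8 × the brain
radius) — a stand-in for a cortical envelope with little inferior
coverage. The inverse is a weighted minimum norm
`J = W Gᵀ (G W Gᵀ + λC)⁻¹ d` with:

* **Noise covariance** C pooled over retained trials and baseline
  samples, diagonal-loaded with 1e−3 × mean diagonal.
* **Depth weighting** per location: gain-column norm to the power −γ,
  γ = 0.5 (a common convention; on the single-radius cap, "depth" means
  distance from the sensor array).
* **Subcorr weighting**: the principal-angle cosine between each
  location's whitened 3-column forward field and the leading left
  singular subspace of the whitened data; the subspace dimension is
  chosen by a broken-stick rule on the data spectrum, capped at 6.
* **Regularization** λ = trace(G̃WG̃ᵀ)/(n_ch · SNR²) in whitened
  coordinates, SNR = 3, overridable.

Source amplitude is the vector norm over the three orientation
components, hence nonnegative. Significance uses an empirical null: pool
amplitudes over all dipoles × baseline samples, threshold at the
(1 − α) quantile with α = 0.001, flag post-event samples above it. The
calibration of this procedure (flagged fraction on held-out noise ≈ α) is
what `scripts/acceptance.py` recomputes; note that because the 2400
source components are driven by only 64 sensors, the pooled samples are
correlated and the threshold estimate is noisy enough to give the
exceedance a small upward bias relative to α — visible but within the
Monte-Carlo error of the 50-replicate study.

## The synthetic generator

The generator emulates a picture-naming session: per-trial stimulus
onsets at a fixed inter-trial interval, reaction times truncated-normal
with mean 651 ms and SD 72 ms on (200, 1500] ms (the response deadline),
~1.3% verbal errors and ~0.5% missing/voice-key-failed responses. Five
dipolar generators in a three-shell spherical head (radii 0.87/0.92/1.0
of 10 cm; conductivity ratio 1 : 1/80 : 1): occipital (peak 100 ms) and
parieto-occipital (150 ms) visual responses and a fronto-central
component (300 ms) locked to the stimulus; a fronto-medial component
peaking 250 ms before vocal onset and a left-frontal ramp rising from
~350 ms before onset to a peak just after it, locked to the response.
Orientations point inward so the overlying surface deflections are
negativities, matching the polarity convention of the measured
components. The forward solution solves the per-degree radial
boundary-value problem of the concentric-sphere conductor (5×5 linear
system per Legendre degree, radii normalized to the scalp for
conditioning), verified against the homogeneous-sphere closed form.

Artifacts:

* **EMG**: per vocal onset, three band-passed (15–110 Hz),
  Hann-windowed noise bursts of 400 ms starting 100 ms before vocal
  onset, loading frontotemporal/inferior channels through smooth gain
  maps around jaw/lower-face anchors. Each burst's map is perturbed
  multiplicatively (uniform 0.5–1.5 per channel) — burst-to-burst
  recruitment variability. Without this, EMG spans one static rank-3
  subspace for the whole recording and the global ocular regression
  cancels it almost completely before BSS-CCA ever runs, which is both
  unrealistic and makes the EMG stage untestable. The EMG onset lag is a
  free parameter of the generator, not an estimate of physiology.
* **Ocular**: Poisson blinks (0.12 Hz) with a smooth 300 ms template,
  propagated from the periocular channels into the EEG with
  distance-decaying factors (stored in the ground truth).
* **Background**: 1/f²-power-spectrum brain noise projected from 40
  random dipoles through the head model — spatially *correlated*, like
  volume-conducted EEG. This matters: spatially independent per-channel
  noise gives CCA 68 effective dimensions and makes its
  minimum-autocorrelation components degenerate. A small white sensor
  noise (0.8 µV RMS) and posterior-weighted, amplitude-modulated 10 Hz
  alpha sit on top.

A deliberate cohort-level feature: the fronto-medial generator's
pre-onset lead grows one-for-one with the subject's mean RT
(peak at −250 − (mean RT − 651) ms). Slower speakers thus engage the
component earlier relative to output, making its latency approximately a
fixed delay after the *stimulus* on average — so response-locked
per-subject latencies correlate negatively with mean RT while
stimulus-locked latencies do not. Without some such coupling the pattern
is impossible: a source at a fixed pre-onset lag yields constant
response-locked latencies (no correlation) and stimulus-locked latencies
that track RT perfectly — the reverse of what dual-locking analyses of
word production report. One RNG seed drives everything; per-source
streams are keyed by source name so the generator is exactly linear in
its source list.

**What the generator does not emulate:** realistic cortical geometry or
conductivity (spherical shells only), tonic EMG, saccades, channel
drift/bridging, trial-to-trial latency jitter of the stimulus-locked
components beyond amplitude jitter, and any linguistic structure
(lexical frequency, repetition). Passing tests therefore demonstrate
that the *pipeline machinery* is correct and calibrated under plausible
signal/artifact statistics — not that any specific human dataset would
yield particular values.

## Study sizes and defaults

The pipeline default is 12 subjects × 100 trials (the emulated study's
participant count at a reduced trial count); the latency-recovery study
uses 12 × 400 trials; the latency–RT power study runs 20 replicate
cohorts of 12 subjects × 60 trials with between-subject RT SD 30 ms;
statistical calibration uses 2000 null replicates. The H0 calibration
study uses 800 dipoles × 100 baseline samples × 50 replicates. These
sizes are the package's validation-study choices and are parameters of
`speecherp.studies`.

## Known limitations

* The EDF writer emits plain 16-bit EDF with 1 s records; a partial
  final record is zero-padded.
* The ocular regression uses all EOG channels jointly over the whole
  recording; datasets whose EOG carries substantial non-ocular signal
  will see part of that regressed out of the EEG too.
* Localization accuracy degrades at the inferior rim of the source cap
  where sensor coverage ends; the localization study samples the covered
  region.
* The subcorr weighting uses the analysis data itself; for very low-SNR
  data the subspace estimate (broken-stick, capped at 6) may understate
  the number of active sources.
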