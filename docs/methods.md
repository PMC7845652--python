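# Methods

This document describes the model implemented by `nmeseeg`: what the
synthetic generator plants, what every analysis stage computes, the numeric
conventions chosen, and the known limitations. Only properties that the
package itself computes are claimed here.

## 1. Study design being simulated

A session emulates an EEG experiment on neuromuscular electrical stimulation
(NMES) of the wrist extensors:

- **9 blocks x 18 trials**, three blocks per stimulation intensity
  (`low`, `medium`, `high`), block order randomized under the balance
  constraint.
- Per trial: a *ready* cue **2.6-3.0 s** (uniform) before stimulation onset,
  a stimulation interval of **3.4-3.8 s** (uniform), and a **3 s**
  inter-trial pause. Blocks are separated by **150 s** breaks by default;
  the break length is configurable and the test-suite compresses it, which
  changes nothing downstream because all analyses are epoch-based.
- **32 EEG channels** in a 10/20 montage plus **2 EMG channels** on the
  stimulated forearm, sampled at **1000 Hz**.
- Stimulation intensities derive from three thresholds (sensory STh, motor
  MTh, functional FTh):
  `low = (MTh - STh) * 0.33 + STh`, `medium = (MTh - STh) * 0.66 + STh`,
  `high = FTh`.

The analysis region of interest (ROI) is the left sensorimotor cortex:
channels **C3, C1, CP3, CP1** (right-hand stimulation).

## 2. Synthetic signal model

Each EEG channel is a sum of independent components (units microvolts):

1. **1/f^a background** (default `a = 1`, amplitude scale 8 uV): white
   Gaussian noise shaped in the frequency domain by `f^(-a/2)`, flat below
   0.5 Hz so the variance stays finite.
2. **Band-limited oscillators**: alpha (7-13 Hz, 12 uV) and beta
   (14-30 Hz, 7 uV) as band-passed Gaussian noise, independent per channel.
3. **ERD modulation** at ROI channels only: during each stimulation interval
   the oscillator of band *b* is multiplied by `sqrt(1 + ERD/100)` so the
   *power* change equals the planted ERD percentage. The envelope has 200 ms
   raised-cosine ramps. An optional habituation slope adds
   `slope * trial_index` percentage points per trial (acquisition order,
   0-based, per intensity), emulating a dose effect.
4. **Stimulation transients**: a 35 Hz pulse train for the duration of every
   stimulation interval, convolved with a biphasic exponentially decaying
   kernel (~5 ms); kernel samples below 15 % of the peak are zeroed so the
   planted transient occupies ~3 samples per pulse. Amplitudes grow with
   intensity (150/300/600 uV) and are scaled by a fixed per-channel gain
   drawn from 1 +/- 0.3.
5. **Power line**: a 50 Hz sinusoid, 2 uV on ordinary channels and 40 uV on
   channels designated *bad* (emulating high electrode impedance).

EMG channels carry only the stimulation artifact (x20 and x16), so the EMG
is flat when artifacts are disabled and onset detection falls back to the
annotated schedule.

Randomness derives from a single `numpy.random.SeedSequence(seed)` spawned
into timeline/neural/artifact substreams (and per-channel neural
substreams), so the schedule is reproducible independently of the neural
noise.

**Realism and limitations of the generator.** Channels are spatially
independent (no volume conduction or spatial mixing), the background is
stationary, eye/muscle artifacts other than the stimulation train are not
modeled, and ERD is planted as a clean multiplicative envelope. These
simplifications make ground truth exact and recoverable; they also mean the
pipeline is *not* being stress-tested against EOG/EMG contamination or
non-stationary baselines. One quantifiable consequence: the in-band part of
the 1/f background is not modulated by the ERD envelope, so measured ERD is
biased toward zero by the ratio of oscillator power to total in-band power
(about 5 % relative for the default alpha amplitudes). Tolerances in the
test suite account for this.

## 3. Artifact removal

**Step 1 - iterative bad-channel rejection.** Excess 48-52 Hz power is used
as an indirect impedance indicator. Per block: a 4th-order 0.1 Hz Butterworth
high-pass is applied to a working copy; per-channel Welch band power
(1 s Hamming windows, 50 % overlap) is averaged over the block's trial
segments; channels above `mean + 4 SD` of the channel population are
discarded; statistics are recomputed on the survivors and the loop repeats
until no channel exceeds the threshold. The original (unfiltered) data of
retained channels flows downstream; rejected channels are excluded through
per-block masks, never silently dropped.

Two conventions are worth noting. The z-score of a single outlier among *n*
values is bounded by `sqrt(n - 1)`, so a 4-SD criterion needs at least 18
channels to fire at all — unproblematic for the 32-channel montage, but the
reason `min_channels` aborts the loop rather than letting the statistics
degenerate. With a zero population SD (identical channels) nothing is
rejected.

**Step 2 - sliding median filter.** A 10 ms window advancing one sample at a
time replaces each sample with the median of its window (even-length median
= mean of the two middle order statistics; output sample at `window // 2`
from the left edge). Edges use shrinking windows by default (`reflect` is
available). The filter removes the ~3-sample stimulation transients exactly
(the transient never occupies the median rank of a 10-sample window) while
attenuating genuine oscillations only mildly.

**Attenuation convention.** The attenuation figures are *peak amplitude*
attenuation, averaged over the initial phase of the sinusoid, measured away
from signal edges. In the continuous limit this equals
`1 - cos(pi * f * T / 2)` for window length `T`, giving **1.23 %, 4.89 %,
10.90 %** at 10/20/30 Hz and 100 % at 100 Hz (one period per window). A
Fourier-fundamental measurement would give smaller numbers (0.2-4.5 %); the
peak convention is the one consistent with the headline values this package
reproduces.

## 4. Preprocessing

Per block, in order:

1. channel rejection (above) determines the block's retained set;
2. sliding median filter on the retained channels;
3. common average reference over the retained channels only (so a bad
   channel cannot re-inject its noise through the mean);
4. 0.1-45 Hz 1st-order Butterworth band-pass, applied forward-backward
   (`sosfiltfilt`): zero phase so ERD latencies stay aligned, at the cost of
   squaring the magnitude response;
5. epoching into [-4, +4) s around each stimulation onset (left-closed →
   exactly 800 samples after downsampling). Onsets are refined on the
   rectified mean EMG with a `median + 5 * MAD` threshold within +/- 0.5 s
   of the annotation, falling back to the annotation when the EMG is flat;
6. downsampling to 100 Hz by decimation (keeping every 10th sample); the
   45 Hz low-pass of stage 4 provides the anti-alias margin below the new
   50 Hz Nyquist;
7. pooling per intensity across blocks in acquisition order.

## 5. ERD/ERS quantification

Power is computed with complex Morlet wavelets, 1-45 Hz in 0.5 Hz steps,
7 cycles. Percent change relative to the baseline interval (-2.5, -1.5) s:

    ERD/ERS_j (%) = (P_j - Baseline) / Baseline * 100

Condition maps average power over trials *first*, then normalize. Trials
with different surviving channel sets are combined mask-aware: each
channel's condition power averages only the trials where that channel
survived; channels rejected everywhere are NaN and excluded from ROI means.
Scalar summaries average ERD over the band's frequency bins and over the
stimulation (0.5, 2.5) s or non-stimulation (-3, -1) s interval.

Two numerical choices:

- **Wavelet length cap.** A 7-cycle wavelet at 1 Hz is longer than the 8 s
  epoch, so the cycle count is capped per frequency at
  `min(7, 0.95 * 2*pi*f*T_epoch / 10)` (the discrete wavelet support is
  ~10 sigma_t). Only display frequencies below ~1.4 Hz are affected; the
  alpha/beta analysis bands use the full 7 cycles.
- **Edge validity.** Time-frequency bins closer to an epoch edge than the
  wavelet half-width are flagged, and interval summaries warn when they
  overlap edge-affected bins (the default baseline is safe above 2.5 Hz).

## 6. Dose-effect analysis

The single-trial ERD of one band/intensity is the trial's band- and
ROI-averaged power in the stimulation interval, normalized by the **grand
average** (over the intensity's trials) of the baseline-interval power —
a shared baseline, so trial-to-trial baseline noise does not leak into the
numerator and denominator simultaneously. Masked ROI channels are excluded
per trial (weighted mean over surviving ROI channels).

Ordinary least squares of the ERD series on the trial index 1..N gives the
dose slope, with Pearson's r and its two-sided p-value (alpha = 0.05).
A zero-variance series is reported as `r_defined = False` rather than NaN.
Complementary block-wise regressions and a *reset* statistic
(`ERD(first trial of block k+1) - ERD(last trial of block k)`) describe
whether within-block trends restart after breaks.

## 7. Input/output formats

Sessions round-trip through **EDF+C** (16-bit, 1 s records, symmetric
per-channel physical ranges rounded to 4 significant digits, events as EDF+
annotations). The writer is implemented directly against the EDF+
specification; reading goes through MNE's independent EDF decoder after a
structural header check, so the writer is cross-validated on every read.
Epoch sets are stored in HDF5 with all trial metadata.

## 8. Open design decisions

- The CAR over a small retained set slightly dilutes ROI ERD (the reference
  contains a share of the ROI signal); with the full 32-channel montage the
  effect is within the stated tolerances, but analyses on few-channel
  subsets should skip the CAR (the dose-effect tests do).
- Downsampling keeps every 10th sample rather than averaging; with the
  45 Hz zero-phase low-pass in place the difference is negligible, and
  decimation keeps the epoch grid exact.
- The rejection statistic uses the population SD including the candidate
  outliers (as specified), which makes single-outlier detection conservative
  on small montages; see the `sqrt(n - 1)` bound above.
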