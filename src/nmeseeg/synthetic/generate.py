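"""Synthesis of annotated NMES-EEG sessions.

The generated EEG is a sum of independent components per channel:

* 1/f^a broadband background (FFT-shaped Gaussian noise),
* band-limited rolandic alpha and beta oscillations whose envelope at the
  ROI channels is suppressed during each stimulation interval according to
  the planted ERD (multiplicative power change, smooth 200 ms ramps),
* a 50 Hz power-line component (large on designated bad-impedance channels),
* 35 Hz trains of ~5 ms biphasic stimulation transients whose amplitude
  scales with the NMES intensity.

The muscle channels carry the stimulation transient train only, which is
what the real recordings use to align stimulation onset.

One global seed fans out to independent substreams for the timeline, the
neural components and the artifacts, so disabling one component does not
change the realization of the others.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from nmeseeg.montage import EEG_CHANNELS, EMG_CHANNELS
from nmeseeg.session import Event, RawSession
from nmeseeg.synthetic.design import SessionDesign, build_timeline, timeline_duration
from nmeseeg.synthetic.ground_truth import BANDS, ArtifactModel, NeuralGroundTruth


def one_over_f_noise(
    n: int, fs: float, exponent: float, rms: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian noise with power spectral density proportional to 1/f^exponent.

    The shaping is flat below 0.5 Hz to keep the variance finite.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.ones_like(f)
    nz = f > 0
    shape[nz] = np.maximum(f[nz], 0.5) ** (-exponent / 2.0)
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def narrowband_noise(
    n: int, fs: float, band: tuple[float, float], rms: float, rng: np.random.Generator
) -> np.ndarray:
    """Band-limited Gaussian oscillation with the requested RMS amplitude."""
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def transient_kernel(fs: float, duration_ms: float = 5.0) -> np.ndarray:
    """Single-pulse EEG transient: biphasic spike * exponential decay.

    Samples below 15% of the peak are zeroed so the transient stays a crisp
    high-amplitude event of a few samples, as in real recordings where the
    amplifier recovers quickly between pulses.
    """
    n = max(2, int(round(duration_ms * fs / 1000.0)))
    tau = duration_ms / 4.0 / 1000.0
    t = np.arange(n) / fs
    decay = np.exp(-t / tau)
    k = np.convolve([1.0, -1.0], decay)[:n]
    k /= np.max(np.abs(k))
    k[np.abs(k) < 0.15] = 0.0
    return k


def _erd_envelope(
    n: int,
    fs: float,
    events: list[Event],
    ground_truth: NeuralGroundTruth,
    band: str,
) -> np.ndarray:
    """Amplitude envelope realizing the planted per-trial ERD for one band."""
    env = np.ones(n)
    ramp_n = int(round(ground_truth.erd_ramp * fs))
    counters: dict[str, int] = {}
    for ev in events:
        if not ev.label.startswith("stim_on/"):
            continue
        intensity = ev.label.split("/", 1)[1]
        idx = counters.get(intensity, 0)
        counters[intensity] = idx + 1
        erd = ground_truth.erd_for(band, intensity, idx)
        g = np.sqrt(max(1.0 + erd / 100.0, 0.0))
        i0 = int(round(ev.onset * fs))
        i1 = int(round((ev.onset + ev.duration) * fs))
        i0, i1 = max(i0, 0), min(i1, n)
        if i1 <= i0:
            continue
        env[i0:i1] = g
        # smooth transitions: 1 -> g entering, g -> 1 after the offset
        r0 = min(ramp_n, i1 - i0)
        if r0 > 0:
            w = 0.5 * (1 + np.cos(np.linspace(0, np.pi, r0)))
            env[i0 : i0 + r0] = g + (1.0 - g) * w
        r1 = min(ramp_n, n - i1)
        if r1 > 0:
            w = 0.5 * (1 + np.cos(np.linspace(0, np.pi, r1)))
            env[i1 : i1 + r1] = 1.0 + (g - 1.0) * w
    return env


def _pulse_train(
    n: int, fs: float, events: list[Event], model: ArtifactModel
) -> np.ndarray:
    """Unit-amplitude transient train (scaled per intensity) over the session."""
    train = np.zeros(n)
    kernel = transient_kernel(fs, model.transient_duration_ms)
    period = 1.0 / model.pulse_rate
    for ev in events:
        if not ev.label.startswith("stim_on/"):
            continue
        amp = model.transient_amplitude.get(ev.label.split("/", 1)[1], 0.0)
        if amp == 0.0:
            continue
        t = ev.onset
        while t < ev.onset + ev.duration:
            i = int(round(t * fs))
            j = min(i + len(kernel), n)
            if i >= n:
                break
            train[i:j] += amp * kernel[: j - i]
            t += period
    return train


def synthesize(
    design: SessionDesign,
    ground_truth: NeuralGroundTruth | None = None,
    artifact_model: ArtifactModel | None = None,
    seed: int = 0,
    channels: tuple[str, ...] = EEG_CHANNELS,
) -> RawSession:
    """Generate a complete annotated session with known ground truth.

    Parameters
    ----------
    channels
        Montage subset to synthesize (defaults to the full 32-channel cap).
        Restricting it speeds up studies that only need the ROI.
    """
    ground_truth = ground_truth if ground_truth is not None else NeuralGroundTruth()
    artifact_model = artifact_model if artifact_model is not None else ArtifactModel()
    unknown = set(channels) - set(EEG_CHANNELS)
    if unknown:
        raise ValueError(f"channels not in montage: {sorted(unknown)}")

    ss = np.random.SeedSequence(seed)
    ss_timeline, ss_neural, ss_artifact = ss.spawn(3)
    events = build_timeline(design, np.random.default_rng(ss_timeline))
    fs = design.fs
    n = int(round(timeline_duration(events) * fs))
    t = np.arange(n) / fs

    envelopes = {
        band: _erd_envelope(n, fs, events, ground_truth, band) for band in BANDS
    }
    train = _pulse_train(n, fs, events, artifact_model)

    rng_art = np.random.default_rng(ss_artifact)
    gains = 1.0 + artifact_model.channel_gain_spread * rng_art.uniform(
        -1.0, 1.0, size=len(channels)
    )

    neural_streams = ss_neural.spawn(len(channels))
    eeg = np.empty((len(channels), n))
    roi = set(ground_truth.roi)
    for ci, (ch, ch_ss) in enumerate(zip(channels, neural_streams)):
        rng = np.random.default_rng(ch_ss)
        x = one_over_f_noise(
            n, fs, ground_truth.background_exponent, ground_truth.background_amplitude, rng
        )
        for band, (lo, hi) in BANDS.items():
            osc = narrowband_noise(
                n, fs, (lo, hi), ground_truth.oscillation_amplitudes[band], rng
            )
            if ch in roi:
                osc = osc * envelopes[band]
            x += osc
        pl_amp = (
            artifact_model.powerline_amplitude
            if ch in artifact_model.bad_channels
            else artifact_model.baseline_powerline
        )
        if pl_amp:
            x += pl_amp * np.sin(
                2 * np.pi * artifact_model.powerline_freq * t + rng.uniform(0, 2 * np.pi)
            )
        x += gains[ci] * train
        eeg[ci] = x

    emg = np.vstack(
        [artifact_model.emg_gain * train, 0.8 * artifact_model.emg_gain * train]
    )
    return RawSession(
        eeg=eeg,
        emg=emg,
        fs=fs,
        annotations=events,
        channels=tuple(channels),
        emg_channels=EMG_CHANNELS,
        ground_truth=ground_truth,
    )
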