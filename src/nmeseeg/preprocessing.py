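"""Referencing, filtering, onset alignment, epoching and pooling.

After the two-step artifact removal, the retained channels are re-referenced
to the common average, band-pass filtered at 0.1-45 Hz (1st-order
Butterworth, applied forward-backward so the ERD latency stays aligned to
the stimulation onset), cut into 8 s trials from -4 to +4 s around each
stimulation onset, downsampled to 100 Hz, and pooled per NMES intensity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from nmeseeg.session import Event, RawSession


@dataclass
class EpochSet:
    """Trials x channels x time array with trial metadata.

    ``data`` is in uV; ``times`` is relative to stimulation onset and spans
    [-4, +4) s (left-closed, so 800 samples at 100 Hz). ``channel_mask``
    records, per trial, which channels survived that trial's block-wise
    rejection. ``order`` is the global acquisition index of each trial.
    """

    data: np.ndarray
    times: np.ndarray
    fs: float
    channels: tuple[str, ...]
    intensity: np.ndarray
    block: np.ndarray
    trial_in_block: np.ndarray
    order: np.ndarray
    channel_mask: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.intensity = np.asarray(self.intensity)
        self.block = np.asarray(self.block, dtype=int)
        self.trial_in_block = np.asarray(self.trial_in_block, dtype=int)
        self.order = np.asarray(self.order, dtype=int)
        self.channel_mask = np.asarray(self.channel_mask, dtype=bool)
        n_tr, n_ch, n_t = self.data.shape
        if self.times.size != n_t or len(self.channels) != n_ch:
            raise ValueError("times/channels inconsistent with data shape")
        for name in ("intensity", "block", "trial_in_block", "order"):
            if getattr(self, name).shape != (n_tr,):
                raise ValueError(f"{name} must have one entry per trial")
        if self.channel_mask.shape != (n_tr, n_ch):
            raise ValueError("channel_mask must be (n_trials, n_channels)")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def channel_index(self, label: str) -> int:
        return self.channels.index(label)

    def select_trials(self, idx: np.ndarray) -> "EpochSet":
        return EpochSet(
            data=self.data[idx],
            times=self.times,
            fs=self.fs,
            channels=self.channels,
            intensity=self.intensity[idx],
            block=self.block[idx],
            trial_in_block=self.trial_in_block[idx],
            order=self.order[idx],
            channel_mask=self.channel_mask[idx],
        )


def common_average_reference(eeg: np.ndarray) -> np.ndarray:
    """Subtract the instantaneous mean over channels from every channel.

    Expects only the retained channels; contaminated channels must be
    excluded beforehand or they would re-inject their artifacts through the
    mean. The output columns sum to zero.
    """
    eeg = np.asarray(eeg, dtype=float)
    if eeg.ndim != 2 or eeg.shape[0] < 2:
        raise ValueError("CAR needs at least two channels")
    return eeg - eeg.mean(axis=0, keepdims=True)


def bandpass(
    eeg: np.ndarray,
    fs: float,
    low: float = 0.1,
    high: float = 45.0,
    order: int = 1,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass (applied forward-backward).

    The default matches the analysis chain: 0.1-45 Hz, 1st order. The
    forward-backward application doubles the effective order and squares the
    magnitude response but leaves the phase untouched.
    """
    if not (0 < low < high < fs / 2):
        raise ValueError(f"cutoffs must satisfy 0 < {low} < {high} < fs/2 = {fs / 2}")
    sos = signal.butter(order, (low, high), btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(eeg, dtype=float), axis=-1)


def detect_stim_onsets(
    emg: np.ndarray,
    fs: float,
    annotations: list[Event],
    mad_multiplier: float = 5.0,
    search_window: float = 0.5,
) -> np.ndarray:
    """Align stimulation onsets on the muscle sensors.

    The rectified EMG (mean over sensors) is thresholded at
    median + ``mad_multiplier`` * MAD (robust to the artifact's heavy tail);
    for every annotated stimulation event the first crossing within
    +/- ``search_window`` s of the annotated onset is taken. When the EMG
    carries no artifact (flat signal, or no crossing near an event) the
    annotated onset is used as a fallback.

    Returns one onset time (s) per ``stim_on`` annotation, in order.
    """
    emg = np.atleast_2d(np.asarray(emg, dtype=float))
    events = sorted(
        (e for e in annotations if e.label.startswith("stim_on/")), key=lambda e: e.onset
    )
    if not events:
        raise ValueError("no stimulation annotations to align")
    rect = np.abs(emg).mean(axis=0)
    mad = np.median(np.abs(rect - np.median(rect)))
    threshold = np.median(rect) + mad_multiplier * mad
    flat = np.max(rect) <= max(threshold, 1e-12)
    onsets = np.empty(len(events))
    for k, ev in enumerate(events):
        if flat:
            onsets[k] = ev.onset
            continue
        i0 = max(int(round((ev.onset - search_window) * fs)), 0)
        i1 = min(int(round((ev.onset + search_window) * fs)), rect.size)
        above = np.flatnonzero(rect[i0:i1] > threshold)
        onsets[k] = (i0 + above[0]) / fs if above.size else ev.onset
    return onsets


def epoch(
    eeg: np.ndarray,
    fs: float,
    onsets: np.ndarray,
    intensity: list[str] | np.ndarray,
    channels: tuple[str, ...],
    block: np.ndarray | None = None,
    trial_in_block: np.ndarray | None = None,
    order: np.ndarray | None = None,
    channel_mask: np.ndarray | None = None,
    tmin: float = -4.0,
    tmax: float = 4.0,
) -> EpochSet:
    """Cut [tmin, tmax) epochs around each onset, at the native rate.

    Onsets whose window does not fit inside the recording are dropped with a
    warning. ``channel_mask`` may be a single per-channel vector (applied to
    every trial) or one row per trial.
    """
    eeg = np.asarray(eeg, dtype=float)
    onsets = np.asarray(onsets, dtype=float)
    intensity = np.asarray(intensity)
    n_ch, n_samp = eeg.shape
    n0, n1 = int(round(tmin * fs)), int(round(tmax * fs))
    n_t = n1 - n0

    usable = []
    for k, on in enumerate(onsets):
        i = int(round(on * fs))
        if i + n0 < 0 or i + n1 > n_samp:
            warnings.warn(
                f"dropping trial at {on:.2f} s: epoch window out of bounds", RuntimeWarning
            )
            continue
        usable.append(k)
    if not usable:
        raise ValueError("no usable stimulation onsets after boundary checks")

    block = np.zeros(onsets.size, dtype=int) if block is None else np.asarray(block)
    trial_in_block = (
        np.arange(onsets.size) if trial_in_block is None else np.asarray(trial_in_block)
    )
    order = np.arange(onsets.size) if order is None else np.asarray(order)
    if channel_mask is None:
        channel_mask = np.ones((onsets.size, n_ch), dtype=bool)
    else:
        channel_mask = np.asarray(channel_mask, dtype=bool)
        if channel_mask.ndim == 1:
            channel_mask = np.tile(channel_mask, (onsets.size, 1))

    data = np.empty((len(usable), n_ch, n_t))
    for j, k in enumerate(usable):
        i = int(round(onsets[k] * fs))
        data[j] = eeg[:, i + n0 : i + n1]
    times = (np.arange(n0, n1)) / fs
    idx = np.asarray(usable)
    return EpochSet(
        data=data,
        times=times,
        fs=fs,
        channels=tuple(channels),
        intensity=intensity[idx],
        block=block[idx],
        trial_in_block=trial_in_block[idx],
        order=order[idx],
        channel_mask=channel_mask[idx],
    )


def downsample(epochs: EpochSet, target_fs: float = 100.0) -> EpochSet:
    """Decimate epochs to ``target_fs`` by an integer factor.

    Relies on the 45 Hz low-pass of the preceding band-pass stage for
    anti-aliasing (Nyquist at 100 Hz is 50 Hz).
    """
    factor = epochs.fs / target_fs
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(
            f"native rate {epochs.fs} Hz is not an integer multiple of {target_fs} Hz"
        )
    factor = int(round(factor))
    return EpochSet(
        data=epochs.data[:, :, ::factor],
        times=epochs.times[::factor],
        fs=target_fs,
        channels=epochs.channels,
        intensity=epochs.intensity,
        block=epochs.block,
        trial_in_block=epochs.trial_in_block,
        order=epochs.order,
        channel_mask=epochs.channel_mask,
    )


def pool_by_intensity(
    epoch_sets: list[EpochSet], labels: tuple[str, ...] | None = None
) -> dict[str, EpochSet]:
    """Pool trials of the same NMES intensity across blocks.

    Trials are concatenated in acquisition order (by the global ``order``
    index), preserving within-block order — the ordering the dose-effect
    regressions rely on. Differing channel sets are represented through the
    per-trial channel masks, never silently truncated. When ``labels`` is
    given, intensities without any trial yield an empty epoch set with a
    warning instead of being dropped from the mapping.
    """
    if not epoch_sets:
        raise ValueError("no epoch sets to pool")
    ref = epoch_sets[0]
    for es in epoch_sets[1:]:
        if es.channels != ref.channels or es.times.shape != ref.times.shape:
            raise ValueError("epoch sets have inconsistent montage or time axis")
    merged = EpochSet(
        data=np.concatenate([es.data for es in epoch_sets]),
        times=ref.times,
        fs=ref.fs,
        channels=ref.channels,
        intensity=np.concatenate([es.intensity for es in epoch_sets]),
        block=np.concatenate([es.block for es in epoch_sets]),
        trial_in_block=np.concatenate([es.trial_in_block for es in epoch_sets]),
        order=np.concatenate([es.order for es in epoch_sets]),
        channel_mask=np.concatenate([es.channel_mask for es in epoch_sets]),
    )
    out: dict[str, EpochSet] = {}
    wanted = (
        list(dict.fromkeys(merged.intensity.tolist())) if labels is None else list(labels)
    )
    for label in wanted:
        idx = np.flatnonzero(merged.intensity == label)
        if idx.size == 0:
            warnings.warn(f"no trials for intensity {label!r}", RuntimeWarning)
        subset = merged.select_trials(idx)
        sort = np.argsort(subset.order, kind="stable")
        out[str(label)] = subset.select_trials(sort)
    return out
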