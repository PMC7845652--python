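"""Containers for continuous recordings and their event annotations."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from nmeseeg.montage import EEG_CHANNELS, EMG_CHANNELS


@dataclass(frozen=True)
class Event:
    """A single annotation: onset (s), duration (s) and a text label.

    Labels follow the convention ``ready``, ``stim_on/<intensity>``,
    ``stim_off`` and ``block_start/<k>``.
    """

    onset: float
    duration: float
    label: str


def stim_onsets(annotations: list[Event]) -> list[Event]:
    """Stimulation-onset events, in temporal order."""
    evs = [e for e in annotations if e.label.startswith("stim_on/")]
    return sorted(evs, key=lambda e: e.onset)


def block_starts(annotations: list[Event]) -> list[Event]:
    evs = [e for e in annotations if e.label.startswith("block_start/")]
    return sorted(evs, key=lambda e: e.onset)


@dataclass
class RawSession:
    """Continuous multichannel EEG + muscle channels + annotations.

    ``eeg`` and ``emg`` are arrays of shape (n_channels, n_samples) in uV,
    synchronously sampled at ``fs`` Hz.
    """

    eeg: np.ndarray
    emg: np.ndarray
    fs: float
    annotations: list[Event]
    channels: tuple[str, ...] = EEG_CHANNELS
    emg_channels: tuple[str, ...] = EMG_CHANNELS
    ground_truth: object | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.eeg = np.asarray(self.eeg, dtype=float)
        self.emg = np.asarray(self.emg, dtype=float)
        if self.eeg.ndim != 2 or self.eeg.shape[0] != len(self.channels):
            raise ValueError(
                f"eeg must be ({len(self.channels)}, n_samples); got {self.eeg.shape}"
            )
        if self.emg.ndim != 2 or self.emg.shape[0] != len(self.emg_channels):
            raise ValueError(
                f"emg must be ({len(self.emg_channels)}, n_samples); got {self.emg.shape}"
            )
        if self.eeg.shape[1] != self.emg.shape[1]:
            raise ValueError("eeg and emg must cover the same samples")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")
        dur = self.n_samples / self.fs
        for ev in self.annotations:
            if not 0 <= ev.onset <= dur:
                raise ValueError(f"annotation {ev.label!r} at {ev.onset} s lies outside the recording")

    @property
    def n_samples(self) -> int:
        return self.eeg.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def stim_onsets(self) -> list[Event]:
        return stim_onsets(self.annotations)

    def block_starts(self) -> list[Event]:
        return block_starts(self.annotations)

    def channel_index(self, label: str) -> int:
        return self.channels.index(label)
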