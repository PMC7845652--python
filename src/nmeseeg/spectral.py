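"""Morlet time-frequency decomposition and ERD/ERS quantification.

Power is estimated with complex Morlet wavelets (1-45 Hz, 0.5 Hz steps,
7 cycles by default) and expressed as the percent change relative to the
mean power in the pre-stimulation baseline interval (-2.5, -1.5) s:

    ERD/ERS_j (%) = (P_j - Baseline) / Baseline * 100

Negative values (ERD) indicate suppression of the rhythm, i.e. cortical
activation. Condition-level maps average power over trials first and then
normalize; single-trial series (dose-effect analysis) share a grand-average
baseline and live in :mod:`nmeseeg.dose`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from nmeseeg.montage import ROI_CHANNELS
from nmeseeg.preprocessing import EpochSet


def _default_freqs() -> np.ndarray:
    return np.arange(1.0, 45.0 + 1e-9, 0.5)


@dataclass
class TFRConfig:
    """Time-frequency analysis parameters."""

    freqs: np.ndarray = field(default_factory=_default_freqs)
    n_cycles: float = 7.0
    baseline: tuple[float, float] = (-2.5, -1.5)
    stim_interval: tuple[float, float] = (0.5, 2.5)
    nostim_interval: tuple[float, float] = (-3.0, -1.0)
    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"alpha": (7.0, 13.0), "beta": (14.0, 30.0)}
    )
    roi: tuple[str, ...] = ROI_CHANNELS

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.size == 0 or np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be a non-empty increasing grid")
        if self.n_cycles <= 0:
            raise ValueError("n_cycles must be positive")
        for name in ("baseline", "stim_interval", "nostim_interval"):
            lo, hi = getattr(self, name)
            if lo >= hi:
                raise ValueError(f"{name} must be an increasing interval")
        for band, (lo, hi) in self.bands.items():
            if not (self.freqs[0] <= lo < hi <= self.freqs[-1]):
                raise ValueError(f"band {band} outside the analysis frequency range")

    def band_freq_grid(self, band: str) -> np.ndarray:
        """The analysis frequencies falling inside a named band."""
        lo, hi = self.bands[band]
        return self.freqs[(self.freqs >= lo) & (self.freqs <= hi)]


@dataclass
class TFR:
    """Time-frequency power, (trials x) channels x freqs x times, in uV^2.

    ``edge_valid[f, t]`` is False where the wavelet's Gaussian half-width
    ``n_cycles / (2 freq)`` reaches beyond the epoch edges.
    """

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    channels: tuple[str, ...]
    edge_valid: np.ndarray

    @property
    def averaged(self) -> bool:
        return self.power.ndim == 3


@dataclass
class ERDMap:
    """Percent power change maps, same layout as :class:`TFR`."""

    values: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    channels: tuple[str, ...]
    edge_valid: np.ndarray

    @property
    def averaged(self) -> bool:
        return self.values.ndim == 3


def _edge_valid(
    times: np.ndarray, freqs: np.ndarray, n_cycles: float | np.ndarray
) -> np.ndarray:
    half = np.asarray(n_cycles) / (2.0 * freqs)
    return (times[None, :] >= times[0] + half[:, None]) & (
        times[None, :] <= times[-1] - half[:, None]
    )


def morlet_tfr(
    epochs: EpochSet,
    cfg: TFRConfig = TFRConfig(),
    picks: tuple[str, ...] | None = None,
    average: bool = False,
    freqs: np.ndarray | None = None,
) -> TFR:
    """Morlet wavelet power of an epoch set.

    Parameters
    ----------
    picks
        Channel labels to decompose (default: all).
    average
        Average power over trials (condition maps) instead of returning the
        per-trial power.
    freqs
        Optional frequency subset (must lie within ``cfg.freqs``); used to
        restrict single-trial band computations.
    """
    from mne.time_frequency import tfr_array_morlet

    f = cfg.freqs if freqs is None else np.asarray(freqs, dtype=float)
    epoch_len = epochs.times[-1] - epochs.times[0]
    # the discrete wavelet support is ~10 sigma_t = 10 n_cycles / (2 pi f);
    # cap the cycle count so wavelets at the lowest display frequencies
    # still fit inside the epoch (analysis bands are unaffected)
    n_cycles = np.minimum(cfg.n_cycles, 0.95 * 2 * np.pi * f * epoch_len / 10.0)
    if np.any(n_cycles < 1):
        raise ValueError("epoch too short for a one-cycle wavelet at the lowest frequency")
    if picks is None:
        picks = epochs.channels
    idx = [epochs.channel_index(ch) for ch in picks]
    data = epochs.data[:, idx, :]
    power = tfr_array_morlet(
        data,
        sfreq=epochs.fs,
        freqs=f,
        n_cycles=n_cycles,
        output="avg_power" if average else "power",
        zero_mean=True,
        verbose="ERROR",
    )
    return TFR(
        power=power,
        freqs=f,
        times=epochs.times,
        channels=tuple(picks),
        edge_valid=_edge_valid(epochs.times, f, n_cycles),
    )


def _interval_slice(times: np.ndarray, interval: tuple[float, float]) -> np.ndarray:
    sel = (times >= interval[0]) & (times <= interval[1])
    if not np.any(sel):
        raise ValueError(f"interval {interval} contains no samples")
    return sel


def _warn_edges(tfr: TFR | ERDMap, interval: tuple[float, float], name: str) -> None:
    sel = _interval_slice(tfr.times, interval)
    bad = ~tfr.edge_valid[:, sel]
    if np.any(bad):
        lowest_safe = tfr.freqs[~np.any(bad, axis=1)]
        msg = (
            f"{name} interval {interval} overlaps wavelet edge effects; "
            + (
                f"lowest safe frequency is {lowest_safe[0]:.1f} Hz"
                if lowest_safe.size
                else "no analysis frequency is edge-safe"
            )
        )
        warnings.warn(msg, RuntimeWarning)


def erd_percent(tfr: TFR, cfg: TFRConfig = TFRConfig()) -> ERDMap:
    """Normalize power to percent change relative to the baseline interval.

    For trial-resolved input every trial is normalized by its own baseline;
    condition maps should average power over trials before normalizing (see
    :func:`condition_erd_map`).
    """
    sel = _interval_slice(tfr.times, cfg.baseline)
    _warn_edges(tfr, cfg.baseline, "baseline")
    baseline = tfr.power[..., sel].mean(axis=-1, keepdims=True)
    if np.any(baseline <= 0):
        raise ValueError("zero baseline power; degenerate input")
    values = (tfr.power - baseline) / baseline * 100.0
    return ERDMap(
        values=values,
        freqs=tfr.freqs,
        times=tfr.times,
        channels=tfr.channels,
        edge_valid=tfr.edge_valid,
    )


def condition_erd_map(
    epochs: EpochSet,
    cfg: TFRConfig = TFRConfig(),
    picks: tuple[str, ...] | None = None,
) -> ERDMap:
    """Condition-averaged ERD/ERS map: trial-averaged power, then Eq-style
    percent normalization by the baseline interval."""
    return erd_percent(morlet_tfr(epochs, cfg, picks=picks, average=True), cfg)


def band_interval_summary(
    erd: ERDMap,
    band: tuple[float, float] | str,
    interval: tuple[float, float],
    cfg: TFRConfig | None = None,
) -> np.ndarray:
    """Scalar percent change per channel (or trial x channel).

    Averages first over the band's frequency bins, then over the interval's
    samples; both steps are linear so the order only matters for bookkeeping.
    """
    if isinstance(band, str):
        if cfg is None:
            raise ValueError("cfg required to resolve a named band")
        band = cfg.bands[band]
    fsel = (erd.freqs >= band[0]) & (erd.freqs <= band[1])
    if not np.any(fsel):
        raise ValueError(f"band {band} contains no analysis frequencies")
    tsel = _interval_slice(erd.times, interval)
    return erd.values[..., fsel, :][..., tsel].mean(axis=(-2, -1))


def roi_average(
    per_channel: np.ndarray,
    channels: tuple[str, ...],
    roi: tuple[str, ...] = ROI_CHANNELS,
    mask: np.ndarray | None = None,
) -> tuple[float, list[str]]:
    """Unweighted mean over the available ROI channels.

    ``mask`` flags channels that survived rejection (True = usable). Raises
    if every ROI channel was rejected. Returns the mean and the labels that
    contributed.
    """
    per_channel = np.asarray(per_channel, dtype=float)
    available = []
    for ch in roi:
        if ch not in channels:
            continue
        i = channels.index(ch)
        if mask is not None and not mask[i]:
            continue
        available.append(i)
    if not available:
        raise ValueError("all ROI channels rejected or absent")
    labels = [channels[i] for i in available]
    return float(per_channel[..., available].mean()), labels
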