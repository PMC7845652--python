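"""Ground-truth neural modulation and artifact parameters for simulation.

Default magnitudes are chosen to resemble resting sensorimotor EEG: rolandic
alpha around 10-12 uV RMS over central channels, weaker beta, and a 1/f
broadband background. ERD values encode the intensity-dependent suppression
of the contralateral sensorimotor rhythms during stimulation; habituation
slopes optionally drift the per-trial ERD to emulate dose effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from nmeseeg.montage import EEG_CHANNELS, ROI_CHANNELS
from nmeseeg.synthetic.design import INTENSITIES

BANDS: dict[str, tuple[float, float]] = {"alpha": (7.0, 13.0), "beta": (14.0, 30.0)}


def _default_erd() -> dict[tuple[str, str], float]:
    return {
        ("alpha", "low"): -10.0,
        ("alpha", "medium"): -25.0,
        ("alpha", "high"): -40.0,
        ("beta", "low"): -5.0,
        ("beta", "medium"): -15.0,
        ("beta", "high"): -25.0,
    }


def _zero_slopes() -> dict[tuple[str, str], float]:
    return {(band, lab): 0.0 for band in BANDS for lab in INTENSITIES}


@dataclass
class NeuralGroundTruth:
    """Planted oscillatory effects, per (band, intensity).

    ``roi_erd`` is the percent power change of the band-limited oscillation at
    the ROI channels during stimulation (negative = desynchronization);
    ``habituation_slope`` adds ``slope * trial_index`` percentage points to the
    ERD of the i-th trial of that intensity (acquisition order, 0-based).
    """

    roi_erd: dict[tuple[str, str], float] = field(default_factory=_default_erd)
    habituation_slope: dict[tuple[str, str], float] = field(default_factory=_zero_slopes)
    background_exponent: float = 1.0
    background_amplitude: float = 8.0
    oscillation_amplitudes: dict[str, float] = field(
        default_factory=lambda: {"alpha": 12.0, "beta": 7.0}
    )
    erd_ramp: float = 0.2  # s, smooth envelope transition at interval edges
    roi: tuple[str, ...] = ROI_CHANNELS

    def __post_init__(self) -> None:
        for key, erd in self.roi_erd.items():
            if erd <= -100:
                raise ValueError(f"roi_erd{key} must be > -100 percent")
        for band, amp in self.oscillation_amplitudes.items():
            if amp < 0:
                raise ValueError(f"amplitude for {band} must be >= 0")
        if self.background_amplitude < 0:
            raise ValueError("background_amplitude must be >= 0")

    def erd_for(self, band: str, intensity: str, trial_index: int = 0) -> float:
        base = self.roi_erd.get((band, intensity), 0.0)
        slope = self.habituation_slope.get((band, intensity), 0.0)
        return base + slope * trial_index


def _default_transients() -> dict[str, float]:
    return {"low": 150.0, "medium": 300.0, "high": 600.0}


@dataclass
class ArtifactModel:
    """Stimulation and power-line artifact parameters.

    Each NMES pulse leaves a ~5 ms biphasic transient in the EEG whose
    amplitude grows with stimulation intensity; pulse trains run at 35 Hz
    for the duration of each stimulation interval. Channels listed in
    ``bad_channels`` behave like high-impedance electrodes and pick up an
    excess 50 Hz power-line component.
    """

    pulse_rate: float = 35.0
    pulse_width_us: float = 300.0
    transient_duration_ms: float = 5.0
    transient_amplitude: dict[str, float] = field(default_factory=_default_transients)
    bad_channels: frozenset[str] = frozenset()
    powerline_amplitude: float = 40.0
    baseline_powerline: float = 2.0
    powerline_freq: float = 50.0
    #: EEG channels pick up the transient with a per-channel gain drawn
    #: uniformly from 1 +/- channel_gain_spread (fixed per session).
    channel_gain_spread: float = 0.3
    emg_gain: float = 20.0

    def __post_init__(self) -> None:
        amps = [self.transient_amplitude.get(lab, 0.0) for lab in INTENSITIES]
        if any(a < 0 for a in amps):
            raise ValueError("transient amplitudes must be >= 0")
        if any(a > 0 for a in amps) and not amps[0] <= amps[1] <= amps[2]:
            raise ValueError("transient amplitude must not decrease with intensity")
        unknown = set(self.bad_channels) - set(EEG_CHANNELS)
        if unknown:
            raise ValueError(f"bad_channels not in montage: {sorted(unknown)}")

    @classmethod
    def disabled(cls) -> "ArtifactModel":
        """No stimulation transients, no excess power line."""
        return cls(
            transient_amplitude={lab: 0.0 for lab in INTENSITIES},
            powerline_amplitude=0.0,
            baseline_powerline=0.0,
        )
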