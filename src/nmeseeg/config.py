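"""YAML pipeline configuration with schema validation.

All defaults equal the study's stated parameters (timing, filter settings,
analysis bands and intervals); unknown keys are rejected so typos surface as
validation errors rather than silently ignored settings.
"""

from __future__ import annotations

import os

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator, model_validator

from nmeseeg.artifact_removal import MedianFilterSpec, RejectionConfig
from nmeseeg.spectral import TFRConfig
from nmeseeg.synthetic.design import INTENSITIES, SessionDesign
from nmeseeg.synthetic.ground_truth import ArtifactModel, NeuralGroundTruth

_EPOCH_SPAN = (-4.0, 4.0)


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DesignSection(_Section):
    n_blocks: int = Field(9, ge=1)
    trials_per_block: int = Field(18, ge=1)
    intensity_schedule: list[str] | None = None
    ready_lead: tuple[float, float] = (2.6, 3.0)
    stim_duration: tuple[float, float] = (3.4, 3.8)
    inter_trial: float = Field(3.0, gt=0)
    inter_block: float = Field(150.0, gt=0)
    fs: float = Field(1000.0, gt=0)

    def build(self) -> SessionDesign:
        return SessionDesign(
            n_blocks=self.n_blocks,
            trials_per_block=self.trials_per_block,
            intensity_schedule=tuple(self.intensity_schedule)
            if self.intensity_schedule
            else None,
            ready_lead=self.ready_lead,
            stim_duration=self.stim_duration,
            inter_trial=self.inter_trial,
            inter_block=self.inter_block,
            fs=self.fs,
        )


class GroundTruthSection(_Section):
    roi_erd: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {
            "alpha": {"low": -10.0, "medium": -25.0, "high": -40.0},
            "beta": {"low": -5.0, "medium": -15.0, "high": -25.0},
        }
    )
    habituation_slope: dict[str, dict[str, float]] = Field(default_factory=dict)
    background_exponent: float = 1.0
    background_amplitude: float = Field(8.0, ge=0)
    oscillation_amplitudes: dict[str, float] = Field(
        default_factory=lambda: {"alpha": 12.0, "beta": 7.0}
    )
    erd_ramp: float = Field(0.2, ge=0)

    @field_validator("roi_erd", "habituation_slope")
    @classmethod
    def _known_labels(cls, v: dict) -> dict:
        for band, mapping in v.items():
            unknown = set(mapping) - set(INTENSITIES)
            if unknown:
                raise ValueError(f"unknown intensity labels in {band}: {sorted(unknown)}")
        return v

    def build(self) -> NeuralGroundTruth:
        flat_erd = {
            (band, lab): val
            for band, m in self.roi_erd.items()
            for lab, val in m.items()
        }
        flat_slope = {
            (band, lab): val
            for band, m in self.habituation_slope.items()
            for lab, val in m.items()
        }
        return NeuralGroundTruth(
            roi_erd=flat_erd,
            habituation_slope=flat_slope,
            background_exponent=self.background_exponent,
            background_amplitude=self.background_amplitude,
            oscillation_amplitudes=dict(self.oscillation_amplitudes),
            erd_ramp=self.erd_ramp,
        )


class ArtifactSection(_Section):
    enabled: bool = True
    pulse_rate: float = Field(35.0, gt=0)
    pulse_width_us: float = Field(300.0, gt=0)
    transient_duration_ms: float = Field(5.0, gt=0)
    transient_amplitude: dict[str, float] = Field(
        default_factory=lambda: {"low": 150.0, "medium": 300.0, "high": 600.0}
    )
    bad_channels: list[str] = Field(default_factory=list)
    powerline_amplitude: float = Field(40.0, ge=0)
    baseline_powerline: float = Field(2.0, ge=0)
    powerline_freq: float = Field(50.0, gt=0)
    channel_gain_spread: float = Field(0.3, ge=0)
    emg_gain: float = Field(20.0, ge=0)

    def build(self) -> ArtifactModel:
        if not self.enabled:
            return ArtifactModel.disabled()
        return ArtifactModel(
            pulse_rate=self.pulse_rate,
            pulse_width_us=self.pulse_width_us,
            transient_duration_ms=self.transient_duration_ms,
            transient_amplitude=dict(self.transient_amplitude),
            bad_channels=frozenset(self.bad_channels),
            powerline_amplitude=self.powerline_amplitude,
            baseline_powerline=self.baseline_powerline,
            powerline_freq=self.powerline_freq,
            channel_gain_spread=self.channel_gain_spread,
            emg_gain=self.emg_gain,
        )


class RejectionSection(_Section):
    band: tuple[float, float] = (48.0, 52.0)
    hp_cutoff: float = Field(0.1, gt=0)
    hp_order: int = Field(4, ge=1)
    welch_window_s: float = Field(1.0, gt=0)
    welch_overlap: float = Field(0.5, ge=0, lt=1)
    sd_multiplier: float = Field(4.0, gt=0)
    min_channels: int = Field(4, ge=2)

    def build(self) -> RejectionConfig:
        return RejectionConfig(
            band=self.band,
            hp_cutoff=self.hp_cutoff,
            hp_order=self.hp_order,
            welch_window_s=self.welch_window_s,
            welch_overlap=self.welch_overlap,
            sd_multiplier=self.sd_multiplier,
            min_channels=self.min_channels,
        )


class MedianFilterSection(_Section):
    window_ms: float = Field(10.0, gt=0)
    step: int = 1
    edge_policy: str = "shrink"

    def build(self) -> MedianFilterSpec:
        return MedianFilterSpec(
            window_ms=self.window_ms, step=self.step, edge_policy=self.edge_policy
        )


class TFRSection(_Section):
    f_min: float = Field(1.0, gt=0)
    f_max: float = 45.0
    f_step: float = Field(0.5, gt=0)
    n_cycles: float = Field(7.0, gt=0)
    baseline: tuple[float, float] = (-2.5, -1.5)
    stim_interval: tuple[float, float] = (0.5, 2.5)
    nostim_interval: tuple[float, float] = (-3.0, -1.0)
    bands: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: {"alpha": (7.0, 13.0), "beta": (14.0, 30.0)}
    )
    roi: list[str] = Field(default_factory=lambda: ["C3", "C1", "CP3", "CP1"])

    @model_validator(mode="after")
    def _intervals_inside_epoch(self) -> "TFRSection":
        for name in ("baseline", "stim_interval", "nostim_interval"):
            lo, hi = getattr(self, name)
            if not (_EPOCH_SPAN[0] <= lo < hi <= _EPOCH_SPAN[1]):
                raise ValueError(
                    f"{name} must be an increasing interval inside the "
                    f"{_EPOCH_SPAN} s epoch"
                )
        return self

    def build(self) -> TFRConfig:
        return TFRConfig(
            freqs=np.arange(self.f_min, self.f_max + 1e-9, self.f_step),
            n_cycles=self.n_cycles,
            baseline=self.baseline,
            stim_interval=self.stim_interval,
            nostim_interval=self.nostim_interval,
            bands={k: tuple(v) for k, v in self.bands.items()},
            roi=tuple(self.roi),
        )


class DoseSection(_Section):
    per_block: bool = True
    mad_multiplier: float = Field(5.0, gt=0)


class PipelineConfig(_Section):
    seed: int = 0
    design: DesignSection = Field(default_factory=DesignSection)
    ground_truth: GroundTruthSection = Field(default_factory=GroundTruthSection)
    artifacts: ArtifactSection = Field(default_factory=ArtifactSection)
    rejection: RejectionSection = Field(default_factory=RejectionSection)
    median_filter: MedianFilterSection = Field(default_factory=MedianFilterSection)
    tfr: TFRSection = Field(default_factory=TFRSection)
    dose: DoseSection = Field(default_factory=DoseSection)


def load_config(path: str | os.PathLike | None = None) -> PipelineConfig:
    """Load and validate a YAML config; ``None`` yields the defaults."""
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(payload)


def validate_config(path: str | os.PathLike) -> list[str]:
    """Return a list of constraint violations (empty when the file is valid)."""
    try:
        load_config(path)
    except ValidationError as err:
        return [
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in err.errors()
        ]
    except (OSError, yaml.YAMLError) as err:
        return [str(err)]
    return []
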