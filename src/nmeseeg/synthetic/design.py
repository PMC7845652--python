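"""Stimulation intensities and session timing.

The experiment delivers 35 Hz pulse trains to the wrist extensors at three
current intensities derived from three individually determined thresholds:
the sensory threshold (STh, first tingling), the motor threshold (MTh, first
finger twitch) and the functional threshold (FTh, complete wrist extension):

    low    = (MTh - STh) * 0.33 + STh
    medium = (MTh - STh) * 0.66 + STh
    high   = FTh

A session consists of nine blocks of 18 trials; each block is assigned one
intensity at random (three blocks per intensity). Within a trial a ready cue
precedes the stimulation interval by 2.6-3.0 s, the stimulation lasts
3.4-3.8 s (uniform), and a 3 s inter-trial period follows the offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from nmeseeg.session import Event

INTENSITIES: tuple[str, ...] = ("low", "medium", "high")

#: Silence before the first ready cue and after the last trial, so that
#: -4..+4 s epochs around every stimulation onset fit inside the recording.
START_PAD_S = 2.0
END_PAD_S = 5.0


@dataclass(frozen=True)
class IntensityThresholds:
    """Stimulation-current thresholds in mA: sensory < motor <= functional."""

    sth: float
    mth: float
    fth: float

    def __post_init__(self) -> None:
        if not (0 < self.sth < self.mth <= self.fth):
            raise ValueError(
                "thresholds must satisfy 0 < sth < mth <= fth; "
                f"got sth={self.sth}, mth={self.mth}, fth={self.fth}"
            )


def compute_intensities(thresholds: IntensityThresholds) -> dict[str, float]:
    """Map the three threshold currents to the low/medium/high intensities (mA)."""
    sth, mth, fth = thresholds.sth, thresholds.mth, thresholds.fth
    return {
        "low": (mth - sth) * 0.33 + sth,
        "medium": (mth - sth) * 0.66 + sth,
        "high": fth,
    }


@dataclass
class SessionDesign:
    """Block/trial structure and timing of one recording session."""

    n_blocks: int = 9
    trials_per_block: int = 18
    intensity_schedule: tuple[str, ...] | None = None
    ready_lead: tuple[float, float] = (2.6, 3.0)
    stim_duration: tuple[float, float] = (3.4, 3.8)
    inter_trial: float = 3.0
    #: Breaks between blocks last around 150 s in the experiment; only the
    #: annotation timing matters downstream, so tests may compress this.
    inter_block: float = 150.0
    fs: float = 1000.0

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.trials_per_block < 1:
            raise ValueError("n_blocks and trials_per_block must be >= 1")
        for name in ("ready_lead", "stim_duration"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be an increasing positive range")
        if self.inter_trial <= 0 or self.inter_block <= 0 or self.fs <= 0:
            raise ValueError("durations and sampling rate must be positive")
        if self.intensity_schedule is not None:
            sched = tuple(self.intensity_schedule)
            if len(sched) != self.n_blocks:
                raise ValueError("intensity_schedule length must equal n_blocks")
            unknown = set(sched) - set(INTENSITIES)
            if unknown:
                raise ValueError(f"unknown intensity labels: {sorted(unknown)}")
            counts = {lab: sched.count(lab) for lab in set(sched)}
            if len(set(counts.values())) != 1:
                raise ValueError("each intensity must appear equally often")
            self.intensity_schedule = sched


def _draw_schedule(design: SessionDesign, rng: np.random.Generator) -> tuple[str, ...]:
    if design.intensity_schedule is not None:
        return design.intensity_schedule
    if design.n_blocks % len(INTENSITIES):
        raise ValueError(
            "n_blocks must be a multiple of 3 when no explicit schedule is given"
        )
    sched = np.repeat(INTENSITIES, design.n_blocks // len(INTENSITIES))
    return tuple(rng.permutation(sched))


def build_timeline(
    design: SessionDesign, seed: int | np.random.Generator
) -> list[Event]:
    """Build the annotated event schedule of a session.

    Deterministic given (design, seed). Emits, in temporal order,
    ``block_start/<k>`` per block and ``ready``, ``stim_on/<intensity>``
    (with the stimulation duration attached) and ``stim_off`` per trial.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    schedule = _draw_schedule(design, rng)
    events: list[Event] = []
    t = START_PAD_S
    for b, intensity in enumerate(schedule):
        events.append(Event(round(t, 4), 0.0, f"block_start/{b}"))
        for _ in range(design.trials_per_block):
            events.append(Event(round(t, 4), 0.0, "ready"))
            lead = rng.uniform(*design.ready_lead)
            onset = t + lead
            dur = rng.uniform(*design.stim_duration)
            events.append(Event(round(onset, 4), round(dur, 4), f"stim_on/{intensity}"))
            events.append(Event(round(onset + dur, 4), 0.0, "stim_off"))
            t = onset + dur + design.inter_trial
        if b < len(schedule) - 1:
            t += design.inter_block
    return events


def timeline_duration(events: list[Event]) -> float:
    """Recording length (s) that accommodates the schedule plus end padding."""
    last = max(e.onset + e.duration for e in events)
    return last + END_PAD_S
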