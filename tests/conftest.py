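"""Shared fixtures: small synthetic sessions and epoch constructors."""

from __future__ import annotations

import numpy as np
import pytest

import nmeseeg as nm
from nmeseeg.preprocessing import EpochSet


@pytest.fixture(scope="session")
def tiny_design() -> nm.SessionDesign:
    """One block of six trials with compressed breaks."""
    return nm.SessionDesign(
        n_blocks=1, trials_per_block=6, intensity_schedule=("high",), inter_block=2.0
    )


@pytest.fixture(scope="session")
def tiny_session(tiny_design) -> nm.RawSession:
    """Small full-montage session with default artifacts."""
    return nm.synthesize(tiny_design, seed=42)


@pytest.fixture(scope="session")
def tiny_clean_session(tiny_design) -> nm.RawSession:
    """Same structure, no stimulation artifacts and no excess power line."""
    return nm.synthesize(tiny_design, seed=42, artifact_model=nm.ArtifactModel.disabled())


def make_epochs(
    data: np.ndarray,
    fs: float = 100.0,
    channels: tuple[str, ...] | None = None,
    intensity: str = "high",
    block: np.ndarray | None = None,
) -> EpochSet:
    """Wrap a (trials, channels, times) array into an EpochSet on -4..+4 s."""
    n_tr, n_ch, n_t = data.shape
    if channels is None:
        channels = tuple(f"CH{i}" for i in range(n_ch))
    times = -4.0 + np.arange(n_t) / fs
    return EpochSet(
        data=data,
        times=times,
        fs=fs,
        channels=channels,
        intensity=np.array([intensity] * n_tr),
        block=np.zeros(n_tr, dtype=int) if block is None else block,
        trial_in_block=np.arange(n_tr),
        order=np.arange(n_tr),
        channel_mask=np.ones((n_tr, n_ch), dtype=bool),
    )
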