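"""HDF5 container for epoch sets.

Layout (all datasets at the file root):

* ``data``   float64, (n_trials, n_channels, n_times), uV
* ``times``  float64, (n_times,), s relative to stimulation onset
* ``intensity`` fixed-length bytes, (n_trials,)
* ``block`` / ``trial_in_block`` / ``order`` int64, (n_trials,)
* ``channel_mask`` bool, (n_trials, n_channels)
* ``channels``  fixed-length bytes, (n_channels,)
* attribute ``fs`` (Hz)

The round-trip is bit-exact for the floating-point payload.
"""

from __future__ import annotations

import os

import h5py
import numpy as np

from nmeseeg.preprocessing import EpochSet


def save_epochs(epochs: EpochSet, path: str | os.PathLike) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("times", data=epochs.times)
        f.create_dataset("intensity", data=np.asarray(epochs.intensity, dtype="S16"))
        f.create_dataset("block", data=np.asarray(epochs.block, dtype=np.int64))
        f.create_dataset(
            "trial_in_block", data=np.asarray(epochs.trial_in_block, dtype=np.int64)
        )
        f.create_dataset("order", data=np.asarray(epochs.order, dtype=np.int64))
        f.create_dataset("channel_mask", data=epochs.channel_mask)
        f.create_dataset("channels", data=np.asarray(epochs.channels, dtype="S16"))
        f.attrs["fs"] = epochs.fs


def load_epochs(path: str | os.PathLike) -> EpochSet:
    with h5py.File(path, "r") as f:
        return EpochSet(
            data=f["data"][()],
            times=f["times"][()],
            fs=float(f.attrs["fs"]),
            channels=tuple(c.decode() for c in f["channels"][()]),
            intensity=np.array([c.decode() for c in f["intensity"][()]]),
            block=f["block"][()],
            trial_in_block=f["trial_in_block"][()],
            order=f["order"][()],
            channel_mask=f["channel_mask"][()],
        )
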