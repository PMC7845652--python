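"""EDF+ session round-trip.

Sessions are stored as EDF+C files (16-bit samples, physical unit uV) with
the event schedule in an "EDF Annotations" signal. Writing is implemented
here directly against the EDF+ specification; reading goes through
:func:`mne.io.read_raw_edf` after a structural sanity check of the header,
so the write path can be cross-validated against an independent decoder.
"""

from __future__ import annotations

import math
import os

import numpy as np

from nmeseeg.session import Event, RawSession

_RECORD_S = 1.0


def _a(text: str, width: int) -> bytes:
    """Fixed-width left-justified ASCII header field."""
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"header field too long: {text!r} > {width}")
    return b.ljust(width)


def _fmt_num(v: float, width: int = 8) -> str:
    for p in range(6, -1, -1):
        s = f"{v:.{p}g}"
        if len(s) <= width and "e" not in s and "E" not in s:
            return s
    raise ValueError(f"cannot format {v} in {width} chars")


def _tal(onset: float, duration: float | None, labels: list[str]) -> bytes:
    s = f"+{onset:.4f}".rstrip("0").rstrip(".")
    if s == "+":
        s = "+0"
    if duration is not None and duration > 0:
        s += "\x15" + f"{duration:.4f}".rstrip("0").rstrip(".")
    s += "\x14" + "\x14".join(labels) + "\x14\x00"
    return s.encode("utf-8")


def write_session(session: RawSession, path: str | os.PathLike) -> None:
    """Write a session to an EDF+C file.

    Samples are quantized to 16 bits over a symmetric per-channel physical
    range; the ground-truth object (if any) is not persisted, as EDF carries
    no such metadata.
    """
    fs = session.fs
    spr = int(round(fs * _RECORD_S))
    if not math.isclose(spr, fs * _RECORD_S):
        raise ValueError("sampling rate must yield an integer number of samples per record")
    data = np.vstack([session.eeg, session.emg])
    labels = list(session.channels) + list(session.emg_channels)
    n_sig = len(labels)
    n_samples = data.shape[1]
    n_records = max(1, math.ceil(n_samples / spr))

    # per-record annotation TALs
    record_tals: list[bytes] = []
    for r in range(n_records):
        t0, t1 = r * _RECORD_S, (r + 1) * _RECORD_S
        chunk = _tal(t0, None, [])
        for ev in session.annotations:
            if t0 <= ev.onset < t1:
                chunk += _tal(ev.onset, ev.duration, [ev.label])
        record_tals.append(chunk)
    ann_bytes = max(max(len(c) for c in record_tals) + 2, 60)
    ann_spr = (ann_bytes + 1) // 2  # two bytes per "sample"

    pmins, pmaxs, gains = [], [], []
    for ch in range(n_sig):
        m = float(np.max(np.abs(data[ch]))) if n_samples else 1.0
        m = max(m * 1.0001, 1e-3)
        # round the range up to 4 significant digits so it formats in 8 chars
        exp = math.floor(math.log10(m))
        m = math.ceil(m / 10 ** (exp - 3)) * 10 ** (exp - 3)
        pmins.append(-m)
        pmaxs.append(m)
        gains.append(2 * m / 65535.0)

    header = b"".join(
        [
            _a("0", 8),
            _a("X X X X", 80),
            _a("Startdate 01-JAN-2000 X X X", 80),
            _a("01.01.00", 8),
            _a("00.00.00", 8),
            _a(str(256 * (1 + n_sig + 1)), 8),
            _a("EDF+C", 44),
            _a(str(n_records), 8),
            _a(_fmt_num(_RECORD_S), 8),
            _a(str(n_sig + 1), 4),
        ]
    )
    sig_labels = labels + ["EDF Annotations"]
    fields: list[list[str]] = [
        [f"EEG {l}" if l in session.channels else f"EMG {l}" for l in labels]
        + ["EDF Annotations"],
        [""] * (n_sig + 1),
        ["uV"] * n_sig + [""],
        [_fmt_num(v) for v in pmins] + ["-1"],
        [_fmt_num(v) for v in pmaxs] + ["1"],
        ["-32768"] * (n_sig + 1),
        ["32767"] * (n_sig + 1),
        [""] * (n_sig + 1),
        [str(spr)] * n_sig + [str(ann_spr)],
        [""] * (n_sig + 1),
    ]
    widths = [16, 80, 8, 8, 8, 8, 8, 80, 8, 32]
    sig_header = b"".join(
        b"".join(_a(v, w) for v in col) for col, w in zip(fields, widths)
    )
    del sig_labels

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        for r in range(n_records):
            i0, i1 = r * spr, (r + 1) * spr
            for ch in range(n_sig):
                seg = data[ch, i0:min(i1, n_samples)]
                if seg.size < spr:
                    seg = np.pad(seg, (0, spr - seg.size))
                dig = np.clip(np.round(seg / gains[ch]), -32768, 32767).astype("<i2")
                fh.write(dig.tobytes())
            ann = record_tals[r].ljust(2 * ann_spr, b"\x00")
            fh.write(ann)


def _check_structure(path: str | os.PathLike) -> None:
    size = os.path.getsize(path)
    if size < 256:
        raise ValueError(f"{path}: not an EDF file (header truncated)")
    with open(path, "rb") as fh:
        head = fh.read(256)
        try:
            header_bytes = int(head[184:192].decode("ascii").strip())
            n_records = int(head[236:244].decode("ascii").strip())
            n_sig = int(head[252:256].decode("ascii").strip())
        except (UnicodeDecodeError, ValueError) as err:
            raise ValueError(f"{path}: malformed EDF header") from err
        if size < header_bytes:
            raise ValueError(f"{path}: truncated EDF header")
        fh.seek(256)
        sig_head = fh.read(header_bytes - 256)
        if len(sig_head) != 256 * n_sig:
            raise ValueError(f"{path}: malformed EDF signal header")
        # field blocks: label16, transducer80, dim8, pmin8, pmax8, dmin8,
        # dmax8, prefilter80 -> samples-per-record starts at 216*n_sig
        spr_block = sig_head[216 * n_sig : 216 * n_sig + 8 * n_sig]
        try:
            sprs = [
                int(spr_block[8 * i : 8 * (i + 1)].decode("ascii").strip())
                for i in range(n_sig)
            ]
        except (UnicodeDecodeError, ValueError) as err:
            raise ValueError(f"{path}: malformed EDF signal header") from err
    expected = header_bytes + n_records * 2 * sum(sprs)
    if size != expected:
        raise ValueError(
            f"{path}: truncated or padded EDF file (expected {expected} bytes, found {size})"
        )


def read_session(path: str | os.PathLike) -> RawSession:
    """Read an EDF+ session written by :func:`write_session`."""
    import mne

    _check_structure(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="ERROR")
    names = [n.removeprefix("EEG ").removeprefix("EMG ") for n in raw.ch_names]
    data = raw.get_data(units="uV")
    emg_idx = [i for i, n in enumerate(names) if n.startswith("EMG")]
    eeg_idx = [i for i in range(len(names)) if i not in emg_idx]
    annotations = [
        Event(float(on), float(du), str(de))
        for on, du, de in zip(
            raw.annotations.onset, raw.annotations.duration, raw.annotations.description
        )
    ]
    return RawSession(
        eeg=data[eeg_idx],
        emg=data[emg_idx],
        fs=float(raw.info["sfreq"]),
        annotations=annotations,
        channels=tuple(names[i] for i in eeg_idx),
        emg_channels=tuple(names[i] for i in emg_idx),
    )


def quantization_step(session: RawSession) -> np.ndarray:
    """Per-EEG-channel physical value of one 16-bit digital step (uV)."""
    steps = []
    for ch in range(session.eeg.shape[0]):
        m = float(np.max(np.abs(session.eeg[ch])))
        m = max(m * 1.0001, 1e-3)
        exp = math.floor(math.log10(m))
        m = math.ceil(m / 10 ** (exp - 3)) * 10 ** (exp - 3)
        steps.append(2 * m / 65535.0)
    return np.asarray(steps)
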