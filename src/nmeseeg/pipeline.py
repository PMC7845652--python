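"""End-to-end pipeline: simulate -> clean -> preprocess -> ERD -> dose.

The processing chain per block is: power-line based channel rejection,
sliding median filter, common average reference over the retained channels,
0.1-45 Hz band-pass, epoching around stimulation onsets (-4..+4 s),
downsampling to 100 Hz; trials are then pooled per NMES intensity for the
condition-level ERD maps and the trial-wise dose-effect regressions.
"""

from __future__ import annotations

import hashlib
import json
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from nmeseeg import __version__
from nmeseeg.artifact_removal import (
    ChannelRejectionReport,
    MedianFilterSpec,
    RejectionConfig,
    reject_contaminated_channels,
    sliding_median_filter,
)
from nmeseeg.config import PipelineConfig
from nmeseeg.preprocessing import (
    EpochSet,
    bandpass,
    common_average_reference,
    detect_stim_onsets,
    downsample,
    epoch,
    pool_by_intensity,
)
from nmeseeg.session import RawSession
from nmeseeg.spectral import (
    ERDMap,
    TFRConfig,
    band_interval_summary,
    erd_percent,
    morlet_tfr,
    roi_average,
)
from nmeseeg.dose import blockwise_regressions, single_trial_erd, trial_regression
from nmeseeg.synthetic.generate import synthesize

#: margin (s) added before a block when slicing, so -4 s epochs fit
_EPOCH_MARGIN = 4.5


def block_spans(session: RawSession) -> list[tuple[int, float, float]]:
    """(block index, start s, end s) spans; ends at the next block's start."""
    starts = session.block_starts()
    if not starts:
        return [(0, 0.0, session.duration)]
    spans = []
    for k, ev in enumerate(starts):
        end = starts[k + 1].onset if k + 1 < len(starts) else session.duration
        spans.append((int(ev.label.split("/", 1)[1]), ev.onset, end))
    return spans


@dataclass
class CleanResult:
    """Cleaned continuous session plus per-block rejection bookkeeping."""

    session: RawSession
    retained: dict[int, list[str]] = field(default_factory=dict)
    reports: dict[int, ChannelRejectionReport] = field(default_factory=dict)

    def reports_dict(self) -> dict:
        return {str(k): r.to_dict() for k, r in self.reports.items()}


def clean_session(
    session: RawSession,
    rejection: RejectionConfig = RejectionConfig(),
    median: MedianFilterSpec = MedianFilterSpec(),
    apply_median: bool = True,
) -> CleanResult:
    """Two-step artifact removal, block by block.

    Channel rejection is evaluated on each block's trial segments; the
    sliding median filter is applied to the retained channels over the
    block's span. Rejected channels keep their raw data (they are excluded
    downstream through per-block masks, never silently truncated).
    """
    fs = session.fs
    cleaned = session.eeg.copy()
    result = CleanResult(
        session=RawSession(
            eeg=cleaned,
            emg=session.emg,
            fs=fs,
            annotations=session.annotations,
            channels=session.channels,
            emg_channels=session.emg_channels,
            ground_truth=session.ground_truth,
        )
    )
    for b, t0, t1 in block_spans(session):
        i0, i1 = int(round(t0 * fs)), int(round(t1 * fs))
        block_events = [e for e in session.stim_onsets() if t0 <= e.onset < t1]
        m0 = max(int(round((t0 - _EPOCH_MARGIN) * fs)), 0)
        segments = [
            (e.onset - 4.0 - m0 / fs, e.onset + 4.0 - m0 / fs) for e in block_events
        ] or None
        retained, report = reject_contaminated_channels(
            session.eeg[:, m0:i1], fs, session.channels, rejection, segments
        )
        result.retained[b] = retained
        result.reports[b] = report
        if apply_median:
            idx = [session.channel_index(ch) for ch in retained]
            cleaned[idx, i0:i1] = sliding_median_filter(
                session.eeg[idx, i0:i1], fs, median
            )
    return result


def preprocess_session(
    clean: CleanResult,
    tfr: TFRConfig = TFRConfig(),
    mad_multiplier: float = 5.0,
    target_fs: float = 100.0,
) -> EpochSet:
    """Reference, filter, epoch and downsample a cleaned session.

    Returns a single epoch set covering all blocks in acquisition order with
    per-trial channel masks; pool with
    :func:`nmeseeg.preprocessing.pool_by_intensity`.
    """
    session = clean.session
    fs = session.fs
    all_onsets = detect_stim_onsets(
        session.emg, fs, session.annotations, mad_multiplier=mad_multiplier
    )
    stim_events = session.stim_onsets()
    per_block: list[EpochSet] = []
    order0 = 0
    for b, t0, t1 in block_spans(session):
        sel = [k for k, e in enumerate(stim_events) if t0 <= e.onset < t1]
        if not sel:
            continue
        m0 = max(int(round((t0 - _EPOCH_MARGIN) * fs)), 0)
        i1 = int(round(t1 * fs))
        retained = clean.retained.get(b, list(session.channels))
        idx = [session.channel_index(ch) for ch in retained]
        x = bandpass(common_average_reference(session.eeg[idx, m0:i1]), fs)
        full = np.zeros((len(session.channels), x.shape[1]))
        full[idx] = x
        mask = np.zeros(len(session.channels), dtype=bool)
        mask[idx] = True
        labels = [stim_events[k].label.split("/", 1)[1] for k in sel]
        onsets_local = all_onsets[sel] - m0 / fs
        eps = epoch(
            full,
            fs,
            onsets_local,
            labels,
            session.channels,
            block=np.full(len(sel), b),
            trial_in_block=np.arange(len(sel)),
            order=np.arange(order0, order0 + len(sel)),
            channel_mask=mask,
        )
        order0 += len(sel)
        per_block.append(downsample(eps, target_fs))
    if not per_block:
        raise ValueError("session contains no stimulation events")
    merged = per_block[0]
    for eps in per_block[1:]:
        merged = EpochSet(
            data=np.concatenate([merged.data, eps.data]),
            times=merged.times,
            fs=merged.fs,
            channels=merged.channels,
            intensity=np.concatenate([merged.intensity, eps.intensity]),
            block=np.concatenate([merged.block, eps.block]),
            trial_in_block=np.concatenate([merged.trial_in_block, eps.trial_in_block]),
            order=np.concatenate([merged.order, eps.order]),
            channel_mask=np.concatenate([merged.channel_mask, eps.channel_mask]),
        )
    return merged


def masked_condition_erd(
    epochs: EpochSet, cfg: TFRConfig, picks: tuple[str, ...] | None = None
) -> ERDMap:
    """Condition-averaged ERD map honoring per-trial channel masks.

    Trials are grouped by identical mask patterns; each channel's power is
    averaged over the trials where that channel survived rejection, then
    normalized to percent change. Channels rejected in every block are NaN.
    """
    picks = epochs.channels if picks is None else picks
    idx = [epochs.channel_index(ch) for ch in picks]
    masks = epochs.channel_mask[:, idx]
    patterns = {}
    for t in range(epochs.n_trials):
        patterns.setdefault(masks[t].tobytes(), []).append(t)
    num = None
    cnt = np.zeros(len(idx))
    freqs = cfg.freqs
    for key, trials in patterns.items():
        sub = epochs.select_trials(np.asarray(trials))
        tfr = morlet_tfr(sub, cfg, picks=picks, average=True)
        m = masks[trials[0]].astype(float)
        contrib = tfr.power * m[:, None, None] * len(trials)
        num = contrib if num is None else num + contrib
        cnt += m * len(trials)
        times, edge_valid = tfr.times, tfr.edge_valid
    with np.errstate(invalid="ignore", divide="ignore"):
        power = num / cnt[:, None, None]
    from nmeseeg.spectral import TFR

    tfr_avg = TFR(
        power=power,
        freqs=freqs,
        times=times,
        channels=tuple(picks),
        edge_valid=edge_valid,
    )
    return erd_percent(tfr_avg, cfg)


def erd_summary_table(
    pooled: dict[str, EpochSet], cfg: TFRConfig
) -> tuple[pd.DataFrame, dict[str, ERDMap]]:
    """Per-condition, per-band, per-interval scalar summaries.

    One row per intensity x band x interval x channel, plus ``ROI`` rows with
    the unweighted mean over the available sensorimotor ROI channels.
    """
    rows = []
    maps: dict[str, ERDMap] = {}
    intervals = {"stim": cfg.stim_interval, "nostim": cfg.nostim_interval}
    for intensity, eps in pooled.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            erd = masked_condition_erd(eps, cfg)
        maps[intensity] = erd
        for band in cfg.bands:
            for iname, interval in intervals.items():
                vals = band_interval_summary(erd, band, interval, cfg)
                for ch, v in zip(erd.channels, vals):
                    rows.append(
                        dict(
                            intensity=intensity,
                            band=band,
                            interval=iname,
                            channel=ch,
                            erd_percent=v,
                        )
                    )
                finite = np.isfinite(vals)
                roi_val, roi_chs = roi_average(
                    np.where(finite, vals, 0.0), erd.channels, cfg.roi, mask=finite
                )
                rows.append(
                    dict(
                        intensity=intensity,
                        band=band,
                        interval=iname,
                        channel="ROI(" + "+".join(roi_chs) + ")",
                        erd_percent=roi_val,
                    )
                )
    return pd.DataFrame(rows), maps


def dose_table(
    pooled: dict[str, EpochSet], cfg: TFRConfig, per_block: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Session- and block-wise regressions for every band x intensity.

    Returns (regressions, trials): the regression table has one row per
    scope (``session``, ``block k`` and ``reset k->k+1``); the trial table
    holds the underlying single-trial ERD series.
    """
    reg_rows, trial_rows = [], []
    for intensity, eps in pooled.items():
        for band in cfg.bands:
            series = single_trial_erd(eps, cfg, band)
            order = np.argsort(eps.order, kind="stable")
            blocks = eps.block[order]
            for i, v in enumerate(series):
                trial_rows.append(
                    dict(band=band, intensity=intensity, trial=i + 1,
                         block=int(blocks[i]), erd_percent=float(v))
                )
            results = [trial_regression(series, band, intensity)]
            resets = np.array([])
            if per_block:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    block_res, resets = blockwise_regressions(
                        series, blocks, band, intensity
                    )
                results.extend(block_res)
            for r in results:
                reg_rows.append(
                    dict(
                        band=r.band,
                        intensity=r.intensity,
                        scope=r.scope,
                        n=r.n,
                        slope=r.slope,
                        intercept=r.intercept,
                        pearson_r=r.pearson_r if r.r_defined else np.nan,
                        p_value=r.p_value if r.r_defined else np.nan,
                        significant=bool(r.significant),
                        reset_diff=np.nan,
                    )
                )
            uniq = list(dict.fromkeys(blocks.tolist()))
            for k, d in enumerate(resets):
                reg_rows.append(
                    dict(
                        band=band,
                        intensity=intensity,
                        scope=f"reset {uniq[k]}->{uniq[k + 1]}",
                        n=2,
                        slope=np.nan,
                        intercept=np.nan,
                        pearson_r=np.nan,
                        p_value=np.nan,
                        significant=False,
                        reset_diff=float(d),
                    )
                )
    return pd.DataFrame(reg_rows), pd.DataFrame(trial_rows)


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def run_all(
    config: PipelineConfig,
    outdir: str | os.PathLike,
    session: RawSession | None = None,
) -> dict:
    """Run the full pipeline and write the result bundle.

    When ``session`` is None a synthetic session is generated from the
    config. Writes ``session.edf``, ``cleaned.edf``, ``rejection.json``,
    ``epochs.h5``, ``erd_summaries.csv``, ``dose.csv``, ``dose_trials.csv``
    and ``manifest.json`` into ``outdir`` and returns the manifest.
    """
    from nmeseeg.io import save_epochs, write_session

    os.makedirs(outdir, exist_ok=True)
    outdir = os.fspath(outdir)
    simulated = session is None
    if simulated:
        session = synthesize(
            config.design.build(),
            config.ground_truth.build(),
            config.artifacts.build(),
            seed=config.seed,
        )
        write_session(session, os.path.join(outdir, "session.edf"))

    clean = clean_session(
        session, config.rejection.build(), config.median_filter.build()
    )
    write_session(clean.session, os.path.join(outdir, "cleaned.edf"))
    with open(os.path.join(outdir, "rejection.json"), "w") as fh:
        json.dump(clean.reports_dict(), fh, indent=2, sort_keys=True)

    cfg = config.tfr.build()
    epochs = preprocess_session(clean, cfg, config.dose.mad_multiplier)
    save_epochs(epochs, os.path.join(outdir, "epochs.h5"))
    pooled = pool_by_intensity([epochs])

    summaries, _maps = erd_summary_table(pooled, cfg)
    summaries.to_csv(os.path.join(outdir, "erd_summaries.csv"), index=False, float_format="%.6f")
    regressions, trials = dose_table(pooled, cfg, config.dose.per_block)
    regressions.to_csv(os.path.join(outdir, "dose.csv"), index=False, float_format="%.6g")
    trials.to_csv(os.path.join(outdir, "dose_trials.csv"), index=False, float_format="%.6f")

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_sha256": _config_hash(config),
        "simulated": simulated,
        "counts": {
            "blocks": len(clean.retained),
            "trials_per_intensity": {
                k: int(v.n_trials) for k, v in sorted(pooled.items())
            },
            "rejected_channels_per_block": {
                str(b): r.all_rejected() for b, r in sorted(clean.reports.items())
            },
        },
        "outputs": sorted(
            f for f in os.listdir(outdir) if not f.startswith("manifest")
        ),
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
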