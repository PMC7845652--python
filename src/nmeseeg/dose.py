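"""Dose-effect analysis: trial-wise ERD series and regressions over trials.

For each band and NMES intensity the single-trial ERD is the band power of
that trial during the stimulation interval, normalized by the grand-average
baseline power of all the intensity's trials (the percent-change definition
with a shared baseline). Ordinary least squares of ERD on the trial sequence
(1..N) plus Pearson's correlation quantify cumulative (dose) effects;
block-wise regressions and a between-block reset statistic describe the
within-block dynamics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from nmeseeg.preprocessing import EpochSet
from nmeseeg.spectral import TFRConfig, morlet_tfr, _interval_slice

ALPHA_LEVEL = 0.05


@dataclass
class DoseRegressionResult:
    """OLS fit of an ERD series on the trial sequence 1..N."""

    band: str
    intensity: str
    erd_series: np.ndarray
    slope: float
    intercept: float
    pearson_r: float | None
    p_value: float | None
    n: int
    scope: str = "session"
    r_defined: bool = True

    @property
    def significant(self) -> bool:
        return self.r_defined and self.p_value is not None and self.p_value < ALPHA_LEVEL


def single_trial_erd(
    epochs: EpochSet,
    cfg: TFRConfig = TFRConfig(),
    band: str = "alpha",
    roi: tuple[str, ...] | None = None,
) -> np.ndarray:
    """Per-trial percent band-power change, acquisition order.

    ``epochs`` should contain the pooled trials of one intensity. Power is
    averaged over the band's frequency bins, the ROI channels available per
    trial, and the stimulation interval; the baseline is the grand average of
    the baseline-interval power over all trials of the intensity.
    """
    if epochs.n_trials < 2:
        raise ValueError("need at least two trials for a single-trial series")
    roi = cfg.roi if roi is None else roi
    picks = tuple(ch for ch in roi if ch in epochs.channels)
    if not picks:
        raise ValueError("no ROI channel present in the epoch set")
    tfr = morlet_tfr(epochs, cfg, picks=picks, freqs=cfg.band_freq_grid(band))
    stim_sel = _interval_slice(tfr.times, cfg.stim_interval)
    base_sel = _interval_slice(tfr.times, cfg.baseline)
    # (trials, channels): band- and interval-averaged power
    p_stim = tfr.power[..., stim_sel].mean(axis=(-2, -1))
    p_base = tfr.power[..., base_sel].mean(axis=(-2, -1))
    mask = np.stack(
        [epochs.channel_mask[:, epochs.channel_index(ch)] for ch in picks], axis=1
    )
    if np.any(~mask.any(axis=1)):
        raise ValueError("some trials have every ROI channel rejected")
    w = mask.astype(float)
    stim_by_trial = (p_stim * w).sum(axis=1) / w.sum(axis=1)
    base_by_trial = (p_base * w).sum(axis=1) / w.sum(axis=1)
    grand_baseline = base_by_trial.mean()
    if grand_baseline <= 0:
        raise ValueError("zero grand-average baseline power")
    series = (stim_by_trial - grand_baseline) / grand_baseline * 100.0
    order = np.argsort(epochs.order, kind="stable")
    return series[order]


def trial_regression(
    erd_series: np.ndarray,
    band: str = "",
    intensity: str = "",
    scope: str = "session",
) -> DoseRegressionResult:
    """OLS of ERD on the trial index 1..N with Pearson r and two-sided p.

    A zero-variance series has an undefined correlation; it is reported
    explicitly (``r_defined=False``) rather than as a silent NaN.
    """
    y = np.asarray(erd_series, dtype=float)
    if y.size < 3:
        raise ValueError("need at least three trials for a regression")
    if not np.all(np.isfinite(y)):
        raise ValueError("ERD series contains non-finite values")
    x = np.arange(1, y.size + 1, dtype=float)
    if np.ptp(y) == 0:
        return DoseRegressionResult(
            band=band,
            intensity=intensity,
            erd_series=y,
            slope=0.0,
            intercept=float(y[0]),
            pearson_r=None,
            p_value=None,
            n=y.size,
            scope=scope,
            r_defined=False,
        )
    fit = stats.linregress(x, y)
    return DoseRegressionResult(
        band=band,
        intensity=intensity,
        erd_series=y,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        pearson_r=float(fit.rvalue),
        p_value=float(fit.pvalue),
        n=y.size,
        scope=scope,
    )


def blockwise_regressions(
    erd_series: np.ndarray,
    block: np.ndarray,
    band: str = "",
    intensity: str = "",
) -> tuple[list[DoseRegressionResult], np.ndarray]:
    """One regression per block plus between-block reset differences.

    ``block`` gives each trial's block index (acquisition order must match
    the series). The reset statistic for consecutive blocks k, k+1 is
    ``ERD(first trial of k+1) - ERD(last trial of k)``, capturing whether the
    within-block trend re-starts after the break. Blocks with fewer than
    three trials are skipped with a warning.
    """
    y = np.asarray(erd_series, dtype=float)
    block = np.asarray(block)
    if y.shape != block.shape:
        raise ValueError("series and block labels must align")
    labels = list(dict.fromkeys(block.tolist()))
    results = []
    for b in labels:
        sub = y[block == b]
        if sub.size < 3:
            warnings.warn(f"block {b} has {sub.size} trials; skipping regression", RuntimeWarning)
            continue
        results.append(trial_regression(sub, band=band, intensity=intensity, scope=f"block {b}"))
    resets = np.array(
        [
            y[block == labels[k + 1]][0] - y[block == labels[k]][-1]
            for k in range(len(labels) - 1)
        ]
    )
    return results, resets
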