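"""Morlet ERD/ERS quantification against analytically constructed epochs."""

import numpy as np
import pytest

from conftest import make_epochs
from nmeseeg.spectral import (
    ERDMap,
    TFRConfig,
    band_interval_summary,
    condition_erd_map,
    erd_percent,
    morlet_tfr,
    roi_average,
)


def modulated_epochs(n_trials=4, f=10.0, drop=0.40, fs=100.0, channels=("C3", "C1")):
    """Sinusoid whose amplitude falls by ``drop`` in power during 0..3 s.

    A power drop of ``drop`` is an amplitude factor sqrt(1 - drop); with the
    percent-change definition the planted ERD is exactly -100 * drop.
    """
    t = -4.0 + np.arange(int(8 * fs)) / fs
    amp = np.where((t >= 0.0) & (t < 3.0), np.sqrt(1.0 - drop), 1.0)
    x = amp * np.sin(2 * np.pi * f * t)
    data = np.tile(x, (n_trials, len(channels), 1))
    return make_epochs(data, fs=fs, channels=channels)


class TestMorletTfr:
    def test_power_concentrates_at_the_oscillation_frequency(self):
        es = modulated_epochs(drop=0.0)
        tfr = morlet_tfr(es, TFRConfig(), average=True)
        prof = tfr.power[0].mean(axis=-1)  # channel 0, per-frequency
        assert tfr.freqs[np.argmax(prof)] == pytest.approx(10.0, abs=0.5)
        assert prof[np.argmax(prof)] > 10 * prof[tfr.freqs == 30.0][0]

    def test_trial_axis_shape_and_average(self):
        es = modulated_epochs(n_trials=3)
        sub = np.arange(8.0, 12.5, 0.5)
        per_trial = morlet_tfr(es, TFRConfig(), freqs=sub)
        avg = morlet_tfr(es, TFRConfig(), freqs=sub, average=True)
        assert per_trial.power.shape == (3, 2, 9, 800)
        assert avg.power.shape == (2, 9, 800)
        np.testing.assert_allclose(per_trial.power.mean(axis=0), avg.power, rtol=1e-6)

    def test_edge_validity_mask(self):
        es = modulated_epochs()
        tfr = morlet_tfr(es, TFRConfig(), average=True)
        i2hz = int(np.flatnonzero(tfr.freqs == 2.0)[0])
        # 7 cycles at 2 Hz: half-width 1.75 s of the 8 s epoch is edge-affected
        assert not tfr.edge_valid[i2hz, 0]
        assert tfr.edge_valid[i2hz, 400]  # t = 0

    def test_picks_restrict_channels(self):
        es = modulated_epochs()
        tfr = morlet_tfr(es, TFRConfig(), picks=("C1",), average=True)
        assert tfr.channels == ("C1",)
        assert tfr.power.shape[0] == 1


class TestErdPercent:
    def test_planted_erd_recovered(self):
        es = modulated_epochs(drop=0.40)
        erd = condition_erd_map(es, TFRConfig())
        got = band_interval_summary(erd, "alpha", (0.5, 2.5), TFRConfig())
        assert got == pytest.approx([-40.0, -40.0], abs=2.0)

    def test_baseline_interval_self_consistency(self):
        es = modulated_epochs(drop=0.40)
        erd = condition_erd_map(es, TFRConfig())
        got = band_interval_summary(erd, "alpha", (-2.5, -1.5), TFRConfig())
        assert got == pytest.approx([0.0, 0.0], abs=0.5)

    def test_ers_positive_for_power_increase(self):
        es = modulated_epochs(drop=-0.50)  # 50% power increase
        erd = condition_erd_map(es, TFRConfig())
        got = band_interval_summary(erd, "alpha", (0.5, 2.5), TFRConfig())
        assert got == pytest.approx([50.0, 50.0], abs=2.5)

    def test_zero_baseline_raises(self):
        es = make_epochs(np.zeros((2, 2, 800)))
        tfr = morlet_tfr(es, TFRConfig(), freqs=np.arange(8.0, 12.5, 0.5))
        with pytest.raises(ValueError):
            erd_percent(tfr, TFRConfig())

    def test_baseline_overlapping_edges_warns(self):
        es = modulated_epochs()
        cfg = TFRConfig(baseline=(-4.0, -3.0))
        tfr = morlet_tfr(es, cfg, average=True)
        with pytest.warns(RuntimeWarning, match="edge"):
            erd_percent(tfr, cfg)


class TestBandIntervalAndRoi:
    def _erd(self):
        values = np.zeros((2, 5, 10))
        values[0, 1:4, :] = -30.0  # channel 0, middle frequencies
        return ERDMap(
            values=values,
            freqs=np.array([8.0, 9.0, 10.0, 11.0, 12.0]),
            times=np.linspace(0, 1, 10),
            channels=("C3", "C1"),
            edge_valid=np.ones((5, 10), dtype=bool),
        )

    def test_band_tuple_selection(self):
        got = band_interval_summary(self._erd(), (9.0, 11.0), (0.0, 1.0))
        np.testing.assert_allclose(got, [-30.0, 0.0])

    def test_named_band_requires_cfg(self):
        with pytest.raises(ValueError):
            band_interval_summary(self._erd(), "alpha", (0.0, 1.0))
        with pytest.raises(ValueError):
            band_interval_summary(self._erd(), (50.0, 60.0), (0.0, 1.0))

    def test_roi_average_masking(self):
        vals = np.array([-40.0, -20.0, 99.0])
        channels = ("C3", "C1", "Fz")
        mean, labels = roi_average(vals, channels)
        assert mean == pytest.approx(-30.0)
        assert labels == ["C3", "C1"]
        mean, labels = roi_average(vals, channels, mask=np.array([True, False, True]))
        assert mean == pytest.approx(-40.0)
        assert labels == ["C3"]
        with pytest.raises(ValueError):
            roi_average(vals, channels, mask=np.array([False, False, True]))


class TestTFRConfigValidation:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            TFRConfig(freqs=np.array([]))
        with pytest.raises(ValueError):
            TFRConfig(freqs=np.array([10.0, 5.0]))
        with pytest.raises(ValueError):
            TFRConfig(n_cycles=0)
        with pytest.raises(ValueError):
            TFRConfig(baseline=(-1.0, -2.0))
        with pytest.raises(ValueError):
            TFRConfig(bands={"gamma": (50.0, 90.0)})

    def test_band_freq_grid(self):
        cfg = TFRConfig()
        grid = cfg.band_freq_grid("alpha")
        assert grid[0] == 7.0 and grid[-1] == 13.0
        assert np.all(np.diff(grid) == 0.5)
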