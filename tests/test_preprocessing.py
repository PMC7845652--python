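"""Referencing, band-pass, onset alignment, epoching and pooling."""

import numpy as np
import pytest
from scipy import signal

from conftest import make_epochs
from nmeseeg.preprocessing import (
    bandpass,
    common_average_reference,
    detect_stim_onsets,
    downsample,
    epoch,
    pool_by_intensity,
)
from nmeseeg.session import Event


class TestCommonAverageReference:
    def test_columns_sum_to_zero_and_differences_preserved(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(8, 500))
        y = common_average_reference(x)
        np.testing.assert_allclose(y.sum(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(y[2] - y[5], x[2] - x[5], atol=1e-12)

    def test_needs_two_channels(self):
        with pytest.raises(ValueError):
            common_average_reference(np.zeros((1, 100)))


class TestBandpass:
    def test_magnitude_response_matches_filter_design(self):
        # Oracle: squared magnitude of the designed Butterworth (the
        # forward-backward pass squares |H|), evaluated via sosfreqz and
        # compared with the measured amplitude of long filtered sinusoids.
        fs = 1000.0
        sos = signal.butter(1, (0.1, 45.0), btype="bandpass", fs=fs, output="sos")
        t = np.arange(int(60 * fs)) / fs
        for f in (0.1, 1.0, 10.0, 45.0, 80.0):
            _, h = signal.sosfreqz(sos, worN=[f], fs=fs)
            expected = np.abs(h[0]) ** 2
            y = bandpass(np.sin(2 * np.pi * f * t), fs)
            measured = np.max(np.abs(y[int(20 * fs) : int(40 * fs)]))
            assert measured == pytest.approx(expected, rel=0.02)

    def test_zero_phase_keeps_peak_position(self):
        fs = 1000.0
        t = np.arange(int(10 * fs)) / fs
        x = np.exp(-((t - 5.0) ** 2) / (2 * 0.2**2))
        y = bandpass(x, fs)
        assert abs(np.argmax(y) - np.argmax(x)) <= 2

    def test_invalid_cutoffs(self):
        with pytest.raises(ValueError):
            bandpass(np.zeros(1000), 1000.0, low=45.0, high=0.1)
        with pytest.raises(ValueError):
            bandpass(np.zeros(1000), 80.0, low=0.1, high=45.0)


class TestDetectStimOnsets:
    def _annots(self, onsets):
        return [Event(o, 3.5, "stim_on/high") for o in onsets]

    def test_emg_burst_refines_annotated_onset(self):
        fs = 1000.0
        true = [10.2, 20.35, 30.0]
        annotated = [10.0, 20.0, 30.3]
        emg = np.zeros((2, int(40 * fs)))
        rng = np.random.default_rng(0)
        emg += rng.normal(scale=0.5, size=emg.shape)
        for o in true:
            i = int(o * fs)
            emg[:, i : i + 3500] += 50.0 * np.sign(
                np.sin(2 * np.pi * 35.0 * np.arange(3500) / fs) + 0.5
            )
        got = detect_stim_onsets(emg, fs, self._annots(annotated))
        np.testing.assert_allclose(got, true, atol=0.02)

    def test_flat_emg_falls_back_to_annotations(self):
        emg = np.zeros((2, 40_000))
        got = detect_stim_onsets(emg, 1000.0, self._annots([10.0, 20.0]))
        np.testing.assert_array_equal(got, [10.0, 20.0])

    def test_no_annotations_raises(self):
        with pytest.raises(ValueError):
            detect_stim_onsets(np.zeros((2, 1000)), 1000.0, [Event(0.5, 0, "ready")])


class TestEpochAndDownsample:
    def test_window_is_left_closed(self):
        fs = 100.0
        eeg = np.arange(3000, dtype=float)[None, :]
        es = epoch(eeg, fs, np.array([15.0]), ["high"], ("C3",))
        assert es.data.shape == (1, 1, 800)
        assert es.times[0] == -4.0
        assert es.times[-1] == pytest.approx(4.0 - 1 / fs)
        # sample at t: eeg[(15 + t) * fs]
        assert es.data[0, 0, 0] == (15.0 - 4.0) * fs

    def test_out_of_bounds_trials_dropped_with_warning(self):
        eeg = np.zeros((1, 2000))
        with pytest.warns(RuntimeWarning):
            es = epoch(eeg, 100.0, np.array([1.0, 10.0, 19.0]), ["a", "b", "c"], ("C3",))
        assert es.n_trials == 1
        assert list(es.intensity) == ["b"]
        with pytest.raises(ValueError), pytest.warns(RuntimeWarning):
            epoch(eeg, 100.0, np.array([1.0]), ["a"], ("C3",))

    def test_downsample_decimates_by_integer_factor(self):
        es = make_epochs(np.random.default_rng(1).normal(size=(2, 3, 8000)), fs=1000.0)
        out = downsample(es, 100.0)
        assert out.data.shape == (2, 3, 800)
        assert out.fs == 100.0
        np.testing.assert_array_equal(out.data, es.data[:, :, ::10])
        with pytest.raises(ValueError):
            downsample(es, 300.0)


class TestPoolByIntensity:
    def test_acquisition_order_restored(self):
        rng = np.random.default_rng(2)
        a = make_epochs(rng.normal(size=(3, 2, 100)), intensity="high")
        a.order = np.array([6, 7, 8])
        a.block = np.full(3, 2)
        b = make_epochs(rng.normal(size=(3, 2, 100)), intensity="high")
        b.order = np.array([0, 1, 2])
        pooled = pool_by_intensity([a, b])
        high = pooled["high"]
        np.testing.assert_array_equal(high.order, [0, 1, 2, 6, 7, 8])
        np.testing.assert_array_equal(high.data[:3], b.data)
        np.testing.assert_array_equal(high.data[3:], a.data)

    def test_missing_intensity_yields_empty_set_with_warning(self):
        a = make_epochs(np.zeros((2, 2, 100)), intensity="low")
        with pytest.warns(RuntimeWarning):
            pooled = pool_by_intensity([a], labels=("low", "medium"))
        assert pooled["medium"].n_trials == 0
        assert pooled["low"].n_trials == 2

    def test_inconsistent_montage_rejected(self):
        a = make_epochs(np.zeros((1, 2, 100)))
        b = make_epochs(np.zeros((1, 3, 100)))
        with pytest.raises(ValueError):
            pool_by_intensity([a, b])
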