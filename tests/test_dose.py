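"""Single-trial ERD series and dose-effect regressions."""

import numpy as np
import pytest

from conftest import make_epochs
from nmeseeg.dose import (
    blockwise_regressions,
    single_trial_erd,
    trial_regression,
)
from nmeseeg.spectral import TFRConfig


def trending_epochs(stim_power, fs=100.0, channels=("C3", "C1")):
    """One 10 Hz trial per entry: baseline power 1, stim-interval power as given."""
    t = -4.0 + np.arange(int(8 * fs)) / fs
    trials = []
    for p in stim_power:
        amp = np.where((t >= 0.0) & (t < 3.0), np.sqrt(p), 1.0)
        trials.append(np.tile(amp * np.sin(2 * np.pi * 10.0 * t), (len(channels), 1)))
    return make_epochs(np.stack(trials), fs=fs, channels=channels)


class TestSingleTrialErd:
    def test_planted_series_recovered(self):
        es = trending_epochs([0.6, 0.7, 0.8, 0.9])
        got = single_trial_erd(es, TFRConfig(), band="alpha")
        # grand baseline power is 1 for every trial, so ERD_i = 100 (p_i - 1)
        np.testing.assert_allclose(got, [-40.0, -30.0, -20.0, -10.0], atol=2.5)

    def test_series_follows_acquisition_order(self):
        es = trending_epochs([0.6, 0.9])
        es.order = np.array([1, 0])  # second stored trial was acquired first
        got = single_trial_erd(es, TFRConfig(), band="alpha")
        assert got[0] == pytest.approx(-10.0, abs=2.5)
        assert got[1] == pytest.approx(-40.0, abs=2.5)

    def test_mask_drops_rejected_channel_from_roi(self):
        es = trending_epochs([0.6, 0.9], channels=("C3", "C1"))
        es.data[0, 1, :] = 0.0  # rejected channels are zero-filled
        es.channel_mask[0, 1] = False
        got = single_trial_erd(es, TFRConfig(), band="alpha")
        assert got[0] == pytest.approx(-40.0, abs=3.0)  # C3 alone, not diluted

    def test_all_roi_rejected_raises(self):
        es = trending_epochs([0.6, 0.9])
        es.channel_mask[0, :] = False
        with pytest.raises(ValueError):
            single_trial_erd(es, TFRConfig(), band="alpha")

    def test_needs_roi_and_two_trials(self):
        es = trending_epochs([0.6, 0.9], channels=("Fz", "Pz"))
        with pytest.raises(ValueError):
            single_trial_erd(es, TFRConfig(), band="alpha")
        with pytest.raises(ValueError):
            single_trial_erd(trending_epochs([0.6]), TFRConfig())


class TestTrialRegression:
    def test_matches_polyfit_and_corrcoef(self):
        rng = np.random.default_rng(0)
        y = -30.0 + 0.8 * np.arange(1, 25) + rng.normal(scale=2.0, size=24)
        res = trial_regression(y, band="alpha", intensity="high")
        slope, intercept = np.polyfit(np.arange(1, 25), y, 1)
        r = np.corrcoef(np.arange(1, 25), y)[0, 1]
        assert res.slope == pytest.approx(slope)
        assert res.intercept == pytest.approx(intercept)
        assert res.pearson_r == pytest.approx(r)
        assert res.n == 24
        assert res.significant

    def test_flat_series_has_undefined_r(self):
        res = trial_regression(np.full(10, -20.0))
        assert not res.r_defined
        assert res.slope == 0.0
        assert res.pearson_r is None and res.p_value is None
        assert not res.significant

    def test_noise_only_series_not_significant(self):
        rng = np.random.default_rng(1)
        res = trial_regression(rng.normal(size=30))
        assert res.p_value > 0.05  # seed chosen before running, plain null draw

    def test_input_validation(self):
        with pytest.raises(ValueError):
            trial_regression(np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            trial_regression(np.array([1.0, np.nan, 2.0]))


class TestBlockwiseRegressions:
    def test_blocks_and_resets(self):
        # two blocks, each trending down by 2 within the block, reset between
        y = np.array([-10.0, -12.0, -14.0, -16.0, -9.0, -11.0, -13.0, -15.0])
        block = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        results, resets = blockwise_regressions(y, block, band="alpha", intensity="high")
        assert len(results) == 2
        for res in results:
            assert res.slope == pytest.approx(-2.0)
        assert resets == pytest.approx([7.0])  # -9 - (-16)

    def test_short_block_skipped_with_warning(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        block = np.array([0, 0, 0, 1, 1])
        with pytest.warns(RuntimeWarning):
            results, resets = blockwise_regressions(y, block)
        assert len(results) == 1
        assert resets == pytest.approx([1.0])

    def test_misaligned_inputs_rejected(self):
        with pytest.raises(ValueError):
            blockwise_regressions(np.zeros(4), np.zeros(5))
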