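"""Ground-truth properties of the synthetic session generator."""

import numpy as np
import pytest
from scipy import signal

import nmeseeg as nm
from nmeseeg.artifact_removal import RejectionConfig, band_power_welch
from nmeseeg.synthetic.ground_truth import BANDS


def _interval_band_power(x, fs, intervals, band):
    """Mean Welch band power pooled over the given (start, stop) intervals."""
    chunks = [
        x[int(s * fs) : int(e * fs)] for s, e in intervals if int(e * fs) <= x.size
    ]
    seg = np.concatenate(chunks)
    f, psd = signal.welch(seg, fs=fs, nperseg=min(2048, seg.size))
    sel = (f >= band[0]) & (f <= band[1])
    return np.trapezoid(psd[sel], f[sel])


class TestSynthesize:
    def test_event_accounting_and_determinism(self, tiny_design):
        a = nm.synthesize(tiny_design, seed=5)
        b = nm.synthesize(tiny_design, seed=5)
        assert len(a.stim_onsets()) == 6
        assert a.annotations == b.annotations
        np.testing.assert_array_equal(a.eeg, b.eeg)
        assert not np.array_equal(a.eeg, nm.synthesize(tiny_design, seed=6).eeg)

    def test_null_effect_leaves_band_power_flat(self, tiny_design):
        gt = nm.NeuralGroundTruth(
            roi_erd={(b, lab): 0.0 for b in BANDS for lab in ("low", "medium", "high")}
        )
        sess = nm.synthesize(tiny_design, gt, nm.ArtifactModel.disabled(), seed=2)
        on = [(e.onset + 0.3, e.onset + e.duration) for e in sess.stim_onsets()]
        off = [(e.onset - 2.5, e.onset - 0.2) for e in sess.stim_onsets()]
        c3 = sess.eeg[sess.channel_index("C3")]
        for band in BANDS.values():
            ratio = _interval_band_power(c3, sess.fs, on, band) / _interval_band_power(
                c3, sess.fs, off, band
            )
            assert 0.8 < ratio < 1.25

    def test_planted_erd_suppresses_roi_band_power(self, tiny_clean_session):
        sess = tiny_clean_session  # alpha ERD -40% at high intensity
        on = [(e.onset + 0.3, e.onset + e.duration) for e in sess.stim_onsets()]
        off = [(e.onset - 2.5, e.onset - 0.2) for e in sess.stim_onsets()]
        c3 = sess.eeg[sess.channel_index("C3")]
        fz = sess.eeg[sess.channel_index("Fz")]
        alpha = BANDS["alpha"]
        roi_ratio = _interval_band_power(c3, sess.fs, on, alpha) / _interval_band_power(
            c3, sess.fs, off, alpha
        )
        ctrl_ratio = _interval_band_power(fz, sess.fs, on, alpha) / _interval_band_power(
            fz, sess.fs, off, alpha
        )
        assert roi_ratio < 0.8  # suppressed towards 1 - 0.40
        assert 0.75 < ctrl_ratio < 1.3  # no ERD planted outside the ROI

    def test_stimulation_raises_35hz_power(self, tiny_session):
        sess = tiny_session
        on = [(e.onset, e.onset + e.duration) for e in sess.stim_onsets()]
        off = [(e.onset - 3.0, e.onset - 0.1) for e in sess.stim_onsets()]
        cz = sess.eeg[sess.channel_index("Cz")]
        ratio = _interval_band_power(cz, sess.fs, on, (34, 36)) / _interval_band_power(
            cz, sess.fs, off, (34, 36)
        )
        assert ratio > 10

    def test_bad_channel_exceeds_rejection_threshold(self, tiny_design):
        am = nm.ArtifactModel(bad_channels=frozenset({"Cz"}))
        sess = nm.synthesize(tiny_design, artifact_model=am, seed=9)
        segs = [(e.onset - 4, e.onset + 4) for e in sess.stim_onsets()]
        powers = band_power_welch(sess.eeg, sess.fs, RejectionConfig(), segs)
        i = sess.channel_index("Cz")
        others = np.delete(powers, i)
        assert powers[i] > others.mean() + 4 * others.std()

    def test_emg_artifact_periodicity(self, tiny_session):
        sess = tiny_session
        ev = sess.stim_onsets()[0]
        seg = sess.emg[0, int(ev.onset * sess.fs) : int((ev.onset + ev.duration) * sess.fs)]
        seg = seg - seg.mean()
        ac = np.correlate(seg, seg, mode="full")[seg.size - 1 :]
        lag = 5 + np.argmax(ac[5:90])
        # strongest off-zero lag must sit on a multiple of the 1/35 s pulse
        # period (28.57 samples; non-integer, so a higher multiple may align
        # better with the sampling grid than the fundamental)
        period = 1000.0 / 35.0
        assert min(abs(lag - k * period) for k in (1, 2, 3)) <= 1.0

    def test_emg_flat_without_artifacts(self, tiny_clean_session):
        assert np.max(np.abs(tiny_clean_session.emg)) == 0.0

    def test_amplitude_monotonicity_enforced(self):
        with pytest.raises(ValueError):
            nm.ArtifactModel(
                transient_amplitude={"low": 300.0, "medium": 200.0, "high": 600.0}
            )
        with pytest.raises(ValueError):
            nm.ArtifactModel(bad_channels=frozenset({"NOPE"}))

    def test_unknown_channel_rejected(self, tiny_design):
        with pytest.raises(ValueError):
            nm.synthesize(tiny_design, seed=0, channels=("C3", "XX"))
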