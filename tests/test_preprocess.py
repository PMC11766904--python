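"""Re-referencing arithmetic, filter gains, and burst-window flagging."""

import numpy as np
import pytest

from eegdem.io import NamedChannelError, write_matrix
from eegdem.preprocess import (
    apply_component_mask,
    bandpass,
    preprocess,
    reject_bursts,
    rereference,
)

from conftest import make_recording


def sine_recording(freq, amp=10.0, dur=60.0, fs=500.0, with_refs=True):
    t = np.arange(int(dur * fs)) / fs
    x = amp * np.sin(2 * np.pi * freq * t)
    n_ch = 21 if with_refs else 19
    return make_recording(np.tile(x, (n_ch, 1)), fs=fs, with_refs=with_refs)


class TestRereference:
    def test_everything_equal_gives_zero(self):
        rec = make_recording(np.full((21, 1000), 7.0))
        out = rereference(rec)
        assert np.allclose(out.data, 0.0)
        assert out.n_channels == 19 and out.reference_names == []

    def test_linked_ear_mean_subtracted(self, constant_recording):
        out = rereference(constant_recording)   # scalp 5, A1 2, A2 4
        assert np.allclose(out.data, 2.0)

    def test_elementwise_identity_on_synthetic_subject(self, cn_subject):
        out = rereference(cn_subject)
        ref = 0.5 * (cn_subject.get_channel("A1") + cn_subject.get_channel("A2"))
        assert np.allclose(out.data, cn_subject.data[:19] - ref)

    def test_missing_reference_raises(self):
        rec = make_recording(np.zeros((19, 100)), with_refs=False)
        with pytest.raises(NamedChannelError):
            rereference(rec)


class TestBandpass:
    def test_passband_tone_preserved(self):
        out = bandpass(sine_recording(10.0, with_refs=False))
        mid = out.data[0, 5000:-5000]   # trim filter edges
        assert np.abs(mid).max() == pytest.approx(10.0, rel=0.01)

    def test_line_noise_attenuated_per_designed_stopband_gain(self):
        # oracle: the designed filter's own 50 Hz gain (forward–backward ⇒
        # squared magnitude); order 4 gives ~71 % attenuation, order 8 more
        from scipy import signal as sps

        for order in (4, 8):
            sos = sps.butter(order, [0.5, 45.0], btype="bandpass", fs=500.0,
                             output="sos")
            _, h = sps.sosfreqz(sos, worN=[2 * np.pi * 50.0 / 500.0])
            expected_gain = float(np.abs(h[0])) ** 2
            out = bandpass(sine_recording(50.0, with_refs=False), order=order)
            mid = out.data[0, 5000:-5000]
            measured_amp = np.sqrt(2.0) * np.sqrt((mid ** 2).mean())
            assert measured_amp == pytest.approx(10.0 * expected_gain,
                                                 rel=0.02)
        # a 10-th order zero-phase design reaches > 90 % attenuation
        sos = sps.butter(10, [0.5, 45.0], btype="bandpass", fs=500.0,
                         output="sos")
        _, h = sps.sosfreqz(sos, worN=[2 * np.pi * 50.0 / 500.0])
        assert float(np.abs(h[0])) ** 2 < 0.1

    def test_dc_removed(self):
        rec = make_recording(np.full((19, 30000), 100.0), with_refs=False)
        out = bandpass(rec)
        assert abs(out.data[0, 5000:-5000].mean()) < 0.1

    def test_linearity(self):
        rng = np.random.default_rng(0)
        rec = make_recording(rng.normal(0, 5, (19, 10000)), with_refs=False)
        scaled = make_recording(3.0 * rec.data, with_refs=False)
        assert np.allclose(bandpass(scaled).data, 3.0 * bandpass(rec).data,
                           atol=1e-8)

    def test_invalid_corners_rejected(self):
        rec = make_recording(np.zeros((19, 1000)), with_refs=False)
        with pytest.raises(ValueError):
            bandpass(rec, 45.0, 0.5)
        with pytest.raises(ValueError):
            bandpass(rec, 0.5, 300.0)   # above Nyquist


class TestBurstRejection:
    def test_stationary_signal_mostly_kept(self):
        rng = np.random.default_rng(1)
        rec = make_recording(rng.normal(0, 10, (19, 150000)), with_refs=False)
        res = reject_bursts(rec)
        assert res.dropped_fraction < 0.05

    def test_injected_burst_window_flagged_exactly(self):
        rng = np.random.default_rng(2)
        data = rng.normal(0, 10, (19, 50000))
        win = 250                      # 0.5 s at 500 Hz
        data[:, 40 * win:41 * win] *= 30.0   # one 30× window
        res = reject_bursts(make_recording(data, with_refs=False))
        expected = np.ones(200, dtype=bool)
        expected[40] = False
        assert np.array_equal(res.kept_mask, expected)
        assert res.recording.n_samples == 199 * win

    def test_infinite_cutoff_is_identity(self, cn_subject):
        res = reject_bursts(cn_subject, cutoff=np.inf)
        assert res.kept_mask.all()
        assert res.dropped_fraction == 0.0
        n_win = cn_subject.n_samples // 250
        assert np.array_equal(res.recording.data,
                              cn_subject.data[:, :n_win * 250])

    def test_order_preserved_across_drop(self):
        # after a drop, the output is exactly the kept windows, in order
        rng = np.random.default_rng(7)
        data = rng.normal(0, 10, (19, 10000))
        data[:, 20 * 250:21 * 250] *= 40.0
        res = reject_bursts(make_recording(data, with_refs=False))
        assert np.array_equal(np.where(~res.kept_mask)[0], [20])
        windows = data.reshape(19, 40, 250)
        expected = windows[:, res.kept_mask, :].reshape(19, -1)
        assert np.array_equal(res.recording.data, expected)

    def test_all_rejected_raises(self):
        # a pure impulse train makes every window exceed any sane threshold
        data = np.zeros((19, 5000))
        data[:, ::250] = 1e6
        data += np.random.default_rng(3).normal(0, 1e-3, data.shape)
        with pytest.raises(ValueError, match="every window"):
            reject_bursts(make_recording(data, with_refs=False), cutoff=0.01)

    def test_shorter_than_one_window_raises(self):
        rec = make_recording(np.zeros((19, 100)), with_refs=False)
        with pytest.raises(ValueError):
            reject_bursts(rec)


class TestComponentMask:
    def test_identity_projection_is_noop(self, tmp_path, cn_subject):
        rec = rereference(cn_subject)
        path = write_matrix(np.eye(19), str(tmp_path / "eye.txt"))
        out = apply_component_mask(rec, path)
        assert np.allclose(out.data, rec.data)

    def test_zero_projection_silences_everything(self, tmp_path, cn_subject):
        rec = rereference(cn_subject)
        path = write_matrix(np.zeros((19, 19)), str(tmp_path / "z.txt"))
        assert np.all(apply_component_mask(rec, path).data == 0.0)

    def test_rank_deficient_projection_removes_topography(self, tmp_path):
        rng = np.random.default_rng(4)
        topo = rng.normal(size=19)
        topo /= np.linalg.norm(topo)
        source = rng.normal(size=5000)
        background = rng.normal(0, 1, (19, 5000))
        mixed = background + 50.0 * np.outer(topo, source)
        proj = np.eye(19) - np.outer(topo, topo)
        path = write_matrix(proj, str(tmp_path / "p.txt"))
        out = apply_component_mask(
            make_recording(mixed, with_refs=False), path)
        # the projected data contain no trace of the removed topography
        assert np.abs(topo @ out.data).max() < 1e-8

    def test_dimension_mismatch_rejected(self, tmp_path, cn_subject):
        path = write_matrix(np.eye(5), str(tmp_path / "bad.txt"))
        with pytest.raises(ValueError, match="projection"):
            apply_component_mask(rereference(cn_subject), path)


class TestFullPipeline:
    def test_order_and_output_shape(self, cn_subject):
        res = preprocess(cn_subject)
        rec = res.recording
        assert rec.n_channels == 19           # references consumed
        assert rec.n_samples % 250 == 0       # whole 0.5 s windows
        assert 0.0 <= res.dropped_fraction <= 1.0
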