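"""OD conversion, TDDR, MBLL, filtering and quality control."""

import numpy as np
import pytest

from covertfnirs import (ExtinctionModel, FilterSpec, Recording, apply_filter,
                         apply_qc, channel_qc, default_montage, forward_od,
                         intensity_to_od, od_to_concentration, tddr)
from covertfnirs.errors import ModelError, ParameterError, ValidationError
from covertfnirs.preprocess import (ChannelQC, ExcludedRecording,
                                    ODSeries, QCReport, _tddr_split,
                                    _tddr_trace, filter_array)
from covertfnirs.recording import EventSchedule
from covertfnirs.simulate import inject_motion_artifacts


def _recording_from_od(od_values, fs=10.17, probe=None):
    probe = probe or default_montage()
    rec = Recording(probe, np.exp(-od_values), (760.0, 850.0), fs,
                    EventSchedule((), od_values.shape[0] / fs))
    return rec


class TestIntensityToOD:
    def test_constant_intensity_gives_zero(self, probe):
        n_ch = len(probe.channels)
        rec = _recording_from_od(np.zeros((50, n_ch, 2)))
        od = intensity_to_od(rec)
        np.testing.assert_allclose(od.values, 0.0, atol=1e-14)

    def test_half_mean_sample_gives_ln2(self, probe):
        n_ch = len(probe.channels)
        inten = np.ones((100, n_ch, 2))
        inten[0] = 0.5
        inten[1] = 1.5  # keeps the temporal mean at exactly 1
        rec = Recording(probe, inten, (760.0, 850.0), 10.0,
                        EventSchedule((), 10.0))
        od = intensity_to_od(rec)
        np.testing.assert_allclose(od.values[0], np.log(2), rtol=1e-12)

    def test_round_trip_up_to_constant(self, probe, rng):
        n_ch = len(probe.channels)
        true_od = 0.05 * rng.standard_normal((200, n_ch, 2))
        rec = _recording_from_od(true_od)
        od = intensity_to_od(rec)
        diff = od.values - true_od
        # equal up to a per-trace additive constant
        assert np.max(np.ptp(diff, axis=0)) < 1e-10

    def test_nonpositive_sample_identified(self, probe):
        n_ch = len(probe.channels)
        inten = np.ones((20, n_ch, 2))
        inten[3, 2, 1] = 0.0
        rec = Recording(probe, inten, (760.0, 850.0), 10.0,
                        EventSchedule((), 2.0))
        with pytest.raises(ValidationError, match="sample 3"):
            intensity_to_od(rec)


class TestTDDR:
    def test_constant_series_unchanged(self):
        x = np.full(500, 2.5)
        out, _ = _tddr_trace(x, 10.0)
        np.testing.assert_array_equal(out, x)

    def test_artifact_free_sinusoid_preserved(self):
        t = np.arange(3000) / 10.0
        x = np.sin(2 * np.pi * 0.05 * t) + 0.01 * np.random.default_rng(0).standard_normal(3000)
        out, _ = _tddr_trace(x, 10.0)
        assert np.corrcoef(out, x)[0, 1] > 0.99

    def test_spike_suppression(self, rng):
        """10x-SD spikes on an OD-scale noise background are attenuated
        >= 90% at the artifact windows by TDDR plus the pipeline's 0.2 Hz
        low-pass (TDDR repairs the sub-0.5 Hz component; the band filter
        removes the spike's zero-area high-frequency remainder)."""
        fs = 10.17
        clean = 0.003 * rng.standard_normal(6000)
        spiky, log = inject_motion_artifacts(clean, 0.5, 0.0, seed=201,
                                             spike_min_mult=10.0,
                                             sampling_rate=fs)
        assert len(log) >= 3
        onsets = sorted(ev.onset_sample for ev in log)
        assert min(np.diff(onsets)) > 2 * fs  # well-separated events
        spec = FilterSpec(0.0, 0.2, detrend=False)
        corrected = filter_array(_tddr_trace(spiky, fs)[0], spec, fs)
        baseline = filter_array(_tddr_trace(clean, fs)[0], spec, fs)
        for ev in log:
            win = slice(ev.onset_sample, ev.onset_sample + ev.duration_samples)
            before = np.max(np.abs(spiky[win] - clean[win]))
            after = np.max(np.abs(corrected[win] - baseline[win]))
            assert after <= 0.1 * before

    def test_never_increases_robust_scale_of_lf_derivative(self, rng):
        def robust_scale(x, fs):
            low, _ = _tddr_split(x, fs)
            d = np.diff(low)
            return 1.4826 * np.median(np.abs(d - np.median(d)))

        for seed in range(5):
            g = np.random.default_rng(seed)
            x = np.cumsum(g.standard_normal(2000)) * 0.01
            x[600:605] += 3.0
            out, _ = _tddr_trace(x, 10.0)
            assert robust_scale(out, 10.0) <= robust_scale(x, 10.0) * (1 + 1e-9)

    def test_too_short_input_rejected(self):
        od = ODSeries(np.zeros((5, 1, 2)), 10.0)
        with pytest.raises(ParameterError):
            tddr(od)


class TestMBLL:
    def test_zero_od_zero_concentration(self, probe):
        od = ODSeries(np.zeros((30, len(probe.channels), 2)), 10.0)
        hemo = od_to_concentration(od, probe, which="long")
        np.testing.assert_array_equal(hemo.hbo, 0)
        np.testing.assert_array_equal(hemo.hbr, 0)

    def test_identity_model(self, probe, rng):
        """With eps = I and d*DPF = 1, dHbO is OD760 and dHbR is OD850."""
        model = ExtinctionModel(epsilon=np.eye(2), dpf=(1 / 3.0, 1 / 3.0))
        vals = rng.standard_normal((40, len(probe.channels), 2))
        od = ODSeries(vals, 10.0)
        hemo = od_to_concentration(od, probe, model, which="long")
        idx = [probe.channel_index(ch.name) for ch in probe.long_channels]
        np.testing.assert_allclose(hemo.hbo, vals[:, idx, 0], rtol=1e-12)
        np.testing.assert_allclose(hemo.hbr, vals[:, idx, 1], rtol=1e-12)

    def test_forward_inverse_round_trip(self, probe, rng):
        model = ExtinctionModel()
        n = 100
        hbo = rng.standard_normal(n)
        hbr = rng.standard_normal(n)
        vals = np.zeros((n, len(probe.channels), 2))
        for c, ch in enumerate(probe.channels):
            vals[:, c, :] = forward_od(hbo, hbr, ch.separation, model)
        hemo = od_to_concentration(ODSeries(vals, 10.0), probe, model, "all")
        for j in range(len(probe.channels)):
            np.testing.assert_allclose(hemo.hbo[:, j], hbo, rtol=1e-8)
            np.testing.assert_allclose(hemo.hbr[:, j], hbr, rtol=1e-8)

    def test_linearity(self, probe, rng):
        model = ExtinctionModel()
        a, b = 2.5, -0.7
        od1 = ODSeries(rng.standard_normal((30, len(probe.channels), 2)), 10.0)
        od2 = ODSeries(rng.standard_normal((30, len(probe.channels), 2)), 10.0)
        combo = ODSeries(a * od1.values + b * od2.values, 10.0)
        h1 = od_to_concentration(od1, probe, model)
        h2 = od_to_concentration(od2, probe, model)
        hc = od_to_concentration(combo, probe, model)
        np.testing.assert_allclose(hc.hbo, a * h1.hbo + b * h2.hbo, atol=1e-10)
        np.testing.assert_allclose(hc.hbr, a * h1.hbr + b * h2.hbr, atol=1e-10)

    def test_singular_model_rejected(self):
        with pytest.raises(ModelError):
            ExtinctionModel(epsilon=np.array([[1.0, 1.0], [1.0, 1.0]])).validate()


class TestFilter:
    def test_passband_sinusoid_preserved(self):
        fs, t = 10.17, np.arange(8000) / 10.17
        x = np.sin(2 * np.pi * 0.05 * t)
        y = filter_array(x, FilterSpec(0.0, 0.2, detrend=False), fs)
        core = slice(1000, -1000)
        assert np.max(np.abs(y[core])) == pytest.approx(1.0, rel=0.05)

    def test_stopband_sinusoid_attenuated(self):
        fs, t = 10.17, np.arange(8000) / 10.17
        x = np.sin(2 * np.pi * 1.2 * t)
        y = filter_array(x, FilterSpec(0.0, 0.2, detrend=False), fs)
        assert np.max(np.abs(y[1000:-1000])) <= 0.05

    def test_detrend_removes_line(self):
        t = np.arange(2000) / 10.0
        x = 3.0 + 0.25 * t
        y = filter_array(x, FilterSpec(0.0, 0.2, detrend=True), 10.0)
        assert np.max(np.abs(y)) < 1e-8 * 0.25 * t[-1]

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ParameterError):
            FilterSpec(0.0, 6.0).validate(10.0)
        with pytest.raises(ParameterError):
            FilterSpec(0.5, 0.2).validate(10.0)

    def test_apply_filter_preserves_shape(self, small_responder):
        rec, _ = small_responder
        hemo = od_to_concentration(intensity_to_od(rec), rec.probe, which="long")
        out = apply_filter(hemo, FilterSpec())
        assert out.hbo.shape == hemo.hbo.shape
        assert out.channels == hemo.channels


def _qc_recording(probe, snrs, cardiac=True, fs=10.17, dur=90.0):
    """Build a recording whose channel c has intensity mean/SD ~ snrs[c]."""
    n = int(dur * fs)
    t = np.arange(n) / fs
    rng = np.random.default_rng(0)
    inten = np.empty((n, len(probe.channels), 2))
    for c in range(len(probe.channels)):
        for w in range(2):
            parts = []
            if cardiac:
                parts.append(np.sin(2 * np.pi * 1.2 * t + 0.1 * c))
            parts.append(rng.standard_normal(n))
            x = sum(parts)
            x = x / x.std() / snrs[c]
            inten[:, c, w] = 1.0 + x - x.mean()
    inten = np.clip(inten, 1e-6, None)
    return Recording(probe, inten, (760.0, 850.0), fs, EventSchedule((), dur))


class TestChannelQC:
    def test_low_snr_channel_flagged_bad(self, probe):
        snrs = [20.0] * len(probe.channels)
        snrs[0] = 5.0
        rec = _qc_recording(probe, snrs)
        qc = channel_qc(rec)
        assert not qc.channels[0].is_good
        assert qc.channels[0].snr == pytest.approx(5.0, rel=0.05)
        assert qc.channels[1].is_good

    def test_strong_cardiac_good(self, probe):
        rec = _qc_recording(probe, [20.0] * len(probe.channels))
        qc = channel_qc(rec)
        assert all(c.cardiac_present for c in qc.channels)
        assert all(c.is_good for c in qc.channels)

    def test_no_cardiac_is_bad(self, probe):
        rec = _qc_recording(probe, [20.0] * len(probe.channels), cardiac=False)
        qc = channel_qc(rec)
        assert not any(c.is_good for c in qc.channels)

    def test_constant_channel_bad_with_infinite_snr(self, probe):
        rec = _qc_recording(probe, [20.0] * len(probe.channels))
        inten = rec.intensity.copy()
        inten[:, 0, :] = 1.0
        rec = rec.copy_with(intensity=inten)
        qc = channel_qc(rec)
        assert np.isinf(qc.channels[0].snr)
        assert not qc.channels[0].cardiac_present
        assert not qc.channels[0].is_good

    def test_scale_invariance(self, probe):
        snrs = [20.0] * len(probe.channels)
        snrs[3] = 4.0
        rec = _qc_recording(probe, snrs)
        scaled = rec.copy_with(intensity=rec.intensity * 7.3)
        qa, qb = channel_qc(rec), channel_qc(scaled)
        for a, b in zip(qa.channels, qb.channels):
            assert a.is_good == b.is_good
            assert a.snr == pytest.approx(b.snr, rel=1e-9)

    def test_short_recording_rejected(self, probe):
        rec = _qc_recording(probe, [20.0] * len(probe.channels), dur=30.0)
        with pytest.raises(ParameterError):
            channel_qc(rec)


class TestApplyQC:
    def test_all_good_unchanged(self, probe):
        rec = _qc_recording(probe, [20.0] * len(probe.channels))
        qc = channel_qc(rec)
        out = apply_qc(rec, qc)
        assert isinstance(out, Recording)
        assert out.meta["bad_channels"] == []

    def test_all_bad_excluded(self, probe):
        rec = _qc_recording(probe, [2.0] * len(probe.channels))
        qc = channel_qc(rec)
        out = apply_qc(rec, qc)
        assert isinstance(out, ExcludedRecording)

    def test_threshold_arithmetic(self, probe):
        # 6 of 10 bad -> bad_fraction 0.6 > 0.5 -> excluded
        chans = [ChannelQC(f"c{i}", 20.0, True, i >= 6) for i in range(10)]
        qc = QCReport(chans, bad_fraction=0.6, recording_excluded=True)
        rec = _qc_recording(probe, [20.0] * len(probe.channels))
        assert isinstance(apply_qc(rec, qc, 0.5), ExcludedRecording)
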