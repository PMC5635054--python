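"""EEG preprocessing: decimation, AAS, R-peak detection, BCG removal,
filtering, ICA proxy, artifact marking, re-referencing, pooling."""

import warnings

import numpy as np
import pytest
from scipy import signal

from alphabold import eeg
from alphabold.eeg import (
    aas_subtract,
    bcg_subtract,
    decimate,
    detect_r_peaks,
    epoch_onsets_from_markers,
    filter_eeg,
    ica_autoclean,
    mark_artifacts,
    pool_occipital,
    rereference_common_average,
)

from conftest import make_recording


def tone(freq, fs, dur, amp=1.0):
    return amp * np.sin(2 * np.pi * freq * np.arange(int(dur * fs)) / fs)


class TestDecimate:
    def test_factor_and_rate(self):
        rec = make_recording(np.random.default_rng(0).normal(size=(2, 50000)),
                             5000.0)
        out = decimate(rec, 250.0)
        assert out.fs == 250.0
        assert out.n_samples == 2500
        assert out.history[-1]["factor"] == 20

    def test_inband_tone_amplitude_preserved(self):
        rec = make_recording(tone(10, 5000, 20)[None, :], 5000.0, ["O1"])
        out = decimate(rec, 250.0)
        seg = out.data[0][250:-250]
        assert abs(np.ptp(seg) / 2 - 1.0) < 0.01

    def test_above_nyquist_tone_attenuated_40db(self):
        rec = make_recording(tone(200, 5000, 20)[None, :], 5000.0, ["O1"])
        out = decimate(rec, 250.0)
        in_rms = np.sqrt(np.mean(rec.data[0] ** 2))
        out_rms = np.sqrt(np.mean(out.data[0][250:-250] ** 2))
        assert 20 * np.log10(in_rms / out_rms) >= 40

    def test_marker_times_unchanged(self):
        rec = make_recording(np.zeros((1, 50000)), 5000.0, ["O1"],
                             markers=[(2.6, "Scanner", "V1")])
        out = decimate(rec, 250.0)
        assert out.markers == [(2.6, "Scanner", "V1")]

    def test_non_integer_factor_rejected(self):
        rec = make_recording(np.zeros((1, 5000)), 5000.0, ["O1"])
        with pytest.raises(ValueError):
            decimate(rec, 300.0)
        with pytest.raises(ValueError):
            decimate(rec, 5000.0)


class TestEpochOnsets:
    def test_regular_markers(self):
        markers = [(k * 2.6, "Scanner", f"V{k}") for k in range(10)]
        rec = make_recording(np.zeros((1, 250 * 30)), 250.0, ["O1"], markers)
        onsets = epoch_onsets_from_markers(rec, "Scanner")
        assert np.allclose(np.diff(onsets), 2.6)

    def test_single_marker_rejected(self):
        rec = make_recording(np.zeros((1, 2500)), 250.0, ["O1"],
                             [(1.0, "Scanner", "V1")])
        with pytest.raises(ValueError):
            epoch_onsets_from_markers(rec, "Scanner")
        with pytest.raises(ValueError, match="no markers"):
            epoch_onsets_from_markers(rec, "Response")

    def test_jittered_markers_warn(self):
        times = np.arange(10) * 2.6
        times[4] += 3 / 250.0  # three samples late
        markers = [(t, "Scanner", "V") for t in times]
        rec = make_recording(np.zeros((1, 250 * 30)), 250.0, ["O1"], markers)
        with pytest.warns(RuntimeWarning, match="spacing"):
            onsets = epoch_onsets_from_markers(rec, "Scanner")
        assert len(onsets) == 10


class TestAAS:
    def _rec_with_artifact(self, n_epochs, fs=250.0, epoch_len=2.6, noise=0.0,
                           seed=0):
        rng = np.random.default_rng(seed)
        L = int(epoch_len * fs)
        template = 100 * signal.sawtooth(2 * np.pi * 5 * np.arange(L) / fs)
        n = L * n_epochs + 100
        data = rng.normal(0, noise, size=(2, n)) if noise else np.zeros((2, n))
        onsets = np.arange(n_epochs) * epoch_len
        for k in range(n_epochs):
            data[:, k * L : (k + 1) * L] += template
        rec = make_recording(data, fs, ["O1", "O2"])
        return rec, onsets, template

    def test_identical_artifact_removed_to_numerical_zero(self):
        rec, onsets, template = self._rec_with_artifact(12)
        out = aas_subtract(rec, onsets, 2.6, n_avg=12)
        art_rms = np.sqrt(np.mean(template**2))
        res_rms = np.sqrt(np.mean(out.data[:, : len(template) * 12] ** 2))
        assert res_rms < 1e-9 * art_rms

    def test_n_avg_one_zeroes_each_epoch(self):
        rec, onsets, template = self._rec_with_artifact(5, noise=1.0, seed=2)
        out = aas_subtract(rec, onsets, 2.6, n_avg=1)
        L = len(template)
        assert np.allclose(out.data[:, : 5 * L], 0.0)
        # samples outside epochs untouched
        assert np.array_equal(out.data[:, 5 * L :], rec.data[:, 5 * L :])

    def test_attenuation_at_tr_harmonics_with_noise(self):
        """Artifact 20 dB above white noise, 180 epochs, sliding window 21:
        >= 20 dB attenuation at the artifact harmonics."""
        fs, epoch_len, n_ep = 250.0, 2.6, 180
        rng = np.random.default_rng(7)
        L = int(epoch_len * fs)
        template = 10 * signal.sawtooth(2 * np.pi * (10 / epoch_len)
                                        * np.arange(L) / fs)
        n = L * n_ep
        noise = rng.normal(0, 1.0, size=(1, n))
        data = noise.copy()
        for k in range(n_ep):
            data[:, k * L : (k + 1) * L] += template
        rec = make_recording(data, fs, ["O1"])
        onsets = np.arange(n_ep) * epoch_len
        out = aas_subtract(rec, onsets, epoch_len, n_avg=21)
        f, p_before = signal.periodogram(data[0], fs=fs)
        _, p_after = signal.periodogram(out.data[0], fs=fs)
        harmonics = np.arange(1, 20) / epoch_len
        idx = [np.argmin(np.abs(f - h)) for h in harmonics]
        atten = 10 * np.log10(np.sum(p_before[idx]) / np.sum(p_after[idx]))
        assert atten >= 20

    def test_overlapping_epochs_rejected(self):
        rec, onsets, _ = self._rec_with_artifact(5)
        with pytest.raises(ValueError, match="overlap"):
            aas_subtract(rec, onsets, 3.0, n_avg=3)

    def test_epoch_past_end_rejected(self):
        rec, onsets, _ = self._rec_with_artifact(5)
        with pytest.raises(ValueError, match="past end"):
            aas_subtract(rec, onsets + 1.0, 2.6, n_avg=3)

    def test_linearity(self):
        rec_a, onsets, _ = self._rec_with_artifact(6, noise=1.0, seed=1)
        rec_b, _, _ = self._rec_with_artifact(6, noise=1.0, seed=2)
        rec_sum = make_recording(rec_a.data + rec_b.data, 250.0, ["O1", "O2"])
        out_a = aas_subtract(rec_a, onsets, 2.6, n_avg=5)
        out_b = aas_subtract(rec_b, onsets, 2.6, n_avg=5)
        out_sum = aas_subtract(rec_sum, onsets, 2.6, n_avg=5)
        assert np.allclose(out_sum.data, out_a.data + out_b.data, atol=1e-10)


def synthetic_ecg(fs, dur, bpm=60, jitter=0.0, seed=0):
    rng = np.random.default_rng(seed)
    n = int(dur * fs)
    ecg = np.zeros(n)
    t, times = 0.5, []
    while t < dur - 0.5:
        times.append(t)
        t += 60 / bpm * (1 + jitter * rng.standard_normal())
    width = int(0.02 * fs)
    kernel = np.exp(-0.5 * ((np.arange(-3 * width, 3 * width + 1)) / width) ** 2)
    for pt in times:
        i = int(pt * fs)
        lo = max(0, i - 3 * width)
        ecg[lo : lo + len(kernel)][: n - lo] += 800 * kernel[: n - lo]
    return ecg, np.array(times)


class TestDetectRPeaks:
    def test_clean_60bpm_timing(self):
        fs = 250.0
        ecg, true_times = synthetic_ecg(fs, 60, bpm=60)
        got = detect_r_peaks(ecg, fs)
        assert abs(len(got) - len(true_times)) <= 1
        matched = [np.min(np.abs(true_times - g)) for g in got]
        assert np.median(matched) < 0.010

    def test_flat_signal_empty_with_warning(self):
        with pytest.warns(RuntimeWarning):
            out = detect_r_peaks(np.zeros(5000), 250.0)
        assert len(out) == 0

    def test_noisy_ecg_sensitivity(self):
        fs = 250.0
        ecg, true_times = synthetic_ecg(fs, 120, bpm=70, jitter=0.03, seed=4)
        sig_rms = np.sqrt(np.mean(ecg**2))
        noisy = ecg + np.random.default_rng(5).normal(
            0, sig_rms / np.sqrt(10), len(ecg))  # 10 dB SNR
        got = detect_r_peaks(noisy, fs)
        hits = sum(np.min(np.abs(got - t)) < 0.05 for t in true_times)
        assert hits / len(true_times) >= 0.95

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            detect_r_peaks(np.zeros(100), 250.0)


class TestBCG:
    def _rec_with_bcg(self, fs=250.0, dur=120.0, jitter=0.0, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        n = int(dur * fs)
        tmpl_t = np.arange(int(0.5 * fs)) / fs
        template = 50 * np.exp(-tmpl_t / 0.15) * np.sin(2 * np.pi * 7 * tmpl_t)
        peaks, t = [], 0.5
        while t < dur - 1.2:
            peaks.append(t)
            t += 1.0 * (1 + jitter * rng.standard_normal())
        peaks = np.array(peaks)
        artifact = np.zeros(n)
        for pk in peaks:
            s = int(np.round((pk + 0.21) * fs))
            artifact[s : s + len(template)] += template
        data = artifact[None, :].copy()
        if noise:
            data = data + rng.normal(0, noise, size=data.shape)
        return make_recording(data, fs, ["O1"]), peaks, artifact

    def test_identical_pulse_removed_to_numerical_zero(self):
        rec, peaks, artifact = self._rec_with_bcg()
        out = bcg_subtract(rec, peaks, delay=0.21, template_len=0.5,
                           n_avg=len(peaks))
        art_rms = np.sqrt(np.mean(artifact**2))
        assert np.sqrt(np.mean(out.data[0] ** 2)) < 1e-9 * art_rms

    def test_jittered_rr_attenuation_15db(self):
        """3% RR jitter plus noise: artifact-band (1-12 Hz) power reduced by
        at least 15 dB, measured against the known injected artifact."""
        rec, peaks, artifact = self._rec_with_bcg(jitter=0.03, noise=1.0, seed=6)
        out = bcg_subtract(rec, peaks, delay=0.21, template_len=0.5, n_avg=21)
        residual = out.data[0] - (rec.data[0] - artifact)
        f, p_art = signal.periodogram(artifact, fs=rec.fs)
        _, p_res = signal.periodogram(residual, fs=rec.fs)
        band = (f >= 1) & (f <= 12)
        atten = 10 * np.log10(np.sum(p_art[band]) / np.sum(p_res[band]))
        assert atten >= 15

    def test_empty_peaks_rejected(self):
        rec, _, _ = self._rec_with_bcg()
        with pytest.raises(ValueError):
            bcg_subtract(rec, np.array([]))

    def test_template_longer_than_rr_rejected(self):
        rec, peaks, _ = self._rec_with_bcg()
        with pytest.raises(ValueError, match="shorter template"):
            bcg_subtract(rec, peaks, template_len=1.5)


class TestFilterEEG:
    def test_notch_attenuates_50hz(self):
        rec = make_recording(tone(50, 250, 30)[None, :], 250.0, ["O1"])
        out = filter_eeg(rec)
        sl = slice(500, -500)
        atten = 20 * np.log10(np.sqrt(np.mean(rec.data[0][sl] ** 2))
                              / np.sqrt(np.mean(out.data[0][sl] ** 2)))
        assert atten >= 30

    def test_passband_tone_preserved(self):
        rec = make_recording(tone(10, 250, 30)[None, :], 250.0, ["O1"])
        out = filter_eeg(rec)
        sl = slice(500, -500)
        assert abs(np.ptp(out.data[0][sl]) / 2 - 1.0) < 0.05

    def test_dc_offset_removed(self):
        rec = make_recording(np.full((1, 250 * 30), 100.0), 250.0, ["O1"])
        out = filter_eeg(rec)
        assert np.max(np.abs(out.data[0][500:-500])) < 1.0

    def test_invalid_edges_rejected(self):
        rec = make_recording(np.zeros((1, 2500)), 250.0, ["O1"])
        with pytest.raises(ValueError):
            filter_eeg(rec, hp=80, lp=70)
        with pytest.raises(ValueError):
            filter_eeg(rec, hp=0.5, lp=130)


class TestICAAutoclean:
    def _mixed_recording(self, with_ecg_comp=False, seed=0):
        rng = np.random.default_rng(seed)
        fs, n = 250.0, 250 * 60
        t = np.arange(n) / fs
        sources = np.vstack([
            np.sin(2 * np.pi * 10 * t) * (1 + 0.3 * np.sin(2 * np.pi * t / 7)),
            signal.sawtooth(2 * np.pi * 6 * t),
            rng.normal(size=n),
            rng.normal(size=n),
        ])
        ecg = np.sin(2 * np.pi * 1.2 * t) ** 21  # spiky pseudo-cardiac trace
        if with_ecg_comp:
            sources[3] = ecg + 0.05 * rng.normal(size=n)
        A = rng.normal(size=(4, 4)) + np.eye(4)
        data = A @ sources
        rec = make_recording(np.vstack([data, ecg]), fs,
                             ["O1", "O2", "Oz", "Pz", "ECG"])
        return rec, ecg

    def test_clean_data_nothing_removed_reconstruction_exact(self):
        rec, ecg = self._mixed_recording(seed=3)
        out = ica_autoclean(rec, ecg, corr_thresh=0.95,
                            lowfreq_frac_thresh=0.99, fit_stride=1)
        assert out.history[-1]["removed"] == []
        rel = (np.linalg.norm(out.data[:4] - rec.data[:4])
               / np.linalg.norm(rec.data[:4]))
        assert rel < 1e-6

    def test_ecg_correlated_component_removed(self):
        rec, ecg = self._mixed_recording(with_ecg_comp=True, seed=4)
        out = ica_autoclean(rec, ecg, corr_thresh=0.3, fit_stride=1)
        removed = out.history[-1]["removed"]
        assert len(removed) >= 1
        # the cleaned data is much less correlated with ECG on every channel
        before = max(abs(np.corrcoef(rec.data[i], ecg)[0, 1]) for i in range(4))
        after = max(abs(np.corrcoef(out.data[i], ecg)[0, 1]) for i in range(4))
        assert after < before

    def test_thresholds_at_one_remove_nothing(self):
        rec, ecg = self._mixed_recording(with_ecg_comp=True, seed=5)
        out = ica_autoclean(rec, ecg, corr_thresh=1.0, lowfreq_frac_thresh=1.0,
                            fit_stride=1)
        assert out.history[-1]["removed"] == []


class TestMarkArtifacts:
    def test_clean_signal_empty_mask(self, rng):
        mask = mark_artifacts(rng.normal(size=2500), 250.0)
        assert mask.intervals == []

    def test_long_burst_flagged_and_covered(self, rng):
        fs = 250.0
        x = rng.normal(size=int(20 * fs))
        x[int(8 * fs) : int(10 * fs)] += 500.0
        mask = mark_artifacts(x, fs)
        flagged = mask.flagged_intervals()
        assert len(flagged) == 1
        s, e = flagged[0]
        overlap = min(e, 10.0) - max(s, 8.0)
        assert overlap >= 0.9 * 2.0

    def test_short_burst_recorded_not_flagged(self, rng):
        fs = 250.0
        x = rng.normal(size=int(20 * fs))
        x[int(8 * fs) : int(8.4 * fs)] += 500.0
        mask = mark_artifacts(x, fs)
        assert len(mask.intervals) >= 1
        assert mask.flagged_intervals() == []


class TestReference:
    def test_sum_to_zero_and_idempotent(self, rng):
        data = rng.normal(size=(5, 1000))
        rec = make_recording(data, 250.0, ["O1", "O2", "Oz", "Pz", "ECG"])
        out = rereference_common_average(rec)
        sums = out.data[:4].sum(axis=0)
        assert np.max(np.abs(sums)) < 1e-10 * np.max(np.abs(out.data[:4]))
        # ECG untouched
        assert np.array_equal(out.data[4], data[4])
        again = rereference_common_average(out)
        assert np.allclose(again.data, out.data, atol=1e-12)

    def test_two_antisymmetric_channels_unchanged(self, rng):
        a = rng.normal(size=1000)
        rec = make_recording(np.vstack([a, -a]), 250.0, ["O1", "O2"])
        out = rereference_common_average(rec)
        assert np.allclose(out.data, rec.data)

    def test_single_channel_rejected(self):
        rec = make_recording(np.zeros((2, 100)), 250.0, ["O1", "ECG"])
        with pytest.raises(ValueError):
            rereference_common_average(rec)


class TestPoolOccipital:
    def test_arithmetic_mean(self):
        data = np.array([[1.0], [2.0], [6.0], [9.0]])
        rec = make_recording(data, 250.0, ["O1", "O2", "Oz", "ECG"])
        assert pool_occipital(rec)[0] == pytest.approx(3.0)

    def test_identical_channels_passthrough(self, rng):
        x = rng.normal(size=100)
        rec = make_recording(np.vstack([x, x, x]), 250.0, ["O1", "O2", "Oz"])
        assert np.allclose(pool_occipital(rec), x)

    def test_missing_channel_named_in_error(self):
        rec = make_recording(np.zeros((2, 100)), 250.0, ["O1", "O2"])
        with pytest.raises(KeyError, match="Oz"):
            pool_occipital(rec)


def test_operations_preserve_channel_count_and_markers(rng):
    markers = [(k * 2.6, "Scanner", "V") for k in range(4)]
    rec = make_recording(rng.normal(size=(3, 5000)), 500.0,
                         ["O1", "O2", "Oz"], markers)
    out = filter_eeg(decimate(rec, 250.0))
    assert out.n_channels == 3
    assert out.markers == markers
    assert [h["op"] for h in out.history] == ["decimate", "filter_eeg"]
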