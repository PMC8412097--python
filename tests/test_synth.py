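"""Artificial test-signal construction and surrogate source generators."""

import numpy as np
import pytest

import respfatigue as rf
from respfatigue.synth import BreathingPattern, ContaminationSpec


@pytest.fixture(scope="module")
def pattern():
    return BreathingPattern()


class TestBreathingModulation:
    def test_default_pattern_has_15_cycles_per_minute(self, pattern):
        msm = rf.make_breathing_modulation(pattern, 60, 1024)
        # count inspiration onsets: upward crossings of the plateau midpoint
        mid = (1 + pattern.exp_activity) / 2
        above = msm.samples > mid
        onsets = np.sum(~above[:-1] & above[1:]) + int(above[0])
        assert onsets == 15

    def test_expiration_plateau_value(self, pattern):
        msm = rf.make_breathing_modulation(pattern, 60, 1024)
        t_mid_exp = 1.0 + 1.5  # mid-expiration of the first cycle
        assert msm.samples[int(t_mid_exp * 1024)] == pytest.approx(0.3)

    def test_inspiration_plateau_value(self, pattern):
        msm = rf.make_breathing_modulation(pattern, 4, 1024)
        assert msm.samples[int(0.5 * 1024)] == pytest.approx(1.0)

    def test_four_seconds_is_one_period(self, pattern):
        msm = rf.make_breathing_modulation(pattern, 8, 1024)
        np.testing.assert_allclose(
            msm.samples[: 4 * 1024], msm.samples[4 * 1024 :], atol=1e-12
        )

    def test_range_and_smoothness(self, pattern):
        msm = rf.make_breathing_modulation(pattern, 8, 1024)
        assert msm.samples.min() >= 0.3 - 1e-12
        assert msm.samples.max() <= 1.0 + 1e-12
        # no jump exceeds the raised-cosine maximum slope per sample
        max_step = (1 - 0.3) * np.pi / 2 / (0.1 * 1024)
        assert np.max(np.abs(np.diff(msm.samples))) <= max_step * 1.01


class TestVolumeWeighting:
    def test_bounded_in_unit_interval(self, pattern):
        wsc = rf.make_volume_weighting(pattern, 60, 1024)
        assert wsc.samples.min() >= 0 and wsc.samples.max() <= 1

    def test_max_within_inspiration(self, pattern):
        wsc = rf.make_volume_weighting(pattern, 4, 1024)
        t_max = np.argmax(wsc.samples) / 1024
        assert t_max < pattern.insp_duration

    def test_decays_during_expiration(self, pattern):
        wsc = rf.make_volume_weighting(pattern, 4, 1024)
        end_insp = wsc.samples[int(0.99 * 1024)]
        end_exp = wsc.samples[int(3.99 * 1024)]
        assert end_exp < end_insp

    def test_periodic(self, pattern):
        wsc = rf.make_volume_weighting(pattern, 8, 1024)
        np.testing.assert_allclose(
            wsc.samples[: 4 * 1024], wsc.samples[4 * 1024 :], atol=1e-9
        )


class TestEcgMixing:
    def _consts(self, a, b, w, n=1000):
        return (
            rf.SampledSignal(np.full(n, a), 1024),
            rf.SampledSignal(np.full(n, b), 1024),
            rf.SampledSignal(np.full(n, w), 1024),
        )

    @pytest.mark.parametrize(
        "w, expected", [(0.0, 2.0), (1.0, 4.0), (0.5, 3.0)]
    )
    def test_convex_combination_limits(self, w, expected):
        e1, e2, wsc = self._consts(2.0, 4.0, w)
        out = rf.mix_ecg_channels(e1, e2, wsc)
        np.testing.assert_allclose(out.samples, expected)

    def test_convexity_bound(self, regular_ecg):
        e1, e2, _ = regular_ecg
        rng = np.random.default_rng(1)
        wsc = rf.SampledSignal(rng.uniform(0, 1, len(e1)), e1.fs)
        out = rf.mix_ecg_channels(e1, e2, wsc)
        lo = np.minimum(e1.samples, e2.samples)
        hi = np.maximum(e1.samples, e2.samples)
        assert np.all(out.samples >= lo - 1e-9) and np.all(out.samples <= hi + 1e-9)

    def test_length_mismatch_rejected(self):
        e1, e2, w = self._consts(1, 2, 0.5)
        short = rf.SampledSignal(w.samples[:10], 1024)
        with pytest.raises(ValueError):
            rf.mix_ecg_channels(e1, e2, short)


class TestSavgolDenoise:
    def test_reproduces_low_order_polynomial_without_beats(self):
        fs = 1024.0
        t = np.arange(2048) / fs
        x = rf.SampledSignal(3 - 2 * t + 0.5 * t**3, fs)
        out = rf.savgol_ecg_denoise(x, rf.QrsAnnotation(np.array([]), fs))
        interior = slice(20, -20)
        np.testing.assert_allclose(
            out.samples[interior], x.samples[interior], atol=1e-9
        )

    def test_smooths_white_noise(self):
        rng = np.random.default_rng(0)
        x = rf.SampledSignal(rng.standard_normal(4096), 1024)
        out = rf.savgol_ecg_denoise(x, rf.QrsAnnotation(np.array([]), 1024))
        assert out.samples.var() < x.samples.var()

    def test_qrs_window_preserves_sharp_structure_better(self):
        # identical step placed at a beat time and away from any beat: the
        # short sharp filter inside the QRS window tracks it more closely
        fs = 1024.0
        x = np.zeros(4096)
        x[1024:] += 1.0  # step at t = 1 s
        sig = rf.SampledSignal(x, fs)
        with_beat = rf.savgol_ecg_denoise(sig, rf.QrsAnnotation(np.array([1.0]), fs))
        without = rf.savgol_ecg_denoise(sig, rf.QrsAnnotation(np.array([]), fs))
        w = slice(1024 - 30, 1024 + 30)
        err_beat = np.sum((with_beat.samples[w] - x[w]) ** 2)
        err_none = np.sum((without.samples[w] - x[w]) ** 2)
        assert err_beat < err_none

    def test_short_record_rejected(self):
        with pytest.raises(ValueError):
            rf.savgol_ecg_denoise(
                rf.SampledSignal(np.zeros(10), 1024), rf.QrsAnnotation(np.array([]), 1024)
            )


class TestQrsPeakToPeak:
    def test_single_triangular_beat(self):
        fs = 1024.0
        x = np.zeros(2048)
        c = 1024
        x[c - 20 : c] = np.linspace(0, 5.0, 20)
        x[c : c + 20] = np.linspace(5.0, 0, 20)
        ann = rf.QrsAnnotation(np.array([c / fs]), fs)
        assert rf.qrs_peak_to_peak(rf.SampledSignal(x, fs), ann) == pytest.approx(5.0)

    def test_aggregation_is_median(self):
        fs = 1024.0
        x = np.zeros(4096)
        for c, h in ((1024, 1.0), (3072, 1.2)):
            x[c] = h
        ann = rf.QrsAnnotation(np.array([1024 / fs, 3072 / fs]), fs)
        assert rf.qrs_peak_to_peak(rf.SampledSignal(x, fs), ann) == pytest.approx(1.1)

    def test_no_beats_rejected(self):
        x = rf.SampledSignal(np.zeros(100), 1024)
        with pytest.raises(ValueError):
            rf.qrs_peak_to_peak(x, rf.QrsAnnotation(np.array([]), 1024))


class TestTestSignalAssembly:
    def test_gain_arithmetic(self):
        assert rf.contamination_gain(0.2, 1000.0, 50.0) == pytest.approx(4.0)

    def test_eta_to_zero_recovers_pure_ecg(self, regular_ecg, stationary_emg):
        ecg = regular_ecg[0]
        mod = rf.SampledSignal(stationary_emg.samples, 1024)
        spec = ContaminationSpec(eta=1e-9)
        ats = rf.build_test_signal(mod, ecg, spec, 1000.0, rf.rms(stationary_emg))
        assert rf.rms(ats.samples - ecg.samples) < 1e-6 * rf.rms(ecg)

    def test_added_component_rms_matches_eta(self, regular_ecg, stationary_emg):
        # on the unmodulated construction: RMS(ATS - ECG) = eta * qrs_pp
        ecg = regular_ecg[0]
        eta, qrs_pp = 0.1, 1234.5
        spec = ContaminationSpec(eta=eta)
        ats = rf.build_test_signal(
            stationary_emg, ecg, spec, qrs_pp, rf.rms(stationary_emg)
        )
        assert rf.rms(ats.samples - ecg.samples) == pytest.approx(
            eta * qrs_pp, rel=1e-9
        )

    def test_linearity_in_eta(self, regular_ecg, stationary_emg):
        ecg = regular_ecg[0]
        r = rf.rms(stationary_emg)
        a1 = rf.build_test_signal(
            stationary_emg, ecg, ContaminationSpec(eta=0.02), 1000.0, r
        )
        a2 = rf.build_test_signal(
            stationary_emg, ecg, ContaminationSpec(eta=0.1), 1000.0, r
        )
        lhs = a2.samples - a1.samples
        rhs = (0.1 - 0.02) / 0.02 * (a1.samples - ecg.samples)
        np.testing.assert_allclose(lhs, rhs, rtol=1e-9, atol=1e-9)

    def test_reference_signals(self, stationary_emg):
        msm = rf.make_breathing_modulation(BreathingPattern(), 30, 1024)
        mod = rf.SampledSignal(msm.samples * stationary_emg.samples, 1024)
        rsm, rs = rf.build_reference_signals(stationary_emg, mod, 1000.0)
        # RSM / RS == MSM sample-wise (where defined)
        m = np.abs(rs.samples) > 1e-9
        np.testing.assert_allclose(
            rsm.samples[m] / rs.samples[m], msm.samples[m], rtol=1e-9
        )
        # scale equals the eta = 0.2 gain
        g = rf.contamination_gain(0.2, 1000.0, rf.rms(stationary_emg))
        np.testing.assert_allclose(rs.samples, g * stationary_emg.samples, rtol=1e-12)


class TestSurrogateEmg:
    def test_deterministic_under_seed(self):
        spec = rf.SurrogateEmgSpec(duration=5, seed=11)
        a = rf.generate_surrogate_emg(spec)
        b = rf.generate_surrogate_emg(spec)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_stationary_mean_frequency(self, stationary_emg):
        from scipy.signal import welch

        f, p = welch(stationary_emg.samples, 1024, nperseg=1024)
        mnf = np.sum(f * p) / np.sum(p)
        assert abs(mnf - 120) < 5

    def test_programmed_decline(self):
        from scipy.signal import welch

        emg = rf.generate_surrogate_emg(
            rf.SurrogateEmgSpec(duration=60, mnf_start=140, mnf_end=90, seed=3)
        )

        def seg_mnf(seg):
            f, p = welch(seg, 1024, nperseg=1024)
            return np.sum(f * p) / np.sum(p)

        first = seg_mnf(emg.samples[: 10 * 1024])
        last = seg_mnf(emg.samples[-10 * 1024 :])
        assert first - last >= 30

    def test_zero_mean(self, stationary_emg):
        assert abs(stationary_emg.samples.mean()) < 1e-9


class TestSurrogateEcg:
    def test_beat_count_regular(self):
        _, _, ann = rf.generate_surrogate_ecg(
            rf.SurrogateEcgSpec(duration=60, heart_rate=60, beat_jitter=0, seed=0)
        )
        assert len(ann) == 60

    def test_identical_beats_when_regular(self, regular_ecg):
        e1, _, ann = regular_ecg
        fs = e1.fs
        idx = ann.indices()
        seg0 = e1.samples[idx[2] - 300 : idx[2] + 300]
        seg1 = e1.samples[idx[10] - 300 : idx[10] + 300]
        assert np.max(np.abs(seg0 - seg1)) < 1e-9

    def test_irregularity_scales_ptp_variation(self):
        e1, _, ann = rf.generate_surrogate_ecg(
            rf.SurrogateEcgSpec(
                duration=60, beat_jitter=0, shape_irregularity=0.2, seed=7
            )
        )
        fs = e1.fs
        pps = []
        for t in ann.beat_times:
            lo, hi = int((t - 0.05) * fs), int((t + 0.1) * fs)
            pps.append(np.ptp(e1.samples[lo:hi]))
        cv = np.std(pps) / np.mean(pps)
        assert 0.1 <= cv <= 0.4  # within a factor of 2 of the programmed 0.2

    def test_channels_share_beat_times(self, regular_ecg):
        e1, e2, ann = regular_ecg
        fs = e1.fs
        for t in ann.beat_times[:5]:
            w = slice(int((t - 0.05) * fs), int((t + 0.05) * fs))
            assert abs(np.argmax(e1.samples[w]) - np.argmax(e2.samples[w])) <= 3
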