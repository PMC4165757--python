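"""Preprocessing chain, beat detection, period statistics and stability."""

import dataclasses

import numpy as np
import pytest
from scipy import signal as sig

import pupaecg as p

FS = 2604.0


class TestNotch:
    def test_60hz_tone_attenuated_30db(self):
        t = np.arange(int(5 * FS)) / FS
        tone = p.ECGTrace(1e-3 * np.sin(2 * np.pi * 60 * t), FS)
        out = p.notch_filter(tone)
        steady = out.samples[int(FS):]  # discard 1 s transient
        rms_in = np.sqrt(np.mean(tone.samples[int(FS):] ** 2))
        rms_out = np.sqrt(np.mean(steady ** 2))
        assert 20 * np.log10(rms_in / rms_out) >= 30.0

    def test_dc_unity_gain_in_steady_state(self):
        tr = p.ECGTrace(np.full(int(3 * FS), 2.5e-3), FS)
        out = p.notch_filter(tr)
        assert np.allclose(out.samples[-100:], 2.5e-3, atol=1e-9)

    def test_response_minimum_at_60hz_on_centihertz_grid(self):
        b, a = sig.iirnotch(60.0, 10.0, fs=FS)
        grid = np.arange(55.0, 65.0 + 1e-9, 0.01)
        _, h = sig.freqz(b, a, worN=2 * np.pi * grid / FS)
        assert grid[np.argmin(np.abs(h))] == pytest.approx(60.0, abs=0.005)

    def test_nyquist_unity_gain(self):
        b, a = sig.iirnotch(60.0, 10.0, fs=FS)
        for f in (0.0, FS / 2):
            _, h = sig.freqz(b, a, worN=[2 * np.pi * f / FS])
            assert abs(h[0]) == pytest.approx(1.0, abs=1e-9)

    def test_supranyquist_center_rejected(self):
        tr = p.ECGTrace(np.zeros(100), FS)
        with pytest.raises(p.ParameterError):
            p.notch_filter(tr, center_freq=1400.0)


class TestMovingAverage:
    def test_constant_signal_unchanged(self):
        tr = p.ECGTrace(np.full(1000, 3e-3), FS)
        out = p.moving_average(tr, 200)
        assert np.allclose(out.samples, 3e-3, atol=1e-15)

    def test_impulse_spreads_to_uniform_kernel(self):
        y = np.zeros(1001)
        y[500] = 1.0
        out = p.moving_average(p.ECGTrace(y, FS), 200).samples
        nz = np.nonzero(out)[0]
        assert nz.size == 200
        assert np.all(np.diff(nz) == 1)
        assert np.allclose(out[nz], 1.0 / 200)

    def test_white_noise_variance_reduction(self):
        rng = np.random.default_rng(3)
        sd = 1e-3
        tr = p.ECGTrace(rng.normal(0, sd, 100_000), FS)
        out = p.moving_average(tr, 200)
        interior = out.samples[200:-200]
        assert np.std(interior) == pytest.approx(sd / np.sqrt(200), rel=0.10)

    def test_length_preserved_and_window_validated(self):
        tr = p.ECGTrace(np.arange(50.0), FS)
        assert p.moving_average(tr, 7).samples.size == 50
        with pytest.raises(p.ParameterError):
            p.moving_average(tr, 51)
        with pytest.raises(p.ParameterError):
            p.moving_average(tr, 0)


class TestPreprocess:
    def test_zero_in_zero_out(self):
        tr = p.ECGTrace(np.zeros(2000), FS)
        assert np.all(p.preprocess(tr).samples == 0.0)

    def test_powerline_band_power_suppressed(self, clean_train):
        sig_rms = np.sqrt(np.mean(clean_train.samples ** 2))
        dirty = p.add_powerline(clean_train, np.sqrt(2) * sig_rms, 60.0)
        out = p.preprocess(dirty)

        def band_power(y):
            spec = np.abs(np.fft.rfft(y)) ** 2
            freqs = np.fft.rfftfreq(y.size, 1 / FS)
            return spec[(freqs >= 59) & (freqs <= 61)].sum()

        assert band_power(out.samples) <= 0.01 * band_power(dirty.samples)

    def test_linearity(self):
        rng = np.random.default_rng(11)
        x = p.ECGTrace(rng.normal(0, 1e-3, 4000), FS)
        y = p.ECGTrace(rng.normal(0, 1e-3, 4000), FS)
        xy = p.ECGTrace(x.samples + y.samples, FS)
        lhs = p.preprocess(xy).samples
        rhs = p.preprocess(x).samples + p.preprocess(y).samples
        assert np.allclose(lhs, rhs, atol=1e-9)

    def test_time_invariance_interior(self):
        rng = np.random.default_rng(12)
        shift = 300
        x = rng.normal(0, 1e-3, 5000)
        a = p.preprocess(p.ECGTrace(x, FS)).samples
        xs = np.concatenate([np.zeros(shift), x])
        b = p.preprocess(p.ECGTrace(xs, FS)).samples
        # compare interior samples away from both edges
        assert np.allclose(a[500:4500], b[500 + shift:4500 + shift],
                           atol=1e-9)


class TestDetectBeats:
    def test_zero_trace_yields_no_beats(self):
        beats = p.detect_beats(p.ECGTrace(np.zeros(1000), FS))
        assert len(beats) == 0

    def test_noise_free_train_counts_and_periods(self, clean_train):
        beats = p.detect_beats(clean_train)
        assert len(beats) == 20
        assert np.allclose(beats.periods, 0.5, atol=1.0 / FS)

    def test_powerline_contamination_preprocessed_same_count(self, clean_train):
        sig_rms = np.sqrt(np.mean(clean_train.samples ** 2))
        dirty = p.add_powerline(clean_train, np.sqrt(2) * sig_rms, 60.0)
        n_clean = len(p.detect_beats(clean_train))
        n_proc = len(p.detect_beats(p.preprocess(dirty)))
        assert n_proc == n_clean

    @pytest.mark.parametrize("rate", [0.5, 1.0, 2.5, 5.0])
    def test_count_matches_rate_across_band(self, rate, std_shape):
        cfg = p.SyntheticConfig(heart_rate=rate, duration=20.0,
                                beat_shape=std_shape)
        beats = p.detect_beats(p.generate_trace(cfg))
        assert abs(len(beats) - int(20.0 * rate)) <= 1

    def test_invalid_threshold_rejected(self, clean_train):
        with pytest.raises(p.ParameterError):
            p.detect_beats(clean_train, threshold_fraction=1.5)


class TestPeriodSummary:
    def _beats_from_periods(self, periods, start=0.0):
        return p.BeatSeries(start + np.concatenate(([0.0],
                                                    np.cumsum(periods))))

    def test_perfectly_periodic(self):
        beats = self._beats_from_periods(np.full(60, 0.5))
        (s,) = p.period_summary(beats, offsets=[10.0])
        assert s.valid and s.n_cycles == 20
        assert s.mean_period == pytest.approx(0.5)
        assert s.sd_period == 0.0

    def test_jittered_sd_within_chi_square_interval(self):
        rng = np.random.default_rng(5)
        true_sd = 0.010
        periods = 0.5 + rng.normal(0, true_sd, 80)
        beats = self._beats_from_periods(periods)
        (s,) = p.period_summary(beats, offsets=[10.0])
        # 99% chi-square interval for the sample SD at n=20
        from scipy import stats
        n = s.n_cycles
        lo = true_sd * np.sqrt(stats.chi2.ppf(0.005, n - 1) / (n - 1))
        hi = true_sd * np.sqrt(stats.chi2.ppf(0.995, n - 1) / (n - 1))
        assert lo <= s.sd_period <= hi

    def test_short_recording_flags_later_offsets(self):
        beats = self._beats_from_periods(np.full(29, 0.5))  # 14.5 s
        out = p.period_summary(beats, offsets=[10.0, 100.0, 1000.0])
        assert [s.valid for s in out] == [False, False, False] or \
            [s.valid for s in out][1:] == [False, False]
        # only the 10 s offset can have any cycles at all
        assert out[0].n_cycles > 0
        assert out[1].n_cycles == 0 and out[2].n_cycles == 0

    def test_sixty_second_trace_satisfies_first_offset(self):
        beats = self._beats_from_periods(np.full(119, 0.5))  # 59.5 s
        out = p.period_summary(beats)
        assert out[0].valid and out[0].n_cycles >= 20


class TestStability:
    def test_stationary_trace_has_tiny_trend(self, std_shape):
        cfg = p.SyntheticConfig(heart_rate=2.0, duration=300.0,
                                beat_shape=std_shape, seed=1,
                                period_jitter_sd=0.005)
        rep = p.stability_analysis(p.generate_trace(cfg), window=60.0)
        assert abs(rep.amplitude_trend) <= 0.005

    def test_injected_amplitude_drift_recovered(self, std_shape):
        cfg = p.SyntheticConfig(heart_rate=2.0, duration=900.0,
                                beat_shape=std_shape, seed=2,
                                amplitude_drift_rate=0.03)
        rep = p.stability_analysis(p.generate_trace(cfg), window=60.0)
        assert rep.amplitude_trend == pytest.approx(-0.03, rel=0.20)

    def test_drifting_beats_stationary_on_both_metrics(self, std_shape):
        base = dict(heart_rate=2.0, duration=900.0, beat_shape=std_shape,
                    period_jitter_sd=0.003)
        invasive = p.SyntheticConfig(**base, seed=3,
                                     amplitude_drift_rate=0.03,
                                     period_drift_rate=0.02)
        noninvasive = p.SyntheticConfig(**base, seed=3)
        rep_inv = p.stability_analysis(p.generate_trace(invasive))
        rep_non = p.stability_analysis(p.generate_trace(noninvasive))
        assert rep_inv.period_cv > rep_non.period_cv
        assert abs(rep_inv.amplitude_trend) > abs(rep_non.amplitude_trend)

    def test_too_short_trace_rejected(self, clean_train):
        with pytest.raises(p.ParameterError):
            p.stability_analysis(clean_train, window=60.0)
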