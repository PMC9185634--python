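"""RIP preprocessing chain, Hilbert phase and synchrony statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from ripfatigue.rip_pipeline import (
    RIPParams,
    compute_rip_synchrony,
    direct_hilbert_sum,
    discrete_hilbert,
    downsample,
    fir_bandpass,
    masked_sift_first_imf,
    phase_synchrony,
    rolling_correlation,
    synchrony_decile_records,
    wrap_phase,
    znorm_and_smooth,
)
from ripfatigue.signal_model import DecileTable, Recording, TimeSeriesChannel, ValidationError
from ripfatigue.synthetic_data import StudyConfig, gen_recording


def sine_channel(freq, rate, duration, amp=1.0, phase=0.0, label="x"):
    t = np.arange(int(duration * rate)) / rate
    return TimeSeriesChannel(label, amp * np.sin(2 * np.pi * freq * t + phase), rate)


def fft_amplitude(x, rate, freq):
    """Single-bin amplitude estimate at ``freq`` (independent FFT oracle)."""
    n = x.size
    spec = np.fft.rfft(x * np.hanning(n))
    f = np.fft.rfftfreq(n, 1.0 / rate)
    return 2 * np.abs(spec[np.argmin(np.abs(f - freq))]) / np.sum(np.hanning(n))


class TestFIRBandpass:
    def test_in_band_sinusoid_passes(self):
        ch = sine_channel(0.25, 1000.0, 300.0)
        out = fir_bandpass(ch)
        core = slice(60_000, -60_000)  # discard filter transients
        r = np.corrcoef(out.samples[core], ch.samples[core])[0, 1]
        assert r > 0.999

    def test_constant_rejected_exactly(self):
        ch = TimeSeriesChannel("c", np.full(200_000, 7.3), 1000.0)
        out = fir_bandpass(ch)
        assert np.max(np.abs(out.samples)) < 1e-8 * 7.3

    def test_out_of_band_tone_attenuated_40db(self):
        rate, dur = 200.0, 400.0
        t = np.arange(int(dur * rate)) / rate
        x = np.sin(2 * np.pi * 0.25 * t) + np.sin(2 * np.pi * 2.0 * t)
        out = fir_bandpass(TimeSeriesChannel("x", x, rate))
        core = out.samples[int(60 * rate):-int(60 * rate)]
        a_in = fft_amplitude(core, rate, 0.25)
        a_out = fft_amplitude(core, rate, 2.0)
        assert 20 * np.log10(a_in / max(a_out, 1e-300)) >= 40

    def test_short_signal_raises(self):
        with pytest.raises(ValidationError, match="shorter"):
            fir_bandpass(sine_channel(0.25, 1000.0, 5.0))


class TestDownsample:
    def test_sample_count_600s(self):
        ch = TimeSeriesChannel("x", np.zeros(600_000), 1000.0)
        out = downsample(ch, 40.0)
        assert out.samples.size == 24_000
        assert out.sampling_rate == 40.0

    def test_dominant_bin_preserved(self):
        ch = sine_channel(0.25, 1000.0, 120.0)
        out = downsample(ch, 40.0)
        f = np.fft.rfftfreq(out.samples.size, 1 / 40.0)
        peak = f[np.argmax(np.abs(np.fft.rfft(out.samples)))]
        assert abs(peak - 0.25) < 0.02

    def test_matches_sinc_interpolation_oracle(self):
        # band-limited signal: decimation must agree with analytic resampling
        rate, target, dur = 200.0, 40.0, 60.0
        t = np.arange(int(dur * rate)) / rate
        x = np.sin(2 * np.pi * 0.25 * t) + 0.4 * np.sin(2 * np.pi * 0.37 * t + 1.0)
        out = downsample(TimeSeriesChannel("x", x, rate), target)
        t_new = np.arange(out.samples.size) / target
        oracle = np.sin(2 * np.pi * 0.25 * t_new) + 0.4 * np.sin(2 * np.pi * 0.37 * t_new + 1.0)
        core = slice(100, -100)
        r = np.corrcoef(out.samples[core], oracle[core])[0, 1]
        assert r > 0.999

    def test_upsampling_rejected(self):
        with pytest.raises(ValidationError):
            downsample(sine_channel(0.25, 40.0, 30.0), 100.0)


class TestMaskedSift:
    def test_clean_sinusoid_is_its_own_first_imf(self):
        ch = sine_channel(0.25, 40.0, 120.0)
        imf = masked_sift_first_imf(ch)
        assert np.corrcoef(imf.samples, ch.samples)[0, 1] > 0.99

    def test_recovers_oscillation_over_slow_drift(self):
        rate, dur = 40.0, 240.0
        t = np.arange(int(dur * rate)) / rate
        fast = np.sin(2 * np.pi * 0.25 * t)
        drift = 1.5 * np.sin(2 * np.pi * 0.05 * t + 0.3)
        imf = masked_sift_first_imf(TimeSeriesChannel("x", fast + drift, rate))
        assert np.corrcoef(imf.samples, fast)[0, 1] > 0.95

    def test_close_tones_stay_in_one_mode(self):
        # 0.25 + 0.30 Hz are too close to be separate modes; both must remain
        rate, dur = 40.0, 400.0
        t = np.arange(int(dur * rate)) / rate
        x = np.sin(2 * np.pi * 0.25 * t) + np.sin(2 * np.pi * 0.30 * t)
        imf = masked_sift_first_imf(TimeSeriesChannel("x", x, rate))
        for f0 in (0.25, 0.30):
            a_in = fft_amplitude(x, rate, f0)
            a_imf = fft_amplitude(imf.samples, rate, f0)
            assert a_imf > 0.8 * a_in
        assert np.corrcoef(imf.samples, x)[0, 1] > 0.95

    def test_imf_conditions_strict_on_clean_tone(self):
        ch = sine_channel(0.25, 40.0, 200.0)
        imf = masked_sift_first_imf(ch).samples
        sign_changes = int(np.count_nonzero(np.diff(np.sign(imf)) != 0))
        extrema = int(np.count_nonzero(np.diff(np.sign(np.diff(imf))) != 0))
        assert abs(extrema - sign_changes) <= 1

    def test_imf_conditions_on_breathing_trace(self, small_rip_config, rng):
        from scipy.signal import find_peaks

        from ripfatigue.rip_pipeline import mean_envelope

        rec, _ = gen_recording(small_rip_config, 0, rng)
        ch = downsample(fir_bandpass(rec.channels["rip_chest"]), 40.0)
        imf = masked_sift_first_imf(ch).samples
        sign_changes = int(np.count_nonzero(np.diff(np.sign(imf)) != 0))
        # count oscillation extrema, ignoring sub-noise ripples
        prom = 0.05 * np.std(imf)
        extrema = len(find_peaks(imf, prominence=prom)[0]) + \
            len(find_peaks(-imf, prominence=prom)[0])
        assert abs(extrema - sign_changes) <= max(1, 0.05 * sign_changes)
        env = mean_envelope(imf)
        assert np.linalg.norm(env) <= 0.1 * np.linalg.norm(imf)

    def test_too_few_extrema_raise(self):
        with pytest.raises(ValidationError, match="extrema"):
            masked_sift_first_imf(TimeSeriesChannel("x", np.linspace(0, 1, 100), 10.0))


class TestZnormSmooth:
    def test_znorm_exact_before_smoothing(self, rng):
        x = TimeSeriesChannel("x", rng.standard_normal(4000) * 3 + 7, 40.0)
        sd = np.std(x.samples)
        z = (x.samples - x.samples.mean()) / sd
        assert abs(z.mean()) < 1e-9 and abs(z.std() - 1) < 1e-9
        out = znorm_and_smooth(x, 10.0)
        assert out.samples.size == x.samples.size

    def test_spike_attenuated_by_window_length(self):
        rate, win_s = 40.0, 10.0
        x = np.zeros(8000)
        x[4000] = 1.0
        x += np.linspace(-1, 1, 8000) * 1e-6  # avoid zero variance
        out = znorm_and_smooth(TimeSeriesChannel("x", x, rate), win_s)
        sd = np.std(x)
        spike_z = 1.0 / sd
        expected = spike_z / (win_s * rate)
        assert np.isclose(np.max(out.samples), expected, rtol=0.05)

    def test_sinusoid_gain_matches_dirichlet_closed_form(self):
        rate, win_s, f0 = 40.0, 10.0, 0.25
        ch = sine_channel(f0, rate, 400.0)
        out = znorm_and_smooth(ch, win_s)
        m = int(win_s * rate)
        # moving-average gain: Dirichlet kernel |sin(pi f m /fs)| / (m sin(pi f/fs))
        w = np.pi * f0 / rate
        gain = abs(np.sin(m * w) / (m * np.sin(w)))
        amp = np.sqrt(2) * np.std(out.samples[m:-m])
        z_amp = np.sqrt(2) * 1.0  # unit-SD sinusoid has amplitude sqrt(2)
        assert np.isclose(amp / z_amp, gain, rtol=0.01)

    def test_constant_raises(self):
        with pytest.raises(ValidationError):
            znorm_and_smooth(TimeSeriesChannel("x", np.ones(100), 10.0), 1.0)


class TestDiscreteHilbert:
    def test_fast_equals_direct_sum_oracle(self, rng):
        for n in (16, 64, 129, 256):
            x = rng.standard_normal(n)
            fast = discrete_hilbert(x).hilbert
            np.testing.assert_allclose(fast, direct_hilbert_sum(x), atol=1e-9)

    def test_cosine_maps_to_sine_in_interior(self):
        # the truncated-sum transform has O(1/edge-distance) leakage, so the
        # Hilbert-pair identity holds tightly only away from the edges
        n, k = 24000, 600
        i = np.arange(n)
        g = discrete_hilbert(np.cos(2 * np.pi * k * i / n)).hilbert
        target = np.sin(2 * np.pi * k * i / n)
        interior = slice(n // 4, 3 * n // 4)
        assert np.max(np.abs(g - target)[interior]) < 1e-3

    def test_phase_zero_at_cosine_maximum(self):
        n, k = 4096, 64
        i = np.arange(n)
        phase = discrete_hilbert(np.cos(2 * np.pi * k * i / n)).phase
        peaks = np.flatnonzero(np.isclose(np.cos(2 * np.pi * k * i / n), 1.0))
        peaks = peaks[(peaks > n // 4) & (peaks < 3 * n // 4)]
        assert np.max(np.abs(phase[peaks])) < 0.01

    def test_short_input_rejected(self):
        with pytest.raises(ValidationError):
            discrete_hilbert(np.ones(3))


class TestPhaseSynchrony:
    def test_identical_phases_give_one(self, rng):
        p = rng.uniform(-np.pi, np.pi, 500)
        np.testing.assert_array_equal(phase_synchrony(p, p), np.ones(500))

    def test_antiphase_gives_zero(self, rng):
        p = rng.uniform(-np.pi, np.pi, 500)
        np.testing.assert_allclose(phase_synchrony(p, p + np.pi), 0.0, atol=1e-12)

    def test_quarter_turn_closed_form(self):
        p = np.linspace(-3, 3, 100)
        expected = 1 - np.sqrt(2) / 2
        np.testing.assert_allclose(phase_synchrony(p, p + np.pi / 2), expected, atol=1e-12)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValidationError):
            phase_synchrony(np.zeros(3), np.zeros(4))

    @given(st.floats(-50, 50), st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_invariant_to_common_phase_offset(self, c, seed):
        r = np.random.default_rng(seed)
        a = r.uniform(-np.pi, np.pi, 64)
        b = r.uniform(-np.pi, np.pi, 64)
        np.testing.assert_allclose(phase_synchrony(a + c, b + c),
                                   phase_synchrony(a, b), atol=1e-9)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_range_invariant(self, seed):
        r = np.random.default_rng(seed)
        phi = phase_synchrony(r.uniform(-20, 20, 128), r.uniform(-20, 20, 128))
        assert np.all(phi >= 0) and np.all(phi <= 1)

    def test_wrap_maps_to_half_open_interval(self):
        d = wrap_phase(np.array([np.pi, -np.pi, 3 * np.pi, 0.0]))
        assert np.all(d > -np.pi) and np.all(d <= np.pi)


class TestRollingCorrelation:
    def test_self_correlation_is_one(self, rng):
        a = rng.standard_normal(2000)
        r = rolling_correlation(a, a, 1.0, 100.0)
        defined = ~np.isnan(r)
        assert defined.any()
        np.testing.assert_allclose(r[defined], 1.0, atol=1e-9)

    def test_sign_flip_gives_minus_one(self, rng):
        a = rng.standard_normal(2000)
        r = rolling_correlation(a, -a, 1.0, 100.0)
        np.testing.assert_allclose(r[~np.isnan(r)], -1.0, atol=1e-9)

    def test_quadrature_over_full_period_near_zero(self):
        rate, f0 = 100.0, 1.0
        t = np.arange(3000) / rate
        a = np.sin(2 * np.pi * f0 * t)
        b = np.sin(2 * np.pi * f0 * t + np.pi / 2)
        r = rolling_correlation(a, b, 1.0 / f0, rate)
        mid = r[1000:2000]
        assert np.nanmax(np.abs(mid)) < 0.05

    def test_tiny_window_rejected(self):
        with pytest.raises(ValidationError):
            rolling_correlation(np.zeros(100), np.zeros(100), 0.01, 100.0)


class TestFullChain:
    def test_identical_channels_give_perfect_synchrony(self, small_rip_config, rng):
        rec, _ = gen_recording(small_rip_config, 0, rng)
        rec.channels["rip_abdomen"] = rec.channels["rip_chest"].replace(
            samples=rec.channels["rip_chest"].samples.copy(), label="rip_abdomen")
        series = compute_rip_synchrony(rec)
        for s in series.values():
            np.testing.assert_allclose(s.phase_synchrony, 1.0, atol=1e-9)
            r = s.correlation[~np.isnan(s.correlation)]
            np.testing.assert_allclose(r, 1.0, atol=1e-9)

    def test_zero_lag_study_is_highly_synchronous(self, rng):
        cfg = StudyConfig(n_subjects=1, trial_length_s=120.0, rest_length_s=15.0,
                          inter_trial_gap_s=5.0, sampling_rate_hz=200.0,
                          modalities=("rip",), phase_lag_rad=(0.0, 0.0, 0.0),
                          phase_lag_between_sd=0.0, phase_lag_within_sd=0.0)
        rec, _ = gen_recording(cfg, 0, rng)
        for s in compute_rip_synchrony(rec).values():
            r_mean, phi_mean = s.trial_means()
            assert phi_mean > 0.95
            assert r_mean > 0.95

    def test_growing_lag_produces_decreasing_decile_trend(self, rng):
        cfg = StudyConfig(n_subjects=1, trial_length_s=200.0, rest_length_s=15.0,
                          inter_trial_gap_s=5.0, sampling_rate_hz=200.0,
                          modalities=("rip",), phase_lag_rad=(0.0, 0.0, 0.0),
                          phase_lag_drift_rad=(0.0, np.pi), phase_lag_between_sd=0.0,
                          phase_lag_within_sd=0.02)
        rec, _ = gen_recording(cfg, 0, rng)
        series = compute_rip_synchrony(rec)
        table = DecileTable.from_records(synchrony_decile_records(series, "S"))
        for trial in series:
            sub = table.df[(table.df.trial == trial) & (table.df.metric == "rip_synchrony")]
            rho = spearmanr(sub.division, sub.value).statistic
            assert rho < -0.9

    def test_missing_trials_raise(self, tiny_recording):
        rec = Recording("S", dict(tiny_recording.channels), [])
        with pytest.raises(ValidationError, match="trial"):
            compute_rip_synchrony(rec)
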