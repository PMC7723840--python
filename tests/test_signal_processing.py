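import numpy as np
import pytest
import scipy.signal as sps

from pvcouple.core import DCA1_BANDS, MPFC_BANDS, BandDefinition, LfpTrace
from pvcouple.signal_processing import (
    aar_spectrogram,
    ar_spectrum,
    bandpass_filter,
    bandpass_gain,
    detect_events,
    sliding_rms,
    welch_psd,
)
from pvcouple.synthetic import SyntheticConfig, gen_lfp, gen_state_sequence

FS = 1000.0


def make_ar2(f0, r, n, rng, fs=FS):
    a1, a2 = 2 * r * np.cos(2 * np.pi * f0 / fs), -(r**2)
    x = np.zeros(n)
    e = rng.standard_normal(n)
    for i in range(2, n):
        x[i] = a1 * x[i - 1] + a2 * x[i - 2] + e[i]
    return x, np.array([a1, a2])


class TestBandpass:
    def test_zero_trace_maps_to_zero(self):
        out = bandpass_filter(LfpTrace(np.zeros(5000), FS), MPFC_BANDS["theta"])
        assert np.allclose(out.samples, 0.0)

    def test_passband_tone_amplitude_matches_frequency_response(self, tone_trace):
        out = bandpass_filter(tone_trace, MPFC_BANDS["theta"])
        measured = np.abs(out.samples[2000:8000]).max()
        oracle = np.sqrt(bandpass_gain(MPFC_BANDS["theta"], FS, 6.0))
        assert measured == pytest.approx(oracle, rel=0.02)
        assert abs(measured - 1.0) < 0.05  # passband within 5% of unity

    def test_stopband_tone_rejected(self):
        t = np.arange(0, 10.0, 1 / FS)
        trace = LfpTrace(np.sin(2 * np.pi * 60.0 * t), FS)
        out = bandpass_filter(trace, MPFC_BANDS["theta"])
        assert np.abs(out.samples[2000:8000]).max() <= 0.01

    def test_zero_phase_no_lag(self):
        rng = np.random.default_rng(0)
        t = np.arange(0, 20.0, 1 / FS)
        x = np.sin(2 * np.pi * 6.0 * t) + 0.1 * rng.standard_normal(t.size)
        out = bandpass_filter(LfpTrace(x, FS), MPFC_BANDS["theta"])
        ref = np.sin(2 * np.pi * 6.0 * t)
        xc = np.correlate(out.samples[5000:15000], ref[4900:15100], mode="valid")
        assert np.argmax(xc) == 100  # zero lag within the +-100-sample search

    def test_band_above_nyquist_rejected(self):
        trace = LfpTrace(np.zeros(5000), 400.0)
        with pytest.raises(ValueError):
            bandpass_filter(trace, MPFC_BANDS["hfo"])

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            bandpass_filter(LfpTrace(np.zeros(10), FS), MPFC_BANDS["theta"])


class TestSlidingRms:
    def test_constant_trace_gives_abs_value(self):
        _, env = sliding_rms(LfpTrace(np.full(1000, -3.0), FS))
        assert np.allclose(env, 3.0)

    def test_sine_interior_is_inv_sqrt2(self):
        t = np.arange(0, 2.0, 1 / FS)
        _, env = sliding_rms(LfpTrace(np.sin(2 * np.pi * 150.0 * t), FS))
        interior = env[50:-50]
        assert np.all(np.abs(interior - 1 / np.sqrt(2)) < 0.05 / np.sqrt(2))

    def test_unit_impulse_hand_computed(self):
        x = np.zeros(100)
        x[50] = 1.0
        _, env = sliding_rms(LfpTrace(x, FS), window=0.010, step=0.001)
        nonzero = env[env > 0]
        # 10-sample (or 11 centered) windows containing the impulse
        assert np.allclose(nonzero, 1 / np.sqrt(11), atol=0.02)
        assert np.count_nonzero(env > 0) in (10, 11)

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            sliding_rms(LfpTrace(np.zeros(1000), FS), window=-1.0)


class TestDetectEvents:
    def test_zero_trace_yields_no_events(self):
        with pytest.warns(UserWarning):
            events = detect_events(
                LfpTrace(np.zeros(10000), FS), MPFC_BANDS["hfo"], 2.0, 1.0
            )
        assert events == []

    def _noise_with_bursts(self, burst_times, seed=0, duration=30.0, amp_sd=4.0):
        from pvcouple.synthetic import one_over_f_noise

        rng = np.random.default_rng(seed)
        n = int(duration * FS)
        x = 0.05 * one_over_f_noise(n, 1.0, rng)
        trace = LfpTrace(x.copy(), FS)
        filt = bandpass_filter(trace, MPFC_BANDS["hfo"])
        _, env = sliding_rms(filt)
        target = env.mean() + amp_sd * env.std()
        for t0 in burst_times:
            i0 = int(t0 * FS)
            L = int(0.040 * FS)
            tt = np.arange(L) / FS
            x[i0 : i0 + L] += target * np.sqrt(2) * np.hanning(L) * np.sin(
                2 * np.pi * 150.0 * tt
            )
        return LfpTrace(x, FS)

    @staticmethod
    def _overlapping(events, t0, t1):
        return [e for e in events if e.start < t1 and e.end > t0]

    def test_embedded_bursts_recovered_with_tight_boundaries(self):
        burst_times = list(np.arange(2.0, 28.0, 1.3))
        trace = self._noise_with_bursts(burst_times)
        events = detect_events(trace, MPFC_BANDS["hfo"], 2.0, 1.0)
        errors = []
        hits = 0
        for t0 in burst_times:
            over = self._overlapping(events, t0, t0 + 0.040)
            if over:
                hits += 1
                errors += [abs(over[0].start - t0), abs(over[0].end - (t0 + 0.040))]
        assert hits >= 0.9 * len(burst_times)
        assert np.median(errors) <= 0.010

    def test_two_bursts_two_ordered_events(self):
        trace = self._noise_with_bursts([10.0, 10.54])
        events = detect_events(trace, MPFC_BANDS["hfo"], 2.0, 1.0)
        first = self._overlapping(events, 10.0, 10.04)
        second = self._overlapping(events, 10.54, 10.58)
        assert len(first) == 1 and len(second) == 1
        assert first[0].end < second[0].start

    def test_dc_offset_invariance(self):
        trace = self._noise_with_bursts([10.0], seed=3)
        events1 = detect_events(trace, MPFC_BANDS["hfo"], 2.0, 1.0)
        shifted = LfpTrace(trace.samples + 5.0, FS)
        events2 = detect_events(shifted, MPFC_BANDS["hfo"], 2.0, 1.0)
        # DC is rejected to ~1e-8 by the band-pass; a borderline noise event
        # may flip, but the embedded burst must be identical within one step
        assert abs(len(events1) - len(events2)) <= 2
        b1 = self._overlapping(events1, 10.0, 10.04)
        b2 = self._overlapping(events2, 10.0, 10.04)
        assert len(b1) == len(b2) == 1
        assert abs(b1[0].start - b2[0].start) <= 0.002
        assert abs(b1[0].end - b2[0].end) <= 0.002

    def test_event_invariants(self):
        trace = self._noise_with_bursts([5.0, 12.0, 20.0], seed=4)
        events = detect_events(trace, MPFC_BANDS["hfo"], 2.0, 1.0)
        for e in events:
            assert e.start < e.end
            assert e.start <= e.peak_time <= e.end
            assert e.peak_power_sd >= 2.0

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            detect_events(LfpTrace(np.zeros(5000), FS), MPFC_BANDS["hfo"], 1.0, 2.0)


class TestWelch:
    def test_tone_peak_at_nearest_bin(self):
        t = np.arange(0, 10.0, 1 / FS)
        psd = welch_psd(LfpTrace(np.sin(2 * np.pi * 7.0 * t), FS))
        peak = psd.frequencies[np.argmax(psd.power)]
        nearest = psd.frequencies[np.argmin(np.abs(psd.frequencies - 7.0))]
        assert peak == nearest

    def test_zero_trace_zero_power(self):
        psd = welch_psd(LfpTrace(np.zeros(2048), FS))
        assert np.allclose(psd.power, 0.0)

    def test_parseval_white_noise(self):
        rng = np.random.default_rng(12)
        psd = welch_psd(LfpTrace(rng.standard_normal(100_000), FS))
        df = psd.frequencies[1] - psd.frequencies[0]
        assert psd.power.sum() * df == pytest.approx(1.0, rel=0.05)

    def test_power_scales_quadratically(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(20_000)
        p1 = welch_psd(LfpTrace(x, FS)).power.sum()
        p3 = welch_psd(LfpTrace(3 * x, FS)).power.sum()
        assert p3 == pytest.approx(9 * p1, rel=1e-9)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            welch_psd(LfpTrace(np.zeros(100), FS))


class TestAarSpectrogram:
    def test_stationary_ar2_peak_matches_closed_form(self):
        rng = np.random.default_rng(1)
        x, coef = make_ar2(10.0, 0.98, int(60 * FS), rng)
        spec = aar_spectrogram(
            LfpTrace(x, FS), p=2, freq_grid=np.arange(0.5, 200.0, 0.25)
        )
        est = spec.mean_spectrum(5.0, 60.0)
        peak_est = est.frequencies[np.argmax(est.power)]
        fine = np.arange(0.5, 200.0, 0.01)
        peak_true = fine[np.argmax(ar_spectrum(coef, 1.0, FS, fine))]
        assert abs(peak_est - peak_true) <= 1.0

    def test_white_noise_small_state_noise_approaches_yule_walker(self):
        rng = np.random.default_rng(5)
        w = rng.standard_normal(int(30 * FS))
        spec = aar_spectrogram(LfpTrace(w, FS), p=2, sigma_w2=1e-10, smooth=False)
        r = np.array([w[: w.size - k] @ w[k:] / w.size for k in range(3)])
        yw = np.linalg.solve([[r[0], r[1]], [r[1], r[0]]], r[1:])
        assert np.abs(spec.coefficients[-1] - yw).max() < 0.05

    def test_switching_resonance_tracked_within_2s(self):
        x1, _ = make_ar2(6.0, 0.98, int(30 * FS), np.random.default_rng(2))
        x2, _ = make_ar2(150.0, 0.98, int(30 * FS), np.random.default_rng(3))
        spec = aar_spectrogram(
            LfpTrace(np.concatenate([x1, x2]), FS),
            p=2,
            freq_grid=np.arange(1.0, 300.0, 0.5),
        )
        pk = spec.peak_frequency()
        after_burn = spec.times >= 5.0
        crossings = spec.times[after_burn][pk[after_burn] > 78.0]
        assert crossings.size > 0
        assert abs(crossings[0] - 30.0) <= 2.0

    def test_pure_tone_power_concentration(self):
        rng = np.random.default_rng(4)
        t = np.arange(0, 20.0, 1 / FS)
        x = np.sin(2 * np.pi * 40.0 * t) + 0.01 * rng.standard_normal(t.size)
        spec = aar_spectrogram(
            LfpTrace(x, FS), p=2, freq_grid=np.arange(1.0, 300.0, 0.5)
        )
        burn = spec.times > 5.0
        f = spec.frequencies
        near = np.abs(f - 40.0) <= 5.0
        frac = spec.power[burn][:, near].sum(axis=1) / spec.power[burn].sum(axis=1)
        assert np.median(frac) >= 0.8

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError):
            aar_spectrogram(LfpTrace(np.zeros(50), FS), p=10)
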