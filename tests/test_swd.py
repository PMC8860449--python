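import numpy as np
import pytest

from swdlab.io_formats import CoarseEvent, Recording
from swdlab.pipeline import coarse_from_truth
from swdlab.swd import (
    BaselineError,
    DetectionConfig,
    SwdEvent,
    atonia_check,
    event_duration,
    event_frequency,
    find_peaks_abs,
    harmonic_score,
    min_duration_filter,
    process_events,
    refine_bounds,
    rms_baseline,
    spectrogram,
)
from swdlab.synth import pink_noise, swd_waveform

from conftest import FS, embedded_event


def _mk_event(duration: float) -> SwdEvent:
    return SwdEvent(
        t_onset=0.0, t_offset=duration, duration=duration, dominant_freq=7.0,
        harmonic_score=3.0, is_harmonic=True, atonia_ok=True,
        rms_baseline=1.0, threshold=2.5,
    )


class TestRmsBaseline:
    def test_constant_signal_is_zero(self):
        x = np.full(int(20 * FS), 3.7)
        assert rms_baseline(x, FS, 15.0) == pytest.approx(0.0)

    def test_sine_closed_form(self):
        """A sine of amplitude A over whole cycles has RMS A/√2."""
        amp, f = 4.0, 5.0
        t = np.arange(int(20 * FS)) / FS
        x = amp * np.sin(2 * np.pi * f * t)
        assert rms_baseline(x, FS, 10.0, 10.0) == pytest.approx(
            amp / np.sqrt(2), rel=1e-3
        )

    def test_matches_direct_loop(self, rng):
        """Brute-force oracle: element-by-element accumulation."""
        x = rng.standard_normal(int(20 * FS))
        got = rms_baseline(x, FS, 15.0, 10.0)
        w = x[int(5 * FS) : int(15 * FS)]
        m = sum(w) / len(w)
        acc = 0.0
        for v in w:
            acc += (v - m) ** 2
        assert got == pytest.approx(np.sqrt(acc / len(w)), rel=1e-12)

    def test_window_before_start_errors(self, rng):
        x = rng.standard_normal(int(5 * FS))
        with pytest.raises(BaselineError, match="truncate"):
            rms_baseline(x, FS, 1.0, 10.0, truncate=False)

    def test_truncation_down_to_minimum(self, rng):
        x = rng.standard_normal(int(5 * FS))
        assert rms_baseline(x, FS, 3.0, 10.0, truncate=True) > 0


class TestRefineBounds:
    def test_recovers_injected_bounds_within_one_cycle(self, rng):
        """Nearly all refined bounds fall within one cycle of the truth;
        occasional background crests adjacent to the event may not."""
        ok = 0
        n = 20
        for _ in range(n):
            x, coarse, (t0, t1, f0) = embedded_event(rng)
            r = refine_bounds(x, FS, coarse)
            assert r is not None
            t_on, t_off, base, thr = r
            assert thr == pytest.approx(2.5 * base)
            ok += abs(t_on - t0) <= 1.0 / f0 and abs(t_off - t1) <= 1.0 / f0
        assert ok >= n - 2

    def test_pure_background_rejected(self, rng):
        """Background windows almost never sustain 2.5× RMS for 0.5 s."""
        rejected = 0
        for _ in range(50):
            x = pink_noise(int(20 * FS), FS, 2.0, 1.0, rng)
            r = refine_bounds(x, FS, CoarseEvent(12.0, 16.0), 2.5, 10.0)
            rejected += r is None
        assert rejected >= 45

    def test_infinite_multiplier_rejects_everything(self, rng):
        x, coarse, _ = embedded_event(rng)
        assert refine_bounds(x, FS, coarse, multiplier=1e12) is None

    def test_multiplier_zero_gives_first_and_last_local_maxima(self, rng):
        x, coarse, _ = embedded_event(rng)
        r = refine_bounds(x, FS, coarse, multiplier=0.0)
        i0 = int(round(coarse.t_start * FS))
        seg = x[i0 : int(round(coarse.t_end * FS))]
        peaks = find_peaks_abs(seg)
        assert r[0] == pytest.approx((i0 + peaks[0]) / FS)
        assert r[1] == pytest.approx((i0 + peaks[-1]) / FS)

    def test_duration_monotone_in_multiplier(self, rng):
        """Raising the threshold can only shrink the refined event."""
        x, coarse, _ = embedded_event(rng)
        last = np.inf
        for m in [0.0, 1.0, 2.5, 4.0, 6.0]:
            r = refine_bounds(x, FS, coarse, multiplier=m)
            dur = (r[1] - r[0]) if r is not None else 0.0
            assert dur <= last + 1e-12
            last = dur

    def test_scale_invariance(self, rng):
        """Scaling the whole trace by c > 0 leaves the bounds unchanged."""
        x, coarse, _ = embedded_event(rng)
        r1 = refine_bounds(x, FS, coarse)
        r2 = refine_bounds(37.5 * x, FS, coarse)
        assert r1[:2] == r2[:2]


class TestDurationAndFrequency:
    def test_duration_is_subtraction(self):
        assert event_duration(10.0, 15.3) == pytest.approx(5.3)
        with pytest.raises(ValueError):
            event_duration(15.3, 10.0)

    def test_pure_cosine_exact_at_matching_resolution(self):
        t = np.arange(int(10 * FS)) / FS
        x = np.cos(2 * np.pi * 6.0 * t)
        f, low = event_frequency(x, FS, 0.0, 10.0)
        assert f == pytest.approx(6.0, abs=1e-9)
        assert not low

    def test_equal_power_tie_breaks_low(self):
        t = np.arange(int(10 * FS)) / FS
        x = np.cos(2 * np.pi * 5.0 * t) + np.cos(2 * np.pi * 9.0 * t)
        f, _ = event_frequency(x, FS, 0.0, 10.0)
        assert f == pytest.approx(5.0, abs=0.05)

    def test_noiseless_comb_grid_within_resolution(self):
        """Harmonic combs across the 5–8 Hz grid recover f0 to ≤ 0.1 Hz."""
        for f0 in np.arange(5.0, 8.01, 0.5):
            w = swd_waveform(f0, 5.0, 4, 0.6, FS, rng=3)
            f, _ = event_frequency(w, FS, 0.0, 5.0)
            assert abs(f - f0) <= 0.1, f0

    def test_short_segment_flagged_low_confidence(self, rng):
        x = rng.standard_normal(int(2 * FS))
        _, low = event_frequency(x, FS, 0.0, 0.2)
        assert low

    def test_recovered_duration_of_injected_events(self, rng):
        """Over synthetic events, duration error stays within two cycles."""
        ok = 0
        n = 50
        for _ in range(n):
            dur = float(rng.uniform(2.5, 8.0))
            x, coarse, (t0, t1, f0) = embedded_event(rng, duration=dur)
            r = refine_bounds(x, FS, coarse)
            if r is None:
                continue
            ok += abs((r[1] - r[0]) - dur) <= 2.0 / f0
        assert ok >= int(0.9 * n)


class TestMinDurationFilter:
    def test_boundary_inclusive(self):
        events = [_mk_event(d) for d in (1.9, 2.0, 5.3)]
        kept = min_duration_filter(events)
        assert [e.duration for e in kept] == [2.0, 5.3]

    def test_empty_and_zero_threshold(self):
        assert min_duration_filter([]) == []
        events = [_mk_event(d) for d in (0.5, 1.0)]
        assert min_duration_filter(events, min_s=0.0) == events

    def test_idempotent(self):
        events = [_mk_event(d) for d in (1.0, 2.5, 3.0, 0.2)]
        once = min_duration_filter(events)
        assert min_duration_filter(once) == once


class TestAtonia:
    def test_atonia_event_passes(self, rng):
        emg = rng.standard_normal(int(30 * FS))
        emg[int(15 * FS) : int(20 * FS)] *= 0.2
        assert atonia_check(emg, FS, 15.0, 20.0)

    def test_unchanged_emg_fails(self, rng):
        emg = rng.standard_normal(int(30 * FS))
        assert not atonia_check(emg, FS, 15.0, 20.0)

    def test_drop_fraction_one_accepts_any_attenuation(self, rng):
        """With drop_fraction 1, any atonia factor ≤ 1 passes (brute force
        over 100 random attenuations of a constant-amplitude EMG tone)."""
        t = np.arange(int(30 * FS)) / FS
        tone = np.sin(2 * np.pi * 40.0 * t)
        for _ in range(100):
            frac = rng.uniform(0.0, 1.0)
            emg = tone.copy()
            emg[int(15 * FS) : int(20 * FS)] *= frac
            assert atonia_check(emg, FS, 15.0, 20.0, drop_fraction=1.0)


class TestSpectrogram:
    def test_tone_ridge_in_every_column(self):
        t = np.arange(int(30 * FS)) / FS
        x = np.cos(2 * np.pi * 7.0 * t)
        spec = spectrogram(x, FS)
        ridge = spec.freqs[np.argmax(spec.power, axis=1)]
        np.testing.assert_allclose(ridge, 7.0, atol=1.0)

    def test_silence_gives_zero_power(self):
        spec = spectrogram(np.zeros(int(10 * FS)), FS)
        assert spec.power.max() == 0.0

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(ValueError, match="window"):
            spectrogram(np.zeros(100), FS, window_s=1.0)

    def test_matches_independent_windowed_periodogram(self, rng):
        """Column oracle: hand-computed Hann periodogram of the same slice."""
        x = rng.standard_normal(int(10 * FS))
        spec = spectrogram(x, FS, window_s=1.0, overlap_fraction=0.5)
        nperseg = int(FS)
        col = 3
        start = col * (nperseg // 2)
        seg = x[start : start + nperseg]
        seg = seg - seg.mean()
        win = np.hanning(nperseg + 1)[:-1]  # periodic Hann, as used for PSDs
        X = np.fft.rfft(seg * win)
        psd = (np.abs(X) ** 2) / (FS * np.sum(win**2))
        psd[1:-1] *= 2.0
        np.testing.assert_allclose(spec.power[col], psd, rtol=1e-7, atol=1e-12)


class TestHarmonicScore:
    def test_synthetic_swd_is_harmonic(self, rng):
        x, coarse, (t0, t1, f0) = embedded_event(rng, f0=6.0, duration=6.0)
        spec = spectrogram(x, FS)
        score, is_harm = harmonic_score(spec, t0, t1)
        assert is_harm and score > 2.0

    def test_pure_sinusoid_is_not_harmonic(self):
        t = np.arange(int(20 * FS)) / FS
        x = np.cos(2 * np.pi * 6.0 * t)
        spec = spectrogram(x, FS)
        _, is_harm = harmonic_score(spec, 5.0, 15.0)
        assert not is_harm

    def test_slow_wave_surrogate_not_harmonic(self, rng):
        """Band-limited 1–4 Hz noise mimics slow-wave sleep, not a SWD."""
        from scipy.signal import butter, filtfilt

        b, a = butter(4, [1.0, 4.0], btype="band", fs=FS)
        false_pos = 0
        n = 40
        for _ in range(n):
            x = filtfilt(b, a, rng.standard_normal(int(20 * FS)))
            spec = spectrogram(x, FS)
            _, is_harm = harmonic_score(spec, 5.0, 15.0)
            false_pos += is_harm
        assert false_pos <= 2


class TestProcessEvents:
    def test_recall_and_precision_on_synthetic_session(self, short_session):
        rec, truth = short_session
        rng = np.random.default_rng(5)
        coarse = coarse_from_truth(truth.events, 1.0, 1.0, rng)
        events, rejections = process_events(rec, coarse)
        truth_long = [e for e in truth.events if e.duration >= 2.0]

        def overlap(a, b):
            inter = min(a.t_offset, b.t_end) - max(a.t_onset, b.t_start)
            return inter / max(b.duration, 1e-9)

        matched = sum(
            any(overlap(d, t) >= 0.5 for d in events) for t in truth_long
        )
        assert len(truth_long) >= 3
        assert matched / len(truth_long) >= 0.9
        false = sum(
            not any(overlap(d, t) >= 0.5 for t in truth_long) for d in events
        )
        assert false == 0

    def test_no_coarse_events_gives_empty_output(self, small_recording):
        events, rejections = process_events(small_recording, [])
        assert events == [] and rejections == []

    def test_short_events_rejected_with_log(self, rng):
        """Sub-2 s discharges are dropped and the rejection names the stage."""
        x, coarse, _ = embedded_event(rng, duration=1.0)
        rec = Recording({"ecog": x}, fs=FS)
        events, rejections = process_events(rec, [coarse])
        assert events == []
        assert any(r.stage == "min_duration" for r in rejections) or any(
            r.stage == "refine" for r in rejections
        )

    def test_missing_emg_skips_atonia_nonstrict(self, rng):
        x, coarse, _ = embedded_event(rng)
        rec = Recording({"ecog": x}, fs=FS)
        events, _ = process_events(rec, [coarse])
        assert len(events) == 1 and events[0].atonia_ok

    def test_strict_mode_requires_emg(self, rng):
        x, coarse, _ = embedded_event(rng)
        rec = Recording({"ecog": x}, fs=FS)
        cfg = DetectionConfig(atonia_strict=True)
        events, rejections = process_events(rec, [coarse], cfg)
        assert events == []
        assert any(r.stage == "atonia" for r in rejections)
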