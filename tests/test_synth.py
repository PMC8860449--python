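import numpy as np
import pytest
from scipy import signal as sps

from swdlab.io_formats import Epoch, ProtocolTimeline
from swdlab.synth import (
    LaserConfig,
    SynthConfig,
    default_protocol,
    draw_events,
    generate_session,
    laser_schedule,
    pink_noise,
    swd_waveform,
)

FS = 200.0


class TestSwdWaveform:
    def test_dominant_frequency_at_f0(self):
        w = swd_waveform(7.0, 4.0, 4, 0.6, FS, rng=0)
        freqs = np.fft.rfftfreq(w.size, 1 / FS)
        power = np.abs(np.fft.rfft(w)) ** 2
        band = (freqs >= 4) & (freqs <= 12)
        assert freqs[band][np.argmax(power[band])] == pytest.approx(7.0, abs=FS / w.size)

    def test_single_harmonic_is_pure_tone(self):
        w = swd_waveform(6.0, 5.0, 1, 0.5, FS, rng=0)
        freqs = np.fft.rfftfreq(w.size, 1 / FS)
        power = np.abs(np.fft.rfft(w)) ** 2
        peak = power.max()
        # away from the 6 Hz mainlobe everything is envelope leakage
        far = np.abs(freqs - 6.0) > 1.0
        assert power[far].max() < 1e-3 * peak

    def test_harmonic_decay_sets_power_ratio(self):
        """decay = 0.5 ⇒ power at 2·f0 is ≈ 0.25 × power at f0."""
        w = swd_waveform(7.0, 8.0, 2, 0.5, FS, rng=1)
        freqs, power = sps.periodogram(w, FS)
        p1 = power[np.abs(freqs - 7.0) < 0.5].max()
        p2 = power[np.abs(freqs - 14.0) < 0.5].max()
        assert p2 / p1 == pytest.approx(0.25, rel=0.10)

    def test_harmonic_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            swd_waveform(30.0, 2.0, 4, 0.6, FS)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            swd_waveform(7.0, 0.0, 4, 0.6, FS)


class TestLaserSchedule:
    def test_one_cycle_forty_pulses(self):
        """20 Hz for 2 s then 2 s off: 40 pulses, all inside [0, 2)."""
        pulses = laser_schedule(LaserConfig(total_min=4 / 60))
        assert len(pulses) == 40
        assert all(0.0 <= t_on < 2.0 for t_on, _ in pulses)
        widths = {round(t_off - t_on, 6) for t_on, t_off in pulses}
        assert widths == {0.010}

    def test_zero_duration_empty(self):
        assert laser_schedule(LaserConfig(total_min=0.0)) == []

    def test_sixty_seconds_gives_fifteen_trains(self):
        pulses = laser_schedule(LaserConfig(total_min=1.0))
        assert len(pulses) == 15 * 40
        trains = {int(t_on // 4) for t_on, _ in pulses}
        assert len(trains) == 15

    def test_closed_form_count_arbitrary_durations(self):
        """Enumerated count matches the closed form for any total duration."""
        cfg = LaserConfig()
        period, on, cycle = 0.05, 2.0, 4.0
        for total_s in [0.0, 0.03, 1.0, 2.0, 2.5, 3.99, 4.0, 7.3, 61.0, 123.45]:
            expected = 0
            k = 0
            while k * cycle < total_s:
                start = k * cycle
                expected += sum(
                    1
                    for i in range(int(np.ceil(on / period)))
                    if start + i * period < min(start + on, total_s)
                )
                k += 1
            got = len(laser_schedule(LaserConfig(total_min=total_s / 60.0)))
            assert got == expected, total_s

    def test_pulse_width_must_fit_period(self):
        with pytest.raises(ValueError, match="period"):
            laser_schedule(LaserConfig(pulse_width_s=0.06))


class TestBackground:
    def test_spectral_slope_matches_exponent(self):
        """Log-log periodogram slope over 1–50 Hz ≈ −α (averaged seeds)."""
        alpha = 2.0
        psds = []
        for seed in range(10):
            x = pink_noise(int(120 * FS), FS, alpha, 1.0, np.random.default_rng(seed))
            freqs, power = sps.welch(x, FS, nperseg=int(8 * FS))
            psds.append(power)
        power = np.mean(psds, axis=0)
        band = (freqs >= 1.0) & (freqs <= 50.0)
        slope = np.polyfit(np.log(freqs[band]), np.log(power[band]), 1)[0]
        assert slope == pytest.approx(-alpha, abs=0.2)

    def test_target_rms(self, rng):
        x = pink_noise(int(60 * FS), FS, 2.0, 50.0, rng)
        assert np.std(x) == pytest.approx(50.0, rel=1e-6)


class TestGenerateSession:
    def test_zero_rate_gives_pure_background(self):
        cfg = SynthConfig(session_length=120.0, seed=3)
        cfg.swd.rate_per_bin = {}
        rec, truth = generate_session(cfg)
        assert truth.events == []
        assert np.std(rec["ecog"]) == pytest.approx(
            cfg.background.amplitude_uV, rel=1e-6
        )

    def test_fixed_seed_bitwise_identical(self):
        cfg = SynthConfig(session_length=120.0, seed=11)
        rec1, truth1 = generate_session(cfg)
        rec2, truth2 = generate_session(cfg)
        for role in rec1.channels:
            np.testing.assert_array_equal(rec1[role], rec2[role])
        assert truth1.events == truth2.events

    def test_events_non_overlapping_and_contained(self):
        """Injected events never overlap and always fit the session."""
        base = np.random.SeedSequence(77)
        for i, child in enumerate(base.spawn(50)):
            rng = np.random.default_rng(child)
            length = float(rng.uniform(300, 1200))
            protocol = default_protocol(length)
            cfg = SynthConfig(session_length=length, seed=i)
            cfg.swd.rate_per_bin = {
                "normoxia": float(rng.uniform(0, 4)),
                "hypoxia": float(rng.uniform(0, 4)),
            }
            events = draw_events(protocol, cfg.swd, rng, length)
            for ev in events:
                assert 0.0 <= ev.t_start < ev.t_end <= length
            for a, b in zip(events, events[1:]):
                assert a.t_end <= b.t_start

    def test_respiration_rate_matches_schedule_by_zero_crossings(self):
        """Zero-crossing breathing rate within 2% of the schedule segment."""
        cfg = SynthConfig(session_length=600.0, seed=5)
        cfg.swd.rate_per_bin = {}
        rec, truth = generate_session(cfg)
        resp = rec["resp"]
        for t0, t1, rate in truth.resp_schedule:
            seg = resp[int(t0 * FS) : int(t1 * FS)]
            crossings = np.sum(np.diff(np.signbit(seg).astype(int)) != 0)
            empirical = crossings / 2.0 / (t1 - t0)
            assert empirical == pytest.approx(rate, rel=0.02)

    def test_gas_channels_relax_to_condition_targets(self):
        cfg = SynthConfig(session_length=900.0, seed=6)
        cfg.swd.rate_per_bin = {}
        rec, truth = generate_session(cfg)
        t_zero = truth.condition_timeline.t_zero
        # several time constants after the switch, O2 has settled near 10%
        i = int((t_zero + 5 * cfg.gas.exchange_tau_s) * FS)
        assert rec["gas_o2"][i] == pytest.approx(10.0, abs=0.2)
        assert rec["gas_o2"][int(t_zero * FS) - 1] == pytest.approx(21.0, abs=0.2)

    def test_emg_drops_during_events(self):
        cfg = SynthConfig(session_length=600.0, seed=8)
        cfg.swd.rate_per_bin = {"normoxia": 3.0, "hypoxia": 3.0}
        rec, truth = generate_session(cfg)
        assert truth.events, "expected at least one injected event"
        emg = rec["emg"]
        ev = truth.events[0]
        seg = emg[int(ev.t_start * FS) : int(ev.t_end * FS)]
        before = emg[int((ev.t_start - 5) * FS) : int(ev.t_start * FS)]
        assert np.std(seg) < 0.5 * np.std(before)

    def test_event_rate_matches_poisson_parameter(self):
        """Mean post-switch bin count over many draws ≈ configured 1.73."""
        protocol = default_protocol(3600.0)
        cfg = SynthConfig(session_length=3600.0)
        counts = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            events = draw_events(protocol, cfg.swd, rng, 3600.0)
            post = [e for e in events if e.t_start >= 2400.0]
            counts.append(len(post) / 4.0)  # 4 five-min bins in 20 min
        mean = np.mean(counts)
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(mean - 1.73) < 2 * se + 0.05

    def test_session_shorter_than_protocol_rejected(self):
        protocol = ProtocolTimeline(
            epochs=[Epoch(0, 2400, "normoxia"), Epoch(2400, 3600, "hypoxia")],
            t_zero=2400.0,
        )
        with pytest.raises(ValueError, match="session"):
            generate_session(
                SynthConfig(session_length=600.0, protocol=protocol, seed=0)
            )

    def test_laser_channel_pulses_only_in_photostim_epochs(self):
        protocol = ProtocolTimeline(
            epochs=[
                Epoch(0, 60, "normoxia"),
                Epoch(60, 120, "normoxia_photostim"),
            ],
            t_zero=60.0,
        )
        cfg = SynthConfig(session_length=120.0, protocol=protocol, seed=9)
        cfg.swd.rate_per_bin = {}
        rec, _ = generate_session(cfg)
        laser = rec["laser"]
        assert laser[: int(60 * FS)].max() == 0.0
        on = laser[int(60 * FS) : int(62 * FS)]
        assert on.max() == 1.0
        # duty cycle within the 2 s train: 10 ms of every 50 ms
        assert on.mean() == pytest.approx(0.2, abs=0.03)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            SynthConfig(fs=50.0)  # default harmonics exceed 25 Hz
        cfg_kwargs = dict(session_length=60.0)
        cfg = SynthConfig(**cfg_kwargs)
        cfg.emg.atonia_fraction = 1.5
        with pytest.raises(ValueError, match="atonia"):
            SynthConfig(**cfg_kwargs, emg=cfg.emg)
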