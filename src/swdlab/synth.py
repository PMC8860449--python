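"""Synthetic ECoG/EMG/plethysmography session generator with ground truth.

Emulates the statistical structure the downstream analysis assumes: 5–8 Hz
harmonic-comb spike-wave bursts with EMG atonia embedded in 1/f^α cortical
background, a breathing trace whose instantaneous rate follows a per-condition
schedule, exponential chamber-gas exchange, and a 20 Hz / 10 ms optogenetic
pulse train gated 2 s on / 2 s off.  Every session comes with a
:class:`GroundTruth` record (injected events, true breathing schedule,
condition timeline) so each pipeline stage has an oracle.

Default condition parameters are seeded from the study conditions this
generator emulates: spike-wave event rates of 0.89 / 1.73 / 0.95 per 5-min
bin and breathing rates of 1.03 / 1.33 / 1.78 Hz for normoxia / hypoxia /
hypercapnia.  They are configurable defaults, not assertions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_formats import Epoch, ProtocolTimeline, Recording

__all__ = [
    "BackgroundConfig",
    "SwdGenConfig",
    "EmgConfig",
    "RespGenConfig",
    "GasConfig",
    "LaserConfig",
    "SynthConfig",
    "InjectedEvent",
    "GroundTruth",
    "swd_waveform",
    "laser_schedule",
    "draw_events",
    "generate_session",
    "default_protocol",
    "pink_noise",
]

PSTH_BIN_S = 300.0  # the 5-min bin that per-condition event rates refer to

#: Conditions during which the laser channel carries the pulse train.
LASER_CONDITIONS = frozenset(
    {"laser_on", "photostim", "normoxia_photostim", "hypercapnia_photostim"}
)


@dataclass
class BackgroundConfig:
    """1/f^α Gaussian ECoG background.

    ``noise_exponent`` is the power-spectral slope α (PSD ∝ f^−α); 2.0 is the
    textbook cortical field-potential slope over 1–50 Hz.  ``amplitude_uV``
    is the target RMS.
    """

    noise_exponent: float = 2.0
    amplitude_uV: float = 50.0


@dataclass
class SwdGenConfig:
    """Spike-wave burst morphology and per-condition occurrence rates.

    Rates are events per 5-min bin (per condition); the waveform is a
    harmonic comb at fundamental f0 with geometric amplitude decay.
    ``amplitude_uV`` is the fundamental's amplitude; at the default background
    RMS of 50 µV the default corresponds to an SNR (fundamental amplitude /
    background RMS) of 10.
    """

    rate_per_bin: dict[str, float] = field(
        default_factory=lambda: {
            "normoxia": 0.89,
            "hypoxia": 1.73,
            "hypoxia_co2": 0.84,
            "hypercapnia": 0.95,
            "normoxia_photostim": 2.27,
        }
    )
    f0_range: tuple[float, float] = (5.0, 8.0)
    n_harmonics: int = 4
    harmonic_decay: float = 0.6
    duration_mean_s: float = 5.3
    duration_sd_s: float = 2.0
    amplitude_uV: float = 500.0
    ramp_s: float = 0.1
    min_gap_s: float = 1.0


@dataclass
class EmgConfig:
    """Nuchal EMG: broadband tone that collapses during events (atonia)."""

    tone_uV: float = 30.0
    atonia_fraction: float = 0.2


@dataclass
class RespGenConfig:
    """Breathing-rate schedule: per-condition mean rate plus slow jitter."""

    rate_by_condition: dict[str, float] = field(
        default_factory=lambda: {
            "normoxia": 1.03,
            "hypoxia": 1.33,
            "hypoxia_co2": 1.88,
            "hypercapnia": 1.78,
            "normoxia_photostim": 1.24,
        }
    )
    rate_jitter_sd: float = 0.02
    jitter_node_s: float = 10.0


@dataclass
class GasConfig:
    """Chamber O₂/CO₂ relax exponentially to each epoch's target (%)."""

    exchange_tau_s: float = 30.0
    o2_by_condition: dict[str, float] = field(
        default_factory=lambda: {
            "normoxia": 21.0,
            "hypoxia": 10.0,
            "hypoxia_co2": 10.0,
            "hypercapnia": 21.0,
            "normoxia_photostim": 21.0,
        }
    )
    co2_by_condition: dict[str, float] = field(
        default_factory=lambda: {
            "normoxia": 0.0,
            "hypoxia": 0.0,
            "hypoxia_co2": 5.0,
            "hypercapnia": 5.0,
            "normoxia_photostim": 0.0,
        }
    )


@dataclass
class LaserConfig:
    """Optogenetic pulse train: 10 ms pulses at 20 Hz, gated 2 s on / 2 s off."""

    pulse_rate_hz: float = 20.0
    pulse_width_s: float = 0.010
    train_on_s: float = 2.0
    train_off_s: float = 2.0
    total_min: float = 15.0


@dataclass
class SynthConfig:
    """Full configuration for one synthetic session."""

    fs: float = 200.0
    session_length: float = 3600.0
    background: BackgroundConfig = field(default_factory=BackgroundConfig)
    swd: SwdGenConfig = field(default_factory=SwdGenConfig)
    emg: EmgConfig = field(default_factory=EmgConfig)
    resp: RespGenConfig = field(default_factory=RespGenConfig)
    gas: GasConfig = field(default_factory=GasConfig)
    laser: LaserConfig = field(default_factory=LaserConfig)
    protocol: ProtocolTimeline | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.swd.f0_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid f0_range {self.swd.f0_range}")
        if hi * self.swd.n_harmonics >= self.fs / 2:
            raise ValueError(
                f"highest harmonic {hi * self.swd.n_harmonics} Hz is at or above "
                f"Nyquist ({self.fs / 2} Hz)"
            )
        if any(r < 0 for r in self.swd.rate_per_bin.values()):
            raise ValueError("event rates must be non-negative")
        if not 0.0 <= self.emg.atonia_fraction <= 1.0:
            raise ValueError("atonia_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class InjectedEvent:
    t_start: float
    t_end: float
    f0: float

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class GroundTruth:
    """The generator's oracle: what was injected and when."""

    events: list[InjectedEvent]
    resp_schedule: list[tuple[float, float, float]]  # (t_start, t_end, rate Hz)
    condition_timeline: ProtocolTimeline


def default_protocol(session_length: float) -> ProtocolTimeline:
    """Two-epoch gas-exchange protocol: normoxia then hypoxia, t_zero at the
    boundary.  A 60-min session gives the study's 40 min / 20 min geometry;
    other lengths keep the 2:1 split."""
    t_switch = session_length * (2.0 / 3.0)
    return ProtocolTimeline(
        epochs=[
            Epoch(0.0, t_switch, "normoxia"),
            Epoch(t_switch, session_length, "hypoxia"),
        ],
        t_zero=t_switch,
    )


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------

def pink_noise(
    n: int, fs: float, exponent: float, rms: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian noise with power spectrum ∝ f^−exponent, scaled to ``rms``.

    Frequencies below 1 Hz share the 1 Hz weight so the variance stays finite
    while the 1–50 Hz slope equals −exponent.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    weight = np.maximum(f, 1.0) ** (-exponent / 2.0)
    weight[0] = 0.0  # zero-mean
    x = np.fft.irfft(spec * weight, n=n)
    scale = rms / np.std(x) if np.std(x) > 0 else 0.0
    return x * scale


def swd_waveform(
    f0: float,
    duration: float,
    n_harmonics: int,
    harmonic_decay: float,
    fs: float,
    rng: np.random.Generator | int | None = None,
    amplitude: float = 1.0,
    ramp_s: float = 0.1,
) -> np.ndarray:
    """Harmonic-comb burst: Σ_k amplitude·decay^(k−1)·cos(2π k f0 t + φ_k).

    Random phases φ_k make successive events differ in shape while keeping
    the harmonic spectral signature (peaks at k·f0, dominant at f0 for
    decay < 1).  A cosine on/off ramp of ``ramp_s`` avoids step transients.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if f0 * n_harmonics >= fs / 2:
        raise ValueError(
            f"harmonic {n_harmonics}·{f0} Hz = {f0 * n_harmonics} Hz is at or "
            f"above Nyquist ({fs / 2} Hz)"
        )
    rng = np.random.default_rng(rng)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)
    for k in range(1, n_harmonics + 1):
        phi = rng.uniform(0.0, 2.0 * np.pi)
        x += amplitude * harmonic_decay ** (k - 1) * np.cos(
            2.0 * np.pi * k * f0 * t + phi
        )
    ramp_n = min(int(round(ramp_s * fs)), n // 2)
    if ramp_n > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(ramp_n) / ramp_n))
        x[:ramp_n] *= ramp
        x[-ramp_n:] *= ramp[::-1]
    return x


def laser_schedule(config: LaserConfig) -> list[tuple[float, float]]:
    """Enumerate (t_on, t_off) laser pulses for the gated train protocol.

    Within each ``train_on_s`` train, pulses repeat at the pulse rate
    (default 50 ms period, 10 ms width → 40 pulses per 2 s train); trains are
    separated by ``train_off_s``; the schedule is truncated at ``total_min``.
    """
    period = 1.0 / config.pulse_rate_hz
    if config.pulse_width_s >= period:
        raise ValueError(
            f"pulse width {config.pulse_width_s} s must be shorter than the "
            f"pulse period {period} s"
        )
    total_s = config.total_min * 60.0
    cycle = config.train_on_s + config.train_off_s
    pulses: list[tuple[float, float]] = []
    n_per_train = int(math.ceil(config.train_on_s / period - 1e-12))
    train_start = 0.0
    while train_start < total_s:
        for i in range(n_per_train):
            t_on = train_start + i * period
            if t_on >= train_start + config.train_on_s or t_on >= total_s:
                break
            pulses.append((t_on, min(t_on + config.pulse_width_s, total_s)))
        train_start += cycle
    return pulses


def draw_events(
    protocol: ProtocolTimeline,
    swd_cfg: SwdGenConfig,
    rng: np.random.Generator,
    session_length: float,
    start_margin_s: float = 2.0,
) -> list[InjectedEvent]:
    """Place events as a piecewise-homogeneous Poisson process.

    Per epoch, the count is Poisson with mean rate_per_bin/300 × epoch length;
    each event's onset is redrawn (up to 100 times, then skipped) until it
    does not overlap an accepted event and clears ``min_gap_s``.  Durations
    are lognormal with the configured arithmetic mean/sd; f0 is uniform on
    ``f0_range``.
    """
    mean, sd = swd_cfg.duration_mean_s, swd_cfg.duration_sd_s
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    accepted: list[InjectedEvent] = []

    def conflicts(t0: float, t1: float) -> bool:
        gap = swd_cfg.min_gap_s
        return any(t0 < e.t_end + gap and e.t_start - gap < t1 for e in accepted)

    for epoch in protocol.epochs:
        rate = swd_cfg.rate_per_bin.get(epoch.condition, 0.0) / PSTH_BIN_S
        n = rng.poisson(rate * (epoch.t_end - epoch.t_start))
        for _ in range(n):
            for _attempt in range(100):
                t0 = rng.uniform(epoch.t_start, epoch.t_end)
                dur = float(rng.lognormal(mu, math.sqrt(sigma2)))
                t1 = t0 + dur
                if t0 < start_margin_s or t1 > session_length:
                    continue
                if not conflicts(t0, t1):
                    f0 = rng.uniform(*swd_cfg.f0_range)
                    accepted.append(InjectedEvent(t0, t1, f0))
                    break
    accepted.sort(key=lambda e: e.t_start)
    return accepted


def _resp_trace(
    n: int,
    fs: float,
    schedule: list[tuple[float, float, float]],
    cfg: RespGenConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Unit sinusoid whose instantaneous frequency follows the schedule plus
    slow zero-mean jitter (linear interpolation between 10 s nodes)."""
    t = np.arange(n) / fs
    rate = np.zeros(n)
    for t0, t1, r in schedule:
        i0, i1 = int(round(t0 * fs)), int(round(t1 * fs))
        rate[i0:i1] = r
    n_nodes = max(int(math.ceil(t[-1] / cfg.jitter_node_s)) + 2, 2)
    node_t = np.arange(n_nodes) * cfg.jitter_node_s
    node_j = rng.normal(0.0, cfg.rate_jitter_sd, size=n_nodes)
    jitter = np.interp(t, node_t, node_j)
    inst = np.maximum(rate + jitter, 0.05)
    phase = 2.0 * np.pi * np.cumsum(inst) / fs
    return np.sin(phase)


def _gas_trace(
    n: int, fs: float, protocol: ProtocolTimeline, targets: dict[str, float],
    tau: float,
) -> np.ndarray:
    target = np.zeros(n)
    for e in protocol.epochs:
        i0, i1 = int(round(e.t_start * fs)), int(round(e.t_end * fs))
        target[i0:i1] = targets.get(e.condition, 0.0)
    out = np.empty(n)
    level = target[0] if n else 0.0
    decay = math.exp(-1.0 / (tau * fs))
    for i in range(n):
        level = target[i] + (level - target[i]) * decay
        out[i] = level
    return out


def _laser_trace(
    n: int, fs: float, protocol: ProtocolTimeline, cfg: LaserConfig
) -> np.ndarray:
    out = np.zeros(n)
    for e in protocol.epochs:
        if e.condition not in LASER_CONDITIONS:
            continue
        sub = LaserConfig(
            pulse_rate_hz=cfg.pulse_rate_hz,
            pulse_width_s=cfg.pulse_width_s,
            train_on_s=cfg.train_on_s,
            train_off_s=cfg.train_off_s,
            total_min=min(cfg.total_min, (e.t_end - e.t_start) / 60.0),
        )
        for t_on, t_off in laser_schedule(sub):
            i0 = int(round((e.t_start + t_on) * fs))
            i1 = max(int(round((e.t_start + t_off) * fs)), i0 + 1)
            out[i0 : min(i1, n)] = 1.0
    return out


# ---------------------------------------------------------------------------
# Session assembly
# ---------------------------------------------------------------------------

def generate_session(config: SynthConfig) -> tuple[Recording, GroundTruth]:
    """Generate one synthetic session and its ground truth.

    Identical config (including seed) yields bitwise-identical output; the
    single seed feeds named deterministic sub-streams per channel.
    """
    protocol = config.protocol or default_protocol(config.session_length)
    lo, hi = protocol.extent
    if lo < 0 or hi > config.session_length + 1e-9:
        raise ValueError(
            f"protocol extent [{lo}, {hi}) exceeds the session "
            f"[0, {config.session_length})"
        )
    if config.session_length < min(e.t_end - e.t_start for e in protocol.epochs):
        raise ValueError("session shorter than one condition epoch")

    n = int(round(config.session_length * config.fs))
    fs = config.fs
    ss = np.random.SeedSequence(config.seed)
    r_events, r_ecog, r_emg, r_resp = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    events = draw_events(protocol, config.swd, r_events, config.session_length)

    ecog = pink_noise(
        n, fs, config.background.noise_exponent, config.background.amplitude_uV,
        r_ecog,
    )
    for ev in events:
        i0 = int(round(ev.t_start * fs))
        w = swd_waveform(
            ev.f0,
            ev.duration,
            config.swd.n_harmonics,
            config.swd.harmonic_decay,
            fs,
            rng=r_events,
            amplitude=config.swd.amplitude_uV,
            ramp_s=config.swd.ramp_s,
        )
        i1 = min(i0 + w.size, n)
        ecog[i0:i1] += w[: i1 - i0]

    emg = r_emg.standard_normal(n) * config.emg.tone_uV
    for ev in events:
        i0, i1 = int(round(ev.t_start * fs)), int(round(ev.t_end * fs))
        emg[i0:i1] *= config.emg.atonia_fraction

    resp_schedule = [
        (e.t_start, e.t_end, config.resp.rate_by_condition.get(e.condition, 1.0))
        for e in protocol.epochs
    ]
    resp = _resp_trace(n, fs, resp_schedule, config.resp, r_resp)

    gas_o2 = _gas_trace(n, fs, protocol, config.gas.o2_by_condition,
                        config.gas.exchange_tau_s)
    gas_co2 = _gas_trace(n, fs, protocol, config.gas.co2_by_condition,
                         config.gas.exchange_tau_s)
    laser = _laser_trace(n, fs, protocol, config.laser)

    rec = Recording(
        channels={
            "ecog": ecog,
            "emg": emg,
            "resp": resp,
            "gas_o2": gas_o2,
            "gas_co2": gas_co2,
            "laser": laser,
        },
        fs=fs,
    )
    truth = GroundTruth(
        events=events, resp_schedule=resp_schedule, condition_timeline=protocol
    )
    return rec, truth
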