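import numpy as np
import pytest

from swdlab.io_formats import CoarseEvent, Recording
from swdlab.synth import SynthConfig, generate_session, pink_noise, swd_waveform

FS = 200.0


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def small_recording(rng):
    """10 s two-channel recording with plain noise."""
    n = int(10 * FS)
    return Recording(
        channels={"ecog": rng.standard_normal(n), "resp": np.sin(np.arange(n) / FS)},
        fs=FS,
    )


@pytest.fixture(scope="session")
def short_session():
    """A 10-min session with elevated event rates so a handful of
    discharges are present, plus its ground truth."""
    cfg = SynthConfig(
        session_length=600.0,
        seed=1234,
    )
    cfg.swd.rate_per_bin = {"normoxia": 2.0, "hypoxia": 3.0}
    # keep candidates independent: real inter-seizure gaps are minutes,
    # comfortably more than the coarse padding plus baseline minimum
    cfg.swd.min_gap_s = 10.0
    return generate_session(cfg)


def embedded_event(
    rng,
    f0=7.0,
    duration=5.0,
    snr=10.0,
    pre=12.0,
    post=3.0,
    alpha=2.0,
    n_harmonics=4,
    decay=0.6,
    fs=FS,
):
    """One harmonic-comb event embedded in unit-RMS 1/f^alpha background.

    Returns (signal, coarse window padded by 1 s, true (t_start, t_end, f0)).
    """
    n = int(round((pre + duration + post) * fs))
    x = pink_noise(n, fs, alpha, 1.0, rng)
    w = swd_waveform(f0, duration, n_harmonics, decay, fs, rng=rng, amplitude=snr)
    i0 = int(round(pre * fs))
    x[i0 : i0 + w.size] += w
    coarse = CoarseEvent(pre - 1.0, pre + duration + 1.0)
    return x, coarse, (pre, pre + duration, f0)
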