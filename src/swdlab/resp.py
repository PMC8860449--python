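"""Respiratory-rate estimation from the plethysmography flow trace.

The trace is cut into consecutive non-overlapping 10 s windows; each window
is mean-subtracted and Fourier-transformed, and the window's rate is the
frequency of maximal power density within the search band (0.5–4 Hz by
default, bracketing rat breathing with margin).  A 30 s centered moving
average then smooths the per-window trace.  Rates are handled internally in
Hz; breaths/min is an exact ×60 away wherever exposed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ProtocolTimeline

__all__ = ["RespRateSeries", "respiratory_rate", "smooth_rate", "epoch_mean_rate",
           "HZ_TO_BPM"]

HZ_TO_BPM = 60.0


@dataclass
class RespRateSeries:
    """Per-window respiratory-rate estimates (Hz) plus the smoothed trace."""

    window_centers: np.ndarray
    raw_rate: np.ndarray
    smoothed_rate: np.ndarray | None = None
    window_s: float = 10.0
    band: tuple[float, float] = (0.5, 4.0)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"window_center_s": self.window_centers, "raw_hz": self.raw_rate}
        )
        if self.smoothed_rate is not None:
            df["smoothed_hz"] = self.smoothed_rate
            df["smoothed_bpm"] = self.smoothed_rate * HZ_TO_BPM
        return df


def respiratory_rate(
    resp: np.ndarray,
    fs: float,
    window_s: float = 10.0,
    band: tuple[float, float] = (0.5, 4.0),
    refine: bool = True,
    start_time: float = 0.0,
) -> RespRateSeries:
    """Windowed-FFT rate estimate: argmax of power density within ``band``.

    Windows are consecutive and non-overlapping; a trailing partial window is
    dropped.  ``refine`` zero-pads ×4 beyond the native 1/window resolution
    for sub-bin argmax (ties break toward the lower frequency); disable it
    for strict native-resolution bins.  All-zero windows yield NaN and are
    excluded from smoothing.
    """
    nwin = int(round(window_s * fs))
    if resp.size < nwin:
        raise ValueError(
            f"signal ({resp.size / fs:.1f} s) shorter than one {window_s:.0f} s "
            "window; no rate can be estimated"
        )
    lo, hi = band
    if not 0 < lo < hi < fs / 2:
        raise ValueError(f"band {band} must lie within (0, {fs / 2})")
    n_windows = resp.size // nwin
    nfft = nwin * 4 if refine else nwin
    centers = np.empty(n_windows)
    rates = np.empty(n_windows)
    for w in range(n_windows):
        seg = resp[w * nwin : (w + 1) * nwin]
        centers[w] = start_time + (w + 0.5) * window_s
        seg = seg - seg.mean()
        if not np.any(seg):
            rates[w] = np.nan
            continue
        power = np.abs(np.fft.rfft(seg, n=nfft)) ** 2
        freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
        idx = np.flatnonzero((freqs >= lo) & (freqs <= hi))
        rates[w] = freqs[idx[np.argmax(power[idx])]]
    return RespRateSeries(
        window_centers=centers, raw_rate=rates, window_s=window_s, band=band
    )


def smooth_rate(series: RespRateSeries, span_s: float = 30.0) -> RespRateSeries:
    """Centered moving average over ``span_s`` (3 windows by default).

    Edges use the shorter available window set; NaN (missing) windows are
    skipped with renormalization over the values present.
    """
    half = max(int(round(span_s / series.window_s)) // 2, 0)
    raw = series.raw_rate
    smoothed = np.empty_like(raw)
    for i in range(raw.size):
        seg = raw[max(i - half, 0) : i + half + 1]
        valid = seg[~np.isnan(seg)]
        smoothed[i] = valid.mean() if valid.size else np.nan
    return RespRateSeries(
        window_centers=series.window_centers,
        raw_rate=raw,
        smoothed_rate=smoothed,
        window_s=series.window_s,
        band=series.band,
    )


def epoch_mean_rate(
    series: RespRateSeries, timeline: ProtocolTimeline
) -> dict[str, float]:
    """Mean smoothed rate per condition epoch (half-open membership of the
    window centers).  Epochs containing no window centers give NaN with a
    warning; repeated conditions are pooled."""
    rate = (
        series.smoothed_rate if series.smoothed_rate is not None else series.raw_rate
    )
    sums: dict[str, list[float]] = {}
    for e in timeline.epochs:
        mask = (series.window_centers >= e.t_start) & (series.window_centers < e.t_end)
        vals = rate[mask]
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            warnings.warn(
                f"epoch [{e.t_start}, {e.t_end}) '{e.condition}' contains no "
                "rate windows",
                stacklevel=2,
            )
        sums.setdefault(e.condition, []).extend(vals.tolist())
    return {
        cond: (float(np.mean(v)) if v else float("nan")) for cond, v in sums.items()
    }
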