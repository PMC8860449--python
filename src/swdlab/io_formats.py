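"""Containers and file formats for multi-channel physiology sessions.

All times are seconds on the session clock (t = 0 at recording start) and
all intervals are half-open ``[t_start, t_end)``.  Three on-disk formats are
supported and kept strictly separate from the math core:

* signals — EDF/EDF+ (16-bit, one signal per channel role) or the package's
  plain-text CSV dialect (UTF-8, '.' decimal, mandatory header; exact
  round-trip);
* event lists — CSV with columns ``t_start,t_end,label``;
* protocol timelines — JSON with ``t_zero`` and an ordered epoch list.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Channel roles the pipeline knows about.
KNOWN_ROLES = ("ecog", "emg", "resp", "gas_o2", "gas_co2", "laser")

#: Physical units written to EDF headers, per role.
ROLE_UNITS = {
    "ecog": "uV",
    "emg": "uV",
    "resp": "au",
    "gas_o2": "%",
    "gas_co2": "%",
    "laser": "",
}

DEFAULT_FS = 200.0  # Hz, the acquisition rate the pipeline assumes by default


class ChannelNotFoundError(KeyError):
    """A requested channel role/name is absent from a file or Recording."""


class EventValidationError(ValueError):
    """An event table row violates ``t_end > t_start`` or extent bounds."""


class ProtocolError(ValueError):
    """A protocol timeline is overlapping, unordered, or misaligned."""


@dataclass
class Recording:
    """Synchronized multi-channel session sampled at a common rate.

    Parameters
    ----------
    channels
        Map from channel role (see :data:`KNOWN_ROLES`) to a 1-D float array.
        All arrays must have equal length.
    fs
        Sampling rate in Hz (default 200, the acquisition rate).
    start_time
        Session-clock time of the first sample, in seconds.
    """

    channels: dict[str, np.ndarray]
    fs: float = DEFAULT_FS
    start_time: float = 0.0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if not self.channels:
            raise ValueError("Recording requires at least one channel")
        self.channels = {
            role: np.asarray(x, dtype=float) for role, x in self.channels.items()
        }
        lengths = {role: x.size for role, x in self.channels.items()}
        if len(set(lengths.values())) != 1:
            raise ValueError(f"channel lengths differ: {lengths}")
        if not ({"ecog", "resp"} & set(self.channels)):
            raise ValueError("Recording needs at least one of {'ecog', 'resp'}")

    @property
    def n_samples(self) -> int:
        return next(iter(self.channels.values())).size

    @property
    def duration(self) -> float:
        """Session length in seconds (n_samples / fs)."""
        return self.n_samples / self.fs

    def time(self) -> np.ndarray:
        """Sample times on the session clock."""
        return self.start_time + np.arange(self.n_samples) / self.fs

    def __getitem__(self, role: str) -> np.ndarray:
        try:
            return self.channels[role]
        except KeyError:
            raise ChannelNotFoundError(
                f"role {role!r} not present; available: {sorted(self.channels)}"
            ) from None


@dataclass(frozen=True)
class CoarseEvent:
    """Coarse, human-style event window handed to the boundary refiner."""

    t_start: float
    t_end: float
    label: str = "sws_candidate"

    def __post_init__(self) -> None:
        if not self.t_end > self.t_start:
            raise EventValidationError(
                f"t_end ({self.t_end}) must exceed t_start ({self.t_start})"
            )

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class Epoch:
    t_start: float
    t_end: float
    condition: str

    def __post_init__(self) -> None:
        if not self.t_end > self.t_start:
            raise ProtocolError(
                f"epoch t_end ({self.t_end}) must exceed t_start ({self.t_start})"
            )

    def contains(self, t: float) -> bool:
        return self.t_start <= t < self.t_end


@dataclass
class ProtocolTimeline:
    """Ordered, non-overlapping condition epochs plus an alignment origin.

    ``t_zero`` is the peristimulus alignment origin (gas-exchange or laser
    onset) and must coincide with an epoch boundary.
    """

    epochs: list[Epoch]
    t_zero: float

    def __post_init__(self) -> None:
        self.epochs = [e if isinstance(e, Epoch) else Epoch(*e) for e in self.epochs]
        for a, b in zip(self.epochs, self.epochs[1:]):
            if b.t_start < a.t_end:
                raise ProtocolError(
                    f"epochs overlap or are unordered: [{a.t_start}, {a.t_end}) "
                    f"followed by [{b.t_start}, {b.t_end})"
                )
        boundaries = {e.t_start for e in self.epochs} | {e.t_end for e in self.epochs}
        if not any(math.isclose(self.t_zero, b, abs_tol=1e-9) for b in boundaries):
            raise ProtocolError(
                f"t_zero = {self.t_zero} does not coincide with an epoch boundary"
            )

    @property
    def extent(self) -> tuple[float, float]:
        return self.epochs[0].t_start, self.epochs[-1].t_end

    def condition_at(self, t: float) -> str | None:
        for e in self.epochs:
            if e.contains(t):
                return e.condition
        return None


# ---------------------------------------------------------------------------
# Event CSV
# ---------------------------------------------------------------------------

def read_events(path: str | Path) -> list[CoarseEvent]:
    """Read a coarse-event CSV (columns ``t_start,t_end,label``)."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"t_start", "t_end", "label"}
    if not required <= set(df.columns):
        raise EventValidationError(
            f"{path}: expected columns {sorted(required)}, got {list(df.columns)}"
        )
    events = []
    for i, row in df.iterrows():
        try:
            events.append(
                CoarseEvent(float(row.t_start), float(row.t_end), str(row.label))
            )
        except EventValidationError as exc:
            raise EventValidationError(f"{path}: row {i}: {exc}") from None
    return events


def write_events(events: Sequence[CoarseEvent], path: str | Path) -> None:
    """Write events to CSV, preserving order; ``read_events`` inverts it."""
    df = pd.DataFrame(
        [(e.t_start, e.t_end, e.label) for e in events],
        columns=["t_start", "t_end", "label"],
    )
    df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Protocol JSON
# ---------------------------------------------------------------------------

def read_protocol(path: str | Path) -> ProtocolTimeline:
    """Read a protocol timeline from JSON ``{"t_zero": ..., "epochs": [...]}``."""
    with open(path, encoding="utf-8") as fh:
        obj = json.load(fh)
    epochs = [Epoch(e["t_start"], e["t_end"], e["condition"]) for e in obj["epochs"]]
    return ProtocolTimeline(epochs=epochs, t_zero=float(obj["t_zero"]))


def write_protocol(timeline: ProtocolTimeline, path: str | Path) -> None:
    obj = {
        "t_zero": timeline.t_zero,
        "epochs": [dataclasses.asdict(e) for e in timeline.epochs],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Signals: text dialect
# ---------------------------------------------------------------------------

def _write_text(rec: Recording, path: Path) -> None:
    df = pd.DataFrame({"time": rec.time()})
    for role, x in rec.channels.items():
        df[role] = x
    df.to_csv(path, index=False, float_format="%.17g")


def _read_text(path: Path, channel_map: Mapping[str, str] | None) -> Recording:
    df = pd.read_csv(path, float_precision="round_trip")
    if "time" not in df.columns:
        raise ValueError(f"{path}: text recording dialect requires a 'time' column")
    t = df["time"].to_numpy(float)
    if t.size < 2:
        raise ValueError(f"{path}: need at least two samples to infer fs")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError(f"{path}: non-uniform sampling in 'time' column")
    fs = 1.0 / dt[0]
    available = [c for c in df.columns if c != "time"]
    if channel_map is None:
        channel_map = {c: c for c in available}
    channels = {}
    for role, name in channel_map.items():
        if name not in available:
            raise ChannelNotFoundError(
                f"{path}: no channel {name!r} for role {role!r}; "
                f"available: {available}"
            )
        channels[role] = df[name].to_numpy(float)
    return Recording(channels=channels, fs=float(np.round(fs, 9)), start_time=t[0])


# ---------------------------------------------------------------------------
# Signals: minimal EDF (continuous, one signal per role, 1 s data records)
# ---------------------------------------------------------------------------

_EDF_DIGITAL_MAX = 32767


def _edf_field(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def _write_edf(rec: Recording, path: Path) -> None:
    fs = rec.fs
    spr = int(round(fs))  # samples per 1 s record
    if not math.isclose(spr, fs, rel_tol=1e-9):
        raise ValueError("EDF writer requires an integer sampling rate; use CSV")
    if rec.n_samples % spr != 0:
        raise ValueError(
            "EDF writer requires a whole number of seconds "
            f"({rec.n_samples} samples at {fs} Hz); use CSV for ragged lengths"
        )
    n_records = rec.n_samples // spr
    roles = list(rec.channels)
    ns = len(roles)

    header = b""
    header += _edf_field("0", 8)  # version
    header += _edf_field("X X X X", 80)  # patient id (anonymous)
    header += _edf_field("Startdate X X X X", 80)  # recording id
    header += _edf_field("01.01.00", 8)
    header += _edf_field("00.00.00", 8)
    header += _edf_field(256 * (ns + 1), 8)
    header += _edf_field("EDF+C", 44)
    header += _edf_field(n_records, 8)
    header += _edf_field("1", 8)  # record duration, s
    header += _edf_field(ns, 4)

    phys_min, phys_max, scaled = [], [], []
    for role in roles:
        x = rec.channels[role]
        lo, hi = float(np.min(x)), float(np.max(x))
        if hi <= lo:  # constant signal: open a unit span so gain is finite
            hi = lo + 1.0
        # EDF stores physical min/max as 8-char ascii; round outward to keep
        # every sample inside the printed span.
        lo_s = float(f"{lo:.6g}")
        hi_s = float(f"{hi:.6g}")
        lo_s = min(lo_s, lo)
        hi_s = max(hi_s, hi)
        span = hi_s - lo_s
        dig = np.round(
            (x - lo_s) / span * (2 * _EDF_DIGITAL_MAX) - _EDF_DIGITAL_MAX
        ).astype("<i2")
        phys_min.append(lo_s)
        phys_max.append(hi_s)
        scaled.append(dig)

    for role in roles:
        header += _edf_field(role, 16)  # label
    for role in roles:
        header += _edf_field("", 80)  # transducer
    for role in roles:
        header += _edf_field(ROLE_UNITS.get(role, ""), 8)
    for v in phys_min:
        header += _edf_field(f"{v:.6g}", 8)
    for v in phys_max:
        header += _edf_field(f"{v:.6g}", 8)
    for _ in roles:
        header += _edf_field(-_EDF_DIGITAL_MAX, 8)
    for _ in roles:
        header += _edf_field(_EDF_DIGITAL_MAX, 8)
    for _ in roles:
        header += _edf_field("", 80)  # prefiltering
    for _ in roles:
        header += _edf_field(spr, 8)
    for _ in roles:
        header += _edf_field("", 32)  # reserved

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            for dig in scaled:
                fh.write(dig[r * spr : (r + 1) * spr].tobytes())


def _read_edf(path: Path, channel_map: Mapping[str, str] | None) -> Recording:
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise ValueError(f"{path}: truncated EDF header")
        n_records = int(head[236:244])
        record_dur = float(head[244:252])
        ns = int(head[252:256])
        sig = fh.read(256 * ns)
        labels = [
            sig[i * 16 : (i + 1) * 16].decode("ascii").strip() for i in range(ns)
        ]
        off = 16 * ns + 80 * ns + 8 * ns
        phys_min = [float(sig[off + 8 * i : off + 8 * (i + 1)]) for i in range(ns)]
        off += 8 * ns
        phys_max = [float(sig[off + 8 * i : off + 8 * (i + 1)]) for i in range(ns)]
        off += 8 * ns
        dig_min = [int(sig[off + 8 * i : off + 8 * (i + 1)]) for i in range(ns)]
        off += 8 * ns
        dig_max = [int(sig[off + 8 * i : off + 8 * (i + 1)]) for i in range(ns)]
        off += 8 * ns + 80 * ns
        spr = [int(sig[off + 8 * i : off + 8 * (i + 1)]) for i in range(ns)]

        rates = [s / record_dur for s in spr]
        if len(set(rates)) != 1:
            raise ValueError(
                f"{path}: per-signal rates differ ({rates}); resampling is not "
                "supported — export at a common rate"
            )
        fs = rates[0]

        raw = [np.empty(n_records * spr[i], dtype=float) for i in range(ns)]
        for r in range(n_records):
            for i in range(ns):
                buf = fh.read(2 * spr[i])
                dig = np.frombuffer(buf, dtype="<i2").astype(float)
                gain = (phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i])
                raw[i][r * spr[i] : (r + 1) * spr[i]] = (
                    phys_min[i] + (dig - dig_min[i]) * gain
                )

    if channel_map is None:
        channel_map = {lab: lab for lab in labels if lab in KNOWN_ROLES}
    channels = {}
    for role, name in channel_map.items():
        if name not in labels:
            raise ChannelNotFoundError(
                f"{path}: no channel {name!r} for role {role!r}; available: {labels}"
            )
        channels[role] = raw[labels.index(name)]
    return Recording(channels=channels, fs=fs, start_time=0.0)


# ---------------------------------------------------------------------------
# Dispatch
# ---------------------------------------------------------------------------

def read_recording(
    path: str | Path, channel_map: Mapping[str, str] | None = None
) -> Recording:
    """Read a Recording from EDF (``.edf``) or the text CSV dialect.

    ``channel_map`` maps channel roles to in-file channel names; when omitted,
    in-file names that already are roles are taken as-is.
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return _read_edf(path, channel_map)
    return _read_text(path, channel_map)


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write a Recording to EDF (``.edf``) or the text CSV dialect.

    The text dialect round-trips exactly; EDF round-trips within its 16-bit
    quantization of each signal's physical span.
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        _write_edf(rec, path)
    else:
        _write_text(rec, path)
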