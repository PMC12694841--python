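"""Raw-trace ingestion, bipolar VEOG derivation, and segment slicing.

Conventions: amplitudes are microvolts throughout (a scale factor converts
other units on ingest), time is seconds from recording start, sample indices
are 0-based, and segment windows are half-open ``[onset, onset + duration)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from veogblink import edf as _edf

__all__ = [
    "ChannelNotFoundError",
    "TraceFormatError",
    "SegmentBoundsError",
    "SignalTrace",
    "SegmentSpec",
    "BipolarVEOG",
    "read_trace",
    "write_trace_csv",
    "derive_bipolar",
    "extract_segments",
    "read_segment_table",
]

# EDF physical-dimension strings mapped to a to-microvolt factor
_UNIT_TO_UV = {"uv": 1.0, "µv": 1.0, "mv": 1e3, "v": 1e6, "": 1.0}


class ChannelNotFoundError(KeyError):
    """A requested channel label is absent from the recording."""

    def __init__(self, label: str, available: list[str]):
        super().__init__(label)
        self.label = label
        self.available = list(available)

    def __str__(self) -> str:
        return (
            f"channel {self.label!r} not found; available channels: "
            f"{', '.join(self.available)}"
        )


class TraceFormatError(ValueError):
    """The on-disk trace violates the expected layout."""


class SegmentBoundsError(ValueError):
    """A segment spec falls outside the recording."""


@dataclass
class SignalTrace:
    """Sampled multichannel trace in microvolts.

    ``samples`` has shape ``(n_channels, n_samples)``.
    """

    samples: np.ndarray
    fs: float
    channel_labels: list[str]
    t0: float = 0.0

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=np.float64))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.shape[0] != len(self.channel_labels):
            raise TraceFormatError(
                f"{self.samples.shape[0]} channels but "
                f"{len(self.channel_labels)} labels"
            )
        if self.samples.shape[1] < 1:
            raise TraceFormatError("trace must contain at least one sample")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise ChannelNotFoundError(label, self.channel_labels) from None
        return self.samples[idx]


@dataclass(frozen=True)
class SegmentSpec:
    """One analysis window within a recording."""

    label: str
    onset: float
    duration: float
    condition: str | None = None

    def __post_init__(self):
        if self.onset < 0:
            raise ValueError(f"segment {self.label!r}: onset must be >= 0")
        if self.duration <= 0:
            raise ValueError(f"segment {self.label!r}: duration must be > 0")


@dataclass
class BipolarVEOG:
    """Single-channel upper-minus-lower eye derivation (blink-positive)."""

    samples: np.ndarray
    fs: float
    derivation: tuple[str, str] = ("upper", "lower")

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64).ravel()
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


def read_trace(
    path,
    format: str | None = None,
    channel_map: list[str] | None = None,
    fs: float | None = None,
    scale_to_uv: float = 1.0,
) -> SignalTrace:
    """Read a multichannel trace from EDF/EDF+ or delimited text.

    Parameters
    ----------
    path:
        Input file.  ``format`` defaults from the extension (``.edf`` vs
        anything else treated as delimited text).
    channel_map:
        Channel labels to load, in the requested order.  ``None`` loads all.
    fs:
        Sampling rate in Hz; required for text input (EDF declares its own).
    scale_to_uv:
        Multiplicative factor applied to text amplitudes to obtain
        microvolts.  EDF physical dimensions are honored instead.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "csv"

    if format == "edf":
        samples, native_fs, labels, headers = _edf.read_edf(path)
        for i, h in enumerate(headers):
            unit = h.physical_dimension.strip().lower()
            factor = _UNIT_TO_UV.get(unit)
            if factor is None:
                raise TraceFormatError(
                    f"{path}: unsupported physical dimension {h.physical_dimension!r}"
                )
            if factor != 1.0:
                samples[i] = samples[i] * factor
        trace = SignalTrace(samples, native_fs, labels)
    elif format == "csv":
        if fs is None:
            raise ValueError("fs is required for delimited-text input")
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
        frame = pd.read_csv(path, sep=sep)
        if frame.shape[0] < 1:
            raise TraceFormatError(f"{path}: no sample rows")
        values = frame.to_numpy(dtype=np.float64).T * scale_to_uv
        if not np.all(np.isfinite(values)):
            raise TraceFormatError(f"{path}: non-numeric or missing sample values")
        trace = SignalTrace(values, fs, [str(c) for c in frame.columns])
    else:
        raise ValueError(f"unknown trace format {format!r}")

    if channel_map is not None:
        rows = [trace.channel(label) for label in channel_map]
        trace = SignalTrace(np.vstack(rows), trace.fs, list(channel_map), trace.t0)
    return trace


def write_trace_csv(trace: SignalTrace, path) -> None:
    """Write a trace as delimited text: header row of labels, one row/sample."""
    frame = pd.DataFrame(trace.samples.T, columns=trace.channel_labels)
    frame.to_csv(path, index=False, float_format="%.6f")


def derive_bipolar(trace: SignalTrace, upper: str, lower: str) -> BipolarVEOG:
    """Upper-minus-lower derivation; blinks deflect positive."""
    return BipolarVEOG(
        trace.channel(upper) - trace.channel(lower),
        trace.fs,
        derivation=(upper, lower),
    )


def extract_segments(
    trace: BipolarVEOG, specs: list[SegmentSpec]
) -> list[tuple[SegmentSpec, BipolarVEOG]]:
    """Slice half-open ``[onset, onset+duration)`` windows out of a recording.

    Each returned segment has ``round(duration * fs)`` samples.  Baselines or
    gaps between listed segments are simply not returned.
    """
    out = []
    n = trace.n_samples
    for spec in specs:
        start = int(round(spec.onset * trace.fs))
        length = int(round(spec.duration * trace.fs))
        if start + length > n:
            raise SegmentBoundsError(
                f"segment {spec.label!r} ([{spec.onset}, "
                f"{spec.onset + spec.duration}) s) exceeds the "
                f"{n / trace.fs:g} s recording"
            )
        out.append(
            (
                spec,
                BipolarVEOG(
                    trace.samples[start : start + length],
                    trace.fs,
                    trace.derivation,
                ),
            )
        )
    return out


def read_segment_table(path) -> list[SegmentSpec]:
    """Read segment specs from CSV columns label, onset_s, duration_s[, condition]."""
    frame = pd.read_csv(path)
    required = {"label", "onset_s", "duration_s"}
    missing = required - set(frame.columns)
    if missing:
        raise TraceFormatError(
            f"{path}: segment table missing columns {sorted(missing)}"
        )
    specs = []
    for row in frame.itertuples(index=False):
        condition = getattr(row, "condition", None)
        if condition is not None and (pd.isna(condition) or condition == ""):
            condition = None
        specs.append(
            SegmentSpec(
                label=str(row.label),
                onset=float(row.onset_s),
                duration=float(row.duration_s),
                condition=None if condition is None else str(condition),
            )
        )
    return specs
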