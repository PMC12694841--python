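"""Minimal EDF/EDF+ continuous-recording I/O.

Implements just enough of the European Data Format to round-trip multichannel
polygraphic traces: the 256-byte fixed header, the per-signal header block,
and 16-bit little-endian sample records with linear digital-to-physical
scaling.  Annotation signals and discontinuous (EDF+D) files are not
supported.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass

import numpy as np

__all__ = ["EdfSignalHeader", "read_edf", "write_edf"]

_HDR_FIXED = 256
# (width, key) pairs of the per-signal header block, in file order
_SIGNAL_FIELDS = [
    (16, "label"),
    (80, "transducer"),
    (8, "physical_dimension"),
    (8, "physical_min"),
    (8, "physical_max"),
    (8, "digital_min"),
    (8, "digital_max"),
    (80, "prefiltering"),
    (8, "samples_per_record"),
    (32, "reserved"),
]


@dataclass
class EdfSignalHeader:
    label: str
    physical_dimension: str
    physical_min: float
    physical_max: float
    digital_min: int
    digital_max: int
    samples_per_record: int

    @property
    def gain(self) -> float:
        return (self.physical_max - self.physical_min) / (
            self.digital_max - self.digital_min
        )


def _ascii(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def _fmt_num(value: float, width: int = 8) -> str:
    """Render a number into an EDF numeric field (<= width ASCII chars)."""
    if float(value) == int(value) and abs(value) < 10 ** (width - 1):
        return str(int(value))
    s = f"{value:.{width}g}"
    while len(s) > width:
        s = s[:-1]
    return s


def read_edf(path) -> tuple[np.ndarray, float, list[str], list[EdfSignalHeader]]:
    """Read a continuous EDF file.

    Returns ``(samples, fs, labels, signal_headers)`` where ``samples`` has
    shape ``(n_channels, n_samples)`` in each signal's physical unit.  All
    signals must share one sampling rate.
    """
    with open(path, "rb") as fh:
        fixed = fh.read(_HDR_FIXED)
        if len(fixed) < _HDR_FIXED:
            raise ValueError(f"{path}: truncated EDF header")
        n_records = int(fixed[236:244].decode("ascii").strip())
        record_duration = float(fixed[244:252].decode("ascii").strip())
        ns = int(fixed[252:256].decode("ascii").strip())

        block = fh.read(ns * sum(w for w, _ in _SIGNAL_FIELDS))
        fields: dict[str, list[str]] = {}
        offset = 0
        for width, key in _SIGNAL_FIELDS:
            fields[key] = [
                block[offset + i * width : offset + (i + 1) * width]
                .decode("ascii")
                .strip()
                for i in range(ns)
            ]
            offset += ns * width

        headers = [
            EdfSignalHeader(
                label=fields["label"][i],
                physical_dimension=fields["physical_dimension"][i],
                physical_min=float(fields["physical_min"][i]),
                physical_max=float(fields["physical_max"][i]),
                digital_min=int(fields["digital_min"][i]),
                digital_max=int(fields["digital_max"][i]),
                samples_per_record=int(fields["samples_per_record"][i]),
            )
            for i in range(ns)
        ]

        spr = headers[0].samples_per_record
        if any(h.samples_per_record != spr for h in headers):
            raise ValueError(f"{path}: signals with mixed sampling rates")
        if record_duration <= 0:
            raise ValueError(f"{path}: non-positive record duration")
        fs = spr / record_duration

        raw = np.fromfile(fh, dtype="<i2", count=n_records * ns * spr)
        if raw.size < n_records * ns * spr:
            raise ValueError(f"{path}: truncated EDF data section")
        raw = raw.reshape(n_records, ns, spr)

    samples = np.empty((ns, n_records * spr), dtype=np.float64)
    for i, h in enumerate(headers):
        dig = raw[:, i, :].reshape(-1).astype(np.float64)
        samples[i] = (dig - h.digital_min) * h.gain + h.physical_min
    return samples, fs, [h.label for h in headers], headers


def write_edf(
    path,
    samples: np.ndarray,
    fs: float,
    labels: list[str],
    physical_dimension: str = "uV",
    start: _dt.datetime | None = None,
) -> None:
    """Write channels (``(n_channels, n_samples)``) to a continuous EDF file."""
    samples = np.atleast_2d(np.asarray(samples, dtype=np.float64))
    ns, n = samples.shape
    if len(labels) != ns:
        raise ValueError("one label per channel required")

    # 1-s records when fs divides the length evenly, else a single long record
    if float(fs).is_integer() and n % int(fs) == 0:
        spr, n_records = int(fs), n // int(fs)
        record_duration = 1.0
    else:
        spr, n_records = n, 1
        record_duration = n / fs

    start = start or _dt.datetime(2000, 1, 1)
    dig_min, dig_max = -32768, 32767
    headers = []
    scaled = np.empty((ns, n), dtype="<i2")
    for i in range(ns):
        lo = float(np.min(samples[i]))
        hi = float(np.max(samples[i]))
        if not math.isfinite(lo) or not math.isfinite(hi):
            raise ValueError("non-finite samples cannot be written to EDF")
        if hi <= lo:
            hi = lo + 1.0
        gain = (hi - lo) / (dig_max - dig_min)
        scaled[i] = np.round((samples[i] - lo) / gain + dig_min).astype("<i2")
        headers.append((lo, hi))

    with open(path, "wb") as fh:
        fh.write(_ascii("0", 8))
        fh.write(_ascii("X X X X", 80))
        fh.write(_ascii("Startdate X X X X", 80))
        fh.write(_ascii(start.strftime("%d.%m.%y"), 8))
        fh.write(_ascii(start.strftime("%H.%M.%S"), 8))
        fh.write(_ascii(_HDR_FIXED + ns * 256, 8))
        fh.write(_ascii("", 44))
        fh.write(_ascii(n_records, 8))
        fh.write(_ascii(_fmt_num(record_duration), 8))
        fh.write(_ascii(ns, 4))

        per_signal = {
            "label": [lab for lab in labels],
            "transducer": [""] * ns,
            "physical_dimension": [physical_dimension] * ns,
            "physical_min": [_fmt_num(h[0]) for h in headers],
            "physical_max": [_fmt_num(h[1]) for h in headers],
            "digital_min": [str(dig_min)] * ns,
            "digital_max": [str(dig_max)] * ns,
            "prefiltering": [""] * ns,
            "samples_per_record": [str(spr)] * ns,
            "reserved": [""] * ns,
        }
        for width, key in _SIGNAL_FIELDS:
            for value in per_signal[key]:
                fh.write(_ascii(value, width))

        fh.write(
            np.ascontiguousarray(
                scaled.reshape(ns, n_records, spr).transpose(1, 0, 2)
            ).tobytes()
        )
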