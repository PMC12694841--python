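"""Per-segment blink indices and their within-subject aggregation.

Four indices per segment:

* BR  — blinks per minute,
* BA  — mean peak voltage (uV) over detected blinks,
* BRV — coefficient of variation (sample SD / mean) of inter-blink intervals,
* BAV — coefficient of variation of per-blink peak amplitudes.

Indices without enough events (BA >= 1 blink, BAV >= 2, BRV >= 3) carry NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from veogblink.blink_detection import BlinkSeries, compute_ibis

__all__ = [
    "BlinkMetrics",
    "blink_rate",
    "blink_amplitude",
    "coefficient_of_variation",
    "compute_metrics",
    "aggregate_films",
    "metrics_frame",
]

MISSING = float("nan")


@dataclass(frozen=True)
class BlinkMetrics:
    br: float
    ba: float
    brv: float
    bav: float
    n_blinks: int
    duration: float

    def as_dict(self) -> dict:
        return {
            "n_blinks": self.n_blinks,
            "duration_s": self.duration,
            "br": self.br,
            "ba_uv": self.ba,
            "brv": self.brv,
            "bav": self.bav,
        }


def blink_rate(series: BlinkSeries) -> float:
    """Blinks per minute."""
    if series.duration <= 0:
        raise ValueError("segment duration must be positive")
    return len(series) / (series.duration / 60.0)


def blink_amplitude(series: BlinkSeries) -> float:
    """Mean peak voltage over events; NaN when the segment has no blinks."""
    if len(series) == 0:
        return MISSING
    return float(np.mean(series.peak_amplitudes))


def coefficient_of_variation(values) -> float:
    """Sample SD (n-1 denominator) divided by the mean.

    NaN for fewer than two values; a non-positive mean is a domain error.
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size < 2:
        return MISSING
    mean = v.mean()
    if mean <= 0:
        raise ValueError("coefficient of variation requires a positive mean")
    return float(v.std(ddof=1) / mean)


def compute_metrics(series: BlinkSeries) -> BlinkMetrics:
    """All four indices for one segment; degenerate inputs yield NaN, never raise."""
    n = len(series)
    ibis = compute_ibis(series)
    return BlinkMetrics(
        br=blink_rate(series),
        ba=blink_amplitude(series),
        brv=coefficient_of_variation(ibis) if n >= 3 else MISSING,
        bav=coefficient_of_variation(series.peak_amplitudes) if n >= 2 else MISSING,
        n_blinks=n,
        duration=series.duration,
    )


def aggregate_films(per_clip: list[BlinkMetrics]) -> BlinkMetrics:
    """Unweighted per-index mean over clips where the index is defined.

    Counts are summed; an index missing in every clip stays missing.
    """
    if not per_clip:
        raise ValueError("need at least one clip to aggregate")

    def _mean(values: list[float]) -> float:
        defined = [v for v in values if not math.isnan(v)]
        return float(np.mean(defined)) if defined else MISSING

    return BlinkMetrics(
        br=_mean([m.br for m in per_clip]),
        ba=_mean([m.ba for m in per_clip]),
        brv=_mean([m.brv for m in per_clip]),
        bav=_mean([m.bav for m in per_clip]),
        n_blinks=int(sum(m.n_blinks for m in per_clip)),
        duration=float(sum(m.duration for m in per_clip)),
    )


def metrics_frame(rows: list[dict]) -> pd.DataFrame:
    """Tidy long-format table: one row per (subject, segment).

    ``rows`` items need keys subject, segment, condition and a BlinkMetrics
    under ``metrics``.
    """
    records = []
    for row in rows:
        rec = {
            "subject": row["subject"],
            "segment": row["segment"],
            "condition": row.get("condition"),
        }
        rec.update(row["metrics"].as_dict())
        records.append(rec)
    return pd.DataFrame.from_records(
        records,
        columns=[
            "subject", "segment", "condition",
            "n_blinks", "duration_s", "br", "ba_uv", "brv", "bav",
        ],
    )
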