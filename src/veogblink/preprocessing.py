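"""Band-pass filtering of the bipolar VEOG ahead of blink detection.

Default passband 0.5-20 Hz, realized as a 4th-order Butterworth applied
forward-backward (zero phase) so blink peak amplitudes and latencies are
preserved.  Filtering is meant to be applied per analysis segment, not across
segment joins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from veogblink.signal_io import BipolarVEOG

__all__ = ["NyquistError", "SignalTooShortError", "FilterSpec", "bandpass_filter"]


class NyquistError(ValueError):
    """Passband edge at or above the Nyquist frequency."""


class SignalTooShortError(ValueError):
    """Signal shorter than the edge padding the zero-phase pass requires."""


@dataclass(frozen=True)
class FilterSpec:
    low_cut: float = 0.5
    high_cut: float = 20.0
    order: int = 4
    zero_phase: bool = True

    def __post_init__(self):
        if not 0 < self.low_cut < self.high_cut:
            raise ValueError("need 0 < low_cut < high_cut")
        if self.order < 1:
            raise ValueError("order must be a positive integer")

    def design(self, fs: float) -> np.ndarray:
        """Second-order sections for this band at sampling rate ``fs``."""
        if fs <= 2 * self.high_cut:
            raise NyquistError(
                f"high cut {self.high_cut} Hz requires fs > {2 * self.high_cut} Hz "
                f"(got fs = {fs} Hz)"
            )
        return sps.butter(
            self.order, [self.low_cut, self.high_cut], btype="bandpass",
            fs=fs, output="sos",
        )

    def response_db(self, freq_hz: float, fs: float) -> float:
        """Magnitude response (dB) of one pass at ``freq_hz``; doubles when
        applied forward-backward."""
        sos = self.design(fs)
        _, h = sps.sosfreqz(sos, worN=[freq_hz], fs=fs)
        mag = 20.0 * np.log10(np.abs(h[0]))
        return 2.0 * mag if self.zero_phase else mag


def bandpass_filter(veog: BipolarVEOG, spec: FilterSpec = FilterSpec()) -> BipolarVEOG:
    """Filter a bipolar VEOG to the configured passband.

    Output has the same length as the input; with ``zero_phase`` the filter is
    run forward and backward over a reflectively padded signal, so symmetric
    waveforms keep their peak latency.
    """
    sos = spec.design(veog.fs)
    x = veog.samples
    if spec.zero_phase:
        # default sosfiltfilt padding: 3 x the filter's per-section state length
        padlen = 3 * (2 * sos.shape[0] + 1)
        if x.size <= padlen:
            raise SignalTooShortError(
                f"signal of {x.size} samples is too short for zero-phase edge "
                f"padding ({padlen} samples)"
            )
        y = sps.sosfiltfilt(sos, x, padlen=padlen)
    else:
        y = sps.sosfilt(sos, x)
    return BipolarVEOG(y, veog.fs, veog.derivation)
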