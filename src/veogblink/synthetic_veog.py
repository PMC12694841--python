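"""Ground-truthed synthetic VEOG traces and multi-subject cohorts.

Blink timing is a gamma-renewal process (independent control of rate and
timing regularity: an IBI gamma shape ``k`` gives a long-run IBI CV of
``1/sqrt(k)``); per-blink peak amplitudes are lognormal (long-run amplitude
CV ``sqrt(exp(sigma^2) - 1)``).  Subject-level blink parameters and anxiety
scores are tied together through a Gaussian copula so that configured
population Pearson correlations are hit exactly in expectation, including an
optional full-mediation structure (trait score acts on blink parameters only
through the state score).

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from veogblink.blink_detection import BlinkEvent, BlinkSeries
from veogblink.blink_metrics import compute_metrics, metrics_frame
from veogblink.signal_io import BipolarVEOG, SegmentSpec, SignalTrace

__all__ = [
    "WaveformParams",
    "ProcessParams",
    "CohortParams",
    "sample_blink_times",
    "synth_trace",
    "synth_cohort",
    "simulate_cohort_metrics",
    "render_subject_recording",
    "series_from_events",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    if seed is None:
        raise ValueError("an explicit seed is required for stochastic generation")
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# waveforms


@dataclass(frozen=True)
class WaveformParams:
    """Blink waveform template: rise/fall half-durations and shape."""

    rise_ms: float = 120.0
    fall_ms: float = 180.0
    peak_uv: float = 1.0
    shape: str = "gaussianlike"  # or "asymmetric-gamma"

    def __post_init__(self):
        total = self.rise_ms + self.fall_ms
        if not 50.0 <= total <= 600.0:
            raise ValueError("total waveform duration must lie in [50, 600] ms")
        if self.peak_uv <= 0:
            raise ValueError("peak amplitude must be positive")
        if self.shape not in {"gaussianlike", "asymmetric-gamma"}:
            raise ValueError(f"unknown waveform shape {self.shape!r}")

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        """Unit-peak waveform at offsets ``t`` (s) relative to the peak."""
        t = np.asarray(t, dtype=np.float64)
        rise = self.rise_ms / 1e3
        fall = self.fall_ms / 1e3
        out = np.zeros_like(t)
        if self.shape == "gaussianlike":
            # half-cosine lobes: smooth, exactly zero outside [-rise, fall]
            m = (t >= -rise) & (t < 0)
            out[m] = 0.5 * (1.0 + np.cos(np.pi * t[m] / rise))
            m = (t >= 0) & (t <= fall)
            out[m] = 0.5 * (1.0 + np.cos(np.pi * t[m] / fall))
        else:
            kappa = self._gamma_kappa()
            m = (t >= -rise) & (t <= fall)
            u = (t[m] + rise) / rise
            out[m] = u**kappa * np.exp(kappa * (1.0 - u))
        return self.peak_uv * out

    def _gamma_kappa(self) -> float:
        # decay exponent such that the tail has fallen to 1% at +fall_ms
        ratio = (self.fall_ms + self.rise_ms) / self.rise_ms

        def edge(kappa):
            return kappa * (math.log(ratio) + 1.0 - ratio) - math.log(0.01)

        return brentq(edge, 1e-3, 1e4)


# ---------------------------------------------------------------------------
# renewal process


@dataclass(frozen=True)
class ProcessParams:
    """Per-segment blink-process parameters."""

    rate: float = 16.9  # blinks per minute
    ibi_shape: float = 4.0  # gamma shape k; IBI CV = 1/sqrt(k)
    amp_log_mu: float = math.log(300.0)
    amp_log_sigma: float = 0.25
    noise_sigma: float = 10.0  # uV
    drift_uv: float = 0.0
    drift_hz: float = 0.1
    min_ibi: float = 0.3  # generated IBIs clipped below at this value (s)

    def __post_init__(self):
        if self.rate <= 0:
            raise ValueError("blink rate must be positive")
        if self.ibi_shape <= 0:
            raise ValueError("gamma shape must be positive")


def sample_blink_times(params: ProcessParams, duration: float, seed) -> np.ndarray:
    """Gamma-renewal blink peak times in ``[0, duration)``.

    IBIs are i.i.d. gamma with mean ``60 / rate`` and shape ``ibi_shape``,
    clipped below at ``min_ibi`` so every generated pair of consecutive
    blinks stays resolvable under the refractory rule.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = _rng(seed)
    mean_ibi = 60.0 / params.rate
    scale = mean_ibi / params.ibi_shape
    chunk = max(16, int(duration / mean_ibi * 1.25) + 16)
    times: list[np.ndarray] = []
    t = 0.0
    while t < duration:
        ibis = np.maximum(
            rng.gamma(params.ibi_shape, scale, size=chunk), params.min_ibi
        )
        cum = t + np.cumsum(ibis)
        times.append(cum)
        t = cum[-1]
    all_times = np.concatenate(times)
    return all_times[all_times < duration]


def synth_trace(
    times: np.ndarray,
    waveform: WaveformParams,
    params: ProcessParams,
    fs: float,
    duration: float,
    seed,
) -> tuple[BipolarVEOG, pd.DataFrame]:
    """Render blink events into a noisy bipolar VEOG trace.

    Returns the trace and a ground-truth table (``time_s``: exact peak time,
    ``amplitude_uv``: noiseless peak amplitude, ``overlap``: whether the
    waveform support overlaps a neighbouring event's).
    """
    if fs < 100:
        raise ValueError("sampling rate must be >= 100 Hz")
    rng = _rng(seed)
    times = np.asarray(times, dtype=np.float64)
    n = int(round(duration * fs))
    x = np.zeros(n)

    amplitudes = np.exp(
        rng.normal(params.amp_log_mu, params.amp_log_sigma, size=times.size)
    )
    rise = waveform.rise_ms / 1e3
    fall = waveform.fall_ms / 1e3
    for t0, amp in zip(times, amplitudes):
        i0 = max(0, int(math.floor((t0 - rise) * fs)))
        i1 = min(n, int(math.ceil((t0 + fall) * fs)) + 1)
        if i1 <= i0:
            continue
        tt = np.arange(i0, i1) / fs - t0
        x[i0:i1] += amp * waveform.evaluate(tt) / waveform.peak_uv

    if params.drift_uv:
        tgrid = np.arange(n) / fs
        x += params.drift_uv * np.sin(2 * np.pi * params.drift_hz * tgrid)
    if params.noise_sigma:
        x += rng.normal(0.0, params.noise_sigma, size=n)

    overlap = np.zeros(times.size, dtype=bool)
    if times.size > 1:
        gaps = np.diff(times)
        close = gaps < (rise + fall)
        overlap[:-1] |= close
        overlap[1:] |= close
    truth = pd.DataFrame(
        {"time_s": times, "amplitude_uv": amplitudes, "overlap": overlap}
    )
    return BipolarVEOG(x, fs, ("synthetic", "zero")), truth


def series_from_events(
    times, amplitudes, duration: float, segment: SegmentSpec | None = None
) -> BlinkSeries:
    """Build a BlinkSeries straight from ground-truth events (detection bypass)."""
    events = [
        BlinkEvent(peak_time=float(t), peak_amplitude=float(a), peak_index=-1)
        for t, a in zip(times, amplitudes)
    ]
    return BlinkSeries(events, duration, segment)


# ---------------------------------------------------------------------------
# cohort generation


FILM_CONDITIONS = [
    "negative1", "negative2", "negative3", "positive1", "positive2", "neutral",
]


@dataclass(frozen=True)
class CohortParams:
    """Population-level targets for a synthetic cohort.

    ``effects`` maps blink indices (``ba``, ``br``, ``brv``) to the target
    population Pearson correlation between the state score and the
    subject-level index; ``direct_effects`` adds trait-score paths that do
    not run through the state score (all zero under full mediation).
    """

    n_subjects: int = 50
    stai_s_mean: float = 40.0
    stai_s_sd: float = 10.0
    stai_t_mean: float = 42.0
    stai_t_sd: float = 9.0
    trait_state_corr: float = 0.67
    effects: dict = field(
        default_factory=lambda: {"ba": 0.557, "br": 0.418, "brv": -0.349}
    )
    direct_effects: dict = field(default_factory=dict)
    mediation: bool = True
    br_mean: float = 16.9  # between-subject mean blink rate (blinks/min)
    br_sd: float = 9.28  # between-subject SD of blink rate
    ba_log_mu: float = math.log(300.0)
    ba_log_sigma: float = 0.3
    brv_logit_mu: float = 0.0  # logit of subject long-run BRV (0.0 -> 0.5)
    brv_logit_sigma: float = 0.4
    amp_within_sigma: float = 0.25  # within-subject lognormal amplitude spread
    noise_sigma: float = 10.0
    n_films: int = 18
    film_duration: float = 120.0
    rest_duration: float = 300.0
    baseline_duration: float = 30.0
    condition_rate_offsets: dict = field(default_factory=dict)
    group_stai_s_delta: float = 0.0
    min_ibi: float = 0.3

    def __post_init__(self):
        for name, value in {"trait_state_corr": self.trait_state_corr,
                            **self.effects, **self.direct_effects}.items():
            if not -1.0 < float(value) < 1.0:
                raise ValueError(f"target correlation {name} must lie in (-1, 1)")
        unknown = set(self.effects) - {"ba", "br", "brv"}
        if unknown:
            raise ValueError(f"unsupported effect targets: {sorted(unknown)}")


def _corr_shrinkage(transform, n_nodes: int = 201) -> float:
    """Corr(Z, g(Z)) for standard-normal Z and monotone g (Gauss-Hermite).

    For any (S, Z) bivariate standard normal with correlation rho,
    Corr(S, g(Z)) = rho * Corr(Z, g(Z)); dividing a target correlation by
    this factor therefore yields the latent correlation to use.
    """
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
    w = weights / weights.sum()
    g = transform(nodes)
    mean = float(w @ g)
    var = float(w @ (g - mean) ** 2)
    cov_zg = float(w @ (nodes * (g - mean)))
    return cov_zg / math.sqrt(var)


def _lognormal_for_mean_sd(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def synth_cohort(params: CohortParams, seed) -> pd.DataFrame:
    """Draw a cohort: one row per (subject, segment), long format.

    Columns: subject, segment, segment_kind, condition, duration_s, stai_s,
    stai_t, group, plus the per-segment renewal parameters (rate, ibi_shape,
    amp_log_mu, amp_log_sigma, noise_sigma).  Subject-level blink parameters
    are drawn from a Gaussian copula whose latent correlations are corrected
    (Gauss-Hermite) for each margin's nonlinearity, so configured targets are
    population Pearson correlations of the observable quantities.
    """
    rng = _rng(seed)
    n = params.n_subjects
    rho_ts = params.trait_state_corr

    z_t = rng.standard_normal(n)
    z_s = rho_ts * z_t + math.sqrt(1 - rho_ts**2) * rng.standard_normal(n)
    z_t_resid = (z_t - rho_ts * z_s) / math.sqrt(1 - rho_ts**2)

    br_log_mu, br_log_sigma = _lognormal_for_mean_sd(params.br_mean, params.br_sd)
    transforms = {
        "ba": lambda z: np.exp(params.ba_log_mu + params.ba_log_sigma * z),
        "br": lambda z: np.exp(br_log_mu + br_log_sigma * z),
        "brv": lambda z: expit(params.brv_logit_mu + params.brv_logit_sigma * z),
    }

    subject_vals: dict[str, np.ndarray] = {}
    for index, g in transforms.items():
        target = float(params.effects.get(index, 0.0))
        direct = float(params.direct_effects.get(index, 0.0))
        if params.mediation and direct != 0.0:
            raise ValueError("direct effects must be zero under full mediation")
        c = _corr_shrinkage(g)
        rho = target / c
        if rho**2 + direct**2 >= 1.0:
            raise ValueError(
                f"targets for {index!r} imply an infeasible (non positive "
                f"definite) latent correlation structure"
            )
        z_x = (
            rho * z_s
            + direct * z_t_resid
            + math.sqrt(1.0 - rho**2 - direct**2) * rng.standard_normal(n)
        )
        subject_vals[index] = g(z_x)

    stai_t = params.stai_t_mean + params.stai_t_sd * z_t
    stai_s = params.stai_s_mean + params.stai_s_sd * z_s
    group = np.where(rng.random(n) < 0.5, "low", "high")
    if params.group_stai_s_delta:
        stai_s = stai_s + np.where(
            group == "high", params.group_stai_s_delta / 2, -params.group_stai_s_delta / 2
        )

    conditions = [
        FILM_CONDITIONS[i % len(FILM_CONDITIONS)] for i in range(params.n_films)
    ]
    rows = []
    for j in range(n):
        base_rate = float(subject_vals["br"][j])
        shape_k = float(1.0 / subject_vals["brv"][j] ** 2)
        amp_mu = float(
            math.log(subject_vals["ba"][j]) - params.amp_within_sigma**2 / 2.0
        )
        common = {
            "subject": f"S{j + 1:03d}",
            "stai_s": float(stai_s[j]),
            "stai_t": float(stai_t[j]),
            "group": str(group[j]),
            "ibi_shape": shape_k,
            "amp_log_mu": amp_mu,
            "amp_log_sigma": params.amp_within_sigma,
            "noise_sigma": params.noise_sigma,
        }
        rows.append(
            {
                **common,
                "segment": "rest",
                "segment_kind": "rest",
                "condition": None,
                "duration_s": params.rest_duration,
                "rate": base_rate,
            }
        )
        order = rng.permutation(params.n_films)
        for pos, film_idx in enumerate(order):
            condition = conditions[film_idx]
            rows.append(
                {
                    **common,
                    "segment": f"film{pos + 1:02d}",
                    "segment_kind": "film",
                    "condition": condition,
                    "duration_s": params.film_duration,
                    "rate": base_rate
                    * float(params.condition_rate_offsets.get(condition, 1.0)),
                }
            )
    return pd.DataFrame(rows)


def simulate_cohort_metrics(cohort: pd.DataFrame, seed) -> pd.DataFrame:
    """Draw ground-truth events per segment and compute blink metrics.

    Operates at the event level (no waveform rendering), so it scales to
    thousands of subjects; use :func:`render_subject_recording` plus the
    detection pipeline when the full signal path should be exercised.
    """
    rng = _rng(seed)
    rows = []
    for rec in cohort.itertuples(index=False):
        pp = ProcessParams(
            rate=rec.rate,
            ibi_shape=rec.ibi_shape,
            amp_log_mu=rec.amp_log_mu,
            amp_log_sigma=rec.amp_log_sigma,
            noise_sigma=rec.noise_sigma,
        )
        times = sample_blink_times(pp, rec.duration_s, rng)
        amps = np.exp(rng.normal(pp.amp_log_mu, pp.amp_log_sigma, size=times.size))
        series = series_from_events(times, amps, rec.duration_s)
        rows.append(
            {
                "subject": rec.subject,
                "segment": rec.segment,
                "condition": rec.condition,
                "metrics": compute_metrics(series),
            }
        )
    frame = metrics_frame(rows)
    kind = cohort[["subject", "segment", "segment_kind"]].drop_duplicates()
    return frame.merge(kind, on=["subject", "segment"], how="left")


def render_subject_recording(
    subject_rows: pd.DataFrame,
    waveform: WaveformParams,
    fs: float,
    seed,
) -> tuple[SignalTrace, list[SegmentSpec], pd.DataFrame]:
    """Render one subject's full session as a two-channel recording.

    Segments are laid out in table order: rest first, then each film
    preceded by a 30 s baseline.  Baselines still contain blinks drawn from
    the subject's parameters; they are simply not listed as analysis
    segments.  The VEOG
    appears on the upper channel; the lower channel carries independent
    noise, so the bipolar derivation reproduces the blink signal.
    """
    rng = _rng(seed)
    specs: list[SegmentSpec] = []
    pieces: list[np.ndarray] = []
    truths: list[pd.DataFrame] = []
    t_cursor = 0.0
    baseline = 30.0

    for rec in subject_rows.itertuples(index=False):
        pp = ProcessParams(
            rate=rec.rate,
            ibi_shape=rec.ibi_shape,
            amp_log_mu=rec.amp_log_mu,
            amp_log_sigma=rec.amp_log_sigma,
            noise_sigma=rec.noise_sigma,
        )
        if rec.segment_kind == "film":
            base_times = sample_blink_times(pp, baseline, rng)
            base_trace, _ = synth_trace(base_times, waveform, pp, fs, baseline, rng)
            pieces.append(base_trace.samples)
            t_cursor += baseline
        times = sample_blink_times(pp, rec.duration_s, rng)
        trace, truth = synth_trace(times, waveform, pp, fs, rec.duration_s, rng)
        pieces.append(trace.samples)
        truth = truth.assign(segment=rec.segment)
        truths.append(truth)
        specs.append(
            SegmentSpec(
                label=rec.segment,
                onset=t_cursor,
                duration=rec.duration_s,
                condition=rec.condition if isinstance(rec.condition, str) else None,
            )
        )
        t_cursor += rec.duration_s

    veog = np.concatenate(pieces)
    lower = rng.normal(0.0, 2.0, size=veog.size)
    trace = SignalTrace(
        np.vstack([veog + lower, lower]), fs, ["Ve1", "Io1"]
    )
    truth_table = pd.concat(truths, ignore_index=True)
    return trace, specs, truth_table
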