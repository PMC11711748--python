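"""Gait signal processing: gap filling, smoothing, step detection, latency.

The processing chain mirrors an offline motion-capture/force-plate pipeline:

1. marker traces (250 Hz) with short missing-data gaps are repaired by cubic
   spline interpolation and smoothed with a Savitzky-Golay filter (124 ms
   window, order 3);
2. steps are detected offline from the combined left+right vertical ground
   reaction force (GRF): the combined signal is low-pass filtered with a
   524 ms window (chosen to cover about one step, never two), and events are
   taken at local maxima plus turning (inflection) points, de-duplicated
   within a 250 ms refractory window;
3. steps-to-response counts the detected steps between perturbation onset and
   the button press, capped at the 10-step response window.

A synthetic two-belt GRF generator provides scripted ground truth for
validating the detector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.signal import find_peaks, savgol_filter

from .exceptions import GapError, InputError, ParameterError, ParseError

__all__ = [
    "SampledTrace",
    "StepEvents",
    "fill_gaps",
    "smooth_markers",
    "detect_steps",
    "steps_to_response",
    "simulate_grf",
    "write_grf_csv",
    "read_grf_csv",
]

logger = logging.getLogger(__name__)

DEFAULT_RATE = 250.0           # samples/s, force plates and motion capture
MIN_STEP_INTERVAL_S = 0.25     # physiological floor at ~1 m/s walking
RESPONSE_WINDOW_STEPS = 10


@dataclass(frozen=True)
class SampledTrace:
    """Uniformly sampled signal with an optional missing-sample mask."""

    values: np.ndarray
    rate: float = DEFAULT_RATE
    missing_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if self.rate <= 0:
            raise ParameterError(f"rate must be > 0, got {self.rate}")
        mask = self.missing_mask
        if mask is None:
            mask = np.isnan(values)
        else:
            mask = np.asarray(mask, dtype=bool) | np.isnan(values)
        if len(mask) != len(values):
            raise ParameterError("missing_mask length must equal values length")
        object.__setattr__(self, "missing_mask", mask)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.rate


@dataclass(frozen=True)
class StepEvents:
    """Detected step event times in seconds, strictly increasing."""

    times: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if len(t) > 1:
            gaps = np.diff(t)
            if not np.all(gaps > 0):
                raise ParameterError("step event times must be strictly increasing")
            if gaps.min() < MIN_STEP_INTERVAL_S - 1e-9:
                raise ParameterError(
                    f"inter-event interval {gaps.min():.3f} s below the "
                    f"{MIN_STEP_INTERVAL_S} s physiological floor"
                )

    def __len__(self) -> int:
        return len(self.times)


def fill_gaps(trace: SampledTrace, max_gap_s: float = 0.2) -> SampledTrace:
    """Replace missing samples by natural cubic-spline interpolation.

    Present samples are left untouched.  Gaps at either edge of the trace, or
    longer than ``max_gap_s``, cannot be interpolated reliably and raise
    :class:`GapError` identifying the offending interval.
    """
    mask = trace.missing_mask
    if not mask.any():
        return trace
    if mask[0] or mask[-1]:
        raise GapError("cannot interpolate a gap at the trace edge (first or last sample missing)")
    idx = np.flatnonzero(mask)
    # split into contiguous runs and check each against the length limit
    run_starts = idx[np.r_[True, np.diff(idx) > 1]]
    run_ends = idx[np.r_[np.diff(idx) > 1, True]]
    max_len = int(round(max_gap_s * trace.rate))
    for s, e in zip(run_starts, run_ends):
        if e - s + 1 > max_len:
            raise GapError(
                f"gap of {(e - s + 1) / trace.rate * 1000:.0f} ms at samples [{s}, {e}] exceeds "
                f"the {max_gap_s * 1000:.0f} ms limit"
            )
    present = ~mask
    t = trace.times
    spline = CubicSpline(t[present], trace.values[present], bc_type="natural")
    values = trace.values.copy()
    values[mask] = spline(t[mask])
    return SampledTrace(values=values, rate=trace.rate, missing_mask=np.zeros_like(mask))


def _odd_window_samples(window_s: float, rate: float) -> int:
    w = int(round(window_s * rate))
    if w % 2 == 0:
        w += 1
        logger.info("even smoothing window adjusted up to %d samples", w)
    return w


def smooth_markers(trace: SampledTrace, window_s: float = 0.124, order: int = 3) -> SampledTrace:
    """Savitzky-Golay smoothing (local least-squares polynomial fit).

    The default 124 ms window is 31 samples at 250 Hz.  Polynomials up to
    ``order`` pass through unchanged.  An even window (after conversion to
    samples) is adjusted up by one sample with a log notice.
    """
    if trace.missing_mask.any():
        raise InputError("smooth_markers requires a gap-free trace; run fill_gaps first")
    w = _odd_window_samples(window_s, trace.rate)
    if order >= w:
        raise ParameterError(f"polynomial order {order} must be below the {w}-sample window")
    values = savgol_filter(trace.values, w, order)
    return replace(trace, values=values)


def _estimate_cadence(combined: np.ndarray, rate: float) -> float:
    """Dominant frequency (Hz) of the mean-removed combined GRF in 0.5-5 Hz."""
    x = combined - combined.mean()
    n = len(x)
    spec = np.abs(np.fft.rfft(x * np.hanning(n)))
    freqs = np.fft.rfftfreq(n, 1.0 / rate)
    band = (freqs >= 0.5) & (freqs <= 5.0)
    if not band.any() or spec[band].max() == 0:
        return 0.0
    return float(freqs[band][np.argmax(spec[band])])


def detect_steps(
    grf_left: SampledTrace,
    grf_right: SampledTrace,
    smooth_width_s: float = 0.524,
    refractory_s: float = MIN_STEP_INTERVAL_S,
) -> StepEvents:
    """Detect step events from the combined left+right GRF.

    The combined force is smoothed with a Savitzky-Golay filter of width
    ``smooth_width_s`` (order 3) and events are placed at local maxima of the
    smoothed signal; turning points (zero crossings of the smoothed second
    derivative) are added where no maximum falls within the refractory
    window.  An all-zero or constant input yields no events.

    The width must cover roughly one step but never two at the signal's
    cadence (estimated spectrally); otherwise a :class:`ParameterError` is
    raised, since maxima of the filtered signal then no longer map one-to-one
    onto steps.
    """
    if len(grf_left.values) != len(grf_right.values) or grf_left.rate != grf_right.rate:
        raise InputError("left and right GRF traces must share length and rate")
    rate = grf_left.rate
    combined = grf_left.values + grf_right.values
    if np.allclose(combined, combined[0]):
        return StepEvents(times=np.array([]))
    cadence = _estimate_cadence(combined, rate)
    coverage = smooth_width_s * cadence
    if not (0.8 <= coverage < 2.0):
        raise ParameterError(
            f"smoothing width {smooth_width_s * 1000:.0f} ms covers {coverage:.2f} steps at the "
            f"estimated cadence {cadence:.2f} steps/s; it must cover about one step but never two"
        )
    w = _odd_window_samples(smooth_width_s, rate)
    smoothed = savgol_filter(combined, w, 3)
    refractory = int(round(refractory_s * rate))
    prominence = 0.05 * np.ptp(smoothed)
    peaks, _ = find_peaks(smoothed, distance=refractory + 1, prominence=prominence)
    # turning points: sign changes of the smoothed second derivative
    d2 = savgol_filter(combined, w, 3, deriv=2)
    turns = np.flatnonzero(np.diff(np.signbit(d2))) + 1
    # only keep events where the belts are actually loaded: sign changes of a
    # near-zero curvature in unloaded stretches are noise, not steps
    loaded = smoothed > smoothed.min() + 0.25 * np.ptp(smoothed)
    peaks = peaks[loaded[peaks]]
    turns = turns[loaded[turns]]
    if len(peaks):
        # turning points on the lead-in/lead-out load ramps are not steps;
        # they only stand in for washed-out maxima between real ones
        turns = turns[(turns > peaks.min()) & (turns < peaks.max())]
    events = _merge_events(peaks, turns, refractory)
    return StepEvents(times=events / rate)


def _merge_events(peaks: np.ndarray, turns: np.ndarray, refractory: int) -> np.ndarray:
    """Maxima take precedence; turning points fill only uncovered stretches."""
    accepted = list(np.sort(peaks))
    for t in np.sort(turns):
        if all(abs(t - a) > refractory for a in accepted):
            accepted.append(t)
    return np.array(sorted(accepted), dtype=float)


def steps_to_response(events: StepEvents, onset: float, response_time: float,
                      cap: int = RESPONSE_WINDOW_STEPS) -> int:
    """Number of detected steps in ``(onset, response_time]``, capped at the window."""
    if onset > response_time:
        raise InputError(f"onset {onset} s must not exceed response time {response_time} s")
    count = int(np.sum((events.times > onset) & (events.times <= response_time)))
    return min(count, cap)


def simulate_grf(
    n_steps: int = 40,
    cadence: float = 2.0,
    rate: float = DEFAULT_RATE,
    noise: float = 0.0,
    rng: np.random.Generator | int | None = None,
    amplitude: float = 700.0,
    jitter: float = 0.01,
) -> tuple[SampledTrace, SampledTrace, np.ndarray]:
    """Synthetic two-belt GRF with scripted foot contacts.

    Alternating feet load half-sine stance curves of duration ``1.25/cadence``
    (overlapping double support), amplitude in newtons, with optional timing
    jitter (fractional SD of the step period) and additive white noise.
    Returns ``(grf_left, grf_right, contact_times)`` where ``contact_times``
    are the scripted ground-truth step onsets.
    """
    if n_steps < 1:
        raise ParameterError(f"n_steps must be >= 1, got {n_steps}")
    if cadence <= 0:
        raise ParameterError(f"cadence must be > 0, got {cadence}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    period = 1.0 / cadence
    contacts = 1.0 + period * np.arange(n_steps)
    if jitter > 0:
        contacts = contacts + rng.normal(0.0, jitter * period, n_steps)
        contacts.sort()
    stance = 1.25 * period
    duration = contacts[-1] + stance + 1.0
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    left = np.zeros(n)
    right = np.zeros(n)
    for i, c in enumerate(contacts):
        phase = (t - c) / stance
        load = np.where((phase >= 0) & (phase <= 1), np.sin(np.pi * np.clip(phase, 0, 1)), 0.0)
        if i % 2 == 0:
            left += amplitude * load
        else:
            right += amplitude * load
    if noise > 0:
        left = left + rng.normal(0.0, noise, n)
        right = right + rng.normal(0.0, noise, n)
    return (
        SampledTrace(values=left, rate=rate),
        SampledTrace(values=right, rate=rate),
        contacts,
    )


def write_grf_csv(grf_left: SampledTrace, grf_right: SampledTrace, path) -> None:
    pd.DataFrame(
        {"time": grf_left.times, "left_grf": grf_left.values, "right_grf": grf_right.values}
    ).to_csv(path, index=False)


def read_grf_csv(path) -> tuple[SampledTrace, SampledTrace]:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("time", "left_grf", "right_grf"):
        if col not in df.columns:
            raise ParseError(f"GRF trace file missing column {col!r}")
    t = df["time"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ParseError("GRF trace needs at least two samples")
    rate = 1.0 / float(np.median(np.diff(t)))
    return (
        SampledTrace(values=df["left_grf"].to_numpy(dtype=float), rate=rate),
        SampledTrace(values=df["right_grf"].to_numpy(dtype=float), rate=rate),
    )
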