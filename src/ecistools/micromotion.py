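"""Micromotion analysis: detrend/normalise, moving variance, and the
high-to-low activity transition half-time.

Defaults follow the windowed-variance convention: non-overlapping
512-sample segments, a 150-sample window slid in 1-sample steps, giving
363 variance points per segment (512 - 150 + 1).  At the 160 s sweep
interval a segment spans 22.75 h (two-decimal truncation of 512*160 s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .core import ChannelTrace
from .errors import DataError, DomainError

__all__ = [
    "VarianceTrace",
    "TransitionEstimate",
    "detrend_normalize",
    "moving_variance",
    "segment_span_hours",
    "micromotion_analysis",
    "transition_half_time",
]

DEFAULT_WINDOW = 150
DEFAULT_STEP = 1
DEFAULT_SEGMENT = 512


def segment_span_hours(segment: int = DEFAULT_SEGMENT,
                       interval_s: float = 160.0,
                       decimals: int = 2) -> float:
    """Duration of one analysis segment in hours, truncated (not rounded)
    to the given number of decimals."""
    span = segment * interval_s / 3600.0
    scale = 10 ** decimals
    return math.floor(span * scale) / scale


@dataclass
class VarianceTrace:
    """Moving variance of a detrended, normalised signal segment."""

    times_h: np.ndarray          # window-centre timestamps
    variance: np.ndarray         # dimensionless
    window: int = DEFAULT_WINDOW
    step: int = DEFAULT_STEP
    segment: int = DEFAULT_SEGMENT
    segment_start_h: float = 0.0

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.variance = np.asarray(self.variance, dtype=float)
        if self.times_h.shape != self.variance.shape:
            raise DataError("times and variance must have equal length")
        if np.any(self.variance < -1e-300):
            raise DataError("variance must be non-negative")


@dataclass
class TransitionEstimate:
    """Descending-logistic fit of a variance trace."""

    half_time_h: float           # relative to segment start
    high_level: float
    low_level: float
    rate_per_h: float
    converged: bool
    message: str = ""


def detrend_normalize(values) -> np.ndarray:
    """Subtract the least-squares line, then divide by the pre-detrend mean.

    The output is dimensionless with mean ~ 0 and is invariant to
    multiplicative rescaling of the input.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise DataError("need at least 3 samples to detrend")
    if not np.all(np.isfinite(v)):
        raise DataError("detrend input contains non-finite samples")
    mean = v.mean()
    if mean == 0.0:
        raise DataError("cannot normalise a zero-mean signal")
    x = np.arange(v.size, dtype=float)
    slope, intercept = np.polyfit(x, v, 1)
    return (v - (slope * x + intercept)) / mean


def moving_variance(values, times_h=None, window: int = DEFAULT_WINDOW,
                    step: int = DEFAULT_STEP) -> VarianceTrace:
    """Unbiased sample variance in a sliding window.

    Output length is ``(n - window) // step + 1`` (363 for the 512/150/1
    defaults).  Timestamps are window centres; sample indices are used
    when ``times_h`` is omitted.
    """
    v = np.asarray(values, dtype=float)
    if window < 2:
        raise DomainError("window must be at least 2 samples")
    if step < 1:
        raise DomainError("step must be at least 1 sample")
    if v.size < window:
        raise DataError(f"series length {v.size} < window {window}")
    if times_h is None:
        times_h = np.arange(v.size, dtype=float)
    t = np.asarray(times_h, dtype=float)
    if t.shape != v.shape:
        raise DataError("times and values must have equal length")
    sw = np.lib.stride_tricks.sliding_window_view(v, window)[::step]
    var = sw.var(axis=1, ddof=1)
    # constant windows are identically zero, not rounding noise
    var[sw.max(axis=1) == sw.min(axis=1)] = 0.0
    tw = np.lib.stride_tricks.sliding_window_view(t, window)[::step]
    centres = tw.mean(axis=1)
    return VarianceTrace(centres, var, window=window, step=step, segment=v.size)


def micromotion_analysis(trace: ChannelTrace, window: int = DEFAULT_WINDOW,
                         step: int = DEFAULT_STEP,
                         segment: int = DEFAULT_SEGMENT,
                         start_h: float | None = None) -> list[VarianceTrace]:
    """Segment a resistance trace and run detrend -> moving variance.

    Consecutive non-overlapping ``segment``-sample blocks are taken from
    ``start_h`` (default: the first sample); a trailing partial block is
    dropped.  Flagged gaps are not permitted inside a block.
    """
    t = trace.times_h
    v = trace.values
    if start_h is not None:
        keep = t >= start_h
        t, v = t[keep], v[keep]
    n_blocks = v.size // segment
    if n_blocks == 0:
        raise DataError(f"trace shorter than one {segment}-sample segment")
    out: list[VarianceTrace] = []
    for b in range(n_blocks):
        sl = slice(b * segment, (b + 1) * segment)
        block_v = v[sl]
        block_t = t[sl]
        if not np.all(np.isfinite(block_v)):
            raise DataError(f"segment {b} contains flagged gaps")
        norm = detrend_normalize(block_v)
        vt = moving_variance(norm, block_t, window=window, step=step)
        vt.segment = segment
        vt.segment_start_h = float(block_t[0])
        out.append(vt)
    return out


def _windowed_logistic(t, high, low, rate, t_half, window_span):
    """Descending logistic averaged over the moving-variance window.

    Each variance point is the window mean of the underlying signal
    variance, so the model convolves the logistic with the same boxcar:
    the closed form uses log(1+exp) integrals.
    """
    a = t - window_span / 2.0
    b = t + window_span / 2.0
    frac = ((b - a) - (np.logaddexp(0.0, rate * (b - t_half))
                       - np.logaddexp(0.0, rate * (a - t_half))) / rate) / (b - a)
    return low + (high - low) * frac


def transition_half_time(vt: VarianceTrace) -> TransitionEstimate:
    """Fit a descending variance schedule; half-time = fitted midpoint.

    The model is a descending logistic *convolved with the moving-variance
    window* (deconvolving the smoothing the window applies to the true
    schedule), fitted on the log scale because variance-estimate noise is
    multiplicative.  The half-time is reported relative to the segment
    start.
    """
    t = vt.times_h - vt.segment_start_h
    y = vt.variance
    if t.size < 8:
        raise DataError("variance trace too short for a transition fit")
    dt = float(np.median(np.diff(t))) if t.size > 1 else 1.0
    raw_dt = dt / max(vt.step, 1)          # trace spacing = step * sample dt
    window_span = max(vt.window * raw_dt, dt)
    log_y = np.log(np.maximum(y, 1e-30))
    hi0 = float(np.quantile(y, 0.9))
    lo0 = max(float(np.quantile(y, 0.1)), 1e-12)
    span = t[-1] - t[0]

    def resid(p):
        m = _windowed_logistic(t, p[0], p[1], p[2], p[3], window_span)
        return np.log(np.maximum(m, 1e-30)) - log_y

    best = None
    for frac in (0.25, 0.5, 0.75):
        p0 = [max(hi0, 1e-10), lo0, 2.0, t[0] + frac * span]
        try:
            sol = optimize.least_squares(
                resid, p0,
                bounds=([0.0, 0.0, 0.05, t[0]],
                        [np.inf, np.inf, 50.0, t[-1]]),
                max_nfev=5000)
        except ValueError:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return TransitionEstimate(math.nan, math.nan, math.nan, math.nan,
                                  False, "all starts failed")
    high, low, rate, t_half = (float(x) for x in best.x)
    converged = bool(best.success and high > low and rate > 0
                     and t[0] <= t_half <= t[-1])
    msg = "" if converged else "no descending transition found"
    return TransitionEstimate(t_half, high, low, rate, converged, msg)
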