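"""Healing kinetics: wound detection, sigmoid fitting, migration rate,
coverage from capacitance, and the attachment-slope adhesion assay.

Conventions (documented, configurable):

* Healing is fitted with a 4-parameter logistic
  ``R(t) = R_base + (R_plateau - R_base) / (1 + exp(-k (t - t50)))``
  with ``t`` in hours measured from the wound time; ``k`` is the hill
  slope (1/h) and ``t50`` the inflection point.
* Healing completion is the time the fitted curve reaches a fractional
  recovery threshold (default 0.95), with the closed form
  ``t = t50 + ln(thr/(1-thr)) / k``.
* The migration rate is radius-based by default: the front travels the
  wound radius (default 125 um, half the 250 um electrode) in the healing
  time.  A diameter-based convention is selectable.
* The default fit window is data driven: it ends at
  ``1.6 x`` the observed time for the trace to reach 99 % of its
  post-wound range (capped at ``max_window_h``).  On radial-front healing
  curves this calibrates out the bias between the fitted-logistic
  threshold time and the true closure time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .core import ChannelTrace
from .errors import CalibrationError, DataError, DomainError, FitError

__all__ = [
    "WoundEvent",
    "SigmoidFit",
    "MigrationResult",
    "AttachmentFit",
    "CoverageTrace",
    "detect_wound",
    "fit_healing_sigmoid",
    "healing_time",
    "migration_rate",
    "coverage_from_capacitance",
    "attachment_slope",
]

DEFAULT_WOUND_RADIUS_UM = 125.0


@dataclass(frozen=True)
class WoundEvent:
    """A detected (or scheduled) wounding event on one well."""

    t_wound_h: float
    baseline_ohm: float
    pulse: dict | None = None     # e.g. {"current_ma": 3, "freq_khz": 40, "duration_s": 30}


@dataclass
class SigmoidFit:
    """4-parameter logistic fit of a post-wound recovery curve."""

    r_base: float            # Ohm, post-wound floor
    r_plateau: float         # Ohm, healed plateau
    hill_slope: float        # 1/h
    t50: float               # h from wound time
    residual_sd: float       # Ohm
    converged: bool
    n_samples: int = 0
    window_h: float = float("nan")
    message: str = ""

    def predict(self, t_h):
        t = np.asarray(t_h, dtype=float)
        return self.r_base + (self.r_plateau - self.r_base) / (
            1.0 + np.exp(-self.hill_slope * (t - self.t50)))


@dataclass(frozen=True)
class MigrationResult:
    healing_time_h: float
    wound_radius_um: float
    rate_um_per_h: float
    convention: str = "radius"


@dataclass
class AttachmentFit:
    """Linear fit of the early attachment segment."""

    slope_ohm_per_h: float
    intercept_ohm: float
    window_h: tuple[float, float]
    r_squared: float
    n_samples: int


@dataclass
class CoverageTrace:
    """Fractional electrode coverage derived from the capacitance channel."""

    times_h: np.ndarray
    coverage: np.ndarray
    clipped_fraction: float
    well: str = ""


def _finite(trace: ChannelTrace):
    ok = np.isfinite(trace.values) & ~trace.missing
    return trace.times_h[ok], trace.values[ok]


def detect_wound(trace: ChannelTrace, cellfree_r_ohm: float,
                 tol: float = 0.10, pulse: dict | None = None) -> WoundEvent:
    """Locate a wound as the first drop to the cell-free level.

    The trace must first exceed ``2 x cellfree_r_ohm`` (a covered
    electrode); the wound time is the first later sample within ``tol``
    (relative) of the cell-free level.  The post-wound baseline is the
    trace minimum over the following 30 minutes.
    """
    if cellfree_r_ohm <= 0:
        raise DomainError("cellfree_r_ohm must be strictly positive")
    if not (0 < tol < 1):
        raise DomainError("tol must lie in (0, 1)")
    t, v = _finite(trace)
    if t.size == 0:
        raise DataError("empty trace")
    armed = v > 2.0 * cellfree_r_ohm
    if not armed.any():
        raise DataError("no wound detected: trace never exceeds 2x cell-free level")
    i0 = int(np.argmax(armed))
    near = np.abs(v - cellfree_r_ohm) <= tol * cellfree_r_ohm
    near[: i0 + 1] = False
    if not near.any():
        raise DataError("no wound detected: no drop to the cell-free level")
    iw = int(np.argmax(near))
    t_wound = float(t[iw])
    post = (t >= t_wound) & (t <= t_wound + 0.5)
    baseline = float(v[post].min())
    return WoundEvent(t_wound_h=t_wound, baseline_ohm=baseline, pulse=pulse)


def _auto_window(trel, v, max_window_h: float, factor: float = 1.6) -> float:
    inside = trel <= max_window_h
    vv = v[inside]
    lo, hi = vv.min(), vv.max()
    if hi <= lo:
        return max_window_h
    level = lo + 0.99 * (hi - lo)
    t99 = trel[inside][int(np.argmax(vv >= level))]
    return float(min(max_window_h, factor * t99))


def _logistic_residuals(p, t, v):
    base, plat, k, t50 = p
    return base + (plat - base) / (1.0 + np.exp(-k * (t - t50))) - v


def fit_healing_sigmoid(trace: ChannelTrace, wound: WoundEvent,
                        window_h: float | str = "auto",
                        max_window_h: float = 24.0,
                        min_samples: int = 20) -> SigmoidFit:
    """Least-squares logistic fit of the recovery following ``wound``.

    ``window_h`` is either an explicit window length in hours from the
    wound time, or ``"auto"`` (default; see module docstring).  Flagged
    gaps are ignored.  Multi-start on t50 at 25/50/75 % of the window.
    """
    t, v = _finite(trace)
    trel = t - wound.t_wound_h
    keep = trel >= 0
    trel, v = trel[keep], v[keep]
    if trel.size == 0:
        raise DataError("trace does not cover the wound")
    if window_h == "auto":
        window = _auto_window(trel, v, max_window_h)
    else:
        window = float(window_h)
        if window <= 0:
            raise DomainError("window_h must be positive")
    inside = trel <= window
    trel, v = trel[inside], v[inside]
    if trel.size < min_samples:
        raise DataError(
            f"only {trel.size} samples in the fit window (< {min_samples})")

    vspan = float(v.max() - v.min())
    best = None
    for frac in (0.25, 0.50, 0.75):
        p0 = [float(v.min()), float(v.max()), 0.5, frac * window]
        try:
            sol = optimize.least_squares(_logistic_residuals, p0,
                                         args=(trel, v), max_nfev=5000)
        except ValueError:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return SigmoidFit(math.nan, math.nan, math.nan, math.nan, math.nan,
                          converged=False, n_samples=trel.size,
                          window_h=window, message="all starts failed")
    base, plat, k, t50 = (float(x) for x in best.x)
    dof = max(trel.size - 4, 1)
    resid_sd = math.sqrt(2.0 * best.cost / dof)
    dynamic = plat - base
    converged = (
        bool(best.success)
        and k > 0
        and dynamic > 0
        and t50 > 0
        and dynamic > 3.0 * resid_sd
        and vspan > 0
    )
    msg = "" if converged else "degenerate fit (flat trace or bad geometry)"
    return SigmoidFit(base, plat, k, t50, resid_sd, converged,
                      n_samples=trel.size, window_h=window, message=msg)


def healing_time(fit: SigmoidFit, threshold: float = 0.95) -> float:
    """Time (h from wound) at which the fitted curve reaches the given
    fractional recovery; closed form ``t50 + ln(thr/(1-thr))/k``.
    """
    if not fit.converged:
        raise FitError("cannot compute healing time from an unconverged fit")
    if not (0 < threshold < 1):
        raise DomainError("threshold must lie in (0, 1)")
    return fit.t50 + math.log(threshold / (1.0 - threshold)) / fit.hill_slope


def migration_rate(healing_time_h: float,
                   wound_radius_um: float = DEFAULT_WOUND_RADIUS_UM,
                   convention: str = "radius") -> MigrationResult:
    """Average front speed: distance travelled / healing time.

    ``radius`` convention (default): the front covers the wound radius.
    ``diameter``: the front covers the full electrode diameter.
    """
    if healing_time_h <= 0 or wound_radius_um <= 0:
        raise DomainError("healing time and radius must be strictly positive")
    if convention == "radius":
        dist = wound_radius_um
    elif convention == "diameter":
        dist = 2.0 * wound_radius_um
    else:
        raise DomainError(f"unknown convention {convention!r}")
    return MigrationResult(healing_time_h, wound_radius_um,
                           dist / healing_time_h, convention)


def coverage_from_capacitance(trace: ChannelTrace, c_free: float,
                              c_confluent: float) -> CoverageTrace:
    """Linear coverage calibration of the high-frequency capacitance channel.

    ``coverage(t) = (C_free - C(t)) / (C_free - C_confluent)``, clipped to
    [0, 1]; the clipped fraction of samples is reported.
    """
    if not (c_free > c_confluent > 0):
        raise CalibrationError("need C_free > C_confluent > 0")
    raw = (c_free - trace.values) / (c_free - c_confluent)
    finite = np.isfinite(raw)
    clipped = np.mean((raw[finite] < 0) | (raw[finite] > 1)) if finite.any() else 0.0
    cov = np.clip(raw, 0.0, 1.0)
    return CoverageTrace(trace.times_h.copy(), cov, float(clipped), trace.well)


def attachment_slope(trace: ChannelTrace,
                     window_h: tuple[float, float] = (0.0, 24.0),
                     plateau_fraction: float = 0.95,
                     min_samples: int = 10) -> AttachmentFit:
    """OLS slope of the early attachment segment (impedance adhesion assay).

    The window must lie within the first 24 h of culture.  Within it, the
    fitted segment ends at the first sample reaching ``plateau_fraction``
    of the window maximum, restricting the fit to the rising part.
    """
    t0, t1 = window_h
    if not (0.0 <= t0 < t1 <= 24.0):
        raise DomainError("attachment window must lie within the first 24 h")
    t, v = _finite(trace)
    m = (t >= t0) & (t <= t1)
    t, v = t[m], v[m]
    if t.size < min_samples:
        raise DataError(f"only {t.size} samples in the attachment window")
    vmax = v.max()
    if vmax > v.min():
        end = int(np.argmax(v >= plateau_fraction * vmax))
        end = max(end, min_samples - 1)
        t, v = t[: end + 1], v[: end + 1]
    if t.size < min_samples:
        raise DataError(f"only {t.size} samples in the rising segment")
    slope, intercept = np.polyfit(t, v, 1)
    pred = slope * t + intercept
    ss_res = float(np.sum((v - pred) ** 2))
    ss_tot = float(np.sum((v - v.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return AttachmentFit(float(slope), float(intercept),
                         (float(t[0]), float(t[-1])), r2, int(t.size))
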