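"""Disk-cell microelectrode impedance model and adhesion-parameter fitting.

The cell-covered electrode is modelled as circular disk cells of radius
``rc`` hovering a distance ``h`` above the electrode in medium of
resistivity ``rho``.  The adhesion parameter ``alpha = rc * sqrt(rho / h)``
(units Ohm^1/2 cm) summarises how tightly the cells seal against the
substrate; together with the cell-cell barrier resistance ``Rb`` and the
membrane capacitance ``Cm`` it determines the transfer function between
the naked (cell-free) and covered specific impedances.

All specific impedances are in Ohm*cm^2; divide by the electrode area to
obtain absolute Ohm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, special

from .errors import DataError, DomainError, FitError

__all__ = [
    "CellModelParams",
    "NakedElectrodeModel",
    "AlphaFitResult",
    "alpha_from_geometry",
    "h_from_alpha",
    "naked_electrode_impedance",
    "covered_electrode_impedance",
    "mixed_coverage_impedance",
    "calibrate_naked_electrode",
    "fit_alpha",
]

#: default electrode area in cm^2 (0.05 mm^2 sensing pad)
DEFAULT_AREA_CM2 = 5e-4

#: default cell radius used when converting alpha to a separation h (10 um)
DEFAULT_CELL_RADIUS_CM = 1e-3


def alpha_from_geometry(rc: float, rho: float, h: float) -> float:
    """Adhesion parameter from disk geometry: ``alpha = rc * sqrt(rho/h)``.

    Parameters
    ----------
    rc : cell radius, cm
    rho : medium resistivity, Ohm*cm
    h : cell-substrate separation, cm
    """
    if rc <= 0 or rho <= 0 or h <= 0:
        raise DomainError("rc, rho and h must all be strictly positive")
    return rc * math.sqrt(rho / h)


def h_from_alpha(alpha: float, rc: float = DEFAULT_CELL_RADIUS_CM,
                 rho: float = 54.0) -> float:
    """Invert the geometry relation for the separation: ``h = rho*rc^2/alpha^2``."""
    if alpha <= 0 or rc <= 0 or rho <= 0:
        raise DomainError("alpha, rc and rho must all be strictly positive")
    return rho * rc * rc / (alpha * alpha)


@dataclass(frozen=True)
class CellModelParams:
    """Parameters of the disk-cell electrode model.

    ``alpha`` may be stored alone; when ``rc``, ``rho`` and ``h`` are all
    provided they must be consistent with ``alpha = rc*sqrt(rho/h)``.
    """

    alpha: float                      # Ohm^1/2 * cm
    rb: float = 2.0                   # cell-cell barrier resistance, Ohm*cm^2
    cm: float = 1.0                   # per-membrane capacitance, uF/cm^2
    rc: float | None = None           # cell radius, cm
    rho: float | None = None          # medium resistivity, Ohm*cm
    h: float | None = None            # cell-substrate separation, cm

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.rb < 0 or self.cm <= 0:
            raise DomainError("alpha, cm must be > 0 and rb >= 0")
        for name in ("rc", "rho", "h"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise DomainError(f"{name} must be strictly positive when set")
        if self.rc is not None and self.rho is not None and self.h is not None:
            expected = alpha_from_geometry(self.rc, self.rho, self.h)
            if not math.isclose(self.alpha, expected, rel_tol=1e-9):
                raise DomainError(
                    f"alpha={self.alpha} inconsistent with geometry "
                    f"(rc*sqrt(rho/h)={expected})"
                )


@dataclass(frozen=True)
class NakedElectrodeModel:
    """Cell-free electrode: constant-phase element in series with Rsol.

    ``Zn(f) = a * (j*2*pi*f)**-n + rsol`` in Ohm*cm^2.
    """

    a: float = 500.0                  # CPE magnitude, Ohm*cm^2*s^-n
    n: float = 0.9                    # CPE exponent, in (0, 1]
    rsol: float = 1.2914              # constriction + solution resistance, Ohm*cm^2
    area_cm2: float = DEFAULT_AREA_CM2

    def __post_init__(self) -> None:
        if not (0.0 < self.n <= 1.0):
            raise DomainError("CPE exponent n must lie in (0, 1]")
        if self.a <= 0 or self.rsol <= 0 or self.area_cm2 <= 0:
            raise DomainError("a, rsol and area must be strictly positive")


def naked_electrode_impedance(f, m: NakedElectrodeModel):
    """Specific impedance of the cell-free electrode, Ohm*cm^2 (complex)."""
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise DomainError("frequency must be strictly positive")
    return m.a * (1j * 2.0 * np.pi * f) ** (-m.n) + m.rsol


def calibrate_naked_electrode(
    r_target_ohm: float = 2600.0,
    f_hz: float = 4000.0,
    a: float = 500.0,
    n: float = 0.9,
    area_cm2: float = DEFAULT_AREA_CM2,
) -> NakedElectrodeModel:
    """Choose ``rsol`` so the absolute series resistance at ``f_hz`` equals
    ``r_target_ohm`` for the given CPE shape.
    """
    omega = 2.0 * np.pi * f_hz
    re_cpe = a * omega ** (-n) * math.cos(n * math.pi / 2.0)
    rsol = r_target_ohm * area_cm2 - re_cpe
    if rsol <= 0:
        raise DomainError(
            "CPE magnitude too large: no positive rsol reaches the target"
        )
    return NakedElectrodeModel(a=a, n=n, rsol=rsol, area_cm2=area_cm2)


def _disk_spreading_term(grc):
    """Evaluate ``(g/2) * I0(g) / I1(g)`` stably for complex ``g``.

    Small |g| uses the series expansion 1 + g^2/8 + O(g^4); moderate and
    large |g| use exponentially scaled Bessel functions whose scale factors
    cancel in the ratio (the ratio tends to 1 as |g| grows).
    """
    g = np.asarray(grc, dtype=complex)
    out = np.empty(g.shape, dtype=complex)
    small = np.abs(g) < 1e-4
    if np.any(small):
        gs = g[small]
        out[small] = 1.0 + gs * gs / 8.0
    if np.any(~small):
        gl = g[~small]
        i0 = special.ive(0, gl)
        i1 = special.ive(1, gl)
        val = 0.5 * gl * i0 / i1
        if not np.all(np.isfinite(val)):
            # asymptotic ratio I0/I1 ~ 1 + 1/(2g) + 3/(8 g^2)
            bad = ~np.isfinite(val)
            gb = gl[bad]
            val[bad] = 0.5 * gb * (1.0 + 0.5 / gb + 0.375 / (gb * gb))
            if not np.all(np.isfinite(val)):
                raise FloatingPointError(
                    "Bessel ratio evaluation failed for |g| = "
                    f"{np.abs(gb).max():g}"
                )
        out[~small] = val
    if out.shape == ():
        return complex(out)
    return out


def _membrane_impedance(f, cm_uf_cm2: float):
    """Two cell membranes in series, purely capacitive, Ohm*cm^2."""
    f = np.asarray(f, dtype=float)
    cm = cm_uf_cm2 * 1e-6
    return 2.0 / (1j * 2.0 * np.pi * f * cm)


def covered_electrode_impedance(f, m: NakedElectrodeModel, p: CellModelParams,
                                rb=None):
    """Specific impedance of the fully covered electrode, Ohm*cm^2.

    ``rb`` may override ``p.rb`` with a scalar or an array broadcastable
    against ``f`` (used by the simulator for time-varying barrier
    resistance).
    """
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise DomainError("frequency must be strictly positive")
    rb_val = p.rb if rb is None else np.asarray(rb, dtype=float)
    zn = naked_electrode_impedance(f, m)
    zm = _membrane_impedance(f, p.cm)
    ysum = 1.0 / zn + 1.0 / zm
    grc = p.alpha * np.sqrt(ysum)   # principal branch: Re(grc) >= 0
    spread = _disk_spreading_term(grc)
    bracket = zn / (zn + zm) + (zm / (zn + zm)) / (spread + rb_val * ysum)
    inv_zc = bracket / zn
    return 1.0 / inv_zc


def mixed_coverage_impedance(f, m: NakedElectrodeModel, p: CellModelParams,
                             coverage, rb=None):
    """Area-parallel mix of covered and naked electrode patches.

    ``1/Zmix = coverage/Zc + (1-coverage)/Zn``; coverage in [0, 1].
    """
    cov = np.asarray(coverage, dtype=float)
    if np.any(cov < 0) or np.any(cov > 1):
        raise DomainError("coverage must lie in [0, 1]")
    zn = naked_electrode_impedance(f, m)
    zc = covered_electrode_impedance(f, m, p, rb=rb)
    return 1.0 / (cov / zc + (1.0 - cov) / zn)


@dataclass
class AlphaFitResult:
    """Result of inverting a covered-electrode spectrum for (alpha, Rb, Cm)."""

    params: CellModelParams
    stderr: Mapping[str, float]
    residuals: np.ndarray
    objective: float
    converged: bool
    degenerate: bool = False
    message: str = ""

    def require_converged(self) -> "AlphaFitResult":
        if not self.converged:
            raise FitError(f"alpha fit did not converge: {self.message}")
        return self


_FREE_DEFAULT = ("alpha", "rb", "cm")
_DEFAULT_START = {"alpha": 5.0, "rb": 2.0, "cm": 1.0}


def _ratio_residuals(theta, free, fixed, f, data_ratio, m):
    vals = dict(fixed)
    vals.update({k: math.exp(t) for k, t in zip(free, theta)})
    p = CellModelParams(alpha=vals["alpha"], rb=vals["rb"], cm=vals["cm"])
    zc = covered_electrode_impedance(f, m, p)
    zn = naked_electrode_impedance(f, m)
    model_ratio = zc / zn
    return np.concatenate([
        np.log(np.abs(model_ratio)) - np.log(np.abs(data_ratio)),
        np.angle(model_ratio) - np.angle(data_ratio),
    ])


def fit_alpha(
    frequencies_hz: Sequence[float],
    z_ohm: Sequence[complex],
    m: NakedElectrodeModel,
    free: Sequence[str] = _FREE_DEFAULT,
    fixed: Mapping[str, float] | None = None,
    alpha_starts: Iterable[float] = (2.0, 5.0, 10.0),
) -> AlphaFitResult:
    """Weighted least-squares inversion of a covered-electrode spectrum.

    The objective compares ``[log|Zc/Zn|, arg(Zc/Zn)]`` between model and
    data across frequencies, which removes the electrode-area scale; the
    input spectrum may therefore be absolute Ohm or specific Ohm*cm^2.
    ``free`` defaults to (alpha, rb, cm); remaining parameters are taken
    from ``fixed`` (falling back to alpha=5, rb=2, cm=1 starting values).
    """
    f = np.asarray(frequencies_hz, dtype=float)
    z = np.asarray(z_ohm, dtype=complex)
    if f.shape != z.shape:
        raise DataError("frequencies and impedances must have equal length")
    if f.size < 6:
        raise DataError("need at least 6 frequencies to fit the model")
    if math.log10(f.max() / f.min()) < 2.0:
        raise DataError("frequencies must span at least two decades")
    if np.any(z.imag >= 0):
        raise DataError("spectrum contains non-capacitive samples (Im >= 0)")
    free = tuple(free)
    unknown = set(free) - set(_FREE_DEFAULT)
    if unknown:
        raise DomainError(f"unknown free parameters: {sorted(unknown)}")
    fixed_full = dict(_DEFAULT_START)
    if fixed:
        fixed_full.update(fixed)

    zn_abs = naked_electrode_impedance(f, m) / m.area_cm2
    # accept either absolute-Ohm or specific spectra: the ratio objective is
    # scale-free, so normalise by whichever naked spectrum matches better
    data_ratio = z / zn_abs
    if np.median(np.abs(data_ratio)) < 0.5:
        data_ratio = z / naked_electrode_impedance(f, m)

    best = None
    for a0 in alpha_starts:
        start = dict(fixed_full)
        start["alpha"] = a0
        theta0 = [math.log(start[k]) for k in free]
        try:
            sol = optimize.least_squares(
                _ratio_residuals, theta0,
                args=(free, fixed_full, f, data_ratio, m),
                method="lm", max_nfev=2000,
            )
        except (FloatingPointError, ValueError):
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return AlphaFitResult(
            params=CellModelParams(alpha=fixed_full["alpha"],
                                   rb=fixed_full["rb"], cm=fixed_full["cm"]),
            stderr={}, residuals=np.array([]), objective=math.inf,
            converged=False, message="all starts failed",
        )

    vals = dict(fixed_full)
    vals.update({k: math.exp(t) for k, t in zip(free, best.x)})
    params = CellModelParams(alpha=vals["alpha"], rb=vals["rb"], cm=vals["cm"])

    # covariance of log-parameters -> delta-method SEs on natural scale
    stderr: dict[str, float] = {}
    dof = best.fun.size - len(free)
    if dof > 0:
        s2 = 2.0 * best.cost / dof
        try:
            cov = s2 * np.linalg.inv(best.jac.T @ best.jac)
            for k, var in zip(free, np.diag(cov)):
                stderr[k] = vals[k] * math.sqrt(max(var, 0.0))
        except np.linalg.LinAlgError:
            pass

    degenerate = "alpha" in free and vals["alpha"] < 5e-2
    converged = bool(best.success) and not degenerate
    return AlphaFitResult(
        params=params, stderr=stderr, residuals=best.fun,
        objective=float(best.cost), converged=converged,
        degenerate=degenerate, message=best.message,
    )
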