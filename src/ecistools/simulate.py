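"""Seeded synthetic impedance experiments.

A simulated experiment reproduces the structure of an epithelial
wound-healing run on a 250 um microelectrode: an attachment rise of the
4 kHz resistance to a peak (default 15 kOhm at 48 h), a slow maturation
decline (default 5.5 days to 8.5 kOhm), an instantaneous wound dropping
the electrode to the cell-free baseline (default 2600 Ohm), sigmoid
recovery driven by an inward radial migration front, and mean-reverting
micromotion fluctuations whose variance follows a descending schedule.

Calibration is exact by construction at the schedule knots: the barrier
resistance Rb is numerically inverted (per well) so the noise-free 4 kHz
resistance equals the scheduled peak and plateau values at full coverage,
and a zero-coverage sample equals the cell-free baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize

from .core import DEFAULT_FREQUENCIES_HZ, ImpedanceTimeSeries
from .errors import ConfigError, DomainError
from .gk import (
    CellModelParams,
    NakedElectrodeModel,
    calibrate_naked_electrode,
    covered_electrode_impedance,
    mixed_coverage_impedance,
    naked_electrode_impedance,
)

__all__ = [
    "PhaseSchedule",
    "MicromotionModel",
    "WoundSpec",
    "GroupParams",
    "SimulationConfig",
    "simulate_wound_recovery_coverage",
    "simulate_spectrum",
    "simulate_timecourse",
    "calibrate_rb",
]

#: standard wounding pulse carried as metadata
DEFAULT_PULSE = {"current_ma": 3.0, "frequency_khz": 40.0, "duration_s": 30.0}


@dataclass(frozen=True)
class PhaseSchedule:
    """Knot values of the noise-free 4 kHz resistance trajectory."""

    rise_h: float = 48.0            # time of the attachment peak
    peak_r4k: float = 15000.0       # Ohm at the peak
    decline_h: float = 132.0        # duration of the maturation decline (5.5 d)
    plateau_r4k: float = 8500.0     # Ohm at the mature plateau
    cellfree_r4k: float = 2600.0    # Ohm, naked electrode

    def __post_init__(self) -> None:
        if not (self.peak_r4k > self.plateau_r4k > self.cellfree_r4k > 0):
            raise ConfigError("schedule requires peak > plateau > baseline > 0")
        if self.rise_h <= 0 or self.decline_h <= 0:
            raise ConfigError("phase durations must be positive")

    @property
    def plateau_start_h(self) -> float:
        return self.rise_h + self.decline_h


@dataclass(frozen=True)
class MicromotionModel:
    """AR(1) multiplicative perturbation of Rb with a scheduled amplitude.

    The *variance* of the perturbation follows a descending logistic from
    ``high_sd**2`` to ``low_sd**2`` with midpoint ``midpoint_h`` (measured
    from ``reference``: "start", "wound", or an absolute hour) and width
    ``width_h``; defining the schedule on the variance scale makes the
    moving-variance midpoint coincide with ``midpoint_h``.
    """

    high_sd: float = 0.05
    low_sd: float = 0.01
    midpoint_h: float = 11.5
    width_h: float = 2.0
    ar_tau_samples: float = 5.0
    reference: str | float = "start"

    def __post_init__(self) -> None:
        if self.high_sd < self.low_sd:
            raise ConfigError("high_sd must be >= low_sd")
        if self.low_sd < 0 or self.width_h <= 0 or self.ar_tau_samples <= 0:
            raise ConfigError("micromotion parameters out of range")

    def sd_at(self, t_h, t_ref_h: float = 0.0):
        """Scheduled perturbation SD at time t (variance-scale logistic)."""
        t = np.asarray(t_h, dtype=float)
        hi2, lo2 = self.high_sd ** 2, self.low_sd ** 2
        var = lo2 + (hi2 - lo2) / (
            1.0 + np.exp((t - t_ref_h - self.midpoint_h) / self.width_h))
        return np.sqrt(var)


@dataclass(frozen=True)
class WoundSpec:
    time_h: float
    pulse: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_PULSE))


@dataclass(frozen=True)
class GroupParams:
    """Per-group cell parameters and healing front speed."""

    alpha: float                    # Ohm^1/2 cm
    cm: float = 1.0                 # uF/cm^2
    front_speed_um_h: float = 10.0
    schedule: PhaseSchedule | None = None   # overrides the experiment schedule

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.cm <= 0 or self.front_speed_um_h <= 0:
            raise ConfigError("group parameters must be strictly positive")


@dataclass
class SimulationConfig:
    seed: int = 0
    interval_s: float = 160.0
    duration_h: float = 222.0
    frequencies_hz: Sequence[float] = DEFAULT_FREQUENCIES_HZ
    wells: Sequence[tuple[str, str]] = (("A1", "control"),)
    groups: Mapping[str, GroupParams] = field(
        default_factory=lambda: {"control": GroupParams(alpha=6.5)})
    schedule: PhaseSchedule = field(default_factory=PhaseSchedule)
    electrode: NakedElectrodeModel | None = None
    wound_radius_um: float = 125.0
    wound: WoundSpec | None = None
    micromotion: MicromotionModel | None = None
    noise_sd: float = 0.0
    well_level_sd_ohm: float = 0.0

    def __post_init__(self) -> None:
        if self.interval_s <= 0 or self.duration_h <= 0:
            raise ConfigError("interval and duration must be positive")
        if self.noise_sd < 0 or self.well_level_sd_ohm < 0:
            raise ConfigError("noise parameters must be non-negative")
        if self.wound_radius_um <= 0:
            raise ConfigError("wound radius must be positive")
        for _, grp in self.wells:
            if grp not in self.groups:
                raise ConfigError(f"well group {grp!r} has no parameters")
        if self.wound is not None:
            for grp in {g for _, g in self.wells}:
                sched = self.groups[grp].schedule or self.schedule
                if self.wound.time_h < sched.plateau_start_h:
                    raise ConfigError(
                        "wound scheduled before maturation completes "
                        f"({self.wound.time_h} h < {sched.plateau_start_h} h)")

    @property
    def times_s(self) -> np.ndarray:
        n = int(math.floor(self.duration_h * 3600.0 / self.interval_s)) + 1
        return np.arange(n) * self.interval_s


def simulate_wound_recovery_coverage(t_h, v_um_h: float, r_um: float):
    """Inward annular front: ``coverage = 1 - ((r - v t)/r)^2`` until
    closure at ``t = r/v``, then 1.  Vectorised over ``t_h``."""
    if v_um_h <= 0 or r_um <= 0:
        raise DomainError("front speed and radius must be strictly positive")
    t = np.asarray(t_h, dtype=float)
    if np.any(t < 0):
        raise DomainError("time since wound must be non-negative")
    frac = np.clip(1.0 - v_um_h * t / r_um, 0.0, 1.0)
    cov = 1.0 - frac ** 2
    if cov.shape == ():
        return float(cov)
    return cov


def calibrate_rb(target_r4k: float, alpha: float, cm: float,
                 m: NakedElectrodeModel, f_hz: float = 4000.0) -> float:
    """Invert Rb so the fully covered absolute resistance at ``f_hz``
    equals ``target_r4k``.  Raises ConfigError when the target lies below
    the Rb -> 0 floor set by ``alpha``."""
    def resid(rb: float) -> float:
        p = CellModelParams(alpha=alpha, rb=max(rb, 0.0), cm=cm)
        z = covered_electrode_impedance(f_hz, m, p) / m.area_cm2
        return z.real - target_r4k

    floor = resid(0.0) + target_r4k
    if floor > target_r4k:
        raise ConfigError(
            f"target {target_r4k:.0f} Ohm below the Rb=0 floor "
            f"{floor:.0f} Ohm for alpha={alpha}")
    hi = 1.0
    while resid(hi) < 0:
        hi *= 4.0
        if hi > 1e6:
            raise ConfigError("Rb calibration failed to bracket the target")
    return float(optimize.brentq(resid, 0.0, hi, xtol=1e-12, rtol=1e-14))


def simulate_spectrum(p: CellModelParams, m: NakedElectrodeModel,
                      coverage: float = 1.0, noise_sd: float = 0.0,
                      seed: int | None = None,
                      frequencies_hz: Sequence[float] = DEFAULT_FREQUENCIES_HZ,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Absolute-Ohm spectrum of a (partially) covered electrode.

    Returns ``(frequencies, z)``; optional multiplicative complex Gaussian
    noise of relative SD ``noise_sd`` (per quadrature), seeded.
    """
    f = np.asarray(frequencies_hz, dtype=float)
    z = mixed_coverage_impedance(f, m, p, coverage) / m.area_cm2
    if noise_sd > 0.0:
        rng = np.random.default_rng(seed)
        g = rng.standard_normal(f.size) + 1j * rng.standard_normal(f.size)
        z = z * (1.0 + noise_sd * g)
    return f, np.asarray(z, dtype=complex)


def _cosine_ramp(t, t0, t1, v0, v1):
    """Smooth monotone interpolant hitting v0 at t0 and v1 at t1 exactly."""
    x = np.clip((t - t0) / (t1 - t0), 0.0, 1.0)
    return v0 + (v1 - v0) * 0.5 * (1.0 - np.cos(np.pi * x))


def _well_trajectory(cfg: SimulationConfig, group: GroupParams,
                     sched: PhaseSchedule, m: NakedElectrodeModel,
                     t_h: np.ndarray, level_shift: float,
                     ) -> tuple[np.ndarray, np.ndarray, dict]:
    """Noise-free coverage(t) and Rb(t) for one well, plus ground truth."""
    peak = sched.peak_r4k + level_shift
    plateau = sched.plateau_r4k + level_shift
    rb_peak = calibrate_rb(peak, group.alpha, group.cm, m)
    rb_plateau = calibrate_rb(plateau, group.alpha, group.cm, m)

    coverage = np.ones_like(t_h)
    rb = np.full_like(t_h, rb_plateau)

    rising = t_h < sched.rise_h
    coverage[rising] = _cosine_ramp(t_h[rising], 0.0, sched.rise_h, 0.0, 1.0)
    rb[rising] = _cosine_ramp(t_h[rising], 0.0, sched.rise_h, 0.0, rb_peak)
    declining = (t_h >= sched.rise_h) & (t_h < sched.plateau_start_h)
    rb[declining] = _cosine_ramp(t_h[declining], sched.rise_h,
                                 sched.plateau_start_h, rb_peak, rb_plateau)

    truth = {
        "alpha": group.alpha, "cm": group.cm,
        "rb_peak": rb_peak, "rb_plateau": rb_plateau,
        "peak_r4k": peak, "plateau_r4k": plateau,
        "front_speed_um_h": group.front_speed_um_h,
        "wound_time_h": None,
    }
    if cfg.wound is not None:
        tw = cfg.wound.time_h
        post = t_h >= tw
        coverage[post] = simulate_wound_recovery_coverage(
            t_h[post] - tw, group.front_speed_um_h, cfg.wound_radius_um)
        rb[post] = rb_plateau
        truth["wound_time_h"] = tw
        truth["closure_time_h"] = cfg.wound_radius_um / group.front_speed_um_h
    return coverage, rb, truth


def simulate_timecourse(cfg: SimulationConfig,
                        ) -> tuple[ImpedanceTimeSeries, dict]:
    """Run the simulator; returns the series and a ground-truth sidecar.

    Fully deterministic for a given config: per-well random streams are
    spawned from ``cfg.seed`` so adding wells does not reshuffle existing
    ones.
    """
    m = cfg.electrode or calibrate_naked_electrode(
        r_target_ohm=cfg.schedule.cellfree_r4k)
    times_s = cfg.times_s
    t_h = times_s / 3600.0
    freqs = np.asarray(cfg.frequencies_hz, dtype=float)
    nt, nw, nf = t_h.size, len(cfg.wells), freqs.size
    z = np.empty((nt, nw, nf), dtype=complex)

    seeds = np.random.SeedSequence(cfg.seed).spawn(nw)
    truth: dict = {"seed": cfg.seed, "wells": {}, "cellfree_r4k":
                   cfg.schedule.cellfree_r4k}

    zn = naked_electrode_impedance(freqs, m)          # per-frequency, Ohm cm^2
    for w, (well, grp_name) in enumerate(cfg.wells):
        group = cfg.groups[grp_name]
        sched = group.schedule or cfg.schedule
        rng = np.random.default_rng(seeds[w])
        level = (rng.normal(0.0, cfg.well_level_sd_ohm)
                 if cfg.well_level_sd_ohm > 0 else 0.0)
        coverage, rb, wt = _well_trajectory(cfg, group, sched, m, t_h, level)

        rb_eff = rb
        if cfg.micromotion is not None:
            mm = cfg.micromotion
            if mm.reference == "wound":
                if cfg.wound is None:
                    raise ConfigError("micromotion reference 'wound' without a wound")
                ref = cfg.wound.time_h
            elif mm.reference == "start":
                ref = 0.0
            else:
                ref = float(mm.reference)
            phi = math.exp(-1.0 / mm.ar_tau_samples)
            innov = rng.standard_normal(nt) * math.sqrt(1.0 - phi * phi)
            x = np.empty(nt)
            x[0] = rng.standard_normal()
            for i in range(1, nt):            # AR(1), unit marginal variance
                x[i] = phi * x[i - 1] + innov[i]
            rb_eff = rb * np.clip(1.0 + mm.sd_at(t_h, ref) * x, 0.0, None)
            wt["micromotion_midpoint_h"] = ref + mm.midpoint_h

        p = CellModelParams(alpha=group.alpha, cm=group.cm, rb=1.0)
        for j in range(nf):
            zc = covered_electrode_impedance(float(freqs[j]), m, p, rb=rb_eff)
            zwell = np.where(
                coverage > 0.0,
                1.0 / (coverage / zc + (1.0 - coverage) / zn[j]),
                zn[j],
            )
            z[:, w, j] = zwell / m.area_cm2
        if cfg.noise_sd > 0.0:
            g = (rng.standard_normal((nt, nf))
                 + 1j * rng.standard_normal((nt, nf)))
            z[:, w, :] *= 1.0 + cfg.noise_sd * g
        wt["group"] = grp_name
        truth["wells"][well] = wt

    ts = ImpedanceTimeSeries(
        times_s=times_s,
        wells=[w for w, _ in cfg.wells],
        frequencies_hz=freqs,
        impedance=z,
        metadata={
            "electrode_area_cm2": m.area_cm2,
            "electrode_diameter_um": 2.0 * cfg.wound_radius_um,
            "interval_s": cfg.interval_s,
        },
    )
    if cfg.wound is not None:
        truth["wound"] = {"time_h": cfg.wound.time_h,
                          "pulse": dict(cfg.wound.pulse),
                          "radius_um": cfg.wound_radius_um}
    return ts, truth
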