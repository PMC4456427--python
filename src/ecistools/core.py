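"""Data model and I/O for multi-frequency impedance time-courses.

The raw object is :class:`ImpedanceTimeSeries`: complex impedance on a
(time, well, frequency) grid with explicit missing-cell flags.  Times are
stored in seconds (instrument native); analysis-facing traces expose hours.
Two CSV dialects are supported:

* ``long`` (canonical): columns ``time_s, well, frequency_hz, z_real_ohm,
  z_imag_ohm``.
* ``wide``: one row per sweep with ``time_s, well`` and paired
  ``R_<freq>`` / ``C_<freq>`` columns in Ohm and nF (instrument-export
  style, series-RC convention).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ChannelLookupError, DataError, DomainError, FormatError

__all__ = [
    "DEFAULT_FREQUENCIES_HZ",
    "ImpedanceTimeSeries",
    "ChannelTrace",
    "read_timecourse",
    "write_timecourse",
    "complex_to_series_rc",
    "complex_to_parallel_rc",
    "series_rc_to_complex",
    "extract_channel",
]

#: standard 11-point acquisition grid, Hz
DEFAULT_FREQUENCIES_HZ = (
    62.5, 125.0, 250.0, 500.0, 1000.0, 2000.0,
    4000.0, 8000.0, 16000.0, 32000.0, 64000.0,
)

_LONG_COLUMNS = ("time_s", "well", "frequency_hz", "z_real_ohm", "z_imag_ohm")


@dataclass
class ImpedanceTimeSeries:
    """Complex impedance indexed by (time, well, frequency).

    Attributes
    ----------
    times_s : 1-D float array, strictly increasing, seconds from start.
    wells : well identifiers, one per axis-1 slot.
    frequencies_hz : 1-D float array, strictly increasing, Hz.
    impedance : complex array of shape (ntime, nwell, nfreq), Ohm.
    missing : boolean array of the same shape; True marks absent sweeps.
    metadata : free-form mapping (electrode area cm^2, diameter um,
        medium resistivity Ohm*cm, ...).
    """

    times_s: np.ndarray
    wells: list[str]
    frequencies_hz: np.ndarray
    impedance: np.ndarray
    missing: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.frequencies_hz = np.asarray(self.frequencies_hz, dtype=float)
        self.impedance = np.asarray(self.impedance, dtype=complex)
        self.wells = [str(w) for w in self.wells]
        if self.missing is None:
            self.missing = np.zeros(self.impedance.shape, dtype=bool)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
        shape = (len(self.times_s), len(self.wells), len(self.frequencies_hz))
        if self.impedance.shape != shape:
            raise DataError(
                f"impedance shape {self.impedance.shape} != grid {shape}"
            )
        if self.missing.shape != shape:
            raise DataError("missing-flag array shape mismatch")
        if np.any(np.diff(self.times_s) <= 0):
            idx = int(np.argmax(np.diff(self.times_s) <= 0)) + 1
            raise DataError(f"times not strictly increasing at index {idx}")
        if np.any(self.frequencies_hz <= 0):
            raise DataError("frequencies must be strictly positive")
        if np.any(np.diff(self.frequencies_hz) <= 0):
            raise DataError("frequencies must be strictly increasing")
        present = ~self.missing
        if np.any(self.impedance.real[present] < 0):
            raise DataError("negative real impedance in a present sample")

    @property
    def n_cells(self) -> int:
        """Number of present (time, well, frequency) samples."""
        return int((~self.missing).sum())

    def well_index(self, well: str) -> int:
        try:
            return self.wells.index(str(well))
        except ValueError:
            raise ChannelLookupError(f"unknown well {well!r}") from None

    def frequency_index(self, f_hz: float) -> int:
        idx = np.nonzero(np.isclose(self.frequencies_hz, f_hz))[0]
        if idx.size == 0:
            raise ChannelLookupError(f"frequency {f_hz} Hz not in grid")
        return int(idx[0])

    def window(self, t0_h: float, t1_h: float) -> "ImpedanceTimeSeries":
        """Sub-series restricted to times in [t0_h, t1_h] (hours)."""
        mask = (self.times_s >= t0_h * 3600.0) & (self.times_s <= t1_h * 3600.0)
        return replace(
            self,
            times_s=self.times_s[mask],
            impedance=self.impedance[mask],
            missing=self.missing[mask],
        )


@dataclass
class ChannelTrace:
    """A single-well scalar channel versus time in hours."""

    times_h: np.ndarray
    values: np.ndarray          # Ohm for kind "R", F for kind "C"
    kind: str                   # "R" or "C"
    frequency_hz: float
    well: str
    missing: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in ("R", "C"):
            raise DomainError("channel kind must be 'R' or 'C'")
        if self.times_h.shape != self.values.shape:
            raise DataError("times and values must have equal length")
        if self.missing is None:
            self.missing = ~np.isfinite(self.values)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)

    @property
    def label(self) -> str:
        f = self.frequency_hz
        ftxt = f"{f/1000:g}kHz" if f >= 1000 else f"{f:g}Hz"
        return f"{self.kind}@{ftxt}"

    @property
    def units(self) -> str:
        return "Ohm" if self.kind == "R" else "F"

    def slice(self, t0_h: float, t1_h: float) -> "ChannelTrace":
        m = (self.times_h >= t0_h) & (self.times_h <= t1_h)
        return ChannelTrace(self.times_h[m], self.values[m], self.kind,
                            self.frequency_hz, self.well, self.missing[m])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_h": self.times_h, "value": self.values,
                             "kind": self.label, "well": self.well})


def complex_to_series_rc(z, f_hz):
    """Series-RC interpretation of a complex impedance.

    ``R = Re(Z)``; ``C = -1/(2*pi*f*Im(Z))`` when ``Im(Z) < 0``, else NaN
    (capacitance undefined for non-capacitive samples).  Vectorised.
    """
    f = np.asarray(f_hz, dtype=float)
    if np.any(f <= 0):
        raise DomainError("frequency must be strictly positive")
    z = np.asarray(z, dtype=complex)
    r = z.real
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(z.imag < 0, -1.0 / (2.0 * np.pi * f * z.imag), np.nan)
    if z.shape == () and np.ndim(f) == 0:
        return float(r), float(c)
    return r, c


def complex_to_parallel_rc(z, f_hz):
    """Parallel-RC interpretation: ``Cp = Im(1/Z)/(2*pi*f)``, ``Rp = 1/Re(1/Z)``.

    Under area mixing of electrode patches the admittance is linear in
    coverage, so the parallel capacitance is exactly area-linear; the
    series convention is only approximately so.  NaN where non-capacitive.
    """
    f = np.asarray(f_hz, dtype=float)
    if np.any(f <= 0):
        raise DomainError("frequency must be strictly positive")
    y = 1.0 / np.asarray(z, dtype=complex)
    with np.errstate(divide="ignore", invalid="ignore"):
        rp = np.where(y.real > 0, 1.0 / y.real, np.nan)
        cp = np.where(y.imag > 0, y.imag / (2.0 * np.pi * f), np.nan)
    if np.ndim(z) == 0 and np.ndim(f) == 0:
        return float(rp), float(cp)
    return rp, cp


def series_rc_to_complex(r_ohm, c_farad, f_hz):
    """Inverse of :func:`complex_to_series_rc`: ``Z = R - j/(2*pi*f*C)``."""
    f = np.asarray(f_hz, dtype=float)
    if np.any(f <= 0):
        raise DomainError("frequency must be strictly positive")
    return np.asarray(r_ohm, dtype=float) - 1j / (
        2.0 * np.pi * f * np.asarray(c_farad, dtype=float))


def extract_channel(ts: ImpedanceTimeSeries, well: str, f_hz: float,
                    kind: str = "R", convention: str = "series") -> ChannelTrace:
    """Pull one (well, frequency) channel as a trace in hours.

    ``convention`` selects the equivalent circuit for the R/C split:
    ``series`` (lock-in in-phase/out-of-phase, default) or ``parallel``.
    Missing sweeps propagate as NaN values flagged in ``missing``.
    """
    if kind not in ("R", "C"):
        raise DomainError("kind must be 'R' or 'C'")
    if convention not in ("series", "parallel"):
        raise DomainError("convention must be 'series' or 'parallel'")
    wi = ts.well_index(well)
    fi = ts.frequency_index(f_hz)
    z = ts.impedance[:, wi, fi]
    miss = ts.missing[:, wi, fi]
    conv = (complex_to_series_rc if convention == "series"
            else complex_to_parallel_rc)
    r, c = conv(z, ts.frequencies_hz[fi])
    values = np.where(miss, np.nan, r if kind == "R" else c)
    return ChannelTrace(ts.times_s / 3600.0, values, kind,
                        float(ts.frequencies_hz[fi]), str(well), miss)


# ---------------------------------------------------------------------------
# CSV I/O


def _read_long(df: pd.DataFrame, path) -> ImpedanceTimeSeries:
    for col in _LONG_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    dup = df.duplicated(subset=["time_s", "well", "frequency_hz"])
    if dup.any():
        row = int(np.argmax(dup.values))
        raise DataError(f"{path}: duplicated (time, well, frequency) at row {row}")
    times = np.sort(df["time_s"].unique())
    wells = sorted(df["well"].astype(str).unique())
    freqs = np.sort(df["frequency_hz"].unique())
    shape = (times.size, len(wells), freqs.size)
    z = np.full(shape, np.nan + 0j, dtype=complex)
    missing = np.ones(shape, dtype=bool)
    ti = {t: i for i, t in enumerate(times)}
    wi = {w: i for i, w in enumerate(wells)}
    fi = {f: i for i, f in enumerate(freqs)}
    idx_t = df["time_s"].map(ti).to_numpy()
    idx_w = df["well"].astype(str).map(wi).to_numpy()
    idx_f = df["frequency_hz"].map(fi).to_numpy()
    z[idx_t, idx_w, idx_f] = (df["z_real_ohm"].to_numpy()
                              + 1j * df["z_imag_ohm"].to_numpy())
    missing[idx_t, idx_w, idx_f] = False
    return ImpedanceTimeSeries(times, wells, freqs, z, missing)


_WIDE_RE = re.compile(r"^([RC])_([0-9.]+)$")


def _read_wide(df: pd.DataFrame, path) -> ImpedanceTimeSeries:
    if "time_s" not in df.columns or "well" not in df.columns:
        raise FormatError(f"{path}: wide dialect requires time_s and well columns")
    freqs: list[float] = []
    for col in df.columns:
        mt = _WIDE_RE.match(col)
        if mt and mt.group(1) == "R":
            f = float(mt.group(2))
            if f"C_{mt.group(2)}" not in df.columns:
                raise FormatError(f"{path}: column R_{mt.group(2)} lacks its "
                                  f"C_{mt.group(2)} pair")
            freqs.append(f)
    if not freqs:
        raise FormatError(f"{path}: no R_<freq>/C_<freq> column pairs found")
    freqs = sorted(freqs)
    rows = []
    for well, sub in df.groupby("well", sort=True):
        t = sub["time_s"].to_numpy(dtype=float)
        bad = np.nonzero(np.diff(t) <= 0)[0]
        if bad.size:
            raise DataError(
                f"{path}: non-monotone time for well {well!r} at row "
                f"{int(sub.index[bad[0] + 1])}")
    times = np.sort(df["time_s"].unique())
    wells = sorted(df["well"].astype(str).unique())
    shape = (times.size, len(wells), len(freqs))
    z = np.full(shape, np.nan + 0j, dtype=complex)
    missing = np.ones(shape, dtype=bool)
    ti = {t: i for i, t in enumerate(times)}
    wi = {w: i for i, w in enumerate(wells)}
    for j, f in enumerate(freqs):
        key = f"{f:g}"
        r = df[f"R_{key}"].to_numpy(dtype=float)
        c_nf = df[f"C_{key}"].to_numpy(dtype=float)
        zz = series_rc_to_complex(r, c_nf * 1e-9, f)   # nF -> F on read
        idx_t = df["time_s"].map(ti).to_numpy()
        idx_w = df["well"].astype(str).map(wi).to_numpy()
        ok = np.isfinite(r) & np.isfinite(c_nf)
        z[idx_t[ok], idx_w[ok], j] = zz[ok]
        missing[idx_t[ok], idx_w[ok], j] = False
    return ImpedanceTimeSeries(times, wells, np.asarray(freqs, float), z, missing)


def read_timecourse(path, dialect: str = "long") -> ImpedanceTimeSeries:
    """Read an impedance time-course CSV in the given dialect."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if dialect == "long":
        return _read_long(df, path)
    if dialect == "wide":
        return _read_wide(df, path)
    raise DomainError(f"unknown dialect {dialect!r}")


def write_timecourse(ts: ImpedanceTimeSeries, path, dialect: str = "long") -> None:
    """Write a time-course CSV; missing cells are omitted (long) or NaN (wide)."""
    path = Path(path)
    if dialect == "long":
        nt, nw, nf = ts.impedance.shape
        tt, ww, ff = np.meshgrid(np.arange(nt), np.arange(nw), np.arange(nf),
                                 indexing="ij")
        present = ~ts.missing
        df = pd.DataFrame({
            "time_s": ts.times_s[tt[present]],
            "well": np.asarray(ts.wells, dtype=object)[ww[present]],
            "frequency_hz": ts.frequencies_hz[ff[present]],
            "z_real_ohm": ts.impedance.real[present],
            "z_imag_ohm": ts.impedance.imag[present],
        })
        df.to_csv(path, index=False)
        return
    if dialect == "wide":
        frames = []
        for w, well in enumerate(ts.wells):
            data = {"time_s": ts.times_s, "well": well}
            for j, f in enumerate(ts.frequencies_hz):
                z = np.where(ts.missing[:, w, j], np.nan + 0j,
                             ts.impedance[:, w, j])
                r, c = complex_to_series_rc(z, f)
                data[f"R_{f:g}"] = r
                data[f"C_{f:g}"] = c * 1e9   # F -> nF on write
            frames.append(pd.DataFrame(data))
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)
        return
    raise DomainError(f"unknown dialect {dialect!r}")
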