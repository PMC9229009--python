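"""Multi-harmonic QCM-D trace container, file I/O and baseline correction.

A QCM-D experiment records, at each odd harmonic *n* of the crystal's
fundamental resonance, a frequency shift Δf_n (proxy for coupled mass) and a
dissipation shift ΔD_n (proxy for film viscoelasticity) against time.  This
module defines the in-memory record (:class:`QCMDTrace`), the flow-event
markers used by downstream kinetics (:class:`FlowMarkers`), a wide-CSV file
dialect, and baseline subtraction.

Conventions
-----------
* time is in minutes, strictly increasing;
* Δf columns are overtone-normalized (Δf_n / n), the scale on which a rigid
  bilayer reads about −26 Hz on every harmonic; ``read_trace`` can divide raw
  shifts by *n* on request;
* ΔD is stored in units of 1e-6, so a printed dissipation of 3.8×10⁻⁶ is the
  number 3.8.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "QCMDTrace",
    "FlowMarkers",
    "TraceFormatError",
    "read_trace",
    "write_trace",
    "rebaseline",
]

_VALID_HARMONICS = (3, 5, 7, 9, 11)


class TraceFormatError(ValueError):
    """Raised for files that cannot be interpreted as a QCM-D trace."""


@dataclass
class QCMDTrace:
    """Time-indexed multi-harmonic Δf/ΔD record.

    Parameters
    ----------
    time
        Sample times in minutes, strictly increasing.
    delta_f
        Mapping harmonic -> overtone-normalized frequency shift in Hz,
        one array per harmonic, aligned with ``time``.
    delta_D
        Mapping harmonic -> dissipation shift in units of 1e-6, aligned
        with ``time``.
    meta
        Free-form metadata (sample name, lipid composition label, ...).
    """

    time: np.ndarray
    delta_f: dict[int, np.ndarray]
    delta_D: dict[int, np.ndarray]
    meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if self.time.ndim != 1 or self.time.size < 2:
            raise ValueError("time must be a 1-D array with at least 2 samples")
        if not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        if not self.delta_f:
            raise ValueError("trace must contain at least one harmonic")
        if set(self.delta_f) != set(self.delta_D):
            raise ValueError("delta_f and delta_D must cover the same harmonics")
        for n in self.delta_f:
            if n not in _VALID_HARMONICS:
                raise ValueError(f"harmonic {n} not an odd harmonic in {_VALID_HARMONICS}")
            self.delta_f[n] = np.asarray(self.delta_f[n], dtype=float)
            self.delta_D[n] = np.asarray(self.delta_D[n], dtype=float)
            if self.delta_f[n].shape != self.time.shape or self.delta_D[n].shape != self.time.shape:
                raise ValueError(f"harmonic {n} series do not share the time grid")
            if not np.all(np.isfinite(self.delta_f[n])) or not np.all(np.isfinite(self.delta_D[n])):
                raise ValueError(f"harmonic {n} contains non-finite values")

    @property
    def harmonics(self) -> list[int]:
        """Harmonics present, ascending."""
        return sorted(self.delta_f)

    def window_mask(self, t0: float, t1: float) -> np.ndarray:
        """Boolean mask of samples with t0 <= time <= t1."""
        return (self.time >= t0) & (self.time <= t1)

    def slice(self, t0: float, t1: float) -> "QCMDTrace":
        """Sub-trace restricted to the closed time interval [t0, t1]."""
        m = self.window_mask(t0, t1)
        if m.sum() < 2:
            raise ValueError(f"window [{t0}, {t1}] contains fewer than 2 samples")
        return QCMDTrace(
            time=self.time[m],
            delta_f={n: v[m] for n, v in self.delta_f.items()},
            delta_D={n: v[m] for n, v in self.delta_D.items()},
            meta=dict(self.meta),
        )


@dataclass(frozen=True)
class FlowMarkers:
    """Flow-event time points: vesicle flow start (a) and final rinse (b)."""

    t_start: float
    t_rinse: float
    t_end: float | None = None

    def __post_init__(self) -> None:
        if not self.t_start < self.t_rinse:
            raise ValueError("t_start must precede t_rinse")
        if self.t_end is not None and not self.t_rinse <= self.t_end:
            raise ValueError("t_rinse must not exceed t_end")


def _harmonic_columns(columns: list[str]) -> list[int]:
    found = []
    for n in _VALID_HARMONICS:
        if f"f{n}" in columns and f"D{n}" in columns:
            found.append(n)
    return found


def read_trace(path, *, raw_shifts: bool = False) -> QCMDTrace:
    """Read a wide-CSV QCM-D trace.

    Expected columns: ``time_min, f3, D3, f5, D5, ...`` with any subset of the
    odd harmonics 3-11; lines starting with ``#`` hold ``key = value`` metadata.
    Rows containing non-finite values are dropped (their indices reported in
    ``meta['dropped_rows']``).

    Parameters
    ----------
    path
        File path or open text handle.
    raw_shifts
        If True, frequency columns hold raw Δf_n and are divided by the
        harmonic number on read to obtain overtone-normalized shifts.
    """
    meta: dict[str, str] = {}
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    body_lines = []
    for line in text.splitlines():
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if "=" in stripped:
                k, v = stripped.split("=", 1)
                meta[k.strip()] = v.strip()
        else:
            body_lines.append(line)
    try:
        df = pd.read_csv(_io.StringIO("\n".join(body_lines)), float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise TraceFormatError(f"unparseable trace file: {exc}") from exc
    if "time_min" not in df.columns:
        raise TraceFormatError("no time column (expected 'time_min')")
    harmonics = _harmonic_columns(list(df.columns))
    if not harmonics:
        raise TraceFormatError("no harmonic columns (expected pairs like f3, D3)")

    used = ["time_min"] + [c for n in harmonics for c in (f"f{n}", f"D{n}")]
    finite = np.isfinite(df[used].to_numpy(dtype=float)).all(axis=1)
    if not finite.all():
        dropped = np.flatnonzero(~finite)
        meta["dropped_rows"] = ",".join(map(str, dropped))
        df = df.loc[finite]
    time = df["time_min"].to_numpy(dtype=float)
    if not np.all(np.diff(time) > 0):
        raise TraceFormatError("time column is not strictly increasing")
    delta_f = {}
    delta_D = {}
    for n in harmonics:
        f = df[f"f{n}"].to_numpy(dtype=float)
        delta_f[n] = f / n if raw_shifts else f
        delta_D[n] = df[f"D{n}"].to_numpy(dtype=float)
    return QCMDTrace(time=time, delta_f=delta_f, delta_D=delta_D, meta=meta)


def write_trace(trace: QCMDTrace, path) -> None:
    """Write a trace as wide CSV; metadata becomes ``# key = value`` header lines."""
    cols = {"time_min": trace.time}
    for n in trace.harmonics:
        cols[f"f{n}"] = trace.delta_f[n]
        cols[f"D{n}"] = trace.delta_D[n]
    df = pd.DataFrame(cols)
    header = "".join(f"# {k} = {v}\n" for k, v in trace.meta.items())
    csv_text = header + df.to_csv(index=False, float_format="%.17g")
    if hasattr(path, "write"):
        path.write(csv_text)
    else:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(csv_text)


def rebaseline(trace: QCMDTrace, window: tuple[float, float]) -> QCMDTrace:
    """Zero each series against its mean over a pre-flow buffer window.

    Subtracting the window mean from every harmonic's Δf and ΔD reproduces the
    instrument convention of reporting shifts relative to the buffer-equilibrated
    crystal.  The operation is a pure per-series shift (all pairwise sample
    differences preserved) and is idempotent on an already-zeroed baseline.
    """
    t0, t1 = window
    m = trace.window_mask(t0, t1)
    if not m.any():
        raise ValueError(f"baseline window [{t0}, {t1}] contains no samples")
    delta_f = {n: v - v[m].mean() for n, v in trace.delta_f.items()}
    delta_D = {n: v - v[m].mean() for n, v in trace.delta_D.items()}
    return replace(trace, delta_f=delta_f, delta_D=delta_D, meta=dict(trace.meta))
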