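"""Dynamic light scattering size-distribution tools.

DLS instruments measure an intensity-weighted size distribution; volume- and
number-weighted views follow by rescaling each diameter bin, assuming
spherical particles in the Rayleigh regime.  For N_i particles of diameter
d_i the three bases are related by

    %I = 100 N_i d_i^6 / Σ N_j d_j^6
    %V = 100 N_i d_i^3 / Σ N_j d_j^3
    %N = 100 N_i       / Σ N_j

so converting between bases multiplies or divides bin values by powers of
d_i and renormalizes to 100.  Distributions are treated as discrete binned
weights; no bin-width correction is applied.

The module also detects modes (peaks) in a distribution and flags vesicle
preparations that aggregate over storage time: a growing primary diameter or
the emergence of new large-diameter peaks both indicate aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "SizeDistribution",
    "convert_distribution",
    "detect_modes",
    "stability_assessment",
    "StabilityReport",
    "read_distribution",
    "write_distribution",
]

_BASIS_POWER = {"number": 0, "volume": 3, "intensity": 6}


@dataclass
class SizeDistribution:
    """Binned particle-size distribution on a stated weighting basis.

    ``d`` holds strictly increasing diameter bins in nm; ``values`` the
    per-bin abundance (percentages when ``normalized``, else raw counts or
    weights); ``basis`` one of ``number``/``volume``/``intensity``;
    ``timestamp`` optional age of the preparation in days.
    """

    d: np.ndarray
    values: np.ndarray
    basis: str
    normalized: bool = False
    timestamp: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.basis not in _BASIS_POWER:
            raise ValueError(f"unknown basis {self.basis!r}")
        if self.d.ndim != 1 or self.d.shape != self.values.shape:
            raise ValueError("d and values must be 1-D arrays of equal length")
        if not np.all(self.d > 0) or not np.all(np.diff(self.d) > 0):
            raise ValueError("diameters must be positive and strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("values must be non-negative")
        if self.normalized and abs(self.values.sum() - 100.0) > 1e-9:
            raise ValueError("normalized distribution must sum to 100")

    def normalize(self) -> "SizeDistribution":
        """Rescale values to sum to 100 (percent)."""
        total = self.values.sum()
        if total <= 0:
            raise ValueError("cannot normalize a zero-weight distribution")
        return SizeDistribution(
            d=self.d, values=100.0 * self.values / total, basis=self.basis,
            normalized=True, timestamp=self.timestamp, meta=dict(self.meta),
        )


def convert_distribution(dist: SizeDistribution, to_basis: str) -> SizeDistribution:
    """Convert between number/volume/intensity weightings.

    Bin values are reweighted by ``d**(p_to - p_from)`` with p = 0/3/6 for
    number/volume/intensity, then renormalized to 100.  Converting to the
    distribution's own basis returns its normalized form.  The map is an exact
    bijection on positive distributions (round trips recover inputs).
    """
    if to_basis not in _BASIS_POWER:
        raise ValueError(f"unknown basis {to_basis!r}")
    power = _BASIS_POWER[to_basis] - _BASIS_POWER[dist.basis]
    weighted = dist.values * dist.d ** power
    total = weighted.sum()
    if total <= 0:
        raise ValueError("distribution has zero total weight")
    return SizeDistribution(
        d=dist.d, values=100.0 * weighted / total, basis=to_basis,
        normalized=True, timestamp=dist.timestamp, meta=dict(dist.meta),
    )


def detect_modes(dist: SizeDistribution, min_fraction: float = 5.0,
                 smooth_window: int = 1) -> list[tuple[float, float]]:
    """Locate modes (peaks) and the percent mass in each peak region.

    A mode is a local maximum of the (optionally smoothed) values; its region
    extends to the local minima (or array ends) on either side.  Modes whose
    region carries less than ``min_fraction`` percent of the total are
    discarded.  Returns ``(d_mode, fraction)`` pairs, largest fraction first.
    """
    if not np.any(dist.values > 0):
        return []
    work = dist if dist.normalized else dist.normalize()
    v = work.values
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        v = np.convolve(v, kernel, mode="same")
    # peaks must rise at least 5% of the maximum above their surroundings,
    # so sampling noise does not split one population into several modes
    peaks = list(find_peaks(v, prominence=0.05 * v.max())[0])
    if not peaks:
        peaks = [int(np.argmax(v))]
    # region boundaries: minima between consecutive peaks
    bounds = [0]
    for a, b in zip(peaks[:-1], peaks[1:]):
        bounds.append(a + int(np.argmin(v[a:b + 1])))
    bounds.append(len(v))
    modes = []
    for k, p in enumerate(peaks):
        frac = work.values[bounds[k]:bounds[k + 1]].sum()
        if frac >= min_fraction:
            modes.append((float(dist.d[p]), float(frac)))
    modes.sort(key=lambda m: -m[1])
    return modes


@dataclass(frozen=True)
class StabilityReport:
    """Per-timepoint aggregation flags and an overall verdict."""

    verdict: str  # "stable" | "aggregating"
    flags: tuple[dict, ...]  # one record per timepoint after day 0


def stability_assessment(series: list[SizeDistribution], shift_tol: float = 25.0,
                         new_peak_fraction: float = 5.0) -> StabilityReport:
    """Flag vesicle aggregation across a stored time course.

    Compares each later distribution against the earliest one: a primary-mode
    diameter shift beyond ``shift_tol`` percent, or a new mode (absent at day
    0) carrying at least ``new_peak_fraction`` percent of the mass, marks the
    timepoint as aggregating.
    """
    if len(series) < 2:
        raise ValueError("need at least two time points")
    if len({s.basis for s in series}) != 1:
        raise ValueError("all distributions must share a basis")
    ordered = sorted(series, key=lambda s: (s.timestamp if s.timestamp is not None else 0.0))
    ref_modes = detect_modes(ordered[0], min_fraction=new_peak_fraction)
    if not ref_modes:
        raise ValueError("reference distribution has no detectable mode")
    ref_primary = ref_modes[0][0]
    ref_diams = [d for d, _ in ref_modes]
    flags = []
    any_flag = False
    for dist in ordered[1:]:
        modes = detect_modes(dist, min_fraction=new_peak_fraction)
        primary = modes[0][0] if modes else ref_primary
        shift_pct = 100.0 * abs(primary - ref_primary) / ref_primary
        shifted = shift_pct > shift_tol
        new_modes = [
            (d, f) for d, f in modes
            if all(100.0 * abs(d - rd) / rd > shift_tol for rd in ref_diams)
        ]
        flagged = shifted or bool(new_modes)
        any_flag = any_flag or flagged
        flags.append({
            "timestamp": dist.timestamp,
            "primary_mode_nm": primary,
            "primary_shift_pct": shift_pct,
            "shifted": shifted,
            "new_modes": new_modes,
            "aggregating": flagged,
        })
    return StabilityReport(verdict="aggregating" if any_flag else "stable",
                           flags=tuple(flags))


def read_distribution(path) -> SizeDistribution:
    """Read a two-column CSV (``d_nm, value``) with ``# key = value`` headers."""
    import io as _io

    import pandas as pd

    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    meta: dict[str, str] = {}
    body = []
    for line in text.splitlines():
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            for part in stripped.split(","):
                if "=" in part:
                    k, v = part.split("=", 1)
                    meta[k.strip()] = v.strip()
        else:
            body.append(line)
    df = pd.read_csv(_io.StringIO("\n".join(body)), float_precision="round_trip")
    basis = meta.get("basis", "number")
    day = meta.get("day")
    values = df["value"].to_numpy(dtype=float)
    normalized = abs(values.sum() - 100.0) <= 1e-9
    return SizeDistribution(
        d=df["d_nm"].to_numpy(dtype=float), values=values, basis=basis,
        normalized=normalized, timestamp=float(day) if day is not None else None,
        meta=meta,
    )


def write_distribution(dist: SizeDistribution, path) -> None:
    """Write ``d_nm, value`` CSV with basis/day comment header."""
    import pandas as pd

    header = f"# basis = {dist.basis}"
    if dist.timestamp is not None:
        header += f", day = {dist.timestamp:g}"
    df = pd.DataFrame({"d_nm": dist.d, "value": dist.values})
    text = header + "\n" + df.to_csv(index=False, float_format="%.17g")
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
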