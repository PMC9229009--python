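"""Kinetic descriptors and signature classification for QCM-D traces.

The trajectory of (Δf, ΔD) during vesicle flow distinguishes four outcomes
on a sensor surface:

1. supported vesicle layer — deep Δf plateau, final ΔD above 1e-6, no
   frequency minimum (intact vesicles trap water, making a soft film);
2. two-step bilayer — Δf overshoots to a minimum at the critical vesicle
   coverage, then recovers as vesicles rupture and expel water, ending near
   the rigid-bilayer plateau with low ΔD;
3. one-step bilayer — monotone Δf decrease straight to the bilayer plateau,
   ΔD low throughout (vesicles rupture on contact);
4. incomplete bilayer — shallow plateau; the final buffer rinse removes lipid
   (Δf rises) while ΔD rises, indicating a patchy film.

A film with final ΔD below 1e-6 is considered rigid, which is also the
applicability condition for the Sauerbrey mass conversion.

All descriptors are evaluated on a single reference harmonic (the 3rd by
default, the conventional reporting harmonic); thresholds live in
:class:`ClassifierConfig` and every decision boundary is configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .traces import FlowMarkers, QCMDTrace

__all__ = [
    "ClassifierConfig",
    "SignatureReport",
    "PhaseStep",
    "initial_slope",
    "detect_frequency_minimum",
    "overtone_spread",
    "phase_trajectory",
    "classify_signature",
]

LABELS = ("vesicle_layer", "two_step_slb", "one_step_slb", "incomplete_bilayer",
          "indeterminate")

#: dissipation (1e-6) below which a film counts as rigid / Sauerbrey-valid
RIGID_D_THRESHOLD = 1.0


@dataclass(frozen=True)
class ClassifierConfig:
    """Decision thresholds for signature classification.

    ``bilayer_band`` is the |Δf| range (Hz) accepted as a complete bilayer
    plateau; ``min_prominence`` the recovery (Hz) required to call a frequency
    minimum real; ``rupture_rise`` the minimum post-minimum recovery for the
    two-step label; ``rinse_D_rise`` (1e-6) and ``rinse_f_rise`` (Hz) the
    rinse-response thresholds for the incomplete-bilayer label;
    ``plateau_window`` the averaging window (min) for plateau estimates;
    ``smooth_window`` the centered moving-average width (samples) applied
    before extremum and phase analysis.
    """

    reference_harmonic: int = 3
    min_prominence: float = 10.0
    rupture_rise: float = 10.0
    bilayer_band: tuple[float, float] = (24.0, 30.0)
    rinse_D_rise: float = 0.1
    rinse_f_rise: float = 1.0
    rigid_D: float = RIGID_D_THRESHOLD
    plateau_window: float = 1.0
    smooth_window: int = 5


@dataclass(frozen=True)
class SignatureReport:
    """Classification label plus the kinetic descriptors behind it."""

    label: str
    f_final: float
    D_final: float
    initial_slope: float
    overtone_spread_final: float
    rinse_delta_f: float
    rinse_delta_D: float
    rigid: bool
    f_min: float | None = None
    t_min: float | None = None
    f_pre_rinse: float | None = None
    D_pre_rinse: float | None = None
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if self.label == "two_step_slb":
            if self.f_min is None or not self.f_min < self.f_final:
                raise ValueError("two_step_slb requires f_min < f_final")
        if self.rigid != (self.D_final < RIGID_D_THRESHOLD):
            raise ValueError("rigid flag must equal (D_final < 1.0)")

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "f_final_Hz": self.f_final,
            "D_final_1e6": self.D_final,
            "initial_slope_Hz_per_min": self.initial_slope,
            "overtone_spread_final_Hz": self.overtone_spread_final,
            "rinse_delta_f_Hz": self.rinse_delta_f,
            "rinse_delta_D_1e6": self.rinse_delta_D,
            "rigid": self.rigid,
            "f_min_Hz": self.f_min,
            "t_min_min": self.t_min,
            "f_pre_rinse_Hz": self.f_pre_rinse,
            "D_pre_rinse_1e6": self.D_pre_rinse,
            "warnings": list(self.warnings),
        }


@dataclass(frozen=True)
class PhaseStep:
    """One smoothed increment on the (−Δf, ΔD) plane with its compass label."""

    t: float
    direction: str  # N, NE, E, SE, S, SW, W, NW or stationary


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge shrinkage."""
    if window <= 1:
        return y
    kernel = np.ones(window)
    num = np.convolve(y, kernel, mode="same")
    den = np.convolve(np.ones_like(y), kernel, mode="same")
    return num / den


def _plateau(trace: QCMDTrace, harmonic: int, t_end: float, window: float) -> tuple[float, float]:
    """Mean (Δf, ΔD) over the `window` minutes preceding t_end."""
    m = trace.window_mask(t_end - window, t_end)
    if not m.any():
        raise ValueError(f"no samples in plateau window ending at {t_end}")
    return float(trace.delta_f[harmonic][m].mean()), float(trace.delta_D[harmonic][m].mean())


def detect_frequency_minimum(trace: QCMDTrace, harmonic: int,
                             prominence: float = 10.0,
                             smooth_window: int = 5) -> tuple[float, float] | None:
    """Locate a real frequency minimum (adsorption overshoot before rupture).

    Returns ``(t_min, f_min)`` of the global minimum of the smoothed Δf series
    when the subsequent recovery (highest later value minus the minimum)
    exceeds ``prominence``; returns None for monotone or noise-only traces.
    """
    if harmonic not in trace.delta_f:
        raise ValueError(f"harmonic {harmonic} not in trace")
    raw = trace.delta_f[harmonic]
    f = _smooth(raw, smooth_window)
    i_min = int(np.argmin(f))
    if i_min >= f.size - 1:
        return None
    recovery = float(f[i_min:].max() - f[i_min])
    if recovery < prominence:
        return None
    # smoothing flattens the cusp; refine location/value on the raw series
    # within the smoothing neighborhood of the smoothed minimum
    lo = max(0, i_min - smooth_window)
    hi = min(raw.size, i_min + smooth_window + 1)
    i_ref = lo + int(np.argmin(raw[lo:hi]))
    return float(trace.time[i_ref]), float(raw[i_ref])


def initial_slope(trace: QCMDTrace, markers: FlowMarkers, harmonic: int = 3,
                  prominence: float = 10.0, smooth_window: int = 5,
                  plateau_fraction: float = 0.9) -> float:
    """Initial adsorption slope (Hz/min) of Δf after vesicle flow begins.

    The slope is the least-squares fit of Δf against time from flow start to
    the frequency minimum.  A steeper negative slope means faster vesicle
    attachment.  When no minimum exists (monotone approach), the window ends
    where Δf first covers ``plateau_fraction`` of its final plateau change —
    a surrogate endpoint so slopes remain comparable across outcomes.
    """
    if harmonic not in trace.delta_f:
        raise ValueError(f"harmonic {harmonic} not in trace")
    t_end_candidate = markers.t_end if markers.t_end is not None else trace.time[-1]
    found = detect_frequency_minimum(trace, harmonic, prominence, smooth_window)
    if found is not None:
        t_win_end = found[0]
    else:
        f_final, _ = _plateau(trace, harmonic, min(t_end_candidate, trace.time[-1]), 1.0)
        if abs(f_final) < 1.0:
            warnings.warn("no adsorption detected; slope is 0", stacklevel=2)
            return 0.0
        f = _smooth(trace.delta_f[harmonic], smooth_window)
        after = trace.time >= markers.t_start
        reached = after & (np.sign(f_final) * f >= plateau_fraction * abs(f_final))
        t_win_end = float(trace.time[np.argmax(reached)]) if reached.any() else trace.time[-1]
    m = trace.window_mask(markers.t_start, t_win_end)
    if m.sum() < 3:
        raise ValueError("slope window shorter than 3 samples")
    coeffs = np.polyfit(trace.time[m], trace.delta_f[harmonic][m], 1)
    return float(coeffs[0])


def overtone_spread(trace: QCMDTrace, window: tuple[float, float]) -> float:
    """Spread (max − min, Hz) of window-averaged Δf across harmonics.

    Coincident overtones indicate a rigid laterally uniform film; separation
    grows with hydration and thickness non-uniformity (e.g. vesicle layers).
    """
    if len(trace.harmonics) < 2:
        raise ValueError("overtone spread requires at least 2 harmonics")
    m = trace.window_mask(*window)
    if not m.any():
        raise ValueError(f"window {window} contains no samples")
    means = [trace.delta_f[n][m].mean() for n in trace.harmonics]
    return float(max(means) - min(means))


_COMPASS = ("E", "NE", "N", "NW", "W", "SW", "S", "SE")


def phase_trajectory(trace: QCMDTrace, harmonic: int = 3, smooth_window: int = 5,
                     dead_band: tuple[float, float] = (0.1, 0.01),
                     stride: int = 10, hz_per_dissipation: float = 20.0) -> list[PhaseStep]:
    """Compass-direction steps of the trace on the (−Δf, ΔD) plane.

    With the frequency axis reversed, eastward motion is mass gain, northward
    motion is viscoelasticity gain: vesicle adsorption runs north-east,
    vesicle rupture south-west, and direct bilayer deposition mainly east
    (mass gain with little dissipation change).  The two axes carry different
    units, so compass angles are evaluated after scaling ΔD by
    ``hz_per_dissipation`` (Hz per 1e-6) — the aspect under which a full
    vesicle-adsorption transient (tens of Hz, a few 1e-6) runs diagonally.
    Increments below ``dead_band`` (Hz, 1e-6) on both axes are stationary.
    ``stride`` sets the sample spacing between evaluated steps.
    """
    if harmonic not in trace.delta_f:
        raise ValueError(f"harmonic {harmonic} not in trace")
    if trace.time.size < max(smooth_window, 2 * stride):
        raise ValueError("trace shorter than smoothing/stride window")
    x = -_smooth(trace.delta_f[harmonic], smooth_window)  # mass axis
    y = _smooth(trace.delta_D[harmonic], smooth_window)   # viscoelasticity axis
    idx = np.arange(0, trace.time.size - stride, stride)
    steps = []
    for i in idx:
        dx = x[i + stride] - x[i]
        dy = y[i + stride] - y[i]
        if abs(dx) < dead_band[0] and abs(dy) < dead_band[1]:
            direction = "stationary"
        else:
            angle = np.arctan2(dy * hz_per_dissipation, dx)
            octant = int(np.round(angle / (np.pi / 4))) % 8
            direction = _COMPASS[octant]
        steps.append(PhaseStep(t=float(trace.time[i + stride]), direction=direction))
    return steps


def classify_signature(trace: QCMDTrace, markers: FlowMarkers,
                       config: ClassifierConfig | None = None) -> SignatureReport:
    """Classify a trace into one of the four formation outcomes.

    Decision rules on the reference harmonic (defaults in
    :class:`ClassifierConfig`):

    1. final ΔD above the rigid threshold and no prominent frequency minimum
       → ``vesicle_layer``;
    2. prominent minimum with recovery ≥ ``rupture_rise`` and rigid final film
       → ``two_step_slb``;
    3. no minimum, rigid film, |Δf_final| inside ``bilayer_band``
       → ``one_step_slb``;
    4. rigid film with |Δf_final| below the band and a rinse response that
       raises both Δf and ΔD → ``incomplete_bilayer``;
    otherwise ``indeterminate``.  If both the vesicle-layer and
    incomplete-bilayer patterns fire, the final ΔD decides.  All descriptor
    fields are populated regardless of the label.
    """
    cfg = config or ClassifierConfig()
    n = cfg.reference_harmonic
    if n not in trace.delta_f:
        raise ValueError(f"reference harmonic {n} not in trace")
    if markers.t_start < trace.time[0] or markers.t_rinse > trace.time[-1]:
        raise ValueError("markers fall outside the trace")

    f_pre, D_pre = _plateau(trace, n, markers.t_rinse, cfg.plateau_window)
    f_final, D_final = _plateau(trace, n, trace.time[-1], cfg.plateau_window)
    rinse_df = f_final - f_pre
    rinse_dD = D_final - D_pre
    minimum = detect_frequency_minimum(trace, n, cfg.min_prominence, cfg.smooth_window)
    try:
        spread = overtone_spread(trace, (markers.t_rinse - cfg.plateau_window, markers.t_rinse))
    except ValueError:
        spread = 0.0
    notes: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        slope = initial_slope(trace, markers, n, cfg.min_prominence, cfg.smooth_window)
        notes.extend(str(w.message) for w in caught)

    rigid = D_final < cfg.rigid_D
    lo, hi = cfg.bilayer_band
    recovery = (f_final - minimum[1]) if minimum else 0.0
    rinse_strips = rinse_df > cfg.rinse_f_rise and rinse_dD > cfg.rinse_D_rise

    f_min_val = minimum[1] if minimum else None
    t_min_val = minimum[0] if minimum else None
    if not rigid and minimum is None:
        label = "vesicle_layer"
    elif minimum is not None and recovery >= cfg.rupture_rise and rigid:
        label = "two_step_slb"
    elif minimum is None and rigid and lo <= abs(f_final) <= hi:
        label = "one_step_slb"
    elif minimum is None and rigid and abs(f_final) < lo and rinse_strips:
        label = "incomplete_bilayer"
    else:
        label = "indeterminate"
        notes.append("no decision rule matched; see descriptors")
    if label != "two_step_slb":
        # descriptor minimum is reported even when it does not drive the label,
        # unless the report invariant (f_min < f_final) would be violated
        if f_min_val is not None and not f_min_val < f_final:
            f_min_val = t_min_val = None
    return SignatureReport(
        label=label, f_final=f_final, D_final=D_final, initial_slope=slope,
        overtone_spread_final=spread, rinse_delta_f=rinse_df, rinse_delta_D=rinse_dD,
        rigid=rigid, f_min=f_min_val, t_min=t_min_val, f_pre_rinse=f_pre,
        D_pre_rinse=D_pre, warnings=tuple(notes),
    )
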