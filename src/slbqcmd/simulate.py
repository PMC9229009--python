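"""Synthetic QCM-D traces for the four vesicle-on-surface outcomes.

When lipid vesicles flow over a sensor crystal, four qualitatively different
Δf/ΔD signatures arise:

``vesicle_layer``
    vesicles adsorb intact: Δf slowly approaches a deep plateau while ΔD
    climbs well above 1e-6 (soft, water-laden film); no frequency minimum.
``two_step_slb``
    vesicles accumulate to a critical coverage then rupture: Δf overshoots to
    a minimum, recovers to the bilayer plateau near −26 Hz while ΔD spikes
    then relaxes below 1e-6.
``one_step_slb``
    vesicles rupture on contact: Δf decreases monotonically to the bilayer
    plateau, ΔD stays low throughout.
``incomplete_bilayer``
    a bilayer forms but loses lipid during the final buffer rinse: the
    pre-rinse plateau is shallow and the rinse raises both Δf and ΔD,
    leaving a patchy film.

Shapes are modeled with saturating exponentials (the simplest forms matching
observed adsorption transients); parameters are exposed so each preset pins
the plateau, minimum, dissipation and timing values reported for the PC, PG
and PG/LPG lipid systems.  All randomness flows from a single integer seed.

Lognormal multi-modal particle populations for DLS fixtures live here too.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .dls import SizeDistribution
from .traces import FlowMarkers, QCMDTrace

__all__ = [
    "ScenarioParams",
    "DLSPopulation",
    "generate_trace",
    "generate_dls_counts",
    "get_preset",
    "list_presets",
    "SCENARIOS",
]

SCENARIOS = ("vesicle_layer", "two_step_slb", "one_step_slb", "incomplete_bilayer")

#: Curvature of the pre-minimum descent: k * t_min = 1 keeps the least-squares
#: initial slope within ~2% of the secant f_min / t_min.
_DESCENT_KT = 1.0
_D_RISE_KT = 2.0


@dataclass(frozen=True)
class ScenarioParams:
    """Full parameterization of one synthetic QCM-D run.

    Frequencies are overtone-normalized Hz, dissipation in 1e-6 units, times
    in minutes, ``rate`` the exponential approach constant in 1/min.
    ``f_min``/``t_min`` apply to ``two_step_slb`` only (``t_min`` measured
    from flow start); ``f_pre_rinse`` applies to ``incomplete_bilayer``
    (plateau held until the rinse moves Δf to ``f_plateau``).
    """

    scenario: str
    f_plateau: float
    D_final: float
    rate: float
    f_min: float | None = None
    t_min: float | None = None
    D_peak: float | None = None
    f_pre_rinse: float | None = None
    rinse_rate: float = 1.0
    overtone_spread: float = 0.0
    noise_sd_f: float = 0.0
    noise_sd_D: float = 0.0
    markers: FlowMarkers = field(default_factory=lambda: FlowMarkers(5.0, 15.0, 20.0))
    harmonics: tuple[int, ...] = (3, 5, 7, 9, 11)
    dt: float = 1.0 / 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.rate <= 0 or self.rinse_rate <= 0:
            raise ValueError("rates must be positive")
        if self.noise_sd_f < 0 or self.noise_sd_D < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if self.scenario == "two_step_slb":
            if self.f_min is None or self.t_min is None:
                raise ValueError("two_step_slb requires f_min and t_min")
            if not (self.f_min < self.f_plateau < 0):
                raise ValueError("two_step_slb requires f_min < f_plateau < 0")
            if self.t_min <= 0:
                raise ValueError("t_min must be positive")
        if self.scenario == "incomplete_bilayer" and self.f_pre_rinse is None:
            raise ValueError("incomplete_bilayer requires f_pre_rinse")
        if self.markers.t_end is None:
            raise ValueError("markers must include t_end for simulation")


def _sat(t: np.ndarray, rate: float) -> np.ndarray:
    """Saturating exponential 1 - e^{-rate t}, zero for t < 0."""
    return np.where(t > 0, -np.expm1(-rate * np.maximum(t, 0.0)), 0.0)


def _scenario_curves(p: ScenarioParams, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free reference-harmonic (f, D) curves on the time grid."""
    ts = t - p.markers.t_start
    f = np.zeros_like(t)
    D = np.zeros_like(t)
    if p.scenario in ("vesicle_layer", "one_step_slb"):
        f = p.f_plateau * _sat(ts, p.rate)
        D = p.D_final * _sat(ts, p.rate)
    elif p.scenario == "two_step_slb":
        k = _DESCENT_KT / p.t_min
        descent = _sat(ts, k) / -np.expm1(-_DESCENT_KT)
        kD = _D_RISE_KT / p.t_min
        rise = _sat(ts, kD) / -np.expm1(-_D_RISE_KT)
        pre = ts <= p.t_min
        D_peak = p.D_peak if p.D_peak is not None else p.D_final
        f = np.where(pre, p.f_min * descent,
                     p.f_plateau + (p.f_min - p.f_plateau) * np.exp(-p.rate * np.maximum(ts - p.t_min, 0.0)))
        D = np.where(pre, D_peak * rise,
                     p.D_final + (D_peak - p.D_final) * np.exp(-p.rate * np.maximum(ts - p.t_min, 0.0)))
    elif p.scenario == "incomplete_bilayer":
        D_pre = p.D_peak if p.D_peak is not None else p.D_final
        f_pre = p.f_pre_rinse * _sat(ts, p.rate)
        D_pre_curve = D_pre * _sat(ts, p.rate)
        tr = t - p.markers.t_rinse
        # continue from the values actually reached at the rinse
        f_at_rinse = p.f_pre_rinse * _sat(np.array([p.markers.t_rinse - p.markers.t_start]), p.rate)[0]
        D_at_rinse = D_pre * _sat(np.array([p.markers.t_rinse - p.markers.t_start]), p.rate)[0]
        post = tr > 0
        f = np.where(post, p.f_plateau + (f_at_rinse - p.f_plateau) * np.exp(-p.rinse_rate * np.maximum(tr, 0.0)), f_pre)
        D = np.where(post, p.D_final + (D_at_rinse - p.D_final) * np.exp(-p.rinse_rate * np.maximum(tr, 0.0)), D_pre_curve)
    return f, D


def generate_trace(params: ScenarioParams) -> QCMDTrace:
    """Simulate a multi-harmonic trace for one scenario.

    The reference curve is scaled per harmonic so the final Δf values span
    ``overtone_spread`` Hz (higher harmonics reading slightly shallower, as
    for hydrated films), then seeded Gaussian noise is added independently to
    every series.  Identical parameters and seed give identical traces.
    """
    p = params
    n_steps = int(round(p.markers.t_end / p.dt))
    t = np.arange(n_steps + 1) * p.dt
    f_ref, D_ref = _scenario_curves(p, t)
    rng = np.random.default_rng(p.seed)
    m = len(p.harmonics)
    delta_f: dict[int, np.ndarray] = {}
    delta_D: dict[int, np.ndarray] = {}
    for i, n in enumerate(sorted(p.harmonics)):
        if m > 1 and p.overtone_spread > 0:
            # lowest harmonic carries the nominal curve (the reporting
            # harmonic); higher harmonics read shallower, spanning the spread
            rel = -i / (m - 1)
            scale = 1.0 + rel * p.overtone_spread / abs(p.f_plateau)
        else:
            scale = 1.0
        f = f_ref * scale
        D = D_ref.copy()
        if p.noise_sd_f > 0:
            f = f + rng.normal(0.0, p.noise_sd_f, size=t.shape)
        if p.noise_sd_D > 0:
            D = D + rng.normal(0.0, p.noise_sd_D, size=t.shape)
        delta_f[n] = f
        delta_D[n] = D
    meta = {"scenario": p.scenario, "seed": str(p.seed),
            "t_start": f"{p.markers.t_start:g}", "t_rinse": f"{p.markers.t_rinse:g}"}
    return QCMDTrace(time=t, delta_f=delta_f, delta_D=delta_D, meta=meta)


@dataclass(frozen=True)
class DLSPopulation:
    """Multi-modal lognormal particle population.

    ``modes`` is a list of (median diameter nm, geometric sd, particle count);
    a geometric sd of exactly 1 is the degenerate single-diameter case.
    """

    modes: tuple[tuple[float, float, int], ...]
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.modes:
            raise ValueError("population needs at least one mode")
        for med, gsd, count in self.modes:
            if med <= 0 or gsd < 1 or count <= 0:
                raise ValueError("modes need median > 0, geometric sd >= 1, count > 0")


def generate_dls_counts(pop: DLSPopulation, bins: np.ndarray) -> SizeDistribution:
    """Sample particle diameters and histogram them onto a diameter grid.

    ``bins`` are bin-center diameters (nm, strictly increasing); edges are
    taken midway between centers.  Returns a number-basis distribution whose
    values are raw particle counts.
    """
    bins = np.asarray(bins, dtype=float)
    if bins.size == 0:
        raise ValueError("empty diameter grid")
    rng = np.random.default_rng(pop.seed)
    draws = []
    for med, gsd, count in pop.modes:
        if gsd == 1.0:
            draws.append(np.full(count, med))
        else:
            draws.append(rng.lognormal(np.log(med), np.log(gsd), size=count))
    sample = np.concatenate(draws)
    edges = np.concatenate((
        [bins[0] - (bins[1] - bins[0]) / 2] if bins.size > 1 else [bins[0] * 0.5],
        (bins[:-1] + bins[1:]) / 2,
        [bins[-1] + (bins[-1] - bins[-2]) / 2] if bins.size > 1 else [bins[0] * 1.5],
    ))
    counts, _ = np.histogram(sample, bins=edges)
    return SizeDistribution(d=bins, values=counts.astype(float), basis="number",
                            normalized=False)


def _load_presets() -> dict:
    text = resources.files("slbqcmd.data").joinpath("presets.yaml").read_text()
    return yaml.safe_load(text)


def list_presets() -> list[str]:
    """Names of the packaged lipid-system presets."""
    return sorted(_load_presets())


def get_preset(name: str, *, seed: int = 0, noise_sd_f: float = 0.0,
               noise_sd_D: float = 0.0) -> ScenarioParams:
    """Load a packaged preset (PC, PG, PG-LPG-10/20/30/40) as ScenarioParams.

    Presets pin each lipid system's reported plateau, minimum, dissipation and
    timing values; seed and noise levels are run-time choices.
    """
    presets = _load_presets()
    if name not in presets:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(presets)}")
    cfg = dict(presets[name])
    markers = FlowMarkers(**cfg.pop("markers"))
    return ScenarioParams(markers=markers, seed=seed, noise_sd_f=noise_sd_f,
                          noise_sd_D=noise_sd_D, **cfg)


def scenario_defaults(scenario: str, *, seed: int = 0, noise_sd_f: float = 0.0,
                      noise_sd_D: float = 0.0) -> ScenarioParams:
    """Representative preset for each scenario (PG, PC, PG-LPG-10, PG-LPG-40)."""
    by_scenario = {"vesicle_layer": "PG", "two_step_slb": "PC",
                   "one_step_slb": "PG-LPG-10", "incomplete_bilayer": "PG-LPG-40"}
    if scenario not in by_scenario:
        raise ValueError(f"unknown scenario {scenario!r}")
    return get_preset(by_scenario[scenario], seed=seed, noise_sd_f=noise_sd_f,
                      noise_sd_D=noise_sd_D)
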