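"""Bilayer molecular-packing geometry from the final QCM-D frequency shift.

The chain runs: Sauerbrey areal mass Δm = −C·Δf (C = 17.8 ng/cm²/Hz for a
5 MHz crystal); subtract the trapped-water layer between bilayer and sensor
(≈102 ng/cm² for a PC bilayer on silica, assumed transferable to anionic
bilayers); divide by the mole-fraction-averaged mass per lipid M_L = M̄/N_A
to get the surface density of lipids; halve for the per-leaflet density N_L;
invert for the area per lipid a_L = 1/N_L; and obtain the hydrophobic-region
thickness from the averaged tail volume, h_L = 2·v̄_L/a_L.

The Sauerbrey conversion assumes a thin rigid film — valid when the final
dissipation shift stays below 1×10⁻⁶.  Softer films (e.g. vesicle layers)
need a viscoelastic model instead; here the conversion still computes but a
warning is attached.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

__all__ = [
    "AVOGADRO",
    "LipidSpecies",
    "Mixture",
    "PackingConfig",
    "PackingResult",
    "sauerbrey_mass",
    "sauerbrey_applicable",
    "mixture_average",
    "packing_from_frequency",
    "packing_table",
    "load_species",
]

AVOGADRO = 6.02214e23  # 1/mol
NM2_PER_CM2 = 1e14


@dataclass(frozen=True)
class LipidSpecies:
    """A lipid (or averaged lipid class) with mass and tail-volume constants."""

    name: str
    mw: float  # g/mol
    v_tail: float  # nm^3 / molecule

    def __post_init__(self) -> None:
        if self.mw <= 0 or self.v_tail <= 0:
            raise ValueError("mw and v_tail must be positive")


@dataclass(frozen=True)
class Mixture:
    """Lipid mixture as (species, mole fraction) pairs summing to 1."""

    components: tuple[tuple[LipidSpecies, float], ...]

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("mixture needs at least one component")
        fracs = [x for _, x in self.components]
        if any(not 0 < x <= 1 for x in fracs):
            raise ValueError("mole fractions must lie in (0, 1]")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("mole fractions must sum to 1")

    @property
    def label(self) -> str:
        return "/".join(f"{s.name}:{x:g}" for s, x in self.components)


@dataclass(frozen=True)
class PackingConfig:
    """Constants of the mass-to-geometry chain.

    ``C`` is the Sauerbrey sensitivity (ng/cm²/Hz, 17.8 for a 5 MHz crystal);
    ``water_correction`` the areal mass of the water layer between bilayer and
    substrate (ng/cm²); ``avogadro`` Avogadro's number (1/mol).
    """

    C: float = 17.8
    water_correction: float = 102.0
    avogadro: float = AVOGADRO

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.water_correction < 0:
            raise ValueError("water_correction must be non-negative")


@dataclass(frozen=True)
class PackingResult:
    """Outputs of the packing chain for one membrane."""

    delta_f: float          # Hz
    areal_mass: float       # ng/cm^2
    corrected_mass: float   # ng/cm^2, water layer removed
    mw_avg: float           # g/mol
    M_L: float              # ng per lipid molecule
    density_total: float    # lipids/nm^2, both leaflets
    N_L: float              # lipids/nm^2 per leaflet
    a_L: float              # nm^2 per lipid
    v_L_avg: float          # nm^3 per molecule
    h_L: float              # nm, hydrophobic-region thickness
    warnings: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "delta_f_Hz": self.delta_f,
            "areal_mass_ng_cm2": self.areal_mass,
            "corrected_mass_ng_cm2": self.corrected_mass,
            "mw_avg_g_mol": self.mw_avg,
            "M_L_ng": self.M_L,
            "density_total_nm2": self.density_total,
            "N_L_nm2": self.N_L,
            "a_L_nm2": self.a_L,
            "v_L_avg_nm3": self.v_L_avg,
            "h_L_nm": self.h_L,
            "warnings": list(self.warnings),
        }


def sauerbrey_mass(delta_f: float, C: float = 17.8) -> float:
    """Areal mass Δm = −C·Δf (ng/cm²); positive for mass addition."""
    return -C * delta_f


def sauerbrey_applicable(D_final: float) -> bool:
    """True when the film is rigid enough for the Sauerbrey conversion.

    The criterion is a final dissipation shift strictly below 1×10⁻⁶
    (``D_final`` given in 1e-6 units, so the boundary value 1.0 fails).
    """
    return D_final < 1.0


def mixture_average(mix: Mixture) -> tuple[float, float]:
    """Mole-fraction-weighted (molecular weight, tail volume) of a mixture."""
    mw = sum(s.mw * x for s, x in mix.components)
    v = sum(s.v_tail * x for s, x in mix.components)
    return float(mw), float(v)


def packing_from_frequency(delta_f: float, mix: Mixture,
                           cfg: PackingConfig | None = None,
                           D_final: float | None = None) -> PackingResult:
    """Run the full packing chain from a final frequency shift.

    All intermediate quantities are kept at full precision; rounding is a
    rendering concern.  Raises ValueError when the Sauerbrey mass does not
    exceed the assumed water-layer mass (no lipid mass would remain).  If
    ``D_final`` (1e-6 units) is supplied and indicates a non-rigid film, the
    result carries a warning rather than failing: the conversion is then an
    effective-mass estimate only.
    """
    cfg = cfg or PackingConfig()
    areal = sauerbrey_mass(delta_f, cfg.C)
    corrected = areal - cfg.water_correction
    if corrected <= 0:
        raise ValueError(
            f"corrected mass {corrected:g} ng/cm^2 <= 0: film lighter than the "
            "assumed water layer")
    mw_avg, v_avg = mixture_average(mix)
    M_L = mw_avg / cfg.avogadro * 1e9  # g/mol -> ng/molecule
    density_total = corrected / M_L / NM2_PER_CM2  # lipids/nm^2
    N_L = density_total / 2.0
    a_L = 1.0 / N_L
    h_L = 2.0 * v_avg / a_L
    notes = ()
    if D_final is not None and not sauerbrey_applicable(D_final):
        notes = (f"Sauerbrey conversion outside rigidity criterion "
                 f"(D_final = {D_final:g} x 1e-6 >= 1): mass is an effective "
                 f"estimate for a viscoelastic film",)
    return PackingResult(delta_f=delta_f, areal_mass=areal, corrected_mass=corrected,
                         mw_avg=mw_avg, M_L=M_L, density_total=density_total,
                         N_L=N_L, a_L=a_L, v_L_avg=v_avg, h_L=h_L, warnings=notes)


def packing_table(rows: list[tuple[str, float, Mixture]],
                  cfg: PackingConfig | None = None):
    """Batch packing results as a pandas DataFrame, one row per membrane.

    Rows whose chain fails (e.g. corrected mass <= 0) are kept with NaN
    values and the error message in an ``error`` column; the rest of the
    batch still computes.
    """
    import pandas as pd

    records = []
    for label, delta_f, mix in rows:
        base = {"lipid": label, "delta_f_Hz": delta_f}
        try:
            r = packing_from_frequency(delta_f, mix, cfg)
            base.update({
                "mw_avg_g_mol": r.mw_avg, "M_L_ng": r.M_L, "N_L_nm2": r.N_L,
                "a_L_nm2": r.a_L, "v_L_nm3": r.v_L_avg, "h_L_nm": r.h_L,
                "areal_mass_ng_cm2": r.areal_mass,
                "corrected_mass_ng_cm2": r.corrected_mass, "error": "",
            })
        except ValueError as exc:
            base.update({k: np.nan for k in (
                "mw_avg_g_mol", "M_L_ng", "N_L_nm2", "a_L_nm2", "v_L_nm3",
                "h_L_nm", "areal_mass_ng_cm2", "corrected_mass_ng_cm2")})
            base["error"] = str(exc)
        records.append(base)
    return pd.DataFrame.from_records(records)


def load_species(path=None) -> dict[str, LipidSpecies]:
    """Load lipid species constants from YAML (packaged file by default)."""
    if path is None:
        text = resources.files("slbqcmd.data").joinpath("species.yaml").read_text()
    elif hasattr(path, "read"):
        text = path.read()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    return {name: LipidSpecies(name=name, mw=float(v["mw"]), v_tail=float(v["v_tail"]))
            for name, v in raw.items()}


def mixture_from_fractions(fractions: dict[str, float],
                           species: dict[str, LipidSpecies] | None = None) -> Mixture:
    """Build a Mixture from {species name: mole fraction} using packaged constants."""
    sp = species or load_species()
    try:
        comps = tuple((sp[name], float(x)) for name, x in fractions.items())
    except KeyError as exc:
        raise KeyError(f"unknown lipid species {exc.args[0]!r}; known: {sorted(sp)}")
    return Mixture(components=comps)
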