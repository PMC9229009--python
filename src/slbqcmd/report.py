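"""End-to-end analysis: trace -> signature -> (if a bilayer formed) packing.

`analyze` composes the pipeline stages and returns a structured report that
serializes to deterministic JSON (sorted keys, fixed float formatting), so
identical inputs give byte-identical output.  Packing geometry is computed
for all bilayer outcomes, including incomplete bilayers — there the area per
lipid is a surface average over patches and gaps, and the report says so.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

from . import __version__
from .kinetics import ClassifierConfig, SignatureReport, classify_signature
from .packing import Mixture, PackingConfig, PackingResult, packing_from_frequency
from .traces import FlowMarkers, QCMDTrace, read_trace

__all__ = ["AnalysisReport", "analyze", "analyze_trace", "report_schema",
           "validate_report"]

_BILAYER_LABELS = ("one_step_slb", "two_step_slb", "incomplete_bilayer")


@dataclass(frozen=True)
class AnalysisReport:
    """Signature classification plus optional packing geometry and provenance."""

    signature: SignatureReport
    packing: PackingResult | None
    warnings: tuple[str, ...]
    config: dict = field(default_factory=dict)
    version: str = ""

    def to_dict(self) -> dict:
        return {
            "signature": self.signature.to_dict(),
            "packing": self.packing.to_dict() if self.packing else None,
            "warnings": list(self.warnings),
            "config": self.config,
            "version": self.version,
        }

    def to_json(self) -> str:
        """Deterministic JSON: sorted keys, floats at 12 significant digits."""
        def _canon(obj):
            if isinstance(obj, float):
                return float(f"{obj:.12g}")
            if isinstance(obj, dict):
                return {k: _canon(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_canon(v) for v in obj]
            return obj
        return json.dumps(_canon(self.to_dict()), sort_keys=True, indent=2)


def analyze_trace(trace: QCMDTrace, markers: FlowMarkers, mixture: Mixture | None,
                  classifier: ClassifierConfig | None = None,
                  packing_cfg: PackingConfig | None = None) -> AnalysisReport:
    """Classify a trace and, for bilayer outcomes, derive packing geometry.

    Packing runs only when a mixture is supplied and the label is a bilayer
    outcome (one-step, two-step or incomplete).  A non-rigid film or an
    incomplete bilayer attaches explicit warnings instead of suppressing the
    numbers, since surface-averaged estimates remain interpretable.
    """
    cfg = classifier or ClassifierConfig()
    pcfg = packing_cfg or PackingConfig()
    sig = classify_signature(trace, markers, cfg)
    notes: list[str] = list(sig.warnings)
    packing: PackingResult | None = None
    if sig.label in _BILAYER_LABELS and mixture is not None:
        try:
            packing = packing_from_frequency(sig.f_final, mixture, pcfg,
                                             D_final=sig.D_final)
            notes.extend(packing.warnings)
        except ValueError as exc:
            notes.append(f"packing stage failed: {exc}")
        if sig.label == "incomplete_bilayer" and packing is not None:
            notes.append("non-continuous film: a_L is a surface average over "
                         "bilayer patches and gaps")
        if packing is not None and not sig.rigid:
            notes.append("packing computed for a non-rigid film (D_final >= 1)")
    config_snapshot = {
        "classifier": {
            "reference_harmonic": cfg.reference_harmonic,
            "min_prominence": cfg.min_prominence,
            "rupture_rise": cfg.rupture_rise,
            "bilayer_band": list(cfg.bilayer_band),
            "rinse_D_rise": cfg.rinse_D_rise,
            "rinse_f_rise": cfg.rinse_f_rise,
            "rigid_D": cfg.rigid_D,
            "plateau_window": cfg.plateau_window,
            "smooth_window": cfg.smooth_window,
        },
        "packing": {"C": pcfg.C, "water_correction": pcfg.water_correction,
                    "avogadro": pcfg.avogadro},
        "mixture": mixture.label if mixture is not None else None,
    }
    return AnalysisReport(signature=sig, packing=packing, warnings=tuple(notes),
                          config=config_snapshot, version=__version__)


def analyze(trace_path, markers: FlowMarkers, mixture: Mixture | None = None,
            classifier: ClassifierConfig | None = None,
            packing_cfg: PackingConfig | None = None,
            raw_shifts: bool = False) -> AnalysisReport:
    """File-level entry point: read a trace CSV and run `analyze_trace`."""
    trace = read_trace(trace_path, raw_shifts=raw_shifts)
    return analyze_trace(trace, markers, mixture, classifier, packing_cfg)


def report_schema() -> dict:
    """The JSON schema the report serialization conforms to."""
    text = resources.files("slbqcmd.data").joinpath("report_schema.json").read_text()
    return json.loads(text)


def validate_report(doc: dict, schema: dict | None = None, path: str = "$") -> None:
    """Minimal structural validation (type/required/properties/enum subset).

    Raises ValueError at the first violation; returns None on success.
    """
    schema = schema if schema is not None else report_schema()
    _TYPES = {"object": dict, "array": list, "string": str, "number": (int, float),
              "boolean": bool, "integer": int, "null": type(None)}
    stype = schema.get("type")
    if stype is not None:
        allowed = stype if isinstance(stype, list) else [stype]
        if not any(isinstance(doc, _TYPES[t]) and not
                   (t == "number" and isinstance(doc, bool)) for t in allowed):
            raise ValueError(f"{path}: expected type {stype}, got {type(doc).__name__}")
    if "enum" in schema and doc not in schema["enum"]:
        raise ValueError(f"{path}: {doc!r} not in enum {schema['enum']}")
    if isinstance(doc, dict):
        for key in schema.get("required", []):
            if key not in doc:
                raise ValueError(f"{path}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in doc:
                validate_report(doc[key], sub, f"{path}.{key}")
    if isinstance(doc, list) and "items" in schema:
        for i, item in enumerate(doc):
            validate_report(item, schema["items"], f"{path}[{i}]")
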