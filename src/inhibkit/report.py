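"""Compound-level report assembly and deterministic JSON serialization.

A report aggregates the per-stage results for one compound (dose-response,
kinetics, binding, thermodynamics, CD) together with provenance: input
files, seeds, software version and every warning any stage emitted.
Serialization is deterministic - keys sorted, floats at six significant
digits - so identical inputs give byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Any

from . import __version__
from .errors import EmptyReportError

SECTION_NAMES = ("ic50", "kinetics", "binding", "thermo", "cd")


def _to_plain(obj: Any) -> Any:
    """Recursively convert dataclasses/arrays to JSON-serializable values."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if hasattr(obj, "tolist"):  # numpy scalars and arrays
        return _to_plain(obj.tolist())
    return obj


def _round_floats(obj: Any) -> Any:
    if isinstance(obj, float):
        return float(f"{obj:.6g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_round_floats(v) for v in obj]
    return obj


def _collect_warnings(section: Any) -> list[str]:
    found: list[str] = []
    if isinstance(section, dict):
        for key, val in section.items():
            if key == "warnings" and isinstance(val, list):
                found.extend(str(w) for w in val)
            else:
                found.extend(_collect_warnings(val))
    elif isinstance(section, list):
        for val in section:
            found.extend(_collect_warnings(val))
    return found


def build_report(
    compound_id: str,
    ic50: Any = None,
    kinetics: Any = None,
    binding: Any = None,
    thermo: Any = None,
    cd: Any = None,
    inputs: dict[str, str] | None = None,
    seed: int | None = None,
) -> dict[str, Any]:
    """Assemble a JSON-serializable compound report.

    Sections may be dataclasses or plain dicts; absent sections are
    explicit nulls.  At least one section must be populated.
    """
    sections = {
        "ic50": ic50,
        "kinetics": kinetics,
        "binding": binding,
        "thermo": thermo,
        "cd": cd,
    }
    if all(v is None for v in sections.values()):
        raise EmptyReportError("report requested with no populated sections")
    body: dict[str, Any] = {"compound_id": compound_id}
    all_warnings: list[str] = []
    for name, section in sections.items():
        plain = _to_plain(section) if section is not None else None
        body[name] = plain
        if plain is not None:
            all_warnings.extend(_collect_warnings(plain))
    body["provenance"] = {
        "software": f"inhibkit {__version__}",
        "inputs": dict(inputs or {}),
        "seed": seed,
        "warnings": all_warnings,
    }
    return body


def serialize_report(report: dict[str, Any]) -> str:
    """Deterministic JSON text: sorted keys, floats at 6 significant digits."""
    return json.dumps(_round_floats(_to_plain(report)), sort_keys=True, indent=2)
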