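"""Registry of the 15 routine laboratory variables used for network mapping.

Each variable stands in for one or more physiological systems (acid-base,
renal, hepatic, ...), so that pairwise correlations between variables can be
read as couplings between organ systems. The registry carries units and broad
plausibility ranges used only for validation warnings, never for filtering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Tuple

import yaml

__all__ = ["VariableSpec", "default_registry", "load_registry", "save_registry"]


@dataclass(frozen=True)
class VariableSpec:
    """One laboratory variable: name, unit, organ-system tags, sanity range."""

    name: str
    unit: str
    systems: frozenset = field(default_factory=frozenset)
    plausibility_range: Optional[Tuple[float, float]] = None

    def __post_init__(self):
        if self.plausibility_range is not None:
            lo, hi = self.plausibility_range
            if not lo < hi:
                raise ValueError(
                    f"plausibility_range for {self.name!r} must satisfy low < high"
                )


def _v(name, unit, systems, rng):
    return VariableSpec(name, unit, frozenset(systems), rng)


# Order matters: it fixes column order in cohort CSVs and matrix layouts.
_DEFAULT = [
    _v("phosphate", "mg/dL", {"renal", "metabolic", "endocrine"}, (0.5, 15.0)),
    _v("arterial_ph", "unitless", {"acid-base"}, (6.8, 7.8)),
    _v("urea", "mg/dL", {"renal"}, (1.0, 250.0)),
    _v("hemoglobin", "mg/dL", {"hematological"}, (3.0, 25.0)),
    _v("lactate", "mmol/L", {"metabolic"}, (0.1, 30.0)),
    _v("wbc", "x1000/uL", {"inflammatory", "hematological"}, (0.1, 100.0)),
    _v("sodium", "mEq/L", {"renal", "metabolic"}, (110.0, 175.0)),
    _v("inr", "unitless", {"coagulation", "hepatic"}, (0.5, 12.0)),
    _v("platelets", "x1000/uL", {"coagulation", "hematological"}, (1.0, 1500.0)),
    _v("bilirubin", "mg/dL", {"hepatic"}, (0.05, 60.0)),
    _v("glucose", "mg/dL", {"metabolic", "endocrine"}, (20.0, 1200.0)),
    _v("creatinine", "mg/dL", {"renal"}, (0.1, 25.0)),
    _v("alt", "U/L", {"hepatic"}, (1.0, 10000.0)),
    _v("bicarbonate", "mEq/L", {"acid-base", "renal", "metabolic"}, (4.0, 50.0)),
    _v("potassium", "mEq/L", {"renal", "metabolic", "endocrine"}, (1.5, 9.0)),
]


def default_registry() -> list[VariableSpec]:
    """The 15-variable laboratory panel, in canonical column order."""
    return list(_DEFAULT)


def _check_unique(specs: Iterable[VariableSpec]) -> list[VariableSpec]:
    specs = list(specs)
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate variable names in registry: {dupes}")
    return specs


def save_registry(specs: Iterable[VariableSpec], path: str | Path) -> None:
    """Write a registry as YAML (or JSON if the suffix is .json)."""
    specs = _check_unique(specs)
    payload = [
        {
            "name": s.name,
            "unit": s.unit,
            "systems": sorted(s.systems),
            "plausibility_range": list(s.plausibility_range)
            if s.plausibility_range
            else None,
        }
        for s in specs
    ]
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(payload, indent=2))
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))


def load_registry(path: str | Path) -> list[VariableSpec]:
    path = Path(path)
    text = path.read_text()
    payload = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    specs = [
        VariableSpec(
            d["name"],
            d["unit"],
            frozenset(d.get("systems", [])),
            tuple(d["plausibility_range"]) if d.get("plausibility_range") else None,
        )
        for d in payload
    ]
    return _check_unique(specs)
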