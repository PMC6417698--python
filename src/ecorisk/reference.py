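"""Reference tables for the risk computations.

The sediment track needs, per metal, the Hakanson toxic response factor Tri
(a dimensionless toxicity weight) and a background reference concentration
Cri (mg/kg dry weight) that serves as the contamination denominator. The
aquatic track needs a single safety factor applied to HC5 to obtain the
PNEC.

The default Cri values follow Grade I of the Marine Sediment Quality
standard (GB 18668-2002) as back-calculated from the bundled Laizhou Bay
scenario: As 20, Cd 0.50, Cr 80, Cu 35, Pb 60, Zn 150 mg/kg. The Hg entry
ships as 0.05 mg/kg — the value under which the scenario's mean
concentrations reproduce the risk factors it encodes — even though the
nominal Grade I Hg limit is 0.20 mg/kg; see docs/methods.md for the
discussion. Override any entry by loading a custom YAML table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .core import Metal, ValidationError

#: Hakanson toxic response factors (dimensionless).
DEFAULT_TRI: dict[Metal, float] = {
    Metal.AS: 10.0,
    Metal.CD: 30.0,
    Metal.CR: 2.0,
    Metal.CU: 5.0,
    Metal.HG: 40.0,
    Metal.PB: 5.0,
    Metal.ZN: 1.0,
}

#: Background reference concentrations, mg/kg dry weight (see module docstring
#: for the Hg caveat).
DEFAULT_CRI: dict[Metal, float] = {
    Metal.AS: 20.0,
    Metal.CD: 0.50,
    Metal.CR: 80.0,
    Metal.CU: 35.0,
    Metal.HG: 0.05,
    Metal.PB: 60.0,
    Metal.ZN: 150.0,
}

#: Nominal GB 18668-2002 Grade I value for Hg, kept for transparency.
NOMINAL_GRADE1_HG = 0.20

#: Analytical detection limits, recorded as metadata only (no censoring model
#: is applied): seawater μg/L, sediment μg/kg.
DETECTION_LIMITS: dict[Metal, dict[str, float]] = {
    Metal.AS: {"seawater_ugL": 0.5, "sediment_ugkg": 0.06},
    Metal.CD: {"seawater_ugL": 0.01, "sediment_ugkg": 0.04},
    Metal.CR: {"seawater_ugL": 0.4, "sediment_ugkg": 2.0},
    Metal.CU: {"seawater_ugL": 0.2, "sediment_ugkg": 0.5},
    Metal.HG: {"seawater_ugL": 0.007, "sediment_ugkg": 0.002},
    Metal.PB: {"seawater_ugL": 0.03, "sediment_ugkg": 1.0},
    Metal.ZN: {"seawater_ugL": 3.1, "sediment_ugkg": 6.0},
}

#: Risk-factor grade boundaries (lower-inclusive): low / moderate /
#: considerable / high / very_high.
ERI_BOUNDS = (40.0, 80.0, 160.0, 320.0)
#: Composite-index grade boundaries (lower-inclusive): low / moderate /
#: considerable / high.
RI_BOUNDS = (150.0, 300.0, 600.0)


@dataclass(frozen=True)
class ReferenceTable:
    """Per-metal Tri and Cri plus the aquatic-track safety factor."""

    tri: Mapping[Metal, float] = field(default_factory=lambda: dict(DEFAULT_TRI))
    cri: Mapping[Metal, float] = field(default_factory=lambda: dict(DEFAULT_CRI))
    safety_factor: float = 5.0

    def __post_init__(self) -> None:
        for name, table in (("Tri", self.tri), ("Cri", self.cri)):
            missing = [m.value for m in Metal if m not in table]
            if missing:
                raise ValidationError(f"{name} table missing metal(s) {missing}")
            bad = [m.value for m, v in table.items() if not v > 0]
            if bad:
                raise ValidationError(f"{name} table has non-positive entries for {bad}")
        if not self.safety_factor > 0:
            raise ValidationError("safety factor must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ReferenceTable":
        """Load a table from YAML with keys ``tri``, ``cri`` (metal code →
        value) and ``safety_factor``."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            tri={Metal.parse(k): float(v) for k, v in raw["tri"].items()},
            cri={Metal.parse(k): float(v) for k, v in raw["cri"].items()},
            safety_factor=float(raw.get("safety_factor", 5.0)),
        )

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "tri": {m.value: float(v) for m, v in self.tri.items()},
            "cri": {m.value: float(v) for m, v in self.cri.items()},
            "safety_factor": float(self.safety_factor),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)


DEFAULT_REFERENCE = ReferenceTable()
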