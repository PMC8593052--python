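"""Clinical parameter schema: 19 laboratory tests and 6 vital signs.

The schema is closed: every measurement row must name one of these
parameters.  The 25 entries double to 50 model features once the
timestep-difference (delta) parameters are appended downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import CohortValidationError

LAB = "lab"
VITAL = "vital"


@dataclass(frozen=True)
class Parameter:
    name: str
    unit: str
    kind: str  # LAB or VITAL

    def __post_init__(self) -> None:
        if self.kind not in (LAB, VITAL):
            raise CohortValidationError(f"parameter kind must be lab/vital, got {self.kind!r}")


@dataclass(frozen=True)
class ParameterSchema:
    """Ordered, closed set of clinical parameters."""

    parameters: tuple[Parameter, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        names = [p.name for p in self.parameters]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise CohortValidationError(f"duplicate parameter names: {dupes}")

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.parameters]

    @property
    def labs(self) -> list[str]:
        return [p.name for p in self.parameters if p.kind == LAB]

    @property
    def vitals(self) -> list[str]:
        return [p.name for p in self.parameters if p.kind == VITAL]

    def __len__(self) -> int:
        return len(self.parameters)

    def __contains__(self, name: str) -> bool:
        return name in self.names


def default_schema() -> ParameterSchema:
    """The packaged 25-parameter schema (19 blood tests + 6 vital signs)."""
    labs = [
        ("P(aB)-Hydrogen carbonate", "mmol/L"),
        ("P(aB)-Potassium", "mmol/L"),
        ("P-Bilirubin", "umol/L"),
        ("P(aB)-pO2", "kPa"),
        ("B-Leukocytes", "10^9/L"),
        ("P-Potassium", "mmol/L"),
        ("P(aB)-pCO2", "kPa"),
        ("B-Neutrophils", "10^9/L"),
        ("P-Glucose", "mmol/L"),
        ("P(aB)-pH", "pH"),
        ("B-Platelets", "10^9/L"),
        ("P-C-reactive protein", "mg/L"),
        ("P(aB)-Lactate", "mmol/L"),
        ("P-Sodium", "mmol/L"),
        ("eGFR", "mL/min/1.73m2"),
        ("P(aB)-Sodium", "mmol/L"),
        ("P-Albumin", "g/L"),
        ("P(aB)-Chloride", "mmol/L"),
        ("P-Creatinine", "umol/L"),
    ]
    vitals = [
        ("Systolic blood pressure", "mmHg"),
        ("Diastolic blood pressure", "mmHg"),
        ("Respiratory frequency", "/min"),
        ("Pulse", "/min"),
        ("SpO2", "%"),
        ("Temperature", "degC"),
    ]
    params = tuple(
        [Parameter(n, u, LAB) for n, u in labs] + [Parameter(n, u, VITAL) for n, u in vitals]
    )
    return ParameterSchema(params)


DEFAULT_SCHEMA = default_schema()
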