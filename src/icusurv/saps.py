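"""SAPS-II severity scoring.

The Simplified Acute Physiology Score II summarises a patient's first 24 h in
the ICU as an integer between 0 and 163, computed from 15 routine
measurements: age, heart rate, systolic blood pressure, temperature,
PaO2/FiO2 ratio (ventilated patients only), urine output, blood urea
nitrogen, sodium, potassium, bicarbonate, bilirubin, white blood cell count,
Glasgow Coma Scale, chronic disease status and admission type.  Each
component maps to a small number of points through the published point table
(Le Gall et al., 1993); the score is the sum over components.

The point table ships as a versioned JSON data file
(``data/saps2_points.json``) so the category boundaries are auditable and
swappable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields
from importlib import resources
from typing import Optional

__all__ = [
    "RiskFactorVector",
    "ValidationError",
    "saps2_score",
    "component_points",
    "max_score",
    "min_score",
    "load_point_table",
    "CHRONIC_DISEASE_LEVELS",
    "ADMISSION_TYPE_LEVELS",
    "DEFAULT_FACTOR_BOUNDS",
]

CHRONIC_DISEASE_LEVELS = ("none", "metastatic_cancer", "hematologic_malignancy", "aids")
ADMISSION_TYPE_LEVELS = ("scheduled_surgical", "medical", "unscheduled_surgical")

#: Physiologic generator bounds (inclusive) for the continuous factors.
DEFAULT_FACTOR_BOUNDS: dict[str, tuple[float, float]] = {
    "age": (18.0, 110.0),
    "heart_rate": (20.0, 220.0),
    "systolic_bp": (40.0, 260.0),
    "temperature": (32.0, 42.5),
    "pao2_fio2_ratio": (30.0, 650.0),
    "urine_output": (0.0, 8000.0),
    "bun": (1.0, 250.0),
    "sodium": (110.0, 175.0),
    "potassium": (1.5, 9.0),
    "bicarbonate": (4.0, 45.0),
    "bilirubin": (0.1, 45.0),
    "wbc": (0.05, 100.0),
    "gcs": (3, 15),
}


class ValidationError(ValueError):
    """A risk-factor field is missing, out of range, or of the wrong kind."""


@dataclass(frozen=True)
class RiskFactorVector:
    """The 15 SAPS-II risk factors for one subject.

    Units: age in years; heart_rate in bpm; systolic_bp in mmHg; temperature
    in °C; pao2_fio2_ratio in mmHg (``None`` = not ventilated, scores 0
    points); urine_output in mL/day; bun in mg/dL; sodium, potassium and
    bicarbonate in mEq/L; bilirubin in mg/dL; wbc in 10^3/µL; gcs an integer
    in [3, 15]; chronic_disease and admission_type categorical.
    """

    age: float
    heart_rate: float
    systolic_bp: float
    temperature: float
    pao2_fio2_ratio: Optional[float]
    urine_output: float
    bun: float
    sodium: float
    potassium: float
    bicarbonate: float
    bilirubin: float
    wbc: float
    gcs: int
    chronic_disease: str
    admission_type: str

    def validate(self, bounds: dict[str, tuple[float, float]] | None = None) -> None:
        bounds = DEFAULT_FACTOR_BOUNDS if bounds is None else bounds
        for f in fields(self):
            value = getattr(self, f.name)
            if f.name == "chronic_disease":
                if value not in CHRONIC_DISEASE_LEVELS:
                    raise ValidationError(
                        f"chronic_disease must be one of {CHRONIC_DISEASE_LEVELS}, got {value!r}"
                    )
                continue
            if f.name == "admission_type":
                if value not in ADMISSION_TYPE_LEVELS:
                    raise ValidationError(
                        f"admission_type must be one of {ADMISSION_TYPE_LEVELS}, got {value!r}"
                    )
                continue
            if f.name == "pao2_fio2_ratio" and value is None:
                continue  # not ventilated
            if value is None:
                raise ValidationError(f"{f.name} is missing")
            try:
                x = float(value)
            except (TypeError, ValueError):
                raise ValidationError(f"{f.name} is not numeric: {value!r}") from None
            if x != x:  # NaN
                raise ValidationError(f"{f.name} is NaN")
            lo, hi = bounds.get(f.name, (-float("inf"), float("inf")))
            if not lo <= x <= hi:
                raise ValidationError(f"{f.name}={x} outside [{lo}, {hi}]")
        if int(self.gcs) != self.gcs:
            raise ValidationError(f"gcs must be an integer, got {self.gcs!r}")


def load_point_table() -> dict:
    """Load the SAPS-II point table bundled with the package."""
    ref = resources.files("icusurv.data").joinpath("saps2_points.json")
    return json.loads(ref.read_text())


_TABLE: dict | None = None


def _table() -> dict:
    global _TABLE
    if _TABLE is None:
        _TABLE = load_point_table()
    return _TABLE


def _bin_points(bins: list[dict], value: float) -> int:
    for b in bins:
        lo, hi = b["lo"], b["hi"]
        if (lo is None or value >= lo) and (hi is None or value < hi):
            return int(b["points"])
    raise ValidationError(f"value {value} falls in no bin")  # pragma: no cover


def component_points(factors: RiskFactorVector) -> dict[str, int]:
    """Per-component SAPS-II points for a validated risk-factor vector."""
    factors.validate()
    table = _table()
    pts: dict[str, int] = {}
    for name, bins in table["continuous"].items():
        value = getattr(factors, name)
        if name == "pao2_fio2_ratio" and value is None:
            pts[name] = 0
            continue
        pts[name] = _bin_points(bins, float(value))
    for name, levels in table["categorical"].items():
        pts[name] = int(levels[getattr(factors, name)])
    return pts


def saps2_score(factors: RiskFactorVector) -> int:
    """Total SAPS-II score: the integer sum of per-component points, in [0, 163]."""
    return sum(component_points(factors).values())


def max_score() -> int:
    """Maximum attainable score by exhaustive per-component maximization."""
    table = _table()
    total = 0
    for bins in table["continuous"].values():
        total += max(int(b["points"]) for b in bins)
    for levels in table["categorical"].values():
        total += max(int(p) for p in levels.values())
    return total


def min_score() -> int:
    """Minimum attainable score by exhaustive per-component minimization."""
    table = _table()
    # pao2_fio2 contributes 0 when not ventilated; every other component has a
    # zero-point category in the published table.
    total = 0
    for name, bins in table["continuous"].items():
        pts = [int(b["points"]) for b in bins]
        if name == "pao2_fio2_ratio":
            pts.append(0)
        total += min(pts)
    for levels in table["categorical"].values():
        total += min(int(p) for p in levels.values())
    return total
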