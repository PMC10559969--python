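"""Health-treatment vocabulary, category map, deduplication rules and costs.

Fourteen treatment types are recognised, grouped into five cost categories:
mastitis (MAST), reproduction (REPRO), lameness (LAME), metabolic (META) and
miscellaneous (MISC).  Each type carries a deduplication rule deciding when a
raw recorded treatment counts as a new billable event within a lactation:

* ``window(k)`` -- a record is a new event only if at least *k* days elapsed
  since the previous record of the same type (k = 3 for hoof, 5 for most
  types, 7 for cystic ovary);
* ``once_per_lactation`` -- a single event per lactation (displaced
  abomasum, retained placenta, miscellaneous reproduction);
* ``per_day`` -- unlimited events but at most one per calendar day
  (mastitis diagnostic test, injury, other).

Each treatment has a fixed cost: veterinary expense + pharmaceuticals +
labor-hours x hourly wage (default $18/h).  Currency is handled in integer
cents internally so that lactational sums are exact.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping

import yaml

DEFAULT_WAGE = 18.0  # $/h for producer labor


class Category(str, enum.Enum):
    MAST = "MAST"
    REPRO = "REPRO"
    LAME = "LAME"
    META = "META"
    MISC = "MISC"


CATEGORIES = [c.value for c in Category]


class DedupKind(str, enum.Enum):
    WINDOW = "window"
    ONCE_PER_LACTATION = "once_per_lactation"
    PER_DAY = "per_day"


@dataclass(frozen=True)
class TreatmentType:
    """One of the 14 recognised treatment types."""

    code: str
    category: Category
    dedup: DedupKind
    window_days: int | None = None  # only for DedupKind.WINDOW

    def __post_init__(self) -> None:
        if self.dedup is DedupKind.WINDOW:
            if self.window_days not in (3, 5, 7):
                raise ValueError(
                    f"window rule for {self.code!r} must use 3, 5 or 7 days"
                )
        elif self.window_days is not None:
            raise ValueError(f"{self.code!r}: window_days only valid for window rule")


def _w(code: str, cat: Category, days: int) -> TreatmentType:
    return TreatmentType(code, cat, DedupKind.WINDOW, days)


def _once(code: str, cat: Category) -> TreatmentType:
    return TreatmentType(code, cat, DedupKind.ONCE_PER_LACTATION)


def _daily(code: str, cat: Category) -> TreatmentType:
    return TreatmentType(code, cat, DedupKind.PER_DAY)


#: The 14-type vocabulary with its category map and deduplication rules.
TREATMENT_TYPES: Mapping[str, TreatmentType] = {
    t.code: t
    for t in [
        _w("mastitis", Category.MAST, 5),
        _daily("mastitis_test", Category.MAST),
        _w("hoof", Category.LAME, 3),
        _w("cystic_ovary", Category.REPRO, 7),
        _once("retained_placenta", Category.REPRO),
        _w("metritis", Category.REPRO, 5),
        _once("misc_repro", Category.REPRO),
        _w("milk_fever", Category.META, 5),
        _once("displaced_abomasum", Category.META),
        _w("ketosis", Category.META, 5),
        _w("digestive", Category.META, 5),
        _w("respiratory", Category.MISC, 5),
        _daily("injury", Category.MISC),
        _daily("other", Category.MISC),
    ]
}

TREATMENT_CODES = list(TREATMENT_TYPES)

#: Specific treatments whose lactational costs are also reported on their own.
SPECIFIC_TREATMENTS = ["metritis", "retained_placenta", "displaced_abomasum", "ketosis"]


def normalize_code(code: str) -> str:
    """Validate a (case-insensitive) treatment code against the vocabulary."""
    key = str(code).strip().lower()
    if key not in TREATMENT_TYPES:
        raise KeyError(f"unknown treatment code: {code!r}")
    return key


@dataclass(frozen=True)
class CostEntry:
    """Fixed-cost components for one treatment type."""

    code: str
    veterinary_cost: float
    pharma_cost: float
    labor_hours: float
    wage: float = DEFAULT_WAGE

    def __post_init__(self) -> None:
        for name in ("veterinary_cost", "pharma_cost", "labor_hours", "wage"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.code}: {name} must be >= 0")

    @property
    def fixed_cost(self) -> float:
        return self.veterinary_cost + self.pharma_cost + self.labor_hours * self.wage

    @property
    def fixed_cost_cents(self) -> int:
        return int(round(self.fixed_cost * 100))


class CostTable:
    """Per-treatment fixed costs (vet + pharma + labor-hours x wage)."""

    def __init__(self, entries: Mapping[str, CostEntry]):
        self.entries = dict(entries)

    def cost_cents(self, code: str) -> int:
        code = normalize_code(code)
        if code not in self.entries:
            raise KeyError(f"no cost entry for treatment code {code!r}")
        return self.entries[code].fixed_cost_cents

    def cost(self, code: str) -> float:
        return self.cost_cents(code) / 100.0

    @classmethod
    def from_dict(cls, data: Mapping, wage: float | None = None) -> "CostTable":
        wage = float(data.get("wage", DEFAULT_WAGE)) if wage is None else wage
        entries = {}
        for code, spec in data.get("treatments", data).items():
            if code == "wage":
                continue
            code = normalize_code(code)
            entries[code] = CostEntry(
                code=code,
                veterinary_cost=float(spec.get("veterinary_cost", 0.0)),
                pharma_cost=float(spec.get("pharma_cost", 0.0)),
                labor_hours=float(spec.get("labor_hours", 0.0)),
                wage=float(spec.get("wage", wage)),
            )
        return cls(entries)

    @classmethod
    def from_yaml(cls, path) -> "CostTable":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {
            "treatments": {
                c: {
                    "veterinary_cost": e.veterinary_cost,
                    "pharma_cost": e.pharma_cost,
                    "labor_hours": e.labor_hours,
                    "wage": e.wage,
                }
                for c, e in sorted(self.entries.items())
            }
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


# Synthetic default cost table.  The per-treatment dollar amounts are not
# published; these defaults were chosen so that, combined with the default
# incidence targets of the herd simulator, mean lactational category costs
# land near the magnitudes reported for commercial Holstein herds (mastitis
# ~$11, reproduction ~$15, lameness ~$13, metabolic ~$8, miscellaneous ~$8
# per first lactation).  The $18/h wage is the only externally fixed number.
_DEFAULT_COSTS = {
    # code: (vet, pharma, labor_hours)
    "mastitis": (12.00, 19.00, 0.50),       # -> 40.00
    "mastitis_test": (5.00, 1.50, 0.083),   # -> ~8.00
    "hoof": (12.00, 9.00, 0.50),            # -> 30.00
    "cystic_ovary": (58.00, 16.60, 0.30),   # -> 80.00
    "retained_placenta": (54.00, 22.50, 0.75),  # -> 90.00
    "metritis": (65.00, 26.00, 0.50),       # -> 100.00
    "misc_repro": (100.00, 22.00, 1.00),    # -> 140.00
    "milk_fever": (45.00, 27.00, 1.00),     # -> 90.00
    "displaced_abomasum": (250.00, 43.00, 1.50),  # -> 320.00
    "ketosis": (12.00, 14.00, 0.50),        # -> 35.00
    "digestive": (18.00, 13.00, 0.50),      # -> 40.00
    "respiratory": (27.00, 26.00, 0.50),    # -> 62.00
    "injury": (23.00, 11.50, 0.75),         # -> 48.00
    "other": (20.00, 16.00, 0.50),          # -> 45.00
}


def default_cost_table(wage: float = DEFAULT_WAGE) -> CostTable:
    """The package's synthetic default cost table (documented above)."""
    return CostTable(
        {
            code: CostEntry(code, vet, pharma, hours, wage)
            for code, (vet, pharma, hours) in _DEFAULT_COSTS.items()
        }
    )
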