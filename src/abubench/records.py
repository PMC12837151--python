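"""Domain types for the antibiotic-use (ABU) benchmarking pipeline.

The pipeline works on three input tables plus a substance catalog:

* prescriptions — one row per antibiotic prescription/application event:
  which practice, which year, which species, which veterinary medicinal
  product (VMP), how many administered treatment days, how many animals;
* consultations — the annual number of consultations per practice and
  species (``NbConsult``), the population at risk that normalises the
  treatment indicator;
* practices — the practice registry with the declared practice type and
  canton;
* substance catalog — active substance → antibiotic class, criticality
  flag and carry-over days (active-substance effective time beyond the
  administered days, e.g. long-acting injectables).

Row-level validation lives here as pydantic models; the pipeline itself
operates on pandas DataFrames with the same column names (see
:mod:`abubench.io` for converters).
"""

from __future__ import annotations

import enum
from typing import NamedTuple, Optional

from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator


class Species(str, enum.Enum):
    CAT = "cat"
    DOG = "dog"


class DeclaredType(str, enum.Enum):
    """Practice type as declared at registration (drop-down menu)."""

    COMPANION_PRACTICE = "companion_practice"
    COMPANION_CLINIC = "companion_clinic"
    MIXED_PRACTICE = "mixed_practice"


class PracticeType(str, enum.Enum):
    """Benchmarking stratum: mixed practices, or companion practices/
    clinics split at 4500 consultations per year (strictly more than
    4500 → large)."""

    MIXED = "mixed"
    SMALL_LT4500 = "small_lt4500"
    SMALL_GE4500 = "small_ge4500"


class Scope(str, enum.Enum):
    """Indicator scope: all antibiotics, or critical antibiotics only."""

    ALL = "all"
    CRITICAL = "critical"


class Category(str, enum.Enum):
    """Four-level ABU classification against the stratum thresholds."""

    VERY_HIGH = "very_high"
    HIGH = "high"
    ACCEPTABLE = "acceptable"
    NONE = "none"


class ExclusionReason(str, enum.Enum):
    NO_NBCONSULT_ANY_YEAR = "no_nbconsult_any_year"
    UNDER_100 = "under_100"


#: Antibiotic classes considered "critical" in the Swiss system
#: (WHO critically-important antimicrobials reserved for second line).
CRITICAL_AB_CLASSES = frozenset(
    {"macrolide", "fluoroquinolone", "cephalosporin_3g", "cephalosporin_4g"}
)


class StratumKey(NamedTuple):
    """One comparison group: practice type × species × antibiotic scope.

    3 practice types × 2 species × 2 scopes = 12 possible strata.
    """

    practice_type: PracticeType
    species: Species
    scope: Scope


class PrescriptionRecord(BaseModel):
    """One antibiotic prescription or application event.

    ``therapy_days`` is the number of *administered* treatment days;
    the carry-over of long-acting substances is added downstream from
    the substance catalog (see :func:`abubench.indicator.therapy_days`).
    """

    model_config = ConfigDict(frozen=True)

    practice_id: str
    year: int = Field(ge=2000, le=2100)
    species: Species
    vmp_id: str
    substances: tuple[str, ...] = Field(min_length=1)
    therapy_days: float = Field(gt=0)
    animals_treated: int = Field(ge=1)
    indication: str = ""
    dosage_mg_per_kg: Optional[float] = Field(default=None, gt=0)

    @field_validator("substances", mode="before")
    @classmethod
    def _split_substances(cls, v):
        if isinstance(v, str):
            v = [s for s in v.split(";") if s]
        return tuple(v)


class ConsultationRecord(BaseModel):
    """Annual consultation count (NbConsult) for one practice × species
    × year. At most one record per key."""

    model_config = ConfigDict(frozen=True)

    practice_id: str
    species: Species
    year: int = Field(ge=2000, le=2100)
    n_consultations: int = Field(ge=0)


class PracticeRecord(BaseModel):
    model_config = ConfigDict(frozen=True)

    practice_id: str
    declared_type: DeclaredType
    canton: str = Field(min_length=2, max_length=2)

    @field_validator("canton")
    @classmethod
    def _upper(cls, v: str) -> str:
        return v.upper()


class SubstanceCatalogEntry(BaseModel):
    model_config = ConfigDict(frozen=True)

    substance_code: str
    ab_class: str
    is_critical: bool
    carryover_days: float = Field(ge=0)

    @model_validator(mode="after")
    def _check_critical_consistency(self):
        expected = self.ab_class in CRITICAL_AB_CLASSES
        if self.is_critical != expected:
            raise ValueError(
                f"substance {self.substance_code!r}: is_critical={self.is_critical} "
                f"inconsistent with ab_class {self.ab_class!r} "
                f"(critical classes: {sorted(CRITICAL_AB_CLASSES)})"
            )
        return self


class SubstanceCatalog:
    """Lookup table for active substances.

    Unknown substance codes raise ``KeyError`` — prescriptions with
    unresolvable substances must be rejected upstream rather than
    silently counted as non-critical.
    """

    def __init__(self, entries: list[SubstanceCatalogEntry]):
        self._entries: dict[str, SubstanceCatalogEntry] = {}
        for e in entries:
            if e.substance_code in self._entries:
                raise ValueError(f"duplicate substance code {e.substance_code!r}")
            self._entries[e.substance_code] = e

    def __contains__(self, code: str) -> bool:
        return code in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries.values())

    def __getitem__(self, code: str) -> SubstanceCatalogEntry:
        return self._entries[code]

    def is_critical(self, code: str) -> bool:
        return self._entries[code].is_critical

    def carryover_days(self, code: str) -> float:
        return self._entries[code].carryover_days

    def ab_class(self, code: str) -> str:
        return self._entries[code].ab_class

    @property
    def codes(self) -> list[str]:
        return list(self._entries)

    def critical_codes(self) -> list[str]:
        return [c for c, e in self._entries.items() if e.is_critical]

    def non_critical_codes(self) -> list[str]:
        return [c for c, e in self._entries.items() if not e.is_critical]
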