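"""Readers and writers for the four input tables.

All files are UTF-8 CSV with a header row and comma delimiter.  The
``substances`` column of the prescriptions table holds a semicolon-joined
list of active-substance codes so that one CSV row stays one
prescription.  The substance catalog can also be loaded from YAML.

Readers validate row by row: a malformed prescription row is rejected
with a row-level diagnostic rather than aborting the whole file, while a
missing column or a duplicate consultation key is a hard
:class:`SchemaError`.
"""

from __future__ import annotations

import csv
import importlib.resources
from pathlib import Path
from typing import NamedTuple

import pandas as pd
import yaml
from pydantic import ValidationError

from .records import (
    ConsultationRecord,
    PracticeRecord,
    PrescriptionRecord,
    SubstanceCatalog,
    SubstanceCatalogEntry,
)

PRESCRIPTION_COLUMNS = [
    "practice_id",
    "year",
    "species",
    "vmp_id",
    "substances",
    "therapy_days",
    "animals_treated",
    "indication",
    "dosage_mg_per_kg",
]
CONSULTATION_COLUMNS = ["practice_id", "species", "year", "n_consultations"]
PRACTICE_COLUMNS = ["practice_id", "declared_type", "canton"]
CATALOG_COLUMNS = ["substance_code", "ab_class", "is_critical", "carryover_days"]


class SchemaError(ValueError):
    """The file header does not match the documented schema, or a
    table-level invariant (e.g. unique consultation keys) is violated."""


class RowDiagnostic(NamedTuple):
    row: int  # 1-based data row number (header not counted)
    reason: str


class PrescriptionReadResult(NamedTuple):
    records: list[PrescriptionRecord]
    rejects: list[RowDiagnostic]


def _check_header(fieldnames, required, path) -> None:
    missing = [c for c in required if c not in (fieldnames or [])]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")


def read_prescriptions(path, catalog: SubstanceCatalog) -> PrescriptionReadResult:
    """Read prescriptions, resolving substances against *catalog*.

    Every row is either parsed into a :class:`PrescriptionRecord` or
    rejected with a diagnostic; accepted + rejected always equals the
    number of data rows.
    """
    records: list[PrescriptionRecord] = []
    rejects: list[RowDiagnostic] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader.fieldnames, PRESCRIPTION_COLUMNS[:7], path)
        for i, row in enumerate(reader, start=1):
            try:
                rec = PrescriptionRecord(
                    practice_id=row["practice_id"],
                    year=row["year"],
                    species=row["species"],
                    vmp_id=row["vmp_id"],
                    substances=row["substances"],
                    therapy_days=row["therapy_days"],
                    animals_treated=row["animals_treated"],
                    indication=row.get("indication", "") or "",
                    dosage_mg_per_kg=(row.get("dosage_mg_per_kg") or None),
                )
            except (ValidationError, ValueError) as exc:
                rejects.append(RowDiagnostic(i, f"invalid field: {exc}"))
                continue
            unknown = [s for s in rec.substances if s not in catalog]
            if unknown:
                rejects.append(RowDiagnostic(i, f"unknown substance code(s) {unknown}"))
                continue
            records.append(rec)
    return PrescriptionReadResult(records, rejects)


def write_prescriptions(records, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=PRESCRIPTION_COLUMNS, lineterminator="\n")
        writer.writeheader()
        for r in records:
            writer.writerow(
                {
                    "practice_id": r.practice_id,
                    "year": r.year,
                    "species": r.species.value,
                    "vmp_id": r.vmp_id,
                    "substances": ";".join(r.substances),
                    "therapy_days": _num(r.therapy_days),
                    "animals_treated": r.animals_treated,
                    "indication": r.indication,
                    "dosage_mg_per_kg": "" if r.dosage_mg_per_kg is None else _num(r.dosage_mg_per_kg),
                }
            )


def _num(x: float):
    # write 7 not 7.0 so that round-trips are textually stable
    return int(x) if float(x) == int(x) else float(x)


def read_consultations(path) -> list[ConsultationRecord]:
    records: list[ConsultationRecord] = []
    seen: set[tuple] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader.fieldnames, CONSULTATION_COLUMNS, path)
        for i, row in enumerate(reader, start=1):
            try:
                rec = ConsultationRecord(
                    practice_id=row["practice_id"],
                    species=row["species"],
                    year=row["year"],
                    n_consultations=row["n_consultations"],
                )
            except (ValidationError, ValueError) as exc:
                raise SchemaError(f"{path}: row {i}: {exc}") from exc
            key = (rec.practice_id, rec.species, rec.year)
            if key in seen:
                raise SchemaError(
                    f"{path}: duplicate consultation key "
                    f"(practice={rec.practice_id!r}, species={rec.species.value}, year={rec.year})"
                )
            seen.add(key)
            records.append(rec)
    return records


def write_consultations(records, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=CONSULTATION_COLUMNS, lineterminator="\n")
        writer.writeheader()
        for r in records:
            writer.writerow(
                {
                    "practice_id": r.practice_id,
                    "species": r.species.value,
                    "year": r.year,
                    "n_consultations": r.n_consultations,
                }
            )


def read_practices(path) -> list[PracticeRecord]:
    records: list[PracticeRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader.fieldnames, PRACTICE_COLUMNS, path)
        for i, row in enumerate(reader, start=1):
            try:
                records.append(
                    PracticeRecord(
                        practice_id=row["practice_id"],
                        declared_type=row["declared_type"],
                        canton=row["canton"],
                    )
                )
            except (ValidationError, ValueError) as exc:
                raise SchemaError(f"{path}: row {i}: {exc}") from exc
    return records


def write_practices(records, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=PRACTICE_COLUMNS, lineterminator="\n")
        writer.writeheader()
        for r in records:
            writer.writerow(
                {
                    "practice_id": r.practice_id,
                    "declared_type": r.declared_type.value,
                    "canton": r.canton,
                }
            )


def _bool(v) -> bool:
    if isinstance(v, bool):
        return v
    s = str(v).strip().lower()
    if s in {"true", "1", "yes"}:
        return True
    if s in {"false", "0", "no"}:
        return False
    raise ValueError(f"not a boolean: {v!r}")


def read_catalog(path) -> SubstanceCatalog:
    """Load a substance catalog from CSV or YAML (by extension)."""
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        rows = raw["substances"] if isinstance(raw, dict) else raw
    else:
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            _check_header(reader.fieldnames, CATALOG_COLUMNS, path)
            rows = list(reader)
    entries = []
    for i, row in enumerate(rows, start=1):
        try:
            entries.append(
                SubstanceCatalogEntry(
                    substance_code=row["substance_code"],
                    ab_class=row["ab_class"],
                    is_critical=_bool(row["is_critical"]),
                    carryover_days=row["carryover_days"],
                )
            )
        except (ValidationError, ValueError) as exc:
            raise SchemaError(f"{path}: catalog row {i}: {exc}") from exc
    return SubstanceCatalog(entries)


def default_catalog() -> SubstanceCatalog:
    """Substance catalog shipped with the package (common companion-animal
    antibiotics; carry-over days for long-acting injectables)."""
    ref = importlib.resources.files("abubench.data") / "substance_catalog.csv"
    with importlib.resources.as_file(ref) as p:
        return read_catalog(p)


# ---------------------------------------------------------------------------
# DataFrame converters — the pipeline's canonical in-memory form


def prescriptions_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "practice_id": r.practice_id,
                "year": r.year,
                "species": r.species.value,
                "vmp_id": r.vmp_id,
                "substances": ";".join(r.substances),
                "therapy_days": float(r.therapy_days),
                "animals_treated": int(r.animals_treated),
                "indication": r.indication,
                "dosage_mg_per_kg": r.dosage_mg_per_kg,
            }
            for r in records
        ],
        columns=PRESCRIPTION_COLUMNS,
    )


def consultations_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "practice_id": r.practice_id,
                "species": r.species.value,
                "year": r.year,
                "n_consultations": r.n_consultations,
            }
            for r in records
        ],
        columns=CONSULTATION_COLUMNS,
    )


def practices_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "practice_id": r.practice_id,
                "declared_type": r.declared_type.value,
                "canton": r.canton,
            }
            for r in records
        ],
        columns=PRACTICE_COLUMNS,
    )


def read_prescriptions_frame(path, catalog) -> tuple[pd.DataFrame, list[RowDiagnostic]]:
    res = read_prescriptions(path, catalog)
    return prescriptions_to_frame(res.records), res.rejects


def read_consultations_frame(path) -> pd.DataFrame:
    return consultations_to_frame(read_consultations(path))


def read_practices_frame(path) -> pd.DataFrame:
    return practices_to_frame(read_practices(path))
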