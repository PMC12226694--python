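"""Bit-stable readers and writers for the tabular record schema.

One row per patient/lesion.  CSV columns, in order:

    id, age_years, laterality, mass_present, peritoneal_disease, fat_present,
    enhancing_component_mm, solid_tissue, t2_dark, dwi_no_restriction,
    enhancement_grade, locularity, fluid_type, wall_enhancement,
    max_diameter_mm, malignant, histology, reader2_class

Booleans are serialized ``true``/``false``, absent optionals as empty fields,
enums lowercase; numbers use "." as the decimal point; encoding is UTF-8.
The JSON-lines mirror uses identical field names with ``null`` for absent
optionals.  Reading is strict: a malformed cell raises :class:`SchemaError`
naming the row and column.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Optional, Sequence, TextIO, Union

from .features import (
    EnhancementGrade,
    FluidType,
    Laterality,
    LesionFeatures,
    Locularity,
    PatientRecord,
)

__all__ = ["SchemaError", "COLUMNS", "read_records", "write_records", "records_to_rows"]


class SchemaError(ValueError):
    """A row violates the record schema; the message names row and column."""


COLUMNS = (
    "id",
    "age_years",
    "laterality",
    "mass_present",
    "peritoneal_disease",
    "fat_present",
    "enhancing_component_mm",
    "solid_tissue",
    "t2_dark",
    "dwi_no_restriction",
    "enhancement_grade",
    "locularity",
    "fluid_type",
    "wall_enhancement",
    "max_diameter_mm",
    "malignant",
    "histology",
    "reader2_class",
)


def _parse_bool(value, row_id: str, column: str, required: bool) -> Optional[bool]:
    if value is None or value == "":
        if required:
            raise SchemaError(f"row {row_id}: column {column}: value required")
        return None
    if isinstance(value, bool):
        return value
    if value == "true":
        return True
    if value == "false":
        return False
    raise SchemaError(
        f"row {row_id}: column {column}: expected true/false, got {value!r}"
    )


def _parse_float(value, row_id: str, column: str) -> Optional[float]:
    if value is None or value == "":
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise SchemaError(
            f"row {row_id}: column {column}: expected a number, got {value!r}"
        ) from None


def _parse_enum(enum_cls, value, row_id: str, column: str):
    if value is None or value == "":
        return None
    try:
        return enum_cls(value)
    except ValueError:
        allowed = ", ".join(e.value for e in enum_cls)
        raise SchemaError(
            f"row {row_id}: column {column}: expected one of [{allowed}], got {value!r}"
        ) from None


def _row_to_record(row: dict, line_no: int) -> PatientRecord:
    row_id = str(row.get("id") or f"<line {line_no}>")
    age = _parse_float(row.get("age_years"), row_id, "age_years")
    if age is None:
        raise SchemaError(f"row {row_id}: column age_years: value required")
    if age < 0:
        raise SchemaError(f"row {row_id}: column age_years: must be >= 0")
    reader2 = _parse_float(row.get("reader2_class"), row_id, "reader2_class")
    if reader2 is not None and (reader2 != int(reader2) or not 1 <= reader2 <= 5):
        raise SchemaError(
            f"row {row_id}: column reader2_class: expected an integer class 1-5"
        )
    features = LesionFeatures(
        mass_present=_parse_bool(row.get("mass_present"), row_id, "mass_present", True),
        peritoneal_disease=bool(
            _parse_bool(row.get("peritoneal_disease"), row_id, "peritoneal_disease", False)
        ),
        fat_present=bool(_parse_bool(row.get("fat_present"), row_id, "fat_present", False)),
        enhancing_component_diameter=_parse_float(
            row.get("enhancing_component_mm"), row_id, "enhancing_component_mm"
        ),
        solid_tissue_present=bool(
            _parse_bool(row.get("solid_tissue"), row_id, "solid_tissue", False)
        ),
        t2_homogeneous_hypointense=_parse_bool(row.get("t2_dark"), row_id, "t2_dark", False),
        dwi_homogeneous_no_restriction=_parse_bool(
            row.get("dwi_no_restriction"), row_id, "dwi_no_restriction", False
        ),
        enhancement_grade=_parse_enum(
            EnhancementGrade, row.get("enhancement_grade"), row_id, "enhancement_grade"
        ),
        locularity=_parse_enum(Locularity, row.get("locularity"), row_id, "locularity"),
        fluid_type=_parse_enum(FluidType, row.get("fluid_type"), row_id, "fluid_type"),
        wall_enhancement=_parse_bool(
            row.get("wall_enhancement"), row_id, "wall_enhancement", False
        ),
        max_diameter=_parse_float(row.get("max_diameter_mm"), row_id, "max_diameter_mm"),
    )
    histology = row.get("histology")
    if histology == "":
        histology = None
    return PatientRecord(
        id=str(row["id"]),
        age=age,
        features=features,
        laterality=_parse_enum(Laterality, row.get("laterality"), row_id, "laterality"),
        malignant=_parse_bool(row.get("malignant"), row_id, "malignant", False),
        histology=histology,
        reader2_class=int(reader2) if reader2 is not None else None,
    )


def _fmt_number(x: Optional[float]) -> str:
    if x is None:
        return ""
    if float(x) == int(x):
        return str(int(x))
    return repr(float(x))


def _record_to_row(r: PatientRecord) -> dict:
    f = r.features

    def b(v: Optional[bool]) -> Optional[str]:
        return None if v is None else ("true" if v else "false")

    return {
        "id": r.id,
        "age_years": _fmt_number(r.age) or None,
        "laterality": r.laterality.value if r.laterality else None,
        "mass_present": b(f.mass_present),
        "peritoneal_disease": b(f.peritoneal_disease) if f.mass_present else None,
        "fat_present": b(f.fat_present) if f.mass_present else None,
        "enhancing_component_mm": _fmt_number(f.enhancing_component_diameter) or None,
        "solid_tissue": b(f.solid_tissue_present) if f.mass_present else None,
        "t2_dark": b(f.t2_homogeneous_hypointense),
        "dwi_no_restriction": b(f.dwi_homogeneous_no_restriction),
        "enhancement_grade": f.enhancement_grade.value if f.enhancement_grade else None,
        "locularity": f.locularity.value if f.locularity else None,
        "fluid_type": f.fluid_type.value if f.fluid_type else None,
        "wall_enhancement": b(f.wall_enhancement),
        "max_diameter_mm": _fmt_number(f.max_diameter) or None,
        "malignant": b(r.malignant),
        "histology": r.histology,
        "reader2_class": str(r.reader2_class) if r.reader2_class is not None else None,
    }


def records_to_rows(
    records: Sequence[PatientRecord], extra: Optional[dict[str, Sequence]] = None
) -> tuple[list[str], list[dict]]:
    """Serialize records to (header, rows); ``extra`` appends named columns."""
    header = list(COLUMNS)
    rows = [_record_to_row(r) for r in records]
    if extra:
        for name, values in extra.items():
            if len(values) != len(rows):
                raise ValueError(f"extra column {name}: length mismatch")
            header.append(name)
            for row, v in zip(rows, values):
                row[name] = "" if v is None else str(v)
    return header, rows


def read_records(path: Union[str, Path]) -> list[PatientRecord]:
    """Read records from CSV (default) or JSON-lines (``.jsonl``/``.ndjson``)."""
    path = Path(path)
    if path.suffix in (".jsonl", ".ndjson"):
        records = []
        with path.open(encoding="utf-8") as fh:
            for line_no, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                obj = json.loads(line)
                records.append(_row_to_record(obj, line_no))
        return records
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError("empty file: a header row is required")
        missing = [c for c in COLUMNS if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"missing columns: {', '.join(missing)}")
        return [_row_to_record(row, i) for i, row in enumerate(reader, start=2)]


def write_records(
    records: Sequence[PatientRecord],
    path_or_fh: Union[str, Path, TextIO],
    extra: Optional[dict[str, Sequence]] = None,
    fmt: Optional[str] = None,
) -> None:
    """Write records as CSV or JSON-lines (chosen by ``fmt`` or suffix)."""
    header, rows = records_to_rows(records, extra)

    def _write(fh: TextIO, kind: str) -> None:
        if kind == "jsonl":
            for row in rows:
                fh.write(json.dumps({k: row.get(k) for k in header}) + "\n")
        else:
            writer = csv.DictWriter(fh, fieldnames=header, lineterminator="\n")
            writer.writeheader()
            for row in rows:
                writer.writerow({k: ("" if row.get(k) is None else row[k]) for k in header})

    if hasattr(path_or_fh, "write"):
        _write(path_or_fh, fmt or "csv")
        return
    path = Path(path_or_fh)
    kind = fmt or ("jsonl" if path.suffix in (".jsonl", ".ndjson") else "csv")
    with path.open("w", newline="", encoding="utf-8") as fh:
        _write(fh, kind)
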