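"""Reading, writing and validating tabular cohort files.

The on-disk dialect is comma-delimited UTF-8 with a header row, one row per
participant.  Tri-state flags serialize as ``1`` / ``0`` / ``NA``; the ANA
titer serializes as its categorical label (``negative``, ``1:80``, ...) or
``NA`` when unknown.  Column order is fixed so that write -> read -> write
is byte-identical.
"""

from __future__ import annotations

import csv
import io
import json
from pathlib import Path
from typing import Mapping, Optional, Union

import yaml

from .records import (
    ANA_TITER_LEVELS,
    FEATURES,
    LN_CLASSES,
    Cohort,
    CohortSchemaError,
    CohortValidationError,
    FeatureSet,
    PatientRecord,
    TriState,
)

#: Serialization order of the cohort file columns.
COLUMNS: tuple[str, ...] = (
    "patient_id", "reference_sle", "sex",
    "age_at_enrollment", "age_at_onset", "disease_duration",
    "ana_titer", "site_id",
    *FEATURES,
    "ln_class", "attribution_exceptions",
)

_MANDATORY = ("patient_id", "reference_sle")


def _fmt_tristate(v: TriState) -> str:
    if v is None:
        return "NA"
    return "1" if v else "0"


def _parse_tristate(cell: str, where: str) -> TriState:
    cell = cell.strip()
    if cell in ("", "NA", "na", "?"):
        return None
    if cell in ("1", "true", "True", "present"):
        return True
    if cell in ("0", "false", "False", "absent"):
        return False
    raise CohortValidationError(f"{where}: cannot parse tri-state cell {cell!r}")


def _fmt_float(x: float) -> str:
    return format(float(x), ".6g")


def write_cohort(cohort: Cohort, path: Union[str, Path]) -> Path:
    """Write a cohort to CSV with the canonical column order."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(COLUMNS)
        for r in cohort.records:
            row = [
                r.patient_id,
                "1" if r.reference_sle else "0",
                r.sex,
                _fmt_float(r.age_at_enrollment),
                _fmt_float(r.age_at_onset),
                _fmt_float(r.disease_duration),
                "NA" if r.ana_titer == "unknown" else r.ana_titer,
                r.site_id or "",
            ]
            row += [_fmt_tristate(r.features.state(f)) for f in FEATURES]
            row.append(r.features.ln_class or "")
            row.append(";".join(sorted(r.features.attribution_exceptions)))
            w.writerow(row)
    return path


def _load_mapping(schema: Union[None, str, Path, Mapping[str, str]]) -> dict[str, str]:
    """Column-mapping config: file header name -> canonical column name."""
    if schema is None:
        return {}
    if isinstance(schema, Mapping):
        return dict(schema)
    text = Path(schema).read_text(encoding="utf-8")
    if str(schema).endswith(".json"):
        return dict(json.loads(text))
    return dict(yaml.safe_load(text))


def read_cohort(path: Union[str, Path],
                schema: Union[None, str, Path, Mapping[str, str]] = None) -> Cohort:
    """Read and validate a cohort CSV.

    Parameters
    ----------
    path
        CSV file with a header row.
    schema
        Optional column mapping (dict or YAML/JSON file) from the file's
        header names to the canonical names in :data:`COLUMNS`; unmapped
        headers are used verbatim.

    Raises
    ------
    CohortSchemaError
        Missing mandatory columns.
    CohortValidationError
        Empty cohort, duplicate ids, or unparsable cells (reported with row
        numbers).
    """
    path = Path(path)
    mapping = _load_mapping(schema)
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise CohortValidationError(f"{path}: empty cohort (no header)")
        header = [mapping.get(h, h) for h in reader.fieldnames]
        missing = [c for c in _MANDATORY if c not in header]
        if missing:
            raise CohortSchemaError(f"{path}: missing mandatory column(s) {missing}")
        rows = list(reader)
    if not rows:
        raise CohortValidationError(f"{path}: empty cohort")

    records: list[PatientRecord] = []
    errors: list[str] = []
    for i, raw in enumerate(rows, start=2):  # data starts on line 2
        row = {mapping.get(k, k): (v if v is not None else "") for k, v in raw.items()}
        where = f"{path.name} row {i}"
        try:
            records.append(_parse_record(row, where))
        except (CohortValidationError, CohortSchemaError, KeyError, ValueError) as exc:
            errors.append(str(exc))
    if errors:
        raise CohortValidationError("malformed rows:\n  " + "\n  ".join(errors))
    return Cohort(records=records, provenance={"source": "file", "path": str(path)})


def _parse_record(row: Mapping[str, str], where: str) -> PatientRecord:
    pid = (row.get("patient_id") or "").strip()
    if not pid:
        raise CohortValidationError(f"{where}: blank patient_id")
    ref = _parse_tristate(row.get("reference_sle", ""), f"{where} reference_sle")
    if ref is None:
        raise CohortValidationError(f"{where}: reference_sle may not be unknown")

    titer = (row.get("ana_titer") or "").strip()
    if titer in ("", "NA", "unknown"):
        titer = "unknown"
    elif titer not in ANA_TITER_LEVELS:
        raise CohortValidationError(f"{where}: unparsable titer string {titer!r} in column ana_titer")

    flags: dict[str, TriState] = {}
    for f in FEATURES:
        flags[f] = _parse_tristate(row.get(f, ""), f"{where} {f}")

    ln_class: Optional[str] = (row.get("ln_class") or "").strip() or None
    if ln_class is not None and ln_class not in LN_CLASSES:
        raise CohortValidationError(f"{where}: invalid ln_class {ln_class!r}")
    exc_cell = (row.get("attribution_exceptions") or "").strip()
    exceptions = frozenset(x for x in exc_cell.split(";") if x)

    def _num(col: str, default: float = 0.0) -> float:
        cell = (row.get(col) or "").strip()
        if cell in ("", "NA"):
            return default
        return float(cell)

    return PatientRecord(
        patient_id=pid,
        reference_sle=bool(ref),
        sex=(row.get("sex") or "female").strip() or "female",
        age_at_enrollment=_num("age_at_enrollment", 30.0),
        age_at_onset=_num("age_at_onset", _num("age_at_enrollment", 30.0)),
        disease_duration=_num("disease_duration"),
        features=FeatureSet(flags=flags, ln_class=ln_class, attribution_exceptions=exceptions),
        ana_titer=titer,
        site_id=(row.get("site_id") or "").strip() or None,
    )


def cohort_to_string(cohort: Cohort) -> str:
    """Serialize a cohort to its CSV text (used for hashing/round-trip checks)."""
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(COLUMNS)
    for r in cohort.records:
        w.writerow([
            r.patient_id, "1" if r.reference_sle else "0", r.sex,
            _fmt_float(r.age_at_enrollment), _fmt_float(r.age_at_onset),
            _fmt_float(r.disease_duration),
            "NA" if r.ana_titer == "unknown" else r.ana_titer,
            r.site_id or "",
            *[_fmt_tristate(r.features.state(f)) for f in FEATURES],
            r.features.ln_class or "",
            ";".join(sorted(r.features.attribution_exceptions)),
        ])
    return buf.getvalue()
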