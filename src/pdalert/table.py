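"""Decision tables: labeled delta records plus CSV input/output.

A decision table (information system) is the training object of the
rough-set machinery: rows are expert-labeled delta records, columns the 21
delta attributes plus the decision.  Rows with identical condition values
but different decisions are allowed — conflicting expert judgment is the
reason rough sets are used here, not a data error.

Deduplication semantics.  Each expert effectively fills in their own
decision table over the same exam pairs, and "repeated entries" are removed
per rater: two rows are duplicates when the same expert produced the same
delta vector with the same decision (which happens when two patient-pairs
have identical score changes).  Rows from different experts are distinct
entries even when they agree.  ``scope="table"`` instead collapses identical
(deltas, decision) rows across all raters.  Contradictory rows — equal
deltas, unequal decisions — are never merged under either scope.
"""
from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .exams import VALID_DECISIONS, DeltaRecord, Provenance, UPDRSExam
from .schema import AttributeSchema


@dataclass(frozen=True)
class DecisionTable:
    """Ordered collection of labeled delta records over one schema."""

    schema: AttributeSchema
    records: tuple[DeltaRecord, ...]

    def __post_init__(self) -> None:
        for rec in self.records:
            if rec.decision is None:
                raise ValidationError("decision-table records must carry a decision")
            rec.validate(self.schema)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def decisions(self) -> tuple[int, ...]:
        return tuple(rec.decision for rec in self.records)

    def value_matrix(self) -> np.ndarray:
        """(n_records, n_attributes) integer array of deltas, schema order."""
        return np.array(
            [rec.values(self.schema) for rec in self.records], dtype=np.int64
        ).reshape(len(self.records), len(self.schema))

    def row_key(self, i: int) -> tuple:
        rec = self.records[i]
        return rec.values(self.schema) + (rec.decision,)


def build_decision_table(
    votes: Iterable[tuple[DeltaRecord, str, int]],
    schema: AttributeSchema,
) -> DecisionTable:
    """Flatten per-(pair, expert) votes into one decision table.

    Each element of ``votes`` is ``(delta_record, expert_id, decision)``.
    Every expert vote becomes its own training row (votes are *not*
    majority-aggregated); conflicting votes on identical delta vectors
    simply make the table inconsistent, which the rough-set layer handles.
    The result is not deduplicated — apply :func:`deduplicate` explicitly.
    """
    records: list[DeltaRecord] = []
    seen: set[tuple] = set()
    for delta, expert_id, decision in votes:
        if decision not in VALID_DECISIONS:
            raise ValidationError(
                f"decision {decision!r} for expert {expert_id!r} not in "
                f"{VALID_DECISIONS}"
            )
        prov = delta.provenance or Provenance()
        key = (prov.patient_id, prov.historical_date, prov.current_date, expert_id)
        if key in seen:
            raise ValidationError(
                f"duplicate vote for pair/expert combination {key}"
            )
        seen.add(key)
        records.append(
            replace(
                delta,
                decision=decision,
                provenance=replace(prov, expert_id=str(expert_id)),
            )
        )
    return DecisionTable(schema=schema, records=tuple(records))


def deduplicate(table: DecisionTable, scope: str = "rater") -> DecisionTable:
    """Remove repeated entries, keeping the first occurrence of each.

    ``scope="rater"`` (default): duplicate = same delta vector, same decision,
    same expert.  ``scope="table"``: duplicate = same delta vector and
    decision, regardless of expert.  Idempotent; never merges rows that
    differ in decision; preserves first-occurrence order.
    """
    if scope not in ("rater", "table"):
        raise ValidationError(f"unknown deduplication scope {scope!r}")
    seen: set[tuple] = set()
    kept: list[DeltaRecord] = []
    for rec in table.records:
        key: tuple = rec.values(table.schema) + (rec.decision,)
        if scope == "rater":
            expert = rec.provenance.expert_id if rec.provenance else None
            key = key + (expert,)
        if key not in seen:
            seen.add(key)
            kept.append(rec)
    return DecisionTable(schema=table.schema, records=tuple(kept))


# ---------------------------------------------------------------------------
# CSV dialects
# ---------------------------------------------------------------------------
# Exams CSV:   patient_id,exam_date,<attribute columns in schema order>
# Table CSV:   <attribute columns>,decision[,patient_id,expert_id,
#              historical_date,current_date]
# All scores/deltas are integers; dates are ISO-8601; UTF-8, comma-separated.

_PROV_COLUMNS = ("patient_id", "expert_id", "historical_date", "current_date")


def _require_int(value, row: int, column: str, low: int, high: int) -> int:
    try:
        as_float = float(value)
        as_int = int(as_float)
        if as_int != as_float:
            raise ValueError
    except (TypeError, ValueError):
        raise ValidationError(
            f"row {row}, column {column!r}: {value!r} is not an integer"
        ) from None
    if not low <= as_int <= high:
        raise ValidationError(
            f"row {row}, column {column!r}: {as_int} outside [{low}, {high}]"
        )
    return as_int


def _parse_date(value, row: int, column: str) -> _dt.date:
    try:
        return _dt.date.fromisoformat(str(value))
    except ValueError:
        raise ValidationError(
            f"row {row}, column {column!r}: {value!r} is not an ISO date"
        ) from None


def read_exams_csv(path, schema: AttributeSchema) -> list[UPDRSExam]:
    """Read clinician examinations; validates scores and the column set."""
    df = pd.read_csv(path, dtype=str)
    required = ["patient_id", "exam_date", *schema.attribute_names]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"exams CSV {path}: missing columns {missing}")
    exams = []
    for i, row in enumerate(df.itertuples(index=False)):
        row = row._asdict()
        scores = {
            a: _require_int(row[a], i, a, 0, 4) for a in schema.attribute_names
        }
        exam = UPDRSExam(
            patient_id=str(row["patient_id"]),
            exam_date=_parse_date(row["exam_date"], i, "exam_date"),
            scores=scores,
        )
        exam.validate(schema)
        exams.append(exam)
    return exams


def write_exams_csv(exams: Sequence[UPDRSExam], path, schema: AttributeSchema) -> None:
    rows = []
    for exam in exams:
        exam.validate(schema)
        row = {"patient_id": exam.patient_id, "exam_date": exam.exam_date.isoformat()}
        row.update({a: exam.scores[a] for a in schema.attribute_names})
        rows.append(row)
    pd.DataFrame(rows, columns=["patient_id", "exam_date", *schema.attribute_names]).to_csv(
        path, index=False
    )


def write_table_csv(table: DecisionTable, path) -> None:
    """Write a decision table; provenance columns appear only if any row has them."""
    schema = table.schema
    has_prov = any(rec.provenance is not None for rec in table.records)
    rows = []
    for rec in table.records:
        row = {a: rec.deltas[a] for a in schema.attribute_names}
        row["decision"] = rec.decision
        if has_prov:
            prov = rec.provenance or Provenance()
            row["patient_id"] = prov.patient_id or ""
            row["expert_id"] = prov.expert_id or ""
            row["historical_date"] = (
                prov.historical_date.isoformat() if prov.historical_date else ""
            )
            row["current_date"] = (
                prov.current_date.isoformat() if prov.current_date else ""
            )
        rows.append(row)
    columns = [*schema.attribute_names, "decision"]
    if has_prov:
        columns += list(_PROV_COLUMNS)
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


def read_table_csv(path, schema: AttributeSchema) -> DecisionTable:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = [*schema.attribute_names, "decision"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"table CSV {path}: missing columns {missing}")
    has_prov = all(c in df.columns for c in _PROV_COLUMNS)
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        row = row._asdict()
        deltas = {
            a: _require_int(row[a], i, a, -4, 4) for a in schema.attribute_names
        }
        decision = _require_int(row["decision"], i, "decision", 0, 2)
        prov: Optional[Provenance] = None
        if has_prov:
            prov = Provenance(
                patient_id=row["patient_id"] or None,
                expert_id=row["expert_id"] or None,
                historical_date=(
                    _parse_date(row["historical_date"], i, "historical_date")
                    if row["historical_date"]
                    else None
                ),
                current_date=(
                    _parse_date(row["current_date"], i, "current_date")
                    if row["current_date"]
                    else None
                ),
            )
        records.append(DeltaRecord(deltas=deltas, decision=decision, provenance=prov))
    return DecisionTable(schema=schema, records=tuple(records))
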