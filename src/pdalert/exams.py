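"""Examinations, score-change records, and expert vote histograms.

An :class:`UPDRSExam` is one clinician-scored motor examination.  The unit
the decision system actually learns from is the *change* between a
historical and a current examination of the same patient: a
:class:`DeltaRecord` holding, per attribute, ``current - historical`` in
UPDRS points, optionally tagged with an expert's deterioration decision
(0 = stable, 1 = warning/slight deterioration, 2 = alarm/severe
deterioration).
"""
from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .errors import SchemaMismatchError, ValidationError
from .schema import AttributeSchema

VALID_SCORES = frozenset(range(5))
VALID_DECISIONS = (0, 1, 2)
DECISION_LABELS = {0: "stable", 1: "warning", 2: "alarm"}


@dataclass(frozen=True)
class UPDRSExam:
    """One motor examination: every schema attribute scored 0-4."""

    patient_id: str
    exam_date: _dt.date
    scores: Mapping[str, int]

    def validate(self, schema: AttributeSchema) -> None:
        missing = [a for a in schema.attribute_names if a not in self.scores]
        extra = [a for a in self.scores if a not in schema.attribute_names]
        if missing or extra:
            raise SchemaMismatchError(
                f"exam {self.patient_id}@{self.exam_date}: "
                f"missing attributes {missing}, unexpected {extra}"
            )
        for attr, score in self.scores.items():
            if not isinstance(score, (int,)) or isinstance(score, bool) or score not in VALID_SCORES:
                raise ValidationError(
                    f"exam {self.patient_id}@{self.exam_date}: score {score!r} for "
                    f"{attr} is not an integer in 0-4"
                )


@dataclass(frozen=True)
class Provenance:
    """Where a delta record came from; all fields optional."""

    patient_id: Optional[str] = None
    expert_id: Optional[str] = None
    historical_date: Optional[_dt.date] = None
    current_date: Optional[_dt.date] = None


@dataclass(frozen=True)
class DeltaRecord:
    """Per-attribute UPDRS change, with an optional expert decision."""

    deltas: Mapping[str, int]
    decision: Optional[int] = None
    provenance: Optional[Provenance] = None

    def __post_init__(self) -> None:
        if self.decision is not None and self.decision not in VALID_DECISIONS:
            raise ValidationError(
                f"decision {self.decision!r} is not in {VALID_DECISIONS}"
            )

    def values(self, schema: AttributeSchema) -> tuple[int, ...]:
        """Delta vector in schema attribute order."""
        return tuple(self.deltas[a] for a in schema.attribute_names)

    def validate(self, schema: AttributeSchema) -> None:
        missing = [a for a in schema.attribute_names if a not in self.deltas]
        extra = [a for a in self.deltas if a not in schema.attribute_names]
        if missing or extra:
            raise SchemaMismatchError(
                f"delta record: missing attributes {missing}, unexpected {extra}"
            )
        for attr, d in self.deltas.items():
            if not isinstance(d, int) or isinstance(d, bool) or not -4 <= d <= 4:
                raise ValidationError(
                    f"delta {d!r} for {attr} is not an integer in [-4, 4]"
                )


def compute_delta(
    historical: UPDRSExam, current: UPDRSExam, schema: AttributeSchema
) -> DeltaRecord:
    """Change vector ``current - historical``, in UPDRS points per attribute.

    Both examinations must conform to ``schema`` and the historical exam must
    not postdate the current one.  The result carries no decision; provenance
    records the patient and both dates.
    """
    historical.validate(schema)
    current.validate(schema)
    if historical.exam_date > current.exam_date:
        raise ValidationError(
            f"historical exam date {historical.exam_date} is after current "
            f"exam date {current.exam_date}"
        )
    deltas = {
        a: current.scores[a] - historical.scores[a] for a in schema.attribute_names
    }
    return DeltaRecord(
        deltas=deltas,
        decision=None,
        provenance=Provenance(
            patient_id=current.patient_id,
            historical_date=historical.exam_date,
            current_date=current.exam_date,
        ),
    )


@dataclass(frozen=True)
class VoteHistogram:
    """Counts of expert votes per decision class for one exam pair."""

    counts: Mapping[int, int]
    n_experts: int


def vote_histogram(votes: Sequence[int]) -> VoteHistogram:
    """Tally a nonempty list of expert decisions into a per-class histogram."""
    if not votes:
        raise ValidationError("vote list must be nonempty")
    bad = [v for v in votes if v not in VALID_DECISIONS]
    if bad:
        raise ValidationError(f"votes {bad} are not in {VALID_DECISIONS}")
    counts = {c: 0 for c in VALID_DECISIONS}
    for v in votes:
        counts[v] += 1
    return VoteHistogram(counts=counts, n_experts=len(votes))
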