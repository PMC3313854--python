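"""Train/test splitting and the three collapsed-class efficiency measures.

Efficiency case 1 is plain 3-class accuracy.  Case 2 merges stable and
warning against alarm and measures how well a *high-priority* alarm is
recognized; case 3 merges warning and alarm against stable and measures how
well *any* alert is recognized.  Collapsing moves error cells onto the
diagonal, so case 2 and case 3 can never fall below case 1.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np

from .classify import ClassificationResult, classify
from .errors import ValidationError
from .rules import RuleSet
from .table import DecisionTable

logger = logging.getLogger(__name__)

CLASSES = (0, 1, 2)


@dataclass(frozen=True)
class ConfusionMatrix:
    """3x3 counts; rows are true classes, columns predicted."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (3, 3) or (counts < 0).any():
            raise ValidationError("confusion matrix must be 3x3 with counts >= 0")
        object.__setattr__(self, "counts", counts)

    @classmethod
    def from_predictions(
        cls, true: Sequence[int], predicted: Sequence[int]
    ) -> "ConfusionMatrix":
        counts = np.zeros((3, 3), dtype=np.int64)
        for t, p in zip(true, predicted, strict=True):
            counts[t, p] += 1
        return cls(counts=counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class EfficiencyReport:
    """The three efficiency percentages, reported to one decimal."""

    case1: float  # 3-class accuracy: {0}, {1}, {2}
    case2: float  # high-priority alarm: {0, 1} vs {2}
    case3: float  # any alert: {0} vs {1, 2}

    @classmethod
    def from_matrix(cls, matrix: ConfusionMatrix) -> "EfficiencyReport":
        c = matrix.counts
        total = matrix.total
        if total == 0:
            raise ValidationError("cannot compute efficiencies of an empty matrix")
        case1 = float(np.trace(c)) / total
        case2 = float(c[:2, :2].sum() + c[2, 2]) / total
        case3 = float(c[0, 0] + c[1:, 1:].sum()) / total
        return cls(
            case1=round(100.0 * case1, 1),
            case2=round(100.0 * case2, 1),
            case3=round(100.0 * case3, 1),
        )

    def as_dict(self) -> dict:
        return {"case1": self.case1, "case2": self.case2, "case3": self.case3}


def split_train_test(
    table: DecisionTable,
    ratio: float = 0.5,
    stratified: bool = True,
    seed: int = 0,
) -> Tuple[DecisionTable, DecisionTable]:
    """Disjoint, exhaustive split; per-class proportions kept within one record.

    Deterministic for a given seed.  Classes with a single record cannot be
    stratified and are sent to the training half with a logged warning.
    """
    if not 0.0 < ratio < 1.0:
        raise ValidationError(f"split ratio must be in (0, 1), got {ratio}")
    n = len(table)
    if n == 0:
        raise ValidationError("cannot split an empty table")
    rng = np.random.default_rng(seed)
    decisions = np.array(table.decisions)
    train_idx: list[int] = []
    if not stratified:
        order = rng.permutation(n)
        train_idx = list(order[: int(round(ratio * n))])
    else:
        target_total = int(round(ratio * n))
        per_class: dict[int, np.ndarray] = {}
        for cls in sorted(set(decisions.tolist())):
            idx = np.flatnonzero(decisions == cls)
            per_class[cls] = rng.permutation(idx)
        quotas = {c: ratio * len(idx) for c, idx in per_class.items()}
        base = {c: int(np.floor(q)) for c, q in quotas.items()}
        forced = [c for c, idx in per_class.items() if len(idx) < 2]
        for c in forced:
            logger.warning(
                "class %d has fewer than 2 records; sending all to training", c
            )
            base[c] = len(per_class[c])
        remainder = target_total - sum(base.values())
        order = sorted(
            (c for c in per_class if c not in forced),
            key=lambda c: (-(quotas[c] - base[c]), c),
        )
        for c in order:
            if remainder <= 0:
                break
            if base[c] < len(per_class[c]):
                base[c] += 1
                remainder -= 1
        for c, idx in per_class.items():
            train_idx.extend(idx[: base[c]])
    train_set = set(int(i) for i in train_idx)
    train_records = tuple(r for i, r in enumerate(table.records) if i in train_set)
    test_records = tuple(r for i, r in enumerate(table.records) if i not in train_set)
    return (
        DecisionTable(schema=table.schema, records=train_records),
        DecisionTable(schema=table.schema, records=test_records),
    )


def evaluate(
    ruleset: RuleSet, table: DecisionTable
) -> Tuple[ConfusionMatrix, EfficiencyReport, Tuple[ClassificationResult, ...]]:
    """Classify every record and compute the confusion matrix and efficiencies."""
    if len(table) == 0:
        raise ValidationError("cannot evaluate on an empty table")
    results = tuple(classify(ruleset, rec) for rec in table.records)
    matrix = ConfusionMatrix.from_predictions(
        table.decisions, [r.predicted for r in results]
    )
    return matrix, EfficiencyReport.from_matrix(matrix), results
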