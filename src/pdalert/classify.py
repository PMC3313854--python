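"""Applying a rule set to new delta records.

Conflict resolution is deliberately conservative in the clinical direction:
when matching rules disagree, classes are weighted by support x confidence;
when no rule matches, the closest rules (highest fraction of satisfied
conditions) vote; any remaining tie goes to the more severe class, so a
borderline case raises an alert rather than silencing one.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Tuple, Union

from .errors import ValidationError
from .exams import DeltaRecord
from .rules import DecisionRule, RuleSet
from .table import DecisionTable


@dataclass(frozen=True)
class ClassificationResult:
    predicted: int
    matched_rules: Tuple[DecisionRule, ...]
    resolution: str  # unique | vote | partial_match | severity_tiebreak


def _weighted_vote(rules: Sequence[DecisionRule]) -> Tuple[int, bool]:
    """(winning class, was_tie) under support x confidence weighting."""
    scores: Dict[int, float] = {}
    for r in rules:
        scores[r.decision] = scores.get(r.decision, 0.0) + r.support * r.confidence
    best = max(scores.values())
    winners = [c for c, s in scores.items() if s == best]
    return max(winners), len(winners) > 1


def classify(
    ruleset: RuleSet, record: Union[DeltaRecord, Dict[str, int]]
) -> ClassificationResult:
    """Assess one delta record with the rule base."""
    if len(ruleset.rules) == 0:
        raise ValidationError("cannot classify with an empty rule set")
    deltas = record.deltas if isinstance(record, DeltaRecord) else record
    matched = tuple(r for r in ruleset.rules if r.matches(deltas))
    if matched:
        classes = {r.decision for r in matched}
        if len(classes) == 1:
            return ClassificationResult(
                predicted=matched[0].decision,
                matched_rules=matched,
                resolution="unique",
            )
        winner, tie = _weighted_vote(matched)
        return ClassificationResult(
            predicted=winner,
            matched_rules=matched,
            resolution="severity_tiebreak" if tie else "vote",
        )
    # partial matching: rules closest to being satisfied vote
    fractions = [(r.match_fraction(deltas), r) for r in ruleset.rules]
    best_fraction = max(f for f, _ in fractions)
    closest = [r for f, r in fractions if f == best_fraction]
    winner, tie = _weighted_vote(closest)
    return ClassificationResult(
        predicted=winner, matched_rules=(), resolution="partial_match"
    )


def nn_baseline(
    train_table: DecisionTable,
    record: Union[DeltaRecord, Dict[str, int]],
    k: int = 1,
) -> int:
    """k-nearest-neighbour sanity baseline (Manhattan distance on deltas).

    Distance ties are resolved toward the lower record index, class ties
    toward the more severe class.
    """
    if len(train_table) == 0:
        raise ValidationError("nearest-neighbour baseline needs a nonempty table")
    deltas = record.deltas if isinstance(record, DeltaRecord) else record
    attrs = train_table.schema.attribute_names
    scored = sorted(
        (
            (sum(abs(deltas[a] - rec.deltas[a]) for a in attrs), idx)
            for idx, rec in enumerate(train_table.records)
        ),
    )
    nearest = scored[: max(1, min(k, len(scored)))]
    counts: Dict[int, int] = {}
    for _, idx in nearest:
        cls = train_table.records[idx].decision
        counts[cls] = counts.get(cls, 0) + 1
    best = max(counts.values())
    return max(c for c, v in counts.items() if v == best)
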