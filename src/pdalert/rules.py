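"""Interval-condition decision rules: plain (RS) and generalized (RS-g).

Rules are conjunctions of open-interval conditions on delta attributes,
e.g. ``IfΔUPDRS13<1&-1<ΔUPDRS14<2&ΔUPDRS23RH<1&ΔUPDRS29<1=>output=1-'warning'``,
exactly the form a neurologist reads off the report.

The RS mode runs a LEM2-style sequential covering per decision class over
the class's lower approximation in the cut-discretized space: grow a
conjunction until everything it covers lies in the lower approximation,
prune redundant conditions, remove what is covered, repeat.  Certain rules
therefore always have confidence 1 on the inducing table.

The RS-g mode is a variable-precision generalization: the covering target
is the β-lower approximation (blocks with ≥ β class purity), and each rule
is afterwards shortened by greedily dropping conditions while its
confidence on the full table stays ≥ β.  Shorter rules match more unseen
records, trading training purity for generalization.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .discretize import CutSet, find_cuts
from .errors import ValidationError
from .exams import DECISION_LABELS
from .schema import AttributeSchema
from .table import DecisionTable

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass(frozen=True)
class Condition:
    """Open integer interval on one attribute; ``None`` bounds mean ±infinity.

    Bounds are exclusive integers, so ``Condition("d14", -1, 2)`` admits the
    delta values {0, 1} and renders as ``-1<ΔUPDRS14<2``.
    """

    attribute: str
    low: Optional[int] = None
    high: Optional[int] = None

    def __post_init__(self) -> None:
        if self.low is not None and self.high is not None and self.high - self.low < 2:
            raise ValidationError(
                f"condition on {self.attribute}: open interval ({self.low}, "
                f"{self.high}) admits no integer"
            )

    def matches(self, value: int) -> bool:
        if self.low is not None and not value > self.low:
            return False
        if self.high is not None and not value < self.high:
            return False
        return True


@dataclass(frozen=True)
class DecisionRule:
    """Conjunction of conditions => decision class, with training support."""

    conditions: Tuple[Condition, ...]
    decision: int
    support: int
    confidence: float

    def __post_init__(self) -> None:
        attrs = [c.attribute for c in self.conditions]
        if len(set(attrs)) != len(attrs):
            raise ValidationError(f"rule has repeated attributes: {attrs}")

    def matches(self, deltas: Dict[str, int]) -> bool:
        return all(c.matches(deltas[c.attribute]) for c in self.conditions)

    def match_fraction(self, deltas: Dict[str, int]) -> float:
        """Fraction of satisfied conditions (1.0 for an unconditional rule)."""
        if not self.conditions:
            return 1.0
        hits = sum(c.matches(deltas[c.attribute]) for c in self.conditions)
        return hits / len(self.conditions)


@dataclass(frozen=True)
class RuleSet:
    """Induced rules plus the induction configuration that produced them."""

    rules: Tuple[DecisionRule, ...]
    induction_mode: str  # "RS" or "RS-g"
    beta: Optional[float] = None
    default_class_policy: str = (
        "weighted vote, partial matching, severity tie-break"
    )

    def __len__(self) -> int:
        return len(self.rules)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "mode": self.induction_mode,
            "beta": self.beta,
            "default_class_policy": self.default_class_policy,
            "rules": [
                {
                    "conditions": [
                        {"attr": c.attribute, "low": c.low, "high": c.high}
                        for c in r.conditions
                    ],
                    "decision": r.decision,
                    "support": r.support,
                    "confidence": r.confidence,
                }
                for r in self.rules
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RuleSet":
        rules = tuple(
            DecisionRule(
                conditions=tuple(
                    Condition(c["attr"], c["low"], c["high"])
                    for c in r["conditions"]
                ),
                decision=int(r["decision"]),
                support=int(r["support"]),
                confidence=float(r["confidence"]),
            )
            for r in data["rules"]
        )
        return cls(
            rules=rules,
            induction_mode=data["mode"],
            beta=data.get("beta"),
            default_class_policy=data.get(
                "default_class_policy",
                "weighted vote, partial matching, severity tie-break",
            ),
        )

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "RuleSet":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Covering
# ---------------------------------------------------------------------------


def _condition_from_interval(
    cuts: CutSet, attribute: str, interval: int
) -> Optional[Condition]:
    low_cut, high_cut = cuts.interval_bounds(attribute, interval)
    if low_cut is None and high_cut is None:
        return None  # unbounded on both sides: no constraint
    low = int(round(low_cut - 0.5)) if low_cut is not None else None
    high = int(round(high_cut + 0.5)) if high_cut is not None else None
    return Condition(attribute=attribute, low=low, high=high)


def _beta_concepts(
    disc: Dict[str, np.ndarray], decisions: np.ndarray, beta: float
) -> Dict[int, np.ndarray]:
    """β-lower approximation mask per class, in the discretized space."""
    n = len(decisions)
    keys = np.stack([disc[a] for a in disc], axis=1)
    _, block_ids = np.unique(keys, axis=0, return_inverse=True)
    concepts = {int(c): np.zeros(n, dtype=bool) for c in np.unique(decisions)}
    for b in np.unique(block_ids):
        members = block_ids == b
        size = int(members.sum())
        for c in concepts:
            purity = int((members & (decisions == c)).sum()) / size
            if purity >= beta - _EPS:
                concepts[c] |= members
    return concepts


def _subset(mask: np.ndarray, of: np.ndarray) -> bool:
    return not bool(np.any(mask & ~of))


def _grow_and_prune(
    disc: Dict[str, np.ndarray],
    concept: np.ndarray,
    n: int,
) -> List[List[Tuple[str, int]]]:
    """LEM2 sequential covering of one concept; returns condition lists."""
    attr_names = sorted(disc)
    goal = concept.copy()
    covers: List[List[Tuple[str, int]]] = []
    while goal.any():
        T: List[Tuple[str, int]] = []
        t_cover = np.ones(n, dtype=bool)
        g_cur = goal.copy()
        while not _subset(t_cover, concept):
            used = {attr for attr, _ in T}
            best = None
            for attr in attr_names:
                if attr in used:
                    continue
                col = disc[attr]
                for interval in np.unique(col[g_cur]):
                    cand_cover = col == interval
                    pos = int(np.count_nonzero(cand_cover & g_cur))
                    if pos == 0:
                        continue
                    neg = int(np.count_nonzero(cand_cover & t_cover & ~concept))
                    key = (-pos, neg, attr, int(interval))
                    if best is None or key < best[0]:
                        best = (key, attr, int(interval), cand_cover)
            if best is None:  # no candidate advances: give up on this goal set
                g_cur = np.zeros(n, dtype=bool)
                break
            _, attr, interval, cand_cover = best
            T.append((attr, interval))
            t_cover &= cand_cover
            g_cur = g_cur & cand_cover
        if not T and not _subset(t_cover, concept):
            break  # defensive: nothing coverable remains
        # prune redundant conditions (in growth order)
        for cond in list(T):
            if len(T) <= 1:
                break
            trial = [c for c in T if c != cond]
            trial_cover = np.ones(n, dtype=bool)
            for a, iv in trial:
                trial_cover &= disc[a] == iv
            if _subset(trial_cover, concept):
                T = trial
                t_cover = trial_cover
        covers.append(T)
        goal &= ~t_cover
    # drop rules made redundant by the rest of the set
    kept = list(covers)
    for cand in list(covers):
        others = [c for c in kept if c is not cand]
        if not others:
            break
        union = np.zeros(n, dtype=bool)
        for T in others:
            cov = np.ones(n, dtype=bool)
            for a, iv in T:
                cov &= disc[a] == iv
            union |= cov
        if _subset(concept, union):
            kept = others
    return kept


def _build_rule(
    table: DecisionTable,
    cuts: CutSet,
    condition_keys: Sequence[Tuple[str, int]],
    decision: int,
) -> DecisionRule:
    conditions = []
    for attr, interval in condition_keys:
        cond = _condition_from_interval(cuts, attr, interval)
        if cond is not None:
            conditions.append(cond)
    support, confidence = rule_stats(table, tuple(conditions), decision)
    return DecisionRule(
        conditions=tuple(conditions),
        decision=decision,
        support=support,
        confidence=confidence,
    )


def rule_stats(
    table: DecisionTable, conditions: Tuple[Condition, ...], decision: int
) -> Tuple[int, float]:
    """(support, confidence) of a conjunction recomputed on the table."""
    matched = [
        rec for rec in table.records if all(c.matches(rec.deltas[c.attribute]) for c in conditions)
    ]
    support = len(matched)
    if support == 0:
        return 0, 0.0
    confidence = sum(rec.decision == decision for rec in matched) / support
    return support, confidence


def induce_rules(
    table: DecisionTable,
    cuts: Optional[CutSet] = None,
    mode: str = "RS",
    beta: float = 0.8,
) -> RuleSet:
    """Induce a rule set from a (deduplicated) decision table.

    ``mode="RS"`` covers each class's classical lower approximation;
    ``mode="RS-g"`` covers the β-lower approximation and then generalizes
    each rule by condition dropping (see :func:`generalize_rules`).
    """
    if mode not in ("RS", "RS-g"):
        raise ValidationError(f"unknown induction mode {mode!r}")
    if mode == "RS-g":
        return generalize_rules(table, cuts=cuts, beta=beta)
    if len(table) == 0:
        raise ValidationError("cannot induce rules from an empty table")
    if cuts is None:
        cuts = find_cuts(table)
    disc = cuts.discretize(table)
    decisions = np.array(table.decisions)
    n = len(table)
    rules: List[DecisionRule] = []
    concepts = _beta_concepts(disc, decisions, beta=1.0)
    for cls in sorted(concepts):
        concept = concepts[cls]
        if not concept.any():
            logger.warning(
                "class %d has an empty lower approximation; no RS rules for it", cls
            )
            continue
        for T in _grow_and_prune(disc, concept, n):
            rules.append(_build_rule(table, cuts, T, cls))
    return RuleSet(rules=tuple(rules), induction_mode="RS", beta=None)


def generalize_rules(
    table: DecisionTable,
    cuts: Optional[CutSet] = None,
    beta: float = 0.8,
) -> RuleSet:
    """Variable-precision (RS-g) induction with confidence-constrained dropping.

    A discretized block belongs to a class's covering target when at least a
    fraction ``beta`` of its records carry that class.  After covering, each
    rule is shortened greedily: at every step the condition whose removal
    leaves the highest table confidence is dropped, as long as that
    confidence stays ≥ ``beta``.  Duplicate rules created by shortening are
    collapsed.
    """
    if not 0.5 < beta <= 1.0:
        raise ValidationError(f"beta must be in (0.5, 1.0], got {beta}")
    if len(table) == 0:
        raise ValidationError("cannot induce rules from an empty table")
    if cuts is None:
        cuts = find_cuts(table)
    disc = cuts.discretize(table)
    decisions = np.array(table.decisions)
    n = len(table)
    rules: List[DecisionRule] = []
    seen: set = set()
    concepts = _beta_concepts(disc, decisions, beta=beta)
    for cls in sorted(concepts):
        concept = concepts[cls]
        if not concept.any():
            logger.warning(
                "class %d has an empty beta-lower approximation (beta=%.2f); "
                "no RS-g rules for it",
                cls,
                beta,
            )
            continue
        for T in _grow_and_prune(disc, concept, n):
            rule = _build_rule(table, cuts, T, cls)
            rule = _shorten_rule(table, rule, beta)
            key = (rule.conditions, rule.decision)
            if key not in seen:
                seen.add(key)
                rules.append(rule)
    return RuleSet(rules=tuple(rules), induction_mode="RS-g", beta=beta)


def _shorten_rule(table: DecisionTable, rule: DecisionRule, beta: float) -> DecisionRule:
    conditions = list(rule.conditions)
    while len(conditions) > 0:
        best_idx, best_stats = None, None
        for idx in range(len(conditions)):
            trial = tuple(c for k, c in enumerate(conditions) if k != idx)
            support, confidence = rule_stats(table, trial, rule.decision)
            if confidence >= beta - _EPS:
                key = (-confidence, -support, idx)
                if best_stats is None or key < best_stats:
                    best_stats = key
                    best_idx = idx
        if best_idx is None:
            break
        del conditions[best_idx]
    support, confidence = rule_stats(table, tuple(conditions), rule.decision)
    return DecisionRule(
        conditions=tuple(conditions),
        decision=rule.decision,
        support=support,
        confidence=confidence,
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _render_condition(cond: Condition, schema: AttributeSchema) -> str:
    name = schema.display_name(cond.attribute)
    if cond.low is not None and cond.high is not None:
        return f"{cond.low}<{name}<{cond.high}"
    if cond.high is not None:
        return f"{name}<{cond.high}"
    return f"{cond.low}<{name}"


def render_rule(rule: DecisionRule, schema: AttributeSchema) -> str:
    """Report-style rendering, e.g. ``IfΔUPDRS23RH<1&ΔUPDRS29<1=>output=1-'warning'``."""
    if rule.conditions:
        antecedent = "&".join(_render_condition(c, schema) for c in rule.conditions)
    else:
        antecedent = "true"
    label = DECISION_LABELS[rule.decision]
    return f"If{antecedent}=>output={rule.decision}-'{label}'"


def render_report(
    ruleset: RuleSet,
    schema: AttributeSchema,
    classification_results: Optional[Sequence] = None,
) -> str:
    """Doctor-readable text report: the rule base, then per-record assessments."""
    lines = [
        "Automatic UPDRS motor-state deterioration assessment",
        f"mode={ruleset.induction_mode}"
        + (f" beta={ruleset.beta}" if ruleset.beta is not None else ""),
        f"{ruleset.induction_mode}--{len(ruleset.rules)} rules",
        "",
        "Rule base:",
    ]
    for rule in ruleset.rules:
        lines.append(
            f"  {render_rule(rule, schema)}  "
            f"[support={rule.support}, confidence={rule.confidence:.3f}]"
        )
    if classification_results:
        lines += ["", "Assessments:"]
        for k, res in enumerate(classification_results):
            label = DECISION_LABELS[res.predicted]
            lines.append(
                f"  record {k}: output={res.predicted}-'{label}' "
                f"({res.resolution}, {len(res.matched_rules)} matching rules)"
            )
    return "\n".join(lines) + "\n"
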