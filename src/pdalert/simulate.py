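"""Synthetic UPDRS cohort: exam pairs, ground-truth labels, noisy experts.

No clinical UPDRS dataset is bundled, so induction and evaluation are
exercised on simulated data with the same statistical shape: integer item
scores 0-4, asymmetric left/right progression (independent per-side
increments), historical/current exam pairs roughly eight months apart, and
a panel of experts whose labels disagree imperfectly and ordinally
(neighbouring severity grades get confused; stable is never confused
directly with alarm).

The default ground-truth labeler scores the positive part of the change on
the high-risk axial symptoms — falling (item 13), freezing of gait (14) and
gait (29) — with weight 2 each, leaving the remaining items unweighted, and
thresholds the sum at 2 (warning) and 4 (alarm).  Clinically this reads:
one point of worsening on any key axial symptom raises a warning; a
two-point jump, or worsening on two key symptoms at once, raises an alarm;
pure improvement is always stable.  The weights and thresholds are
configuration, not a claim about true clinical weighting; this particular
default keeps every class region a union of per-attribute intervals, so an
interval-rule learner can represent the labeler exactly.
"""
from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .classify import classify
from .errors import ValidationError
from .exams import UPDRSExam, compute_delta
from .rules import RuleSet
from .schema import AttributeSchema, default_schema
from .table import DecisionTable, build_decision_table, deduplicate

#: Baseline score distribution over 0..4 (moderate-stage motor cohort).
DEFAULT_BASELINE_PROBS = (0.25, 0.30, 0.25, 0.15, 0.05)
#: Per-item score increment over ~8 months and its distribution: mostly
#: unchanged, worsening biased, occasional one-point improvement.
DEFAULT_INCREMENTS = (-1, 0, 1, 2, 3)
DEFAULT_INCREMENT_PROBS = (0.06, 0.64, 0.20, 0.08, 0.02)

_EPOCH = _dt.date(2010, 3, 1)


@dataclass(frozen=True)
class GroundTruthLabeler:
    """Deterministic delta -> class map: weighted severity score with two thresholds.

    ``score = sum_a weight[a] * max(delta[a], 0)``; class 0 below
    ``warning_threshold``, class 2 at or above ``alarm_threshold``, class 1
    between.  Records in which nothing worsened score 0 and are stable.
    An explicit :class:`RuleSet` can be used instead via
    :meth:`from_ruleset`.
    """

    weights: Dict[str, float] = field(
        default_factory=lambda: {"d13": 2.0, "d14": 2.0, "d29": 2.0}
    )
    warning_threshold: float = 2.0
    alarm_threshold: float = 4.0
    ruleset: Optional[RuleSet] = None

    def __post_init__(self) -> None:
        if not self.warning_threshold <= self.alarm_threshold:
            raise ValidationError("warning threshold must not exceed alarm threshold")

    @classmethod
    def from_ruleset(cls, ruleset: RuleSet) -> "GroundTruthLabeler":
        return cls(weights={}, ruleset=ruleset)

    def __call__(self, deltas: Dict[str, int]) -> int:
        if self.ruleset is not None:
            return classify(self.ruleset, deltas).predicted
        score = sum(w * max(deltas.get(a, 0), 0) for a, w in self.weights.items())
        if score < self.warning_threshold:
            return 0
        if score < self.alarm_threshold:
            return 1
        return 2


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-generation settings; the defaults emulate the study conditions
    of the clinical panel this package models: 74 historical/current exam
    pairs, each labeled by 4 experts."""

    n_pairs: int = 74
    n_experts: int = 4
    expert_noise: float = 0.15
    baseline_probs: Tuple[float, ...] = DEFAULT_BASELINE_PROBS
    increments: Tuple[int, ...] = DEFAULT_INCREMENTS
    increment_probs: Tuple[float, ...] = DEFAULT_INCREMENT_PROBS
    interval_days_low: int = 150
    interval_days_high: int = 340
    labeler: GroundTruthLabeler = field(default_factory=GroundTruthLabeler)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_experts < 1:
            raise ValidationError("need at least one expert")
        if not 0.0 <= self.expert_noise < 0.5:
            raise ValidationError("expert_noise must be in [0, 0.5)")
        for probs in (self.baseline_probs, self.increment_probs):
            if abs(sum(probs) - 1.0) > 1e-9 or any(p < 0 for p in probs):
                raise ValidationError("probabilities must be nonnegative and sum to 1")


def simulate_exam_pairs(
    config: SimulationConfig,
    schema: Optional[AttributeSchema] = None,
    rng: Optional[np.random.Generator] = None,
) -> List[Tuple[UPDRSExam, UPDRSExam]]:
    """Draw historical/current exam pairs.

    Baseline scores are i.i.d. per attribute from ``baseline_probs``;
    current scores add an independently drawn integer increment per
    attribute (so left and right sides progress asymmetrically) and are
    clipped to 0-4.  Exam dates are ~8 months apart with wide jitter.
    """
    schema = schema or default_schema()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n, m = config.n_pairs, len(schema)
    baseline = rng.choice(5, size=(n, m), p=config.baseline_probs)
    increments = rng.choice(
        config.increments, size=(n, m), p=config.increment_probs
    )
    current = np.clip(baseline + increments, 0, 4)
    start_offsets = rng.integers(0, 365, size=n)
    intervals = rng.integers(config.interval_days_low, config.interval_days_high, size=n)
    pairs = []
    for i in range(n):
        pid = f"P{i:03d}"
        hist_date = _EPOCH + _dt.timedelta(days=int(start_offsets[i]))
        curr_date = hist_date + _dt.timedelta(days=int(intervals[i]))
        hist = UPDRSExam(
            patient_id=pid,
            exam_date=hist_date,
            scores={a: int(baseline[i, k]) for k, a in enumerate(schema.attribute_names)},
        )
        curr = UPDRSExam(
            patient_id=pid,
            exam_date=curr_date,
            scores={a: int(current[i, k]) for k, a in enumerate(schema.attribute_names)},
        )
        pairs.append((hist, curr))
    return pairs


def _noisy_vote(true_class: int, noise: float, rng: np.random.Generator) -> int:
    """Ordinal-adjacent rater confusion: 0<->1, 2<->1, 1 -> 0 or 2."""
    if rng.random() >= noise:
        return true_class
    if true_class == 0:
        return 1
    if true_class == 2:
        return 1
    return 0 if rng.random() < 0.5 else 2


def label_with_experts(
    pairs: Sequence[Tuple[UPDRSExam, UPDRSExam]],
    labeler: GroundTruthLabeler,
    n_experts: int = 4,
    expert_noise: float = 0.15,
    seed: Union[int, np.random.Generator] = 0,
    schema: Optional[AttributeSchema] = None,
    dedup: bool = True,
) -> DecisionTable:
    """Label each pair with a panel of noisy experts and flatten the votes.

    Each expert reports the ground-truth class with probability
    ``1 - expert_noise`` and an ordinally adjacent class otherwise.  One
    table row per (pair, expert) vote; repeated per-rater entries are then
    removed unless ``dedup=False``.
    """
    if not 0.0 <= expert_noise < 0.5:
        raise ValidationError("expert_noise must be in [0, 0.5)")
    schema = schema or default_schema()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    votes = []
    for hist, curr in pairs:
        delta = compute_delta(hist, curr, schema)
        true_class = labeler(dict(delta.deltas))
        for e in range(n_experts):
            votes.append((delta, f"E{e + 1}", _noisy_vote(true_class, expert_noise, rng)))
    table = build_decision_table(votes, schema)
    return deduplicate(table, scope="rater") if dedup else table


def sample_labeled_records(
    config: SimulationConfig,
    n_records: int,
    seed: int,
    schema: Optional[AttributeSchema] = None,
) -> DecisionTable:
    """Fresh noise-free ground-truth-labeled delta records (one per pair)."""
    schema = schema or default_schema()
    cfg = replace(config, n_pairs=n_records)
    rng = np.random.default_rng(seed)
    pairs = simulate_exam_pairs(cfg, schema=schema, rng=rng)
    return label_with_experts(
        pairs,
        cfg.labeler,
        n_experts=1,
        expert_noise=0.0,
        seed=rng,
        schema=schema,
        dedup=False,
    )


def panel_cohort_pairs(
    rng: np.random.Generator,
    schema: Optional[AttributeSchema] = None,
    config: Optional[SimulationConfig] = None,
) -> List[Tuple[UPDRSExam, UPDRSExam]]:
    """The 74-pair cohort underlying the bookkeeping fixture.

    71 pairs carry pairwise-distinct delta vectors; the remaining three are
    delta-vector clones of three of them (the same change pattern recurring
    in different patients), appended at the end.
    """
    schema = schema or default_schema()
    config = config or SimulationConfig()
    n_unique = config.n_pairs - 3
    pairs: List[Tuple[UPDRSExam, UPDRSExam]] = []
    seen: set = set()
    while len(pairs) < n_unique:
        batch_cfg = replace(config, n_pairs=n_unique - len(pairs) + 8)
        for hist, curr in simulate_exam_pairs(batch_cfg, schema=schema, rng=rng):
            key = tuple(
                curr.scores[a] - hist.scores[a] for a in schema.attribute_names
            )
            if key in seen or len(pairs) >= n_unique:
                continue
            seen.add(key)
            pairs.append((hist, curr))
    clone_of = rng.choice(n_unique, size=3, replace=False)
    for j, src in enumerate(sorted(int(x) for x in clone_of)):
        hist, curr = pairs[src]
        pid = f"P{n_unique + j:03d}"
        pairs.append(
            (
                UPDRSExam(pid, hist.exam_date, dict(hist.scores)),
                UPDRSExam(pid, curr.exam_date, dict(curr.scores)),
            )
        )
    return pairs


def make_panel_fixture(
    seed: int,
    schema: Optional[AttributeSchema] = None,
    config: Optional[SimulationConfig] = None,
) -> DecisionTable:
    """The bookkeeping fixture: 296 rows that deduplicate to exactly 284.

    74 exam pairs (see :func:`panel_cohort_pairs`) are each labeled by 4
    noise-free experts.  Each of the three clone pairs repeats its
    original's row once per expert, so the table holds exactly 12 repeated
    per-rater entries; :func:`deduplicate` therefore returns 284 records.
    Regeneration from the same seed is byte-identical.
    """
    schema = schema or default_schema()
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    pairs = panel_cohort_pairs(rng, schema=schema, config=config)
    return label_with_experts(
        pairs,
        config.labeler,
        n_experts=config.n_experts,
        expert_noise=0.0,
        seed=rng,
        schema=schema,
        dedup=False,
    )
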