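"""Rough-set machinery over a decision table.

The table's delta values are treated as discrete symbols here.  Records
indiscernible on a chosen attribute subset form the elementary sets of the
approximation space; a decision class is approximated from below (blocks
wholly inside it) and from above (blocks touching it).  The positive region
and its fraction γ quantify how consistently the attributes determine the
expert decision; reducts are minimal attribute subsets preserving that
consistency, computed either exhaustively or with Johnson's greedy heuristic
on the discernibility matrix.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, Tuple

from .errors import ValidationError
from .table import DecisionTable

#: Exhaustive reduct search is refused above this many attributes.
DEFAULT_EXHAUSTIVE_BOUND = 15


@dataclass(frozen=True)
class Partition:
    """Disjoint equivalence classes of record indices; ordered by first member."""

    blocks: tuple[FrozenSet[int], ...]

    def block_of(self) -> Dict[int, int]:
        """Map record index -> block position."""
        out: Dict[int, int] = {}
        for b, block in enumerate(self.blocks):
            for i in block:
                out[i] = b
        return out


@dataclass(frozen=True)
class Approximation:
    """Lower/upper approximation of one decision class."""

    lower: FrozenSet[int]
    upper: FrozenSet[int]
    target_class: int

    @property
    def boundary(self) -> FrozenSet[int]:
        return self.upper - self.lower


@dataclass(frozen=True)
class Reduct:
    """Minimal attribute subset preserving the positive region."""

    attributes: Tuple[str, ...]

    def __contains__(self, attr: str) -> bool:
        return attr in self.attributes


def _rows(table: DecisionTable, attrs: Tuple[str, ...]) -> list[tuple]:
    return [tuple(rec.deltas[a] for a in attrs) for rec in table.records]


def indiscernibility(table: DecisionTable, attrs: Iterable[str]) -> Partition:
    """Partition record indices by equality on ``attrs``."""
    attrs = table.schema.validate_attrs(attrs)
    groups: Dict[tuple, list[int]] = {}
    for i, row in enumerate(_rows(table, attrs)):
        groups.setdefault(row, []).append(i)
    return Partition(blocks=tuple(frozenset(g) for g in groups.values()))


def approximate(
    table: DecisionTable, attrs: Iterable[str], target_class: int
) -> Approximation:
    """Lower/upper approximation of ``target_class`` under ``attrs``."""
    if target_class not in (0, 1, 2):
        raise ValidationError(f"target class {target_class!r} not in (0, 1, 2)")
    part = indiscernibility(table, attrs)
    decisions = table.decisions
    lower: set[int] = set()
    upper: set[int] = set()
    for block in part.blocks:
        in_class = [decisions[i] == target_class for i in block]
        if all(in_class):
            lower.update(block)
        if any(in_class):
            upper.update(block)
    return Approximation(
        lower=frozenset(lower), upper=frozenset(upper), target_class=target_class
    )


def positive_region(table: DecisionTable, attrs: Iterable[str]) -> FrozenSet[int]:
    """Union over classes of the lower approximations: records whose block is pure."""
    part = indiscernibility(table, attrs)
    decisions = table.decisions
    pos: set[int] = set()
    for block in part.blocks:
        classes = {decisions[i] for i in block}
        if len(classes) == 1:
            pos.update(block)
    return frozenset(pos)


def quality_gamma(table: DecisionTable, attrs: Iterable[str]) -> float:
    """Dependency γ = |positive region| / |table|; 1 iff the table is consistent."""
    if len(table) == 0:
        raise ValidationError("gamma undefined on an empty table")
    return len(positive_region(table, attrs)) / len(table)


def discernibility_matrix(
    table: DecisionTable,
) -> Dict[Tuple[int, int], FrozenSet[str]]:
    """Attributes separating each decision-differing record pair.

    Entries exist only for pairs ``i < j`` with different decisions; an empty
    entry marks a contradictory pair (indiscernible but differently labeled),
    which is unsatisfiable and skipped by reduct search.
    """
    attrs = table.schema.attribute_names
    rows = _rows(table, attrs)
    decisions = table.decisions
    matrix: Dict[Tuple[int, int], FrozenSet[str]] = {}
    n = len(table)
    for i in range(n):
        for j in range(i + 1, n):
            if decisions[i] != decisions[j]:
                matrix[(i, j)] = frozenset(
                    a for a, vi, vj in zip(attrs, rows[i], rows[j]) if vi != vj
                )
    return matrix


def find_reducts(
    table: DecisionTable,
    max_attributes: int = DEFAULT_EXHAUSTIVE_BOUND,
) -> list[Reduct]:
    """All reducts by exhaustive subset search (small attribute counts only).

    Enumerates attribute subsets in increasing size and keeps those matching
    the full-set γ while containing no smaller kept subset.  Refused above
    ``max_attributes`` attributes; use :func:`greedy_reduct` instead there.
    """
    attrs = table.schema.attribute_names
    if len(attrs) > max_attributes:
        raise ValidationError(
            f"exhaustive reduct search refused for {len(attrs)} > "
            f"{max_attributes} attributes; use greedy_reduct"
        )
    full_gamma = quality_gamma(table, attrs)
    reducts: list[Reduct] = []
    found_sets: list[frozenset] = []
    for size in range(1, len(attrs) + 1):
        for subset in itertools.combinations(attrs, size):
            sset = frozenset(subset)
            if any(f <= sset for f in found_sets):
                continue  # a smaller reduct is contained: not minimal
            if quality_gamma(table, subset) == full_gamma:
                reducts.append(Reduct(attributes=subset))
                found_sets.append(sset)
    return reducts


def greedy_reduct(table: DecisionTable) -> Reduct:
    """One reduct via Johnson's heuristic on the discernibility matrix.

    Repeatedly picks the attribute covering the most still-uncovered
    nonempty matrix entries (ties broken lexicographically), then prunes
    attributes whose removal keeps γ at the full-set value.  The result
    preserves γ and is minimal under single-attribute removal.
    """
    attrs = table.schema.attribute_names
    entries = [e for e in discernibility_matrix(table).values() if e]
    chosen: list[str] = []
    uncovered = entries
    while uncovered:
        counts = {a: 0 for a in attrs}
        for entry in uncovered:
            for a in entry:
                counts[a] += 1
        best = min(counts, key=lambda a: (-counts[a], a))
        if counts[best] == 0:  # cannot happen: entries are nonempty
            break
        chosen.append(best)
        uncovered = [e for e in uncovered if best not in e]
    full_gamma = quality_gamma(table, attrs)
    kept = list(chosen) if chosen else [attrs[0]]
    for a in sorted(kept):
        if len(kept) == 1:
            break
        trial = [x for x in kept if x != a]
        if quality_gamma(table, trial) == full_gamma:
            kept = trial
    kept_in_order = tuple(a for a in attrs if a in kept)
    return Reduct(attributes=kept_in_order)


def core(
    table: DecisionTable, max_attributes: int = DEFAULT_EXHAUSTIVE_BOUND
) -> Tuple[str, ...]:
    """Intersection of all reducts; provided for completeness.

    Computed exactly from the exhaustive reducts when the attribute count
    permits; above the bound it falls back to the singleton entries of the
    discernibility matrix (exact on consistent tables).
    """
    if len(table.schema.attribute_names) <= max_attributes:
        reducts = find_reducts(table, max_attributes=max_attributes)
        common = set(table.schema.attribute_names)
        for r in reducts:
            common &= set(r.attributes)
        return tuple(a for a in table.schema.attribute_names if a in common)
    singles: set[str] = set()
    for entry in discernibility_matrix(table).values():
        if len(entry) == 1:
            singles.update(entry)
    return tuple(a for a in table.schema.attribute_names if a in singles)


def inconsistency_report(table: DecisionTable) -> dict:
    """Contradictory record groups and per-class boundary sizes, as plain data."""
    attrs = table.schema.attribute_names
    part = indiscernibility(table, attrs)
    decisions = table.decisions
    conflicts = []
    for block in part.blocks:
        classes = sorted({decisions[i] for i in block})
        if len(classes) > 1:
            conflicts.append(
                {"records": sorted(block), "decisions": classes}
            )
    boundaries = {}
    for cls in sorted(set(decisions)):
        approx = approximate(table, attrs, cls)
        boundaries[cls] = len(approx.boundary)
    return {
        "n_records": len(table),
        "gamma": quality_gamma(table, attrs),
        "contradictory_groups": conflicts,
        "boundary_sizes": boundaries,
    }
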