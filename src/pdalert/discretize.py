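"""Interval cuts on delta attributes (Boolean-reasoning MD heuristic).

Decision rules are rendered with strict inequalities over integer UPDRS
changes ("-1<ΔUPDRS14<2"), so the induction step first discretizes each
attribute with half-integer cut points.  Candidate cuts sit between
consecutive observed values; the retained set is chosen greedily to discern
the most decision-differing record pairs per step, until every pair that the
raw integers can discern is discerned.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

from .table import DecisionTable


@dataclass(frozen=True)
class Cut:
    """A half-integer threshold on one delta attribute (units: UPDRS change)."""

    attribute: str
    threshold: float


@dataclass(frozen=True)
class CutSet:
    """Retained cuts, grouped per attribute, with interval arithmetic."""

    cuts: Tuple[Cut, ...]

    def thresholds(self, attribute: str) -> Tuple[float, ...]:
        return tuple(
            sorted(c.threshold for c in self.cuts if c.attribute == attribute)
        )

    def interval_index(self, attribute: str, value: int) -> int:
        """Index of the open interval (between consecutive cuts) containing value."""
        ths = self.thresholds(attribute)
        return int(np.searchsorted(ths, value))

    def interval_bounds(
        self, attribute: str, index: int
    ) -> Tuple[float | None, float | None]:
        """(low, high) cut thresholds of an interval; None marks ±infinity."""
        ths = self.thresholds(attribute)
        low = ths[index - 1] if index > 0 else None
        high = ths[index] if index < len(ths) else None
        return low, high

    def discretize(self, table: DecisionTable) -> Dict[str, np.ndarray]:
        """Per attribute, the interval index of every record's delta."""
        values = table.value_matrix()
        out: Dict[str, np.ndarray] = {}
        for k, attr in enumerate(table.schema.attribute_names):
            ths = np.array(self.thresholds(attr), dtype=float)
            out[attr] = np.searchsorted(ths, values[:, k]).astype(np.int64)
        return out


def _entropy(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def _mdl_thresholds(values: np.ndarray, decisions: np.ndarray) -> List[float]:
    """Fayyad-Irani recursive entropy discretization of one attribute.

    Splits at the half-integer boundary with maximal information gain and
    accepts a split only when the gain clears the minimum-description-length
    criterion; recursion continues on both halves.  Attributes whose class
    distribution does not depend on the value receive no thresholds.
    """
    classes = np.unique(decisions)
    cmap = {c: k for k, c in enumerate(classes)}
    labels = np.array([cmap[d] for d in decisions])
    n_classes = len(classes)

    def class_counts(mask: np.ndarray) -> np.ndarray:
        return np.bincount(labels[mask], minlength=n_classes)

    accepted: List[float] = []
    stack = [np.ones(len(values), dtype=bool)]
    while stack:
        mask = stack.pop()
        vals = values[mask]
        n = int(mask.sum())
        if n < 2:
            continue
        observed = np.unique(vals)
        if len(observed) < 2:
            continue
        parent_counts = class_counts(mask)
        h_parent = _entropy(parent_counts)
        best = None
        for lo in observed[:-1]:
            thr = float(lo) + 0.5
            left = mask & (values <= lo)
            right = mask & ~(values <= lo)
            lc, rc = class_counts(left), class_counts(right)
            nl, nr = lc.sum(), rc.sum()
            h_split = (nl * _entropy(lc) + nr * _entropy(rc)) / n
            gain = h_parent - h_split
            key = (-gain, thr)
            if best is None or key < best[0]:
                best = (key, thr, left, right, lc, rc)
        if best is None:
            continue
        (neg_gain, _), thr, left, right, lc, rc = best
        gain = -neg_gain
        k = int((parent_counts > 0).sum())
        k1 = int((lc > 0).sum())
        k2 = int((rc > 0).sum())
        delta = (
            np.log2(3**k - 2)
            - (k * h_parent - k1 * _entropy(lc) - k2 * _entropy(rc))
        )
        if gain > (np.log2(n - 1) + delta) / n:
            accepted.append(thr)
            stack.append(left)
            stack.append(right)
    return sorted(accepted)


def find_cuts(table: DecisionTable) -> CutSet:
    """Supervised cut selection: MDL-filtered candidates, then greedy discernment.

    Candidates are ``v + 0.5`` for every observed value ``v`` with a larger
    observed successor, per attribute.  Candidates that pass the per-attribute
    Fayyad-Irani MDL criterion (a real marginal association between the
    attribute and the decision) are preferred: the greedy step retains the
    preferred candidate newly discerning the most decision-differing pairs
    (ties: attribute name, then threshold).  When the preferred pool is
    exhausted but discernible pairs remain — typical of noisy, inconsistent
    tables — selection continues greedily over all remaining candidates, so
    every pair the raw integers discern ends up discerned.  A final
    elimination pass drops cuts (newest first) that the rest of the set makes
    redundant.  Constant attributes contribute no cuts.
    """
    if len(table) == 0:
        raise ValueError("cannot derive cuts from an empty table")
    attrs = table.schema.attribute_names
    values = table.value_matrix()
    decisions = np.array(table.decisions)

    # Decision-differing pairs that differ on at least one attribute.
    n = len(table)
    ii, jj = np.triu_indices(n, k=1)
    differ_dec = decisions[ii] != decisions[jj]
    differ_val = (values[ii] != values[jj]).any(axis=1)
    mask = differ_dec & differ_val
    ii, jj = ii[mask], jj[mask]

    candidates: List[Tuple[str, float, np.ndarray]] = []
    for k, attr in enumerate(attrs):
        observed = np.unique(values[:, k])
        for lo in observed[:-1]:  # every observed value with a larger successor
            threshold = float(lo) + 0.5
            below = values[:, k] <= lo
            discerns = below[ii] != below[jj]
            candidates.append((attr, threshold, discerns))

    preferred: set = set()
    for k, attr in enumerate(attrs):
        for thr in _mdl_thresholds(values[:, k], decisions):
            preferred.add((attr, thr))

    retained: List[Tuple[Cut, np.ndarray]] = []
    uncovered = np.ones(len(ii), dtype=bool)
    for pool in (
        [c for c in candidates if (c[0], c[1]) in preferred],
        candidates,
    ):
        while uncovered.any():
            best = None
            for attr, threshold, discerns in pool:
                gain = int(np.count_nonzero(discerns & uncovered))
                key = (-gain, attr, threshold)
                if gain > 0 and (best is None or key < best[0]):
                    best = (key, attr, threshold, discerns)
            if best is None:
                break  # pool exhausted; remaining pairs fall to the next pool
            _, attr, threshold, discerns = best
            retained.append((Cut(attribute=attr, threshold=threshold), discerns))
            uncovered &= ~discerns
    # redundancy elimination, newest first
    for cut, _ in reversed(list(retained)):
        others = [d for c, d in retained if c is not cut]
        covered = np.zeros(len(ii), dtype=bool)
        for d in others:
            covered |= d
        if covered.all():
            retained = [(c, d) for c, d in retained if c is not cut]
    return CutSet(cuts=tuple(c for c, _ in retained))
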