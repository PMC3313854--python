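"""Literal set-comprehension implementations of the rough-set definitions.

Independent oracle for the package's rough-set layer: everything here works
on plain value tuples and is written directly from the definitions, with no
shared code with the implementation under test.
"""
from itertools import combinations


def blocks(rows, attr_idx):
    """Equivalence classes of row indices under equality on attr_idx."""
    keys = {}
    for i, row in enumerate(rows):
        keys.setdefault(tuple(row[k] for k in attr_idx), set()).add(i)
    return set(frozenset(b) for b in keys.values())


def lower_upper(rows, decisions, attr_idx, target):
    lower = {
        i
        for b in blocks(rows, attr_idx)
        for i in b
        if all(decisions[j] == target for j in b)
    }
    upper = {
        i
        for b in blocks(rows, attr_idx)
        for i in b
        if any(decisions[j] == target for j in b)
    }
    return lower, upper


def positive_region(rows, decisions, attr_idx):
    return {
        i
        for target in set(decisions)
        for i in lower_upper(rows, decisions, attr_idx, target)[0]
    }


def gamma(rows, decisions, attr_idx):
    return len(positive_region(rows, decisions, attr_idx)) / len(rows)


def all_reducts(rows, decisions, n_attrs):
    """Every minimal attribute-index subset preserving the full-set gamma."""
    full = gamma(rows, decisions, tuple(range(n_attrs)))
    preserving = [
        subset
        for size in range(1, n_attrs + 1)
        for subset in combinations(range(n_attrs), size)
        if gamma(rows, decisions, subset) == full
    ]
    return [
        set(s)
        for s in preserving
        if not any(set(t) < set(s) for t in preserving)
    ]
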