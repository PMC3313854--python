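import numpy as np
import pytest

from pdalert import (
    AttributeSchema,
    DecisionTable,
    DeltaRecord,
    ItemSpec,
    default_schema,
)

_NONE_ITEMS = (13, 14, 28, 29, 31, 32, 39)


@pytest.fixture(scope="session")
def schema():
    return default_schema()


def mini_schema(n_attrs: int) -> AttributeSchema:
    """A small schema with n_attrs attributes (1..9), for oracle-sized tables."""
    if n_attrs <= len(_NONE_ITEMS):
        items = tuple(ItemSpec(i) for i in _NONE_ITEMS[:n_attrs])
    else:
        items = tuple(ItemSpec(i) for i in _NONE_ITEMS[: n_attrs - 2]) + (
            ItemSpec(23, "hands"),
        )
    return AttributeSchema(items=items)


def random_table(
    rng: np.random.Generator,
    n_attrs: int,
    n_records: int,
    low: int = -2,
    high: int = 3,
) -> DecisionTable:
    """Random decision table; repeated delta vectors (hence inconsistency) allowed."""
    schema_ = mini_schema(n_attrs)
    values = rng.integers(low, high + 1, size=(n_records, n_attrs))
    decisions = rng.integers(0, 3, size=n_records)
    records = tuple(
        DeltaRecord(
            deltas={a: int(values[i, k]) for k, a in enumerate(schema_.attribute_names)},
            decision=int(decisions[i]),
        )
        for i in range(n_records)
    )
    return DecisionTable(schema=schema_, records=records)


def table_from_rows(rows, decisions, n_attrs: int) -> DecisionTable:
    """Build a table from explicit value tuples (test-case construction helper)."""
    schema_ = mini_schema(n_attrs)
    records = tuple(
        DeltaRecord(
            deltas={a: int(row[k]) for k, a in enumerate(schema_.attribute_names)},
            decision=int(dec),
        )
        for row, dec in zip(rows, decisions)
    )
    return DecisionTable(schema=schema_, records=records)
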