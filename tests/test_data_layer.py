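import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pdalert import (
    DecisionTable,
    DeltaRecord,
    Provenance,
    SchemaMismatchError,
    UPDRSExam,
    ValidationError,
    build_decision_table,
    compute_delta,
    deduplicate,
    read_exams_csv,
    read_table_csv,
    vote_histogram,
    write_exams_csv,
    write_table_csv,
)
from conftest import mini_schema, random_table

D1 = dt.date(2010, 1, 1)
D2 = dt.date(2010, 9, 1)


def make_exam(schema, patient="P1", date=D1, **overrides):
    scores = {a: 0 for a in schema.attribute_names}
    scores.update(overrides)
    return UPDRSExam(patient_id=patient, exam_date=date, scores=scores)


class TestComputeDelta:
    def test_identical_exams_give_zero_deltas(self, schema):
        a = make_exam(schema)
        b = make_exam(schema, date=D2)
        delta = compute_delta(a, b, schema)
        assert all(v == 0 for v in delta.deltas.values())
        assert delta.decision is None
        assert delta.provenance.historical_date == D1
        assert delta.provenance.current_date == D2

    def test_single_item_worsening(self, schema):
        hist = make_exam(schema, d23RH=1)
        curr = make_exam(schema, date=D2, d23RH=3)
        delta = compute_delta(hist, curr, schema)
        assert delta.deltas["d23RH"] == 2
        assert all(v == 0 for a, v in delta.deltas.items() if a != "d23RH")

    @settings(deadline=None, max_examples=30)
    @given(data=st.data())
    def test_antisymmetry(self, schema, data):
        s1 = {a: data.draw(st.integers(0, 4)) for a in schema.attribute_names}
        s2 = {a: data.draw(st.integers(0, 4)) for a in schema.attribute_names}
        a = UPDRSExam("P", D1, s1)
        b = UPDRSExam("P", D1, s2)
        fwd = compute_delta(a, b, schema)
        back = compute_delta(b, a, schema)
        assert all(fwd.deltas[k] == -back.deltas[k] for k in fwd.deltas)

    def test_date_order_violation_rejected(self, schema):
        with pytest.raises(ValidationError):
            compute_delta(make_exam(schema, date=D2), make_exam(schema, date=D1), schema)

    def test_schema_mismatch_rejected(self, schema):
        small = mini_schema(3)
        with pytest.raises(SchemaMismatchError):
            compute_delta(make_exam(small), make_exam(schema, date=D2), schema)

    def test_out_of_range_score_rejected(self, schema):
        bad = make_exam(schema, d13=5)
        with pytest.raises(ValidationError):
            compute_delta(bad, make_exam(schema, date=D2), schema)


def _vote(schema, deltas, expert, decision, patient="P1"):
    rec = DeltaRecord(
        deltas={a: deltas.get(a, 0) for a in schema.attribute_names},
        provenance=Provenance(patient_id=patient, historical_date=D1, current_date=D2),
    )
    return (rec, expert, decision)


class TestBuildAndDeduplicate:
    def test_votes_flatten_one_row_per_pair_expert(self, schema):
        votes = [
            _vote(schema, {"d13": 1}, f"E{e}", 1, patient=f"P{p}")
            for p in range(5)
            for e in range(4)
        ]
        table = build_decision_table(votes, schema)
        assert len(table) == 20
        assert {r.provenance.expert_id for r in table.records} == {"E0", "E1", "E2", "E3"}

    def test_duplicate_pair_expert_combination_rejected(self, schema):
        votes = [_vote(schema, {}, "E1", 0), _vote(schema, {}, "E1", 1)]
        with pytest.raises(ValidationError):
            build_decision_table(votes, schema)

    def test_invalid_decision_rejected(self, schema):
        with pytest.raises(ValidationError):
            build_decision_table([_vote(schema, {}, "E1", 7)], schema)

    def test_unanimous_votes_collapse_under_table_scope(self, schema):
        table = build_decision_table(
            [_vote(schema, {}, f"E{e}", 0) for e in range(4)], schema
        )
        assert len(deduplicate(table, scope="table")) == 1
        # per-rater scope keeps one entry per expert
        assert len(deduplicate(table, scope="rater")) == 4

    def test_contradictory_rows_are_never_merged(self, schema):
        votes = [
            _vote(schema, {"d29": 1}, "E1", 0, patient="P1"),
            _vote(schema, {"d29": 1}, "E1", 1, patient="P2"),
        ]
        table = build_decision_table(votes, schema)
        for scope in ("rater", "table"):
            assert len(deduplicate(table, scope=scope)) == 2

    def test_rater_scope_removes_repeated_entries_of_one_expert(self, schema):
        votes = [
            _vote(schema, {"d29": 1}, "E1", 1, patient="P1"),
            _vote(schema, {"d29": 1}, "E1", 1, patient="P2"),  # same expert, same row
        ]
        table = build_decision_table(votes, schema)
        assert len(deduplicate(table)) == 1

    @pytest.mark.parametrize("scope", ["rater", "table"])
    def test_idempotent_and_order_preserving(self, scope):
        rng_table = random_table(np.random.default_rng(5), 3, 30, 0, 1)
        once = deduplicate(rng_table, scope=scope)
        twice = deduplicate(once, scope=scope)
        assert once == twice
        # set of distinct (deltas, decision) rows is preserved
        key = lambda t: {t.row_key(i) for i in range(len(t))}
        assert key(once) == key(rng_table)
        # first occurrences keep their relative order
        order = [rng_table.records.index(r) for r in once.records]
        assert order == sorted(order)

    def test_all_distinct_table_unchanged(self):
        table = random_table(np.random.default_rng(0), 4, 15, -2, 3)
        distinct = len({table.row_key(i) for i in range(len(table))})
        if distinct == len(table):
            assert deduplicate(table, scope="table") == table


class TestVoteHistogram:
    @pytest.mark.parametrize(
        "votes,expected",
        [
            ([0, 0, 0, 0], {0: 4, 1: 0, 2: 0}),
            ([0, 1, 1, 2], {0: 1, 1: 2, 2: 1}),
            ([2, 2, 2, 2], {0: 0, 1: 0, 2: 4}),
        ],
    )
    def test_counting(self, votes, expected):
        hist = vote_histogram(votes)
        assert dict(hist.counts) == expected
        assert hist.n_experts == len(votes)
        assert sum(hist.counts.values()) == hist.n_experts

    def test_empty_votes_rejected(self):
        with pytest.raises(ValidationError):
            vote_histogram([])

    def test_invalid_vote_rejected(self):
        with pytest.raises(ValidationError):
            vote_histogram([0, 3])


class TestCsvRoundTrips:
    def test_exams_round_trip(self, schema, tmp_path):
        exams = [
            make_exam(schema, patient="P1", d13=2, d29=1),
            make_exam(schema, patient="P2", date=D2, d23RH=4),
        ]
        path = tmp_path / "exams.csv"
        write_exams_csv(exams, path, schema)
        assert read_exams_csv(path, schema) == exams

    @settings(deadline=None, max_examples=15)
    @given(data=st.data())
    def test_table_round_trip_random(self, data, tmp_path_factory):
        n_attrs = data.draw(st.integers(1, 6))
        n_records = data.draw(st.integers(1, 12))
        seed = data.draw(st.integers(0, 10_000))
        table = random_table(np.random.default_rng(seed), n_attrs, n_records)
        path = tmp_path_factory.mktemp("csv") / "t.csv"
        write_table_csv(table, path)
        assert read_table_csv(path, table.schema) == table

    def test_table_round_trip_with_provenance(self, schema, tmp_path):
        rec = DeltaRecord(
            deltas={a: 0 for a in schema.attribute_names},
            decision=1,
            provenance=Provenance("P1", "E2", D1, D2),
        )
        table = DecisionTable(schema=schema, records=(rec,))
        path = tmp_path / "t.csv"
        write_table_csv(table, path)
        assert read_table_csv(path, schema) == table

    def test_out_of_range_score_names_row_and_column(self, schema, tmp_path):
        exams = [make_exam(schema)]
        path = tmp_path / "exams.csv"
        write_exams_csv(exams, path, schema)
        text = path.read_text().replace("2010-01-01,0", "2010-01-01,5", 1)
        path.write_text(text)
        with pytest.raises(ValidationError, match=r"row 0.*d13"):
            read_exams_csv(path, schema)

    def test_missing_schema_column_rejected(self, schema, tmp_path):
        exams = [make_exam(schema)]
        path = tmp_path / "exams.csv"
        write_exams_csv(exams, path, schema)
        lines = path.read_text().splitlines()
        lines[0] = lines[0].replace("d13,", "")
        lines[1] = lines[1].replace("P1,2010-01-01,0,", "P1,2010-01-01,", 1)
        path.write_text("\n".join(lines))
        with pytest.raises(ValidationError, match="missing columns"):
            read_exams_csv(path, schema)

    def test_non_integer_delta_rejected(self, schema, tmp_path):
        rec = DeltaRecord(deltas={a: 0 for a in schema.attribute_names}, decision=0)
        table = DecisionTable(schema=schema, records=(rec,))
        path = tmp_path / "t.csv"
        write_table_csv(table, path)
        path.write_text(path.read_text().replace("\n0,0", "\nx,0", 1))
        with pytest.raises(ValidationError, match="not an integer"):
            read_table_csv(path, schema)
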