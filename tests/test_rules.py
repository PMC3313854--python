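import numpy as np
import pytest

from conftest import random_table, table_from_rows
from pdalert import (
    Condition,
    DecisionRule,
    RuleSet,
    ValidationError,
    classify,
    find_cuts,
    generalize_rules,
    induce_rules,
    positive_region,
    render_rule,
    rule_stats,
)
from pdalert.rules import _beta_concepts


def reference_rule():
    """The report-style rule used as the rendering reference."""
    return DecisionRule(
        conditions=(
            Condition("d13", None, 1),
            Condition("d14", -1, 2),
            Condition("d23RH", None, 1),
            Condition("d29", None, 1),
        ),
        decision=1,
        support=1,
        confidence=1.0,
    )


class TestRendering:
    def test_interval_rule_renders_with_strict_inequalities(self, schema):
        assert render_rule(reference_rule(), schema) == (
            "IfΔUPDRS13<1&-1<ΔUPDRS14<2&ΔUPDRS23RH<1&ΔUPDRS29<1=>output=1-'warning'"
        )

    def test_unconditional_rule_renders_true_antecedent(self, schema):
        rule = DecisionRule(conditions=(), decision=0, support=3, confidence=1.0)
        assert render_rule(rule, schema) == "Iftrue=>output=0-'stable'"

    def test_lower_bound_only_condition(self, schema):
        rule = DecisionRule(
            conditions=(Condition("d29", 0, None),), decision=2, support=1,
            confidence=1.0,
        )
        assert render_rule(rule, schema) == "If0<ΔUPDRS29=>output=2-'alarm'"

    @pytest.mark.parametrize("seed", range(5))
    def test_render_is_injective_over_an_induced_set(self, seed):
        rng = np.random.default_rng(400 + seed)
        table = random_table(rng, 3, 25, 0, 2)
        ruleset = induce_rules(table)
        rendered = {render_rule(r, table.schema) for r in ruleset.rules}
        assert len(rendered) == len(ruleset.rules)


class TestConditions:
    def test_empty_interval_rejected(self):
        with pytest.raises(ValidationError):
            Condition("d13", 0, 1)

    def test_repeated_attribute_in_rule_rejected(self):
        with pytest.raises(ValidationError):
            DecisionRule(
                conditions=(Condition("d13", None, 1), Condition("d13", 0, None)),
                decision=0,
                support=1,
                confidence=1.0,
            )


class TestInduceRS:
    def test_single_attribute_threshold_concept(self):
        table = table_from_rows([(0,), (0,), (1,), (2,)], [0, 0, 1, 1], 1)
        ruleset = induce_rules(table)
        attr = table.schema.attribute_names[0]
        by_class = {r.decision: r for r in ruleset.rules}
        assert by_class[1].conditions == (Condition(attr, 0, None),)
        assert by_class[0].conditions == (Condition(attr, None, 1),)
        assert all(r.confidence == 1.0 for r in ruleset.rules)

    def test_single_class_table_gives_one_unconditional_rule(self, schema):
        table = table_from_rows([(0, 1), (1, 0), (2, 2)], [1, 1, 1], 2)
        ruleset = induce_rules(table)
        assert len(ruleset.rules) == 1
        assert ruleset.rules[0].conditions == ()
        assert ruleset.rules[0].decision == 1
        assert ruleset.rules[0].support == 3

    @pytest.mark.parametrize("seed", range(6))
    def test_rs_rules_are_certain_and_cover_the_positive_region(self, seed):
        rng = np.random.default_rng(500 + seed)
        table = random_table(rng, int(rng.integers(2, 5)), int(rng.integers(8, 40)), 0, 2)
        ruleset = induce_rules(table)
        assert all(r.confidence == 1.0 for r in ruleset.rules)
        pos = positive_region(table, table.schema.attribute_names)
        for i in pos:
            rec = table.records[i]
            assert any(
                r.decision == rec.decision and r.matches(rec.deltas)
                for r in ruleset.rules
            ), i

    @pytest.mark.parametrize("seed", range(4))
    def test_stored_support_and_confidence_match_a_recount(self, seed):
        rng = np.random.default_rng(600 + seed)
        table = random_table(rng, 3, 30, 0, 2)
        for ruleset in (induce_rules(table), generalize_rules(table, beta=0.8)):
            for rule in ruleset.rules:
                matched = [
                    rec
                    for rec in table.records
                    if all(c.matches(rec.deltas[c.attribute]) for c in rule.conditions)
                ]
                assert rule.support == len(matched)
                assert rule.confidence == pytest.approx(
                    sum(r.decision == rule.decision for r in matched) / len(matched)
                )

    def test_determinism_same_table_same_ruleset(self):
        table = random_table(np.random.default_rng(9), 4, 35, 0, 2)
        assert induce_rules(table).to_dict() == induce_rules(table).to_dict()
        assert (
            generalize_rules(table, beta=0.8).to_dict()
            == generalize_rules(table, beta=0.8).to_dict()
        )

    def test_empty_table_rejected(self, schema):
        from pdalert import DecisionTable

        with pytest.raises(ValidationError):
            induce_rules(DecisionTable(schema=schema, records=()))

    def test_unknown_mode_rejected(self):
        table = table_from_rows([(0,)], [0], 1)
        with pytest.raises(ValidationError):
            induce_rules(table, mode="PART")


class TestGeneralizeRSg:
    def test_beta_out_of_range_rejected(self):
        table = table_from_rows([(0,)], [0], 1)
        for beta in (0.5, 0.0, 1.2):
            with pytest.raises(ValidationError):
                generalize_rules(table, beta=beta)

    def test_droppable_condition_is_dropped(self):
        # class 1 is x=1 & y<3; dropping either condition keeps confidence 0.8
        rows = [(1, -1), (1, 0), (1, 1), (1, 2), (1, 3), (0, 0)]
        decisions = [1, 1, 1, 1, 0, 0]
        table = table_from_rows(rows, decisions, 2)
        rs_rule = [r for r in induce_rules(table).rules if r.decision == 1][0]
        rsg_rule = [r for r in generalize_rules(table, beta=0.8).rules if r.decision == 1][0]
        assert len(rs_rule.conditions) == 2
        assert len(rsg_rule.conditions) == 1
        assert rsg_rule.confidence == pytest.approx(0.8)

    def test_beta_one_matches_rs_classification_on_consistent_table(self):
        table = table_from_rows(
            [(0, 0), (0, 1), (1, 0), (1, 1), (2, 0), (2, 2)],
            [0, 0, 1, 1, 2, 2],
            2,
        )
        rs = induce_rules(table)
        rsg = generalize_rules(table, beta=1.0)
        for rec in table.records:
            assert classify(rs, rec).predicted == classify(rsg, rec).predicted

    @pytest.mark.parametrize("seed", range(4))
    def test_rsg_covers_the_beta_positive_region(self, seed):
        rng = np.random.default_rng(700 + seed)
        table = random_table(rng, 3, 30, 0, 1)
        beta = 0.8
        cuts = find_cuts(table)
        ruleset = generalize_rules(table, cuts=cuts, beta=beta)
        disc = cuts.discretize(table)
        concepts = _beta_concepts(disc, np.array(table.decisions), beta)
        for cls, mask in concepts.items():
            for i in np.flatnonzero(mask):
                rec = table.records[i]
                assert any(
                    r.decision == cls and r.matches(rec.deltas) for r in ruleset.rules
                ), (cls, i)

    def test_lowering_beta_never_shrinks_the_beta_positive_region(self):
        table = random_table(np.random.default_rng(13), 3, 40, 0, 1)
        cuts = find_cuts(table)
        disc = cuts.discretize(table)
        decisions = np.array(table.decisions)
        sizes = []
        for beta in (1.0, 0.9, 0.8, 0.7, 0.6):
            concepts = _beta_concepts(disc, decisions, beta)
            region = np.zeros(len(table), dtype=bool)
            for mask in concepts.values():
                region |= mask
            sizes.append(int(region.sum()))
        assert sizes == sorted(sizes)

    def test_rule_stats_recomputes_from_scratch(self):
        table = table_from_rows([(0,), (1,), (1,), (2,)], [0, 1, 2, 2], 1)
        attr = table.schema.attribute_names[0]
        support, confidence = rule_stats(table, (Condition(attr, 0, None),), 2)
        assert (support, confidence) == (3, 2 / 3)
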