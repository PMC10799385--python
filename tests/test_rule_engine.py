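"""Rule parsing, atom matching, builtins and forward chaining."""

import random

import pytest

from cdmo.fixtures import CANONICAL_INDIVIDUALS, make_micro_ontology
from cdmo.onto_core import Concept, OntologyGraph, concept_iri
from cdmo.rule_engine import (
    Atom,
    EvaluationError,
    KnowledgeBase,
    ParseError,
    Quantity,
    Variable,
    eval_builtin,
    explain,
    forward_chain,
    match_class_atom,
    parse_rule,
    parse_rules,
)

from oracles import naive_forward_chain

DIAGNOSIS_1 = (
    "Diagnosis_1: patient(?p) ^ polyphagia(?s1) ^ polyuria(?s2) ^ polydipsia(?s3)"
    " ^ weight_loss(?s4) ^ fasting_blood_glucose_measurement(?t1) ^"
    " diabetes_mellitus(?d1) ^ patient_has_symptom(?p, ?s1) ^"
    " patient_has_symptom(?p, ?s2) ^ patient_has_symptom’(?p, ?s3) ^"
    " patient_has_symptom(?p, ?s4) ^ patient_has_test(?p, ?t1) ^"
    " test_has_value(?t1, ?v1) ^ swrlb:greaterThanOrEqual(?v1, 7.0)"
    "—> patient_has_diagnosis(?p, ?d1)"
)


class TestParser:
    def test_diagnosis_rule_atom_census(self):
        """The published diagnosis rule parses to 14 antecedent atoms:
        7 class, 6 property, 1 builtin — and 1 consequent atom."""
        rule = parse_rule(DIAGNOSIS_1)
        assert len(rule.antecedent) == 14
        kinds = [a.kind for a in rule.antecedent]
        assert kinds.count("class") == 7
        assert kinds.count("object_property") == 6
        assert kinds.count("builtin") == 1
        assert len(rule.consequent) == 1
        # the typographic-apostrophe atom still unifies with the others
        symptom_atoms = [a for a in rule.antecedent if a.predicate == "patient_has_symptom"]
        assert len(symptom_atoms) == 4

    def test_minimal_rule(self):
        rule = parse_rule("r: p(?x) -> q(?x)")
        assert len(rule.antecedent) == len(rule.consequent) == 1

    def test_therapy_rule_has_three_consequents(self, clinical_rules):
        therapy = next(r for r in clinical_rules if r.name == "Therapy_1")
        assert len(therapy.consequent) == 3
        preds = sorted(a.predicate for a in therapy.consequent)
        assert preds == [
            "patient_has_therapy",
            "patient_has_therapy_drug",
            "patient_has_therapy_drug",
        ]

    def test_namespace_prefixes_stripped(self, clinical_rules):
        contra = next(r for r in clinical_rules if r.name == "Constraindication_drug_1")
        assert all(":" not in a.predicate for a in contra.antecedent + contra.consequent)

    def test_comments_attach_as_explanation(self, clinical_rules):
        diag = next(r for r in clinical_rules if r.name == "Diagnosis_1")
        assert "fasting blood glucose" in diag.comment

    def test_unbound_consequent_variable_rejected(self):
        with pytest.raises(ParseError, match=r"\?y"):
            parse_rule("r: p(?x) -> q(?x, ?y)")

    def test_builtin_in_consequent_rejected(self):
        with pytest.raises(ParseError, match="builtin"):
            parse_rule("r: p(?x) ^ q(?x, ?v) -> swrlb:greaterThan(?v, 1)")

    def test_malformed_atom_reports_offset(self):
        with pytest.raises(ParseError, match="offset"):
            parse_rule("r: p(?x) ^ garbage -> q(?x)")

    def test_duplicate_rule_names_rejected(self):
        with pytest.raises(ParseError, match="duplicate"):
            parse_rules("r: p(?x) -> q(?x)\n\nr: a(?x) -> b(?x)")


class TestBuiltins:
    @pytest.mark.parametrize(
        "pred,a,b,expected",
        [
            ("greaterThanOrEqual", 7.0, 7.0, True),   # boundary inclusive
            ("greaterThanOrEqual", 6.9, 7.0, False),
            ("greaterThan", 7.0, 7.0, False),
            ("lessThanOrEqual", 27.0, 27.0, True),
            ("lessThan", 26.0, 27.0, True),
            ("equal", 3.0, 3.0, True),
            ("notEqual", 3.0, 3.0, False),
        ],
    )
    def test_comparisons(self, pred, a, b, expected):
        assert eval_builtin(pred, [a, b]) is expected

    def test_randomized_pairs_match_python_comparison(self):
        rng = random.Random(8)
        ops = {
            "greaterThanOrEqual": lambda a, b: a >= b,
            "greaterThan": lambda a, b: a > b,
            "lessThanOrEqual": lambda a, b: a <= b,
            "lessThan": lambda a, b: a < b,
            "equal": lambda a, b: a == b,
            "notEqual": lambda a, b: a != b,
        }
        for _ in range(200):
            a, b = rng.choice([rng.uniform(-10, 10), float(rng.randint(-3, 3))]), float(
                rng.randint(-3, 3)
            )
            pred = rng.choice(list(ops))
            assert eval_builtin(pred, [a, b]) is ops[pred](a, b)

    def test_unbound_argument_rejected(self):
        with pytest.raises(EvaluationError, match="unbound"):
            eval_builtin("greaterThan", [Variable("v"), 1.0])

    def test_unknown_builtin_named(self):
        with pytest.raises(EvaluationError, match="pow"):
            eval_builtin("pow", [1.0, 2.0])

    def test_mismatched_units_rejected(self):
        with pytest.raises(EvaluationError, match="unit"):
            eval_builtin(
                "greaterThan", [Quantity(8.0, "mmol/L"), Quantity(27.0, "kg/m2")]
            )

    def test_unitless_literal_comparable_with_united_value(self):
        assert eval_builtin("greaterThanOrEqual", [Quantity(8.0, "mmol/L"), Quantity(7.0)])


class TestClassAtomMatching:
    def test_subclass_typed_individual_matches_superclass_atom(self, micro_onto):
        """An individual typed type-2 diabetes satisfies a diabetes atom."""
        kb = KnowledgeBase(micro_onto)
        kb.add_individual("d", concept_iri("2型糖尿病"))
        atom = Atom("class", "diabetes_mellitus", (Variable("x"),))
        assert list(match_class_atom(kb, atom, {})) == [{"x": "d"}]

    def test_unrelated_type_does_not_match(self, micro_onto):
        kb = KnowledgeBase(micro_onto)
        kb.add_individual("k", concept_iri("肾脏"))
        atom = Atom("class", "diabetes_mellitus", (Variable("x"),))
        assert list(match_class_atom(kb, atom, {})) == []

    def test_matches_equal_bruteforce_subclass_filter(self, micro_onto):
        rng = random.Random(13)
        kb = KnowledgeBase(micro_onto)
        iris = sorted(micro_onto.concepts)
        for i in range(40):
            kb.add_individual(f"ind{i}", rng.choice(iris))
        from cdmo.onto_core import is_subclass_of

        for predicate in ["disorder", "symptom", "substance", "procedure", "patient"]:
            atom = Atom("class", predicate, (Variable("x"),))
            got = sorted(b["x"] for b in match_class_atom(kb, atom, {}))
            cls = micro_onto.find_by_name_en(predicate).iri
            want = sorted(
                ind
                for ind, types in kb.individuals.items()
                if any(is_subclass_of(micro_onto, t, cls) for t in types)
            )
            assert got == want


def _class_of_factory(tbox):
    def class_of(predicate):
        c = tbox.find_by_name_en(predicate) or tbox.find_by_label_zh(predicate)
        return c.iri

    return class_of


class TestForwardChaining:
    def test_fig6_scenario_derives_diabetes_diagnosis(self, patient_bundle, clinical_rules):
        """Four symptoms plus fasting glucose 8.0 mmol/L => diabetes."""
        kb, _ = patient_bundle
        result = forward_chain(kb, clinical_rules)
        assert ("obj", "patient_has_diagnosis", "patient_a", "dm_canonical") in result.derived

    def test_below_threshold_derives_nothing(self, micro_onto, clinical_rules):
        kb = _single_patient_kb(micro_onto, fbg=6.9)
        assert forward_chain(kb, clinical_rules).derived == set()

    def test_three_of_four_symptoms_insufficient(self, micro_onto, clinical_rules):
        kb = _single_patient_kb(micro_onto, fbg=9.0, symptoms=3)
        assert forward_chain(kb, clinical_rules).derived == set()

    def test_fig7_scenario_recommends_therapy_and_both_drugs(
        self, patient_bundle, clinical_rules
    ):
        """Type 2 diabetes with BMI 28 => lifestyle therapy + GLP-1 RA + orlistat."""
        kb, _ = patient_bundle
        derived = forward_chain(kb, clinical_rules).derived
        assert ("obj", "patient_has_therapy", "patient_b", "lifestyle_therapy_canonical") in derived
        assert ("obj", "patient_has_therapy_drug", "patient_b", "glp1ra_canonical") in derived
        assert ("obj", "patient_has_therapy_drug", "patient_b", "orlistat_canonical") in derived

    def test_closure_matches_fixture_ground_truth(self, patient_bundle, clinical_rules):
        kb, truth = patient_bundle
        derived = forward_chain(kb, clinical_rules).derived
        expected = {tuple(f) for facts in truth.values() for f in facts}
        assert derived == expected

    def test_equivalent_to_naive_evaluator(self, patient_bundle, clinical_rules, micro_onto):
        kb, _ = patient_bundle
        derived = forward_chain(kb, clinical_rules).derived
        assert derived == naive_forward_chain(kb, clinical_rules, _class_of_factory(micro_onto))

    def test_equivalent_to_naive_on_random_kbs(self, micro_onto, clinical_rules):
        """Random small ABoxes around the thresholds agree with the naive
        full-rescan evaluator."""
        rng = random.Random(17)
        for _ in range(5):
            kb = _random_patient_kb(micro_onto, rng)
            got = forward_chain(kb, clinical_rules).derived
            want = naive_forward_chain(kb, clinical_rules, _class_of_factory(micro_onto))
            assert got == want

    def test_monotone_under_new_facts(self, micro_onto, clinical_rules):
        kb = _single_patient_kb(micro_onto, fbg=7.5)
        before = forward_chain(kb, clinical_rules).derived
        kb.assert_object("patient_has_diagnosis", "p0", "hypoglycemia_canonical")
        after = forward_chain(kb, clinical_rules).derived
        assert before <= after

    def test_idempotent_on_closure(self, patient_bundle, clinical_rules):
        kb, _ = patient_bundle
        closed = kb.copy()
        forward_chain(closed, clinical_rules, in_place=True)
        rerun = forward_chain(closed, clinical_rules)
        assert rerun.derived == set()

    def test_order_independent(self, patient_bundle, clinical_rules):
        kb, _ = patient_bundle
        reference = forward_chain(kb, clinical_rules).derived
        rng = random.Random(21)
        for _ in range(4):
            rules = list(clinical_rules)
            rng.shuffle(rules)
            shuffled = kb.copy()
            shuffled.object_assertions = set(shuffled.object_assertions)
            assert forward_chain(shuffled, rules).derived == reference

    def test_nonconvergence_guard(self, micro_onto):
        # an ever-growing chain cannot exist with positive ground rules,
        # so exercise the guard with a tiny iteration budget instead
        kb = _single_patient_kb(micro_onto, fbg=8.0)
        rules = parse_rules("r: patient(?p) -> patient_has_diagnosis(?p, ?p)")
        with pytest.raises(EvaluationError, match="converge"):
            forward_chain(kb, rules, max_iterations=0)


class TestExplain:
    def test_trace_carries_binding_value(self, patient_bundle, clinical_rules):
        kb, _ = patient_bundle
        result = forward_chain(kb, clinical_rules)
        fact = ("obj", "patient_has_diagnosis", "patient_a", "dm_canonical")
        entries = explain(result, fact)
        assert entries and entries[0][0] == "Diagnosis_1"
        assert entries[0][1]["v1"] == Quantity(8.0, "mmol/L")

    def test_underived_assertion_rejected(self, patient_bundle, clinical_rules):
        kb, _ = patient_bundle
        result = forward_chain(kb, clinical_rules)
        with pytest.raises(LookupError):
            explain(result, ("obj", "patient_has_diagnosis", "nobody", "dm_canonical"))

    def test_trace_count_matches_bruteforce_firings(self, micro_onto, clinical_rules):
        """Each distinct satisfying binding yields exactly one trace entry."""
        kb = _single_patient_kb(micro_onto, fbg=8.0)
        result = forward_chain(kb, clinical_rules)
        fact = ("obj", "patient_has_diagnosis", "p0", "dm_canonical")
        rule = next(r for r in clinical_rules if r.name == "Diagnosis_1")
        from cdmo.rule_engine import _match_rule

        closed = kb.copy()
        forward_chain(closed, clinical_rules, in_place=True)
        firings = sum(
            1
            for b in _match_rule(closed, rule, None, False)
            if b["p"] == "p0" and b["d1"] == "dm_canonical"
        )
        assert len(explain(result, fact)) == firings


# ---------------------------------------------------------------------
# helpers


def _base_kb(tbox) -> KnowledgeBase:
    kb = KnowledgeBase(tbox)
    for name, zh in CANONICAL_INDIVIDUALS.items():
        kb.add_individual(name, concept_iri(zh))
    return kb


def _single_patient_kb(tbox, fbg=None, bmi=None, symptoms=4, diagnoses=()) -> KnowledgeBase:
    kb = _base_kb(tbox)
    kb.add_individual("p0", concept_iri("患者"))
    for s in ["polyphagia_canonical", "polyuria_canonical", "polydipsia_canonical",
              "weight_loss_canonical"][:symptoms]:
        kb.assert_object("patient_has_symptom", "p0", s)
    if fbg is not None:
        kb.add_individual("p0_fbg", concept_iri("空腹血糖测定"))
        kb.assert_object("patient_has_test", "p0", "p0_fbg")
        kb.assert_data("test_has_value", "p0_fbg", fbg, "mmol/L")
    if bmi is not None:
        kb.add_individual("p0_bmi", concept_iri("体重指数"))
        kb.assert_object("patient_has_observable_entity", "p0", "p0_bmi")
        kb.assert_data("observable_entity_has_value", "p0_bmi", bmi, "kg/m2")
    for d in diagnoses:
        kb.assert_object("patient_has_diagnosis", "p0", d)
    return kb


def _random_patient_kb(tbox, rng) -> KnowledgeBase:
    kb = _base_kb(tbox)
    for i in range(rng.randint(1, 4)):
        name = f"rp{i}"
        kb.add_individual(name, concept_iri("患者"))
        for s in rng.sample(
            ["polyphagia_canonical", "polyuria_canonical", "polydipsia_canonical",
             "weight_loss_canonical"], rng.randint(2, 4)
        ):
            kb.assert_object("patient_has_symptom", name, s)
        if rng.random() < 0.8:
            kb.add_individual(f"{name}_fbg", concept_iri("空腹血糖测定"))
            kb.assert_object("patient_has_test", name, f"{name}_fbg")
            kb.assert_data("test_has_value", f"{name}_fbg",
                           round(7.0 + rng.choice([-1.0, -0.1, 0.0, 0.1, 1.0]), 2),
                           "mmol/L")
        if rng.random() < 0.6:
            kb.add_individual(f"{name}_bmi", concept_iri("体重指数"))
            kb.assert_object("patient_has_observable_entity", name, f"{name}_bmi")
            kb.assert_data("observable_entity_has_value", f"{name}_bmi",
                           float(27 + rng.choice([-2, -1, 0, 1, 2])), "kg/m2")
        for d, prob in [("t2dm_canonical", 0.4), ("renal_insufficiency_canonical", 0.3),
                        ("hypoglycemia_canonical", 0.3)]:
            if rng.random() < prob:
                kb.assert_object("patient_has_diagnosis", name, d)
    return kb
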