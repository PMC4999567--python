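"""Ontology model: loading, hierarchies, validation, derived variables."""

import pandas as pd
import pytest

from ontokdd.errors import DanglingReferenceError, SchemaError, UnknownConceptError
from ontokdd.ontology import (
    ConceptHierarchy,
    Rule,
    evaluate_derived,
    load_ontology,
    lowest_common_ancestor,
    validate_records,
)

MINIMAL_DOC = """
schema_version: 1
name: minimal
entities:
  - name: Thing
attributes:
  - name: Thing.Size
    kind: numeric
    range: [0, 10]
"""


class TestLoading:
    def test_bundled_registry_ontology_links_both_entities(self, ontology):
        assert set(ontology.entities) == {"Patient", "Aneurysm"}
        assert ontology.entities["Aneurysm"].parent == "Patient"
        spec = ontology.attribute("Aneurysm.Presentation")
        assert set(spec.categories) == {"Epilepsy", "Follow-up", "SAH", "Coincidental"}
        assert ontology.attribute("Aneurysm.Width").unit == "mm"

    def test_minimal_single_attribute_document(self):
        ont = load_ontology(MINIMAL_DOC)
        assert list(ont.entities) == ["Thing"]
        assert ont.attribute("Thing.Size").numeric_range == (0, 10)

    def test_round_trip_preserves_structure(self, ontology):
        again = load_ontology(ontology.to_yaml())
        assert again == ontology

    def test_undeclared_hierarchy_reference_is_an_error(self):
        doc = MINIMAL_DOC + (
            "  - name: Thing.Kind\n    kind: hierarchical\n    hierarchy: nowhere\n"
        )
        with pytest.raises(DanglingReferenceError):
            load_ontology(doc)

    def test_unparsable_or_unversioned_documents_rejected(self):
        with pytest.raises(SchemaError):
            load_ontology("schema_version: 99\nname: x\n")
        with pytest.raises(SchemaError):
            load_ontology("a: [unclosed\n  - ]broken")


class TestConceptHierarchy:
    def test_lca_is_reflexive(self, location_hierarchy):
        assert lowest_common_ancestor(location_hierarchy, "MCA", "MCA").id == "MCA"

    def test_lca_of_siblings_under_root_is_root(self):
        h = ConceptHierarchy.from_dict(
            "flat", {"id": "r", "children": [{"id": "a"}, {"id": "b"}]}
        )
        assert lowest_common_ancestor(h, "a", "b").id == "r"

    def test_lca_within_anterior_circulation(self, location_hierarchy):
        assert lowest_common_ancestor(location_hierarchy, "AComm", "MCA").id == "anterior_circulation"
        assert (
            lowest_common_ancestor(location_hierarchy, "AComm", "BasilarTip").id
            == "cerebral_vasculature"
        )

    def test_depths_follow_tree_levels(self, location_hierarchy):
        assert location_hierarchy.depth("cerebral_vasculature") == 0
        assert location_hierarchy.depth("posterior_circulation") == 1
        assert location_hierarchy.depth("AComm") == 2

    def test_unknown_concept_raises_lookup_error(self, location_hierarchy):
        with pytest.raises(UnknownConceptError):
            location_hierarchy.node("Ophthalmic")

    def test_duplicate_ids_rejected(self):
        with pytest.raises(SchemaError):
            ConceptHierarchy.from_dict("bad", {"id": "r", "children": [{"id": "r"}]})


class TestValidation:
    def test_clean_mini_registry_yields_empty_report(self, ontology, mini_records):
        report = validate_records(ontology, mini_records)
        assert report.empty
        assert report.counts_by_rule() == {}

    def test_negative_width_is_one_range_violation(self, ontology, mini_records):
        records = {k: v.copy() for k, v in mini_records.items()}
        records["Aneurysm"].loc[0, "Aneurysm.Width"] = -3.0
        report = validate_records(ontology, records)
        assert report.counts_by_rule() == {"range": 1}
        v = report.violations[0]
        assert (v.record_id, v.attribute) == ("A1", "Aneurysm.Width")

    def test_sah_presentation_is_a_declared_category(self, ontology, mini_records):
        records = {k: v.copy() for k, v in mini_records.items()}
        records["Aneurysm"].loc[1, "Aneurysm.Presentation"] = "SAH"
        assert validate_records(ontology, records).empty

    def test_unknown_column_reported_as_structural_not_raised(self, ontology, mini_records):
        records = {k: v.copy() for k, v in mini_records.items()}
        records["Aneurysm"]["Aneurysm.Color"] = "red"
        report = validate_records(ontology, records)
        assert report.counts_by_rule() == {"structural": 1}

    def test_unparsable_boolean_flagged(self, ontology, mini_records):
        records = {k: v.copy() for k, v in mini_records.items()}
        records["Aneurysm"]["Aneurysm.Ruptured"] = records["Aneurysm"][
            "Aneurysm.Ruptured"
        ].astype(object)
        records["Aneurysm"].loc[2, "Aneurysm.Ruptured"] = "maybe"
        report = validate_records(ontology, records)
        assert report.counts_by_rule() == {"boolean": 1}

    def test_adding_a_rule_never_removes_violations(self, ontology, mini_records):
        records = {k: v.copy() for k, v in mini_records.items()}
        records["Aneurysm"].loc[0, "Aneurysm.Width"] = -3.0
        base = validate_records(ontology, records)
        stricter = load_ontology(ontology.to_yaml())
        stricter.rules.append(
            Rule("range", "Patient.Age", (("max", 60.0), ("min", 40.0)))
        )
        extended = validate_records(stricter, records)
        base_set = {(v.record_id, v.attribute, v.rule) for v in base.violations}
        ext_set = {(v.record_id, v.attribute, v.rule) for v in extended.violations}
        assert base_set <= ext_set
        assert len(ext_set) > len(base_set)

    def test_cross_field_rule_detects_inconsistent_presentation(self, ontology, mini_records):
        records = {k: v.copy() for k, v in mini_records.items()}
        strict = load_ontology(ontology.to_yaml())
        strict.rules.append(
            Rule(
                "implies",
                "Aneurysm.Presentation",
                (
                    ("then_attribute", "Aneurysm.Ruptured"),
                    ("then_value", True),
                    ("when_value", "SAH"),
                ),
            )
        )
        assert validate_records(strict, records).empty
        records["Aneurysm"].loc[0, "Aneurysm.Ruptured"] = False  # A1 presents as SAH
        report = validate_records(strict, records)
        assert report.counts_by_rule() == {"implies": 1}


class TestDerivedVariables:
    def test_counts_linked_aneurysms_including_zero(self, ontology, mini_records):
        records = {k: v.copy() for k, v in mini_records.items()}
        records["Patient"] = pd.concat(
            [records["Patient"], pd.DataFrame({"id": ["P7"], "Patient.Sex": ["male"], "Patient.Age": [50.0]})],
            ignore_index=True,
        )
        out = evaluate_derived(ontology, records)
        counts = out["Patient"].set_index("id")["Patient.NumberOfAneurysms"]
        assert counts["P2"] == 2 and counts["P4"] == 2
        assert counts["P1"] == 1
        assert counts["P7"] == 0

    def test_re_evaluation_is_idempotent(self, ontology, mini_records):
        once = evaluate_derived(ontology, mini_records)
        twice = evaluate_derived(ontology, once)
        pd.testing.assert_frame_equal(once["Patient"], twice["Patient"])

    def test_independent_of_record_order(self, ontology, mini_records):
        shuffled = {
            "Patient": mini_records["Patient"].sample(frac=1, random_state=3).reset_index(drop=True),
            "Aneurysm": mini_records["Aneurysm"].sample(frac=1, random_state=4).reset_index(drop=True),
        }
        a = evaluate_derived(ontology, mini_records)["Patient"].set_index("id")
        b = evaluate_derived(ontology, shuffled)["Patient"].set_index("id")
        assert (
            a["Patient.NumberOfAneurysms"].sort_index() == b["Patient.NumberOfAneurysms"].sort_index()
        ).all()

    def test_age_at_diagnosis_from_date_difference(self):
        doc = """
schema_version: 1
name: dated
entities:
  - name: Case
attributes:
  - name: Case.BirthDate
    kind: categorical
    categories: [any]
  - name: Case.DiagnosisDate
    kind: categorical
    categories: [any]
  - name: Case.AgeAtDiagnosis
    kind: numeric
derived:
  - name: Case.AgeAtDiagnosis
    expression: years_between(Case.DiagnosisDate, Case.BirthDate)
"""
        ont = load_ontology(doc)
        records = {
            "Case": pd.DataFrame(
                {
                    "id": ["C1", "C2"],
                    "Case.BirthDate": ["1950-03-20", "1960-08-01"],
                    "Case.DiagnosisDate": ["2010-06-15", "2010-06-15"],
                }
            )
        }
        out = evaluate_derived(ont, records)["Case"]
        assert list(out["Case.AgeAtDiagnosis"]) == [60.0, 49.0]

    def test_division_by_zero_yields_null_not_abort(self, caplog):
        doc = """
schema_version: 1
name: ratio
entities:
  - name: Case
attributes:
  - name: Case.A
    kind: numeric
  - name: Case.B
    kind: numeric
  - name: Case.Ratio
    kind: numeric
derived:
  - name: Case.Ratio
    expression: Case.A / Case.B
"""
        ont = load_ontology(doc)
        records = {"Case": pd.DataFrame({"id": ["C1", "C2"], "Case.A": [4.0, 1.0], "Case.B": [2.0, 0.0]})}
        with caplog.at_level("WARNING"):
            out = evaluate_derived(ont, records)["Case"]
        assert out["Case.Ratio"].iloc[0] == 2.0
        assert pd.isna(out["Case.Ratio"].iloc[1])
        assert any("division" in m for m in caplog.messages)

    def test_cyclic_derived_definitions_rejected(self):
        doc = """
schema_version: 1
name: cyclic
entities:
  - name: Case
attributes:
  - name: Case.A
    kind: numeric
  - name: Case.B
    kind: numeric
derived:
  - name: Case.A
    expression: Case.B + 1
  - name: Case.B
    expression: Case.A + 1
"""
        with pytest.raises(SchemaError):
            load_ontology(doc)

    def test_arbitrary_code_in_expressions_rejected(self):
        doc = MINIMAL_DOC + (
            "derived:\n  - name: Thing.Size\n    expression: __import__('os').system('true')\n"
        )
        with pytest.raises(SchemaError):
            load_ontology(doc)
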