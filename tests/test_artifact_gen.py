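"""Artifact derivation: JSON Schema, tabular templates/DDL, SHACL shapes."""

import json

import jsonschema
import pytest

from healthkg import (bundle_to_json, bundle_to_quads, gen_json_schema,
                      gen_shacl, gen_tabular_templates, parse_schema,
                      shacl_validate, IriPolicy)
from healthkg.errors import GenerationError
from healthkg.fixtures import make_patients, _apply_mutation
import random


class TestJsonSchema:
    def test_value_set_becomes_enum(self, model):
        js = gen_json_schema(model)
        enum = js["definitions"]["Subject"]["properties"][
            "has_administrative_sex"]["enum"]
        assert enum == ["male", "female", "other"]

    def test_zero_property_concept_requires_only_id(self):
        m = parse_schema("""@prefix : <https://example.org/z#> .
@prefix dialect: <https://w3id.org/healthkg/dialect#> .
@prefix owl: <http://www.w3.org/2002/07/owl#> .
<https://example.org/z> dialect:schemaPrefix "z" .
:Subject a owl:Class ; dialect:isSubjectClass true .
""")
        js = gen_json_schema(m)
        assert js["definitions"]["Subject"]["required"] == ["id"]

    def test_missing_mandatory_matches_handwritten_mini_schema(self, model):
        """A bundle lacking a mandatory field fails the generated schema with
        exactly one error, agreeing with a hand-written schema for the same
        concept."""
        bundles, _ = make_patients(model, 1, seed=5)
        patient = bundle_to_json(bundles[0], model)
        del patient["records"]["Subject"][0]["has_administrative_sex"]
        doc = {"patients": [patient]}

        generated = jsonschema.Draft7Validator(gen_json_schema(model))
        gen_errors = list(generated.iter_errors(doc))
        assert len(gen_errors) == 1

        mini = {"type": "object", "required": ["id", "has_administrative_sex"]}
        mini_errors = list(jsonschema.Draft7Validator(mini).iter_errors(
            patient["records"]["Subject"][0]))
        assert len(mini_errors) == len(gen_errors) == 1
        assert "has_administrative_sex" in gen_errors[0].message

    def test_temporal_format_constraints(self, model):
        js = gen_json_schema(model)
        bd = js["definitions"]["Subject"]["properties"]["birth_date"]
        assert bd["format"] == "date" and "pattern" in bd
        rd = js["definitions"]["Diagnosis"]["properties"]["recorded_datetime"]
        assert rd["format"] == "date-time"

    def test_generation_is_deterministic(self, model):
        a = json.dumps(gen_json_schema(model), sort_keys=True)
        b = json.dumps(gen_json_schema(model), sort_keys=True)
        assert a == b


class TestTabularTemplates:
    def test_core_link_is_identifier_column_only(self, model):
        art = gen_tabular_templates(model)
        diag_cols = [c.column_name for c in art.template.tables["Diagnosis"]]
        assert "administrative_case_id" in diag_cols
        # no AdministrativeCase metadata leaks into the referencing table
        assert not any(c.startswith("admission_") for c in diag_cols)
        ref = next(c for c in art.template.tables["Diagnosis"]
                   if c.column_name == "administrative_case_id")
        assert ref.references == "AdministrativeCase"

    def test_embedded_concept_contributes_prefixed_columns(self, model):
        art = gen_tabular_templates(model)
        case_cols = [c.column_name for c in art.template.tables["AdministrativeCase"]]
        assert case_cols == ["patient_id", "administrative_case_id",
                             "admission_admission_datetime",
                             "admission_discharge_datetime"]

    def test_zero_property_concept_gets_identifier_columns_only(self):
        m = parse_schema("""@prefix : <https://example.org/z#> .
@prefix dialect: <https://w3id.org/healthkg/dialect#> .
@prefix owl: <http://www.w3.org/2002/07/owl#> .
<https://example.org/z> dialect:schemaPrefix "z" .
:Subject a owl:Class ; dialect:isSubjectClass true .
""")
        art = gen_tabular_templates(m)
        assert [c.column_name for c in art.template.tables["Subject"]] == [
            "patient_id", "subject_id"]

    def test_value_set_column_gets_check_constraint(self, model):
        ddl = gen_tabular_templates(model).ddl
        assert "CHECK (administrative_sex IN ('male', 'female', 'other'))" in ddl

    def test_csv_headers_match_ddl_column_order(self, model):
        art = gen_tabular_templates(model)
        for concept, cols in art.template.tables.items():
            from healthkg import table_name_for
            assert art.csv_headers[table_name_for(concept)].split(",") == [
                c.column_name for c in cols]

    def test_every_property_realized_exactly_once(self, model):
        """Coverage: each schema property maps to exactly one tabular column
        (or reference/patient-id column) and appears once in the shapes."""
        art = gen_tabular_templates(model)
        expected = {(c, p.name) for c, cdef in model.concepts.items()
                    for p in cdef.properties}
        assert set(art.template.property_map) == expected
        shapes = gen_shacl(model)
        for _, pname in expected:
            assert shapes.count(f"sh:path :{pname} ") == 1

    def test_column_collision_raises_naming_both_paths(self):
        doc = """@prefix : <https://example.org/c#> .
@prefix dialect: <https://w3id.org/healthkg/dialect#> .
@prefix owl: <http://www.w3.org/2002/07/owl#> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
@prefix xsd: <http://www.w3.org/2001/XMLSchema#> .
<https://example.org/c> dialect:schemaPrefix "c" .
:Subject a owl:Class ; dialect:isSubjectClass true ;
    rdfs:subClassOf [ a owl:Restriction ; owl:onProperty :note ;
                      owl:maxCardinality 1 ] ;
    rdfs:subClassOf [ a owl:Restriction ; owl:onProperty :has_note ;
                      owl:maxCardinality 1 ] .
:note a owl:DatatypeProperty ;
    rdfs:domain :Subject ; rdfs:range xsd:string ; dialect:order 1 .
:has_note a owl:DatatypeProperty ;
    rdfs:domain :Subject ; rdfs:range xsd:string ; dialect:order 2 .
"""
        with pytest.raises(GenerationError, match="note"):
            gen_tabular_templates(parse_schema(doc))

    def test_multivalued_scalar_becomes_side_table(self):
        doc = """@prefix : <https://example.org/m#> .
@prefix dialect: <https://w3id.org/healthkg/dialect#> .
@prefix owl: <http://www.w3.org/2002/07/owl#> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
@prefix xsd: <http://www.w3.org/2001/XMLSchema#> .
<https://example.org/m> dialect:schemaPrefix "m" .
:Subject a owl:Class ; dialect:isSubjectClass true .
:alias a owl:DatatypeProperty ;
    rdfs:domain :Subject ; rdfs:range xsd:string ; dialect:order 1 .
"""
        art = gen_tabular_templates(parse_schema(doc))
        assert "subject__alias" in art.template.side_tables
        assert art.template.property_map[("Subject", "alias")] == (
            "subject__alias", "alias")

    def test_ddl_regeneration_is_byte_identical(self, model):
        assert gen_tabular_templates(model).ddl == gen_tabular_templates(model).ddl


class TestShacl:
    def test_mandatory_coded_property_shape(self, model):
        shapes = gen_shacl(model)
        line = next(l for l in shapes.splitlines() if "sh:path :has_code" in l)
        assert "sh:minCount 1" in line
        assert "sh:in (" in line
        assert "dialect:terminologyCheck true" in line

    def test_zero_property_concept_has_bare_node_shape(self):
        m = parse_schema("""@prefix : <https://example.org/z#> .
@prefix dialect: <https://w3id.org/healthkg/dialect#> .
@prefix owl: <http://www.w3.org/2002/07/owl#> .
<https://example.org/z> dialect:schemaPrefix "z" .
:Subject a owl:Class ; dialect:isSubjectClass true .
""")
        shapes = gen_shacl(m)
        assert ":SubjectShape a sh:NodeShape" in shapes
        assert "sh:property" not in shapes

    def test_generated_and_oracle_shapes_agree_on_mixed_corpus(
            self, model, schema_and_oracle, terminology):
        """Verdict equivalence on 50 synthetic patients, 25 clean and 25 with
        injected violations of mixed kinds."""
        _, oracle = schema_and_oracle
        generated = gen_shacl(model)
        clean, _ = make_patients(model, 25, seed=31)
        dirty, ledger = make_patients(model, 25, seed=32, violation_rate=1.0)
        policy = IriPolicy("CHE-1", model.schema_prefix)
        n_nonconforming = 0
        for bundle in clean + dirty:
            try:
                quads = bundle_to_quads(bundle, model, policy)
            except Exception:
                continue  # hard errors (malformed ids) never reach SHACL
            va = shacl_validate(quads, generated, [terminology], model)
            vb = shacl_validate(quads, oracle, [terminology])
            assert va.conforms == vb.conforms
            assert sorted((f.constraint_kind, f.focus_node)
                          for f in va.findings) == \
                   sorted((f.constraint_kind, f.focus_node)
                          for f in vb.findings)
            n_nonconforming += (not va.conforms)
        assert n_nonconforming > 0  # the dirty half actually exercises shapes

    def test_shapes_regeneration_is_byte_identical(self, model):
        assert gen_shacl(model) == gen_shacl(model)
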