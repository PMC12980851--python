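"""Self-contained test fixtures: a toy schema, a toy terminology, hand-written
oracle shapes, and a seeded synthetic patient generator with an explicit
violation-injection ledger.

The toy schema mirrors the canonical worked example of patient-centric
clinical modeling: a Subject directly linked to Diagnosis, AdministrativeCase
and Measurement concepts (core), with an Admission concept embedded inside
AdministrativeCase (non-core).  Diagnoses are coded against a toy terminology
of eight codes of which one (C08) is retired — permitted by the schema value
set but absent from the current terminology graph, so using it is an
"outdated code" finding.

The generator never creates accidental violations: with an empty ledger every
bundle passes pre-check, the generated JSON Schema, SHACL and the logic
check.  Each ledger entry corresponds to exactly one mutation applied to the
corpus (at most one mutation per patient), so validation findings can be
compared against the ledger one-to-one on (patient, kind).
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from datetime import date, datetime, timedelta

from rdflib import Graph

from .ingest import InstanceRecord, PatientBundle
from .schema_model import ConceptModel, parse_schema

SCHEMA_NS = "https://example.org/toy-schema#"
TERM_NS = "https://example.org/toy-term/"

#: codes the current terminology knows
ACTIVE_CODES = tuple(f"{TERM_NS}C{i:02d}" for i in range(1, 8))
#: permitted by the schema value set but retired from the terminology
RETIRED_CODE = f"{TERM_NS}C08"

VIOLATION_KINDS = ("missing_mandatory", "bad_value_set", "bad_datatype",
                   "start_after_end", "malformed_id", "unknown_code")

TOY_SCHEMA = f"""@prefix : <{SCHEMA_NS}> .
@prefix dialect: <https://w3id.org/healthkg/dialect#> .
@prefix owl: <http://www.w3.org/2002/07/owl#> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
@prefix xsd: <http://www.w3.org/2001/XMLSchema#> .

<{SCHEMA_NS.rstrip('#')}> dialect:schemaPrefix "toy" .

:AdministrativeSex a owl:Class ;
    dialect:isValueSet true ;
    owl:oneOf ( "male" "female" "other" ) .

:DiagnosisCode a owl:Class ;
    dialect:isValueSet true ;
    owl:oneOf ( {' '.join(f'<{c}>' for c in ACTIVE_CODES)} <{RETIRED_CODE}> ) .

:Subject a owl:Class ;
    dialect:isSubjectClass true ;
    rdfs:subClassOf [ a owl:Restriction ; owl:onProperty :has_administrative_sex ;
                      owl:minCardinality 1 ; owl:maxCardinality 1 ] ;
    rdfs:subClassOf [ a owl:Restriction ; owl:onProperty :birth_date ;
                      owl:minCardinality 0 ; owl:maxCardinality 1 ] ;
    rdfs:subClassOf [ a owl:Restriction ; owl:onProperty :insurance_number ;
                      owl:minCardinality 0 ; owl:maxCardinality 1 ] .

:has_administrative_sex a owl:ObjectProperty ;
    rdfs:domain :Subject ; rdfs:range :AdministrativeSex ; dialect:order 1 .
:birth_date a owl:DatatypeProperty ;
    rdfs:domain :Subject ; rdfs:range xsd:date ; dialect:order 2 .
:insurance_number a owl:DatatypeProperty ;
    rdfs:domain :Subject ; rdfs:range xsd:string ; dialect:order 3 .
:has_diagnosis a owl:ObjectProperty ;
    rdfs:domain :Subject ; rdfs:range :Diagnosis ; dialect:order 4 .
:has_administrative_case a owl:ObjectProperty ;
    rdfs:domain :Subject ; rdfs:range :AdministrativeCase ; dialect:order 5 .
:has_measurement a owl:ObjectProperty ;
    rdfs:domain :Subject ; rdfs:range :Measurement ; dialect:order 6 .

:Diagnosis a owl:Class ;
    rdfs:subClassOf [ a owl:Restriction ; owl:onProperty :has_code ;
                      owl:minCardinality 1 ; owl:maxCardinality 1 ] ;
    rdfs:subClassOf [ a owl:Restriction ; owl:onProperty :recorded_datetime ;
                      owl:minCardinality 1 ; owl:maxCardinality 1 ] ;
    rdfs:subClassOf [ a owl:Restriction ; owl:onProperty :severity_score ;
                      owl:minCardinality 0 ; owl:maxCardinality 1 ] ;
    rdfs:subClassOf [ a owl:Restriction ; owl:onProperty :note ;
                      owl:minCardinality 0 ; owl:maxCardinality 1 ] ;
    rdfs:subClassOf [ a owl:Restriction ; owl:onProperty :has_case ;
                      owl:minCardinality 0 ; owl:maxCardinality 1 ] .

:has_code a owl:ObjectProperty ;
    rdfs:domain :Diagnosis ; rdfs:range :DiagnosisCode ; dialect:order 1 .
:recorded_datetime a owl:DatatypeProperty ;
    rdfs:domain :Diagnosis ; rdfs:range xsd:dateTime ; dialect:order 2 .
:severity_score a owl:DatatypeProperty ;
    rdfs:domain :Diagnosis ; rdfs:range xsd:integer ; dialect:order 3 .
:note a owl:DatatypeProperty ;
    rdfs:domain :Diagnosis ; rdfs:range xsd:string ; dialect:order 4 .
:has_case a owl:ObjectProperty ;
    rdfs:domain :Diagnosis ; rdfs:range :AdministrativeCase ; dialect:order 5 .

:AdministrativeCase a owl:Class ;
    rdfs:subClassOf [ a owl:Restriction ; owl:onProperty :has_admission ;
                      owl:minCardinality 1 ; owl:maxCardinality 1 ] .

:has_admission a owl:ObjectProperty ;
    rdfs:domain :AdministrativeCase ; rdfs:range :Admission ; dialect:order 1 .

:Admission a owl:Class ;
    rdfs:subClassOf [ a owl:Restriction ; owl:onProperty :admission_datetime ;
                      owl:minCardinality 1 ; owl:maxCardinality 1 ] ;
    rdfs:subClassOf [ a owl:Restriction ; owl:onProperty :discharge_datetime ;
                      owl:minCardinality 0 ; owl:maxCardinality 1 ] ;
    dialect:startEndPair [ dialect:startProperty :admission_datetime ;
                           dialect:endProperty :discharge_datetime ] .

:admission_datetime a owl:DatatypeProperty ;
    rdfs:domain :Admission ; rdfs:range xsd:dateTime ; dialect:order 1 .
:discharge_datetime a owl:DatatypeProperty ;
    rdfs:domain :Admission ; rdfs:range xsd:dateTime ; dialect:order 2 .

:Measurement a owl:Class ;
    rdfs:subClassOf [ a owl:Restriction ; owl:onProperty :quantity_value ;
                      owl:minCardinality 1 ; owl:maxCardinality 1 ] ;
    rdfs:subClassOf [ a owl:Restriction ; owl:onProperty :measure_datetime ;
                      owl:minCardinality 0 ; owl:maxCardinality 1 ] ;
    rdfs:subClassOf [ a owl:Restriction ; owl:onProperty :has_shared_identifier ;
                      owl:minCardinality 0 ; owl:maxCardinality 1 ] .

:quantity_value a owl:DatatypeProperty ;
    rdfs:domain :Measurement ; rdfs:range xsd:decimal ; dialect:order 1 .
:measure_datetime a owl:DatatypeProperty ;
    rdfs:domain :Measurement ; rdfs:range xsd:dateTime ; dialect:order 2 .
:has_shared_identifier a owl:DatatypeProperty ;
    rdfs:domain :Measurement ; rdfs:range xsd:string ; dialect:order 3 ;
    dialect:isSharedIdentifier true .
"""

#: independently hand-written shapes for the toy schema; used only as an
#: oracle for verdict comparison against the generated shapes
ORACLE_SHAPES = f"""@prefix : <{SCHEMA_NS}> .
@prefix sh: <http://www.w3.org/ns/shacl#> .
@prefix dialect: <https://w3id.org/healthkg/dialect#> .
@prefix xsd: <http://www.w3.org/2001/XMLSchema#> .

:OracleSubject a sh:NodeShape ;
    sh:targetClass :Subject ;
    sh:property [ sh:path :has_administrative_sex ; sh:minCount 1 ; sh:maxCount 1 ;
                  sh:in ( "male" "female" "other" ) ] ;
    sh:property [ sh:path :birth_date ; sh:maxCount 1 ; sh:datatype xsd:date ] ;
    sh:property [ sh:path :insurance_number ; sh:maxCount 1 ; sh:datatype xsd:string ] ;
    sh:property [ sh:path :has_diagnosis ; sh:class :Diagnosis ] ;
    sh:property [ sh:path :has_administrative_case ; sh:class :AdministrativeCase ] ;
    sh:property [ sh:path :has_measurement ; sh:class :Measurement ] .

:OracleDiagnosis a sh:NodeShape ;
    sh:targetClass :Diagnosis ;
    sh:property [ sh:path :has_code ; sh:minCount 1 ; sh:maxCount 1 ;
                  sh:in ( {' '.join(f'<{c}>' for c in ACTIVE_CODES)} <{RETIRED_CODE}> ) ;
                  dialect:terminologyCheck true ] ;
    sh:property [ sh:path :recorded_datetime ; sh:minCount 1 ; sh:maxCount 1 ;
                  sh:datatype xsd:dateTime ] ;
    sh:property [ sh:path :severity_score ; sh:maxCount 1 ; sh:datatype xsd:integer ] ;
    sh:property [ sh:path :note ; sh:maxCount 1 ; sh:datatype xsd:string ] ;
    sh:property [ sh:path :has_case ; sh:maxCount 1 ; sh:class :AdministrativeCase ] .

:OracleCase a sh:NodeShape ;
    sh:targetClass :AdministrativeCase ;
    sh:property [ sh:path :has_admission ; sh:minCount 1 ; sh:maxCount 1 ;
                  sh:class :Admission ] .

:OracleAdmission a sh:NodeShape ;
    sh:targetClass :Admission ;
    sh:property [ sh:path :admission_datetime ; sh:minCount 1 ; sh:maxCount 1 ;
                  sh:datatype xsd:dateTime ] ;
    sh:property [ sh:path :discharge_datetime ; sh:maxCount 1 ;
                  sh:datatype xsd:dateTime ] .

:OracleMeasurement a sh:NodeShape ;
    sh:targetClass :Measurement ;
    sh:property [ sh:path :quantity_value ; sh:minCount 1 ; sh:maxCount 1 ;
                  sh:datatype xsd:decimal ] ;
    sh:property [ sh:path :measure_datetime ; sh:maxCount 1 ;
                  sh:datatype xsd:dateTime ] .
"""


def make_toy_schema() -> tuple[str, str]:
    """Return (schema document, hand-written oracle shapes), both Turtle."""
    return TOY_SCHEMA, ORACLE_SHAPES


def toy_model() -> ConceptModel:
    return parse_schema(TOY_SCHEMA)


def make_toy_terminology() -> str:
    """Turtle terminology graph listing the currently valid code IRIs."""
    lines = [
        "@prefix dialect: <https://w3id.org/healthkg/dialect#> .",
        "@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .",
        "",
    ]
    for i, code in enumerate(ACTIVE_CODES, start=1):
        lines.append(f"<{code}> a dialect:TerminologyCode ;")
        lines.append(f'    rdfs:label "toy condition {i:02d}" .')
        lines.append("")
    return "\n".join(lines)


def toy_terminology_graph() -> Graph:
    return Graph().parse(data=make_toy_terminology(), format="turtle")


@dataclass(frozen=True)
class InjectionEntry:
    patient_local_id: str
    concept: str
    property: str | None
    violation_kind: str


NOTE_WORDS = ("follow-up", "stable", "routine check", "referred", "observation",
              "post-operative", "chronic", "acute episode")


def _mk_patient(pid: str, rng: random.Random, model: ConceptModel) -> PatientBundle:
    bundle = PatientBundle(patient_local_id=pid)
    n_cases = rng.randint(1, 5)
    n_diag = rng.randint(0, 10)
    n_meas = rng.randint(0, 3)

    case_ids = [f"case-{pid}-{j:02d}" for j in range(1, n_cases + 1)]
    for cid in case_ids:
        adm = datetime(2015, 1, 1) + timedelta(days=rng.randint(0, 3000),
                                               hours=rng.randint(0, 23))
        stay = rng.randint(0, 30)
        admission = InstanceRecord(
            concept="Admission", instance_local_id=cid,
            fields={
                "admission_datetime": adm.isoformat(),
                "discharge_datetime": (adm + timedelta(days=stay)).isoformat(),
            })
        case = InstanceRecord(concept="AdministrativeCase", instance_local_id=cid,
                              links={"has_admission": cid})
        bundle.records += [admission, case]

    diag_ids = [f"diag-{pid}-{j:02d}" for j in range(1, n_diag + 1)]
    for did in diag_ids:
        rec_dt = datetime(2015, 1, 1) + timedelta(days=rng.randint(0, 3000),
                                                  minutes=rng.randint(0, 1439))
        diag = InstanceRecord(
            concept="Diagnosis", instance_local_id=did,
            fields={"has_code": rng.choice(ACTIVE_CODES),
                    "recorded_datetime": rec_dt.isoformat()})
        if rng.random() < 0.7:
            diag.fields["severity_score"] = rng.randint(1, 5)
        if rng.random() < 0.5:
            diag.fields["note"] = rng.choice(NOTE_WORDS)
        if rng.random() < 0.8:
            diag.links["has_case"] = rng.choice(case_ids)
        bundle.records.append(diag)

    meas_ids = [f"meas-{pid}-{j:02d}" for j in range(1, n_meas + 1)]
    for mid in meas_ids:
        meas = InstanceRecord(
            concept="Measurement", instance_local_id=mid,
            fields={"quantity_value": round(rng.uniform(50, 200), 1)})
        if rng.random() < 0.8:
            m_dt = datetime(2015, 1, 1) + timedelta(days=rng.randint(0, 3000))
            meas.fields["measure_datetime"] = m_dt.isoformat()
        if rng.random() < 0.2:
            meas.shared_identifiers["has_shared_identifier"] = (
                f"https://example.org/shared/sample-{rng.randint(0, 10**6):06d}")
        bundle.records.append(meas)

    birth = date(1930, 1, 1) + timedelta(days=rng.randint(0, 29000))
    subject = InstanceRecord(
        concept="Subject", instance_local_id=pid,
        fields={
            "has_administrative_sex": rng.choice(("male", "female", "other")),
            "birth_date": birth.isoformat(),
            "insurance_number": (f"756.{rng.randint(0, 9999):04d}."
                                 f"{rng.randint(0, 9999):04d}."
                                 f"{rng.randint(0, 99):02d}"),
        },
        links={k: v for k, v in (("has_diagnosis", sorted(diag_ids)),
                                 ("has_administrative_case", sorted(case_ids)),
                                 ("has_measurement", sorted(meas_ids))) if v})
    bundle.records.append(subject)
    bundle.records.sort(key=lambda r: (r.concept, r.instance_local_id))
    return bundle


def _apply_mutation(bundle: PatientBundle, kind: str,
                    rng: random.Random) -> InjectionEntry:
    pid = bundle.patient_local_id
    if kind == "missing_mandatory":
        subj = bundle.by_concept("Subject")[0]
        del subj.fields["has_administrative_sex"]
        return InjectionEntry(pid, "Subject", "has_administrative_sex", kind)
    if kind == "bad_value_set":
        subj = bundle.by_concept("Subject")[0]
        subj.fields["has_administrative_sex"] = "unknown"
        return InjectionEntry(pid, "Subject", "has_administrative_sex", kind)
    if kind == "bad_datatype":
        diags = bundle.by_concept("Diagnosis")
        if diags:
            diag = rng.choice(diags)
            diag.fields["severity_score"] = "severe"
            return InjectionEntry(pid, "Diagnosis", "severity_score", kind)
        subj = bundle.by_concept("Subject")[0]
        subj.fields["birth_date"] = "1980-13-45"  # unparseable; blocks at pre-check
        return InjectionEntry(pid, "Subject", "birth_date", kind)
    if kind == "start_after_end":
        adm = rng.choice(bundle.by_concept("Admission"))
        start = datetime.fromisoformat(adm.fields["admission_datetime"])
        adm.fields["discharge_datetime"] = (
            start - timedelta(days=rng.randint(1, 10))).isoformat()
        return InjectionEntry(pid, "Admission", "discharge_datetime", kind)
    if kind == "malformed_id":
        # a space makes the patient identifier IRI-unsafe
        bad = pid.replace("-", " ", 1)
        for rec in bundle.records:
            if rec.concept == "Subject":
                rec.instance_local_id = bad
        bundle.patient_local_id = bad
        return InjectionEntry(bad, "Subject", None, kind)
    if kind == "unknown_code":
        diag = rng.choice(bundle.by_concept("Diagnosis"))
        diag.fields["has_code"] = RETIRED_CODE
        return InjectionEntry(pid, "Diagnosis", "has_code", kind)
    raise ValueError(f"unknown violation kind {kind!r}")


def make_patients(model: ConceptModel, n: int, seed: int,
                  violation_rate: float = 0.0
                  ) -> tuple[list[PatientBundle], list[InjectionEntry]]:
    """Generate ``n`` synthetic patient bundles plus the injection ledger.

    Clean bundles have 1–5 administrative cases (admission ≤ discharge by
    construction), 0–10 diagnoses coded with currently valid codes, and 0–3
    measurements.  ``round(violation_rate * n)`` patients receive exactly one
    mutation each, drawn round-robin over the six violation kinds; kinds that
    need a diagnosis are assigned to patients that have one.  Same seed, same
    corpus — byte for byte.
    """
    if not 0.0 <= violation_rate <= 1.0:
        raise ValueError("violation_rate must be within [0, 1]")
    rng = random.Random(seed)
    bundles = [_mk_patient(f"p-{i:04d}", rng, model) for i in range(1, n + 1)]

    ledger: list[InjectionEntry] = []
    k = round(violation_rate * n)
    if k:
        candidates = list(range(n))
        rng.shuffle(candidates)
        kinds = [VIOLATION_KINDS[i % len(VIOLATION_KINDS)] for i in range(k)]
        chosen: list[tuple[int, str]] = []
        used: set[int] = set()
        for kind in kinds:
            needs_diag = kind == "unknown_code"
            idx = next(i for i in candidates
                       if i not in used and
                       (not needs_diag or bundles[i].by_concept("Diagnosis")))
            used.add(idx)
            chosen.append((idx, kind))
        for idx, kind in chosen:
            ledger.append(_apply_mutation(bundles[idx], kind, rng))
    ledger.sort(key=lambda e: e.patient_local_id)
    return bundles, ledger
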