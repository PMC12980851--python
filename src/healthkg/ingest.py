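"""Normalize JSON or tabular patient data into per-patient bundles.

A :class:`PatientBundle` is the intermediate normalized form every downstream
step consumes ("Landing Zone" representation).  Both ingestion routes (JSON
documents validated against the generated JSON Schema, and CSV tables matching
the generated templates) must produce identical bundles for equivalent
content; the test suite asserts this cross-route equivalence.

Pre-check findings are *findings*, not exceptions: identifier IRI-safety,
value-set membership and temporal parseability are reported per record so the
pipeline can decide which ones block a patient (see ``zones``).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from datetime import date, datetime

import jsonschema

from .errors import IngestionError
from .schema_model import ConceptModel, PropertyDef

#: IRI-safe unreserved characters permitted in provider-supplied local ids.
LOCAL_ID_RE = re.compile(r"^[A-Za-z0-9._~-]+$")


@dataclass
class InstanceRecord:
    concept: str
    instance_local_id: str
    #: property name -> scalar value or list of values (str/int/float/bool)
    fields: dict[str, object] = field(default_factory=dict)
    #: property name -> local id(s) of linked concept instances
    links: dict[str, object] = field(default_factory=dict)
    #: property name -> externally agreed identifier, exempt from IRI minting
    shared_identifiers: dict[str, str] = field(default_factory=dict)

    def link_ids(self, prop: str) -> list[str]:
        v = self.links.get(prop, [])
        return list(v) if isinstance(v, list) else [v]

    def field_values(self, prop: str) -> list[object]:
        v = self.fields.get(prop)
        if v is None:
            return []
        return list(v) if isinstance(v, list) else [v]


@dataclass
class PatientBundle:
    patient_local_id: str
    records: list[InstanceRecord] = field(default_factory=list)

    def by_concept(self, concept: str) -> list[InstanceRecord]:
        return [r for r in self.records if r.concept == concept]

    def find(self, concept: str, instance_id: str) -> InstanceRecord | None:
        for r in self.records:
            if r.concept == concept and r.instance_local_id == instance_id:
                return r
        return None

    def copy(self) -> "PatientBundle":
        return PatientBundle(
            patient_local_id=self.patient_local_id,
            records=[
                replace(r, fields=dict(r.fields), links=dict(r.links),
                        shared_identifiers=dict(r.shared_identifiers))
                for r in self.records
            ],
        )


@dataclass(frozen=True)
class Finding:
    """A pre-check finding; ``kind`` uses the pipeline-wide violation taxonomy."""
    kind: str  # malformed_id | bad_value_set | bad_datatype
    concept: str
    instance_id: str
    prop: str | None
    message: str
    blocking: bool


# ---------------------------------------------------------------------------
# structural validation helpers

def validate_bundle_structure(bundle: PatientBundle, model: ConceptModel) -> None:
    """Check the bundle invariants; raises IngestionError on breach."""
    seen: set[tuple[str, str]] = set()
    for r in bundle.records:
        if r.concept not in model.concepts:
            raise IngestionError(
                f"patient {bundle.patient_local_id}: unknown concept {r.concept!r}"
            )
        key = (r.concept, r.instance_local_id)
        if key in seen:
            raise IngestionError(
                f"patient {bundle.patient_local_id}: duplicate instance id "
                f"{r.instance_local_id!r} for concept {r.concept}"
            )
        seen.add(key)
    for r in bundle.records:
        cdef = model.concepts[r.concept]
        for prop, _ in r.links.items():
            try:
                pdef = cdef.property(prop)
            except KeyError:
                raise IngestionError(f"{r.concept}.{prop}: unknown link property") from None
            for target_id in r.link_ids(prop):
                if (pdef.target, target_id) not in seen:
                    raise IngestionError(
                        f"patient {bundle.patient_local_id}: {r.concept} "
                        f"{r.instance_local_id!r} links {prop} to missing "
                        f"{pdef.target} instance {target_id!r}"
                    )


def _coerce(value: object, pdef: PropertyDef, lenient: bool = False) -> object:
    """Coerce a raw JSON/CSV value to the property's declared type.

    Temporal values stay ISO-8601 strings (validated later by pre-check);
    numeric strings from CSV become numbers.  In lenient mode (Landing-zone
    re-reads) an uncoercible value is kept as-is so validation can report it.
    """
    if pdef.range_kind in ("value_set", "temporal") or pdef.is_shared_identifier:
        return str(value)
    dt = pdef.scalar_datatype
    try:
        if dt == "integer":
            return int(value)
        if dt == "decimal":
            return float(value)
        if dt == "boolean":
            if isinstance(value, bool):
                return value
            return {"true": True, "false": False}[str(value).lower()]
    except (ValueError, KeyError) as exc:
        if lenient:
            return value
        raise IngestionError(f"cannot coerce {value!r} to {dt}") from exc
    return str(value)


# ---------------------------------------------------------------------------
# JSON route

def ingest_json(doc: str | dict, model: ConceptModel,
                json_schema: dict | None = None) -> list[PatientBundle]:
    """Ingest a JSON document (one or many patients) into bundles.

    The document must validate against the generated JSON Schema; structural
    failures reject the whole offending patient (patient-level atomicity) and
    are reported with their JSON paths.
    """
    from .artifact_gen import gen_json_schema  # local import: avoid cycle

    if isinstance(doc, str):
        try:
            payload = json.loads(doc)
        except json.JSONDecodeError as exc:
            raise IngestionError(f"invalid JSON: {exc}") from exc
    else:
        payload = doc
    schema = json_schema or gen_json_schema(model)
    validator = jsonschema.Draft7Validator(schema)
    errors = sorted(validator.iter_errors(payload),
                    key=lambda e: [str(p) for p in e.absolute_path])
    if errors:
        paths = ["/" + "/".join(str(p) for p in e.absolute_path) for e in errors]
        raise IngestionError(
            "document does not conform to the generated JSON Schema: "
            + "; ".join(f"{p}: {e.message}" for p, e in zip(paths, errors)),
            paths=paths,
        )

    bundles = []
    for patient in payload["patients"]:
        bundles.append(_patient_json_to_bundle(patient, model))
    return bundles


def _patient_json_to_bundle(patient: dict, model: ConceptModel,
                            lenient: bool = False) -> PatientBundle:
    bundle = PatientBundle(patient_local_id=str(patient["patient_id"]))
    records = patient.get("records", {})
    for concept_name in model.concepts:
        cdef = model.concepts[concept_name]
        if not cdef.is_core:
            continue  # embedded concepts arrive nested inside their owner
        for inst in records.get(concept_name, []):
            _instance_json_to_records(inst, concept_name, model, bundle, lenient)
    bundle.records.sort(key=lambda r: (r.concept, r.instance_local_id))
    validate_bundle_structure(bundle, model)
    return bundle


def _instance_json_to_records(inst: dict, concept: str, model: ConceptModel,
                              bundle: PatientBundle,
                              lenient: bool = False) -> InstanceRecord:
    cdef = model.concepts[concept]
    rec = InstanceRecord(concept=concept, instance_local_id=str(inst["id"]))
    for pdef in cdef.properties:
        raw = inst.get(pdef.name)
        if raw is None or raw == [] or raw == "":
            continue
        values = raw if isinstance(raw, list) else [raw]
        if pdef.is_shared_identifier:
            rec.shared_identifiers[pdef.name] = str(values[0])
        elif pdef.range_kind == "concept":
            target_core = model.concepts[pdef.target].is_core
            if target_core:
                ids = [str(v) for v in values]
                rec.links[pdef.name] = ids if pdef.max_count != 1 else ids[0]
            else:
                # embedded concept: nested object(s); the embedded instance
                # inherits the owner's local id (one embedded instance per owner)
                ids = []
                for nested in values:
                    nested = dict(nested)
                    nested.setdefault("id", rec.instance_local_id)
                    child = _instance_json_to_records(nested, pdef.target, model,
                                                      bundle, lenient)
                    ids.append(child.instance_local_id)
                rec.links[pdef.name] = ids if pdef.max_count != 1 else ids[0]
        else:
            coerced = [_coerce(v, pdef, lenient=lenient) for v in values]
            rec.fields[pdef.name] = coerced if pdef.max_count != 1 else coerced[0]
    bundle.records.append(rec)
    return rec


def bundle_to_json(bundle: PatientBundle, model: ConceptModel) -> dict:
    """Inverse of the JSON route: emit a patient object in template form."""
    embedded_owned: set[tuple[str, str]] = set()
    for r in bundle.records:
        cdef = model.concepts[r.concept]
        for pdef in cdef.properties:
            if pdef.range_kind == "concept" and not model.concepts[pdef.target].is_core:
                for tid in r.link_ids(pdef.name):
                    embedded_owned.add((pdef.target, tid))

    def instance_json(rec: InstanceRecord) -> dict:
        out: dict[str, object] = {"id": rec.instance_local_id}
        cdef = model.concepts[rec.concept]
        for pdef in cdef.properties:
            if pdef.name in rec.shared_identifiers:
                out[pdef.name] = rec.shared_identifiers[pdef.name]
            elif pdef.name in rec.fields:
                out[pdef.name] = rec.fields[pdef.name]
            elif pdef.name in rec.links:
                if pdef.range_kind == "concept" and not model.concepts[pdef.target].is_core:
                    nested = [
                        instance_json(bundle.find(pdef.target, tid))
                        for tid in rec.link_ids(pdef.name)
                    ]
                    out[pdef.name] = nested if pdef.max_count != 1 else nested[0]
                else:
                    out[pdef.name] = rec.links[pdef.name]
        return out

    records: dict[str, list] = {}
    for r in bundle.records:
        if (r.concept, r.instance_local_id) in embedded_owned:
            continue
        records.setdefault(r.concept, []).append(instance_json(r))
    return {"patient_id": bundle.patient_local_id, "records": records}


# ---------------------------------------------------------------------------
# tabular route

def ingest_tabular(tables: dict[str, list[dict[str, str]]],
                   model: ConceptModel) -> list[PatientBundle]:
    """Ingest CSV-shaped tables (lists of header->value row dicts, as produced
    by ``csv.DictReader`` on the generated templates) into bundles.

    Rows are grouped by the patient-id column; reference-id columns become
    links; embedded prefixed columns are reassembled into nested records.
    Rows whose value-set columns hold non-permitted members are rejected with
    their row number, mirroring enumerated column types in a database load.
    """
    from .artifact_gen import gen_tabular_templates, table_name_for, column_plan

    template = gen_tabular_templates(model).template
    by_patient: dict[str, PatientBundle] = {}
    known = {table_name_for(c): c for c in model.concepts if model.concepts[c].is_core}

    for tname in tables:
        if tname not in known and tname not in template.side_tables:
            raise IngestionError(f"unknown table {tname!r}")

    # deterministic concept order; Subject first so links can resolve lazily
    order = sorted(known.items(), key=lambda kv: (kv[1] != model.subject_concept, kv[0]))
    for tname, concept in order:
        rows = tables.get(tname, [])
        expected = [c.column_name for c in template.tables[concept]]
        plan = column_plan(model, concept)
        for i, row in enumerate(rows, start=2):  # header is line 1
            unknown = set(row) - set(expected)
            if unknown:
                raise IngestionError(f"table {tname}, row {i}: unknown column(s) "
                                     + ", ".join(sorted(unknown)))
            _check_enumerated(row, plan, model, tname, i)
            pid = row["patient_id"]
            bundle = by_patient.setdefault(pid, PatientBundle(patient_local_id=pid))
            _row_to_records(row, concept, plan, model, bundle)

    # side tables: one row per value of a multi-valued property
    for stname in sorted(template.side_tables):
        rows = tables.get(stname, [])
        if not rows:
            continue
        base_table, prop_base = stname.split("__", 1)
        concept = known[base_table]
        cdef = model.concepts[concept]
        pdef = next(p for p in cdef.properties
                    if column_base_name(p.name) == prop_base)
        vcol = template.side_tables[stname][-1].column_name
        for i, row in enumerate(rows, start=2):
            pid = row["patient_id"]
            bundle = by_patient.get(pid)
            rec = bundle.find(concept, row[f"{base_table}_id"]) if bundle else None
            if rec is None:
                raise IngestionError(
                    f"table {stname}, row {i}: no {concept} row with id "
                    f"{row.get(base_table + '_id')!r} for patient {pid!r}"
                )
            if pdef.range_kind == "value_set":
                allowed = {str(m) for m in model.value_sets[pdef.target].members}
                if row[vcol] not in allowed:
                    raise IngestionError(
                        f"table {stname}, row {i}: value {row[vcol]!r} not "
                        f"permitted for enumerated column {vcol}"
                    )
            if pdef.range_kind == "concept":
                rec.links.setdefault(pdef.name, [])
                rec.links[pdef.name].append(row[vcol])
            else:
                rec.fields.setdefault(pdef.name, [])
                rec.fields[pdef.name].append(_coerce(row[vcol], pdef))

    bundles = []
    for pid in sorted(by_patient):
        bundle = by_patient[pid]
        _attach_subject_links(bundle, model)
        bundle.records.sort(key=lambda r: (r.concept, r.instance_local_id))
        validate_bundle_structure(bundle, model)
        bundles.append(bundle)
    return bundles


def column_base_name(prop: str) -> str:
    from .artifact_gen import column_base
    return column_base(prop)


def _check_enumerated(row, plan, model, tname, lineno) -> None:
    for col in plan:
        if col.kind == "value_set" and row.get(col.column_name):
            vs = model.value_sets[col.pdef.target]
            allowed = {str(m) for m in vs.members}
            for v in _split_multi(row[col.column_name]):
                if v not in allowed:
                    raise IngestionError(
                        f"table {tname}, row {lineno}: value {v!r} not permitted "
                        f"for enumerated column {col.column_name}"
                    )


def _split_multi(raw: str) -> list[str]:
    return [v for v in (s.strip() for s in raw.split("|")) if v]


def _row_to_records(row, concept, plan, model, bundle) -> None:
    cdef = model.concepts[concept]
    id_col = f"{table_name_for_concept(concept)}_id"
    rec = InstanceRecord(concept=concept, instance_local_id=row[id_col])
    embedded: dict[str, InstanceRecord] = {}
    for col in plan:
        raw = row.get(col.column_name, "")
        if raw == "" or raw is None:
            continue
        if col.kind == "link":
            ids = _split_multi(raw)
            rec.links[col.pdef.name] = ids if col.pdef.max_count != 1 else ids[0]
        elif col.kind == "embedded":
            child = embedded.get(col.owner_prop.name)
            if child is None:
                child = InstanceRecord(concept=col.owner_prop.target,
                                       instance_local_id=rec.instance_local_id)
                embedded[col.owner_prop.name] = child
            values = [_coerce(v, col.pdef) for v in _split_multi(raw)]
            if col.pdef.is_shared_identifier:
                child.shared_identifiers[col.pdef.name] = values[0]
            else:
                child.fields[col.pdef.name] = values if col.pdef.max_count != 1 else values[0]
        elif col.kind == "shared":
            rec.shared_identifiers[col.pdef.name] = raw
        else:  # scalar / temporal / value_set field
            values = [_coerce(v, col.pdef) for v in _split_multi(raw)]
            rec.fields[col.pdef.name] = values if col.pdef.max_count != 1 else values[0]
    for prop_name, child in embedded.items():
        bundle.records.append(child)
        pdef = cdef.property(prop_name)
        rec.links[prop_name] = (child.instance_local_id if pdef.max_count == 1
                                else [child.instance_local_id])
    bundle.records.append(rec)


def _attach_subject_links(bundle: PatientBundle, model: ConceptModel) -> None:
    """Subject→core links are implied by the patient-id grouping in tables."""
    subject = model.concepts[model.subject_concept]
    subj_recs = bundle.by_concept(model.subject_concept)
    if not subj_recs:
        raise IngestionError(
            f"patient {bundle.patient_local_id}: no {model.subject_concept} row"
        )
    subj = subj_recs[0]
    for pdef in subject.properties:
        if pdef.range_kind != "concept":
            continue
        ids = sorted(r.instance_local_id for r in bundle.by_concept(pdef.target))
        if not ids:
            continue
        subj.links[pdef.name] = ids if pdef.max_count != 1 else ids[0]


def table_name_for_concept(concept: str) -> str:
    from .artifact_gen import table_name_for
    return table_name_for(concept)


def bundles_to_tables(bundles: list[PatientBundle],
                      model: ConceptModel) -> dict[str, list[dict[str, str]]]:
    """Emit bundles in tabular template form (round-trip inverse of
    :func:`ingest_tabular`)."""
    from .artifact_gen import (gen_tabular_templates, table_name_for,
                               column_plan, column_base, _multi_valued)

    template = gen_tabular_templates(model).template
    tables: dict[str, list[dict[str, str]]] = {
        table_name_for(c): [] for c in model.concepts if model.concepts[c].is_core
    }
    tables.update({st: [] for st in template.side_tables})
    for bundle in bundles:
        for concept in model.concepts:
            if not model.concepts[concept].is_core:
                continue
            plan = column_plan(model, concept)
            for rec in bundle.by_concept(concept):
                row = {c.column_name: "" for c in template.tables[concept]}
                row["patient_id"] = bundle.patient_local_id
                row[f"{table_name_for(concept)}_id"] = rec.instance_local_id
                for col in plan:
                    if col.kind == "link":
                        ids = rec.link_ids(col.pdef.name)
                        row[col.column_name] = "|".join(ids)
                    elif col.kind == "embedded":
                        for cid in rec.link_ids(col.owner_prop.name):
                            child = bundle.find(col.owner_prop.target, cid)
                            if child is None:
                                continue
                            if col.pdef.is_shared_identifier:
                                vals = ([child.shared_identifiers[col.pdef.name]]
                                        if col.pdef.name in child.shared_identifiers else [])
                            else:
                                vals = child.field_values(col.pdef.name)
                            row[col.column_name] = "|".join(str(v) for v in vals)
                    elif col.kind == "shared":
                        row[col.column_name] = rec.shared_identifiers.get(col.pdef.name, "")
                    else:
                        vals = rec.field_values(col.pdef.name)
                        row[col.column_name] = "|".join(
                            str(v).lower() if isinstance(v, bool) else str(v) for v in vals
                        )
                tables[table_name_for(concept)].append(row)
                tname = table_name_for(concept)
                for p in _multi_valued(model, concept):
                    stname = f"{tname}__{column_base(p.name)}"
                    vcol = template.side_tables[stname][-1].column_name
                    values = (rec.link_ids(p.name) if p.range_kind == "concept"
                              else rec.field_values(p.name))
                    for v in values:
                        tables[stname].append({
                            "patient_id": bundle.patient_local_id,
                            f"{tname}_id": rec.instance_local_id,
                            vcol: str(v).lower() if isinstance(v, bool) else str(v),
                        })
    return tables


# ---------------------------------------------------------------------------
# pre-check

def _parse_temporal(value: str, token: str):
    if token == "date":
        return date.fromisoformat(str(value))
    return datetime.fromisoformat(str(value))


def precheck(bundle: PatientBundle, model: ConceptModel) -> list[Finding]:
    """Early formatting checks on a structurally valid bundle.

    Findings cover IRI-unsafe local identifiers (blocking: no IRI can be
    minted), unparseable temporal values (blocking: date shifting would
    corrupt them), and unknown value-set members (non-blocking: reported
    again as SHACL violations downstream so the patient still reaches the
    Release zone with a failing report).
    """
    findings: list[Finding] = []
    ids_to_check = [("", bundle.patient_local_id)]
    for r in bundle.records:
        ids_to_check.append((r.concept, r.instance_local_id))
    for concept, local_id in ids_to_check:
        if not LOCAL_ID_RE.match(local_id or ""):
            findings.append(Finding(
                kind="malformed_id", concept=concept or model.subject_concept,
                instance_id=local_id, prop=None, blocking=True,
                message=(f"local id {local_id!r} is not IRI-safe (allowed: "
                         "unreserved characters A-Za-z0-9._~-; no spaces)"),
            ))
    for r in bundle.records:
        cdef = model.concepts[r.concept]
        for pdef in cdef.properties:
            if pdef.range_kind == "temporal":
                for v in r.field_values(pdef.name):
                    try:
                        _parse_temporal(str(v), pdef.scalar_datatype)
                    except ValueError:
                        findings.append(Finding(
                            kind="bad_datatype", concept=r.concept,
                            instance_id=r.instance_local_id, prop=pdef.name,
                            blocking=True,
                            message=f"unparseable {pdef.scalar_datatype} value {v!r}",
                        ))
            elif pdef.range_kind == "value_set":
                allowed = {str(m) for m in model.value_sets[pdef.target].members}
                for v in r.field_values(pdef.name):
                    if str(v) not in allowed:
                        findings.append(Finding(
                            kind="bad_value_set", concept=r.concept,
                            instance_id=r.instance_local_id, prop=pdef.name,
                            blocking=False,
                            message=f"value {v!r} not in value set {pdef.target}",
                        ))
    return findings
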