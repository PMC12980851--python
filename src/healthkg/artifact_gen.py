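"""Derive the data-facing artifacts from a ConceptModel.

Three artifact families are generated, all from the same model so they stay
mutually consistent:

* a draft-07 JSON Schema for the JSON ingestion route (one object definition
  per core concept, embedded concepts as nested objects);
* tabular templates — one table per core concept — as CSV header rows plus an
  ANSI SQL DDL script (enumerated columns emulated with CHECK constraints);
* a SHACL shapes graph (Turtle) expressing cardinality, datatype, class and
  value-set membership constraints, plus a terminology-membership annotation
  for coded properties.

Generation is deterministic: the same model always yields byte-identical
artifacts (concepts and properties are iterated in model order).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from rdflib import URIRef

from .errors import GenerationError
from .schema_model import ConceptModel, ConceptDef, PropertyDef, DIALECT

SQL_TYPES = {
    "string": "VARCHAR",
    "integer": "INTEGER",
    "decimal": "DECIMAL",
    "boolean": "BOOLEAN",
    "date": "DATE",
    "dateTime": "TIMESTAMP",
}

JSON_TYPES = {
    "string": {"type": "string", "minLength": 1},
    "integer": {"type": "integer"},
    "decimal": {"type": "number"},
    "boolean": {"type": "boolean"},
    "date": {"type": "string", "format": "date",
             "pattern": r"^\d{4}-\d{2}-\d{2}$"},
    "dateTime": {"type": "string", "format": "date-time",
                 "pattern": r"^\d{4}-\d{2}-\d{2}T\d{2}:\d{2}(:\d{2}(\.\d+)?)?$"},
}


def table_name_for(concept: str) -> str:
    """CamelCase concept name -> snake_case table name."""
    return re.sub(r"(?<=[a-z0-9])(?=[A-Z])", "_", concept).lower()


def column_base(prop: str) -> str:
    """Column base name for a property: snake name with a leading has_ stripped."""
    name = prop.lower()
    return name[4:] if name.startswith("has_") else name


@dataclass(frozen=True)
class ColumnSpec:
    column_name: str
    column_type: str
    required: bool
    references: str | None = None  # core concept whose instance ids this column holds


@dataclass(frozen=True)
class PlanColumn:
    """Internal mapping of one model property to its tabular realization."""
    kind: str  # scalar | value_set | link | embedded | shared
    column_name: str
    pdef: PropertyDef
    owner_prop: PropertyDef | None = None  # set for embedded child columns


@dataclass
class TabularTemplate:
    #: one entry per core concept, in model order
    tables: dict[str, list[ColumnSpec]]
    #: side tables for multi-valued scalar/value-set/link properties
    side_tables: dict[str, list[ColumnSpec]]
    #: (concept, property) -> (table name, column name); subject-link
    #: properties map to the patient-id column of the target concept's table
    property_map: dict[tuple[str, str], tuple[str, str]]


@dataclass
class TabularArtifacts:
    template: TabularTemplate
    ddl: str
    csv_headers: dict[str, str]  # table name -> CSV header row


# ---------------------------------------------------------------------------
# JSON Schema

def gen_json_schema(model: ConceptModel) -> dict:
    """Generate the draft-07 JSON Schema for the JSON ingestion template."""
    definitions: dict[str, dict] = {}
    for cname, cdef in model.concepts.items():
        definitions[cname] = _concept_definition(cdef, model)

    record_props = {
        cname: {"type": "array", "items": {"$ref": f"#/definitions/{cname}"}}
        for cname, cdef in model.concepts.items() if cdef.is_core
    }
    record_props[model.subject_concept]["minItems"] = 1
    record_props[model.subject_concept]["maxItems"] = 1

    return {
        "$schema": "http://json-schema.org/draft-07/schema#",
        "title": f"{model.schema_prefix} patient batch",
        "type": "object",
        "required": ["patients"],
        "additionalProperties": False,
        "properties": {
            "patients": {
                "type": "array",
                "items": {
                    "type": "object",
                    "required": ["patient_id", "records"],
                    "additionalProperties": False,
                    "properties": {
                        "patient_id": {"type": "string", "minLength": 1},
                        "records": {
                            "type": "object",
                            "required": [model.subject_concept],
                            "additionalProperties": False,
                            "properties": record_props,
                        },
                    },
                },
            }
        },
        "definitions": definitions,
    }


def _concept_definition(cdef: ConceptDef, model: ConceptModel) -> dict:
    props: dict[str, dict] = {"id": {"type": "string", "minLength": 1}}
    required = [] if not cdef.is_core else ["id"]  # embedded ids default to owner id
    for p in cdef.properties:
        if p.is_shared_identifier:
            item: dict = {"type": "string", "minLength": 1}
        elif p.range_kind in ("scalar", "temporal"):
            item = dict(JSON_TYPES[p.scalar_datatype])
        elif p.range_kind == "value_set":
            item = {"enum": [str(m) for m in model.value_sets[p.target].members]}
        else:  # concept
            if model.concepts[p.target].is_core:
                item = {"type": "string", "minLength": 1}
            else:
                item = {"$ref": f"#/definitions/{p.target}"}
        if p.max_count == 1:
            props[p.name] = item
        else:
            arr: dict = {"type": "array", "items": item, "minItems": max(p.min_count, 0)}
            if p.max_count is not None:
                arr["maxItems"] = p.max_count
            props[p.name] = arr
        if p.min_count >= 1:
            required.append(p.name)
    out: dict = {"type": "object", "additionalProperties": False, "properties": props}
    if required:
        out["required"] = required
    return out


# ---------------------------------------------------------------------------
# tabular templates

def column_plan(model: ConceptModel, concept: str) -> list[PlanColumn]:
    """The ordered property→column realization for one core concept's table.

    Multi-valued scalar/value-set/link properties are excluded here (they get
    side tables); subject-link properties are excluded for the Subject table
    itself (they are realized by the patient-id grouping of the target table).
    """
    cdef = model.concepts[concept]
    is_subject = concept == model.subject_concept
    plan: list[PlanColumn] = []
    for p in cdef.properties:
        if p.is_shared_identifier:
            plan.append(PlanColumn("shared", column_base(p.name), p))
        elif p.range_kind == "concept":
            target = model.concepts[p.target]
            if target.is_core:
                if is_subject:
                    continue  # realized by the target table's patient_id column
                if p.max_count == 1:
                    # reference column named after the linked concept
                    plan.append(PlanColumn("link", table_name_for(p.target) + "_id", p))
            else:
                if p.max_count != 1:
                    raise GenerationError(
                        f"{concept}.{p.name}: embedded concept {p.target} is "
                        "multi-valued; flat tables embed single instances only"
                    )
                prefix = column_base(p.name)
                for child in target.properties:
                    if child.range_kind == "concept":
                        raise GenerationError(
                            f"{concept}.{p.name}: embedded concept {p.target} "
                            f"links further ({child.name}); one level of "
                            "embedding is supported in tabular templates"
                        )
                    if child.max_count != 1:
                        raise GenerationError(
                            f"{p.target}.{child.name}: multi-valued property "
                            "inside an embedded concept is not representable"
                        )
                    kind = "embedded"
                    plan.append(PlanColumn(kind, f"{prefix}_{column_base(child.name)}",
                                           child, owner_prop=p))
        elif p.max_count == 1:
            kind = "value_set" if p.range_kind == "value_set" else "scalar"
            plan.append(PlanColumn(kind, column_base(p.name), p))
        # multi-valued scalars/value sets/links: side tables, handled separately
    return plan


def _multi_valued(model: ConceptModel, concept: str) -> list[PropertyDef]:
    cdef = model.concepts[concept]
    is_subject = concept == model.subject_concept
    out = []
    for p in cdef.properties:
        if p.is_shared_identifier or p.max_count == 1:
            continue
        if p.range_kind == "concept":
            if not model.concepts[p.target].is_core or is_subject:
                continue
        out.append(p)
    return out


def _column_type(p: PropertyDef, model: ConceptModel) -> str:
    if p.is_shared_identifier:
        return "VARCHAR"
    if p.range_kind == "value_set":
        return "VARCHAR"
    if p.range_kind == "concept":
        return "VARCHAR"
    return SQL_TYPES[p.scalar_datatype]


def gen_tabular_templates(model: ConceptModel) -> TabularArtifacts:
    """Generate the tabular template, its SQL DDL, and CSV header rows."""
    tables: dict[str, list[ColumnSpec]] = {}
    side_tables: dict[str, list[ColumnSpec]] = {}
    property_map: dict[tuple[str, str], tuple[str, str]] = {}

    for concept, cdef in model.concepts.items():
        if not cdef.is_core:
            continue
        tname = table_name_for(concept)
        cols: list[ColumnSpec] = [
            ColumnSpec("patient_id", "VARCHAR", required=True),
            ColumnSpec(f"{tname}_id", "VARCHAR", required=True),
        ]
        seen: dict[str, str] = {c.column_name: "(identifier column)" for c in cols}
        for col in column_plan(model, concept):
            path = (f"{concept}.{col.owner_prop.name}.{col.pdef.name}"
                    if col.owner_prop else f"{concept}.{col.pdef.name}")
            if col.column_name in seen:
                raise GenerationError(
                    f"column name collision in table {tname}: {path} and "
                    f"{seen[col.column_name]} both map to {col.column_name!r}"
                )
            seen[col.column_name] = path
            required = col.pdef.min_count >= 1 and (
                col.owner_prop is None or col.owner_prop.min_count >= 1
            )
            references = (col.pdef.target if col.kind == "link" else None)
            cols.append(ColumnSpec(col.column_name, _column_type(col.pdef, model),
                                   required=required, references=references))
            owner = col.owner_prop
            key = (owner.target, col.pdef.name) if owner else (concept, col.pdef.name)
            property_map[key] = (tname, col.column_name)
            if owner and (concept, owner.name) not in property_map:
                property_map[(concept, owner.name)] = (tname, f"{column_base(owner.name)}_*")
        tables[concept] = cols

        for p in _multi_valued(model, concept):
            base = column_base(p.name)
            stname = f"{tname}__{base}"
            if stname in side_tables:
                raise GenerationError(
                    f"side-table name collision: {concept}.{p.name} maps to "
                    f"{stname!r} which is already taken")
            vcol = (table_name_for(p.target) + "_id"
                    if p.range_kind == "concept" else base)
            side_tables[stname] = [
                ColumnSpec("patient_id", "VARCHAR", required=True),
                ColumnSpec(f"{tname}_id", "VARCHAR", required=True),
                ColumnSpec(vcol, _column_type(p, model), required=True,
                           references=p.target if p.range_kind == "concept" else None),
            ]
            property_map[(concept, p.name)] = (stname, vcol)

    # subject-link properties are realized by the target table's patient id
    subject = model.concepts[model.subject_concept]
    for p in subject.properties:
        if p.range_kind == "concept" and model.concepts[p.target].is_core:
            property_map[(model.subject_concept, p.name)] = (
                table_name_for(p.target), "patient_id")

    template = TabularTemplate(tables=tables, side_tables=side_tables,
                               property_map=property_map)
    return TabularArtifacts(
        template=template,
        ddl=_render_ddl(template, model),
        csv_headers=_render_headers(template),
    )


def _check_clause(col: ColumnSpec, pdef: PropertyDef | None,
                  model: ConceptModel) -> str:
    if pdef is not None and pdef.range_kind == "value_set":
        members = ", ".join(
            "'" + str(m).replace("'", "''") + "'"
            for m in model.value_sets[pdef.target].members
        )
        return f" CHECK ({col.column_name} IN ({members}))"
    return ""


def _render_ddl(template: TabularTemplate, model: ConceptModel) -> str:
    lines: list[str] = ["-- generated from the schema model; do not edit", ""]

    def emit(tname: str, cols: list[ColumnSpec], concept: str | None) -> None:
        lines.append(f"CREATE TABLE {tname} (")
        body = []
        plan = {c.column_name: c for c in
                (column_plan(model, concept) if concept else [])}
        for col in cols:
            pdef = plan[col.column_name].pdef if col.column_name in plan else None
            entry = f"    {col.column_name} {col.column_type}"
            entry += _check_clause(col, pdef, model)
            if col.required:
                entry += " NOT NULL"
            if col.references is not None:
                ref_t = table_name_for(col.references)
                entry += f" REFERENCES {ref_t} ({ref_t}_id)"
            body.append(entry)
        lines.append(",\n".join(body))
        lines.append(");")
        lines.append("")

    for concept, cols in template.tables.items():
        emit(table_name_for(concept), cols, concept)
    for stname, cols in template.side_tables.items():
        concept = next(c for c in template.tables
                       if table_name_for(c) == stname.split("__")[0])
        lines.append(f"CREATE TABLE {stname} (")
        body = []
        mv = {(table_name_for(p.target) + "_id" if p.range_kind == "concept"
               else column_base(p.name)): p
              for p in _multi_valued(model, concept)}
        for col in cols:
            pdef = mv.get(col.column_name)
            entry = f"    {col.column_name} {col.column_type}"
            entry += _check_clause(col, pdef, model)
            if col.required:
                entry += " NOT NULL"
            if col.references is not None:
                ref_t = table_name_for(col.references)
                entry += f" REFERENCES {ref_t} ({ref_t}_id)"
            body.append(entry)
        lines.append(",\n".join(body))
        lines.append(");")
        lines.append("")
    return "\n".join(lines)


def _render_headers(template: TabularTemplate) -> dict[str, str]:
    headers = {}
    for concept, cols in template.tables.items():
        headers[table_name_for(concept)] = ",".join(c.column_name for c in cols)
    for stname, cols in template.side_tables.items():
        headers[stname] = ",".join(c.column_name for c in cols)
    return headers


# ---------------------------------------------------------------------------
# SHACL shapes

SH = "http://www.w3.org/ns/shacl#"


def gen_shacl(model: ConceptModel) -> str:
    """Generate the SHACL shapes graph (Turtle) for the model.

    One node shape per concept targeting its class IRI; one property shape per
    property carrying min/max-count, datatype, class or in-list constraints.
    Coded properties (value sets whose members are IRIs) additionally carry a
    ``dialect:terminologyCheck`` marker telling the validator to verify the
    code against the loaded terminology graphs.  The shapes graph embeds the
    model digest so validation can refuse shapes from a stale model version.
    """
    ns = model.namespace
    out = [
        f"@prefix : <{ns}> .",
        f"@prefix sh: <{SH}> .",
        f"@prefix dialect: <{DIALECT}> .",
        "@prefix xsd: <http://www.w3.org/2001/XMLSchema#> .",
        "",
        f":shapesManifest a dialect:ShapesManifest ;",
        f'    dialect:modelDigest "{model.digest()}" .',
        "",
    ]
    for cname, cdef in model.concepts.items():
        head = f":{cname}Shape a sh:NodeShape ;\n    sh:targetClass :{cname}"
        pshapes = []
        for p in cdef.properties:
            parts = [f"sh:path :{p.name}", f"sh:minCount {p.min_count}"]
            if p.max_count is not None:
                parts.append(f"sh:maxCount {p.max_count}")
            if p.is_shared_identifier:
                pass  # shared identifiers are free-form (IRI or literal)
            elif p.range_kind in ("scalar", "temporal"):
                parts.append(f"sh:datatype xsd:{p.scalar_datatype}")
            elif p.range_kind == "concept":
                parts.append(f"sh:class :{p.target}")
            else:
                vs = model.value_sets[p.target]
                members = " ".join(
                    f"<{m}>" if isinstance(m, URIRef)
                    else '"' + str(m).replace('"', '\\"') + '"'
                    for m in vs.members
                )
                parts.append(f"sh:in ( {members} )")
                if vs.is_coded:
                    parts.append("dialect:terminologyCheck true")
            pshapes.append("    sh:property [ " + " ; ".join(parts) + " ]")
        if pshapes:
            head += " ;\n" + " ;\n".join(pshapes)
        out.append(head + " .")
        out.append("")
    return "\n".join(out)
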