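"""Parse an RDF schema document into an internal concept model.

The schema dialect is a small, self-contained OWL-style vocabulary:

* concepts are ``owl:Class`` declarations in the schema namespace;
* properties are ``owl:DatatypeProperty`` / ``owl:ObjectProperty`` with
  ``rdfs:domain`` and ``rdfs:range``; ranges are XSD datatypes (scalar or
  temporal), value-set classes, or concept classes;
* cardinalities are ``owl:Restriction`` nodes attached to the domain class
  via ``rdfs:subClassOf`` (``owl:minCardinality`` / ``owl:maxCardinality``);
* value sets are classes flagged ``dialect:isValueSet`` whose permitted
  members are given as an ``owl:oneOf`` RDF list (IRIs or literals);
* the one patient-root class is flagged ``dialect:isSubjectClass``;
* ``dialect:order`` gives each property an explicit position — an RDF graph
  is a statement *set*, so textual declaration order is not recoverable and
  the dialect makes ordering explicit instead (ties break lexicographically);
* ``dialect:startEndPair`` declares (start, end) temporal property pairs for
  the event-ordering logic check;
* ``dialect:isSharedIdentifier`` marks a property whose values are
  externally agreed identifiers, exempt from IRI minting.

The parsed :class:`ConceptModel` is the single source of truth for every
downstream artifact (JSON Schema, tabular templates, SHACL shapes) and for
the transformation itself.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

from rdflib import BNode, Graph, Literal, Namespace, RDF, RDFS, OWL, URIRef, XSD
from rdflib.collection import Collection

from .errors import SchemaConfigError, SchemaParseError

#: Annotation vocabulary of the schema dialect (fixed constants of the tool).
DIALECT = Namespace("https://w3id.org/healthkg/dialect#")

#: Datatype tokens accepted for scalar/temporal properties, mapped to XSD.
XSD_BY_TOKEN: dict[str, URIRef] = {
    "string": XSD.string,
    "integer": XSD.integer,
    "decimal": XSD.decimal,
    "boolean": XSD.boolean,
    "date": XSD.date,
    "dateTime": XSD.dateTime,
}
TOKEN_BY_XSD = {v: k for k, v in XSD_BY_TOKEN.items()}
TEMPORAL_TOKENS = frozenset({"date", "dateTime"})

UNBOUNDED = None  # max_count sentinel


@dataclass(frozen=True)
class PropertyDef:
    name: str
    range_kind: str  # scalar | temporal | value_set | concept
    scalar_datatype: str | None = None
    target: str | None = None
    min_count: int = 0
    max_count: int | None = 1
    is_shared_identifier: bool = False
    order: int = 0

    def __post_init__(self) -> None:
        if self.range_kind in ("scalar", "temporal"):
            if self.scalar_datatype not in XSD_BY_TOKEN:
                raise SchemaParseError(
                    f"property {self.name!r}: unknown datatype {self.scalar_datatype!r}"
                )
            if self.target is not None:
                raise SchemaParseError(f"property {self.name!r}: target set on a {self.range_kind}")
        elif self.range_kind in ("value_set", "concept"):
            if not self.target:
                raise SchemaParseError(f"property {self.name!r}: {self.range_kind} needs a target")
        else:
            raise SchemaParseError(f"property {self.name!r}: bad range_kind {self.range_kind!r}")
        if self.max_count is not None and self.min_count > self.max_count:
            raise SchemaParseError(
                f"property {self.name!r}: min_count {self.min_count} > max_count {self.max_count}"
            )
        if self.min_count < 0:
            raise SchemaParseError(f"property {self.name!r}: negative min_count")

    @property
    def datatype_iri(self) -> URIRef | None:
        return XSD_BY_TOKEN[self.scalar_datatype] if self.scalar_datatype else None


@dataclass
class ConceptDef:
    name: str
    is_core: bool = False
    properties: list[PropertyDef] = field(default_factory=list)
    #: (start_property, end_property) pairs for the temporal logic check
    start_end_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [p.name for p in self.properties]
        if len(names) != len(set(names)):
            raise SchemaParseError(f"concept {self.name!r}: duplicate property names")

    def property(self, name: str) -> PropertyDef:
        for p in self.properties:
            if p.name == name:
                return p
        raise KeyError(name)


@dataclass
class ValueSetDef:
    name: str
    #: permitted members, in declared order; URIRef for code IRIs, str for code strings
    members: tuple[URIRef | str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise SchemaParseError(f"value set {self.name!r}: empty member list")
        if len(set(self.members)) != len(self.members):
            raise SchemaParseError(f"value set {self.name!r}: duplicate members")

    @property
    def is_coded(self) -> bool:
        """True when members are IRIs (codes from a terminology)."""
        return all(isinstance(m, URIRef) for m in self.members)


@dataclass
class ConceptModel:
    schema_prefix: str
    namespace: str
    concepts: dict[str, ConceptDef]
    value_sets: dict[str, ValueSetDef]
    subject_concept: str

    def __post_init__(self) -> None:
        if self.subject_concept not in self.concepts:
            raise SchemaConfigError(f"subject concept {self.subject_concept!r} not declared")
        for c in self.concepts.values():
            for p in c.properties:
                if p.range_kind == "concept" and p.target not in self.concepts:
                    raise SchemaParseError(
                        f"property {c.name}.{p.name}: dangling concept range {p.target!r}"
                    )
                if p.range_kind == "value_set" and p.target not in self.value_sets:
                    raise SchemaParseError(
                        f"property {c.name}.{p.name}: dangling value-set range {p.target!r}"
                    )

    def class_iri(self, concept: str) -> URIRef:
        return URIRef(self.namespace + concept)

    def property_iri(self, prop: str) -> URIRef:
        return URIRef(self.namespace + prop)

    def core_concepts(self) -> set[str]:
        return {name for name, c in self.concepts.items() if c.is_core}

    def digest(self) -> str:
        """Stable content hash, used to pin shapes to a model version."""
        return hashlib.sha256(serialize_schema(self).encode()).hexdigest()


# ---------------------------------------------------------------------------
# parsing

def _local(ns: str, iri: URIRef) -> str:
    return str(iri)[len(ns):]


def parse_schema(schema_doc: str) -> ConceptModel:
    """Parse a Turtle schema document in the dialect into a ConceptModel.

    Raises :class:`SchemaParseError` for malformed RDF or dialect breaches and
    :class:`SchemaConfigError` when no (or more than one) Subject class is
    marked.  Property order is the ``dialect:order`` annotation with
    lexicographic tie-break, so parsing is stable under statement reordering.
    """
    g = Graph()
    try:
        g.parse(data=schema_doc, format="turtle")
    except Exception as exc:  # rdflib raises BadSyntax with line info in str()
        raise SchemaParseError(f"malformed RDF schema: {exc}") from exc

    prefixes = list(g.objects(None, DIALECT.schemaPrefix))
    if len(prefixes) != 1:
        raise SchemaConfigError(
            f"expected exactly one dialect:schemaPrefix declaration, found {len(prefixes)}"
        )
    schema_prefix = str(prefixes[0])
    onto = next(g.subjects(DIALECT.schemaPrefix, prefixes[0]))
    namespace = str(onto)
    if not namespace.endswith(("#", "/")):
        namespace += "#"

    value_set_iris = {s for s in g.subjects(DIALECT.isValueSet, Literal(True)) if isinstance(s, URIRef)}
    concept_iris = {
        s
        for s in g.subjects(RDF.type, OWL.Class)
        if isinstance(s, URIRef) and s not in value_set_iris
    }

    subject_iris = [s for s in g.subjects(DIALECT.isSubjectClass, Literal(True))]
    if len(subject_iris) != 1:
        raise SchemaConfigError(
            f"schema must mark exactly one Subject class; found {len(subject_iris)}"
        )
    subject_iri = subject_iris[0]
    if subject_iri not in concept_iris:
        raise SchemaConfigError("the marked Subject class is not a declared concept")

    value_sets: dict[str, ValueSetDef] = {}
    for vs_iri in sorted(value_set_iris):
        name = _local(namespace, vs_iri)
        list_head = g.value(vs_iri, OWL.oneOf)
        if list_head is None:
            raise SchemaParseError(f"value set {name!r}: missing owl:oneOf member list")
        members: list[URIRef | str] = []
        for item in Collection(g, list_head):
            members.append(item if isinstance(item, URIRef) else str(item))
        value_sets[name] = ValueSetDef(name=name, members=tuple(members))

    # cardinality restrictions attached to each domain class
    card: dict[tuple[URIRef, URIRef], tuple[int, int | None]] = {}
    for cls in concept_iris:
        for restr in g.objects(cls, RDFS.subClassOf):
            if not isinstance(restr, BNode):
                continue
            prop = g.value(restr, OWL.onProperty)
            if prop is None:
                continue
            lo = g.value(restr, OWL.minCardinality)
            hi = g.value(restr, OWL.maxCardinality)
            card[(cls, prop)] = (
                int(lo) if lo is not None else 0,
                int(hi) if hi is not None else UNBOUNDED,
            )

    concepts: dict[str, ConceptDef] = {}
    props_by_domain: dict[URIRef, list[PropertyDef]] = {c: [] for c in concept_iris}
    prop_iris = set(g.subjects(RDF.type, OWL.DatatypeProperty)) | set(
        g.subjects(RDF.type, OWL.ObjectProperty)
    )
    for p_iri in prop_iris:
        domain = g.value(p_iri, RDFS.domain)
        rng = g.value(p_iri, RDFS.range)
        if domain is None or rng is None:
            raise SchemaParseError(f"property <{p_iri}>: missing rdfs:domain or rdfs:range")
        if domain not in concept_iris:
            raise SchemaParseError(f"property <{p_iri}>: domain <{domain}> is not a concept")
        pname = _local(namespace, p_iri)
        lo, hi = card.get((domain, p_iri), (0, UNBOUNDED))
        order_lit = g.value(p_iri, DIALECT.order)
        order = int(order_lit) if order_lit is not None else 0
        shared = g.value(p_iri, DIALECT.isSharedIdentifier) == Literal(True)
        if rng in TOKEN_BY_XSD:
            token = TOKEN_BY_XSD[rng]
            kind = "temporal" if token in TEMPORAL_TOKENS else "scalar"
            pdef = PropertyDef(pname, kind, scalar_datatype=token, min_count=lo,
                               max_count=hi, is_shared_identifier=shared, order=order)
        elif rng in value_set_iris:
            pdef = PropertyDef(pname, "value_set", target=_local(namespace, rng),
                               min_count=lo, max_count=hi, order=order)
        elif rng in concept_iris:
            pdef = PropertyDef(pname, "concept", target=_local(namespace, rng),
                               min_count=lo, max_count=hi, order=order)
        else:
            raise SchemaParseError(
                f"property {pname!r}: range <{rng}> is neither a datatype, "
                "a declared value set, nor a declared concept"
            )
        props_by_domain[domain].append(pdef)

    for c_iri in sorted(concept_iris):
        cname = _local(namespace, c_iri)
        props = sorted(props_by_domain[c_iri], key=lambda p: (p.order, p.name))
        pairs: list[tuple[str, str]] = []
        for pair_node in g.objects(c_iri, DIALECT.startEndPair):
            start = g.value(pair_node, DIALECT.startProperty)
            end = g.value(pair_node, DIALECT.endProperty)
            if start is None or end is None:
                raise SchemaParseError(f"concept {cname!r}: incomplete start/end pair")
            pairs.append((_local(namespace, start), _local(namespace, end)))
        concepts[cname] = ConceptDef(name=cname, properties=props,
                                     start_end_pairs=sorted(pairs))

    model = ConceptModel(
        schema_prefix=schema_prefix,
        namespace=namespace,
        concepts=dict(sorted(concepts.items())),
        value_sets=value_sets,
        subject_concept=_local(namespace, subject_iri),
    )
    core = identify_core_concepts(model)
    for name, c in model.concepts.items():
        c.is_core = name in core
    return model


def identify_core_concepts(model: ConceptModel) -> set[str]:
    """Concepts directly linked to the patient: the Subject class itself plus
    every concept that is the range of a Subject-domain property (one hop)."""
    core = {model.subject_concept}
    subject = model.concepts[model.subject_concept]
    for p in subject.properties:
        if p.range_kind == "concept":
            core.add(p.target)
    return core


# ---------------------------------------------------------------------------
# serialization (round-trip support; also used for the model digest)

def serialize_schema(model: ConceptModel) -> str:
    """Emit the model back as a dialect Turtle document.

    Deterministic: concepts, properties and value sets are emitted in model
    order, so regeneration is byte-identical and
    ``parse_schema(serialize_schema(parse_schema(doc)))`` is a fixed point.
    """
    ns = model.namespace
    lines = [
        f"@prefix : <{ns}> .",
        f"@prefix dialect: <{DIALECT}> .",
        "@prefix owl: <http://www.w3.org/2002/07/owl#> .",
        "@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .",
        "@prefix xsd: <http://www.w3.org/2001/XMLSchema#> .",
        "",
        f"<{ns.rstrip('#/')}> dialect:schemaPrefix \"{model.schema_prefix}\" .",
        "",
    ]

    def term(member: URIRef | str) -> str:
        if isinstance(member, URIRef):
            return f"<{member}>"
        return '"' + str(member).replace('"', '\\"') + '"'

    for vs in model.value_sets.values():
        members = " ".join(term(m) for m in vs.members)
        lines += [
            f":{vs.name} a owl:Class ;",
            "    dialect:isValueSet true ;",
            f"    owl:oneOf ( {members} ) .",
            "",
        ]

    for c in model.concepts.values():
        head = f":{c.name} a owl:Class"
        if c.name == model.subject_concept:
            head += " ;\n    dialect:isSubjectClass true"
        restrictions = []
        for p in c.properties:
            parts = [f"owl:onProperty :{p.name}", f"owl:minCardinality {p.min_count}"]
            if p.max_count is not None:
                parts.append(f"owl:maxCardinality {p.max_count}")
            restrictions.append(
                "    rdfs:subClassOf [ a owl:Restriction ; " + " ; ".join(parts) + " ]"
            )
        if restrictions:
            head += " ;\n" + " ;\n".join(restrictions)
        for start, end in c.start_end_pairs:
            head += (
                " ;\n    dialect:startEndPair [ "
                f"dialect:startProperty :{start} ; dialect:endProperty :{end} ]"
            )
        lines += [head + " .", ""]
        for p in c.properties:
            if p.range_kind in ("scalar", "temporal"):
                ptype, rng = "owl:DatatypeProperty", f"xsd:{p.scalar_datatype}"
            else:
                ptype, rng = "owl:ObjectProperty", f":{p.target}"
            plines = [
                f":{p.name} a {ptype} ;",
                f"    rdfs:domain :{c.name} ;",
                f"    rdfs:range {rng} ;",
                f"    dialect:order {p.order}",
            ]
            if p.is_shared_identifier:
                plines.append("    dialect:isSharedIdentifier true")
            lines += [" ;\n".join(plines) + " .", ""]

    return "\n".join(lines)
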