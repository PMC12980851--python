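"""Mint IRIs and transform patient bundles into per-patient named graphs.

Every data instance gets a four-part IRI::

    <base>/<provider_uid>/<schema_prefix>/<ClassName>/<local_id>

The first three parts are supplied by the system; only the local identifier
comes from the data provider.  Distinct provider UIDs therefore guarantee
globally collision-free IRIs when graphs from several institutions are
merged.  Each patient's statements live in exactly one named graph whose IRI
is minted like an instance IRI of the Subject class, so the graph name
inherits the same collision-free scheme.  No blank nodes are emitted.

Serialization supports TriG and N-Quads (carrying the graph component) and
Turtle for single-graph exports.  Output is deterministic: statements are
sorted, so regeneration is byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from rdflib import Dataset, Graph, Literal, RDF, URIRef

# ill-typed literals are deliberate (they carry datatype violations through to
# validation); rdflib logs a stack trace for each unless quieted
logging.getLogger("rdflib.term").setLevel(logging.ERROR)

from .errors import MintingError, SerializationError, TransformationError
from .ingest import LOCAL_ID_RE, PatientBundle
from .schema_model import ConceptModel

#: default base of the IRI convention; any fixed resolvable prefix works
DEFAULT_BASE = "https://example.org/healthkg/resource"

Quad = tuple[URIRef, URIRef, "URIRef | Literal", URIRef]


@dataclass(frozen=True)
class IriPolicy:
    provider_uid: str
    schema_prefix: str
    base: str = DEFAULT_BASE

    def __post_init__(self) -> None:
        for part, label in ((self.provider_uid, "provider_uid"),
                            (self.schema_prefix, "schema_prefix")):
            if not LOCAL_ID_RE.match(part or ""):
                raise MintingError(f"{label} {part!r} contains IRI-unsafe characters")


@dataclass
class QuadSet:
    quads: set[Quad] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.quads)

    def graphs(self) -> set[URIRef]:
        return {g for *_, g in self.quads}

    def graph_quads(self, graph_iri: URIRef) -> "QuadSet":
        return QuadSet({q for q in self.quads if q[3] == graph_iri})

    def union(self, other: "QuadSet") -> "QuadSet":
        return QuadSet(self.quads | other.quads)

    def to_dataset(self) -> Dataset:
        ds = Dataset()
        for s, p, o, g in self.quads:
            ds.add((s, p, o, g))
        return ds

    def as_graph(self) -> Graph:
        """All quads collapsed into one plain graph (for SHACL evaluation)."""
        g = Graph()
        for s, p, o, _ in self.quads:
            g.add((s, p, o))
        return g


def mint_iri(policy: IriPolicy, class_name: str, local_id: str) -> URIRef:
    """Mint the four-part instance IRI; rejects IRI-unsafe local ids."""
    if not LOCAL_ID_RE.match(local_id or ""):
        raise MintingError(
            f"local id {local_id!r} contains whitespace or forbidden characters; "
            "allowed: A-Za-z0-9._~-")
    return URIRef(f"{policy.base}/{policy.provider_uid}/{policy.schema_prefix}"
                  f"/{class_name}/{local_id}")


def patient_graph_iri(policy: IriPolicy, model: ConceptModel,
                      patient_local_id: str) -> URIRef:
    """Graph IRI of a patient: an instance IRI of the Subject class."""
    return mint_iri(policy, model.subject_concept, patient_local_id)


def _literal(value: object, pdef) -> Literal:
    if isinstance(value, bool):
        return Literal(value)
    return Literal(str(value), datatype=pdef.datatype_iri)


def _shared_term(value: str) -> "URIRef | Literal":
    """Shared identifiers are emitted verbatim: absolute IRIs as IRIs,
    anything else as a plain literal."""
    if "://" in value:
        return URIRef(value)
    return Literal(value)


def bundle_to_quads(bundle: PatientBundle, model: ConceptModel,
                    policy: IriPolicy) -> QuadSet:
    """Transform one bundle into its named graph.

    Per record: one ``rdf:type`` statement, one typed-literal statement per
    populated field value, one object statement per link (to the minted IRI
    of the linked instance) and one verbatim statement per shared identifier.
    A link to an instance absent from the bundle fails the whole patient.
    """
    quads: set[Quad] = set()
    if not bundle.records:
        return QuadSet(quads)
    g = patient_graph_iri(policy, model, bundle.patient_local_id)
    for rec in bundle.records:
        cdef = model.concepts[rec.concept]
        subj = mint_iri(policy, rec.concept, rec.instance_local_id)
        quads.add((subj, RDF.type, model.class_iri(rec.concept), g))
        for pdef in cdef.properties:
            pred = model.property_iri(pdef.name)
            if pdef.name in rec.shared_identifiers:
                quads.add((subj, pred, _shared_term(rec.shared_identifiers[pdef.name]), g))
                continue
            for value in rec.field_values(pdef.name):
                if pdef.range_kind == "value_set":
                    vs = model.value_sets[pdef.target]
                    obj = URIRef(str(value)) if vs.is_coded else Literal(str(value))
                else:
                    obj = _literal(value, pdef)
                quads.add((subj, pred, obj, g))
            for target_id in rec.link_ids(pdef.name):
                if bundle.find(pdef.target, target_id) is None:
                    raise TransformationError(
                        f"patient {bundle.patient_local_id}: {rec.concept} "
                        f"{rec.instance_local_id!r} links {pdef.name} to missing "
                        f"{pdef.target} instance {target_id!r}")
                quads.add((subj, pred, mint_iri(policy, pdef.target, target_id), g))
    return QuadSet(quads)


def expected_triple_count(bundle: PatientBundle) -> int:
    """Closed-form statement count for a transformed bundle:
    records + Σ field values + Σ links + Σ shared identifiers."""
    n = 0
    for rec in bundle.records:
        n += 1  # type statement
        for v in rec.fields.values():
            n += len(v) if isinstance(v, list) else 1
        for v in rec.links.values():
            n += len(v) if isinstance(v, list) else 1
        n += len(rec.shared_identifiers)
    return n


# ---------------------------------------------------------------------------
# serialization

FORMATS = ("trig", "nquads", "turtle")


def _nq_term(t) -> str:
    return t.n3()


def serialize_quads(quads: QuadSet, format: str = "trig") -> bytes:
    """Serialize to TriG, N-Quads or (single-graph only) Turtle.

    Statements are emitted in sorted order so output is deterministic;
    TriG/N-Quads output re-parses to an equal quad set.
    """
    if format not in FORMATS:
        raise SerializationError(
            f"unsupported format {format!r}; supported: {', '.join(FORMATS)}")
    lines: list[str] = []
    if format == "nquads":
        for s, p, o, g in sorted(quads.quads, key=lambda q: tuple(t.n3() for t in q)):
            lines.append(f"{_nq_term(s)} {_nq_term(p)} {_nq_term(o)} {_nq_term(g)} .")
        return ("\n".join(lines) + ("\n" if lines else "")).encode()
    if format == "turtle":
        graphs = quads.graphs()
        if len(graphs) > 1:
            raise SerializationError(
                "turtle carries no graph component; export a single patient "
                "graph or choose trig/nquads")
        for s, p, o, _ in sorted(quads.quads, key=lambda q: tuple(t.n3() for t in q)):
            lines.append(f"{_nq_term(s)} {_nq_term(p)} {_nq_term(o)} .")
        return ("\n".join(lines) + ("\n" if lines else "")).encode()
    # trig
    by_graph: dict[URIRef, list[Quad]] = {}
    for q in sorted(quads.quads, key=lambda q: tuple(t.n3() for t in q)):
        by_graph.setdefault(q[3], []).append(q)
    for g in sorted(by_graph):
        lines.append(f"{_nq_term(g)} {{")
        for s, p, o, _ in by_graph[g]:
            lines.append(f"    {_nq_term(s)} {_nq_term(p)} {_nq_term(o)} .")
        lines.append("}")
    return ("\n".join(lines) + ("\n" if lines else "")).encode()


def parse_quads(data: bytes, format: str) -> QuadSet:
    """Parse TriG or N-Quads bytes back into a QuadSet."""
    if format not in ("trig", "nquads"):
        raise SerializationError(f"cannot parse quad format {format!r}")
    ds = Dataset()
    ds.parse(data=data.decode(), format=format)
    quads: set[Quad] = set()
    for s, p, o, g in ds.quads((None, None, None, None)):
        gid = g.identifier if hasattr(g, "identifier") else g
        quads.add((s, p, o, URIRef(str(gid))))
    return QuadSet(quads)


def file_extension(format: str) -> str:
    return {"trig": ".trig", "nquads": ".nq", "turtle": ".ttl"}[format]
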