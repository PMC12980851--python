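"""Validate patient graphs against SHACL shapes, terminologies and the
temporal logic check, and compute completeness statistics.

The validator interprets the constraint vocabulary the shape generator emits
(``sh:minCount``, ``sh:maxCount``, ``sh:datatype``, ``sh:class``, ``sh:in``,
plus the ``dialect:terminologyCheck`` marker).  It reads the *shapes graph*,
not the concept model, so hand-written shape documents validate through the
identical code path — the test suite compares verdicts of generated and
hand-written shapes on the same corpora.

Validation asserts schema integrity only, never clinical correctness: a
physiologically absurd but schema-valid value (a systolic blood pressure of
300) yields no finding.  The single semantic rule beyond the schema is the
event-ordering check: an instance whose declared start property is strictly
after its end property is a Violation (equality passes — same-day admission
and discharge are routine).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdflib import Graph, Literal, RDF, URIRef, XSD
from rdflib.collection import Collection
from rdflib.namespace import SH

from .errors import ValidationSetupError
from .rdfize import QuadSet
from .schema_model import ConceptModel, DIALECT

SEV_VIOLATION = "Violation"
SEV_WARNING = "Warning"

#: constraint kinds share the pipeline-wide violation taxonomy
KIND_MIN = "missing_mandatory"
KIND_MAX = "too_many_values"
KIND_DATATYPE = "bad_datatype"
KIND_CLASS = "bad_link_class"
KIND_IN = "bad_value_set"
KIND_TERMINOLOGY = "unknown_code"
KIND_LOGIC = "start_after_end"


@dataclass(frozen=True)
class ReportFinding:
    severity: str
    constraint_kind: str
    focus_node: str
    property: str | None
    message: str


@dataclass
class ValidationReport:
    patient_id: str
    findings: list[ReportFinding] = field(default_factory=list)
    completeness: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def conforms(self) -> bool:
        return not any(f.severity == SEV_VIOLATION for f in self.findings)

    def add(self, findings: list[ReportFinding]) -> None:
        self.findings.extend(findings)

    def to_json_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "conforms": self.conforms,
            "findings": [
                {"severity": f.severity, "constraint_kind": f.constraint_kind,
                 "focus_node": f.focus_node, "property": f.property,
                 "message": f.message}
                for f in self.findings
            ],
            "completeness": {f"{c}.{p}": n for (c, p), n in
                             sorted(self.completeness.items())},
        }

    def to_text(self) -> str:
        lines = [f"patient {self.patient_id}: "
                 f"{'conforms' if self.conforms else 'DOES NOT CONFORM'}"]
        for f in self.findings:
            prop = f" [{f.property}]" if f.property else ""
            lines.append(f"  {f.severity} {f.constraint_kind}{prop} "
                         f"on <{f.focus_node}>: {f.message}")
        return "\n".join(lines)


def _local_name(iri: URIRef) -> str:
    s = str(iri)
    return s.rsplit("#", 1)[-1].rsplit("/", 1)[-1]


def _terminology_codes(terminologies: list[Graph]) -> set[URIRef]:
    codes: set[URIRef] = set()
    for t in terminologies:
        codes.update(s for s in t.subjects() if isinstance(s, URIRef))
    return codes


def _datatype_matches(value, expected: URIRef) -> bool:
    if not isinstance(value, Literal):
        return False
    actual = value.datatype or XSD.string  # RDF 1.1: plain literal == xsd:string
    if actual != expected:
        return False
    return value.ill_typed is not True


def shacl_validate(quads: QuadSet, shapes: str | Graph,
                   terminologies: list[Graph] | None = None,
                   model: ConceptModel | None = None) -> ValidationReport:
    """Validate a patient QuadSet against a SHACL shapes document.

    ``terminologies`` are RDF graphs whose subjects enumerate currently valid
    code IRIs; a coded value permitted by the schema value set but absent
    from every loaded terminology is reported as an outdated/unknown code.
    When ``model`` is given its digest is compared with the one embedded in
    the shapes graph and a mismatch is a hard error (stale artifacts).
    """
    sg = shapes if isinstance(shapes, Graph) else Graph().parse(
        data=shapes, format="turtle")

    if model is not None:
        embedded = next(sg.objects(None, DIALECT.modelDigest), None)
        if embedded is not None and str(embedded) != model.digest():
            raise ValidationSetupError(
                "shapes graph was generated from a different schema model "
                "version; regenerate artifacts before validating")

    data = quads.as_graph()
    graphs = quads.graphs()
    patient_id = _local_name(sorted(graphs)[0]) if graphs else ""
    codes = _terminology_codes(terminologies or [])
    findings: list[ReportFinding] = []

    for shape in sorted(sg.subjects(RDF.type, SH.NodeShape)):
        target = sg.value(shape, SH.targetClass)
        if target is None:
            continue
        focus_nodes = sorted(data.subjects(RDF.type, target), key=str)
        pshapes = sorted(sg.objects(shape, SH.property),
                         key=lambda b: str(sg.value(b, SH.path)))
        for focus in focus_nodes:
            for ps in pshapes:
                path = sg.value(ps, SH.path)
                pname = _local_name(path)
                values = sorted(data.objects(focus, path), key=lambda t: t.n3())
                min_count = sg.value(ps, SH.minCount)
                max_count = sg.value(ps, SH.maxCount)
                datatype = sg.value(ps, SH.datatype)
                klass = sg.value(ps, SH["class"])
                in_list = sg.value(ps, SH["in"])
                term_check = sg.value(ps, DIALECT.terminologyCheck) == Literal(True)

                if min_count is not None and len(values) < int(min_count):
                    findings.append(ReportFinding(
                        SEV_VIOLATION, KIND_MIN, str(focus), pname,
                        f"{len(values)} value(s), minimum {int(min_count)}"))
                if max_count is not None and len(values) > int(max_count):
                    findings.append(ReportFinding(
                        SEV_VIOLATION, KIND_MAX, str(focus), pname,
                        f"{len(values)} value(s), maximum {int(max_count)}"))
                if datatype is not None:
                    for v in values:
                        if not _datatype_matches(v, datatype):
                            findings.append(ReportFinding(
                                SEV_VIOLATION, KIND_DATATYPE, str(focus), pname,
                                f"value {v.n3()} is not a valid "
                                f"{_local_name(datatype)} literal"))
                if klass is not None:
                    for v in values:
                        if not isinstance(v, URIRef) or (v, RDF.type, klass) not in data:
                            findings.append(ReportFinding(
                                SEV_VIOLATION, KIND_CLASS, str(focus), pname,
                                f"value {v.n3()} is not an instance of "
                                f"{_local_name(klass)}"))
                if in_list is not None:
                    allowed = list(Collection(sg, in_list))
                    for v in values:
                        if v not in allowed:
                            findings.append(ReportFinding(
                                SEV_VIOLATION, KIND_IN, str(focus), pname,
                                f"value {v.n3()} is not a permitted member"))
                        elif term_check and isinstance(v, URIRef) and v not in codes:
                            findings.append(ReportFinding(
                                SEV_VIOLATION, KIND_TERMINOLOGY, str(focus), pname,
                                f"code {v.n3()} is absent from the loaded "
                                "terminologies (outdated or unknown code)"))
                elif term_check:
                    for v in values:
                        if isinstance(v, URIRef) and v not in codes:
                            findings.append(ReportFinding(
                                SEV_VIOLATION, KIND_TERMINOLOGY, str(focus), pname,
                                f"code {v.n3()} is absent from the loaded "
                                "terminologies (outdated or unknown code)"))

    report = ValidationReport(patient_id=patient_id, findings=findings)
    if model is not None:
        report.completeness = completeness_stats(quads, model)
    return report


def logic_check_dates(quads: QuadSet, model: ConceptModel) -> list[ReportFinding]:
    """One Violation per instance whose declared start date is strictly after
    its end date; equal start and end pass.  Date shifting moves both ends by
    the same offset, so verdicts are invariant under shifting."""
    data = quads.as_graph()
    findings: list[ReportFinding] = []
    for cname, cdef in model.concepts.items():
        if not cdef.start_end_pairs:
            continue
        cls = model.class_iri(cname)
        for focus in sorted(data.subjects(RDF.type, cls), key=str):
            for start_prop, end_prop in cdef.start_end_pairs:
                starts = [v for v in data.objects(focus, model.property_iri(start_prop))
                          if isinstance(v, Literal) and v.ill_typed is not True]
                ends = [v for v in data.objects(focus, model.property_iri(end_prop))
                        if isinstance(v, Literal) and v.ill_typed is not True]
                for s in starts:
                    for e in ends:
                        try:
                            if s.toPython() > e.toPython():
                                findings.append(ReportFinding(
                                    SEV_VIOLATION, KIND_LOGIC, str(focus), start_prop,
                                    f"start {s} is after end {e}"))
                        except TypeError:
                            continue  # incomparable values; datatype check reports
    return findings


def completeness_stats(quads: QuadSet, model: ConceptModel
                       ) -> dict[tuple[str, str], int]:
    """Presence counts via SPARQL: per concept the instance count (keyed
    ``(concept, "")``), per (concept, property) the number of instances
    carrying at least one value."""
    data = quads.as_graph()
    out: dict[tuple[str, str], int] = {}
    for cname, cdef in model.concepts.items():
        cls = model.class_iri(cname)
        rows = data.query(
            "SELECT (COUNT(DISTINCT ?i) AS ?n) WHERE { ?i a ?cls }",
            initBindings={"cls": cls})
        out[(cname, "")] = int(next(iter(rows))[0])
        for p in cdef.properties:
            rows = data.query(
                "SELECT (COUNT(DISTINCT ?i) AS ?n) WHERE "
                "{ ?i a ?cls . ?i ?p ?v }",
                initBindings={"cls": cls, "p": model.property_iri(p.name)})
            out[(cname, p.name)] = int(next(iter(rows))[0])
    return out
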