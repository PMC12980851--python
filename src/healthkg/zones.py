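"""Project orchestration over a file-based data-lake store.

A project is a directory tree holding everything derived from one schema::

    <root>/<project_id>/
        config.json               project configuration
        artifacts/                schema copy, JSON Schema, DDL, CSV headers,
                                  SHACL shapes, terminology graphs
        deid/log.json             de-identification log (original↔pseudonym,
                                  patient↔offset) — access-controlled path
        zones/landing/            normalized per-patient bundles (JSON)
        zones/quarantine/         patients failing hard pre-check/transform
        zones/release/            per-patient RDF files + validation reports
        logs/run.jsonl            structured per-batch run log

Two projects never share state: identical patients processed in two projects
get independent pseudonyms, offsets and files.  Patients are independent
work units — each one runs pre-check → de-identification → transformation →
validation on its own, and a failing patient never alters another patient's
outputs.  Patient graphs that fail validation still land in the Release zone
together with their failing report; only hard errors (IRI-unsafe ids,
unparseable dates, dangling links) quarantine a patient.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

from rdflib import Graph

from .artifact_gen import gen_json_schema, gen_shacl, gen_tabular_templates
from .deidentify import DeidConfig, DeidLog, apply_deidentification
from .errors import HealthKGError, StoreError, TransformationError
from .ingest import (PatientBundle, bundle_to_json, ingest_json, ingest_tabular,
                     precheck)
from .rdfize import (IriPolicy, QuadSet, bundle_to_quads, file_extension,
                     parse_quads, patient_graph_iri, serialize_quads)
from .schema_model import ConceptModel, parse_schema
from .validate import (ReportFinding, SEV_WARNING, ValidationReport,
                       logic_check_dates, shacl_validate)


@dataclass
class ProjectConfig:
    project_id: str
    provider_uid: str
    serialization_format: str = "trig"
    deid_enabled: bool = True

    def to_json(self) -> dict:
        return {
            "project_id": self.project_id,
            "provider_uid": self.provider_uid,
            "serialization_format": self.serialization_format,
            "deid_enabled": self.deid_enabled,
        }


@dataclass
class ReleaseEntry:
    original_patient_id: str
    graph_iri: str
    file: Path
    report: ValidationReport

    @property
    def conforms(self) -> bool:
        return self.report.conforms


@dataclass
class QuarantineEntry:
    original_patient_id: str
    reasons: list[dict]


@dataclass
class BatchResult:
    released: list[ReleaseEntry] = field(default_factory=list)
    quarantined: list[QuarantineEntry] = field(default_factory=list)

    def violation_pairs(self) -> set[tuple[str, str]]:
        """Unique (original patient id, violation kind) pairs across release
        reports (Violations only) and quarantine reasons."""
        pairs: set[tuple[str, str]] = set()
        for e in self.released:
            for f in e.report.findings:
                if f.severity == "Violation":
                    pairs.add((e.original_patient_id, f.constraint_kind))
        for q in self.quarantined:
            for r in q.reasons:
                pairs.add((q.original_patient_id, r["kind"]))
        return pairs


class Project:
    """A configured project rooted under ``<root>/<project_id>``."""

    def __init__(self, root: Path, config: ProjectConfig, model: ConceptModel,
                 deid_config: DeidConfig | None):
        self.dir = Path(root) / config.project_id
        self.config = config
        self.model = model
        self.deid_config = deid_config
        self.policy = IriPolicy(provider_uid=config.provider_uid,
                                schema_prefix=model.schema_prefix)
        self._shapes_graph: Graph | None = None
        self._terminologies: list[Graph] | None = None

    # -- setup --------------------------------------------------------------

    @classmethod
    def create(cls, root: Path, project_id: str, schema_doc: str,
               provider_uid: str, serialization_format: str = "trig",
               deid_config: DeidConfig | None = None,
               terminology_docs: tuple[str, ...] = ()) -> "Project":
        """Initialize a project: parse the schema and derive all artifacts."""
        model = parse_schema(schema_doc)
        config = ProjectConfig(project_id=project_id, provider_uid=provider_uid,
                               serialization_format=serialization_format,
                               deid_enabled=deid_config is not None)
        project = cls(root, config, model, deid_config)
        art = project.dir / "artifacts"
        for sub in ("artifacts", "artifacts/terminology", "artifacts/csv_headers",
                    "deid", "zones/landing", "zones/quarantine", "zones/release",
                    "logs"):
            (project.dir / sub).mkdir(parents=True, exist_ok=True)
        (project.dir / "config.json").write_text(
            json.dumps(config.to_json(), indent=1))
        (art / "schema.ttl").write_text(schema_doc)
        (art / "json_schema.json").write_text(
            json.dumps(gen_json_schema(model), indent=1, sort_keys=True))
        tab = gen_tabular_templates(model)
        (art / "templates.sql").write_text(tab.ddl)
        for tname, header in tab.csv_headers.items():
            (art / "csv_headers" / f"{tname}.csv").write_text(header + "\n")
        (art / "shapes.ttl").write_text(gen_shacl(model))
        for i, doc in enumerate(terminology_docs, start=1):
            (art / "terminology" / f"terminology-{i:02d}.ttl").write_text(doc)
        if deid_config is not None:
            (project.dir / "deid" / "config.json").write_text(json.dumps({
                "scramble_fields": [list(s) for s in deid_config.scramble_fields],
                "date_shift_range": list(deid_config.date_shift_range),
                "substitutions": [
                    ({"replacement": r.replacement, "values": list(r.values)}
                     if r.values else
                     {"replacement": r.replacement, "pattern": r.pattern})
                    for r in deid_config.substitutions],
                "logging_enabled": deid_config.logging_enabled,
                "project_salt": deid_config.project_salt,
                "scramble_patient_id": deid_config.scramble_patient_id,
            }, indent=1))
        return project

    @classmethod
    def open(cls, root: Path, project_id: str) -> "Project":
        pdir = Path(root) / project_id
        if not (pdir / "config.json").exists():
            raise StoreError(f"no project {project_id!r} under {root}")
        raw = json.loads((pdir / "config.json").read_text())
        config = ProjectConfig(**raw)
        model = parse_schema((pdir / "artifacts" / "schema.ttl").read_text())
        deid_cfg = None
        deid_path = pdir / "deid" / "config.json"
        if config.deid_enabled and deid_path.exists():
            deid_cfg = DeidConfig.from_json(deid_path.read_text())
        return cls(root, config, model, deid_cfg)

    # -- cached artifacts ---------------------------------------------------

    @property
    def shapes(self) -> Graph:
        if self._shapes_graph is None:
            self._shapes_graph = Graph().parse(
                self.dir / "artifacts" / "shapes.ttl", format="turtle")
        return self._shapes_graph

    @property
    def terminologies(self) -> list[Graph]:
        if self._terminologies is None:
            self._terminologies = [
                Graph().parse(p, format="turtle")
                for p in sorted((self.dir / "artifacts" / "terminology").glob("*.ttl"))
            ]
        return self._terminologies

    @property
    def deid_log_path(self) -> Path:
        return self.dir / "deid" / "log.json"

    def load_deid_log(self) -> DeidLog:
        if self.deid_log_path.exists():
            return DeidLog.from_json(self.deid_log_path.read_text())
        return DeidLog(project_id=self.config.project_id)

    # -- ingestion (Landing zone) -------------------------------------------

    def ingest_json_doc(self, doc: str | dict) -> list[str]:
        """Validate and normalize a JSON batch into the Landing zone."""
        schema = json.loads((self.dir / "artifacts" / "json_schema.json").read_text())
        bundles = ingest_json(doc, self.model, json_schema=schema)
        return [self._land(b) for b in bundles]

    def ingest_csv_dir(self, csv_dir: Path) -> list[str]:
        """Read ``<table>.csv`` files matching the generated templates."""
        tables: dict[str, list[dict[str, str]]] = {}
        for path in sorted(Path(csv_dir).glob("*.csv")):
            with open(path, newline="") as fh:
                tables[path.stem] = list(csv.DictReader(fh))
        bundles = ingest_tabular(tables, self.model)
        return [self._land(b) for b in bundles]

    def land_bundles(self, bundles: list[PatientBundle]) -> list[str]:
        """Place already-normalized bundles into the Landing zone."""
        return [self._land(b) for b in bundles]

    def _land(self, bundle: PatientBundle) -> str:
        pid = bundle.patient_local_id
        safe = "".join(c if c.isalnum() or c in "._~-" else "%" for c in pid)
        path = self.dir / "zones" / "landing" / f"{safe}.json"
        path.write_text(json.dumps(
            {"patients": [bundle_to_json(bundle, self.model)]}, indent=1))
        return pid

    def landed_bundles(self) -> list[PatientBundle]:
        bundles = []
        for path in sorted((self.dir / "zones" / "landing").glob("*.json")):
            doc = json.loads(path.read_text())
            # landing documents may hold injected violations that the JSON
            # Schema would reject; they must still reach validation, so the
            # normalized form is read back without re-validating structure
            bundles.append(_bundle_from_landing(doc["patients"][0], self.model))
        return bundles

    # -- processing ---------------------------------------------------------

    def process(self, seed: int = 0, deid: bool | None = None) -> BatchResult:
        """Run the full per-patient pipeline over every landed patient."""
        result = BatchResult()
        log = self.load_deid_log()
        for bundle in self.landed_bundles():
            entry = self._process_one(bundle, seed, log, deid=deid)
            if isinstance(entry, ReleaseEntry):
                result.released.append(entry)
            else:
                result.quarantined.append(entry)
        if self.deid_config is not None and self.deid_config.logging_enabled:
            log.save(self.deid_log_path)
        self._append_run_log(result, seed)
        return result

    def process_patient(self, bundle: PatientBundle, seed: int = 0,
                        deid: bool | None = None):
        """Land and process a single patient (delta-load entry point)."""
        self._land(bundle)
        log = self.load_deid_log()
        entry = self._process_one(bundle, seed, log, deid=deid)
        if self.deid_config is not None and self.deid_config.logging_enabled:
            log.save(self.deid_log_path)
        return entry

    def _process_one(self, bundle: PatientBundle, seed: int, log: DeidLog,
                     deid: bool | None = None):
        original_pid = bundle.patient_local_id
        findings = precheck(bundle, self.model)
        blocking = [f for f in findings if f.blocking]
        if blocking:
            return self._quarantine(original_pid, [
                {"kind": f.kind, "concept": f.concept, "instance_id": f.instance_id,
                 "property": f.prop, "message": f.message} for f in blocking])

        use_deid = self.deid_config is not None if deid is None else (
            deid and self.deid_config is not None)
        if use_deid:
            bundle = apply_deidentification(bundle, self.deid_config, log,
                                            self.model, seed)
        try:
            quads = bundle_to_quads(bundle, self.model, self.policy)
        except (TransformationError, HealthKGError) as exc:
            return self._quarantine(original_pid, [
                {"kind": "transformation_error", "concept": None,
                 "instance_id": original_pid, "property": None,
                 "message": str(exc)}])

        report = shacl_validate(quads, self.shapes, self.terminologies, self.model)
        report.add(logic_check_dates(quads, self.model))
        report.add([
            ReportFinding(SEV_WARNING, f.kind,
                          f"{f.concept}/{f.instance_id}", f.prop, f.message)
            for f in findings if not f.blocking])

        g_iri = patient_graph_iri(self.policy, self.model, bundle.patient_local_id)
        seg = str(g_iri).rsplit("/", 1)[-1]
        ext = file_extension(self.config.serialization_format)
        release = self.dir / "zones" / "release"
        out_file = release / f"{seg}{ext}"
        out_file.write_bytes(serialize_quads(quads, self.config.serialization_format))
        (release / f"{seg}.report.json").write_text(
            json.dumps(report.to_json_dict(), indent=1, sort_keys=True))
        self._index_update(original_pid, seg)
        # a previously quarantined patient that now processes is un-quarantined
        q = self.dir / "zones" / "quarantine" / f"{original_pid}.json"
        if q.exists():
            q.unlink()
        return ReleaseEntry(original_patient_id=original_pid,
                            graph_iri=str(g_iri), file=out_file, report=report)

    def _quarantine(self, pid: str, reasons: list[dict]) -> QuarantineEntry:
        safe = "".join(c if c.isalnum() or c in "._~-" else "%" for c in pid)
        path = self.dir / "zones" / "quarantine" / f"{safe}.json"
        path.write_text(json.dumps({"patient_id": pid, "reasons": reasons}, indent=1))
        return QuarantineEntry(original_patient_id=pid, reasons=reasons)

    def _index_path(self) -> Path:
        return self.dir / "release_index.json"

    def _index(self) -> dict[str, str]:
        p = self._index_path()
        return json.loads(p.read_text()) if p.exists() else {}

    def _index_update(self, pid: str, seg: str) -> None:
        idx = self._index()
        idx[pid] = seg
        self._index_path().write_text(json.dumps(idx, indent=1, sort_keys=True))

    def _append_run_log(self, result: BatchResult, seed: int) -> None:
        with open(self.dir / "logs" / "run.jsonl", "a") as fh:
            stamp = datetime.now(timezone.utc).isoformat()
            for e in result.released:
                fh.write(json.dumps({
                    "ts": stamp, "seed": seed, "patient": e.original_patient_id,
                    "outcome": "released", "conforms": e.conforms,
                    "violations": sum(1 for f in e.report.findings
                                      if f.severity == "Violation")}) + "\n")
            for q in result.quarantined:
                fh.write(json.dumps({
                    "ts": stamp, "seed": seed, "patient": q.original_patient_id,
                    "outcome": "quarantined",
                    "reasons": [r["kind"] for r in q.reasons]}) + "\n")

    # -- Release-zone store operations ---------------------------------------

    @property
    def store(self) -> "ReleaseStore":
        return ReleaseStore(self.dir / "zones" / "release",
                            self.config.serialization_format)

    def delta_update(self, bundle: PatientBundle, seed: int = 0,
                     deid: bool | None = None):
        """Replace one patient's graph with a reprocessed bundle; every other
        patient's files stay byte-identical."""
        return self.process_patient(bundle, seed=seed, deid=deid)

    def revoke_consent(self, patient_id: str) -> None:
        """Remove a patient's named graph, report and landing record entirely.

        ``patient_id`` is the provider's original identifier.  Revoking an
        unknown patient is an explicit error so revocations stay auditable.
        """
        idx = self._index()
        if patient_id not in idx:
            raise StoreError(f"no released graph for patient {patient_id!r}")
        seg = idx.pop(patient_id)
        ext = file_extension(self.config.serialization_format)
        release = self.dir / "zones" / "release"
        safe = "".join(c if c.isalnum() or c in "._~-" else "%" for c in patient_id)
        for path in (release / f"{seg}{ext}", release / f"{seg}.report.json",
                     self.dir / "zones" / "landing" / f"{safe}.json"):
            if path.exists():
                path.unlink()
        self._index_path().write_text(json.dumps(idx, indent=1, sort_keys=True))

    def status(self) -> dict:
        zones = self.dir / "zones"
        ext = file_extension(self.config.serialization_format)
        return {
            "project_id": self.config.project_id,
            "landing": len(list((zones / "landing").glob("*.json"))),
            "quarantine": len(list((zones / "quarantine").glob("*.json"))),
            "release": len(list((zones / "release").glob(f"*{ext}"))),
        }


@dataclass
class ReleaseStore:
    """Read-side view over the Release zone: one serialized graph per patient."""
    path: Path
    serialization_format: str = "trig"

    def graph_files(self) -> dict[str, Path]:
        ext = file_extension(self.serialization_format)
        return {p.stem: p for p in sorted(self.path.glob(f"*{ext}"))}

    def load_graph(self, seg: str) -> QuadSet:
        ext = file_extension(self.serialization_format)
        return parse_quads((self.path / f"{seg}{ext}").read_bytes(),
                           self.serialization_format)

    def load_all(self) -> QuadSet:
        total = QuadSet()
        for seg in self.graph_files():
            total = total.union(self.load_graph(seg))
        return total

    def quad_total(self) -> int:
        return sum(len(self.load_graph(seg)) for seg in self.graph_files())


def _bundle_from_landing(patient: dict, model: ConceptModel) -> PatientBundle:
    """Rebuild a bundle from its landing-zone JSON without schema validation
    (landing may legitimately hold records that fail the JSON Schema)."""
    from .ingest import _patient_json_to_bundle

    return _patient_json_to_bundle(patient, model, lenient=True)
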