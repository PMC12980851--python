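# healthkg

Schema-driven construction of validated, de-identified RDF knowledge graphs
from heterogeneous per-patient health records — with one named graph per
patient.

## The problem

Hospitals and research institutions hold patient data in incompatible shapes:
JSON exports, CSV extracts, relational tables. Federated research networks
need that data as semantically explicit RDF so records from different sites
can be merged or queried jointly — but each site must transform, validate and
de-identify locally, under its own governance. Hand-maintained per-site
pipelines drift apart; the resulting graphs stop being mergeable.

`healthkg` makes a single RDF schema the sole source of truth. From one
schema document it derives every data-facing artifact, so ingestion
templates, transformation and validation can never disagree:

* a **JSON Schema** for document ingestion,
* **tabular templates** (CSV headers + SQL DDL, one table per core concept)
  for table/relational ingestion,
* **SHACL shapes** expressing cardinality, datatype, class and value-set
  constraints, plus terminology-membership checks for coded values.

Incoming records are normalized into per-patient bundles, optionally
de-identified (UUID pseudonymization, per-patient date shifting, list/regex
substitution — all replayable from a protected log), transformed into RDF,
and validated. Each patient's statements live in exactly one named graph, so
a later delivery replaces one graph (delta load) and consent revocation
deletes one graph, without touching any other patient.

## Core conventions

**IRI minting.** Every instance IRI has four parts, of which the provider
supplies only the last:

```
<base>/<provider_uid>/<schema_prefix>/<ClassName>/<local_id>
```

Distinct provider identifiers make IRIs globally collision-free, so graphs
from several institutions merge without coordination. Local identifiers must
use the IRI-safe unreserved characters `A-Za-z0-9._~-`; a pre-check rejects
anything else before transformation. A patient's graph IRI is minted like an
instance of the Subject class, inheriting the same guarantee. Externally
agreed *shared identifiers* (e.g. a sample analyzed at another site) are
exempt from minting and emitted verbatim, enabling cross-site linkage.

**Core concepts.** A concept is *core* when it is directly linked to the
patient (the range of a Subject-domain property, one hop). Core concepts get
their own tables; a link between core concepts is an identifier column only.
Non-core concepts (e.g. an Admission inside an AdministrativeCase) are
embedded: nested objects in JSON, prefixed columns (`admission_*`) in tables.

**Validation is schema-integrity only.** Missing mandatory values, cardinality
breaches, wrong datatypes, non-permitted value-set members and codes absent
from the loaded terminologies are Violations; the single semantic rule beyond
the schema is that an event's start date must not come after its end date
(equality passes). A physiologically absurd but schema-valid value — a
systolic pressure of 300 — raises nothing, by design. Patients failing
validation are still released, together with their failing report; only hard
errors (IRI-unsafe ids, unparseable dates, dangling links) quarantine a
patient, and never affect the rest of the batch.

## Worked example

The package ships a self-contained toy schema (Subject, Diagnosis,
AdministrativeCase with embedded Admission, Measurement, an administrative-sex
value set, and a toy diagnosis terminology) plus a seeded synthetic patient
generator, so the whole pipeline runs with no external data:

```python
import json
from pathlib import Path
import healthkg as hk
from healthkg import fixtures

m = fixtures.toy_model()
schema, _ = fixtures.make_toy_schema()
Path("schema.ttl").write_text(schema)
Path("terminology.ttl").write_text(fixtures.make_toy_terminology())
Path("deid.json").write_text(json.dumps({
    "scramble_fields": [["Subject", "insurance_number"]],
    "date_shift_range": [-30, 30],
    "project_salt": "demo-salt"}))
bundles, _ = fixtures.make_patients(m, 3, seed=11)
Path("batch.json").write_text(json.dumps(
    {"patients": [hk.bundle_to_json(b, m) for b in bundles]}))
```

```
$ healthkg create-project --root store --project demo --schema schema.ttl \
    --provider-uid CHE-123.456.789 --deid-config deid.json --terminology terminology.ttl
project demo created under store/demo
$ healthkg ingest --root store --project demo --json batch.json
landed 3 patient(s): p-0001, p-0002, p-0003
$ healthkg process --root store --project demo --seed 42
released 3 (0 failing validation), quarantined 0
$ healthkg status --root store --project demo
{
 "project_id": "demo",
 "landing": 3,
 "quarantine": 0,
 "release": 3
}
```

Three patients were normalized into the Landing zone, de-identified,
transformed and validated; each now sits in the Release zone as one TriG file
(named graph) plus a JSON validation report. The file names are the patients'
UUID pseudonyms — originals are recoverable only through the project's
access-controlled de-identification log:

```
$ ls store/demo/zones/release | head -2
20e49f71-aa3e-4f53-aad7-369b4e96f497.report.json
20e49f71-aa3e-4f53-aad7-369b4e96f497.trig
$ head -2 store/demo/zones/release/20e49f71-aa3e-4f53-aad7-369b4e96f497.trig
<https://example.org/healthkg/resource/CHE-123.456.789/toy/Subject/20e49f71-aa3e-4f53-aad7-369b4e96f497> {
    <https://example.org/healthkg/resource/CHE-123.456.789/toy/AdministrativeCase/case-p-0003-01> <http://www.w3.org/1999/02/22-rdf-syntax-ns#type> <https://example.org/toy-schema#AdministrativeCase> .
```

All dates inside the graph are shifted by this patient's constant offset, so
every within-patient interval (e.g. length of stay) is preserved. A new
delivery for the same patient (`healthkg delta`) replaces exactly this file;
`healthkg revoke p-0003` deletes it entirely.

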