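# Methods

This note records how the pipeline works, the parameters that matter, what
the synthetic corpus does and does not emulate, and the design choices made
where more than one reasonable option existed.

## Schema dialect and the concept model

The pipeline is schema-driven: a single Turtle document determines the
ingestion templates, the transformation and the validation rules. Rather than
depending on any external clinical schema distribution, `healthkg` defines a
small, fully documented OWL-style dialect (`schema_model.py`): concepts are
`owl:Class` declarations; properties carry `rdfs:domain`/`rdfs:range`;
cardinalities are `owl:Restriction` nodes on the domain class; value sets are
classes flagged `dialect:isValueSet` with an `owl:oneOf` member list (IRIs
for coded sets, strings for plain enumerations); one class is flagged
`dialect:isSubjectClass`. Start/end property pairs for the temporal logic
check are declared per concept with `dialect:startEndPair`, and shared
external identifiers with `dialect:isSharedIdentifier`.

An RDF graph is a statement *set*, so "declaration order" of properties is
not recoverable after parsing. The dialect therefore carries an explicit
`dialect:order` annotation; ordering is (order, then property name). This
makes parsing idempotent — `parse(serialize(parse(doc)))` is a fixed point,
asserted field-by-field in the tests — and keeps every generated artifact
byte-stable.

**Core concepts.** A concept is core iff it is the Subject class or the range
of a property whose domain is the Subject class (one hop). This is a
deliberate, simple criterion: it classifies the canonical worked example
(Diagnosis and AdministrativeCase core, the embedded Admission not) correctly
and is trivially auditable. Deeper reachability is *not* considered; a
concept only referenced from another non-subject concept is embedded.

## Derived artifacts

All three artifact families are generated from the same model, in model
order, so regeneration is byte-identical.

* **JSON Schema** (draft-07): one object definition per concept; core
  concepts appear as arrays under `records`, non-core concepts as nested
  objects inside their owner (inheriting the owner's instance id when none is
  given). `min_count ≥ 1` becomes `required`, bounded `max_count` becomes
  `maxItems`, value sets become `enum`s, temporal properties get `format` plus
  a regex pattern (the `format` keyword alone is advisory in draft-07
  validators). String fields carry `minLength: 1` so an empty string cannot
  satisfy a mandatory field that the bundle normalization would then drop —
  this is what makes "accepted by the JSON Schema ⇒ passes SHACL (absent
  terminology issues)" hold.
* **Tabular templates**: one table per core concept with a `patient_id` and a
  `<table>_id` column. Links between core concepts become a single reference
  column named after the linked concept (`administrative_case_id`), never the
  linked concept's metadata. Embedded concepts contribute underscore-prefixed
  columns (`admission_admission_datetime`). Subject→core link properties are
  realized by the *target* table's `patient_id` column (row grouping implies
  the link); the generator's explicit property→column map records this so the
  coverage invariant — every property realized exactly once — is checkable.
  Multi-valued scalar/value-set/link properties cannot live in a flat row and
  get a child side table `<table>__<property>` with one row per value.
  Multi-valued *embedded concepts* are rejected at generation time with a
  clear error: one level of single-instance embedding is supported, which
  matches how flat clinical extracts are actually shaped. Column-name
  collisions after prefixing abort generation naming both property paths.
  The DDL is ANSI-flavoured text; enumerated columns are emulated portably
  with `CHECK (col IN (...))` constraints. CSV headers equal DDL column order.
* **SHACL shapes**: one node shape per concept targeting its class IRI;
  property shapes carry `sh:minCount`/`sh:maxCount` always, plus
  `sh:datatype` (scalars/temporals), `sh:class` (concept links) or `sh:in`
  (value sets). Coded value sets additionally carry
  `dialect:terminologyCheck true`. The shapes graph embeds a SHA-256 digest
  of the model so validation can refuse shapes generated from a stale schema
  version.

## Ingestion and pre-check

Both routes normalize into the same per-patient bundle form and are tested
for cross-route equivalence (records are canonically ordered by (concept,
instance id) so route-specific processing order cannot leak into equality).
Ingestion is atomic per patient: a structurally invalid patient (dangling
link, duplicate instance id, JSON Schema failure) is rejected whole; numbers
are coerced to their declared types; temporal values stay ISO-8601 strings.

The pre-check reports three finding kinds. IRI-unsafe local identifiers
(anything outside `A-Za-z0-9._~-`) and unparseable temporal values are
*blocking*: no IRI can be minted and no date can be shifted, so the patient
is quarantined with a machine-readable reason. Unknown value-set members are
*non-blocking* warnings: the patient proceeds, the SHACL membership
constraint reports the Violation, and the record still reaches the Release
zone with a failing report — failing data is delivered with its report, not
silently dropped.

## De-identification

Three mechanisms, configured per project as JSON; the project salt isolates
projects, so the same patient delivered to two projects gets unrelated
pseudonyms and offsets.

* **Pseudonymization**: version-4-format UUIDs minted from a generator seeded
  by (project salt, run seed, selector, original). The token carries no
  information derived from the original value beyond this keying — it cannot
  be reversed without the log — and the keyed minting means independent
  per-patient workers produce identical tokens without coordination, which is
  also what makes a delta-sequence store equal a from-scratch rebuild. The
  (selector, original) → pseudonym map is persisted in the project log;
  replay consults the log first, so later deliveries are byte-identical even
  under a different run seed or salt. With logging disabled the mapping lives
  only in memory (one-off exports); attempting to load a log that was never
  written is an explicit `ReplayError`.
* **Date shifting**: one offset per patient, uniform on the configured
  `[lo, hi]` day range (default ±30 days, a common de-identification window;
  0 is permitted when the range includes it). The offset is keyed by the
  *original* patient identifier and logged, so re-deliveries reuse it. All
  temporal fields of the patient move by the same offset — every
  within-patient interval is preserved exactly, and the start≤end verdicts
  are invariant under shifting.
* **Substitution**: explicit value lists or regular expressions with a
  replacement string, applied to all string-valued fields. Patterns are
  compiled at configuration load; a bad pattern fails there, not mid-run.

Which fields are temporal is decided by the schema model (range kind), never
by name heuristics. The log is written under the project's `deid/` path,
separate from every data zone.

## Transformation and serialization

Each record becomes a typed node (minted IRI, `rdf:type` statement); scalar
and temporal fields become XSD-typed literals (string→`xsd:string`,
integer→`xsd:integer`, decimal→`xsd:decimal`, boolean→`xsd:boolean`,
date→`xsd:date`, dateTime→`xsd:dateTime`); links become object statements to
the minted IRIs of the linked instances; shared identifiers are emitted
verbatim (absolute IRIs as IRIs, anything else as a plain literal). A value
that failed coercion upstream is emitted as an *ill-typed* literal on purpose,
so the SHACL datatype constraint reports it instead of the pipeline crashing.
No blank nodes are emitted, and the statement count obeys a closed formula
(records + field values + links + shared identifiers), asserted on random
corpora.

All statements of a patient carry the patient's graph IRI. Serialization
(TriG, N-Quads; Turtle for single-graph exports, where the graph component is
dropped) writes statements in sorted N3 order: output is deterministic and
re-parses to the identical quad set.

## Validation

`pyshacl` is not part of this package's dependency set; `validate.py`
implements a focused SHACL interpreter for exactly the constraint vocabulary
the generator emits (`sh:minCount`, `sh:maxCount`, `sh:datatype`, `sh:class`,
`sh:in`, the terminology marker). Crucially it reads the *shapes graph*, not
the concept model, so independently hand-written shape documents validate
through the identical engine; the tests compare verdicts of generated and
hand-written oracle shapes over mixed corpora.

Terminology semantics: a coded value outside the schema value set is one
membership Violation; the terminology check applies only to values *inside*
the value set but absent from every loaded terminology graph (an
outdated/retired code). Each injected fault therefore maps to exactly one
reported (patient, kind) pair. Datatype checking treats a plain literal as
`xsd:string` (RDF 1.1) and uses the literal's lexical-form validity for the
ill-typed case.

The logic check flags an instance whose declared start property is strictly
after its end property. Equality passes — same-day admission and discharge
are routine clinical reality, so the boundary is deliberately inclusive.
Completeness statistics are SPARQL presence counts: per concept the instance
count, per (concept, property) the number of instances carrying at least one
value. Validation never mutates the data graph.

## Zones, delta loads and revocation

A project is a plain directory tree (Landing, quarantine, Release zones as
subdirectories; artifacts and the de-identification log beside them) — files
are inspectable at every stage and the store needs no database. Patients are
independent work units; one patient's failure never changes another's bytes
(asserted by hashing). Release files are named by the final IRI segment of
the patient graph (the pseudonym when scrambling is on); a private index maps
original identifiers to graph segments so `revoke` and `delta` take the
provider's own identifier without leaking the mapping into the Release zone.

`delta_update` reprocesses one bundle and replaces exactly that patient's
graph and report. `revoke_consent` removes the graph, the report and the
landing record; revoking an unknown patient is an explicit error (a silent
no-op would make revocations unauditable). Because pseudonyms and offsets are
log-stable and order-independent, any sequence of deltas and revocations ends
in a store equal, graph by graph, to a from-scratch build of the final
states.

Landing-zone re-reads use a lenient coercion mode: a landed bundle may
legitimately hold values that the JSON Schema would reject (that is what the
Release-zone report is for), so re-reading keeps uncoercible values as-is
rather than failing.

## Synthetic corpus

The generator (`fixtures.py`) emulates heterogeneous per-patient clinical
shape: 1–5 administrative cases per patient (admission ≤ discharge by
construction, stays of 0–30 days), 0–10 coded diagnoses (codes drawn from the
seven currently-valid toy terminology codes), 0–3 numeric measurements,
always-present birth date and insurance number. These ranges are fixed,
documented defaults chosen to span minimal-to-rich records; they model
*shape* heterogeneity, not clinical content realism — no disease
co-occurrence, no plausible vital-sign distributions, no free-text clinical
language. Passing tests therefore demonstrate the mechanics (template
derivation, transformation, validation, de-identification, store semantics)
on realistic structure, not statistical fidelity to any hospital population.

Violations are injected explicitly: `round(rate × n)` patients get exactly
one mutation each, round-robin over six kinds (missing mandatory field,
non-permitted value-set member, wrong datatype, start-after-end, IRI-unsafe
identifier, retired code), recorded in a ledger. The wrong-datatype mutation
prefers a non-numeric string in an integer field (surfacing through SHACL in
the Release zone) and falls back to an unparseable date (surfacing at
pre-check) for patients without a diagnosis. The ledger is the oracle:
end-to-end findings, matched on (patient, kind), must equal it exactly, which
is only meaningful because the generator provably creates no accidental
violations (a rate-0 corpus passes every check end to end).

Problem sizes used by the acceptance script — 200 patients for the clean and
10 %-violation runs, 100 for de-identification invariants, 10 patients × 50
operations for the delta/revocation sequence, 50 patients for serialization
round-trips — are the package's standard demonstration scales; all complete
in about a minute on one CPU.

## Known limitations

* One level of concept embedding in tabular templates; multi-valued embedded
  concepts are rejected rather than flattened.
* OWL reasoning (subclass inference, imports) is out of scope; the dialect is
  deliberately closed.
* Terminology checking is membership in the loaded graphs; versioned
  terminology timelines (a code valid at recording time but retired later)
  are not modelled.
* The SHACL interpreter covers the generated constraint vocabulary, not the
  full SHACL recommendation (no property paths beyond single predicates, no
  logical combinators).
* Live database connections are represented by the DDL + CSV pair; Excel and
  streaming ingestion are not implemented.
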