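"""Configurable, replayable de-identification of patient bundles.

Three mechanisms, driven by a project-level JSON configuration:

* **field scrambling** — selected (concept, property) values are replaced by
  UUID pseudonyms, minted randomly on first encounter and persisted in the
  project log so the same original always maps to the same pseudonym within
  a project ("consistent within a dataset"), while carrying no information
  derived from the original value;
* **date shifting** — every temporal value of a patient moves by one constant
  per-patient offset drawn uniformly from a configured day range, preserving
  all within-patient intervals; the offset is logged and reused for
  subsequent deliveries of the same patient;
* **substitution** — explicit value lists or regular-expression patterns,
  each with a replacement string, applied to free-text fields.

The log (original↔pseudonym map and patient↔offset map) is the only artifact
that can reverse or replay the process; it is written as JSON under a
project-scoped path and never mixed into the data outputs.
"""

from __future__ import annotations

import json
import random
import re
import uuid
from dataclasses import dataclass, field as dc_field
from datetime import date, datetime, timedelta
from pathlib import Path

from .errors import DeidConfigError, ReplayError, TransformationError
from .ingest import PatientBundle
from .schema_model import ConceptModel

UUID_RE = re.compile(
    r"^[0-9a-f]{8}-[0-9a-f]{4}-[0-9a-f]{4}-[0-9a-f]{4}-[0-9a-f]{12}$")

#: selector used to scramble the patient identifier itself
PATIENT_ID_SELECTOR = ("__subject__", "patient_id")


@dataclass(frozen=True)
class SubstitutionRule:
    replacement: str
    values: tuple[str, ...] = ()
    pattern: str | None = None

    def __post_init__(self) -> None:
        if bool(self.values) == bool(self.pattern):
            raise DeidConfigError(
                "substitution rule needs exactly one of a value list or a pattern")
        if self.pattern is not None:
            try:
                re.compile(self.pattern)
            except re.error as exc:
                raise DeidConfigError(f"invalid pattern {self.pattern!r}: {exc}") from exc

    def apply(self, text: str) -> str:
        if self.pattern is not None:
            return re.sub(self.pattern, self.replacement, text)
        return self.replacement if text in self.values else text


@dataclass
class DeidConfig:
    scramble_fields: list[tuple[str, str]] = dc_field(default_factory=list)
    date_shift_range: tuple[int, int] = (-30, 30)
    substitutions: list[SubstitutionRule] = dc_field(default_factory=list)
    logging_enabled: bool = True
    project_salt: str = ""
    scramble_patient_id: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.date_shift_range
        if lo > hi:
            raise DeidConfigError(f"date shift range [{lo}, {hi}] has lo > hi")

    @classmethod
    def from_json(cls, text: str) -> "DeidConfig":
        raw = json.loads(text)
        rules = [
            SubstitutionRule(replacement=r["replacement"],
                             values=tuple(r.get("values", ())),
                             pattern=r.get("pattern"))
            for r in raw.get("substitutions", [])
        ]
        return cls(
            scramble_fields=[tuple(s) for s in raw.get("scramble_fields", [])],
            date_shift_range=tuple(raw.get("date_shift_range", (-30, 30))),
            substitutions=rules,
            logging_enabled=raw.get("logging_enabled", True),
            project_salt=raw.get("project_salt", ""),
            scramble_patient_id=raw.get("scramble_patient_id", True),
        )


@dataclass
class DeidLog:
    """Persistent original↔pseudonym and patient↔offset mappings of a project."""
    project_id: str
    value_map: dict[tuple[str, str, str], str] = dc_field(default_factory=dict)
    offset_map: dict[str, int] = dc_field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({
            "project_id": self.project_id,
            "value_map": [
                {"concept": k[0], "property": k[1], "original": k[2], "pseudonym": v}
                for k, v in sorted(self.value_map.items())
            ],
            "offset_map": dict(sorted(self.offset_map.items())),
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "DeidLog":
        raw = json.loads(text)
        return cls(
            project_id=raw["project_id"],
            value_map={(e["concept"], e["property"], e["original"]): e["pseudonym"]
                       for e in raw["value_map"]},
            offset_map={k: int(v) for k, v in raw["offset_map"].items()},
        )

    def save(self, path: Path) -> None:
        path.write_text(self.to_json())

    @classmethod
    def load(cls, path: Path) -> "DeidLog":
        if not path.exists():
            raise ReplayError(
                f"no de-identification log at {path}; replay is only possible "
                "when logging was enabled on the first delivery")
        return cls.from_json(path.read_text())


def _rng_for(config: DeidConfig, seed: int, *context: str) -> random.Random:
    """Seed a generator from the project salt, the run seed and a context key.

    The salt isolates projects (the same patient processed in two projects
    gets unrelated pseudonyms and offsets); the context key makes draws
    independent of processing order, so parallel per-patient workers reach
    identical results."""
    return random.Random(f"{config.project_salt}\x1f{seed}\x1f" + "\x1f".join(context))


def pseudonymize_value(original: str, selector: tuple[str, str],
                       config: DeidConfig, log: DeidLog, rng_seed: int = 0) -> str:
    """Return the stable UUID pseudonym for ``original`` under ``selector``.

    The pseudonym is minted from a salted generator keyed by (selector,
    original) so repeated calls agree without coordination, and recorded in
    the log (when logging is enabled) so later deliveries replay it exactly.
    The mapping is recoverable only through the log.
    """
    key = (selector[0], selector[1], original)
    if key in log.value_map:
        return log.value_map[key]
    rng = _rng_for(config, rng_seed, "scramble", selector[0], selector[1], original)
    token = str(uuid.UUID(int=rng.getrandbits(128), version=4))
    log.value_map[key] = token
    return token


def assign_date_offset(patient_local_id: str, config: DeidConfig,
                       log: DeidLog, rng_seed: int) -> int:
    """Draw (or replay) the per-patient day offset, uniform on the configured
    ``[lo, hi]`` range; a previously logged patient keeps its offset."""
    if patient_local_id in log.offset_map:
        return log.offset_map[patient_local_id]
    lo, hi = config.date_shift_range
    rng = _rng_for(config, rng_seed, "dateshift", patient_local_id)
    offset = rng.randint(lo, hi)
    log.offset_map[patient_local_id] = offset
    return offset


def _shift_iso(value: str, token: str, offset_days: int) -> str:
    delta = timedelta(days=offset_days)
    if token == "date":
        return (date.fromisoformat(value) + delta).isoformat()
    return (datetime.fromisoformat(value) + delta).isoformat()


def shift_dates(bundle: PatientBundle, offset: int,
                model: ConceptModel) -> PatientBundle:
    """Shift every temporal field of the bundle by exactly ``offset`` days.

    All within-patient day differences are preserved.  An unparseable value
    (which pre-check should have caught) raises, naming record and property.
    """
    out = bundle.copy()
    for rec in out.records:
        cdef = model.concepts[rec.concept]
        for pdef in cdef.properties:
            if pdef.range_kind != "temporal" or pdef.name not in rec.fields:
                continue
            try:
                raw = rec.fields[pdef.name]
                if isinstance(raw, list):
                    rec.fields[pdef.name] = [
                        _shift_iso(str(v), pdef.scalar_datatype, offset) for v in raw]
                else:
                    rec.fields[pdef.name] = _shift_iso(str(raw), pdef.scalar_datatype,
                                                       offset)
            except ValueError as exc:
                raise TransformationError(
                    f"{rec.concept} {rec.instance_local_id}.{pdef.name}: "
                    f"unparseable temporal value ({exc})") from exc
    return out


def substitute_values(bundle: PatientBundle,
                      rules: list[SubstitutionRule]) -> PatientBundle:
    """Apply list/regex substitution rules to every string-valued field."""
    if not rules:
        return bundle.copy()
    out = bundle.copy()

    def rewrite(v: object) -> object:
        if not isinstance(v, str):
            return v
        for rule in rules:
            v = rule.apply(v)
        return v

    for rec in out.records:
        for prop, value in list(rec.fields.items()):
            if isinstance(value, list):
                rec.fields[prop] = [rewrite(v) for v in value]
            else:
                rec.fields[prop] = rewrite(value)
    return out


def apply_deidentification(bundle: PatientBundle, config: DeidConfig,
                           log: DeidLog, model: ConceptModel,
                           rng_seed: int) -> PatientBundle:
    """Run the full per-patient de-identification: scrambling, date shift,
    substitution.  Order matters: the date offset is keyed by the *original*
    patient identifier so re-deliveries replay, then the identifier itself
    may be scrambled."""
    offset = assign_date_offset(bundle.patient_local_id, config, log, rng_seed)
    out = shift_dates(bundle, offset, model)
    out = substitute_values(out, config.substitutions)

    selectors = set(map(tuple, config.scramble_fields))
    for rec in out.records:
        cdef = model.concepts[rec.concept]
        for pdef in cdef.properties:
            sel = (rec.concept, pdef.name)
            if sel not in selectors:
                continue
            if pdef.name in rec.fields:
                raw = rec.fields[pdef.name]
                if isinstance(raw, list):
                    rec.fields[pdef.name] = [
                        pseudonymize_value(str(v), sel, config, log, rng_seed)
                        for v in raw]
                else:
                    rec.fields[pdef.name] = pseudonymize_value(
                        str(raw), sel, config, log, rng_seed)
            elif pdef.name in rec.shared_identifiers:
                rec.shared_identifiers[pdef.name] = pseudonymize_value(
                    rec.shared_identifiers[pdef.name], sel, config, log, rng_seed)

    if config.scramble_patient_id:
        original = out.patient_local_id
        pseudo = pseudonymize_value(original, PATIENT_ID_SELECTOR, config, log,
                                    rng_seed)
        out.patient_local_id = pseudo
        # the Subject record carries the patient identifier as its instance id
        for rec in out.records:
            if rec.concept == model.subject_concept and rec.instance_local_id == original:
                rec.instance_local_id = pseudo
        for rec in out.records:
            cdef = model.concepts[rec.concept]
            for prop, v in list(rec.links.items()):
                if cdef.property(prop).target != model.subject_concept:
                    continue
                if isinstance(v, list):
                    rec.links[prop] = [pseudo if x == original else x for x in v]
                elif v == original:
                    rec.links[prop] = pseudo
    return out
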