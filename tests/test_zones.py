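"""Zone orchestration: per-patient atomicity, delta loads, consent revocation."""

import hashlib
import json
import random

import pytest

from healthkg import Project
from healthkg.errors import StoreError
from healthkg.fixtures import make_patients
from healthkg.ingest import InstanceRecord


def release_hashes(project):
    out = {}
    for f in sorted((project.dir / "zones" / "release").iterdir()):
        out[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    return out


class TestProcessing:
    def test_clean_patient_is_released_conforming(self, model, project_factory):
        project = project_factory()
        bundles, _ = make_patients(model, 3, seed=81)
        project.land_bundles(bundles)
        result = project.process(seed=1)
        assert len(result.released) == 3 and not result.quarantined
        assert all(e.conforms for e in result.released)

    def test_value_set_violation_still_reaches_release_zone(
            self, model, project_factory):
        """A failing patient is released with a failing report, not dropped."""
        project = project_factory()
        bundles, _ = make_patients(model, 1, seed=82)
        bundles[0].by_concept("Subject")[0].fields["has_administrative_sex"] = "frog"
        project.land_bundles(bundles)
        result = project.process(seed=1)
        assert len(result.released) == 1 and not result.quarantined
        entry = result.released[0]
        assert not entry.conforms
        assert any(f.constraint_kind == "bad_value_set"
                   for f in entry.report.findings)
        assert entry.file.exists()

    def test_hard_error_quarantines_only_that_patient(self, model,
                                                      project_factory):
        project = project_factory()
        bundles, _ = make_patients(model, 10, seed=83)
        bundles[4].patient_local_id = "p 0005"  # IRI-unsafe
        for rec in bundles[4].by_concept("Subject"):
            rec.instance_local_id = "p 0005"
        project.land_bundles(bundles)
        result = project.process(seed=1)
        assert len(result.released) == 9
        assert [q.original_patient_id for q in result.quarantined] == ["p 0005"]
        assert result.quarantined[0].reasons[0]["kind"] == "malformed_id"

    def test_record_accounting_is_conserved(self, model, project_factory):
        """No patient is silently dropped: released + quarantined = landed."""
        project = project_factory()
        bundles, _ = make_patients(model, 40, seed=84, violation_rate=0.3)
        project.land_bundles(bundles)
        result = project.process(seed=1)
        assert len(result.released) + len(result.quarantined) == len(bundles)

    def test_rerun_is_byte_identical(self, model, project_factory):
        project = project_factory()
        bundles, _ = make_patients(model, 8, seed=85)
        project.land_bundles(bundles)
        project.process(seed=9)
        first = release_hashes(project)
        Project.open(project.dir.parent, project.config.project_id).process(seed=9)
        assert release_hashes(project) == first


class TestProjectIsolation:
    def test_same_patients_two_projects_disjoint_state(self, model, tmp_path,
                                                       project_factory):
        pa = project_factory("projA", salt="saltA")
        pb = project_factory("projB", salt="saltB")
        bundles, _ = make_patients(model, 6, seed=86)
        pa.land_bundles(bundles)
        pb.land_bundles(bundles)
        ra, rb = pa.process(seed=1), pb.process(seed=1)
        ga = {e.original_patient_id: e.graph_iri for e in ra.released}
        gb = {e.original_patient_id: e.graph_iri for e in rb.released}
        assert all(ga[p] != gb[p] for p in ga)  # different pseudonyms
        la, lb = pa.load_deid_log(), pb.load_deid_log()
        assert any(la.offset_map[p] != lb.offset_map[p] for p in la.offset_map)
        assert pa.dir != pb.dir and not set(
            f.name for f in (pa.dir / "zones" / "release").iterdir()) & set(
            f.name for f in (pb.dir / "zones" / "release").iterdir())

    def test_second_delivery_replays_pseudonyms_and_offsets(
            self, model, project_factory):
        project = project_factory()
        bundles, _ = make_patients(model, 5, seed=87)
        project.land_bundles(bundles)
        r1 = project.process(seed=1)
        first = release_hashes(project)
        first_offsets = dict(project.load_deid_log().offset_map)
        # second delivery of identical content, different run seed
        r2 = project.process(seed=222)
        assert release_hashes(project) == first
        assert project.load_deid_log().offset_map == first_offsets
        assert {e.graph_iri for e in r1.released} == {
            e.graph_iri for e in r2.released}


class TestDeltaAndRevocation:
    def test_delta_changes_only_that_patient(self, model, project_factory):
        project = project_factory()
        bundles, _ = make_patients(model, 6, seed=88)
        project.land_bundles(bundles)
        project.process(seed=1)
        before = release_hashes(project)
        updated = bundles[2].copy()
        mid = f"meas-{updated.patient_local_id}-90"
        updated.records.append(InstanceRecord(
            concept="Measurement", instance_local_id=mid,
            fields={"quantity_value": 118.0}))
        subj = updated.by_concept("Subject")[0]
        subj.links["has_measurement"] = sorted(
            subj.link_ids("has_measurement") + [mid])
        updated.records.sort(key=lambda r: (r.concept, r.instance_local_id))
        entry = project.delta_update(updated, seed=1)
        after = release_hashes(project)
        seg = entry.graph_iri.rsplit("/", 1)[-1]
        changed = {n for n in after if before[n] != after[n]}
        assert changed == {f"{seg}.trig", f"{seg}.report.json"}

    def test_identical_delta_leaves_store_unchanged(self, model,
                                                    project_factory):
        project = project_factory()
        bundles, _ = make_patients(model, 3, seed=89)
        project.land_bundles(bundles)
        project.process(seed=1)
        before = release_hashes(project)
        project.delta_update(bundles[1], seed=1)
        assert release_hashes(project) == before

    def test_store_totals_update_on_delta(self, model, project_factory):
        project = project_factory()
        bundles, _ = make_patients(model, 4, seed=90)
        project.land_bundles(bundles)
        project.process(seed=1)
        store = project.store
        old_total = store.quad_total()
        updated = bundles[0].copy()
        mid = f"meas-{updated.patient_local_id}-90"
        updated.records.append(InstanceRecord(
            concept="Measurement", instance_local_id=mid,
            fields={"quantity_value": 99.0}))
        subj = updated.by_concept("Subject")[0]
        subj.links["has_measurement"] = sorted(
            subj.link_ids("has_measurement") + [mid])
        # the patient's graph segment is stable across deliveries
        seg = project.process_patient(bundles[0], seed=1).graph_iri.rsplit("/", 1)[-1]
        old_patient = len(store.load_graph(seg))
        entry = project.delta_update(updated, seed=1)
        assert entry.graph_iri.rsplit("/", 1)[-1] == seg
        new_patient = len(project.store.load_graph(seg))
        # total = old − old patient quads + new patient quads
        assert new_patient == old_patient + 3  # new record: type+value, +1 link
        assert project.store.quad_total() == old_total - old_patient + new_patient

    def test_revoke_removes_exactly_one_graph(self, model, project_factory):
        project = project_factory()
        bundles, _ = make_patients(model, 3, seed=91)
        project.land_bundles(bundles)
        project.process(seed=1)
        before = release_hashes(project)
        project.revoke_consent(bundles[1].patient_local_id)
        after = release_hashes(project)
        assert len(after) == len(before) - 2  # graph file + report gone
        assert all(before[n] == after[n] for n in after)  # others untouched
        # no residual statement mentions the revoked patient's graph
        revoked = set(before) - set(after)
        union = project.store.load_all()
        for g in union.graphs():
            assert f"{g.rsplit('/', 1)[-1]}.trig" not in revoked

    def test_revoke_unknown_patient_is_explicit_error(self, model,
                                                      project_factory):
        project = project_factory()
        with pytest.raises(StoreError, match="ghost"):
            project.revoke_consent("ghost")

    def test_revoke_then_delta_reappears_with_new_data_only(
            self, model, project_factory):
        project = project_factory()
        bundles, _ = make_patients(model, 2, seed=92)
        project.land_bundles(bundles)
        project.process(seed=1)
        pid = bundles[0].patient_local_id
        project.revoke_consent(pid)
        slim = bundles[0].copy()
        slim.records = [r for r in slim.records if r.concept == "Subject"]
        slim.by_concept("Subject")[0].links.clear()
        entry = project.delta_update(slim, seed=1)
        seg = entry.graph_iri.rsplit("/", 1)[-1]
        graph = project.store.load_graph(seg)
        # type + sex + birth date + insurance number, nothing from the old data
        assert len(graph) == 4
        assert not any("Diagnosis" in str(s) for s, *_ in graph.quads)

    def test_revoke_all_patients_empties_the_store(self, model,
                                                   project_factory):
        project = project_factory()
        bundles, _ = make_patients(model, 5, seed=93)
        project.land_bundles(bundles)
        project.process(seed=1)
        for b in bundles:
            project.revoke_consent(b.patient_local_id)
        assert list((project.dir / "zones" / "release").iterdir()) == []
        assert project.store.quad_total() == 0

    def test_random_delta_sequence_equals_from_scratch_rebuild(
            self, model, project_factory):
        """After 50 random deltas/revocations over 10 patients, the store
        equals a clean rebuild of the final bundle states, per graph."""
        p_seq = project_factory("sequential", salt="saltX")
        p_new = project_factory("fromscratch", salt="saltX")
        pool, _ = make_patients(model, 10, seed=94)
        rng = random.Random(12)
        final = {}
        for _ in range(50):
            b = rng.choice(pool).copy()
            meas = b.by_concept("Measurement")
            if meas:
                meas[0].fields["quantity_value"] = round(rng.uniform(50, 200), 1)
            if rng.random() < 0.15 and b.patient_local_id in final:
                p_seq.revoke_consent(b.patient_local_id)
                del final[b.patient_local_id]
            else:
                p_seq.delta_update(b, seed=4)
                final[b.patient_local_id] = b
        p_new.land_bundles(list(final.values()))
        p_new.process(seed=4)
        qa = {g: p_seq.store.load_graph(g).quads
              for g in p_seq.store.graph_files()}
        qb = {g: p_new.store.load_graph(g).quads
              for g in p_new.store.graph_files()}
        assert qa == qb and len(qa) == len(final)
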