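"""Triage rules, review-queue construction, revision and ingestion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from veqr.engine import (
    Candidate,
    NoEvaluableImagesError,
    TriageAction,
    TriageConfig,
    VeqrDatabase,
    aggregate_score,
    apply_review_decision,
    build_review_queue,
    ingest_new_image,
    passes_development_gate,
    select_evaluation_set,
    select_worst_case_set,
    triage,
)
from veqr.label_store import AssessmentRecord, Grade, ImageRecord, LabelMap
from veqr.phantoms import (
    PhantomSpec,
    SegmenterAdapter,
    generate_phantom,
    phantom_image_record,
    region_subvolume,
)

DEFAULTS = TriageConfig()


class TestTriage:
    @pytest.mark.parametrize(
        "grade, dc, action",
        [
            ("good", 0.98, TriageAction.NO_UPDATE_EQUIVALENT),
            ("good", 0.50, TriageAction.NO_UPDATE_INFERIOR),
            ("acceptable", 0.85, TriageAction.REVIEW),
            ("unacceptable", 0.99, TriageAction.REVIEW),
        ],
    )
    def test_three_branch_rule(self, grade, dc, action):
        assert triage(grade, dc, DEFAULTS).action == action

    def test_failed_reference_reason(self):
        d = triage("unacceptable", 0.99, DEFAULTS)
        assert d.reason == "reference-unacceptable"

    def test_both_thresholds_map_to_review(self):
        assert triage("good", 0.75, DEFAULTS).action == TriageAction.REVIEW
        assert triage("good", 0.95, DEFAULTS).action == TriageAction.REVIEW

    @given(
        st.sampled_from(["good", "acceptable", "unacceptable"]),
        st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
    )
    def test_total_partition(self, grade, dc):
        # exactly one action for every (grade, dc)
        d = triage(grade, dc, DEFAULTS)
        assert d.action in (
            TriageAction.NO_UPDATE_INFERIOR,
            TriageAction.NO_UPDATE_EQUIVALENT,
            TriageAction.REVIEW,
        )

    def test_dc_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            triage("good", 1.2, DEFAULTS)

    def test_failed_reference_falls_through_when_disabled(self):
        cfg = TriageConfig(review_failed_reference=False)
        assert triage("unacceptable", 0.99, cfg).action == TriageAction.NO_UPDATE_EQUIVALENT

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            TriageConfig(td_low=0.9, td_high=0.8)


class TestEvaluationSets:
    def _db_with_grades(self, scheme, grades):
        db = VeqrDatabase(scheme)
        for image_id, grade in grades.items():
            rec = ImageRecord(image_id, "T", 1.0, shape=(2, 2, 2))
            lm = LabelMap(image_id, np.zeros((2, 2, 2), np.uint16))
            db.add_image(rec, lm, {"airway": grade})
        return db

    def test_good_and_acceptable_selected(self, scheme):
        db = self._db_with_grades(
            scheme, {"i1": "good", "i2": "acceptable", "i3": "unacceptable"}
        )
        assert select_evaluation_set(db, "airway") == ["i1", "i2"]
        assert select_worst_case_set(db, "airway") == ["i3"]

    def test_all_unacceptable_gives_empty_set(self, scheme):
        db = self._db_with_grades(scheme, {"i1": "unacceptable"})
        assert select_evaluation_set(db, "airway") == []

    def test_membership_matches_filter_oracle_and_partition(self, scheme):
        rng = np.random.default_rng(11)
        grades = {
            f"i{k:03d}": ["good", "acceptable", "unacceptable"][rng.integers(3)]
            for k in range(100)
        }
        db = self._db_with_grades(scheme, grades)
        ev = select_evaluation_set(db, "airway")
        oracle = sorted(k for k, g in grades.items() if g in ("good", "acceptable"))
        assert ev == oracle
        # worst-case set is the exact complement over graded images
        worst = select_worst_case_set(db, "airway")
        assert sorted(ev + worst) == sorted(grades)

    def test_unknown_region_rejected(self, scheme):
        db = VeqrDatabase(scheme)
        with pytest.raises(KeyError):
            select_evaluation_set(db, "spleen")


class TestAggregateScore:
    def test_examples(self):
        assert aggregate_score([("i1", 1.0)]) == 1.0
        assert aggregate_score([("i1", 0.8), ("i2", 0.9)]) == pytest.approx(0.85)

    def test_empty_set_is_an_error_not_zero(self):
        with pytest.raises(NoEvaluableImagesError):
            aggregate_score([])

    def test_matches_independent_summation(self):
        rng = np.random.default_rng(5)
        dcs = [(f"i{k}", float(rng.random())) for k in range(1000)]
        total = 0.0
        for _, d in dcs:
            total += d
        assert aggregate_score(dcs) == pytest.approx(total / 1000, abs=1e-12)


class TestDevelopmentGate:
    def test_gate_level(self):
        grades = ["good"] * 90 + ["unacceptable"] * 10
        assert passes_development_gate(grades, 0.90)
        assert not passes_development_gate(grades[:-1] + ["unacceptable"] * 2, 0.90)


def _lung_db(scheme, n=4, seed0=0, grid=32):
    """Small lungs-only database with perfect references graded good."""
    db = VeqrDatabase(scheme)
    truths = {}
    for k in range(n):
        spec = PhantomSpec(shape=(grid,) * 3, organs=("lung",), seed=seed0 + k)
        lm, truth = generate_phantom(spec, scheme)
        iid = f"img-{k:03d}"
        lm.image_id = iid
        db.add_image(phantom_image_record(spec, iid), lm, {"lung": "good"})
        truths[iid] = truth["lung"]
    return db, truths


class TestReviewQueue:
    def test_identical_candidates_produce_no_events(self, scheme):
        db, truths = _lung_db(scheme)
        cands = [Candidate(i, "lung", truths[i]) for i in truths]
        assert build_review_queue(db, cands) == []
        assert len(db.triage_log) == len(truths)

    def test_unknown_image_and_region_rejected_processing_continues(self, scheme):
        db, truths = _lung_db(scheme)
        some = next(iter(truths))
        cands = [
            Candidate("ghost", "lung", truths[some]),
            Candidate(some, "spleen", truths[some]),
            Candidate(some, "lung", truths[some]),
        ]
        events = build_review_queue(db, cands)
        assert events == []
        assert len(db.triage_log) == 1  # only the valid candidate was triaged

    def test_events_ordered_and_reasons_recorded(self, scheme):
        db, truths = _lung_db(scheme)
        ids = sorted(truths)
        # make one reference unacceptable; give another a mid-band candidate
        db.assessments.append(
            AssessmentRecord(ids[1], "lung", Grade.UNACCEPTABLE),
            scheme,
        )
        half = truths[ids[0]].copy()
        flat = np.flatnonzero(half)
        half.flat[flat[: len(flat) // 3]] = False  # dc ~ 0.8
        cands = [
            Candidate(ids[0], "lung", half),
            Candidate(ids[1], "lung", truths[ids[1]]),
        ]
        events = build_review_queue(db, cands)
        assert [e.image_id for e in events] == [ids[0], ids[1]]
        assert events[0].reason == "dc-in-range"
        assert events[1].reason == "reference-unacceptable"

    def test_widening_band_never_shrinks_queue(self, scheme):
        db, truths = _lung_db(scheme, n=6)
        rng = np.random.default_rng(3)
        cands = []
        for iid, mask in truths.items():
            keep = mask.copy()
            flat = np.flatnonzero(keep)
            drop = rng.integers(0, len(flat) // 2)
            keep.flat[flat[:drop]] = False
            cands.append(Candidate(iid, "lung", keep))
        sizes = []
        for lo, hi in [(0.85, 0.90), (0.75, 0.95), (0.50, 0.99)]:
            db2, _ = _lung_db(scheme, n=6)
            sizes.append(
                len(build_review_queue(db2, cands, TriageConfig(td_low=lo, td_high=hi)))
            )
        assert sizes == sorted(sizes)


class TestReviewDecision:
    def test_accept_replaces_region_and_upgrades_grade(self, scheme):
        db, truths = _lung_db(scheme, n=1)
        iid = next(iter(truths))
        db.assessments.append(
            AssessmentRecord(iid, "lung", Grade.UNACCEPTABLE),
            scheme,
        )
        lm = db.label_maps[iid]
        cand = Candidate(iid, "lung", region_subvolume(lm, "lung", scheme), "new/2.0")
        (event,) = build_review_queue(db, [cand])
        v0 = lm.version
        apply_review_decision(
            db, event, cand, "accept-candidate", new_grade="good", reviewer_id="r1"
        )
        assert db.current_grade(iid, "lung") == Grade.GOOD
        assert db.label_maps[iid].version == v0 + 1
        assert db.label_maps[iid].provenance["lung"] == "new/2.0"

    def test_keep_reference_leaves_database_unchanged(self, scheme):
        db, truths = _lung_db(scheme, n=1)
        iid = next(iter(truths))
        shrunk = truths[iid].copy()
        flat = np.flatnonzero(shrunk)
        shrunk.flat[flat[: len(flat) // 3]] = False
        cand = Candidate(iid, "lung", shrunk)
        (event,) = build_review_queue(db, [cand])
        before = db.label_maps[iid].volume.copy()
        apply_review_decision(
            db, event, None, "keep-reference", new_grade="unacceptable",
            reviewer_id="r1",
        )
        np.testing.assert_array_equal(db.label_maps[iid].volume, before)
        assert db.current_grade(iid, "lung") == Grade.GOOD  # archived, not current

    def test_accept_then_requeue_is_idempotent(self, scheme):
        db, truths = _lung_db(scheme, n=1)
        iid = next(iter(truths))
        db.assessments.append(
            AssessmentRecord(iid, "lung", Grade.UNACCEPTABLE),
            scheme,
        )
        grown = np.asarray(truths[iid]).copy()
        grown[0:2] = True  # candidate distinct from reference
        cand = Candidate(iid, "lung", grown)
        (event,) = build_review_queue(db, [cand])
        apply_review_decision(
            db, event, cand, "accept-candidate", new_grade="good", reviewer_id="r1"
        )
        assert build_review_queue(db, [cand]) == []  # dc = 1 now

    def test_partition_preserved_after_accept(self, scheme, full_phantom):
        lm, truth = full_phantom
        db = VeqrDatabase(scheme)
        spec = PhantomSpec(seed=3)
        db.add_image(
            phantom_image_record(spec, lm.image_id), lm.copy(),
            {r: "good" if r not in ("lung", "skin") else "good" for r in truth},
        )
        db.assessments.append(
            AssessmentRecord(lm.image_id, "lung", Grade.UNACCEPTABLE),
            scheme,
        )
        cand_vol = region_subvolume(lm, "lung", scheme)
        cand = Candidate(lm.image_id, "lung", cand_vol)
        (event,) = build_review_queue(db, [cand])
        apply_review_decision(
            db, event, cand, "accept-candidate", new_grade="good", reviewer_id="r1"
        )
        db.label_maps[lm.image_id].validate(scheme)
        # other regions untouched
        np.testing.assert_array_equal(
            db.reference_mask(lm.image_id, "rib"),
            np.isin(lm.volume, scheme.region_labels("rib")),
        )

    def test_candidate_claiming_foreign_labels_refused(self, scheme, full_phantom):
        lm, truth = full_phantom
        db = VeqrDatabase(scheme)
        db.add_image(
            phantom_image_record(PhantomSpec(seed=3), lm.image_id), lm.copy(),
            {"lung": "unacceptable"},
        )
        bad = truth["lung"] | truth["cardiac region"]  # claims heart voxels
        cand = Candidate(lm.image_id, "lung", bad)
        (event,) = build_review_queue(db, [cand])
        with pytest.raises(ValueError, match="refused"):
            apply_review_decision(
                db, event, cand, "accept-candidate", new_grade="good",
                reviewer_id="r1",
            )

    def test_decided_event_cannot_be_redecided(self, scheme):
        db, truths = _lung_db(scheme, n=1)
        iid = next(iter(truths))
        db.assessments.append(
            AssessmentRecord(iid, "lung", Grade.UNACCEPTABLE),
            scheme,
        )
        cand = Candidate(iid, "lung", truths[iid])
        (event,) = build_review_queue(db, [cand])
        apply_review_decision(db, event, None, "keep-reference", reviewer_id="r1")
        with pytest.raises(ValueError, match="already decided"):
            apply_review_decision(db, event, None, "keep-reference", reviewer_id="r1")


class TestIngestion:
    def _adapter(self, scheme, volume, regions, failed=False, name="a"):
        return SegmenterAdapter(
            name=name, version="1.0", regions=tuple(regions),
            fn=lambda _id: (volume, failed),
        )

    def test_ingest_grows_all_database_components(self, scheme):
        spec = PhantomSpec(shape=(32,) * 3, organs=("lung",), seed=9)
        lm, truth = generate_phantom(spec, scheme)
        db = VeqrDatabase(scheme)
        adapter = self._adapter(scheme, region_subvolume(lm, "lung", scheme), ["lung"])
        ingest_new_image(db, phantom_image_record(spec, "n1"), [adapter], {"lung": "good"})
        assert set(db.images) == {"n1"}
        assert set(db.label_maps) == {"n1"}
        assert db.current_grade("n1", "lung") == Grade.GOOD

    def test_adapter_failure_forces_unacceptable_and_no_labels(self, scheme):
        spec = PhantomSpec(shape=(32,) * 3, organs=("lung",), seed=9)
        lm, _ = generate_phantom(spec, scheme)
        db = VeqrDatabase(scheme)
        failing = self._adapter(
            scheme, region_subvolume(lm, "lung", scheme), ["lung"], failed=True
        )
        ingest_new_image(db, phantom_image_record(spec, "n1"), [failing], {"lung": "good"})
        assert db.current_grade("n1", "lung") == Grade.UNACCEPTABLE
        assert not db.reference_mask("n1", "lung").any()

    def test_duplicate_image_id_refused(self, scheme):
        spec = PhantomSpec(shape=(32,) * 3, organs=("lung",), seed=9)
        lm, _ = generate_phantom(spec, scheme)
        db = VeqrDatabase(scheme)
        adapter = self._adapter(scheme, region_subvolume(lm, "lung", scheme), ["lung"])
        rec = phantom_image_record(spec, "n1")
        ingest_new_image(db, rec, [adapter], {"lung": "good"})
        with pytest.raises(ValueError, match="already documented"):
            ingest_new_image(db, rec, [adapter], {"lung": "good"})

    def test_collision_resolved_by_adapter_precedence(self, scheme):
        vol_a = np.zeros((8, 8, 8), np.uint16)
        vol_a[2:5] = 4  # lung_left
        vol_b = np.zeros((8, 8, 8), np.uint16)
        vol_b[4:7] = 60  # skin, overlapping plane 4
        db = VeqrDatabase(scheme)
        rec = ImageRecord("c1", "T", 1.0, shape=(8, 8, 8))
        ingest_new_image(
            db, rec,
            [
                self._adapter(scheme, vol_a, ["lung"], name="lung"),
                self._adapter(scheme, vol_b, ["skin"], name="skin"),
            ],
            {"lung": "good", "skin": "good"},
        )
        vol = db.label_maps["c1"].volume
        assert (vol[4] == 4).all()  # first adapter wins the contested plane
        assert (vol[5] == 60).all()

    def test_stray_labels_rejected(self, scheme):
        vol = np.zeros((8, 8, 8), np.uint16)
        vol[0] = 6  # heart label from a lung adapter
        db = VeqrDatabase(scheme)
        rec = ImageRecord("s1", "T", 1.0, shape=(8, 8, 8))
        with pytest.raises(ValueError, match="outside"):
            ingest_new_image(
                db, rec, [self._adapter(scheme, vol, ["lung"])], {"lung": "good"}
            )


class TestPersistence:
    def test_save_load_roundtrip(self, scheme, tmp_path):
        db, truths = _lung_db(scheme, n=2)
        iid = sorted(truths)[0]
        shrunk = truths[iid].copy()
        flat = np.flatnonzero(shrunk)
        shrunk.flat[flat[: len(flat) // 3]] = False
        events = build_review_queue(db, [Candidate(iid, "lung", shrunk)])
        db.save(tmp_path / "db")
        back = VeqrDatabase.load(tmp_path / "db")
        assert set(back.images) == set(db.images)
        for i in db.images:
            np.testing.assert_array_equal(
                back.label_maps[i].volume, db.label_maps[i].volume
            )
        assert back.current_grade(iid, "lung") == db.current_grade(iid, "lung")
        assert [e.to_dict() for e in back.queue] == [e.to_dict() for e in db.queue]
        assert len(back.triage_log) == len(db.triage_log)
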