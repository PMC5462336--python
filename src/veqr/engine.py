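"""The review protocol engine: evaluation, triage, revision, ingestion.

The documented-image database ``D`` has four parts: the image set ``I``,
the label maps ``L`` (one per image), the assessment set ``A`` (one grade
per image and graded region) and the reference algorithm set ``R`` (the
segmenter adapters that document new images).

Evaluating a new algorithm for region *s* runs over the evaluation subset
``I_EV`` -- images whose reference segmentation of *s* is graded good or
acceptable -- computes the Dice coefficient of each candidate against the
reference, and averages it into an aggregate score.  Database revision
applies a three-branch triage to each comparison:

* ``DC < T_low``       -> the candidate is inferior; no update;
* ``DC > T_high``      -> no significant difference; no update;
* ``T_low <= DC <= T_high`` -> a human must look: queue a side-by-side
  review event.

Images whose *reference* is graded unacceptable are always queued (the
Dice value against a failed reference is meaningless).  With the default
band [0.75, 0.95] only a small fraction of a large cohort ever reaches a
human, which is what makes documentation of tens of thousands of scans
tractable.
"""

from __future__ import annotations

import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .label_store import (
    AssessmentRecord,
    AssessmentStore,
    Grade,
    ImageRecord,
    LabelMap,
    LabelScheme,
    default_chest_scheme,
    extract_region_mask,
    read_label_map,
    write_label_map,
)
from .region_compare import dice
from .phantoms import SegmenterAdapter

__all__ = [
    "TriageConfig",
    "TriageAction",
    "TriageDecision",
    "ReviewEvent",
    "Candidate",
    "VeqrDatabase",
    "triage",
    "select_evaluation_set",
    "select_worst_case_set",
    "aggregate_score",
    "build_review_queue",
    "apply_review_decision",
    "ingest_new_image",
    "passes_development_gate",
    "NoEvaluableImagesError",
]

log = logging.getLogger("veqr")


class NoEvaluableImagesError(RuntimeError):
    """The evaluation set I_EV is empty; an aggregate score is undefined."""


@dataclass(frozen=True)
class TriageConfig:
    """Thresholds governing selective review.

    ``td_low``/``td_high`` bracket the needs-review Dice band (defaults
    0.75 / 0.95).  Both branch rules are strict inequalities, so a Dice
    exactly equal to either threshold falls into the review band.
    ``review_failed_reference`` queues every candidate whose reference is
    graded unacceptable regardless of Dice.  ``development_gate`` is the
    minimum acceptable-fraction a new algorithm must reach on the
    development set before a full-dataset run (default 90%).
    """

    td_low: float = 0.75
    td_high: float = 0.95
    review_failed_reference: bool = True
    development_gate: float = 0.90

    def __post_init__(self) -> None:
        if not 0.0 <= self.td_low <= self.td_high <= 1.0:
            raise ValueError(
                f"need 0 <= td_low <= td_high <= 1, got "
                f"({self.td_low}, {self.td_high})"
            )


class TriageAction:
    NO_UPDATE_INFERIOR = "no-update-inferior"
    NO_UPDATE_EQUIVALENT = "no-update-equivalent"
    REVIEW = "review"


@dataclass(frozen=True)
class TriageDecision:
    action: str
    reason: str | None = None  # {"dc-in-range", "reference-unacceptable"}


def triage(
    ref_grade: Grade | str | None, dc: float | None, cfg: TriageConfig
) -> TriageDecision:
    """Apply the three-branch revision rule to one comparison.

    An unacceptable (or missing) reference grade short-circuits to review
    when ``cfg.review_failed_reference`` is set.  Otherwise ``dc`` must be
    in [0, 1]: below the band is inferior, above it is equivalent, inside
    (inclusive at both endpoints) requires review.
    """
    grade = Grade.parse(ref_grade) if ref_grade is not None else None
    failed_ref = grade is None or grade == Grade.UNACCEPTABLE
    if failed_ref and cfg.review_failed_reference:
        return TriageDecision(TriageAction.REVIEW, "reference-unacceptable")
    if dc is None or not 0.0 <= dc <= 1.0:
        raise ValueError(f"Dice value must be in [0, 1], got {dc!r}")
    if dc < cfg.td_low:
        return TriageDecision(TriageAction.NO_UPDATE_INFERIOR)
    if dc > cfg.td_high:
        return TriageDecision(TriageAction.NO_UPDATE_EQUIVALENT)
    return TriageDecision(TriageAction.REVIEW, "dc-in-range")


@dataclass
class ReviewEvent:
    """One queued side-by-side comparison and (eventually) its decision."""

    event_id: int
    image_id: str
    region: str
    ref_version: int
    candidate_provenance: str
    dc: float | None
    reason: str  # {"dc-in-range", "reference-unacceptable"}
    decision: str = "pending"  # {"pending", "accept-candidate", "keep-reference"}
    new_grade: Grade | None = None
    reviewer_id: str | None = None
    timestamp: str | None = None

    def __post_init__(self) -> None:
        if self.new_grade is not None:
            self.new_grade = Grade.parse(self.new_grade)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["new_grade"] = self.new_grade.value if self.new_grade else None
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ReviewEvent":
        d = dict(d)
        if d.get("new_grade"):
            d["new_grade"] = Grade.parse(d["new_grade"])
        return cls(**d)


@dataclass(frozen=True)
class Candidate:
    """One candidate segmentation to be triaged against the database."""

    image_id: str
    region: str
    mask: np.ndarray  # binary region mask or labelled uint16 subvolume
    provenance: str = "candidate/1.0"

    @property
    def binary(self) -> np.ndarray:
        m = np.asarray(self.mask)
        return m if m.dtype == bool else m > 0


@dataclass(frozen=True)
class TriageRecord:
    """Audit-log entry for one triaged comparison (queued or not)."""

    image_id: str
    region: str
    dc: float | None
    action: str
    reason: str | None
    algorithm: str


class VeqrDatabase:
    """In-memory documented-image database with directory persistence."""

    def __init__(self, scheme: LabelScheme | None = None) -> None:
        self.scheme = scheme or default_chest_scheme()
        self.images: dict[str, ImageRecord] = {}
        self.label_maps: dict[str, LabelMap] = {}
        self.assessments = AssessmentStore()
        self.queue: list[ReviewEvent] = []
        self.triage_log: list[TriageRecord] = []
        self._next_event_id = 1

    # -- bookkeeping -----------------------------------------------------

    def add_image(
        self,
        record: ImageRecord,
        label_map: LabelMap,
        grades: Mapping[str, Grade | str] | None = None,
        algorithm_version: str = "",
        reviewer: str = "",
        timestamp: str = "",
    ) -> None:
        if record.image_id in self.images:
            raise ValueError(f"image {record.image_id!r} already documented")
        label_map.validate(self.scheme)
        if record.shape != (0, 0, 0) and tuple(label_map.volume.shape) != record.shape:
            raise ValueError(
                f"label map grid {label_map.volume.shape} does not match "
                f"image record grid {record.shape}"
            )
        self.images[record.image_id] = record
        self.label_maps[record.image_id] = label_map
        for region, grade in (grades or {}).items():
            self.assessments.append(
                AssessmentRecord(
                    image_id=record.image_id,
                    region=region,
                    grade=Grade.parse(grade),
                    reviewer=reviewer,
                    algorithm_version=algorithm_version,
                    timestamp=timestamp,
                ),
                scheme=self.scheme,
            )

    def current_grade(self, image_id: str, region: str) -> Grade | None:
        return self.assessments.current_grade(image_id, region)

    def reference_mask(self, image_id: str, region: str) -> np.ndarray:
        return extract_region_mask(self.label_maps[image_id], region, self.scheme)

    def next_event_id(self) -> int:
        eid = self._next_event_id
        self._next_event_id += 1
        return eid

    # -- persistence -----------------------------------------------------

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        if path.exists():
            shutil.rmtree(path)
        (path / "labels").mkdir(parents=True)
        self.scheme.to_json(path / "scheme.json")
        with (path / "images.jsonl").open("w") as fh:
            for rec in self.images.values():
                fh.write(json.dumps(rec.to_dict()) + "\n")
        self.assessments.to_jsonl(path / "assessments.jsonl")
        with (path / "queue.jsonl").open("w") as fh:
            for ev in self.queue:
                fh.write(json.dumps(ev.to_dict()) + "\n")
        with (path / "triage_log.jsonl").open("w") as fh:
            for tr in self.triage_log:
                fh.write(json.dumps(tr.__dict__) + "\n")
        meta = {}
        for image_id, lm in self.label_maps.items():
            write_label_map(lm, path / "labels" / f"{image_id}.nii.gz")
            meta[image_id] = {"version": lm.version, "provenance": lm.provenance}
        (path / "label_meta.json").write_text(json.dumps(meta, indent=1))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "VeqrDatabase":
        path = Path(path)
        db = cls(scheme=LabelScheme.from_json(path / "scheme.json"))
        with (path / "images.jsonl").open() as fh:
            for line in fh:
                if line.strip():
                    rec = ImageRecord.from_dict(json.loads(line))
                    db.images[rec.image_id] = rec
        db.assessments = AssessmentStore.from_jsonl(path / "assessments.jsonl")
        qpath = path / "queue.jsonl"
        if qpath.exists():
            with qpath.open() as fh:
                db.queue = [
                    ReviewEvent.from_dict(json.loads(line))
                    for line in fh
                    if line.strip()
                ]
            db._next_event_id = max((e.event_id for e in db.queue), default=0) + 1
        tpath = path / "triage_log.jsonl"
        if tpath.exists():
            with tpath.open() as fh:
                db.triage_log = [
                    TriageRecord(**json.loads(line)) for line in fh if line.strip()
                ]
        meta = json.loads((path / "label_meta.json").read_text())
        for image_id in db.images:
            lm = read_label_map(
                path / "labels" / f"{image_id}.nii.gz", db.scheme, image_id=image_id
            )
            m = meta.get(image_id, {})
            lm.version = int(m.get("version", 1))
            lm.provenance = dict(m.get("provenance", {}))
            db.label_maps[image_id] = lm
        return db


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


def select_evaluation_set(db: VeqrDatabase, region: str) -> list[str]:
    """The evaluation subset I_EV: images whose current reference grade for
    *region* is good or acceptable, sorted by image id."""
    db.scheme.region_labels(region)  # raises on unknown region
    return sorted(
        image_id
        for image_id in db.images
        if (g := db.current_grade(image_id, region)) is not None
        and g >= Grade.ACCEPTABLE
    )


def select_worst_case_set(db: VeqrDatabase, region: str) -> list[str]:
    """Images graded unacceptable (or not graded at all) for *region* --
    the worst-case development set."""
    out = []
    for image_id in sorted(db.images):
        g = db.current_grade(image_id, region)
        if g is None or g == Grade.UNACCEPTABLE:
            out.append(image_id)
    return out


def aggregate_score(dcs: Sequence[tuple[str, float]]) -> float:
    """Arithmetic mean Dice over the evaluation set."""
    if not dcs:
        raise NoEvaluableImagesError(
            "no evaluable images: the evaluation set I_EV is empty"
        )
    return float(np.mean([d for _, d in dcs]))


def passes_development_gate(
    grades: Iterable[Grade | str], level: float = 0.90
) -> bool:
    """Minimum-performance gate for introducing a new algorithm: at least
    ``level`` of development-set outcomes graded acceptable or better."""
    gs = [Grade.parse(g) for g in grades]
    if not gs:
        return False
    frac = sum(g >= Grade.ACCEPTABLE for g in gs) / len(gs)
    return frac >= level


# ---------------------------------------------------------------------------
# Review queue construction
# ---------------------------------------------------------------------------


def build_review_queue(
    db: VeqrDatabase,
    candidates: Sequence[Candidate],
    cfg: TriageConfig | None = None,
) -> list[ReviewEvent]:
    """Triage candidate segmentations; queue one pending event per review.

    Every candidate is compared (Dice) against the current reference region
    mask and routed through :func:`triage`; only review actions produce
    events.  Candidates for unknown images or regions are rejected with a
    logged diagnostic and processing continues.  Events are created in
    deterministic ``(image_id, region)`` order.  Every triaged comparison
    (queued or not) is appended to ``db.triage_log``.
    """
    cfg = cfg or TriageConfig()
    events: list[ReviewEvent] = []
    for cand in sorted(candidates, key=lambda c: (c.image_id, c.region)):
        if cand.image_id not in db.images:
            log.warning("candidate for unknown image %r rejected", cand.image_id)
            continue
        if cand.region not in db.scheme.regions:
            log.warning(
                "candidate for unknown region %r (image %r) rejected",
                cand.region, cand.image_id,
            )
            continue
        ref_grade = db.current_grade(cand.image_id, cand.region)
        ref_mask = db.reference_mask(cand.image_id, cand.region)
        dc = dice(ref_mask, cand.binary)
        decision = triage(ref_grade, dc, cfg)
        db.triage_log.append(
            TriageRecord(
                image_id=cand.image_id,
                region=cand.region,
                dc=dc,
                action=decision.action,
                reason=decision.reason,
                algorithm=cand.provenance,
            )
        )
        log.info(
            "triage %s/%s dc=%.4f -> %s%s",
            cand.image_id, cand.region, dc, decision.action,
            f" ({decision.reason})" if decision.reason else "",
        )
        if decision.action == TriageAction.REVIEW:
            event = ReviewEvent(
                event_id=db.next_event_id(),
                image_id=cand.image_id,
                region=cand.region,
                ref_version=db.label_maps[cand.image_id].version,
                candidate_provenance=cand.provenance,
                dc=dc,
                reason=decision.reason,
            )
            db.queue.append(event)
            events.append(event)
    return events


# ---------------------------------------------------------------------------
# Database revision
# ---------------------------------------------------------------------------


def apply_review_decision(
    db: VeqrDatabase,
    event: ReviewEvent,
    candidate: Candidate | None,
    decision: str,
    new_grade: Grade | str | None = None,
    reviewer_id: str = "",
    timestamp: str = "",
) -> VeqrDatabase:
    """Record a reviewer decision on a pending event and revise the database.

    ``accept-candidate`` replaces the voxels of the region's labels in the
    label map with the candidate's labels: previous region voxels not
    claimed by the candidate revert to background, the map version
    increments, and a new assessment record (the candidate's grade) is
    appended.  The candidate may only claim voxels that are currently
    background or belong to the region being replaced; anything else would
    break the partition and the update is refused.

    ``keep-reference`` leaves the label map and current grades untouched;
    if a candidate grade is supplied it is archived in the assessment
    history (kind ``candidate-archived``) without ever becoming current.
    """
    if event.decision != "pending":
        raise ValueError(f"event {event.event_id} already decided")
    if decision not in ("accept-candidate", "keep-reference"):
        raise ValueError(f"unknown decision {decision!r}")
    if not reviewer_id:
        raise ValueError("a reviewer id is required to decide an event")

    if decision == "accept-candidate":
        if candidate is None:
            raise ValueError("accept-candidate requires the candidate segmentation")
        if new_grade is None:
            raise ValueError("accept-candidate requires the candidate's grade")
        grade = Grade.parse(new_grade)
        members = db.scheme.region_labels(event.region)
        lm = db.label_maps[event.image_id]
        cand = np.asarray(candidate.mask)
        if cand.shape != lm.volume.shape:
            raise ValueError("candidate grid does not match the label map grid")
        if cand.dtype == bool:
            cand_labels = np.where(cand, np.uint16(members[0]), np.uint16(0))
        else:
            cand_labels = cand.astype(np.uint16, copy=False)
            present = set(np.unique(cand_labels).tolist()) - {0}
            stray = sorted(present - set(members))
            if stray:
                raise ValueError(
                    f"candidate for region {event.region!r} carries labels "
                    f"{stray} outside the region; update refused"
                )
        claim = cand_labels > 0
        occupied = lm.volume[claim]
        blocked = ~np.isin(occupied, members + [db.scheme.background])
        if blocked.any():
            offending = sorted(set(occupied[blocked].tolist()))
            raise ValueError(
                "candidate overlaps non-replaceable labels "
                f"{offending}; update refused"
            )
        vol = lm.volume.copy()
        vol[np.isin(vol, members)] = db.scheme.background
        vol[claim] = cand_labels[claim]
        lm.volume = vol
        lm.version += 1
        lm.provenance[event.region] = event.candidate_provenance
        db.assessments.append(
            AssessmentRecord(
                image_id=event.image_id,
                region=event.region,
                grade=grade,
                reviewer=reviewer_id,
                algorithm_version=event.candidate_provenance,
                timestamp=timestamp,
            ),
            scheme=db.scheme,
        )
        event.new_grade = grade
    else:
        if new_grade is not None:
            db.assessments.append(
                AssessmentRecord(
                    image_id=event.image_id,
                    region=event.region,
                    grade=Grade.parse(new_grade),
                    reviewer=reviewer_id,
                    algorithm_version=event.candidate_provenance,
                    timestamp=timestamp,
                    kind="candidate-archived",
                ),
                scheme=db.scheme,
            )
            event.new_grade = Grade.parse(new_grade)

    event.decision = decision
    event.reviewer_id = reviewer_id
    event.timestamp = timestamp or "unset"
    return db


# ---------------------------------------------------------------------------
# New image ingestion
# ---------------------------------------------------------------------------


def ingest_new_image(
    db: VeqrDatabase,
    record: ImageRecord,
    adapters: Sequence[SegmenterAdapter],
    grades: Mapping[str, Grade | str],
    algorithm_version: str = "reference",
    reviewer: str = "",
    timestamp: str = "",
) -> VeqrDatabase:
    """Document a new image: run the reference adapters, merge, grade.

    Adapters run in list order, which is also the label-collision
    precedence: a voxel claimed by an earlier adapter is never overwritten.
    An adapter that self-reports failure forces grade unacceptable for its
    regions and contributes no labels.  ``grades`` supplies the visual
    grades for the successful regions.
    """
    if record.image_id in db.images:
        raise ValueError(f"image {record.image_id!r} already documented")
    covered = {r for a in adapters for r in a.regions}
    merged: np.ndarray | None = None
    final_grades: dict[str, Grade] = {}
    for adapter in adapters:
        out, failed = adapter(record.image_id)
        out = np.asarray(out)
        if merged is None:
            merged = np.zeros(out.shape, dtype=np.uint16)
        if failed:
            for region in adapter.regions:
                final_grades[region] = Grade.UNACCEPTABLE
            continue
        allowed = {
            lv for region in adapter.regions
            for lv in db.scheme.region_labels(region)
        }
        present = set(np.unique(out).tolist()) - {0}
        stray = sorted(present - allowed)
        if stray:
            raise ValueError(
                f"adapter {adapter.name!r} produced labels {stray} outside "
                f"its declared regions {adapter.regions}"
            )
        free = (merged == 0) & (out > 0)
        merged[free] = out.astype(np.uint16, copy=False)[free]
        for region in adapter.regions:
            if region in grades:
                final_grades[region] = Grade.parse(grades[region])
    if merged is None:
        raise ValueError("ingestion requires at least one adapter")
    for region in grades:
        if region not in covered:
            raise ValueError(
                f"grade supplied for region {region!r} not covered by any adapter"
            )
    lm = LabelMap(
        image_id=record.image_id,
        volume=merged,
        spacing_mm=record.spacing_mm,
        provenance={
            region: f"{a.name}/{a.version}"
            for a in adapters for region in a.regions
        },
    )
    db.add_image(
        record, lm, final_grades,
        algorithm_version=algorithm_version,
        reviewer=reviewer, timestamp=timestamp,
    )
    return db
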