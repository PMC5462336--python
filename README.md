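# veqr — visual evaluation with quantitative review

`veqr` is a toolkit for curating segmentation quality across very large 3-D
image databases, built for the regime where tens of thousands of low-dose
chest CT scans are segmented fully automatically and no human can look at
every outcome.  It implements the VEQR protocol: every image carries a
*label map* (one anatomical label per voxel) and a set of categorical
grades — good (G), acceptable (A), unacceptable (U) — per graded region
(lung, airway, rib, vertebra, skin, cardiac region, breast), and new
algorithm outcomes are triaged by the Dice coefficient so that only a small
fraction ever needs side-by-side human review.

## The protocol

For a region *s* with reference segmentation `l_s(i)` and a new candidate
`l_s^n(i)`, the comparison score is the Dice coefficient

    DC = 2 |l_s ∩ l_s^n| / (|l_s| + |l_s^n|)

evaluated over I_EV, the images whose reference grade for *s* is G or A.
Database revision applies a three-branch rule with thresholds
T_low = 0.75 and T_high = 0.95:

* `DC < T_low` — the candidate is inferior; no update, no review;
* `DC > T_high` — no significant difference; no update, no review;
* `T_low ≤ DC ≤ T_high` — a human decides, side by side.

Images whose *reference* is graded U are always reviewed (Dice against a
failed reference means nothing).  Accepted candidates replace the region's
voxels in the label map and the new grade is recorded; the history is
append-only.

Two error classes drive the grading.  *Precision* errors (EP) are
boundary-detail disagreements spread along the region surface.
*Catastrophic* errors (EC) are connected wrong regions touching less than
half of the true surface while changing volume or spatial extent
significantly — a lung leaking into the bowel, a dropped bronchus.
`veqr.classify_error` detects EC automatically from connected components of
the mask disagreement; this matters because a compact leak of a few percent
of a large organ leaves DC above 0.95, so overlap alone would wave it
through.

A dependency graph gates downstream processing: a module whose input region
is graded below its minimum must not run (failed lung ⇒ no nodule
analysis), and each quantitative biomarker (emphysema index, coronary
calcium, breast density, …) is evaluable only when its required regions
meet their minimum grades.  A cohort ledger accounts for scan
inclusion/exclusion under the screening protocol (low-dose, slice thickness
≤ 2 mm, noncontrast, supine, whole-lung coverage, no implant artifacts).

Everything is testable without real CT data: `veqr.phantoms` generates
seeded multi-organ label-map phantoms (two lungs, branching airway, cardiac
triple, 15 vertebrae, 24 ribs, skin shell, breast caps) with controlled
EP/EC error injection and simulated segmentation algorithms of known
failure rate.

## Worked example

```python
from veqr import (Candidate, ErrorSpec, PhantomSpec, VeqrDatabase,
                  build_review_queue, classify_error, default_chest_scheme,
                  generate_phantom, inject_error, phantom_image_record)

scheme = default_chest_scheme()
label_map, truth = generate_phantom(PhantomSpec(seed=7), scheme)
lung = truth["lung"]

benign = inject_error(lung, ErrorSpec("boundary", target="lung", seed=1))
leak = inject_error(lung, ErrorSpec("leak_blob", target="lung", seed=1,
                                    volume_fraction=0.08))
for name, seg in [("boundary bumps", benign), ("attached leak", leak)]:
    res = classify_error(lung, seg)
    print(f"{name:14s}  DC = {res.dc:.3f}  error class = {res.error_class}")
```

prints

```
boundary bumps  DC = 0.997  error class = precision
attached leak   DC = 0.970  error class = catastrophic
```

Both candidates have DC > 0.95 — quantitative triage alone would file both
as "equivalent to the reference" — yet the second contains a leak of 8% of
the lung volume attached to a small surface patch: the error classifier
flags it catastrophic, which is exactly why visual grading is part of the
protocol and why a high Dice score never certifies a segmentation.

A larger leak lands in the review band and queues an event:

```python
big_leak = inject_error(lung, ErrorSpec("leak_blob", target="lung", seed=1,
                                        volume_fraction=0.3))
db = VeqrDatabase(scheme)
db.add_image(phantom_image_record(PhantomSpec(seed=7), label_map.image_id),
             label_map, {r: "good" for r in truth})
events = build_review_queue(
    db, [Candidate(label_map.image_id, "lung", big_leak, "algo/2.0")])
print(events[0].reason, round(events[0].dc, 3))
```

prints

```
dc-in-range 0.875
```

The same flow is scriptable from a shell: `veqr simulate` writes a phantom
cohort, `veqr ingest` documents it, `veqr evaluate` scores a candidate
algorithm over I_EV, `veqr revise` queues review events, `veqr decide`
records decisions, `veqr report` prints grade-distribution and
review-burden tables, and `veqr montage` writes side-by-side
orthogonal-slice snapshots for a queued event.

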