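# Methods

## The documented-image database

The database `D` holds four components: the image set `I` (metadata records
referencing the raw scans; the package never interprets intensities), the
label-map set `L` (one dense uint16 volume per image, every voxel exactly
one label — the partition property, revalidated after every mutation), the
assessment set `A` (append-only grade history; the current state is the
latest *reference* record per (image, region); grades of rejected
candidates are archived with `kind="candidate-archived"` and never become
current), and the reference algorithm set `R` (pluggable segmenter
adapters).

Volumes are ordered `(z, y, x)` (slice-major), 0-based voxel indices, with
physical spacing carried in mm.  Comparisons require identical grids and
are never resampled: the Dice coefficient is a set operation on voxels.
Background is label 0; "no-data" (outside the scan reconstruction circle)
is the reserved value 65535.  The shipped chest scheme defines 50
anatomical labels grouped into seven graded regions; the reserved values
are extras outside the label count.

A graded region may comprise many subregion labels (rib: 24, vertebra: 15,
cardiac region: 3).  When subregions are graded individually the region
grade is the **minimum** under `unacceptable < acceptable < good` — one
mislabelled rib makes the rib region unusable for rib-based measurement.
The grade vocabulary is configured per region: lung and skin use two levels
(G/U), the others three.  Two levels express algorithms for which any
visible defect already compromises the biomarker (whole-lung measures).

## Dice triage

`triage(grade, dc, cfg)` is a total function: a failed (or missing)
reference grade routes to review when `review_failed_reference` is set
(default true — Dice against a bad reference is meaningless); otherwise
`dc < td_low` is *inferior*, `dc > td_high` is *equivalent*, and the closed
band `[td_low, td_high]` requires review.  Both published branch rules are
strict inequalities, so Dice exactly equal to either threshold falls in the
review band; this endpoint convention changes queue sizes silently if
gotten wrong, hence it is pinned by tests.  Defaults: `td_low = 0.75`,
`td_high = 0.95`.  Empty/empty masks have Dice 1.0 and one-empty pairs 0.0
(the standard fixed points; they keep triage defined on degenerate
regions).

A new algorithm must reach a 90% acceptable fraction on the development set
before a full-dataset run (`development_gate`, enforced in the CLI `revise
--gate` path) to avoid flooding the review queue.  Revision is an explicit
two-phase workflow — `revise` queues, `decide` applies — never implicit.

## The precision / catastrophic error classifier

Disagreement between a candidate and the reference is split into connected
components (26-connectivity) of `test∖ref` (over-segmentation) and
`ref∖test` (under-segmentation); components are labelled separately per
sign so each is pure.  The reference *surface* is the set of reference
voxels with at least one background 6-neighbour.

For each component:

* **surface contact** — the fraction of surface voxels 6-adjacent to (or
  inside) the component, normalised over the connected reference parts the
  component touches.  The normalisation is per-part because a graded
  region can be anatomically disconnected (two lungs, 24 ribs): a boundary
  shell hugging one lung touches essentially all of *that lung's* surface,
  which is precisely what makes it a precision error, yet it would only
  reach ~50% of the pooled two-lung surface.
* **omission** — an under-component covering at least half of a connected
  reference part counts as localised regardless of contact: dropping a
  whole lung "touches 100% of its surface" but is the canonical
  catastrophic failure, not a boundary error.
* **volume change** — component size over total reference volume;
  significant at ≥ 5% (configurable).
* **extent change** — the largest relative bounding-box extent shift the
  component causes, significant at ≥ 10% (configurable) *and* at least
  2 voxels in absolute terms.  The absolute floor exists because thin
  structures (the vertebra stack's cross-axis box is ~6 voxels) would
  otherwise flag a single-voxel boundary bump as a significant spatial
  change; sub-resolution shifts are boundary noise.

A component is **catastrophic** when it is localised (contact < 0.5, or
omission) and significant (volume or extent); the comparison is
catastrophic if any component is, else precision if any disagreement
exists, else none.  The < 0.5 contact bound has no lower limit.  Connectivity
conventions (26 for components and parts, 6 for surface and adjacency) are
fixed for reproducibility.  An empty reference is an error, not a class.

Out of scope by design: Hausdorff-type locally sensitive distances and
surface-mesh metrics.

## Synthetic phantoms

Phantoms are geometric, not anatomically realistic — the framework consumes
label maps, never intensities, so realism buys nothing.  On the default
64×64×64 grid at 1 mm isotropic spacing (minimum 48³ for the full organ
set, 24³ for lungs-only), the generator paints, in fixed precedence order:
airway (tracheal tube branching into two bronchi), two ellipsoidal lungs,
the cardiac triple (heart ellipsoid, aortic and pulmonary-trunk tubes), 15
vertebral boxes, 24 rib arcs following the body contour with a posterior
gap, two breast surface caps, and a one-voxel body-shell skin.  Later
organs never overwrite earlier ones, so the partition property holds by
construction; ground-truth masks are taken from the final map.  The seed
jitters centres (±2 voxels) and semi-axes (±1); generation is a pure
function of `(spec, seed)` and raises if any requested organ (or rib /
vertebra subregion) comes out empty.

### Error injection

* `boundary` (precision): `max(3, |surface|/150)` random surface sites
  gain or lose a ball of the given radius.  At the default radius 1 this
  leaves Dice ≥ 0.95 on every default organ (measured ~0.99 on the lungs)
  — the scale of disagreement between two competent algorithms.  Site
  selection depends only on the seed, so Dice decreases monotonically in
  the radius.  A uniform whole-boundary dilation is deliberately *not*
  used as the precision model: it costs ~0.11 Dice on a 64³ lung,
  indistinguishable from a sizeable leak, which would make a simulated
  reviewer unable to separate good candidates from failed references.
* `leak_blob` (catastrophic): a ball of the requested volume fraction
  (default 30%, capped at 45%) attached tangentially at a random surface
  point, touching a small surface patch (target contact 5%).  A
  `volume_fraction` of 0.08 produces the instructive case DC ≥ 0.95 *and*
  catastrophic.
* `truncate` (catastrophic): a planar cap of the requested volume fraction
  (default 30%) cut from one end of the longest axis.
* `drop_subregion` / `mislabel_subregion` (catastrophic): remove or
  relabel one subregion label in a labelled subvolume.

Documented default targets for the classifier operating-point suite:
precision on all seven regions; leaks on lung, cardiac region and breast;
truncation on lung, vertebra, airway and breast; drops of a lung, a main
bronchus and the heart.  Truncation is not offered on the cardiac region —
a 30% planar cap of that compact blob touches slightly over half its
surface (measured 0.507), violating the taxonomy's own localisation bound
— nor on the rib region, where each severed rib is ~4% of region volume,
below the 5% significance default: a missing rib is the subregion-grading
path's job, not the binary classifier's.

### Simulated algorithms and reviewer

`simulate_algorithm` wraps the injectors into a segmenter adapter: per
image (decided once, seeded, order-independent) it emits ground truth under
a precision perturbation, or with the configured failure probability
substitutes a catastrophic error from a menu.  Multi-label regions are
relabelled by nearest original label after binary perturbation.  An
explicit failure-id set can replace the random draw; the end-to-end
recovery simulation uses it to express *nested* failures — a corrected
algorithm still failing on a subset of the images the reference failed on —
which is how algorithm revisions behave in practice (they fix failures and
rarely break working cases) and which makes the final unacceptable
fraction converge to the corrected algorithm's own rate.

The simulated reviewer (test machinery standing in for the human step)
accepts a candidate iff its Dice against ground truth strictly exceeds the
reference's; ties keep the reference.  The automatic grader maps
classifier output to grades: catastrophic (or empty) → U, exact → G,
precision → A on three-level vocabularies and G on two-level ones.

### What phantom validation does and does not show

Passing these suites shows the bookkeeping, triage arithmetic, revision
semantics and classifier operating point are correct on label maps whose
error structure is known exactly.  It says nothing about segmentation
accuracy on real CT (no intensities, no noise, no pathology, no scanner
variation), about human grading consistency, or about the classifier's
behaviour on error morphologies outside the injected families.

## Dependency graph and biomarker gating

The chest-analysis module graph and the biomarker table ship as editable
JSON (the label inventory grows; configuration should not require code
changes).  `execution_order` is a deterministic Kahn topological sort
(lexicographic among ready modules) that names the members of any cycle.
`blocked_modules` blocks a module when any prerequisite produced a region
graded below that prerequisite's minimum-input grade (default acceptable)
and propagates transitively; ungraded regions never block — absence of
evidence is not failure.  Biomarker minimum grades default to acceptable;
whole-lung measures (nodule work-up, emphysema index) require good.  Only
dependencies stated by the pipeline design are encoded; modules with no
documented prerequisite beyond the image-quality profile depend on
`image_quality` alone, and the graph computes no biomarker values — that
is downstream science, not curation.

## Cohort ledger

`apply_inclusion` is deterministic and reason-complete: an excluded record
lists every failed criterion (`thickness` > 2.0 mm, `dose`, `position`,
`contrast`, `coverage`, `artifact`), and missing metadata raises rather
than silently including.  "Low-dose" is a recorded metadata flag — the
ledger records, it does not adjudicate dose physics.  All images of a
multi-image case are retained.  The shipped 2016 and 2017 cohort snapshots
are independent tables and are not reconciled against each other.

## Reporting

Reports are pure functions of database state and history; regeneration is
byte-identical.  Grade tables print `count (percent)` with integer
percents, switching to one decimal only when rounding would show 0% for a
non-zero count or 100% for an incomplete one (363/364 → 99.7%).
Replacement fractions use two decimals.  Percentages are always recomputed
from counts, never stored.  Montages replace interactive 3-D review with
deterministic 2-D snapshots: per requested plane, a side-by-side
reference/candidate overlay cut at the centroid slice of the mask union,
composed as an RGB array and written as PNG (empty masks produce an
annotated placeholder).

## Problem sizes and numerical notes

The test and acceptance suites run at the 64³ default grid: the classifier
operating point is measured on 200 seeded injections (100 precision, 100
catastrophic at the documented defaults; both error rates must be zero),
and the end-to-end recovery simulation documents 500 lungs-only phantoms
with a 10%-catastrophic reference and a corrected algorithm of 2% true
rate, asserting the final unacceptable fraction within 3 binomial standard
deviations of 2%.  The published-accounting replay builds its 7173
comparison records as 1×1×120 voxel strips, where a candidate of length
*k* against a 60-voxel reference has exactly DC = 2k/(60+k), so every band
is hit by construction and the queue counts are integer-exact.

Known limitations: same-region subregion mislabelling (rib 3 labelled rib
4) is invisible to the binary region classifier — it changes no region
mask — and is caught only by per-subregion visual grading; the montage
shows one slice per plane, not the full 3-D rendering a production review
station would offer; the database keeps label maps in memory and persists
whole directories, which is adequate for cohorts of thousands of phantom
volumes but not a server-scale store.
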