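"""Seeded multi-organ label-map phantoms and controlled error injection.

The review framework consumes label maps, never raw CT intensities, so its
test data can be purely geometric: two ellipsoidal lungs, a branching
airway tube, a cardiac triple (heart blob, aorta and pulmonary-trunk
tubes), a stack of 15 vertebral boxes, 24 rib arcs, a body-shell skin and
two breast surface caps.  Phantoms are deterministic functions of
``(spec, seed)``; the seed jitters organ positions and sizes so that a
cohort of phantoms varies like a cohort of patients varies.

Error injection produces the two error classes the grading protocol
distinguishes:

* *precision* -- a uniform boundary perturbation (dilate or erode by a
  small radius), the benign disagreement expected between two competent
  algorithms;
* *catastrophic* -- a compact leak blob attached to a small patch of the
  surface, a truncation of part of the organ, or a dropped/mislabelled
  subregion: connected wrong regions that touch well under half of the
  true surface while changing volume or extent substantially.

``simulate_algorithm`` wraps these into a pluggable segmenter stand-in
that emits ground truth perturbed by a precision error and, for a seeded
subset of images, substitutes a catastrophic error -- emulating a real
algorithm with a known failure rate.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import ndimage

from .label_store import (
    Grade,
    ImageRecord,
    LabelMap,
    LabelScheme,
    default_chest_scheme,
)
from .region_compare import classify_error, dice

__all__ = [
    "PhantomSpec",
    "ErrorSpec",
    "generate_phantom",
    "phantom_image_record",
    "inject_error",
    "simulate_algorithm",
    "SegmenterAdapter",
    "auto_grade",
    "SimulatedReviewer",
    "region_subvolume",
]

ALL_ORGANS = (
    "airway",
    "lung",
    "cardiac region",
    "vertebra",
    "rib",
    "breast",
    "skin",
)

#: Smallest grid on which the full organ set is generated.
MIN_FULL_GRID = 48
#: Smallest grid for any phantom at all.
MIN_GRID = 24


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry specification for one phantom.

    ``organs`` lists the graded regions to generate (paint precedence is
    the order of :data:`ALL_ORGANS`: overlapping primitives never collide;
    earlier organs keep their voxels).  ``jitter`` perturbs centres by up
    to ±2 voxels and semi-axes by up to ±1 voxel per seed.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    organs: tuple[str, ...] = ALL_ORGANS
    seed: int = 0
    jitter: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(
            self, "spacing_mm", tuple(float(s) for s in self.spacing_mm)
        )
        object.__setattr__(self, "organs", tuple(self.organs))
        unknown = set(self.organs) - set(ALL_ORGANS)
        if unknown:
            raise ValueError(f"unknown organs {sorted(unknown)}")
        minimum = MIN_FULL_GRID if set(self.organs) - {"lung", "skin"} else MIN_GRID
        if min(self.shape) < minimum:
            raise ValueError(
                f"grid {self.shape} too small for organ set "
                f"{self.organs} (minimum {minimum} per axis)"
            )


def _grids(shape: tuple[int, int, int]):
    return np.meshgrid(
        np.arange(shape[0]), np.arange(shape[1]), np.arange(shape[2]),
        indexing="ij",
    )


def _ellipsoid(zz, yy, xx, center, semi) -> np.ndarray:
    cz, cy, cx = center
    az, ay, ax = semi
    return (
        ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2
    ) <= 1.0


def _tube(zz, yy, xx, p0, p1, radius) -> np.ndarray:
    """Voxels within *radius* of the segment p0-p1 (capsule)."""
    p0 = np.asarray(p0, dtype=float)
    d = np.asarray(p1, dtype=float) - p0
    L2 = float(d @ d)
    vz = zz - p0[0]
    vy = yy - p0[1]
    vx = xx - p0[2]
    t = (vz * d[0] + vy * d[1] + vx * d[2]) / L2 if L2 > 0 else 0.0
    t = np.clip(t, 0.0, 1.0)
    dz = vz - t * d[0]
    dy = vy - t * d[1]
    dx = vx - t * d[2]
    return dz * dz + dy * dy + dx * dx <= radius * radius


def _ball(radius: int) -> np.ndarray:
    r = int(radius)
    ax = np.arange(-r, r + 1)
    z, y, x = np.meshgrid(ax, ax, ax, indexing="ij")
    return z * z + y * y + x * x <= r * r


def _sub_rng(seed: int, *tokens: str) -> np.random.Generator:
    """Independent stream per (seed, tokens); stable across run order."""
    crcs = [zlib.crc32(t.encode()) for t in tokens]
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *crcs])


def generate_phantom(
    spec: PhantomSpec, scheme: LabelScheme | None = None
) -> tuple[LabelMap, dict[str, np.ndarray]]:
    """Generate one phantom label map plus per-region ground-truth masks.

    Returns ``(label_map, truth)`` where ``truth[region]`` is the binary
    mask of that region in the final (precedence-resolved) map, so the
    partition property holds by construction.  Deterministic for a fixed
    spec.

    Raises ``RuntimeError`` when jittered geometry leaves a requested organ
    (or any rib/vertebra subregion) without voxels.
    """
    scheme = scheme or default_chest_scheme()
    Z, Y, X = spec.shape
    rng = _sub_rng(spec.seed, "phantom")
    zz, yy, xx = _grids(spec.shape)
    cz, cy, cx = Z / 2, Y / 2, X / 2

    def jit(lo: float = -2.0, hi: float = 2.0) -> float:
        return float(rng.uniform(lo, hi)) if spec.jitter else 0.0

    body_semi = (0.47 * Z + jit(-1, 1), 0.41 * Y + jit(-1, 1), 0.44 * X + jit(-1, 1))
    body = _ellipsoid(zz, yy, xx, (cz, cy, cx), body_semi)

    vol = np.zeros(spec.shape, dtype=np.uint16)
    truth: dict[str, np.ndarray] = {}
    name_to_value = {v: k for k, v in scheme.labels.items()}

    def paint(mask: np.ndarray, label_name: str) -> np.ndarray:
        claimed = mask & (vol == scheme.background)
        vol[claimed] = name_to_value[label_name]
        return claimed

    # precedence order: ALL_ORGANS; each primitive only claims background
    if "airway" in spec.organs:
        carina = (0.47 * Z + jit(), 0.47 * Y + jit(), cx + jit())
        r_tr = max(2.0, 0.032 * X)
        trachea = _tube(zz, yy, xx, (0.09 * Z, carina[1], carina[2]), carina, r_tr)
        r_br = max(1.5, 0.024 * X)
        br_l = _tube(zz, yy, xx, carina, (0.62 * Z, carina[1], 0.36 * X), r_br)
        br_r = _tube(zz, yy, xx, carina, (0.62 * Z, carina[1], 0.64 * X), r_br)
        paint(trachea, "trachea")
        paint(br_l & ~trachea, "main_bronchus_left")
        paint(br_r & ~trachea & ~br_l, "main_bronchus_right")

    if "lung" in spec.organs:
        semi = (0.28 * Z + jit(-1, 1), 0.19 * Y + jit(-1, 1), 0.14 * X + jit(-1, 1))
        left = _ellipsoid(zz, yy, xx, (cz + jit(), 0.47 * Y + jit(), 0.31 * X + jit()), semi)
        right = _ellipsoid(zz, yy, xx, (cz + jit(), 0.47 * Y + jit(), 0.69 * X + jit()), semi)
        paint(left, "lung_left")
        paint(right & ~left, "lung_right")

    if "cardiac region" in spec.organs:
        heart = _ellipsoid(
            zz, yy, xx,
            (0.62 * Z + jit(), 0.56 * Y + jit(), cx + jit()),
            (0.125 * Z, 0.11 * Y, 0.11 * X),
        )
        aorta = _tube(
            zz, yy, xx,
            (0.31 * Z, 0.53 * Y, cx), (0.69 * Z, 0.53 * Y, cx),
            max(2.0, 0.04 * X),
        )
        trunk = _tube(
            zz, yy, xx,
            (0.44 * Z, 0.44 * Y, 0.53 * X), (0.58 * Z, 0.44 * Y, 0.53 * X),
            max(1.5, 0.03 * X),
        )
        paint(heart, "heart")
        paint(aorta & ~heart, "aorta")
        paint(trunk & ~heart & ~aorta, "pulmonary_trunk")

    if "vertebra" in spec.organs:
        pitch = max(4, int(round(Z / 16)))
        thick = pitch - 1
        z0 = int(round(0.03 * Z))
        y_lo, y_hi = int(0.75 * Y), int(0.85 * Y)
        x_lo, x_hi = int(0.45 * X), int(0.55 * X)
        for k in range(15):
            zlo = z0 + k * pitch
            box = (
                (zz >= zlo) & (zz < zlo + thick)
                & (yy >= y_lo) & (yy < y_hi)
                & (xx >= x_lo) & (xx < x_hi)
            )
            paint(box, f"vertebra_{k + 1:02d}")

    if "rib" in spec.organs:
        # elliptical arcs following the body contour, posterior gap for the
        # spine, 12 levels x left/right
        fz_scale = np.sqrt(
            np.clip(1.0 - ((zz - cz) / (0.47 * Z)) ** 2, 0.0, None)
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            u = np.where(
                fz_scale > 0.3,
                ((yy - cy) / (0.38 * Y * fz_scale + 1e-9)) ** 2
                + ((xx - cx) / (0.41 * X * fz_scale + 1e-9)) ** 2,
                np.inf,
            )
        ring = (u >= 0.70) & (u <= 1.0)
        phi = np.degrees(np.arctan2(xx - cx, yy - cy))  # 0 deg = posterior
        z_lo, z_hi = 0.16 * Z, 0.84 * Z
        levels = np.linspace(z_lo, z_hi, 12)
        for k, zk in enumerate(levels):
            band = (zz >= int(zk)) & (zz < int(zk) + 2)
            paint(band & ring & (phi <= -10) & (phi >= -80), f"rib_left_{k + 1:02d}")
            paint(band & ring & (phi >= 10) & (phi <= 80), f"rib_right_{k + 1:02d}")

    if "breast" in spec.organs:
        r_b = 0.11 * X + jit(-1, 1)
        for side, x0 in (("left", 0.34 * X), ("right", 0.66 * X)):
            cap = _ellipsoid(
                zz, yy, xx,
                (0.69 * Z + jit(-1, 1), 0.12 * Y, x0),
                (r_b, r_b, r_b),
            )
            paint(cap & body, f"breast_{side}")

    if "skin" in spec.organs:
        shell = body & ~ndimage.binary_erosion(
            body, structure=np.ones((3, 3, 3), dtype=bool)
        )
        paint(shell, "skin")

    for organ in spec.organs:
        mask = np.isin(vol, scheme.region_labels(organ))
        if not mask.any():
            raise RuntimeError(
                f"phantom geometry left region {organ!r} empty on grid "
                f"{spec.shape} (seed {spec.seed})"
            )
        truth[organ] = mask

    lm = LabelMap(
        image_id=f"phantom-{spec.seed:06d}",
        volume=vol,
        spacing_mm=spec.spacing_mm,
        provenance={organ: "phantom/1.0" for organ in spec.organs},
    )
    return lm, truth


def phantom_image_record(
    spec: PhantomSpec, image_id: str, cohort: str = "PHANTOM"
) -> ImageRecord:
    """Metadata record for a phantom, compatible with cohort inclusion."""
    return ImageRecord(
        image_id=image_id,
        cohort=cohort,
        slice_thickness_mm=spec.spacing_mm[0],
        dose="low",
        position="supine",
        whole_lung=True,
        contrast=False,
        artifact_excluded=False,
        shape=spec.shape,
        spacing_mm=spec.spacing_mm,
    )


# ---------------------------------------------------------------------------
# Error injection
# ---------------------------------------------------------------------------

_BINARY_KINDS = ("boundary", "leak_blob", "truncate")
_LABEL_KINDS = ("drop_subregion", "mislabel_subregion")


@dataclass(frozen=True)
class ErrorSpec:
    """One controlled segmentation error.

    kind
        ``boundary`` (precision) or one of the catastrophic kinds
        ``leak_blob``, ``truncate``, ``drop_subregion``,
        ``mislabel_subregion``.
    target
        The graded region the error is applied to.
    radius
        Boundary-perturbation radius in voxels (precision; default 1).
    volume_fraction
        Leak-blob / truncation size relative to the region volume.  Kept at
        most 0.45 so the wrong component stays under half the reference
        surface.
    contact_fraction
        Intended fraction of the reference surface touched by a leak blob
        (must be < 0.5).
    label / new_label
        Source (and for mislabel, destination) subregion label value.
    """

    kind: str
    target: str = ""
    seed: int = 0
    radius: int = 1
    volume_fraction: float = 0.30
    contact_fraction: float = 0.05
    label: int | None = None
    new_label: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in _BINARY_KINDS + _LABEL_KINDS:
            raise ValueError(f"unknown error kind {self.kind!r}")
        if self.kind == "boundary" and self.radius < 1:
            raise ValueError("boundary perturbation radius must be >= 1")
        if self.kind in ("leak_blob", "truncate"):
            if not 0.0 < self.volume_fraction <= 0.45:
                raise ValueError(
                    "volume_fraction must be in (0, 0.45] to keep the error "
                    "component under half the reference surface"
                )
        if self.kind == "leak_blob" and not 0.0 < self.contact_fraction < 0.5:
            raise ValueError("contact_fraction must be in (0, 0.5)")
        if self.kind in _LABEL_KINDS and self.label is None:
            raise ValueError(f"{self.kind} requires a source label value")
        if self.kind == "mislabel_subregion" and self.new_label is None:
            raise ValueError("mislabel_subregion requires new_label")

    @property
    def error_class(self) -> str:
        return "precision" if self.kind == "boundary" else "catastrophic"


def inject_error(mask_or_labels: np.ndarray, err: ErrorSpec) -> np.ndarray:
    """Apply a seeded error to a binary region mask or labelled subvolume.

    Binary kinds (``boundary``, ``leak_blob``, ``truncate``) take and
    return a boolean mask; subregion kinds take and return an integer
    labelled subvolume (region labels only).  Pure function of
    ``(input, err)``.
    """
    arr = np.asarray(mask_or_labels)
    rng = _sub_rng(err.seed, "inject", err.kind, err.target)
    if err.kind in _LABEL_KINDS:
        if not np.issubdtype(arr.dtype, np.integer):
            raise TypeError(f"{err.kind} requires a labelled integer volume")
        if not (arr == err.label).any():
            raise ValueError(f"label {err.label} absent from the subvolume")
        out = arr.copy()
        if err.kind == "drop_subregion":
            out[out == err.label] = 0
        else:
            out[out == err.label] = err.new_label
        return out

    mask = arr.astype(bool, copy=False)
    if not mask.any():
        raise ValueError("cannot inject an error into an empty mask")
    if err.kind == "boundary":
        return _perturb_boundary(mask, err.radius, rng)
    if err.kind == "leak_blob":
        return _leak_blob(mask, err.volume_fraction, err.contact_fraction, rng)
    return _truncate(mask, err.volume_fraction, rng)


def _perturb_boundary(
    mask: np.ndarray, radius: int, rng: np.random.Generator
) -> np.ndarray:
    """Add/remove small bumps of the given radius at random surface sites.

    Emulates the boundary-detail disagreement between two competent
    algorithms: a few percent of the surface shifts by ``radius`` voxels,
    leaving Dice against the unperturbed mask high (>= 0.95 at radius 1 on
    the default organs).  The site set depends only on the rng state, so
    growing the radius at a fixed seed perturbs supersets of the same
    voxels and Dice decreases monotonically with radius.
    """
    surface = mask & ~ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(3, 1), border_value=0
    )
    pts = np.argwhere(surface)
    k = min(len(pts), max(3, len(pts) // 150))
    idx = rng.choice(len(pts), size=k, replace=False)
    add = rng.random(k) < 0.5
    offsets = np.argwhere(_ball(radius)) - radius
    out = mask.copy()
    shape = np.asarray(mask.shape)
    for point, grow in zip(pts[idx], add):
        vox = point + offsets
        ok = np.all((vox >= 0) & (vox < shape), axis=1)
        vz, vy, vx = vox[ok].T
        out[vz, vy, vx] = grow
    if not out.any():  # degenerate tiny mask fully removed; keep one bump
        return ndimage.binary_dilation(mask, structure=_ball(radius))
    return out


def _leak_blob(
    mask: np.ndarray,
    volume_fraction: float,
    contact_fraction: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Attach a compact blob to a small surface patch (a 'leak')."""
    v_ref = int(np.count_nonzero(mask))
    target = volume_fraction * v_ref
    rb = max(2, int(round((3.0 * target / (4.0 * np.pi)) ** (1.0 / 3.0))))
    surface = mask & ~ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(3, 1), border_value=0
    )
    pts = np.argwhere(surface)
    centroid = np.argwhere(mask).mean(axis=0)
    shape = np.asarray(mask.shape)
    zz, yy, xx = _grids(tuple(mask.shape))
    order = rng.permutation(len(pts))
    for idx in order[: min(64, len(pts))]:
        s = pts[idx].astype(float)
        normal = s - centroid
        norm = np.linalg.norm(normal)
        if norm == 0:
            continue
        normal /= norm
        center = np.round(s + normal * rb).astype(int)
        if (center < rb).any() or (center > shape - 1 - rb).any():
            continue  # blob would clip against the grid edge
        blob = (
            (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
        ) <= rb * rb
        blob = blob & ~mask
        size = int(np.count_nonzero(blob))
        if size < 0.5 * target:
            continue
        # must attach: 26-adjacent to the mask
        if not (ndimage.binary_dilation(blob, structure=np.ones((3, 3, 3), bool)) & mask).any():
            continue
        return mask | blob
    raise RuntimeError(
        "could not place a leak blob satisfying the surface-contact bound; "
        "organ too small or too close to the grid edge"
    )


def _truncate(
    mask: np.ndarray, volume_fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Cut away a planar cap holding ~volume_fraction of the organ."""
    v_ref = int(np.count_nonzero(mask))
    ext = [np.ptp(np.flatnonzero(np.any(mask, axis=tuple(i for i in range(3) if i != ax))))
           for ax in range(3)]
    axis = int(np.argmax(ext))
    counts = np.count_nonzero(mask, axis=tuple(i for i in range(3) if i != axis))
    from_low = bool(rng.random() < 0.5)
    order = np.arange(mask.shape[axis]) if from_low else np.arange(mask.shape[axis])[::-1]
    cum = np.cumsum(counts[order])
    k = int(np.searchsorted(cum, volume_fraction * v_ref, side="left")) + 1
    cut_planes = order[:k]
    sel = np.zeros(mask.shape[axis], dtype=bool)
    sel[cut_planes] = True
    shape = [1, 1, 1]
    shape[axis] = mask.shape[axis]
    out = mask & ~sel.reshape(shape)
    if not out.any():
        raise RuntimeError("truncation removed the whole organ")
    return out


# ---------------------------------------------------------------------------
# Simulated segmentation algorithms
# ---------------------------------------------------------------------------


@dataclass
class SegmenterAdapter:
    """Pluggable segmenter contract: image-id -> (labelled volume, failed).

    ``fn`` returns a partial label map (region labels only, background
    elsewhere) and a self-reported failure flag.  Output labels must stay
    within the scheme labels of the declared ``regions``.
    """

    name: str
    version: str
    regions: tuple[str, ...]
    fn: Callable[[str], tuple[np.ndarray, bool]]

    def __call__(self, image_id: str) -> tuple[np.ndarray, bool]:
        return self.fn(image_id)


def region_subvolume(lm: LabelMap, region: str, scheme: LabelScheme) -> np.ndarray:
    """Labelled subvolume of one region (other labels zeroed)."""
    members = scheme.region_labels(region)
    return np.where(np.isin(lm.volume, members), lm.volume, 0).astype(np.uint16)


def _relabel_nearest(binary: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Assign every mask voxel the label of its nearest labelled truth voxel."""
    values = np.unique(labels[labels > 0])
    if len(values) == 1:
        return np.where(binary, values[0], 0).astype(np.uint16)
    _, (iz, iy, ix) = ndimage.distance_transform_edt(
        labels == 0, return_indices=True
    )
    nearest = labels[iz, iy, ix]
    return np.where(binary, nearest, 0).astype(np.uint16)


def simulate_algorithm(
    truths: Mapping[str, Mapping[str, np.ndarray]],
    failure_rate: float,
    error_menu: Sequence[ErrorSpec],
    seed: int,
    scheme: LabelScheme | None = None,
    name: str = "simulated",
    version: str = "1.0",
    precision_radius: int = 1,
    fail_image_ids: "set[str] | None" = None,
) -> SegmenterAdapter:
    """Build a segmenter stand-in with a known catastrophic-failure rate.

    ``truths`` maps image-id -> region -> labelled subvolume (or binary mask
    for single-label regions).  Per image the adapter emits ground truth
    perturbed by a precision boundary error; with probability
    ``failure_rate`` (decided once per image, seeded) it instead substitutes
    a catastrophic error drawn from ``error_menu``.  ``fail_image_ids``
    overrides the random failure draw with an explicit set, for modelling
    correlated failures (e.g. a corrected algorithm that still fails on a
    subset of the images the reference failed on).

    The per-image draw sequence is fully determined by ``seed`` and the
    image-id (independent of evaluation order).
    """
    if not 0.0 <= failure_rate <= 1.0:
        raise ValueError("failure_rate must be in [0, 1]")
    if failure_rate > 0 and not error_menu and fail_image_ids is None:
        raise ValueError("nonzero failure_rate requires a non-empty error menu")
    if fail_image_ids is not None and fail_image_ids and not error_menu:
        raise ValueError("explicit failure ids require a non-empty error menu")
    scheme = scheme or default_chest_scheme()
    truths = {k: dict(v) for k, v in truths.items()}
    first = next(iter(truths.values()), {})
    regions = tuple(first.keys())

    def fn(image_id: str) -> tuple[np.ndarray, bool]:
        per_image = truths[image_id]
        rng = _sub_rng(seed, "simalg", name, image_id)
        if fail_image_ids is not None:
            failed = image_id in fail_image_ids
        else:
            failed = bool(rng.random() < failure_rate)
        chosen: ErrorSpec | None = None
        if failed and error_menu:
            chosen = error_menu[int(rng.integers(len(error_menu)))]
            if chosen.target not in per_image:
                chosen = replace(chosen, target=regions[0])
        shape = next(iter(per_image.values())).shape
        out = np.zeros(shape, dtype=np.uint16)
        for region in regions:
            labels = np.asarray(per_image[region])
            if labels.dtype == bool:
                members = scheme.region_labels(region)
                labels = np.where(labels, members[0], 0).astype(np.uint16)
            binary = labels > 0
            sub_seed = int(rng.integers(2**31 - 1))
            if chosen is not None and chosen.target == region:
                err = replace(chosen, seed=sub_seed)
            else:
                err = ErrorSpec(
                    "boundary", target=region, seed=sub_seed,
                    radius=precision_radius,
                )
            if err.kind in _LABEL_KINDS:
                seg_labels = inject_error(labels, err)
            else:
                seg_binary = inject_error(binary, err)
                seg_labels = _relabel_nearest(seg_binary, labels)
            out[(out == 0) & (seg_labels > 0)] = seg_labels[(out == 0) & (seg_labels > 0)]
        return out, False

    return SegmenterAdapter(name=name, version=version, regions=regions, fn=fn)


# ---------------------------------------------------------------------------
# Simulated grading / review (deterministic stand-ins for the human steps)
# ---------------------------------------------------------------------------


def auto_grade(
    truth_mask: np.ndarray, seg_mask: np.ndarray, levels: int = 3
) -> Grade:
    """Grade a segmentation against ground truth the way a reviewer would.

    Catastrophic disagreement (or an empty segmentation) is unacceptable;
    perfect agreement is good; precision-level disagreement is acceptable
    on a three-level vocabulary and good on a two-level one (small boundary
    defects do not make a segmentation unusable).
    """
    if not np.asarray(seg_mask).astype(bool).any():
        return Grade.UNACCEPTABLE
    result = classify_error(truth_mask, seg_mask)
    if result.error_class == "catastrophic":
        return Grade.UNACCEPTABLE
    if result.error_class == "none":
        return Grade.GOOD
    return Grade.ACCEPTABLE if levels == 3 else Grade.GOOD


@dataclass
class SimulatedReviewer:
    """Deterministic reviewer for tests: accepts a candidate iff its Dice
    against ground truth strictly exceeds the reference's (ties keep the
    reference)."""

    truths: Mapping[str, Mapping[str, np.ndarray]]
    reviewer_id: str = "sim-reviewer"

    def _truth_mask(self, image_id: str, region: str) -> np.ndarray:
        t = np.asarray(self.truths[image_id][region])
        return t if t.dtype == bool else t > 0

    def decide(
        self,
        image_id: str,
        region: str,
        ref_mask: np.ndarray,
        cand_mask: np.ndarray,
        levels: int = 3,
    ) -> tuple[str, Grade]:
        """Return ``(decision, grade)`` where decision is ``accept-candidate``
        or ``keep-reference`` and grade is the graded quality of the chosen
        side's candidate (for accepts) or the archived candidate grade (for
        keeps)."""
        truth = self._truth_mask(image_id, region)
        cand_grade = auto_grade(truth, cand_mask, levels=levels)
        if dice(truth, cand_mask) > dice(truth, ref_mask):
            return "accept-candidate", cand_grade
        return "keep-reference", cand_grade
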