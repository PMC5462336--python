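"""Quantitative comparison of two segmentations of the same region.

Two measures drive the review protocol:

* the Dice coefficient ``DC = 2|A∩B| / (|A|+|B|)``, the global overlap score
  used to decide which algorithm outcomes need human review; and
* an error classification separating *precision* errors (small boundary
  discrepancies spread along the region surface) from *catastrophic* errors
  (a connected wrong region touching only a small part of the true surface
  yet changing the segmented volume or spatial extent significantly, e.g. a
  lung segmentation leaking into the bowel).

A high Dice value does not imply an acceptable segmentation: a compact leak
of a few percent of a large organ's volume leaves DC above 0.95 while making
every derived biomarker unreliable.  ``classify_error`` makes that failure
mode detectable automatically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "dice",
    "classify_error",
    "ComparisonResult",
    "ErrorComponent",
    "GridMismatchError",
]

# 26-connectivity for error components, 6-connectivity for surface adjacency.
_STRUCT26 = np.ones((3, 3, 3), dtype=bool)
_STRUCT6 = ndimage.generate_binary_structure(3, 1)

#: A connected error component is catastrophic when it touches less than
#: half of the reference surface...
SURFACE_CONTACT_BOUND = 0.5
#: ...and changes the region volume by at least this fraction,
DEFAULT_VOLUME_CHANGE = 0.05
#: or shifts some bounding-box extent by at least this fraction.
DEFAULT_EXTENT_CHANGE = 0.10


class GridMismatchError(ValueError):
    """The two masks are not on the same voxel grid (never resampled)."""


def _as_mask(arr: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(arr)
    if a.ndim != 3:
        raise ValueError(f"{name} must be a 3-D array, got ndim={a.ndim}")
    return a.astype(bool, copy=False)


def dice(ref: np.ndarray, test: np.ndarray) -> float:
    """Dice coefficient ``2|A∩B| / (|A|+|B|)`` of two binary masks.

    Symmetric in its arguments.  By convention two empty masks agree
    perfectly (1.0) and an empty/non-empty pair is fully discordant (0.0).
    Masks must share a grid; grids are never silently resampled.
    """
    a = _as_mask(ref, "ref")
    b = _as_mask(test, "test")
    if a.shape != b.shape:
        raise GridMismatchError(
            f"mask grids differ: {a.shape} vs {b.shape}"
        )
    na = int(np.count_nonzero(a))
    nb = int(np.count_nonzero(b))
    if na + nb == 0:
        return 1.0
    overlap = int(np.count_nonzero(a & b))
    return 2.0 * overlap / (na + nb)


@dataclass(frozen=True)
class ErrorComponent:
    """One connected component of disagreement between test and reference."""

    size: int
    surface_contact: float  # fraction of adjacent-part surface voxels touched
    sign: str  # "over" (test \\ ref) or "under" (ref \\ test)
    volume_change: float  # size / reference volume
    extent_change: float  # max relative bounding-box extent shift
    omits_part: bool  # swallows >= half of a connected reference part
    catastrophic: bool


@dataclass(frozen=True)
class ComparisonResult:
    """Dice, voxel counts and EP/EC classification of one comparison."""

    dc: float
    ref_volume: int
    test_volume: int
    overlap: int
    error_class: str  # {"none", "precision", "catastrophic"}
    components: tuple[ErrorComponent, ...] = field(default_factory=tuple)


def _extents(mask: np.ndarray) -> np.ndarray:
    """Per-axis bounding-box extent (voxels); zeros for an empty mask."""
    if not mask.any():
        return np.zeros(mask.ndim, dtype=float)
    ext = np.empty(mask.ndim, dtype=float)
    for ax in range(mask.ndim):
        proj = np.any(
            mask, axis=tuple(i for i in range(mask.ndim) if i != ax)
        )
        idx = np.flatnonzero(proj)
        ext[ax] = idx[-1] - idx[0] + 1
    return ext


def classify_error(
    ref: np.ndarray,
    test: np.ndarray,
    volume_change_threshold: float = DEFAULT_VOLUME_CHANGE,
    extent_change_threshold: float = DEFAULT_EXTENT_CHANGE,
) -> ComparisonResult:
    """Classify the disagreement between *test* and *ref* as EP or EC.

    Connected components (26-connectivity) of ``test∖ref`` (over-
    segmentation) and ``ref∖test`` (under-segmentation) are measured
    individually.  The *surface contact* of a component is the fraction of
    surface voxels (reference voxels with a background 6-neighbor) that
    are 6-adjacent to the component, normalised over the connected
    reference parts the component touches -- a region such as the lungs
    has two disjoint anatomical parts, and a boundary shell hugging one
    lung touches essentially all of *that lung's* surface, which is what
    makes it a precision error.  A component is catastrophic when it is
    localised -- surface contact below 0.5, or it swallows at least half
    of a connected reference part outright (a dropped subregion) -- **and**
    it changes the region volume by at least ``volume_change_threshold``
    or shifts some bounding-box extent by at least
    ``extent_change_threshold`` (both relative to the whole reference).
    The comparison is catastrophic if any component is; otherwise
    precision if any disagreement exists; otherwise none.

    Raises
    ------
    ValueError
        If the reference mask is empty (the classification is undefined).
    GridMismatchError
        If the masks live on different grids.
    """
    a = _as_mask(ref, "ref")
    b = _as_mask(test, "test")
    if a.shape != b.shape:
        raise GridMismatchError(f"mask grids differ: {a.shape} vs {b.shape}")
    ref_volume = int(np.count_nonzero(a))
    if ref_volume == 0:
        raise ValueError("classify_error is undefined for an empty reference")
    test_volume = int(np.count_nonzero(b))
    overlap = int(np.count_nonzero(a & b))
    dc = 2.0 * overlap / (ref_volume + test_volume) if test_volume or ref_volume else 1.0

    surface = a & ~ndimage.binary_erosion(a, structure=_STRUCT6, border_value=0)
    ref_ext = _extents(a)
    ref_parts, n_parts = ndimage.label(a, structure=_STRUCT26)
    part_sizes = ndimage.sum_labels(a, ref_parts, index=np.arange(1, n_parts + 1))
    part_surfaces = ndimage.sum_labels(
        surface, ref_parts, index=np.arange(1, n_parts + 1)
    )

    components: list[ErrorComponent] = []
    for sign, diff in (("over", b & ~a), ("under", a & ~b)):
        labeled, n = ndimage.label(diff, structure=_STRUCT26)
        for comp_idx in range(1, n + 1):
            comp = labeled == comp_idx
            size = int(np.count_nonzero(comp))
            # surface voxels 6-adjacent to (or inside) the component,
            # normalised over the reference parts the component touches
            halo = ndimage.binary_dilation(comp, structure=_STRUCT6)
            touched = np.unique(ref_parts[halo & a])
            touched = touched[touched > 0]
            denom = float(part_surfaces[touched - 1].sum()) if touched.size else 0.0
            contact = (
                int(np.count_nonzero(surface & halo)) / denom if denom else 0.0
            )
            omits_part = False
            if sign == "under" and touched.size:
                inside = ndimage.sum_labels(comp, ref_parts, index=touched)
                omits_part = bool(
                    np.any(inside >= 0.5 * part_sizes[touched - 1])
                )
            volume_change = size / ref_volume
            modified = (a | comp) if sign == "over" else (a & ~comp)
            mod_ext = _extents(modified)
            abs_change = np.abs(mod_ext - ref_ext)
            rel = abs_change / np.where(ref_ext > 0, ref_ext, 1.0)
            extent_change = float(rel.max()) if rel.size else 0.0
            # a shift under 2 voxels is boundary-scale, never "significant"
            extent_significant = bool(
                np.any((abs_change >= 2.0) & (rel >= extent_change_threshold))
            )
            localised = contact < SURFACE_CONTACT_BOUND or omits_part
            catastrophic = localised and (
                volume_change >= volume_change_threshold or extent_significant
            )
            components.append(
                ErrorComponent(
                    size=size,
                    surface_contact=contact,
                    sign=sign,
                    volume_change=volume_change,
                    extent_change=extent_change,
                    omits_part=omits_part,
                    catastrophic=catastrophic,
                )
            )

    if any(c.catastrophic for c in components):
        error_class = "catastrophic"
    elif components:
        error_class = "precision"
    else:
        error_class = "none"
    return ComparisonResult(
        dc=dc,
        ref_volume=ref_volume,
        test_volume=test_volume,
        overlap=overlap,
        error_class=error_class,
        components=tuple(components),
    )
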