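"""Grade-distribution tables, review-burden reports and montage snapshots.

Reports are pure functions of database state and history: regenerating a
report from the same database yields byte-identical output.  Grade tables
print ``count (percent)`` with integer percents, switching to one decimal
only when rounding would misleadingly show 0% for a non-zero count or
100% for an incomplete one (363 of 364 prints as 99.7%, not 100%).
Replacement fractions are printed with two decimals.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw

from .engine import VeqrDatabase
from .label_store import Grade

__all__ = [
    "GradeDistribution",
    "grade_table",
    "BurdenReport",
    "burden_report",
    "format_percent",
    "montage",
]

_GRADE_ROWS = (Grade.GOOD, Grade.ACCEPTABLE, Grade.UNACCEPTABLE)


def format_percent(count: int, denominator: int) -> str:
    """Integer percent, one decimal at the degenerate ends (0.3%, 99.7%)."""
    if denominator == 0:
        return "-"
    pct = 100.0 * count / denominator
    rounded = round(pct)
    if count > 0 and rounded == 0:
        return f"{pct:.1f}%"
    if count < denominator and rounded == 100:
        return f"{pct:.1f}%"
    return f"{rounded:d}%"


@dataclass
class GradeDistribution:
    """Per (region, grade) counts over the graded images of each region."""

    counts: pd.DataFrame  # index G/A/U, one column per region
    denominators: dict[str, int]

    def percentages(self) -> pd.DataFrame:
        """Recomputed percentages (never stored independently)."""
        out = self.counts.astype(float).copy()
        for region in out.columns:
            d = self.denominators.get(region, 0)
            out[region] = 100.0 * out[region] / d if d else np.nan
        return out

    def formatted(self) -> pd.DataFrame:
        """``count (percent)`` cells in the style of a published grade table."""
        out = pd.DataFrame(index=self.counts.index, columns=self.counts.columns)
        for region in self.counts.columns:
            d = self.denominators.get(region, 0)
            for grade in self.counts.index:
                c = int(self.counts.loc[grade, region])
                out.loc[grade, region] = f"{c} ({format_percent(c, d)})"
        return out

    def to_markdown(self) -> str:
        return self.formatted().to_markdown()

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.formatted().to_csv(path, index_label="grade")
        return path


def grade_table(
    db: VeqrDatabase, regions: "list[str] | None" = None
) -> GradeDistribution:
    """Tally current grades: one row per grade, one column per region.

    The denominator of each region is the number of images currently
    graded for it; ungraded images never enter the table.
    """
    regions = regions or sorted(db.scheme.regions)
    current = db.assessments.current()
    counts = {r: Counter() for r in regions}
    denominators = {r: 0 for r in regions}
    for (image_id, region), rec in current.items():
        if region in counts and image_id in db.images:
            counts[region][rec.grade] += 1
            denominators[region] += 1
    df = pd.DataFrame(
        {r: [counts[r][g] for g in _GRADE_ROWS] for r in regions},
        index=[g.short for g in _GRADE_ROWS],
    )
    return GradeDistribution(counts=df, denominators=denominators)


@dataclass
class BurdenReport:
    """Review burden of one evaluation run over the triage history."""

    outcomes_evaluated: int
    events_queued: int
    queued_by_reason: dict[str, int] = field(default_factory=dict)
    events_decided: int = 0
    updates_applied: int = 0

    def __post_init__(self) -> None:
        ok = (
            self.updates_applied <= self.events_decided
            <= self.events_queued <= self.outcomes_evaluated
        )
        if not ok:
            raise ValueError(
                "burden invariant violated: need updates <= decided <= "
                f"queued <= outcomes, got {self.updates_applied} <= "
                f"{self.events_decided} <= {self.events_queued} <= "
                f"{self.outcomes_evaluated}"
            )

    @property
    def replacement_fraction_percent(self) -> float:
        """Updates applied per outcome evaluated, two-decimal percent."""
        if self.outcomes_evaluated == 0:
            return 0.0
        return round(100.0 * self.updates_applied / self.outcomes_evaluated, 2)

    def to_markdown(self) -> str:
        lines = [
            "| quantity | value |",
            "|---|---|",
            f"| module outcomes evaluated | {self.outcomes_evaluated} |",
            f"| review events queued | {self.events_queued} |",
        ]
        for reason, n in sorted(self.queued_by_reason.items()):
            lines.append(f"| queued: {reason} | {n} |")
        lines += [
            f"| events decided | {self.events_decided} |",
            f"| database updates applied | {self.updates_applied} |",
            f"| replacement fraction | {self.replacement_fraction_percent:.2f}% |",
        ]
        return "\n".join(lines)


def burden_report(db: VeqrDatabase) -> BurdenReport:
    """Aggregate the triage log and queue into a burden report."""
    queued = [e for e in db.queue]
    by_reason = Counter(e.reason for e in queued)
    decided = [e for e in queued if e.decision != "pending"]
    updates = [e for e in decided if e.decision == "accept-candidate"]
    return BurdenReport(
        outcomes_evaluated=len(db.triage_log),
        events_queued=len(queued),
        queued_by_reason=dict(by_reason),
        events_decided=len(decided),
        updates_applied=len(updates),
    )


# ---------------------------------------------------------------------------
# Montage snapshots (2-D stand-in for interactive 3-D review)
# ---------------------------------------------------------------------------

_PLANES = {"axial": 0, "coronal": 1, "sagittal": 2}
_BG = (24, 24, 24)
_REF_COLOR = (80, 200, 120)
_CAND_COLOR = (80, 160, 240)
_SEP = (90, 90, 90)


def _slice2d(vol: np.ndarray, plane: str, index: int) -> np.ndarray:
    ax = _PLANES[plane]
    return np.take(vol, index, axis=ax)


def _panel(mask2d: np.ndarray, color: tuple[int, int, int]) -> np.ndarray:
    h, w = mask2d.shape
    rgb = np.empty((h, w, 3), dtype=np.uint8)
    rgb[...] = _BG
    rgb[mask2d] = color
    return rgb


def montage(
    ref_mask: np.ndarray,
    cand_mask: np.ndarray,
    out_dir: str | Path,
    basename: str = "montage",
    planes: "tuple[str, ...]" = ("axial", "coronal", "sagittal"),
    upscale: int = 3,
) -> list[Path]:
    """Write side-by-side reference/candidate overlay snapshots.

    One PNG per requested plane, cut at the centroid slice of the mask
    union (deterministic).  The left panel shows the reference, the right
    the candidate; disagreeing voxels therefore appear in one panel only.
    With two empty masks a placeholder image carrying a warning annotation
    is written instead.
    """
    ref = np.asarray(ref_mask).astype(bool)
    cand = np.asarray(cand_mask).astype(bool)
    if ref.shape != cand.shape:
        raise ValueError(f"mask grids differ: {ref.shape} vs {cand.shape}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    unknown = set(planes) - set(_PLANES)
    if unknown:
        raise ValueError(f"unknown planes {sorted(unknown)}")

    union = ref | cand
    paths: list[Path] = []
    if not union.any():
        for plane in planes:
            img = Image.new("RGB", (320, 120), _BG)
            draw = ImageDraw.Draw(img)
            draw.text((10, 50), f"WARNING: empty masks ({plane})", fill=(240, 80, 80))
            p = out_dir / f"{basename}_{plane}.png"
            img.save(p)
            paths.append(p)
        return paths

    centroid = np.round(np.argwhere(union).mean(axis=0)).astype(int)
    for plane in planes:
        idx = int(centroid[_PLANES[plane]])
        left = _panel(_slice2d(ref, plane, idx), _REF_COLOR)
        right = _panel(_slice2d(cand, plane, idx), _CAND_COLOR)
        sep = np.empty((left.shape[0], 2, 3), dtype=np.uint8)
        sep[...] = _SEP
        composite = np.concatenate([left, sep, right], axis=1)
        if upscale > 1:
            composite = np.kron(composite, np.ones((upscale, upscale, 1), dtype=np.uint8))
        p = out_dir / f"{basename}_{plane}.png"
        Image.fromarray(composite).save(p)
        paths.append(p)
    return paths
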