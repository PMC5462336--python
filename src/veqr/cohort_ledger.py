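"""Cohort inclusion/exclusion accounting.

Dataset curation for low-dose chest CT screening admits only scans
consistent with the screening protocol: low-dose, thin-slice (<= 2.0 mm),
noncontrast, supine, covering the whole lung, and free of severe implant
artifacts.  The ledger records per-cohort case/image/include/exclude
counts and can total them; it records, it never adjudicates -- dose is a
metadata flag, not a physics judgement, and every exclusion carries at
least one machine-readable reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd

from .label_store import ImageRecord

__all__ = [
    "InclusionCriteria",
    "InclusionResult",
    "apply_inclusion",
    "CohortRow",
    "ledger_summary",
    "count_module_outcomes",
    "load_cohort_table",
    "rows_from_frame",
    "rows_to_frame",
    "IncompleteRecordError",
]


class IncompleteRecordError(ValueError):
    """A metadata field needed for an inclusion decision is missing."""


@dataclass(frozen=True)
class InclusionCriteria:
    """Screening-protocol inclusion criteria with their defaults."""

    max_slice_thickness_mm: float = 2.0
    require_low_dose: bool = True
    require_supine: bool = True
    require_noncontrast: bool = True
    require_whole_lung: bool = True
    exclude_artifacts: bool = True


@dataclass(frozen=True)
class InclusionResult:
    included: bool
    reasons: tuple[str, ...] = ()  # every failed criterion, machine-readable


_REQUIRED_FIELDS = (
    "slice_thickness_mm", "dose", "position",
    "contrast", "whole_lung", "artifact_excluded",
)


def apply_inclusion(
    record: ImageRecord, criteria: InclusionCriteria | None = None
) -> InclusionResult:
    """Decide inclusion; an excluded record lists every failed criterion.

    Missing metadata raises :class:`IncompleteRecordError` -- a record with
    unknown dose or thickness must never be silently included.
    """
    criteria = criteria or InclusionCriteria()
    missing = [f for f in _REQUIRED_FIELDS if getattr(record, f, None) is None]
    if missing:
        raise IncompleteRecordError(
            f"image {record.image_id!r} is missing metadata fields {missing}"
        )
    reasons: list[str] = []
    if record.slice_thickness_mm > criteria.max_slice_thickness_mm:
        reasons.append("thickness")
    if criteria.require_low_dose and record.dose != "low":
        reasons.append("dose")
    if criteria.require_supine and record.position != "supine":
        reasons.append("position")
    if criteria.require_noncontrast and record.contrast:
        reasons.append("contrast")
    if criteria.require_whole_lung and not record.whole_lung:
        reasons.append("coverage")
    if criteria.exclude_artifacts and record.artifact_excluded:
        reasons.append("artifact")
    return InclusionResult(included=not reasons, reasons=tuple(reasons))


@dataclass(frozen=True)
class CohortRow:
    """One cohort's accounting row: cases, images, included, excluded."""

    cohort: str
    cases: int
    images: int
    included: int
    excluded: int
    slice_thickness_range_mm: str = ""

    def __post_init__(self) -> None:
        for name in ("cases", "images", "included", "excluded"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.cohort}: {name} must be non-negative")
        if self.included + self.excluded != self.images:
            raise ValueError(
                f"{self.cohort}: included ({self.included}) + excluded "
                f"({self.excluded}) != images ({self.images})"
            )


@dataclass(frozen=True)
class LedgerSummary:
    total: CohortRow
    excluded_percent: float  # one decimal, excluded / images * 100


def ledger_summary(rows: Sequence[CohortRow]) -> LedgerSummary:
    """Componentwise totals plus the excluded fraction (one-decimal %)."""
    total = CohortRow(
        cohort="Total",
        cases=sum(r.cases for r in rows),
        images=sum(r.images for r in rows),
        included=sum(r.included for r in rows),
        excluded=sum(r.excluded for r in rows),
        slice_thickness_range_mm="<=2",
    )
    pct = round(100.0 * total.excluded / total.images, 1) if total.images else 0.0
    return LedgerSummary(total=total, excluded_percent=pct)


def count_module_outcomes(n_images: int, n_modules: int) -> int:
    """Number of module outcomes a full review covers: images x modules."""
    if n_images < 0 or n_modules < 0:
        raise ValueError("counts must be non-negative")
    return n_images * n_modules


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------


def rows_from_frame(df: pd.DataFrame) -> list[CohortRow]:
    return [
        CohortRow(
            cohort=str(r["cohort"]),
            cases=int(r["cases"]),
            images=int(r["images"]),
            included=int(r["included"]),
            excluded=int(r["excluded"]),
            slice_thickness_range_mm=str(r.get("slice_thickness_range_mm", "")),
        )
        for _, r in df.iterrows()
    ]


def rows_to_frame(rows: Sequence[CohortRow]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])


def load_cohort_table(
    source: str | Path | int = 2017,
) -> list[CohortRow]:
    """Load a cohort accounting table.

    ``source`` may be a CSV path or one of the shipped snapshot years
    (2016, 2017).  The two snapshots are independent; they are not
    reconciled against each other.
    """
    if isinstance(source, int):
        name = f"cohorts_{source}.csv"
        with resources.files("veqr.data").joinpath(name).open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(source)
    return rows_from_frame(df)
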