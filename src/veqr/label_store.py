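"""Documented-image database primitives: label schemes, label maps, grades.

A documented image is a 3-D scan paired with (a) a *label map* -- an integer
volume assigning every voxel to exactly one anatomical label -- and (b) a set
of *assessment records* holding the categorical quality grade of each graded
region.  A graded region (e.g. ``"rib"``) may group many voxel labels (24 rib
labels); its grade is the worst of its subregion grades.

Conventions
-----------
* Volumes are ``numpy`` arrays ordered ``(z, y, x)`` (slice-major), voxel
  dtype unsigned 16-bit.  Physical spacing is carried alongside in mm.
* Label value 0 is background; the scheme reserves a high value for
  "no-data" (voxels outside the scan reconstruction circle).
* Comparisons between label maps require identical grids; nothing here ever
  resamples.
"""

from __future__ import annotations

import enum
import functools
import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import SimpleITK as sitk

__all__ = [
    "Grade",
    "region_grade",
    "LabelScheme",
    "ImageRecord",
    "LabelMap",
    "AssessmentRecord",
    "AssessmentStore",
    "default_chest_scheme",
    "read_label_map",
    "write_label_map",
    "extract_region_mask",
    "LabelValidationError",
]

NO_DATA_DEFAULT = 65535


class LabelValidationError(ValueError):
    """A label volume contains values absent from the governing scheme."""


@functools.total_ordering
class Grade(enum.Enum):
    """Categorical segmentation quality grade.

    Ordering is ``unacceptable < acceptable < good``: a grade compares lower
    when the segmentation is less usable for biomarker evaluation.
    """

    UNACCEPTABLE = "unacceptable"
    ACCEPTABLE = "acceptable"
    GOOD = "good"

    @property
    def rank(self) -> int:
        return _GRADE_RANK[self]

    def __lt__(self, other: "Grade") -> bool:
        if not isinstance(other, Grade):
            return NotImplemented
        return self.rank < other.rank

    @property
    def short(self) -> str:
        return {"good": "G", "acceptable": "A", "unacceptable": "U"}[self.value]

    @classmethod
    def parse(cls, value: "str | Grade") -> "Grade":
        if isinstance(value, Grade):
            return value
        v = str(value).strip().lower()
        aliases = {"g": "good", "a": "acceptable", "u": "unacceptable"}
        return cls(aliases.get(v, v))


_GRADE_RANK = {Grade.UNACCEPTABLE: 0, Grade.ACCEPTABLE: 1, Grade.GOOD: 2}


def region_grade(subgrades: Sequence[Grade | str]) -> Grade:
    """Overall grade of a region from its subregion grades (the minimum).

    A region with many labelled subregions (24 ribs, 15 vertebrae) is graded
    by its weakest member: one mislabelled rib makes the whole rib region
    unusable for rib-based measurements.
    """
    grades = [Grade.parse(g) for g in subgrades]
    if not grades:
        raise ValueError("region_grade requires at least one subregion grade")
    return min(grades)


@dataclass(frozen=True)
class LabelScheme:
    """Dictionary of voxel label values, names and region grouping.

    Parameters
    ----------
    labels
        Map label-value -> label-name for every anatomical label.
    regions
        Map region-name -> ordered member label values.  Every label belongs
        to at most one region; background/no-data belong to none.
    background, no_data
        Reserved values; ``no_data`` marks voxels outside the reconstruction.
    grade_levels
        Number of grade levels (2 or 3) per region.  Two-level regions use
        {good, unacceptable} only.
    """

    labels: Mapping[int, str]
    regions: Mapping[str, Sequence[int]]
    background: int = 0
    no_data: int = NO_DATA_DEFAULT
    grade_levels: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", dict(self.labels))
        object.__setattr__(
            self, "regions", {r: list(m) for r, m in self.regions.items()}
        )
        seen: dict[int, str] = {}
        for region, members in self.regions.items():
            if not members:
                raise ValueError(f"region {region!r} has an empty member list")
            for lv in members:
                if lv in (self.background, self.no_data):
                    raise ValueError(
                        f"reserved label {lv} cannot belong to region {region!r}"
                    )
                if lv not in self.labels:
                    raise ValueError(
                        f"region {region!r} member {lv} is not a known label"
                    )
                if lv in seen:
                    raise ValueError(
                        f"label {lv} in both {seen[lv]!r} and {region!r}"
                    )
                seen[lv] = region
        for region, n in self.grade_levels.items():
            if region not in self.regions:
                raise ValueError(f"grade_levels for unknown region {region!r}")
            if n not in (2, 3):
                raise ValueError(f"grade_levels[{region!r}] must be 2 or 3")

    # -- lookups ---------------------------------------------------------

    @property
    def all_values(self) -> frozenset[int]:
        """Every value a voxel may legally hold."""
        return frozenset(self.labels) | {self.background, self.no_data}

    def region_labels(self, region: str) -> list[int]:
        try:
            return list(self.regions[region])
        except KeyError:
            raise KeyError(f"unknown region {region!r}") from None

    def grade_vocabulary(self, region: str) -> list[Grade]:
        n = self.grade_levels.get(region, 3)
        if n == 2:
            return [Grade.GOOD, Grade.UNACCEPTABLE]
        return [Grade.GOOD, Grade.ACCEPTABLE, Grade.UNACCEPTABLE]

    # -- (de)serialisation ----------------------------------------------

    def to_json(self, path: str | Path) -> Path:
        doc = {
            "labels": {str(k): v for k, v in self.labels.items()},
            "regions": dict(self.regions),
            "background": self.background,
            "no_data": self.no_data,
            "grade_levels": dict(self.grade_levels),
        }
        path = Path(path)
        path.write_text(json.dumps(doc, indent=1))
        return path

    @classmethod
    def from_json(cls, source: str | Path | Mapping) -> "LabelScheme":
        if isinstance(source, (str, Path)):
            doc = json.loads(Path(source).read_text())
        else:
            doc = source
        return cls(
            labels={int(k): v for k, v in doc["labels"].items()},
            regions=doc["regions"],
            background=doc.get("background", 0),
            no_data=doc.get("no_data", NO_DATA_DEFAULT),
            grade_levels=doc.get("grade_levels", {}),
        )


def default_chest_scheme() -> LabelScheme:
    """The shipped multi-organ chest scheme.

    Seven graded regions -- lung, airway, rib (24 labels), vertebra (15
    labels), skin, cardiac region (heart/aorta/pulmonary trunk) and breast.
    Lung and skin are graded on two levels, the rest on three.
    """
    with resources.files("veqr.data").joinpath("chest_scheme.json").open() as fh:
        return LabelScheme.from_json(json.load(fh))


@dataclass
class ImageRecord:
    """Scan-level metadata for one 3-D image in the database."""

    image_id: str
    cohort: str
    slice_thickness_mm: float
    dose: str = "low"  # {"low", "regular"}
    position: str = "supine"  # {"supine", "other"}
    whole_lung: bool = True
    contrast: bool = False
    artifact_excluded: bool = False
    shape: tuple[int, int, int] = (0, 0, 0)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    sequestered: bool = False

    def __post_init__(self) -> None:
        if not self.image_id:
            raise ValueError("image_id must be non-empty")
        if self.slice_thickness_mm is not None and self.slice_thickness_mm <= 0:
            raise ValueError("slice thickness must be positive")
        self.shape = tuple(int(s) for s in self.shape)  # type: ignore[assignment]
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)  # type: ignore[assignment]

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["shape"] = list(self.shape)
        d["spacing_mm"] = list(self.spacing_mm)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ImageRecord":
        d = dict(d)
        d["shape"] = tuple(d.get("shape", (0, 0, 0)))
        d["spacing_mm"] = tuple(d.get("spacing_mm", (1.0, 1.0, 1.0)))
        return cls(**d)


@dataclass
class LabelMap:
    """One label volume: every voxel holds exactly one scheme label value."""

    image_id: str
    volume: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    version: int = 1
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vol = np.asarray(self.volume)
        if vol.ndim != 3:
            raise ValueError("label volume must be 3-D")
        if not np.issubdtype(vol.dtype, np.integer):
            raise LabelValidationError(
                f"label volume must have integer dtype, got {vol.dtype}"
            )
        if vol.size and (vol.min() < 0 or vol.max() > NO_DATA_DEFAULT):
            raise LabelValidationError("label values outside uint16 range")
        self.volume = vol.astype(np.uint16, copy=False)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)  # type: ignore[assignment]

    def validate(self, scheme: LabelScheme) -> None:
        """Check the partition property against *scheme*.

        Every voxel holds one value (guaranteed by the dense array) and that
        value must be known to the scheme.
        """
        present = np.unique(self.volume)
        unknown = sorted(int(v) for v in present if int(v) not in scheme.all_values)
        if unknown:
            raise LabelValidationError(
                f"label map {self.image_id!r} contains values not in the "
                f"scheme: {unknown}"
            )

    def copy(self) -> "LabelMap":
        return replace(self, volume=self.volume.copy(), provenance=dict(self.provenance))


# ---------------------------------------------------------------------------
# Label-volume file I/O (NIfTI-1 via nibabel; NRRD / MetaImage via SimpleITK)
# ---------------------------------------------------------------------------

_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_SITK_SUFFIXES = (".nrrd", ".mha", ".mhd")


def _dialect(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(_NIFTI_SUFFIXES):
        return "nifti"
    if name.endswith(_SITK_SUFFIXES):
        return "sitk"
    raise ValueError(
        f"unsupported label-volume format {path.name!r} "
        f"(expected one of {_NIFTI_SUFFIXES + _SITK_SUFFIXES})"
    )


def read_label_map(
    path: str | Path, scheme: LabelScheme, image_id: str | None = None
) -> LabelMap:
    """Read a label volume and validate every voxel value against *scheme*.

    Supports NIfTI-1 (``.nii``/``.nii.gz``), NRRD and MetaImage.  The
    in-memory array is ordered ``(z, y, x)``; spacing is taken from the file
    header.  Non-integer voxel types and unknown label values are rejected.
    """
    path = Path(path)
    if _dialect(path) == "nifti":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if not np.issubdtype(data.dtype, np.integer):
            raise LabelValidationError(
                f"{path.name}: label volumes must use an integer voxel type, "
                f"got {data.dtype}"
            )
        vol = np.ascontiguousarray(data.transpose(2, 1, 0))
        zooms = img.header.get_zooms()[:3]
        spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    else:
        img = sitk.ReadImage(str(path))
        vol = sitk.GetArrayFromImage(img)
        if not np.issubdtype(vol.dtype, np.integer):
            raise LabelValidationError(
                f"{path.name}: label volumes must use an integer voxel type, "
                f"got {vol.dtype}"
            )
        sx, sy, sz = img.GetSpacing()
        spacing = (float(sz), float(sy), float(sx))
    lm = LabelMap(
        image_id=image_id or path.name.split(".")[0],
        volume=vol,
        spacing_mm=spacing,
    )
    lm.validate(scheme)
    return lm


def write_label_map(
    lm: LabelMap, path: str | Path, scheme: LabelScheme | None = None
) -> Path:
    """Write a label map; voxel content round-trips bit-identically.

    Values are stored as unsigned 16-bit integers.  When *scheme* is given
    the map is validated first and writing is refused on violation.
    """
    path = Path(path)
    if scheme is not None:
        lm.validate(scheme)
    vol = lm.volume.astype(np.uint16, copy=False)
    sz, sy, sx = lm.spacing_mm
    if _dialect(path) == "nifti":
        affine = np.diag([sx, sy, sz, 1.0])
        img = nib.Nifti1Image(vol.transpose(2, 1, 0), affine)
        img.header.set_zooms((sx, sy, sz))
        nib.save(img, str(path))
    else:
        img = sitk.GetImageFromArray(vol)
        img.SetSpacing((sx, sy, sz))
        sitk.WriteImage(img, str(path), useCompression=True)
    return path


def extract_region_mask(
    lm: LabelMap, region: str, scheme: LabelScheme
) -> np.ndarray:
    """Binary mask of a graded region: union of its member label masks."""
    members = scheme.region_labels(region)
    return np.isin(lm.volume, members)


# ---------------------------------------------------------------------------
# Assessment records (append-only grade history)
# ---------------------------------------------------------------------------


@dataclass
class AssessmentRecord:
    """One visual-quality grade for (image, region), with provenance.

    ``kind`` distinguishes the live reference documentation from archived
    grades of rejected candidate segmentations (kept for history, never
    current).
    """

    image_id: str
    region: str
    grade: Grade
    reviewer: str = ""
    algorithm_version: str = ""
    timestamp: str = ""
    subregion_grades: dict[int, Grade] | None = None
    kind: str = "reference"  # {"reference", "candidate-archived"}

    def __post_init__(self) -> None:
        self.grade = Grade.parse(self.grade)
        if self.subregion_grades is not None:
            self.subregion_grades = {
                int(k): Grade.parse(v) for k, v in self.subregion_grades.items()
            }
            worst = region_grade(list(self.subregion_grades.values()))
            if self.grade != worst:
                raise ValueError(
                    "region grade must equal the worst subregion grade "
                    f"({worst.value}), got {self.grade.value}"
                )
        if self.kind not in ("reference", "candidate-archived"):
            raise ValueError(f"unknown assessment kind {self.kind!r}")

    def to_dict(self) -> dict:
        d = {
            "image_id": self.image_id,
            "region": self.region,
            "grade": self.grade.value,
            "reviewer": self.reviewer,
            "algorithm_version": self.algorithm_version,
            "timestamp": self.timestamp,
            "kind": self.kind,
        }
        if self.subregion_grades is not None:
            d["subregion_grades"] = {
                str(k): v.value for k, v in self.subregion_grades.items()
            }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "AssessmentRecord":
        return cls(**dict(d))


class AssessmentStore:
    """Append-only assessment history; current state = latest per (image, region)."""

    def __init__(self, records: Iterable[AssessmentRecord] = ()) -> None:
        self.records: list[AssessmentRecord] = []
        self._current: dict[tuple[str, str], AssessmentRecord] = {}
        for rec in records:
            self.append(rec)

    def append(
        self, record: AssessmentRecord, scheme: LabelScheme | None = None
    ) -> None:
        if scheme is not None:
            vocab = scheme.grade_vocabulary(record.region)
            if record.grade not in vocab:
                raise ValueError(
                    f"grade {record.grade.value!r} is not in the "
                    f"{len(vocab)}-level vocabulary of region {record.region!r}"
                )
        self.records.append(record)
        if record.kind == "reference":
            self._current[(record.image_id, record.region)] = record

    def current(self) -> dict[tuple[str, str], AssessmentRecord]:
        """Latest *reference* record per (image_id, region); archived grades
        of rejected candidates never become current."""
        return dict(self._current)

    def current_grade(self, image_id: str, region: str) -> Grade | None:
        rec = self._current.get((image_id, region))
        return rec.grade if rec else None

    # -- persistence -----------------------------------------------------

    def to_jsonl(self, path: str | Path) -> Path:
        path = Path(path)
        with path.open("w") as fh:
            for rec in self.records:
                fh.write(json.dumps(rec.to_dict()) + "\n")
        return path

    @classmethod
    def from_jsonl(cls, path: str | Path) -> "AssessmentStore":
        records = []
        with Path(path).open() as fh:
            for line in fh:
                line = line.strip()
                if line:
                    records.append(AssessmentRecord.from_dict(json.loads(line)))
        return cls(records)

    def to_csv(self, path: str | Path) -> Path:
        rows = [
            {
                "image_id": r.image_id,
                "region": r.region,
                "grade": r.grade.value,
                "reviewer": r.reviewer,
                "algorithm_version": r.algorithm_version,
                "timestamp": r.timestamp,
            }
            for r in self.records
        ]
        df = pd.DataFrame(
            rows,
            columns=[
                "image_id", "region", "grade", "reviewer",
                "algorithm_version", "timestamp",
            ],
        )
        path = Path(path)
        df.to_csv(path, index=False)
        return path
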