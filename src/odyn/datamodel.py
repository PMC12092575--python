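"""Canonical in-memory data model shared by all pipeline stages.

Coordinate convention (used everywhere in the package): x = column,
y = row, 0-based, pixel centres at integer coordinates. Masks are binary
label grids (0 = background, 1 = positive class) with an isotropic
microns-per-pixel (mpp) resolution attached.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

RAW_CLASSES = ("dysplastic_epithelial", "normal_epithelial", "other")

#: Case-insensitive synonyms for nuclear class labels found in annotation
#: exports. Editable: io.read_nuclei accepts an override mapping.
DEFAULT_CLASS_SYNONYMS: Mapping[str, str] = {
    "dysplastic_epithelial": "dysplastic_epithelial",
    "dysplastic epithelial": "dysplastic_epithelial",
    "dysplastic": "dysplastic_epithelial",
    "normal_epithelial": "normal_epithelial",
    "normal epithelial": "normal_epithelial",
    "epithelial": "normal_epithelial",
    "epithelium": "normal_epithelial",
    "other": "other",
    "lymphocyte": "other",
    "inflammatory": "other",
    "connective": "other",
    "stroma": "other",
}


class ValidationError(ValueError):
    """Raised when an input artefact violates a data-model invariant."""


@dataclass(frozen=True)
class MaskRaster:
    """A binary label image with resolution metadata.

    Parameters
    ----------
    pixels
        2D uint8 array containing only {0, 1}; 1 is the positive class.
    mpp
        Isotropic microns per pixel, > 0.
    slide_id
        Identifier of the slide the mask belongs to.
    """

    pixels: np.ndarray
    mpp: float
    slide_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValidationError(f"mask must be 2D, got shape {px.shape}")
        if px.size and px.min() < 0:
            raise ValidationError("mask contains negative labels")
        # any nonzero value counts as positive (tolerant of 255-valued PNGs)
        object.__setattr__(self, "pixels", (px != 0).astype(np.uint8))
        if not self.mpp > 0:
            raise ValidationError(f"mpp must be > 0, got {self.mpp}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def positive_pixels(self) -> int:
        return int(self.pixels.sum())


def check_coregistered(a: MaskRaster, b: MaskRaster) -> None:
    """Raise unless two masks of one slide share shape and resolution."""
    if a.shape != b.shape:
        raise ValidationError(
            f"masks are not co-registered: shapes {a.shape} vs {b.shape}"
            + (f" (slide {a.slide_id})" if a.slide_id else "")
        )
    if not np.isclose(a.mpp, b.mpp):
        raise ValidationError(f"masks differ in mpp: {a.mpp} vs {b.mpp}")


@dataclass(frozen=True)
class NucleusInstance:
    """One segmented nucleus: class label, closed contour, centroid.

    The contour is an (n, 2) array of (x, y) pixel coordinates at a stated
    mpp; it must have >= 3 vertices and positive area.
    """

    nucleus_id: str
    raw_class: str
    contour: np.ndarray
    centroid: tuple[float, float]

    def __post_init__(self) -> None:
        if self.raw_class not in RAW_CLASSES:
            raise ValidationError(f"unknown nuclear class {self.raw_class!r}")
        c = np.asarray(self.contour, dtype=float)
        if c.ndim != 2 or c.shape[1] != 2 or c.shape[0] < 3:
            raise ValidationError("contour must be an (n>=3, 2) array")
        object.__setattr__(self, "contour", c)
        if polygon_area(c) <= 0:
            raise ValidationError("contour has non-positive area")
        x, y = self.centroid
        if not (c[:, 0].min() <= x <= c[:, 0].max() and c[:, 1].min() <= y <= c[:, 1].max()):
            raise ValidationError("centroid outside contour bounding box")


def polygon_area(contour: np.ndarray) -> float:
    """Unsigned shoelace area of a closed polygon given as (n, 2) vertices."""
    x = contour[:, 0]
    y = contour[:, 1]
    return abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))) / 2.0


WHO_GRADES = ("mild", "moderate", "severe")
BINARY_GRADES = ("low_risk", "high_risk")


@dataclass(frozen=True)
class SlideRecord:
    """Clinical record for one slide.

    ``follow_up_months`` may be NaN; such slides remain usable for scoring
    and threshold fitting but are flagged ineligible for survival analyses.
    """

    slide_id: str
    patient_id: str
    transformed: int
    follow_up_months: float
    who_grade: str | None = None
    binary_grade: str | None = None
    age: float = float("nan")
    sex: str = ""
    site: str | None = None
    cohort_tag: str = "internal"

    def __post_init__(self) -> None:
        if self.transformed not in (0, 1):
            raise ValidationError(f"transformed must be 0/1, got {self.transformed}")
        if not np.isnan(self.follow_up_months) and self.follow_up_months < 0:
            raise ValidationError("follow_up_months must be >= 0")
        if self.who_grade is not None and self.who_grade not in WHO_GRADES:
            raise ValidationError(f"bad who_grade {self.who_grade!r}")
        if self.binary_grade is not None and self.binary_grade not in BINARY_GRADES:
            raise ValidationError(f"bad binary_grade {self.binary_grade!r}")
        if self.cohort_tag not in ("internal", "external"):
            raise ValidationError(f"bad cohort_tag {self.cohort_tag!r}")

    @property
    def survival_eligible(self) -> bool:
        return not np.isnan(self.follow_up_months)


class CohortTable:
    """Ordered collection of SlideRecord with lookup by slide and patient.

    Invariants: slide_id unique; slides sharing a patient_id share
    cohort_tag (and, for generated cohorts, outcome).
    """

    def __init__(self, records: Sequence[SlideRecord]):
        self._records = list(records)
        ids = [r.slide_id for r in self._records]
        dupes = {s for s in ids if ids.count(s) > 1}
        if dupes:
            raise ValidationError(f"duplicate slide_id(s): {sorted(dupes)}")
        by_patient: dict[str, list[SlideRecord]] = {}
        for r in self._records:
            by_patient.setdefault(r.patient_id, []).append(r)
        for pid, recs in by_patient.items():
            if len({r.cohort_tag for r in recs}) > 1:
                raise ValidationError(f"patient {pid} spans multiple cohorts")
        self._by_slide = {r.slide_id: r for r in self._records}
        self._by_patient = by_patient

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[SlideRecord]:
        return iter(self._records)

    def slide(self, slide_id: str) -> SlideRecord:
        return self._by_slide[slide_id]

    def patient(self, patient_id: str) -> list[SlideRecord]:
        return self._by_patient[patient_id]

    @property
    def slide_ids(self) -> list[str]:
        return [r.slide_id for r in self._records]

    @property
    def patient_ids(self) -> list[str]:
        return list(self._by_patient)

    def survival_eligible(self) -> "CohortTable":
        return CohortTable([r for r in self._records if r.survival_eligible])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "slide_id": [r.slide_id for r in self._records],
                "patient_id": [r.patient_id for r in self._records],
                "transformed": [r.transformed for r in self._records],
                "follow_up_months": [r.follow_up_months for r in self._records],
                "who_grade": [r.who_grade for r in self._records],
                "binary_grade": [r.binary_grade for r in self._records],
                "age": [r.age for r in self._records],
                "sex": [r.sex for r in self._records],
                "site": [r.site for r in self._records],
                "cohort_tag": [r.cohort_tag for r in self._records],
            }
        )
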