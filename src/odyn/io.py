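"""Readers/writers for masks, nuclear annotations, cohort tables and results.

Formats:

* masks — single-channel PNG or single-page TIFF; any nonzero pixel is
  positive;
* nuclei — GeoJSON FeatureCollection (Polygon geometries, class label in
  ``properties``, QuPath-style) or CSV with columns
  ``nucleus_id, class, wkt_contour``;
* cohort — CSV with the SlideRecord columns.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from PIL import Image
from shapely import wkt as shapely_wkt
from shapely.geometry import Polygon

from odyn.datamodel import (
    DEFAULT_CLASS_SYNONYMS,
    CohortTable,
    MaskRaster,
    NucleusInstance,
    SlideRecord,
    ValidationError,
    polygon_area,
)

logger = logging.getLogger(__name__)

COHORT_COLUMNS = [
    "slide_id",
    "patient_id",
    "transformed",
    "follow_up_months",
    "who_grade",
    "binary_grade",
    "age",
    "sex",
    "site",
    "cohort_tag",
]


# ---------------------------------------------------------------------------
# masks


def read_mask(path: str | Path, mpp: float, slide_id: str = "") -> MaskRaster:
    """Read a binary mask image; any nonzero pixel maps to label 1."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"mask file not found: {path}")
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    if arr.ndim == 3:
        # allow grayscale stored with redundant channels; refuse real colour
        if arr.shape[2] in (2, 4):
            arr = arr[..., 0]
        elif np.all(arr[..., 0:1] == arr):
            arr = arr[..., 0]
        else:
            raise ValidationError(
                f"{path.name}: multi-channel colour image has no binarization rule"
            )
    return MaskRaster(pixels=arr, mpp=mpp, slide_id=slide_id or path.stem)


def write_mask(mask: MaskRaster, path: str | Path) -> None:
    """Write a mask as 8-bit PNG/TIFF with positives stored as 255."""
    path = Path(path)
    out = (mask.pixels * 255).astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, out)
    else:
        Image.fromarray(out).save(path)


# ---------------------------------------------------------------------------
# nuclei


def _canonical_class(label: str, synonyms: Mapping[str, str]) -> str:
    key = str(label).strip().lower()
    if key not in synonyms:
        raise ValidationError(f"unknown nuclear class label {label!r}")
    return synonyms[key]


def _make_instance(
    nucleus_id: str, label: str, coords: np.ndarray, synonyms: Mapping[str, str]
) -> NucleusInstance | None:
    """Build one instance; return None for degenerate polygons."""
    coords = np.asarray(coords, dtype=float)
    # drop a repeated closing vertex (GeoJSON rings close explicitly)
    if len(coords) > 1 and np.allclose(coords[0], coords[-1]):
        coords = coords[:-1]
    if len(coords) < 3 or polygon_area(coords) <= 0:
        return None
    poly = Polygon(coords)
    cx, cy = poly.centroid.x, poly.centroid.y
    return NucleusInstance(
        nucleus_id=str(nucleus_id),
        raw_class=_canonical_class(label, synonyms),
        contour=coords,
        centroid=(cx, cy),
    )


def read_nuclei(
    path: str | Path,
    dialect: str | None = None,
    synonyms: Mapping[str, str] = DEFAULT_CLASS_SYNONYMS,
) -> list[NucleusInstance]:
    """Read nuclear instances from GeoJSON or CSV.

    Degenerate polygons (< 3 distinct vertices or zero area) are dropped
    with a logged count. Unknown class labels raise ValidationError listing
    the offending labels.
    """
    path = Path(path)
    if dialect is None:
        dialect = "geojson" if path.suffix.lower() in (".json", ".geojson") else "csv"
    raw: list[tuple[str, str, np.ndarray]] = []
    if dialect == "geojson":
        with open(path) as fh:
            fc = json.load(fh)
        for i, feat in enumerate(fc.get("features", [])):
            geom = feat.get("geometry", {})
            if geom.get("type") != "Polygon":
                continue
            props = feat.get("properties", {})
            label = props.get("classification", props.get("class", ""))
            if isinstance(label, dict):  # QuPath nests {"name": ...}
                label = label.get("name", "")
            nid = props.get("nucleus_id", props.get("id", f"n{i}"))
            raw.append((nid, label, np.asarray(geom["coordinates"][0], dtype=float)))
    elif dialect == "csv":
        df = pd.read_csv(path)
        for _, row in df.iterrows():
            poly = shapely_wkt.loads(row["wkt_contour"])
            raw.append(
                (row["nucleus_id"], row["class"], np.asarray(poly.exterior.coords))
            )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    unknown = sorted(
        {lbl for _, lbl, _ in raw if str(lbl).strip().lower() not in synonyms}
    )
    if unknown:
        raise ValidationError(f"unknown nuclear class labels: {unknown}")

    out, dropped = [], 0
    for nid, label, coords in raw:
        inst = _make_instance(nid, label, coords, synonyms)
        if inst is None:
            dropped += 1
        else:
            out.append(inst)
    if dropped:
        logger.info("read_nuclei(%s): dropped %d degenerate polygon(s)", path.name, dropped)
    return out


def write_nuclei_geojson(nuclei: Iterable[NucleusInstance], path: str | Path) -> None:
    features = []
    for n in nuclei:
        ring = n.contour.tolist() + [n.contour[0].tolist()]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {"nucleus_id": n.nucleus_id, "classification": {"name": n.raw_class}},
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def write_nuclei_csv(nuclei: Iterable[NucleusInstance], path: str | Path) -> None:
    rows = []
    for n in nuclei:
        poly = Polygon(n.contour)
        rows.append({"nucleus_id": n.nucleus_id, "class": n.raw_class, "wkt_contour": poly.wkt})
    pd.DataFrame(rows, columns=["nucleus_id", "class", "wkt_contour"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# cohort


def read_cohort(path: str | Path) -> CohortTable:
    """Read a cohort CSV into a CohortTable.

    Rows with missing follow_up_months are retained (usable for training)
    but flagged ineligible for survival analyses.
    """
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"cohort CSV missing required columns: {missing}")
    records = []
    for _, row in df.iterrows():
        fum = row["follow_up_months"]
        fum = float(fum) if not pd.isna(fum) else math.nan

        def _opt(v):
            return None if pd.isna(v) else str(v)

        records.append(
            SlideRecord(
                slide_id=str(row["slide_id"]),
                patient_id=str(row["patient_id"]),
                transformed=int(row["transformed"]),
                follow_up_months=fum,
                who_grade=_opt(row["who_grade"]),
                binary_grade=_opt(row["binary_grade"]),
                age=float(row["age"]) if not pd.isna(row["age"]) else math.nan,
                sex=str(row["sex"]),
                site=_opt(row["site"]),
                cohort_tag=str(row["cohort_tag"]),
            )
        )
    n_flagged = sum(not r.survival_eligible for r in records)
    if n_flagged:
        logger.info("read_cohort(%s): %d slide(s) lack follow-up, ineligible for survival", Path(path).name, n_flagged)
    return CohortTable(records)


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    cohort.to_frame().to_csv(path, index=False)
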