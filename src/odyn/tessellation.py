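"""Patch tessellation, the dysplasia-epithelium ratio, and OED classification.

A slide is tessellated into fixed-size overlapping patches at a target
resolution (512 px, 256 px overlap at 0.5 mpp for risk scoring; 184 px
overlap at 1.0 mpp matches the segmentation-training geometry). The
dysplasia-epithelium ratio

    R_epith = |dysplasia ∩ epithelium| / |epithelium|

drives slide-level OED classification against a threshold selected for
maximal F1 on a training set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import f1_score, roc_auc_score

from odyn.datamodel import MaskRaster, check_coregistered

logger = logging.getLogger(__name__)

SCORING_PATCH = 512
SCORING_OVERLAP = 256
SCORING_MPP = 0.5
SEGMENTATION_OVERLAP = 184
SEGMENTATION_MPP = 1.0


@dataclass(frozen=True)
class PatchGrid:
    """Deterministic tessellation of a rectangular region.

    Patches are half-open windows ``[x, x+patch_size) × [y, y+patch_size)``
    at ``target_mpp``; origins are sorted row-major. ``source_rescale`` is
    the factor mapping source-mask coordinates to target coordinates
    (mask_mpp / target_mpp).
    """

    patch_size: int
    overlap: int
    target_mpp: float
    origins: tuple[tuple[int, int], ...]
    source_rescale: float
    region_shape: tuple[int, int]  # (height, width) at target mpp

    @property
    def stride(self) -> int:
        return self.patch_size - self.overlap

    def __len__(self) -> int:
        return len(self.origins)


def _axis_origins(extent: int, patch: int, stride: int) -> list[int]:
    """Stride-grid origins along one axis with the shift-to-fit edge rule."""
    if extent <= patch:
        return [0]
    last = extent - patch
    origins = list(range(0, last + 1, stride))
    if origins[-1] != last:
        origins.append(last)  # shift final patch back to end at the boundary
    return origins


def make_patch_grid(
    region_shape: tuple[int, int],
    mask_mpp: float,
    patch_size: int = SCORING_PATCH,
    overlap: int = SCORING_OVERLAP,
    target_mpp: float = SCORING_MPP,
) -> PatchGrid:
    """Build the patch grid covering a region given at mask resolution.

    The region (height, width at ``mask_mpp``) is rescaled to ``target_mpp``
    and tiled with stride ``patch_size - overlap``. Whenever the plain
    stride grid would leave an uncovered margin, a final row/column origin
    is shifted back so the last patch ends exactly at the region boundary.
    Regions smaller than one patch yield a single origin at (0, 0) with a
    logged warning (the window is edge-padded downstream).
    """
    if overlap >= patch_size:
        raise ValueError(f"overlap {overlap} must be < patch_size {patch_size}")
    rescale = mask_mpp / target_mpp
    h = int(round(region_shape[0] * rescale))
    w = int(round(region_shape[1] * rescale))
    if h <= 0 or w <= 0:
        raise ValueError(f"region {region_shape} empty after rescale {rescale}")
    stride = patch_size - overlap
    if h < patch_size or w < patch_size:
        logger.warning(
            "region %dx%d smaller than patch %d at target mpp; single edge-padded patch",
            h, w, patch_size,
        )
    ys = _axis_origins(h, patch_size, stride)
    xs = _axis_origins(w, patch_size, stride)
    origins = tuple((x, y) for y in ys for x in xs)  # row-major
    return PatchGrid(
        patch_size=patch_size,
        overlap=overlap,
        target_mpp=target_mpp,
        origins=origins,
        source_rescale=rescale,
        region_shape=(h, w),
    )


def rescale_mask(mask: MaskRaster, target_mpp: float) -> MaskRaster:
    """Nearest-neighbour rescale of a label mask to a target resolution."""
    if np.isclose(mask.mpp, target_mpp):
        return mask
    factor = mask.mpp / target_mpp
    h = int(round(mask.shape[0] * factor))
    w = int(round(mask.shape[1] * factor))
    rows = np.minimum((np.arange(h) / factor).astype(int), mask.shape[0] - 1)
    cols = np.minimum((np.arange(w) / factor).astype(int), mask.shape[1] - 1)
    return MaskRaster(mask.pixels[np.ix_(rows, cols)], mpp=target_mpp, slide_id=mask.slide_id)


def patch_window(mask: MaskRaster, origin: tuple[int, int], patch_size: int) -> np.ndarray:
    """Extract the half-open patch window, zero-padding past the boundary."""
    x, y = origin
    win = np.zeros((patch_size, patch_size), dtype=mask.pixels.dtype)
    sub = mask.pixels[y : y + patch_size, x : x + patch_size]
    win[: sub.shape[0], : sub.shape[1]] = sub
    return win


# ---------------------------------------------------------------------------
# R_epith and OED classification


@dataclass(frozen=True)
class RepithResult:
    """Per-slide dysplasia-epithelium ratio.

    ``r_epith`` is None for slides with no epithelium pixels ("no
    epithelium" flag) — such slides are unclassifiable, never scored 0.
    """

    slide_id: str
    r_epith: float | None
    epithelium_pixels: int
    dysplastic_pixels: int

    @property
    def no_epithelium(self) -> bool:
        return self.r_epith is None


def compute_repith(epithelium: MaskRaster, dysplasia: MaskRaster) -> RepithResult:
    """Fraction of epithelium-mask pixels also labelled dysplastic.

    The numerator intersects dysplasia with epithelium, guaranteeing
    r_epith <= 1 regardless of mask quality.
    """
    check_coregistered(epithelium, dysplasia)
    epith = int(epithelium.pixels.sum())
    dysp = int((epithelium.pixels & dysplasia.pixels).sum())
    if epith == 0:
        logger.info("slide %s: no epithelium pixels, R_epith undefined", epithelium.slide_id)
        return RepithResult(epithelium.slide_id, None, 0, dysp)
    return RepithResult(epithelium.slide_id, dysp / epith, epith, dysp)


@dataclass(frozen=True)
class ThresholdModel:
    """R_epith cut point fitted on a training set, with training metrics."""

    threshold: float
    training_f1: float
    training_auroc: float
    n_training_slides: int


def select_threshold(ratios: np.ndarray, labels: np.ndarray) -> ThresholdModel:
    """Pick the R_epith threshold maximizing training F1 of the OED class.

    Candidates are midpoints between consecutive sorted unique ratios plus
    {0, 1}; ties in F1 break toward the smaller threshold. Training AUROC
    is reported alongside.
    """
    ratios = np.asarray(ratios, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("select_threshold requires both classes present")
    uniq = np.unique(ratios)
    candidates = np.concatenate([[0.0], (uniq[:-1] + uniq[1:]) / 2.0, [1.0]])
    best_t, best_f1 = 0.0, -1.0
    for t in candidates:  # ascending: first max wins the tie toward smaller t
        f1 = f1_score(labels, (ratios >= t).astype(int), zero_division=0.0)
        if f1 > best_f1:
            best_t, best_f1 = float(t), float(f1)
    auroc = float(roc_auc_score(labels, ratios))
    return ThresholdModel(best_t, best_f1, auroc, len(ratios))


def classify_slide(r: RepithResult, model: ThresholdModel) -> str | None:
    """Classify one slide as dysplastic (r_epith >= threshold) or not.

    Returns None for no-epithelium slides (unclassifiable).
    """
    if r.no_epithelium:
        logger.info("slide %s unclassifiable (no epithelium)", r.slide_id)
        return None
    return "dysplastic" if r.r_epith >= model.threshold else "non_dysplastic"


def filter_scoring_patches(
    grid: PatchGrid, dysplasia: MaskRaster, min_coverage: float = 0.5
) -> PatchGrid:
    """Retain patches whose dysplastic-pixel fraction >= min_coverage.

    Risk scoring uses tissue in the dysplastic regions alone; the mask is
    rescaled to the grid's target resolution first. An empty result flags
    the slide as having no dysplastic patches (excluded from scoring).
    """
    if not 0 <= min_coverage <= 1:
        raise ValueError("min_coverage must lie in [0, 1]")
    dy = rescale_mask(dysplasia, grid.target_mpp)
    area = grid.patch_size**2
    kept = []
    for origin in grid.origins:
        frac = patch_window(dy, origin, grid.patch_size).sum() / area
        if frac >= min_coverage and frac > 0:
            kept.append(origin)
    if not kept:
        logger.info("slide %s: no dysplastic patches at coverage >= %.2f", dysplasia.slide_id, min_coverage)
    return PatchGrid(
        patch_size=grid.patch_size,
        overlap=grid.overlap,
        target_mpp=grid.target_mpp,
        origins=tuple(kept),
        source_rescale=grid.source_rescale,
        region_shape=grid.region_shape,
    )
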