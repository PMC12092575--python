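"""End-to-end orchestration: synth → classify → features → score → evaluate.

Library counterpart of the CLI subcommands; every stage is callable on
in-memory objects so tests and the acceptance script can run the whole
pipeline without touching disk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from odyn.datamodel import CohortTable, MaskRaster, NucleusInstance
from odyn.features import (
    DEFAULT_REGISTRY,
    CompartmentNucleus,
    FeatureRegistry,
    assign_compartments,
    slide_feature_matrix,
)
from odyn.mlp import MLPSpec, TrainConfig
from odyn.scoring import (
    CVPlan,
    CVResult,
    SlideScore,
    aggregate_slide,
    ensemble_external,
    run_cv,
)
from odyn.stats import (
    CENSOR_HORIZON_MONTHS,
    apply_censor_horizon,
    auprc,
    auroc,
    concordance_index,
    conservative_p,
    km_logrank,
    patch_area_ratios,
    top_tile_feature_analysis,
)
from odyn.tessellation import (
    PatchGrid,
    RepithResult,
    ThresholdModel,
    classify_slide,
    compute_repith,
    filter_scoring_patches,
    make_patch_grid,
    patch_window,
    rescale_mask,
    select_threshold,
)

logger = logging.getLogger(__name__)

SlideBundle = dict[str, tuple[MaskRaster, MaskRaster, list[NucleusInstance]]]


# ---------------------------------------------------------------------------
# OED classification stage


def classify_cohort(
    bundle: SlideBundle, is_dysplastic: dict[str, int],
    threshold_model: ThresholdModel | None = None,
) -> tuple[pd.DataFrame, ThresholdModel]:
    """Compute R_epith per slide; fit (or apply) the classification threshold.

    Returns a per-slide DataFrame (slide_id, r_epith, label, prediction)
    and the threshold model. Slides without epithelium are retained with a
    null prediction and excluded from metric computation upstream.
    """
    results: dict[str, RepithResult] = {}
    for sid, (ep, dy, _) in bundle.items():
        results[sid] = compute_repith(ep, dy)
    defined = {s: r for s, r in results.items() if not r.no_epithelium}
    if threshold_model is None:
        ratios = np.array([defined[s].r_epith for s in defined])
        labels = np.array([is_dysplastic[s] for s in defined])
        threshold_model = select_threshold(ratios, labels)
    rows = []
    for sid, r in results.items():
        pred = classify_slide(r, threshold_model)
        rows.append(
            {
                "slide_id": sid,
                "r_epith": r.r_epith if not r.no_epithelium else np.nan,
                "is_dysplastic": is_dysplastic.get(sid),
                "predicted": pred,
            }
        )
    return pd.DataFrame(rows), threshold_model


# ---------------------------------------------------------------------------
# feature extraction stage


@dataclass
class SlideFeatures:
    """Per-slide scoring grid, compartment nuclei, and feature matrix."""

    grid: PatchGrid
    nuclei: list[CompartmentNucleus]
    matrix: np.ndarray  # (n_patches, 168)


def extract_features(
    bundle: SlideBundle,
    min_coverage: float = 0.5,
    registry: FeatureRegistry = DEFAULT_REGISTRY,
    patch_size: int = 512,
    overlap: int = 256,
    target_mpp: float = 0.5,
) -> dict[str, SlideFeatures]:
    """Build the dysplastic-region patch grid and the 168-feature matrix
    for every slide. Slides with no dysplastic patches are dropped with a
    logged count (they cannot be risk-scored)."""
    out: dict[str, SlideFeatures] = {}
    n_dropped = 0
    for sid, (ep, dy, nuclei) in bundle.items():
        grid = make_patch_grid(ep.shape, ep.mpp, patch_size, overlap, target_mpp)
        grid = filter_scoring_patches(grid, dy, min_coverage)
        if len(grid) == 0:
            n_dropped += 1
            continue
        comp = assign_compartments(nuclei, ep)
        mat = slide_feature_matrix(grid, comp, ep.mpp, registry)
        out[sid] = SlideFeatures(grid, comp, mat)
    if n_dropped:
        logger.info("extract_features: %d slide(s) had no dysplastic patches", n_dropped)
    return out


# ---------------------------------------------------------------------------
# scoring + evaluation stage


@dataclass
class ScoringEvaluation:
    """Cross-validated scoring metrics plus survival analyses."""

    auroc_per_repeat: list[float]
    auprc_per_repeat: list[float]
    auroc_pooled: float
    auprc_pooled: float
    c_index_per_repeat: list[float]
    c_index_mean: float
    logrank_p_per_repeat: list[float]
    conservative_p: float
    mean_scores: dict[str, float]


def evaluate_scoring(
    cohort: CohortTable, cv: CVResult, risk_cutoff: float = 0.5,
    censor_horizon: float = CENSOR_HORIZON_MONTHS,
) -> ScoringEvaluation:
    """AUROC/AUPRC per repeat and pooled, C-index (mean over repeats), and
    the conservative 2×median log-rank p for the risk-group split."""
    aurocs, auprcs, cidx, lps = [], [], [], []
    for rep in cv.per_repeat_scores:
        sids = sorted(rep)
        scores = np.array([rep[s].odyn_score for s in sids])
        labels = np.array([cohort.slide(s).transformed for s in sids])
        aurocs.append(auroc(scores, labels))
        auprcs.append(auprc(scores, labels))
        elig = [i for i, s in enumerate(sids) if cohort.slide(s).survival_eligible]
        times = np.array([cohort.slide(sids[i]).follow_up_months for i in elig])
        events = labels[elig]
        times, events = apply_censor_horizon(times, events, censor_horizon)
        cidx.append(concordance_index(scores[elig], times, events))
        groups = np.where(scores[elig] >= risk_cutoff, "high", "low")
        if len(np.unique(groups)) == 2 and events.sum() > 0:
            lps.append(km_logrank(times, events, groups)["p_value"])
        else:
            lps.append(1.0)
    mean_scores = cv.mean_scores()
    sids = sorted(mean_scores)
    pooled_scores = np.array([mean_scores[s] for s in sids])
    pooled_labels = np.array([cohort.slide(s).transformed for s in sids])
    return ScoringEvaluation(
        auroc_per_repeat=aurocs,
        auprc_per_repeat=auprcs,
        auroc_pooled=auroc(pooled_scores, pooled_labels),
        auprc_pooled=auprc(pooled_scores, pooled_labels),
        c_index_per_repeat=cidx,
        c_index_mean=float(np.mean(cidx)),
        logrank_p_per_repeat=lps,
        conservative_p=conservative_p(lps),
        mean_scores=mean_scores,
    )


# ---------------------------------------------------------------------------
# top-tile feature analysis wiring


def _patch_measures(
    sf: SlideFeatures, ep: MaskRaster, dy: MaskRaster, patch_idx: np.ndarray
) -> pd.DataFrame:
    """Nuclear counts and area ratios for the selected patches of one slide."""
    ep_t = rescale_mask(ep, sf.grid.target_mpp)
    dy_t = rescale_mask(dy, sf.grid.target_mpp)
    factor = ep.mpp / sf.grid.target_mpp
    rows = []
    for i in patch_idx:
        x0, y0 = sf.grid.origins[i]
        size = sf.grid.patch_size
        counts = {c: 0 for c in ("dysplastic_epithelial", "normal_epithelial", "IEL", "PEL")}
        for n in sf.nuclei:
            cx, cy = n.centroid[0] * factor, n.centroid[1] * factor
            if x0 <= cx < x0 + size and y0 <= cy < y0 + size:
                counts[n.compartment_class] += 1
        ratios = patch_area_ratios(
            patch_window(ep_t, (x0, y0), size), patch_window(dy_t, (x0, y0), size)
        )
        rows.append({**counts, **{f"area_{k}": v for k, v in ratios.items()}})
    return pd.DataFrame(rows)


def run_top_tile_analysis(
    cohort: CohortTable,
    bundle: SlideBundle,
    features: dict[str, SlideFeatures],
    slide_scores: dict[str, SlideScore],
    risk_cutoff: float = 0.5,
    n_tiles: int = 10,
) -> pd.DataFrame:
    """Nuclear count / area-ratio comparison in the top-ranked tiles of
    correctly predicted transforming (TP) vs non-transforming (TN) slides."""
    tp_frames, tn_frames = [], []
    for sid, score in slide_scores.items():
        if sid not in features:
            continue
        rec = cohort.slide(sid)
        predicted_high = score.odyn_score >= risk_cutoff
        if rec.transformed == 1 and predicted_high:
            target = tp_frames
        elif rec.transformed == 0 and not predicted_high:
            target = tn_frames
        else:
            continue
        order = np.argsort(score.patch_scores)[::-1][:n_tiles]
        ep, dy, _ = bundle[sid]
        target.append(_patch_measures(features[sid], ep, dy, order))
    if not tp_frames or not tn_frames:
        raise ValueError("need both correctly predicted transforming (TP) and "
                         "non-transforming (TN) slides")
    return top_tile_feature_analysis(pd.concat(tp_frames), pd.concat(tn_frames))


# ---------------------------------------------------------------------------
# one-call pipeline on a synthetic cohort


def run_synthetic_pipeline(
    cohort: CohortTable,
    bundle: SlideBundle,
    plan: CVPlan = CVPlan(),
    cfg: TrainConfig | None = None,
    spec: MLPSpec | None = None,
    min_coverage: float = 0.5,
):
    """Features → grouped CV scoring → evaluation on an in-memory cohort.

    Returns (features, CVResult, ScoringEvaluation).
    """
    feats = extract_features(bundle, min_coverage)
    matrices = {s: f.matrix for s, f in feats.items()}
    cv = run_cv(cohort, matrices, plan, cfg, spec)
    ev = evaluate_scoring(cohort, cv)
    return feats, cv, ev
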