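"""Slide-level malignant-transformation risk scoring (the ODYN-score).

A slide is a weakly labelled bag of dysplastic patches. Training uses
iterative draw-and-rank sampling (IDaRS): each epoch, every training slide
contributes its k patches currently ranked highest for the slide's own
label plus r patches drawn uniformly at random (epoch 0 ranks uniformly at
random; slides with fewer than k + r patches contribute all patches). The
pool is optimized in minibatches with Adam on the symmetric cross-entropy
loss. At inference the network scores every patch and the slide-level
ODYN-score is the mean of the top 50% (⌈n/2⌉) of patch scores.

Evaluation follows patient-grouped repeated 5-fold cross-validation
(3 repeats, 90/10 inner train/validation split for checkpoint selection)
producing 15 models; external cohorts are scored by ensembling all 15.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedGroupKFold

from odyn.datamodel import CohortTable
from odyn.mlp import MLP, MLPSpec, TrainConfig

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SlideScore:
    """Per-patch scores plus the aggregated slide-level risk score."""

    slide_id: str
    patch_scores: np.ndarray
    odyn_score: float
    risk_group: str  # "high" | "low"


@dataclass(frozen=True)
class CVPlan:
    """Patient-grouped, outcome-stratified repeated k-fold plan."""

    n_folds: int = 5
    n_repeats: int = 3
    val_fraction: float = 0.1
    seed: int = 0


DEFAULT_RISK_CUTOFF = 0.5


def aggregate_slide(patch_scores: np.ndarray, slide_id: str = "",
                    risk_cutoff: float = DEFAULT_RISK_CUTOFF) -> SlideScore:
    """Mean of the top 50% (⌈n/2⌉) ranked patch scores."""
    s = np.asarray(patch_scores, dtype=float)
    if s.size == 0:
        raise ValueError("aggregate_slide needs at least one patch score")
    top = np.sort(s)[::-1][: math.ceil(len(s) / 2)]
    score = float(top.mean())
    return SlideScore(slide_id, s, score, "high" if score >= risk_cutoff else "low")


class TrainedModel:
    """An MLP plus the feature standardization fitted on its training set."""

    def __init__(self, mlp: MLP, feat_mean: np.ndarray, feat_sd: np.ndarray):
        self.mlp = mlp
        self.feat_mean = feat_mean
        self.feat_sd = feat_sd

    def predict_patches(self, features: np.ndarray) -> np.ndarray:
        """Positive-class probability per patch (dropout disabled)."""
        X = (np.asarray(features, dtype=float) - self.feat_mean) / self.feat_sd
        return self.mlp.predict_proba(X)[:, 1]

    def score_slide(self, features: np.ndarray, slide_id: str = "",
                    risk_cutoff: float = DEFAULT_RISK_CUTOFF) -> SlideScore:
        return aggregate_slide(self.predict_patches(features), slide_id, risk_cutoff)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(
            path.with_suffix(".npz"),
            feat_mean=self.feat_mean, feat_sd=self.feat_sd, **self.mlp.get_params(),
        )
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump({"spec": self.mlp.spec_dict()}, fh, indent=1)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        path = Path(path)
        if not path.with_suffix(".npz").exists():
            raise FileNotFoundError(f"model file missing: {path.with_suffix('.npz')}")
        with open(path.with_suffix(".json")) as fh:
            spec = MLPSpec(**json.load(fh)["spec"])
        data = np.load(path.with_suffix(".npz"))
        mlp = MLP(spec)
        mlp.set_params({k: data[k] for k in ("W1", "b1", "W2", "b2")})
        return cls(mlp, data["feat_mean"], data["feat_sd"])


def _standardize_fit(stack: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0)
    sd[sd == 0] = 1.0  # constant features pass through centred
    return mean, sd


def idars_train(
    features: dict[str, np.ndarray],
    labels: dict[str, int],
    cfg: TrainConfig,
    spec: MLPSpec | None = None,
    val_features: dict[str, np.ndarray] | None = None,
    val_labels: dict[str, int] | None = None,
) -> TrainedModel:
    """Train the scoring MLP with iterative draw-and-rank sampling.

    ``features`` maps slide_id to an (n_patches, n_in) array; slides with
    zero patches are excluded with a logged count. When a validation split
    is given, the parameters from the epoch with the best validation slide
    AUROC are kept (final-epoch parameters otherwise). Fully deterministic
    given ``cfg.seed`` and ``spec.param_seed``.
    """
    slides = [s for s in features if len(features[s]) > 0]
    n_empty = len(features) - len(slides)
    if n_empty:
        logger.info("idars_train: excluded %d slide(s) with no scoring patches", n_empty)
    if len({labels[s] for s in slides}) < 2:
        raise ValueError("training requires at least one slide per class")

    spec = spec or MLPSpec(param_seed=cfg.seed)
    stack = np.vstack([features[s] for s in slides])
    mean, sd = _standardize_fit(stack)
    Z = {s: (features[s] - mean) / sd for s in slides}

    mlp = MLP(spec)
    model = TrainedModel(mlp, mean, sd)
    rng = np.random.default_rng(cfg.seed)

    # epoch-0 ranking is uniform random
    ranking = {s: rng.permutation(len(Z[s])) for s in slides}

    best_val, best_params = -np.inf, None
    for epoch in range(cfg.epochs):
        xs, ys = [], []
        for s in slides:
            n = len(Z[s])
            if n <= cfg.k + cfg.r:
                idx = np.arange(n)  # all patches, without replacement
            else:
                top = ranking[s][: cfg.k]
                rest = np.setdiff1d(np.arange(n), top, assume_unique=False)
                rand = rng.choice(rest, size=min(cfg.r, len(rest)), replace=False)
                idx = np.concatenate([top, rand])
            xs.append(Z[s][idx])
            ys.append(np.full(len(idx), labels[s], dtype=int))
        X = np.vstack(xs)
        y = np.concatenate(ys)
        order = rng.permutation(len(X))
        X, y = X[order], y[order]
        for i in range(0, len(X), cfg.batch_size):
            mlp.train_step(X[i : i + cfg.batch_size], y[i : i + cfg.batch_size], cfg, rng)

        # re-rank each slide by the probability of its own label class
        if cfg.k > 0:
            for s in slides:
                p_pos = mlp.predict_proba(Z[s])[:, 1]
                own = p_pos if labels[s] == 1 else 1.0 - p_pos
                ranking[s] = np.argsort(own)[::-1]

        if val_features:
            vs = [s for s in val_features if len(val_features[s]) > 0]
            scores = [model.score_slide(val_features[s]).odyn_score for s in vs]
            vl = [val_labels[s] for s in vs]
            if len(set(vl)) == 2:
                auc = roc_auc_score(vl, scores)
                if auc > best_val:
                    best_val, best_params = auc, mlp.get_params()

    if best_params is not None:
        mlp.set_params(best_params)
    return model


# ---------------------------------------------------------------------------
# cross-validation and ensembling


def _patient_table(cohort: CohortTable, slide_ids: list[str]):
    pids, outcomes = [], []
    for pid in cohort.patient_ids:
        recs = [r for r in cohort.patient(pid) if r.slide_id in slide_ids]
        if recs:
            pids.append(pid)
            outcomes.append(max(r.transformed for r in recs))
    return pids, outcomes


@dataclass
class CVResult:
    """Out-of-fold scores (per repeat and their mean) plus all 15 models."""

    per_repeat_scores: list[dict[str, SlideScore]]  # n_repeats dicts
    models: list[TrainedModel]  # n_folds * n_repeats
    fold_assignment: list[dict[str, int]]  # patient -> fold, per repeat

    def mean_scores(self) -> dict[str, float]:
        ids = self.per_repeat_scores[0].keys()
        return {
            s: float(np.mean([rep[s].odyn_score for rep in self.per_repeat_scores]))
            for s in ids
        }


def run_cv(
    cohort: CohortTable,
    features: dict[str, np.ndarray],
    plan: CVPlan = CVPlan(),
    cfg: TrainConfig | None = None,
    spec: MLPSpec | None = None,
) -> CVResult:
    """Patient-grouped repeated k-fold cross-validation of the scorer.

    Every slide receives one out-of-fold score per repeat; slides of one
    patient never straddle a train/test boundary. Emits
    ``n_folds * n_repeats`` trained models for external ensembling.
    """
    cfg = cfg or TrainConfig()
    slide_ids = [s for s in cohort.slide_ids if s in features and len(features[s]) > 0]
    labels = {s: cohort.slide(s).transformed for s in slide_ids}
    pids, outcomes = _patient_table(cohort, slide_ids)
    if len(pids) < 2 or len(set(outcomes)) < 2:
        raise ValueError("cross-validation needs >= 2 patients and both outcomes")

    models: list[TrainedModel] = []
    per_repeat: list[dict[str, SlideScore]] = []
    assignments: list[dict[str, int]] = []
    for rep in range(plan.n_repeats):
        rep_seed = plan.seed * 1009 + rep
        splitter = StratifiedGroupKFold(
            n_splits=plan.n_folds, shuffle=True, random_state=rep_seed % (2**31)
        )
        pid_arr = np.array(pids)
        fold_of: dict[str, int] = {}
        rep_scores: dict[str, SlideScore] = {}
        for fold, (_, test_idx) in enumerate(
            splitter.split(pid_arr, np.array(outcomes), groups=pid_arr)
        ):
            for p in pid_arr[test_idx]:
                fold_of[p] = fold
        assignments.append(fold_of)
        for fold in range(plan.n_folds):
            test_p = {p for p, f in fold_of.items() if f == fold}
            train_p = [p for p in pids if p not in test_p]
            # inner train/validation split of the remaining patients
            rng = np.random.default_rng(rep_seed * 7 + fold)
            perm = rng.permutation(len(train_p))
            n_val = max(1, int(round(plan.val_fraction * len(train_p))))
            val_p = {train_p[i] for i in perm[:n_val]}
            fit_p = [p for p in train_p if p not in val_p]

            def _slides(pset):
                return [s for s in slide_ids if cohort.slide(s).patient_id in pset]

            fit_s, val_s, test_s = _slides(set(fit_p)), _slides(val_p), _slides(test_p)
            fold_cfg = TrainConfig(**{**cfg.__dict__, "seed": rep_seed * 131 + fold})
            fold_spec = spec or MLPSpec(param_seed=fold_cfg.seed + 1)
            model = idars_train(
                {s: features[s] for s in fit_s}, {s: labels[s] for s in fit_s},
                fold_cfg, fold_spec,
                {s: features[s] for s in val_s}, {s: labels[s] for s in val_s},
            )
            models.append(model)
            for s in test_s:
                rep_scores[s] = model.score_slide(features[s], s)
        per_repeat.append(rep_scores)
    return CVResult(per_repeat, models, assignments)


def ensemble_external(
    models: list[TrainedModel],
    features: dict[str, np.ndarray],
    risk_cutoff: float = DEFAULT_RISK_CUTOFF,
) -> dict[str, SlideScore]:
    """Score an external cohort as the mean over all models' slide scores."""
    if not models:
        raise ValueError("no models to ensemble")
    out: dict[str, SlideScore] = {}
    for s, X in features.items():
        if len(X) == 0:
            logger.info("ensemble_external: slide %s has no patches, skipped", s)
            continue
        per_model = np.array([m.score_slide(X).odyn_score for m in models])
        patch_mean = np.mean([m.predict_patches(X) for m in models], axis=0)
        score = float(per_model.mean())
        out[s] = SlideScore(s, patch_mean, score, "high" if score >= risk_cutoff else "low")
    return out
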