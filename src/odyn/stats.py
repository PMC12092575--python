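"""Evaluation statistics: classification and mask metrics, rank tests with
effect sizes, FDR control, survival analyses, and the top-tile feature
analysis.

Conventions follow standard practice in prognostic-model studies:
pixel-level F1/recall/precision for segmentation masks (specificity alone
for all-negative control slides), AUROC/AUPRC for slide classification,
Kaplan-Meier with log-rank tests and Harrell's C for transformation-free
survival, multivariate Cox proportional hazards (Efron ties), Mann-Whitney
U with rank-biserial effect sizes and Benjamini-Hochberg FDR for group
comparisons, and a conservative combined p across CV repeats equal to
twice the median log-rank p (clamped at 1). Transformation events are
right-censored at 96 months before any survival fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import concordance_index as _lifelines_cindex
from scipy import stats as sps
from sklearn.metrics import average_precision_score, roc_auc_score
from statsmodels.stats.multitest import multipletests

from odyn.datamodel import MaskRaster, check_coregistered

CENSOR_HORIZON_MONTHS = 96.0


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test with effect size and descriptives."""

    statistic: float
    p_value: float
    effect_size: float | None = None
    n: tuple[int, ...] = ()
    descriptives: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# classification / mask metrics


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve (rank/Mann-Whitney formulation, midrank ties)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC undefined with a single class")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def auprc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the precision-recall curve (step-wise integration)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUPRC undefined with a single class")
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


def mask_metrics(pred: MaskRaster, truth: MaskRaster) -> dict[str, float]:
    """Pixel-level F1, recall, precision of a predicted binary mask."""
    check_coregistered(pred, truth)
    p = pred.pixels.astype(bool)
    t = truth.pixels.astype(bool)
    tp = int((p & t).sum())
    fp = int((p & ~t).sum())
    fn = int((~p & t).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    return {"f1": f1, "recall": recall, "precision": precision}


def specificity(pred: MaskRaster, truth: MaskRaster) -> float:
    """TN / (TN + FP); the reported measure for all-negative control slides."""
    check_coregistered(pred, truth)
    p = pred.pixels.astype(bool)
    t = truth.pixels.astype(bool)
    tn = int((~p & ~t).sum())
    fp = int((p & ~t).sum())
    return tn / (tn + fp) if tn + fp else 1.0


# ---------------------------------------------------------------------------
# rank tests


def _rank_sum_null_distribution(ranks2: np.ndarray, n_x: int) -> dict[int, float]:
    """Exact permutation null of the doubled rank sum of a size-n_x subset.

    Dynamic program over the multiset of doubled midranks (integers), so
    ties are handled exactly. Returns {doubled rank sum: probability}.
    """
    # dp[j] maps doubled-ranksum -> count of j-subsets achieving it
    dp: list[dict[int, int]] = [{0: 1}] + [dict() for _ in range(n_x)]
    for r in ranks2:
        for j in range(min(n_x, 1_000_000), 0, -1):
            if dp[j - 1]:
                tgt = dp[j]
                for s, c in dp[j - 1].items():
                    tgt[s + r] = tgt.get(s + r, 0) + c
    total = sum(dp[n_x].values())
    return {s: c / total for s, c in dp[n_x].items()}


def mann_whitney_rrb(x: Sequence[float], y: Sequence[float],
                     exact_max_product: int = 400) -> TestResult:
    """Two-tailed Mann-Whitney U test with rank-biserial effect size.

    U_x counts pairs with x > y (+1/2 per tie); r_rb = 2 U_x/(n_x n_y) − 1.
    The p-value is exact (permutation null over midranks, handled by a
    subset-sum dynamic program) when n_x·n_y <= ``exact_max_product``,
    otherwise a normal approximation with tie correction and continuity
    correction. Descriptives report per-group medians and IQRs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    n_x, n_y = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u_x = ranks[:n_x].sum() - n_x * (n_x + 1) / 2.0
    r_rb = 2.0 * u_x / (n_x * n_y) - 1.0

    mu = n_x * n_y / 2.0
    if n_x * n_y <= exact_max_product:
        ranks2 = np.round(ranks * 2).astype(int)
        dist = _rank_sum_null_distribution(ranks2, n_x)
        # doubled rank sum -> U: u = (s2 - n_x(n_x+1)) / 2
        dev = abs(u_x - mu)
        p = sum(
            pr for s2, pr in dist.items()
            if abs((s2 - n_x * (n_x + 1)) / 2.0 - mu) >= dev - 1e-9
        )
    else:
        tie_counts = np.unique(pooled, return_counts=True)[1]
        n = n_x + n_y
        tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
        sd = np.sqrt(n_x * n_y / 12.0 * (n + 1 - tie_term))
        if sd == 0:
            p = 1.0
        else:
            z = (abs(u_x - mu) - 0.5) / sd  # continuity correction
            p = 2.0 * sps.norm.sf(max(z, 0.0))
    p = float(min(p, 1.0))

    def _desc(v):
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        return {"median": float(med), "iqr": (float(q1), float(q3))}

    return TestResult(float(u_x), p, float(r_rb), (n_x, n_y),
                      {"x": _desc(x), "y": _desc(y)})


def spearman_perm(x: Sequence[float], y: Sequence[float],
                  n_perm: int = 9999, seed: int = 0) -> TestResult:
    """Spearman's rho on midranks with a permutation p-value.

    p = (1 + #{permutations with |rho*| >= |rho|}) / (n_perm + 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman rho undefined for a constant vector")
    rho = float(sps.spearmanr(x, y).statistic)
    rng = np.random.default_rng(seed)
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum())
    obs = abs((rx_c * ry_c).sum() / denom)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(ry_c)
        if abs((rx_c * perm).sum() / denom) >= obs - 1e-12:
            hits += 1
    return TestResult(rho, (1 + hits) / (n_perm + 1), rho, (len(x),))


def shapiro_wilk(x: Sequence[float]) -> TestResult:
    """Shapiro-Wilk normality test (gate before rank tests)."""
    x = np.asarray(x, dtype=float)
    if not 3 <= len(x) <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk undefined for a constant vector")
    w, p = sps.shapiro(x)
    return TestResult(float(w), float(p), None, (len(x),))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# survival


def apply_censor_horizon(times: np.ndarray, events: np.ndarray,
                         horizon: float = CENSOR_HORIZON_MONTHS) -> tuple[np.ndarray, np.ndarray]:
    """Right-censor at the horizon: later times clip to it, events past it drop."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    over = times > horizon
    return np.where(over, horizon, times), np.where(over, 0, events)


def km_logrank(times: Sequence[float], events: Sequence[int],
               groups: Sequence) -> dict:
    """Kaplan-Meier curves per group plus the log-rank test.

    Returns {"curves": {group: DataFrame(time, survival, at_risk)},
    "chi2": float, "p_value": float, "df": int}.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise ValueError("log-rank requires >= 2 groups")
    if events.sum() == 0:
        raise ValueError("log-rank requires >= 1 event")
    curves = {}
    for g in uniq:
        m = groups == g
        if m.sum() == 0:
            raise ValueError(f"group {g} has no records")
        kmf = KaplanMeierFitter()
        kmf.fit(times[m], events[m])
        sf = kmf.survival_function_
        at_risk = kmf.event_table["at_risk"].reindex(sf.index).to_numpy()
        curves[g] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy(),
             "at_risk": at_risk}
        )
    res = multivariate_logrank_test(times, groups, events)
    return {"curves": curves, "chi2": float(res.test_statistic),
            "p_value": float(res.p_value), "df": len(uniq) - 1}


def concordance_index(scores: Sequence[float], times: Sequence[float],
                      events: Sequence[int]) -> float:
    """Harrell's C between predicted risk and transformation-free survival.

    Higher scores should pair with shorter survival; score ties count 1/2.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if events.sum() == 0:
        raise ValueError("no comparable pairs (no events)")
    try:
        # lifelines' C rewards scores concordant with longer survival
        return float(_lifelines_cindex(times, -scores, events))
    except ZeroDivisionError as e:  # all events at the latest time
        raise ValueError("no comparable pairs") from e


def conservative_p(log_rank_ps: Sequence[float]) -> float:
    """Conservative combined p across CV repeats: min(1, 2 * median)."""
    ps = np.asarray(log_rank_ps, dtype=float)
    if ps.size == 0:
        raise ValueError("need >= 1 p-value")
    return float(min(1.0, 2.0 * np.median(ps)))


def cox_multivariate(df: pd.DataFrame, duration_col: str, event_col: str,
                     covariates: list[str]) -> pd.DataFrame:
    """Multivariate Cox proportional hazards fit (Efron tie handling).

    Categorical covariates are one-hot encoded (first level dropped).
    Returns a DataFrame indexed by covariate with columns log_hr, hr,
    hr_ci_low, hr_ci_high, p_value.
    """
    data = df[[duration_col, event_col]].copy()
    for c in covariates:
        col = df[c]
        if col.dtype == object or str(col.dtype) == "category":
            dummies = pd.get_dummies(col, prefix=c, drop_first=True, dtype=float)
            data = pd.concat([data, dummies], axis=1)
        else:
            data[c] = col.astype(float)
    bad = [c for c in data.columns if data[c].nunique() <= 1 and c not in (duration_col, event_col)]
    if bad:
        raise ValueError(f"constant covariate(s): {bad}")
    n_events = int(data[event_col].sum())
    if n_events < len(data.columns) - 1:
        raise ValueError("fewer events than covariates + 1")
    cph = CoxPHFitter()
    cph.fit(data, duration_col=duration_col, event_col=event_col)
    s = cph.summary
    return pd.DataFrame(
        {
            "log_hr": s["coef"],
            "hr": s["exp(coef)"],
            "hr_ci_low": s["exp(coef) lower 95%"],
            "hr_ci_high": s["exp(coef) upper 95%"],
            "p_value": s["p"],
        }
    )


# ---------------------------------------------------------------------------
# top-tile feature analysis


NUCLEAR_COUNT_MEASURES = ["dysplastic_epithelial", "normal_epithelial", "IEL", "PEL"]
AREA_RATIO_MEASURES = ["other_tissue", "dysplastic_epithelium", "normal_epithelium"]


def patch_area_ratios(epith_win: np.ndarray, dysp_win: np.ndarray) -> dict[str, float]:
    """Partition of one patch into other tissue / dysplastic / normal epithelium."""
    area = epith_win.size
    dysp = int((epith_win.astype(bool) & dysp_win.astype(bool)).sum())
    epith = int(epith_win.astype(bool).sum())
    return {
        "other_tissue": (area - epith) / area,
        "dysplastic_epithelium": dysp / area,
        "normal_epithelium": (epith - dysp) / area,
    }


def top_tile_feature_analysis(
    tp_measures: pd.DataFrame, tn_measures: pd.DataFrame,
    measures: list[str] | None = None,
) -> pd.DataFrame:
    """Compare per-patch nuclear counts and area ratios between the top-10
    tiles of true-positive vs true-negative slides.

    ``tp_measures``/``tn_measures`` hold one row per patch with one column
    per measure. Each measure gets a Shapiro-Wilk normality gate, a
    two-tailed Mann-Whitney U with rank-biserial effect size, and BH-FDR
    adjustment across the measure family; medians and IQRs are reported.
    """
    if len(tp_measures) == 0 or len(tn_measures) == 0:
        raise ValueError("need patches from both TP and TN slides")
    measures = measures or list(tp_measures.columns)
    rows = []
    for m in measures:
        x = tp_measures[m].to_numpy(dtype=float)
        y = tn_measures[m].to_numpy(dtype=float)
        try:
            sw_p = min(shapiro_wilk(x).p_value, shapiro_wilk(y).p_value)
        except ValueError:
            sw_p = np.nan
        res = mann_whitney_rrb(x, y)
        rows.append(
            {
                "measure": m,
                "shapiro_p": sw_p,
                "u_statistic": res.statistic,
                "p_value": res.p_value,
                "r_rb": res.effect_size,
                "tp_median": res.descriptives["x"]["median"],
                "tp_iqr_low": res.descriptives["x"]["iqr"][0],
                "tp_iqr_high": res.descriptives["x"]["iqr"][1],
                "tn_median": res.descriptives["y"]["median"],
                "tn_iqr_low": res.descriptives["y"]["iqr"][0],
                "tn_iqr_high": res.descriptives["y"]["iqr"][1],
                "n_tp": len(x),
                "n_tn": len(y),
            }
        )
    out = pd.DataFrame(rows)
    out["p_adjusted"] = bh_fdr(out["p_value"].to_numpy())
    return out
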