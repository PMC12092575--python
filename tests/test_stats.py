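"""Every reported statistic matches an independent brute-force oracle or a
hand-computed value."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from odyn.datamodel import MaskRaster
from odyn.stats import (
    apply_censor_horizon,
    auprc,
    auroc,
    bh_fdr,
    concordance_index,
    conservative_p,
    cox_multivariate,
    km_logrank,
    mann_whitney_rrb,
    mask_metrics,
    patch_area_ratios,
    shapiro_wilk,
    spearman_perm,
    specificity,
    top_tile_feature_analysis,
)

# ---------------------------------------------------------------------------
# brute-force oracles


def brute_auroc(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    c = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return c / (len(pos) * len(neg))


def brute_auprc(scores, labels):
    """Step-wise PR integration over distinct score thresholds:
    AP = sum (R_i - R_{i-1}) * P_i."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = labels.sum()
    ap, prev_recall = 0.0, 0.0
    for thr in sorted(set(scores), reverse=True):
        above = scores >= thr
        tp = int((labels[above] == 1).sum())
        precision = tp / above.sum()
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def brute_u_and_rrb(x, y):
    gt = sum(1.0 for a in x for b in y if a > b)
    eq = sum(1.0 for a in x for b in y if a == b)
    u = gt + 0.5 * eq
    return u, 2 * u / (len(x) * len(y)) - 1


def brute_mw_exact_p(x, y):
    """Exact two-tailed permutation p over all group assignments."""
    pooled = list(x) + list(y)
    n_x = len(x)
    mu = n_x * len(y) / 2.0
    obs = abs(brute_u_and_rrb(x, y)[0] - mu)
    hits = total = 0
    for comb in itertools.combinations(range(len(pooled)), n_x):
        xs = [pooled[i] for i in comb]
        ys = [pooled[i] for i in range(len(pooled)) if i not in comb]
        if abs(brute_u_and_rrb(xs, ys)[0] - mu) >= obs - 1e-9:
            hits += 1
        total += 1
    return hits / total


def brute_cindex(scores, times, events):
    num = den = 0.0
    n = len(scores)
    for i in range(n):
        for j in range(n):
            if i == j or not events[i]:
                continue
            if times[i] < times[j] or (times[i] == times[j] and not events[j]):
                den += 1
                if scores[i] > scores[j]:
                    num += 1
                elif scores[i] == scores[j]:
                    num += 0.5
    return num / den


def brute_km(times, events):
    """Product-limit estimate at each distinct event time."""
    out = {}
    s = 1.0
    for t in sorted(set(times)):
        at_risk = sum(1 for u in times if u >= t)
        d = sum(1 for u, e in zip(times, events) if u == t and e)
        if d:
            s *= 1 - d / at_risk
        out[t] = s
    return out


def brute_bh(p):
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank_from_end, i in enumerate(order[::-1]):
        rank = m - rank_from_end
        prev = min(prev, p[i] * m / rank)
        adj[i] = prev
    return adj


# ---------------------------------------------------------------------------


class TestAUROCandAUPRC:
    def test_known_values(self):
        assert auroc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0
        assert auroc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_matches_pairwise_enumeration(self, rng):
        for _ in range(30):
            n = int(rng.integers(6, 40))
            scores = rng.integers(0, 10, n) / 10.0  # ties likely
            labels = rng.integers(0, 2, n)
            if len(np.unique(labels)) < 2:
                continue
            assert auroc(scores, labels) == pytest.approx(brute_auroc(scores, labels))
            assert auprc(scores, labels) == pytest.approx(brute_auprc(scores, labels))

    def test_random_balanced_auprc_near_prevalence(self, rng):
        scores = rng.random(2000)
        labels = rng.integers(0, 2, 2000)
        assert auprc(scores, labels) == pytest.approx(labels.mean(), abs=0.05)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.2], [1, 1])


class TestMaskMetrics:
    def _mask(self, arr):
        return MaskRaster(np.asarray(arr, dtype=np.uint8), 0.5)

    def test_identical_and_disjoint(self):
        a = self._mask([[1, 1], [0, 0]])
        b = self._mask([[0, 0], [1, 1]])
        assert mask_metrics(a, a)["f1"] == 1.0
        assert mask_metrics(a, b)["f1"] == 0.0

    def test_half_coverage(self):
        truth = self._mask([[1, 1, 1, 1]])
        pred = self._mask([[1, 1, 0, 0]])
        m = mask_metrics(pred, truth)
        assert m["recall"] == 0.5
        assert m["precision"] == 1.0
        assert m["f1"] == pytest.approx(2 / 3)

    def test_specificity_on_all_negative_truth(self):
        truth = self._mask([[0, 0, 0, 0]])
        pred = self._mask([[1, 0, 0, 0]])
        assert specificity(pred, truth) == 0.75


class TestMannWhitney:
    def test_complete_separation(self):
        res = mann_whitney_rrb([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0
        assert res.effect_size == -1

    def test_identical_multisets_zero_effect(self):
        res = mann_whitney_rrb([1, 2, 2, 5], [1, 2, 2, 5])
        assert res.effect_size == 0

    def test_interleaved_example_matches_enumeration(self):
        res = mann_whitney_rrb([1, 4], [2, 3])
        assert res.statistic == 2
        assert res.effect_size == 0
        assert res.p_value == pytest.approx(brute_mw_exact_p([1, 4], [2, 3]))

    def test_exact_p_matches_full_enumeration_with_ties(self, rng):
        for _ in range(25):
            nx, ny = rng.integers(2, 7, 2)
            x = rng.integers(0, 5, nx).tolist()
            y = rng.integers(0, 5, ny).tolist()
            res = mann_whitney_rrb(x, y)
            assert res.statistic == pytest.approx(brute_u_and_rrb(x, y)[0])
            assert res.effect_size == pytest.approx(brute_u_and_rrb(x, y)[1])
            assert res.p_value == pytest.approx(brute_mw_exact_p(x, y))

    def test_large_sample_uses_normal_approximation(self, rng):
        from scipy import stats as sps

        x = rng.normal(0, 1, 40)
        y = rng.normal(0.5, 1, 40)
        res = mann_whitney_rrb(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert res.p_value == pytest.approx(ref.pvalue, rel=0.05)

    def test_descriptives_report_median_iqr(self):
        res = mann_whitney_rrb([1, 2, 3, 4, 100], [5, 6])
        assert res.descriptives["x"]["median"] == 3
        assert res.n == (5, 2)


class TestSpearman:
    def test_monotone_extremes(self):
        assert spearman_perm([1, 2, 3, 4], [10, 20, 30, 40], 200, 0).statistic == 1.0
        assert spearman_perm([1, 2, 3, 4], [8, 6, 4, 2], 200, 0).statistic == -1.0

    def test_sampled_p_matches_exhaustive_enumeration(self):
        from scipy import stats as sps

        x = [1.0, 2.0, 3.0, 4.0]
        y = [2.0, 1.0, 4.0, 3.0]
        obs = abs(sps.spearmanr(x, y).statistic)
        hits = sum(
            1
            for perm in itertools.permutations(y)
            if abs(sps.spearmanr(x, perm).statistic) >= obs - 1e-12
        )
        exact = hits / math.factorial(4)
        res = spearman_perm(x, y, n_perm=4999, seed=1)
        assert res.p_value == pytest.approx(exact, abs=0.03)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman_perm([1, 1, 1], [1, 2, 3], 100, 0)


class TestShapiro:
    def test_normal_samples_rarely_rejected(self):
        ps = []
        for seed in range(20):
            x = np.random.default_rng(seed).normal(size=100)
            ps.append(shapiro_wilk(x).p_value)
        assert np.mean(np.array(ps) > 0.01) >= 0.9

    def test_bimodal_rejected(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(-4, 0.3, 60), rng.normal(4, 0.3, 60)])
        assert shapiro_wilk(x).p_value < 0.01

    def test_constant_and_bad_sizes_rejected(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 2.0])


class TestBH:
    def test_hand_applied_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_matches_independent_stepup(self, rng):
        for _ in range(20):
            p = rng.random(int(rng.integers(1, 15)))
            np.testing.assert_allclose(bh_fdr(p), brute_bh(p), atol=1e-12)

    def test_permutation_equivariance_and_bounds(self, rng):
        p = rng.random(10)
        adj = bh_fdr(p)
        assert np.all(adj >= p) and np.all(adj <= 1)
        perm = rng.permutation(10)
        np.testing.assert_allclose(bh_fdr(p[perm]), adj[perm])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestKaplanMeier:
    def test_product_limit_by_hand(self):
        km = km_logrank([1, 2, 1, 2], [1, 1, 0, 1], ["a", "a", "b", "b"])
        curve_a = km["curves"]["a"].set_index("time")["survival"]
        assert curve_a.loc[1] == pytest.approx(0.5)
        assert curve_a.loc[2] == pytest.approx(0.0)

    def test_identical_groups_null(self):
        times = [3, 5, 8, 3, 5, 8]
        events = [1, 0, 1, 1, 0, 1]
        km = km_logrank(times, events, ["a"] * 3 + ["b"] * 3)
        assert km["chi2"] == pytest.approx(0.0, abs=1e-9)
        assert km["p_value"] == pytest.approx(1.0, abs=1e-6)

    def test_censored_only_group_flat_at_one(self):
        km = km_logrank([2, 4, 3, 6], [0, 0, 1, 1], ["a", "a", "b", "b"])
        assert (km["curves"]["a"]["survival"] == 1.0).all()

    def test_no_censoring_equals_empirical_survival(self, rng):
        times = rng.integers(1, 20, 15).astype(float)
        events = np.ones(15, dtype=int)
        km = km_logrank(
            np.concatenate([times, [50.0]]),
            np.concatenate([events, [1]]),
            ["a"] * 15 + ["b"],
        )
        curve = km["curves"]["a"].set_index("time")["survival"]
        for t in np.unique(times):
            assert curve.loc[t] == pytest.approx((times > t).mean())

    def test_brute_force_product_limit(self, rng):
        times = rng.integers(1, 10, 12).astype(float)
        events = rng.integers(0, 2, 12)
        if events.sum() == 0:
            events[0] = 1
        km = km_logrank(
            np.concatenate([times, [3.0, 4.0]]),
            np.concatenate([events, [1, 0]]),
            ["a"] * 12 + ["b"] * 2,
        )
        oracle = brute_km(times.tolist(), events.tolist())
        curve = km["curves"]["a"].set_index("time")["survival"]
        for t, s in oracle.items():
            assert curve.loc[t] == pytest.approx(s)


class TestConcordance:
    def test_perfect_anti_ordering(self):
        assert concordance_index([4, 3, 2, 1], [1, 2, 3, 4], [1, 1, 1, 1]) == 1.0

    def test_constant_scores_half(self):
        assert concordance_index([1, 1, 1], [1, 2, 3], [1, 1, 1]) == 0.5

    def test_matches_pairwise_oracle_with_censoring(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 20))
            scores = rng.integers(0, 6, n) / 6.0
            times = rng.integers(1, 10, n).astype(float)
            events = rng.integers(0, 2, n)
            if events.sum() == 0:
                events[0] = 1
            assert concordance_index(scores, times, events) == pytest.approx(
                brute_cindex(scores, times, events)
            )

    def test_equals_auroc_when_all_events_and_times_anti_monotone(self, rng):
        scores = rng.random(20)
        labels = rng.integers(0, 2, 20)
        if len(np.unique(labels)) < 2:
            labels[:2] = [0, 1]
        # times: strictly decreasing transform of score -> C equals
        # concordance of score with -time = 1 exactly; AUROC analogy:
        times = 10 - np.argsort(np.argsort(scores)).astype(float)
        assert concordance_index(scores, times, np.ones(20, int)) == 1.0


class TestCox:
    def _simulate(self, rng, n, log_hr):
        x = rng.integers(0, 2, n)
        t = rng.exponential(1.0 / (0.02 * np.exp(log_hr * x)))
        c = rng.exponential(80.0, n)
        times = np.minimum(t, c)
        events = (t <= c).astype(int)
        return pd.DataFrame({"time": times, "event": events, "x": x})

    def test_recovers_known_log_hazard_ratio(self):
        df = self._simulate(np.random.default_rng(3), 500, 0.7)
        out = cox_multivariate(df, "time", "event", ["x"])
        assert out.loc["x", "log_hr"] == pytest.approx(0.7, abs=0.15)

    def test_null_covariate_ci_covers_one(self):
        hits = 0
        for seed in range(50):
            df = self._simulate(np.random.default_rng(seed), 120, 0.0)
            out = cox_multivariate(df, "time", "event", ["x"])
            if out.loc["x", "hr_ci_low"] <= 1.0 <= out.loc["x", "hr_ci_high"]:
                hits += 1
        assert hits >= 45

    def test_matches_partial_likelihood_grid_search(self):
        # 5 records, distinct times, single binary covariate
        df = pd.DataFrame(
            {"time": [1.0, 2.0, 3.0, 4.0, 5.0], "event": [1, 1, 1, 1, 0],
             "x": [1.0, 0.0, 1.0, 0.0, 1.0]}
        )
        out = cox_multivariate(df, "time", "event", ["x"])

        def neg_pl(beta):
            order = np.argsort(df["time"].to_numpy())
            t, e, x = (df[c].to_numpy()[order] for c in ("time", "event", "x"))
            ll = 0.0
            for i in range(len(t)):
                if e[i]:
                    risk = x[i:]  # all with time >= t[i]
                    ll += beta * x[i] - np.log(np.exp(beta * risk).sum())
            return -ll

        grid = np.arange(-4, 4, 0.001)
        best = grid[np.argmin([neg_pl(b) for b in grid])]
        assert out.loc["x", "log_hr"] == pytest.approx(best, abs=0.01)

    def test_constant_covariate_rejected(self):
        df = pd.DataFrame({"time": [1.0, 2, 3], "event": [1, 1, 0], "x": [1.0, 1, 1]})
        with pytest.raises(ValueError):
            cox_multivariate(df, "time", "event", ["x"])


class TestConservativeP:
    @pytest.mark.parametrize(
        "ps,expected", [([0.01, 0.02, 0.03], 0.04), ([0.9], 1.0), ([0.2, 0.2, 0.2], 0.4)]
    )
    def test_two_times_median_clamped(self, ps, expected):
        assert conservative_p(ps) == pytest.approx(expected)


class TestCensorHorizon:
    def test_clips_times_and_drops_late_events(self):
        t, e = apply_censor_horizon([50.0, 100.0, 120.0], [1, 1, 0], 96.0)
        np.testing.assert_allclose(t, [50, 96, 96])
        np.testing.assert_array_equal(e, [1, 0, 0])


from hypothesis import given, settings
from hypothesis import strategies as st


class TestProperties:
    """Derandomized property tests for the scale-free invariants."""

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bh_bounds_and_monotone_in_raw(self, p):
        adj = bh_fdr(p)
        assert np.all(adj >= np.asarray(p) - 1e-15)
        assert np.all(adj <= 1.0)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=15))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_conservative_p_bounds(self, ps):
        v = conservative_p(ps)
        assert 0 <= v <= 1
        assert v >= min(1.0, np.median(ps))

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12),
           st.integers(0, 11), st.floats(0, 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_slide_aggregation_monotone(self, scores, idx, bump):
        from odyn.scoring import aggregate_slide

        base = aggregate_slide(scores).odyn_score
        raised = list(scores)
        i = idx % len(raised)
        raised[i] = min(1.0, raised[i] + bump)
        assert aggregate_slide(raised).odyn_score >= base - 1e-12


class TestTopTileAnalysis:
    def test_area_ratios_partition_patch(self, rng):
        ep = (rng.random((32, 32)) < 0.6).astype(np.uint8)
        dy = (ep & (rng.random((32, 32)) < 0.5)).astype(np.uint8)
        r = patch_area_ratios(ep, dy)
        assert sum(r.values()) == pytest.approx(1.0, abs=1e-9)

    def test_known_direction_detected(self, rng):
        tp = pd.DataFrame({"PEL": rng.poisson(18, 60), "IEL": rng.poisson(5, 60)})
        tn = pd.DataFrame({"PEL": rng.poisson(8, 60), "IEL": rng.poisson(5, 60)})
        out = top_tile_feature_analysis(tp, tn).set_index("measure")
        assert out.loc["PEL", "p_adjusted"] < 0.01
        assert out.loc["PEL", "r_rb"] > 0  # TPs have more PELs
        assert out.loc["IEL", "p_adjusted"] > 0.05

    def test_empty_side_rejected(self):
        with pytest.raises(ValueError):
            top_tile_feature_analysis(pd.DataFrame({"a": []}), pd.DataFrame({"a": [1.0]}))
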