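"""Oracle validation of the survival estimators.

Each wrapped estimator is checked against an independently coded
brute-force implementation (closed-form products, O(n^2) pair counts,
Newton on the explicit partial likelihood) on small random instances.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from pris.survival import (cox_fit, harrell_cindex, interaction_test,
                           km_estimate, logrank_scan, logrank_test,
                           point_biserial, td_auc)


def brute_force_km(times, events):
    """Product over risk sets at each distinct event time."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    ev = np.sort(np.unique(times[events == 1]))
    s, out = 1.0, []
    for t in ev:
        d = np.sum((times == t) & (events == 1))
        n = np.sum(times >= t)
        s *= 1.0 - d / n
        out.append(s)
    return ev, np.array(out)


def brute_force_cindex(scores, times, events):
    """O(n^2) concordant / comparable pair count with 0.5 for score ties."""
    n = len(times)
    num = den = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            # i is comparable to j if i's event precedes j's observed time;
            # an event tied with a censoring time precedes it
            if events[i] == 1 and (times[i] < times[j]
                                   or (times[i] == times[j] and events[j] == 0)):
                den += 1
                if scores[i] > scores[j]:
                    num += 1
                elif scores[i] == scores[j]:
                    num += 0.5
    return num / den


def brute_force_cox_binary(x, times, events, iters=50):
    """Newton solve of the explicit no-ties partial likelihood for one
    binary covariate."""
    order = np.argsort(times)
    x, times, events = x[order], times[order], events[order]
    beta = 0.0
    n = len(x)
    for _ in range(iters):
        U = H = 0.0
        for i in range(n):
            if not events[i]:
                continue
            risk = np.arange(i, n)
            w = np.exp(beta * x[risk])
            xb = np.sum(w * x[risk]) / np.sum(w)
            x2 = np.sum(w * x[risk] ** 2) / np.sum(w)
            U += x[i] - xb
            H += x2 - xb ** 2
        if H <= 0:
            break
        beta += U / H
    return beta


class TestKaplanMeier:
    def test_closed_form_three_events(self):
        km = km_estimate([1, 2, 3], [1, 1, 1])
        np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3, 0.0])

    def test_all_censored_curve_is_one(self):
        km = km_estimate([1, 2, 3], [0, 0, 0])
        assert km.at(2.5) == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_product(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 30)
        t = rng.exponential(5, n).round(1)  # induce ties
        e = rng.integers(0, 2, n)
        if e.sum() == 0:
            e[0] = 1
        km = km_estimate(t, e)
        ev, s = brute_force_km(t, e)
        np.testing.assert_allclose(km.survival, s)
        np.testing.assert_allclose(km.times, ev)


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = np.array([1.0, 2, 3, 4])
        e = np.array([1, 1, 0, 1])
        stat, p = logrank_test(t, e, t, e)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_group_relabeling_invariance(self, rng):
        ta, tb = rng.exponential(5, 30), rng.exponential(3, 25)
        ea, eb = np.ones(30, int), np.ones(25, int)
        s1, _ = logrank_test(ta, ea, tb, eb)
        s2, _ = logrank_test(tb, eb, ta, ea)
        assert s1 == pytest.approx(s2)

    def test_power_at_hazard_ratio_3(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            ta = rng.exponential(1.0, 200)
            tb = rng.exponential(3.0, 200)
            _, p = logrank_test(ta, np.ones(200), tb, np.ones(200))
            hits += p < 0.05
        assert hits >= 48  # >= 95% power

    def test_null_p_uniform(self):
        ps = []
        for seed in range(300):
            rng = np.random.default_rng(seed)
            t = rng.exponential(2.0, 60)
            e = rng.integers(0, 2, 60)
            e[:2] = 1
            _, p = logrank_test(t[:30], e[:30], t[30:], e[30:])
            ps.append(p)
        assert sstats.kstest(ps, "uniform").pvalue > 0.01

    def test_scan_agrees_with_per_split_tests(self, rng):
        sc = rng.normal(size=50)
        t = rng.exponential(5, 50)
        e = rng.integers(0, 2, 50)
        e[:5] = 1
        cuts = np.unique(sc)[8:-8]
        ps = logrank_scan(sc, t, e, cuts)
        for c, p in zip(cuts, ps):
            hi = sc > c
            _, p_ref = logrank_test(t[hi], e[hi], t[~hi], e[~hi])
            assert p == pytest.approx(p_ref, abs=1e-10)


class TestCox:
    @pytest.mark.parametrize("seed", range(5))
    def test_binary_covariate_matches_newton_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 20
        x = rng.integers(0, 2, n).astype(float)
        if x.sum() in (0, n):
            x[0] = 1 - x[0]
        t = rng.exponential(1.0 / np.exp(0.5 * x))  # continuous: no ties
        e = np.ones(n, int)
        fit = cox_fit(pd.DataFrame({"x": x}), t, e)
        beta_ref = brute_force_cox_binary(x, t, e)
        assert fit.coef["x"] == pytest.approx(beta_ref, abs=1e-3)

    def test_log_hr_recovered_on_average(self):
        ests = []
        for seed in range(60):
            rng = np.random.default_rng(seed)
            x = rng.integers(0, 2, 500).astype(float)
            t = rng.exponential(1.0 / np.exp(0.7 * x))
            fit = cox_fit(pd.DataFrame({"x": x}), t, np.ones(500, int))
            ests.append(fit.coef["x"])
        assert np.mean(ests) == pytest.approx(0.7, abs=0.15)

    def test_ci_brackets_hr(self, rng):
        x = rng.normal(size=100)
        t = rng.exponential(1.0 / np.exp(0.3 * x))
        fit = cox_fit(pd.DataFrame({"x": x}), t, np.ones(100, int))
        assert fit.ci_low["x"] < fit.hr["x"] < fit.ci_high["x"]
        assert fit.hr["x"] > 0

    def test_constant_covariate_rejected(self, rng):
        with pytest.raises(ValueError):
            cox_fit(pd.DataFrame({"x": np.ones(20)}),
                    rng.exponential(1, 20), np.ones(20, int))


class TestHarrellC:
    def test_perfect_and_inverted_ranking(self):
        t = np.array([1.0, 2, 3, 4, 5])
        e = np.ones(5, int)
        assert harrell_cindex(-t, t, e) == 1.0
        assert harrell_cindex(t, t, e) == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 100
        s = rng.normal(size=n).round(1)  # induce score ties
        t = rng.exponential(5, n).round(1)
        e = rng.integers(0, 2, n)
        e[:3] = 1
        assert harrell_cindex(s, t, e) == pytest.approx(
            brute_force_cindex(s, t, e))

    def test_negation_symmetry(self, rng):
        s = rng.normal(size=60)
        t = rng.exponential(5, 60)
        e = rng.integers(0, 2, 60)
        e[:3] = 1
        assert harrell_cindex(s, t, e) == pytest.approx(
            1.0 - harrell_cindex(-s, t, e))


class TestTdAuc:
    def test_random_scores_near_half(self):
        aucs = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            t = rng.exponential(5, 300)
            aucs.append(td_auc(rng.normal(size=300), t, np.ones(300, int),
                               horizon=np.median(t)))
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.03)

    def test_auc_increases_with_effect_size(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=500)
        aucs = []
        for beta in (0.0, 0.5, 1.0, 2.0):
            t = rng.exponential(1.0 / np.exp(beta * x))
            aucs.append(td_auc(x, t, np.ones(500, int), horizon=np.median(t)))
        assert all(np.diff(aucs) > 0)

    def test_no_censoring_reduces_to_binary_auc(self, rng):
        n = 400
        x = rng.normal(size=n)
        t = rng.exponential(1.0 / np.exp(0.8 * x))
        h = np.median(t)
        auc = td_auc(x, t, np.ones(n, int), horizon=h)
        cases = x[t <= h]
        controls = x[t > h]
        u = sstats.mannwhitneyu(cases, controls).statistic
        binary_auc = u / (len(cases) * len(controls))
        assert auc == pytest.approx(binary_auc, abs=1e-10)

    def test_horizon_beyond_followup_rejected(self, rng):
        t = rng.exponential(5, 50)
        with pytest.raises(ValueError):
            td_auc(rng.normal(size=50), t, np.ones(50, int), horizon=t.max() + 1)


class TestInteraction:
    def test_arm_relabeling_flips_sign(self, rng):
        n = 200
        treat = rng.integers(0, 2, n)
        group = rng.integers(0, 2, n)
        t = rng.exponential(1.0 / np.exp(-0.8 * treat * group))
        e = np.ones(n, int)
        a = interaction_test(treat, group, t, e)
        b = interaction_test(1 - treat, group, t, e)
        assert a["interaction_p"] == pytest.approx(b["interaction_p"], rel=0.05)
        assert np.sign(a["interaction_coef"]) == -np.sign(b["interaction_coef"])

    def test_empty_cell_rejected(self, rng):
        treat = np.ones(50, int)
        group = rng.integers(0, 2, 50)
        with pytest.raises(ValueError, match="empty cell"):
            interaction_test(treat, group, rng.exponential(1, 50),
                             np.ones(50, int))


class TestPointBiserial:
    def test_indicator_feature_is_perfectly_correlated(self):
        f = np.array([0, 0, 0, 1, 1, 1], float)
        r, _ = point_biserial(f, f.astype(int))
        assert r == pytest.approx(1.0)

    def test_balanced_mirrored_values_give_zero(self):
        vals = np.array([1.0, 2, 3, 1, 2, 3])
        fac = np.array([0, 0, 0, 1, 1, 1])
        r, _ = point_biserial(vals, fac)
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_matches_pearson_formula_on_hand_example(self):
        vals = np.array([2.0, 4, 3, 7, 6, 8, 9, 5, 1, 10])
        fac = np.array([0, 0, 0, 1, 1, 1, 1, 0, 0, 1])
        r, _ = point_biserial(vals, fac)
        ref = np.corrcoef(vals, fac)[0, 1]
        assert r == pytest.approx(ref)

    def test_constant_values_rejected(self):
        with pytest.raises(ValueError):
            point_biserial(np.ones(6), [0, 0, 0, 1, 1, 1])
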