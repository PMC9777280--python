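"""Evaluation metrics against brute-force oracles and reference libraries."""

import numpy as np
import pytest
from scipy import stats

from trajsurv.evaluation import (
    TimeGrid,
    brier_score,
    calibration,
    censoring_km,
    harrell_cindex,
    km_estimate,
    logrank_test,
    stratify_high_risk,
    td_auc,
)
from trajsurv.simulate import generate_cohort, strong_signal_config


def brute_cindex(s, t, d):
    num = den = 0.0
    for i in range(len(t)):
        for j in range(len(t)):
            if t[i] < t[j] and d[i] == 1:
                den += 1
                if s[i] > s[j]:
                    num += 1
                elif s[i] == s[j]:
                    num += 0.5
    return num / den


def brute_ipcw_auc(s, t, d, h, G):
    cases = [(i, 1.0 / G.evaluate(t[i], side="left")[0])
             for i in range(len(t)) if t[i] <= h and d[i] == 1]
    controls = [(j, 1.0 / G.evaluate(h)[0]) for j in range(len(t)) if t[j] > h]
    num = den = 0.0
    for i, wi in cases:
        for j, wj in controls:
            den += wi * wj
            if s[i] > s[j]:
                num += wi * wj
            elif s[i] == s[j]:
                num += 0.5 * wi * wj
    return num / den


class TestHarrellCindex:
    def test_perfect_anti_monotone(self):
        t = np.array([1.0, 2, 3, 4])
        assert harrell_cindex(-t, t, np.ones(4, int)) == 1.0

    def test_all_ties_half(self):
        t = np.array([1.0, 2, 3, 4])
        assert harrell_cindex(np.zeros(4), t, np.ones(4, int)) == 0.5

    def test_no_comparable_pairs_error(self):
        with pytest.raises(ValueError):
            harrell_cindex([1.0, 2.0], [5.0, 5.0], [1, 1])

    @pytest.mark.parametrize("trial", range(50))
    def test_matches_brute_force(self, trial):
        rng = np.random.default_rng(trial)
        n = 50
        s = rng.normal(size=n).round(1)  # rounding forces score ties
        t = rng.choice(np.arange(1.0, 20.0), size=n)
        d = rng.integers(0, 2, size=n)
        if not ((d == 1) & (t < t.max())).any():
            d[np.argmin(t)] = 1
        assert abs(harrell_cindex(s, t, d) - brute_cindex(s, t, d)) < 1e-12

    def test_score_negation_flips(self, rng):
        s = rng.normal(size=40)
        t = rng.permutation(np.arange(1.0, 41))
        d = rng.integers(0, 2, 40)
        d[0] = 1
        c1 = harrell_cindex(s, t, d)
        c2 = harrell_cindex(-s, t, d)
        assert abs(c1 - (1 - c2)) < 1e-12

    def test_shift_invariant(self, rng):
        s = rng.normal(size=30)
        t = rng.permutation(np.arange(1.0, 31))
        d = np.ones(30, int)
        assert harrell_cindex(s, t, d) == harrell_cindex(s + 7.3, t, d)


class TestKaplanMeier:
    def test_no_censoring_is_one_minus_ecdf(self, rng):
        t = rng.exponential(5, 200)
        km = km_estimate(t, np.ones(200, int))
        grid = np.quantile(t, [0.1, 0.5, 0.9])
        ecdf = np.array([(t <= g).mean() for g in grid])
        np.testing.assert_allclose(km.evaluate(grid), 1 - ecdf, atol=1e-12)

    def test_hand_computed_product_limit(self):
        km = km_estimate([1.0, 2.0, 3.0], [1, 0, 1])
        np.testing.assert_allclose(km.evaluate([1.0])[0], 2 / 3)
        np.testing.assert_allclose(km.evaluate([3.0])[0], 0.0)

    def test_all_censored_survival_one(self):
        km = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        np.testing.assert_array_equal(km.evaluate([0.5, 2.5, 10.0]), 1.0)

    def test_matches_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        t = rng.exponential(10, 150)
        d = rng.integers(0, 2, 150)
        d[0] = 1
        km = km_estimate(t, d)
        kmf = lifelines.KaplanMeierFitter().fit(t, d)
        grid = np.quantile(t, [0.2, 0.5, 0.8])
        theirs = kmf.survival_function_at_times(grid).to_numpy()
        np.testing.assert_allclose(km.evaluate(grid), theirs, atol=1e-10)


class TestLogrank:
    def test_identical_groups_null(self):
        t = np.array([1.0, 2, 3, 4])
        d = np.array([1, 0, 1, 1])
        stat, p = logrank_test(t, d, t, d)
        assert stat == 0.0 and p == 1.0

    def test_hand_oracle_small_instance(self):
        # direct observed-minus-expected / hypergeometric-variance formula
        ta, da = np.array([1.0, 3.0, 5.0]), np.array([1, 1, 0])
        tb, db = np.array([2.0, 4.0, 6.0]), np.array([1, 0, 1])
        t = np.concatenate([ta, tb]); d = np.concatenate([da, db])
        grp = np.array([0, 0, 0, 1, 1, 1])
        o_e = v = 0.0
        for u in sorted(t[d == 1]):
            at = t >= u
            nj, n1 = at.sum(), (at & (grp == 0)).sum()
            dj = ((t == u) & (d == 1)).sum()
            d1 = ((t == u) & (d == 1) & (grp == 0)).sum()
            o_e += d1 - dj * n1 / nj
            if nj > 1:
                v += dj * (n1 / nj) * (1 - n1 / nj) * (nj - dj) / (nj - 1)
        stat, p = logrank_test(ta, da, tb, db)
        assert abs(stat - o_e ** 2 / v) < 1e-10

    def test_matches_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        from lifelines.statistics import logrank_test as ll_logrank

        ta = rng.exponential(10, 80); da = rng.integers(0, 2, 80)
        tb = rng.exponential(5, 70); db = rng.integers(0, 2, 70)
        da[0] = db[0] = 1
        stat, p = logrank_test(ta, da, tb, db)
        res = ll_logrank(ta, tb, da, db)
        assert abs(stat - res.test_statistic) < 1e-8
        assert abs(p - res.p_value) < 1e-8

    def test_power_under_hazard_ratio(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            ta = rng.exponential(10, 250)
            tb = rng.exponential(10 / 3, 250)  # hazard ratio 3
            _, p = logrank_test(ta, np.ones(250, int), tb, np.ones(250, int))
            hits += p < 0.001
        assert hits >= 19

    def test_zero_events_error(self):
        with pytest.raises(ValueError):
            logrank_test([1.0], [0], [2.0], [0])


class TestTdAuc:
    def test_separable_scores_auc_one(self):
        t = np.arange(1.0, 21)
        d = np.ones(20, int)
        grid = TimeGrid(np.array([5.0, 10.0, 15.0]))
        auc = td_auc(-t, t, d, grid)
        np.testing.assert_allclose(auc, 1.0)

    def test_random_scores_near_half(self):
        aucs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            t = rng.exponential(10, 1000)
            d = np.ones(1000, int)
            s = rng.normal(size=1000)
            grid = TimeGrid(np.quantile(t, [0.25, 0.5, 0.75]))
            aucs.append(td_auc(s, t, d, grid))
        mean_auc = np.mean(aucs, axis=0)
        assert np.all(mean_auc >= 0.45) and np.all(mean_auc <= 0.55)

    @pytest.mark.parametrize("trial", range(25))
    def test_matches_brute_ipcw_oracle(self, trial):
        rng = np.random.default_rng(trial)
        n = 12
        t = rng.choice(np.arange(1.0, 15.0), size=n)
        d = rng.integers(0, 2, size=n)
        s = rng.normal(size=n)
        h = float(np.median(t))
        if not (((t <= h) & (d == 1)).any() and (t > h).any()):
            return
        G = censoring_km(t, d)
        if G.evaluate(h)[0] <= 0:
            return
        mine = td_auc(s, t, d, TimeGrid(np.array([h])), G)[0]
        oracle = brute_ipcw_auc(s, t, d, h, G)
        assert abs(mine - oracle) < 1e-10

    def test_no_censoring_equals_unweighted_pairs(self, rng):
        n = 100
        t = rng.exponential(10, n)
        d = np.ones(n, int)
        s = rng.normal(size=n)
        h = float(np.median(t))
        mine = td_auc(s, t, d, TimeGrid(np.array([h])))[0]
        cases = s[(t <= h)]
        controls = s[t > h]
        wins = (cases[:, None] > controls[None, :]).sum() \
            + 0.5 * (cases[:, None] == controls[None, :]).sum()
        assert abs(mine - wins / (len(cases) * len(controls))) < 1e-12

    def test_undefined_horizon_is_nan(self):
        t = np.array([5.0, 6.0, 7.0, 8.0])
        d = np.array([1, 1, 1, 1])
        auc = td_auc([1.0, 2, 3, 4], t, d, TimeGrid(np.array([1.0, 6.0, 20.0])))
        assert np.isnan(auc[0]) and not np.isnan(auc[1]) and np.isnan(auc[2])


class TestBrier:
    def test_perfect_predictions_zero(self):
        t = np.array([2.0, 4.0, 10.0, 12.0])
        d = np.ones(4, int)
        grid = TimeGrid(np.array([5.0]))
        S = np.array([[0.0], [0.0], [1.0], [1.0]])
        np.testing.assert_allclose(brier_score(S, t, d, grid), 0.0)

    def test_constant_half_quarter(self):
        t = np.array([2.0, 4.0, 10.0, 12.0])
        d = np.ones(4, int)
        S = np.full((4, 1), 0.5)
        np.testing.assert_allclose(
            brier_score(S, t, d, TimeGrid(np.array([5.0]))), 0.25)

    def test_no_censoring_equals_mse(self, rng):
        n = 60
        t = rng.exponential(10, n)
        d = np.ones(n, int)
        grid = TimeGrid(np.array([5.0, 12.0]))
        S = rng.uniform(size=(n, 2))
        mine = brier_score(S, t, d, grid)
        for k, h in enumerate(grid.horizons):
            mse = np.mean(((t > h).astype(float) - S[:, k]) ** 2)
            assert abs(mine[k] - mse) < 1e-12

    def test_km_prediction_not_beaten_by_permuted_scores(self, rng):
        cohort, _ = generate_cohort(strong_signal_config(400, seed=0))
        t, d = cohort.time, cohort.event
        km = km_estimate(t, d)
        h = float(np.quantile(t, 0.5))
        grid = TimeGrid(np.array([h]))
        S_km = np.full((len(t), 1), km.evaluate(h)[0])
        base = brier_score(S_km, t, d, grid)[0]
        perm = rng.permutation(len(t))
        S_perm = S_km[perm] * rng.uniform(0.5, 1.0, size=(len(t), 1))
        worse = brier_score(S_perm, t, d, grid)[0]
        assert worse >= base - 0.02


class TestCalibration:
    def test_deciles_partition(self, rng):
        n = 200
        S = rng.uniform(size=n)
        t = rng.exponential(20, n)
        d = rng.integers(0, 2, n)
        res = calibration(S, t, d, horizon=10.0)
        assert sum(g["n"] for g in res.groups) == n
        assert len(res.groups) == 10

    def test_too_few_patients_error(self):
        with pytest.raises(ValueError):
            calibration([0.5] * 5, [1.0] * 5, [1] * 5, horizon=1.0)


class TestStratifyHighRisk:
    def test_floor_count(self, rng):
        high, other = stratify_high_risk(rng.normal(size=10))
        assert len(high) == 2 and len(other) == 8

    def test_tie_break_by_id_deterministic(self):
        scores = np.zeros(10)
        ids = np.array([f"P{i}" for i in range(10)], dtype=object)
        high, other = stratify_high_risk(scores, patient_ids=ids)
        assert list(ids[high]) == ["P0", "P1"]

    def test_high_risk_group_is_riskiest(self, rng):
        s = rng.normal(size=50)
        high, other = stratify_high_risk(s)
        assert s[high].min() >= s[other].max()

    def test_strong_signal_separation(self):
        cohort, eta = generate_cohort(strong_signal_config(500, seed=1))
        high, other = stratify_high_risk(eta, patient_ids=cohort.patient_ids)
        f_high = cohort.event[high].mean()
        f_other = cohort.event[other].mean()
        assert f_high >= 2 * f_other
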