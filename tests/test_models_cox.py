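"""Partial likelihood, Breslow baseline and the penalized Cox fitter."""

import numpy as np
import pytest

from trajsurv.cohort import CovariateSpec
from trajsurv.models import (
    breslow_baseline,
    fit_cph,
    neg_log_partial_likelihood,
    partial_likelihood_value_and_grad,
    predict_survival,
)
from trajsurv.models.cph import cph_objective
from trajsurv.simulate import generate_cohort, single_covariate_config

from conftest import make_cohort


def brute_force_nlpl(eta, t, d):
    """Independent double-loop Breslow partial likelihood."""
    terms = []
    for i in range(len(t)):
        if d[i] == 1:
            risk = np.flatnonzero(t >= t[i])
            terms.append(np.log(np.exp(eta[risk]).sum()) - eta[i])
    return float(np.mean(terms))


def brute_force_breslow(eta, t, d):
    uniq = np.unique(t[d == 1])
    increments = []
    for u in uniq:
        d_t = int(((t == u) & (d == 1)).sum())
        risk = np.flatnonzero(t >= u)
        increments.append(d_t / np.exp(eta[risk]).sum())
    return uniq, np.cumsum(increments)


class TestPartialLikelihood:
    def test_single_event_patient_zero_loss(self):
        assert neg_log_partial_likelihood([1.7], [5.0], [1]) == 0.0

    def test_closed_form_three_distinct_events(self):
        loss = neg_log_partial_likelihood([0, 0, 0], [1, 2, 3], [1, 1, 1])
        expected = (np.log(3) + np.log(2) + np.log(1)) / 3
        assert abs(loss - expected) < 1e-12

    def test_zero_events_error(self):
        with pytest.raises(ValueError):
            neg_log_partial_likelihood([0.0, 1.0], [1, 2], [0, 0])

    @pytest.mark.parametrize("trial", range(100))
    def test_matches_brute_force_with_ties(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(2, 40))
        eta = rng.normal(size=n)
        t = rng.choice(np.arange(1.0, 8.0), size=n)  # forces ties
        d = rng.integers(0, 2, size=n)
        if d.sum() == 0:
            d[rng.integers(n)] = 1
        loss, _ = partial_likelihood_value_and_grad(eta, t, d)
        assert abs(loss - brute_force_nlpl(eta, t, d)) < 1e-10

    @pytest.mark.parametrize("trial", range(30))
    def test_gradient_matches_finite_differences(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(2, 20))
        eta = rng.normal(size=n)
        t = rng.choice(np.arange(1.0, 6.0), size=n)
        d = rng.integers(0, 2, size=n)
        if d.sum() == 0:
            d[0] = 1
        _, grad = partial_likelihood_value_and_grad(eta, t, d)
        h = 1e-6
        for k in range(n):
            up, dn = eta.copy(), eta.copy()
            up[k] += h
            dn[k] -= h
            fd = (brute_force_nlpl(up, t, d) - brute_force_nlpl(dn, t, d)) / (2 * h)
            assert abs(grad[k] - fd) < 1e-5 * max(1.0, abs(fd))


class TestBreslowBaseline:
    def test_zero_scores_equal_nelson_aalen(self, rng):
        n = 40
        t = rng.exponential(10, n)
        d = rng.integers(0, 2, n)
        d[0] = 1
        bh = breslow_baseline(np.zeros(n), t, d)
        # Nelson-Aalen: sum d_t / n_at_risk
        uniq = np.unique(t[d == 1])
        na = np.cumsum([((t == u) & (d == 1)).sum() / (t >= u).sum() for u in uniq])
        np.testing.assert_allclose(bh.cumulative_hazard, na, atol=1e-12)

    def test_constant_shift_rescales_hazard(self, rng):
        n = 30
        t = rng.exponential(10, n)
        d = np.ones(n, int)
        eta = rng.normal(size=n)
        b0 = breslow_baseline(eta, t, d)
        b1 = breslow_baseline(eta + 2.0, t, d)
        np.testing.assert_allclose(b1.cumulative_hazard,
                                   b0.cumulative_hazard * np.exp(-2.0), rtol=1e-10)

    @pytest.mark.parametrize("trial", range(100))
    def test_matches_brute_force(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(2, 50))
        eta = rng.normal(size=n)
        t = rng.choice(np.arange(1.0, 10.0), size=n)
        d = rng.integers(0, 2, size=n)
        if d.sum() == 0:
            d[0] = 1
        bh = breslow_baseline(eta, t, d)
        uniq, cum = brute_force_breslow(eta, t, d)
        np.testing.assert_array_equal(bh.event_times, uniq)
        np.testing.assert_allclose(bh.cumulative_hazard, cum, atol=1e-10)


class TestPredictSurvival:
    def test_before_first_event_survival_one(self, rng):
        bh = breslow_baseline(rng.normal(size=20), np.arange(1, 21.0),
                              np.ones(20, int))
        s = predict_survival([0.3], bh, [0.0, 0.5])
        np.testing.assert_allclose(s, 1.0)

    def test_very_negative_score_survives(self, rng):
        bh = breslow_baseline(rng.normal(size=20), np.arange(1, 21.0),
                              np.ones(20, int))
        s = predict_survival([-40.0], bh, [5, 10, 20])
        np.testing.assert_allclose(s, 1.0, atol=1e-12)

    def test_monotone_in_time_and_score(self, rng):
        for _ in range(20):
            n = 30
            t = rng.exponential(10, n)
            d = rng.integers(0, 2, n)
            d[0] = 1
            eta = rng.normal(size=n)
            bh = breslow_baseline(eta, t, d)
            grid = np.linspace(0, t.max(), 25)
            S = predict_survival(eta, bh, grid)
            assert np.all(S >= 0) and np.all(S <= 1)
            assert np.all(np.diff(S, axis=1) <= 1e-12)
            order = np.argsort(eta)
            assert np.all(np.diff(S[order], axis=0) <= 1e-12)


class TestCoxFitter:
    def test_recovers_log_hazard_ratio(self):
        cohort, _ = generate_cohort(single_covariate_config(2000, seed=0, beta=0.7))
        model = fit_cph(cohort, l2_penalty=0.0)
        assert abs(model.beta_[0] - 0.7) < 0.1

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        import pandas as pd

        cohort, _ = generate_cohort(single_covariate_config(500, seed=2, beta=0.5))
        model = fit_cph(cohort, l2_penalty=0.0)
        df = pd.DataFrame({"x": cohort.values[:, 0], "T": cohort.time,
                           "E": cohort.event})
        ll = lifelines.CoxPHFitter().fit(df, "T", "E")
        assert abs(model.beta_[0] - ll.params_["x"]) < 1e-4
        assert abs(model.summary()["x"]["p"] - ll.summary.loc["x", "p"]) < 1e-3

    def test_ridge_shrinkage_monotone(self):
        cohort, _ = generate_cohort(single_covariate_config(300, seed=3, beta=0.8))
        norms = []
        for pen in (0.0, 1.0, 10.0, 100.0, 1e4):
            m = fit_cph(cohort, l2_penalty=pen)
            norms.append(abs(m.beta_[0]))
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))
        assert norms[-1] < 0.05  # ridge limit: beta -> 0

    def test_gradient_zero_at_optimum(self):
        cohort, _ = generate_cohort(single_covariate_config(300, seed=4, beta=0.4))
        m = fit_cph(cohort, l2_penalty=0.05, tol=1e-8)
        _, grad, _ = cph_objective(cohort.values, cohort.time, cohort.event,
                                   m.beta_, 0.05)
        assert np.linalg.norm(grad) < 1e-8

    @pytest.mark.parametrize("ties", ["breslow", "efron"])
    def test_objective_gradient_matches_finite_differences(self, ties):
        rng = np.random.default_rng(9)
        for _ in range(10):
            n, p = int(rng.integers(5, 20)), int(rng.integers(1, 4))
            X = rng.normal(size=(n, p))
            t = rng.choice(np.arange(1.0, 6.0), size=n)
            d = rng.integers(0, 2, size=n)
            if d.sum() == 0:
                d[0] = 1
            beta = rng.normal(size=p) * 0.5
            val, grad, _ = cph_objective(X, t, d, beta, 0.3, ties=ties)
            h = 1e-6
            for k in range(p):
                up, dn = beta.copy(), beta.copy()
                up[k] += h
                dn[k] -= h
                fd = (cph_objective(X, t, d, up, 0.3, ties=ties)[0]
                      - cph_objective(X, t, d, dn, 0.3, ties=ties)[0]) / (2 * h)
                assert abs(grad[k] - fd) < 1e-5 * max(1.0, abs(fd))

    def test_efron_equals_breslow_without_ties(self, rng):
        n, p = 40, 2
        X = rng.normal(size=(n, p))
        t = rng.permutation(np.arange(1.0, n + 1))  # distinct times
        d = rng.integers(0, 2, size=n)
        d[:2] = 1
        beta = rng.normal(size=p)
        vb = cph_objective(X, t, d, beta, 0.0, ties="breslow")
        ve = cph_objective(X, t, d, beta, 0.0, ties="efron")
        assert abs(vb[0] - ve[0]) < 1e-10
        np.testing.assert_allclose(vb[1], ve[1], atol=1e-10)

    def test_requires_expanded_cohort(self):
        c = make_cohort([[1, 2, 3], [2, 1, 0]], [1, 2], [1, 1],
                        specs=[CovariateSpec("a"),
                               CovariateSpec("z", "continuous", "time_varying")])
        with pytest.raises(ValueError, match="expand"):
            fit_cph(c)
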