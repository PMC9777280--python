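"""Predictor screening: missingness, imputation, scaling, screens."""

import numpy as np
import pytest

from trajsurv.cohort import CovariateSpec
from trajsurv.selection import (
    collinearity_filter,
    filter_missingness,
    lasso_cox_screen,
    select_candidates,
    simple_impute,
    univariate_cph_screen,
    zscore_standardize,
)
from trajsurv.simulate import (
    GeneratorConfig,
    InvariantCovariate,
    generate_cohort,
    inject_missingness,
    null_config,
    single_covariate_config,
    trajectory_signal_config,
)

from conftest import make_cohort


def cohort_with_missing(n_missing, n=100):
    mask = np.zeros((n, 2), bool)
    mask[:n_missing, 0] = True
    rng = np.random.default_rng(0)
    return make_cohort(rng.normal(size=(n, 2)), rng.exponential(10, n),
                       rng.integers(0, 2, n), mask=mask)


class TestFilterMissingness:
    def test_over_threshold_dropped(self):
        out, dropped = filter_missingness(cohort_with_missing(21))
        assert "x1" in dropped and out.covariate_names == ["x2"]

    def test_exact_threshold_kept(self):
        out, dropped = filter_missingness(cohort_with_missing(20))
        assert dropped == {} and out.covariate_names == ["x1", "x2"]

    def test_no_missing_identity(self):
        out, dropped = filter_missingness(cohort_with_missing(0))
        assert dropped == {}

    def test_time_varying_dropped_if_either_slot_exceeds(self):
        specs = [CovariateSpec("z", "continuous", "time_varying")]
        mask = np.zeros((10, 2), bool)
        mask[:3, 1] = True  # discharge slot 30% missing
        c = make_cohort(np.ones((10, 2)), np.ones(10), np.ones(10, int),
                        specs=specs, mask=mask)
        _, dropped = filter_missingness(c)
        assert "z" in dropped


class TestSimpleImpute:
    def test_continuous_mean_fill(self):
        c = cohort_with_missing(0, n=3)
        c.mask[2, 0] = True
        c.values[:2, 0] = [1.0, 2.0]
        out, vals = simple_impute(c)
        assert vals["x1"] == 1.5
        assert out.values[2, 0] == 1.5
        assert not out.mask.any()

    def test_binary_mode_fill_ties_to_zero(self):
        specs = [CovariateSpec("b", "binary")]
        mask = np.array([[False], [False], [False], [False], [True]])
        c = make_cohort([[0], [0], [1], [1], [0]], np.arange(1.0, 6), [1] * 5,
                        specs=specs, mask=mask)
        _, vals = simple_impute(c)
        assert vals["b"] == 0.0

    def test_no_missing_returns_empty_map(self):
        c = cohort_with_missing(0)
        out, vals = simple_impute(c)
        assert vals == {}
        np.testing.assert_array_equal(out.values, c.values)

    def test_stored_values_reused_on_new_cohort(self):
        dev = cohort_with_missing(10)
        _, vals = simple_impute(dev)
        val = cohort_with_missing(5)
        out, _ = simple_impute(val, values=vals)
        assert np.all(out.values[:5, 0] == vals["x1"])


class TestZscore:
    def test_standardizes_to_unit_scale(self):
        c = make_cohort([[1.0], [2.0], [3.0]], [1, 2, 3], [1, 1, 1])
        out, params = zscore_standardize(c)
        assert abs(out.values[:, 0].mean()) < 1e-12
        assert abs(out.values[:, 0].std() - 1) < 1e-12

    def test_dev_params_applied_to_identical_data_match(self):
        c = make_cohort([[1.0], [2.0], [3.0]], [1, 2, 3], [1, 1, 1])
        a, params = zscore_standardize(c)
        b, _ = zscore_standardize(c, params=params)
        np.testing.assert_array_equal(a.values, b.values)

    def test_constant_column_error(self):
        c = make_cohort([[5.0], [5.0]], [1, 2], [1, 1])
        with pytest.raises(ValueError, match="constant"):
            zscore_standardize(c)

    def test_binary_untouched(self):
        c = make_cohort([[0.0], [1.0], [1.0]], [1, 2, 3], [1, 1, 1],
                        specs=[CovariateSpec("b", "binary")])
        out, params = zscore_standardize(c)
        np.testing.assert_array_equal(out.values, c.values)
        assert params == {}

    def test_time_varying_slots_pooled(self):
        specs = [CovariateSpec("z", "continuous", "time_varying")]
        c = make_cohort([[0.0, 2.0], [4.0, 6.0]], [1, 2], [1, 1], specs=specs)
        out, params = zscore_standardize(c)
        mean, sd = params["z"]
        assert mean == 3.0  # pooled over both slots
        # deltas scale by 1/sd but stay proportional
        d0 = out.values[0, 1] - out.values[0, 0]
        d1 = out.values[1, 1] - out.values[1, 0]
        assert abs(d0 - d1) < 1e-12


class TestUnivariateScreen:
    def test_strong_covariate_detected(self):
        cohort, _ = generate_cohort(single_covariate_config(500, seed=1, beta=0.7))
        results, sig = univariate_cph_screen(cohort)
        assert "x" in sig
        assert results["x"]["p"] < 1e-3

    def test_null_identity_hazard_ratio(self):
        # a coefficient estimated at ~0 gives HR ~1 with a CI symmetric on
        # the log scale
        cohort, _ = generate_cohort(single_covariate_config(800, seed=2, beta=0.0))
        results, _ = univariate_cph_screen(cohort)
        r = results["x"]
        log_lo = np.log(r["ci_lower"])
        log_hi = np.log(r["ci_upper"])
        center = np.log(r["hazard_ratio"])
        assert abs((center - log_lo) - (log_hi - center)) < 1e-9


class TestLassoScreen:
    def test_huge_penalty_empty_selection(self):
        cohort, _ = generate_cohort(trajectory_signal_config(300, seed=3))
        assert lasso_cox_screen(cohort, seed=0, penalty=1e6) == []

    def test_penalty_zero_matches_unpenalized_fit(self):
        cohort, _ = generate_cohort(trajectory_signal_config(300, seed=4))
        sel = lasso_cox_screen(cohort, seed=0, penalty=0.0)
        from trajsurv.cohort import expand_time_varying
        from trajsurv.models import fit_cph
        m = fit_cph(expand_time_varying(cohort), l2_penalty=0.0)
        expected = [c for c, b in zip(m.column_names, m.beta_) if abs(b) > 1e-8]
        assert sel == expected

    def test_strong_covariates_selected(self):
        hits = {f"s{i}": 0 for i in range(3)}
        for seed in range(5):
            cfg = GeneratorConfig(
                n_patients=1000, seed=seed,
                invariant=[InvariantCovariate(f"s{i}", beta=0.6) for i in range(3)]
                + [InvariantCovariate(f"n{i}", beta=0.0) for i in range(5)],
                baseline_shape=1.0, baseline_scale=30.0,
                admin_censor_time=60.0)
            cohort, _ = generate_cohort(cfg)
            sel = lasso_cox_screen(cohort, seed=seed)
            for name in hits:
                hits[name] += name in sel
        assert all(v >= 4 for v in hits.values())


class TestCollinearity:
    def test_duplicate_column_dropped(self, rng):
        x = rng.normal(size=50)
        c = make_cohort(np.column_stack([x, x]), rng.exponential(10, 50),
                        np.ones(50, int))
        kept, dropped = collinearity_filter(c)
        assert len(kept) == 1
        assert dropped[0][2] == pytest.approx(1.0)

    def test_independent_columns_untouched(self, rng):
        c = make_cohort(rng.normal(size=(1000, 4)), rng.exponential(10, 1000),
                        np.ones(1000, int))
        kept, dropped = collinearity_filter(c)
        assert dropped == [] and len(kept) == 4

    def test_mutually_correlated_triple_thinned(self, rng):
        base = rng.normal(size=500)
        cols = [base + rng.normal(scale=0.3, size=500) for _ in range(3)]
        c = make_cohort(np.column_stack(cols), rng.exponential(10, 500),
                        np.ones(500, int))
        kept, dropped = collinearity_filter(c)
        assert 1 <= len(kept) <= 2
        if len(kept) == 2:
            vals = {name: c.values[:, c.column_index(name)] for name in kept}
            r = np.corrcoef(*vals.values())[0, 1]
            assert abs(r) < 0.60

    def test_smaller_p_wins(self, rng):
        x = rng.normal(size=100)
        c = make_cohort(np.column_stack([x, x]), rng.exponential(10, 100),
                        np.ones(100, int))
        kept, dropped = collinearity_filter(c, p_values={"x1": 0.5, "x2": 0.01})
        assert "x2" in kept and dropped[0][1] == "x1"


class TestSelectCandidates:
    def test_dispositions_partition_input(self):
        cohort, _ = generate_cohort(trajectory_signal_config(400, seed=5))
        cohort = inject_missingness(cohort, 0.05, seed=6)
        candidates, report = select_candidates(cohort, seed=5)
        dis = report.dispositions()
        assert sorted(dis) == sorted(cohort.covariate_names)
        assert set(candidates) == {k for k, v in dis.items() if v == "candidate"}

    def test_strong_cohort_keeps_signal_covariates(self):
        cohort, _ = generate_cohort(trajectory_signal_config(800, seed=7))
        candidates, _ = select_candidates(cohort, seed=7)
        assert {"x1", "x2", "z1"} <= set(candidates)

    def test_validation_reuses_dev_parameters_exactly(self):
        dev, _ = generate_cohort(trajectory_signal_config(400, seed=8))
        dev = inject_missingness(dev, 0.1, seed=8)
        _, report = select_candidates(dev, seed=8)
        assert report.imputation_values  # learned on dev
        # applying stored z-params twice gives bit-identical output
        imputed, _ = simple_impute(dev.select_covariates(report.candidates))
        a, _ = zscore_standardize(imputed, params=report.zscore_params)
        b, _ = zscore_standardize(imputed, params=report.zscore_params)
        np.testing.assert_array_equal(a.values, b.values)

    def test_intersection_mode_is_subset_of_union(self):
        cohort, _ = generate_cohort(trajectory_signal_config(500, seed=9))
        u, _ = select_candidates(cohort, seed=9, combine="union")
        i, _ = select_candidates(cohort, seed=9, combine="intersection")
        assert set(i) <= set(u)
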