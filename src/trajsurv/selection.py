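"""Candidate-predictor identification.

The screening pipeline mirrors common clinical-prediction practice on
small cohorts: covariates missing in more than 20% of patients are
excluded; remaining gaps are filled by simple (mean/mode) imputation;
covariates associated with mortality are identified by univariate Cox
screening and L1-penalized (LASSO) Cox regression, combined by union;
collinear continuous columns (|Pearson r| >= 0.60) are thinned, keeping
the more prognostic member; finally continuous covariates are Z-score
standardized, with a time-varying covariate's two slots pooled so the
recurrent branch sees a common scale.

All fitted quantities (imputation fills, standardization parameters) are
learned on development data and must be reused verbatim on validation
data; the report carries them for exactly that purpose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import (
    BINARY,
    CONTINUOUS,
    TIME_VARYING,
    CohortTable,
    CovariateSpec,
    expand_time_varying,
)
from .folds import stratified_fold_assignment
from .models.cph import ConvergenceError, fit_cph
from .models.loss import neg_log_partial_likelihood

__all__ = [
    "SelectionReport",
    "filter_missingness",
    "simple_impute",
    "zscore_standardize",
    "univariate_cph_screen",
    "lasso_cox_screen",
    "collinearity_filter",
    "select_candidates",
]


def filter_missingness(cohort: CohortTable, threshold: float = 0.20
                       ) -> tuple[CohortTable, dict[str, float]]:
    """Drop covariates missing in strictly more than ``threshold`` of patients.

    For a time-varying covariate the fraction is assessed per slot and the
    whole covariate is dropped if either slot exceeds the threshold.
    Returns the filtered cohort and {name: worst missing fraction} for the
    dropped covariates.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    dropped: dict[str, float] = {}
    for s in cohort.specs:
        fracs = [cohort.mask[:, cohort.column_index(c)].mean() for c in s.columns]
        worst = max(fracs)
        if worst > threshold:
            dropped[s.name] = float(worst)
    return cohort.drop_covariates(dropped), dropped


def simple_impute(cohort: CohortTable,
                  values: dict[str, float] | None = None
                  ) -> tuple[CohortTable, dict[str, float]]:
    """Fill missing cells column-wise: observed mean (continuous) or mode
    (binary, ties to 0).

    Pass ``values`` (from a development-set run) to reuse fills verbatim on
    validation data.
    """
    out = cohort.copy()
    fitted: dict[str, float] = {}
    for s in out.specs:
        for col in s.columns:
            j = out.column_index(col)
            miss = out.mask[:, j]
            if values is not None:
                if miss.any():
                    if col not in values:
                        raise KeyError(f"no stored imputation value for {col!r}")
                    out.values[miss, j] = values[col]
                    out.mask[miss, j] = False
                continue
            if not miss.any():
                continue
            obs = out.values[~miss, j]
            if len(obs) == 0:
                raise ValueError(f"covariate column {col!r} is entirely missing; "
                                 "filter it before imputing")
            if s.kind == BINARY:
                ones = (obs == 1).sum()
                fill = 1.0 if ones > len(obs) - ones else 0.0
            else:
                fill = float(obs.mean())
            fitted[col] = fill
            out.values[miss, j] = fill
            out.mask[miss, j] = False
    return out, (values if values is not None else fitted)


def zscore_standardize(cohort: CohortTable,
                       params: dict[str, tuple[float, float]] | None = None
                       ) -> tuple[CohortTable, dict[str, tuple[float, float]]]:
    """Z-score continuous covariates; binary covariates pass through.

    A time-varying covariate uses one (mean, sd) pooled over its admission
    and discharge slots, preserving the scale of the admission-to-discharge
    change.  Returns the transformed cohort and the parameters, which must
    be reused on validation data.
    """
    if cohort.mask.any():
        raise ValueError("standardization requires a complete cohort; impute first")
    out = cohort.copy()
    fitted: dict[str, tuple[float, float]] = {}
    for s in out.specs:
        if s.kind != CONTINUOUS:
            continue
        cols = [out.column_index(c) for c in s.columns]
        if params is not None:
            if s.name not in params:
                raise KeyError(f"no standardization parameters for {s.name!r}")
            mean, sd = params[s.name]
        else:
            pooled = out.values[:, cols].ravel()
            mean, sd = float(pooled.mean()), float(pooled.std(ddof=0))
            if sd == 0.0:
                raise ValueError(f"covariate {s.name!r} is constant; cannot standardize")
            fitted[s.name] = (mean, sd)
        if sd == 0.0:
            raise ValueError(f"covariate {s.name!r} has zero stored sd")
        out.values[:, cols] = (out.values[:, cols] - mean) / sd
    return out, (params if params is not None else fitted)


def univariate_cph_screen(cohort: CohortTable, alpha: float = 0.05
                          ) -> tuple[dict[str, dict[str, float]], list[str]]:
    """One-covariate Cox fits per expanded column.

    Returns per-column Wald summaries (hazard ratio, 95% CI, p) and the
    list of columns with p < alpha.  Columns whose fit fails to converge
    are flagged and treated as non-significant.
    """
    if cohort.n_events < 2:
        raise ValueError("univariate screening requires at least two events")
    expanded = expand_time_varying(cohort)
    results: dict[str, dict[str, float]] = {}
    significant: list[str] = []
    for name in expanded.covariate_names:
        sub = expanded.select_covariates([name])
        try:
            model = fit_cph(sub, l2_penalty=0.0)
        except (ConvergenceError, np.linalg.LinAlgError):
            results[name] = {"hazard_ratio": float("nan"), "ci_lower": float("nan"),
                             "ci_upper": float("nan"), "p": float("nan"),
                             "converged": 0.0}
            continue
        row = model.summary()[name]
        results[name] = {"hazard_ratio": row["hazard_ratio"],
                         "ci_lower": row["ci_lower"], "ci_upper": row["ci_upper"],
                         "p": row["p"], "converged": 1.0}
        if row["p"] < alpha:
            significant.append(name)
    return results, significant


def lasso_cox_screen(cohort: CohortTable, n_folds: int = 10, seed: int = 0,
                     penalty: float | None = None) -> list[str]:
    """LASSO Cox screen over expanded columns.

    The L1 path is solved by the elastic-net Cox solver; the penalty is
    chosen by ``n_folds``-fold cross-validated partial likelihood (unless a
    fixed ``penalty`` is given).  Returns the columns with nonzero
    coefficients at the chosen penalty.  ``penalty=0`` reduces to thresholding
    an unpenalized Cox fit.
    """
    expanded = expand_time_varying(cohort)
    if expanded.n_events < 2:
        raise ValueError("LASSO screening requires at least two events")
    if penalty == 0.0:
        model = fit_cph(expanded, l2_penalty=0.0)
        return [c for c, b in zip(expanded.columns, model.beta_)
                if abs(b) > 1e-8]

    from sksurv.linear_model import CoxnetSurvivalAnalysis

    X = expanded.complete_values()
    # screen-internal standardization so one penalty acts evenly on columns
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    y = np.empty(len(X), dtype=[("event", bool), ("time", float)])
    y["event"] = expanded.event.astype(bool)
    y["time"] = expanded.time

    path = CoxnetSurvivalAnalysis(l1_ratio=1.0, alpha_min_ratio=0.01,
                                  n_alphas=30, fit_baseline_model=False)
    path.fit(Xs, y)
    alphas = path.alphas_

    if penalty is not None:
        best_alpha = float(penalty)
    else:
        folds = stratified_fold_assignment(expanded.event, n_folds, seed)
        cv_loss = np.zeros(len(alphas))
        counts = np.zeros(len(alphas))
        for f in range(n_folds):
            tr, te = folds != f, folds == f
            if expanded.event[te].sum() == 0 or expanded.event[tr].sum() < 2:
                continue
            m = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas,
                                       fit_baseline_model=False)
            m.fit(Xs[tr], y[tr])
            for a_i, alpha in enumerate(m.alphas_):
                k = int(np.flatnonzero(np.isclose(alphas, alpha))[0])
                coefs = m.coef_[:, a_i]
                scores = Xs[te] @ coefs
                cv_loss[k] += neg_log_partial_likelihood(
                    scores, expanded.time[te], expanded.event[te])
                counts[k] += 1
        valid = counts > 0
        if not valid.any():
            return []
        mean_loss = np.where(valid, cv_loss / np.maximum(counts, 1), np.inf)
        best_alpha = float(alphas[int(np.argmin(mean_loss))])

    a_idx = int(np.argmin(np.abs(np.asarray(path.alphas_) - best_alpha)))
    coefs = path.coef_[:, a_idx]
    return [c for c, b in zip(expanded.columns, coefs) if abs(b) > 1e-8]


def collinearity_filter(cohort: CohortTable, r_threshold: float = 0.60,
                        p_values: dict[str, float] | None = None
                        ) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Thin collinear continuous columns until no |Pearson r| >= threshold.

    Of an offending pair, the column with the larger univariate p-value is
    dropped (missing p counts as 1; exact ties break lexicographically).
    Returns the kept column names (all kinds) and the (kept, dropped, r)
    decisions.
    """
    expanded = expand_time_varying(cohort)
    cont = [s.name for s in expanded.specs if s.kind == CONTINUOUS]
    values = expanded.complete_values()
    alive = list(cont)
    dropped: list[tuple[str, str, float]] = []

    def pval(name: str) -> float:
        if p_values is None or name not in p_values:
            return 1.0
        p = p_values[name]
        return 1.0 if np.isnan(p) else p

    while len(alive) > 1:
        cols = [expanded.column_index(c) for c in alive]
        sub = values[:, cols]
        sd = sub.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(sub, rowvar=False)
        corr = np.nan_to_num(corr, nan=0.0)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        r = corr[i, j]
        if abs(r) < r_threshold:
            break
        a, b = alive[i], alive[j]
        pa, pb = pval(a), pval(b)
        if pa > pb or (pa == pb and a > b):
            keep, drop = b, a
        else:
            keep, drop = a, b
        dropped.append((keep, drop, float(abs(r))))
        alive.remove(drop)

    kept = [s.name for s in expanded.specs
            if s.kind != CONTINUOUS or s.name in alive]
    return kept, dropped


@dataclass
class SelectionReport:
    """Audit trail of the screening pipeline.

    Every input covariate lands in exactly one disposition:
    ``dropped_missingness``, ``dropped_screening`` (neither screen chose
    any of its columns), ``dropped_collinear`` (all its columns thinned),
    or ``candidates``.
    """

    input_covariates: list[str] = field(default_factory=list)
    dropped_missingness: dict[str, float] = field(default_factory=dict)
    imputation_values: dict[str, float] = field(default_factory=dict)
    univariate_results: dict[str, dict[str, float]] = field(default_factory=dict)
    univariate_significant: list[str] = field(default_factory=list)
    lasso_selected: list[str] = field(default_factory=list)
    screened_columns: list[str] = field(default_factory=list)
    dropped_screening: list[str] = field(default_factory=list)
    dropped_collinear: list[tuple[str, str, float]] = field(default_factory=list)
    zscore_params: dict[str, tuple[float, float]] = field(default_factory=dict)
    candidates: list[str] = field(default_factory=list)

    def dispositions(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for name in self.input_covariates:
            if name in self.dropped_missingness:
                out[name] = "dropped_missingness"
            elif name in self.dropped_screening:
                out[name] = "dropped_screening"
            elif name in self.candidates:
                out[name] = "candidate"
            else:
                out[name] = "dropped_collinear"
        return out


def _unit_of(column: str, cohort: CohortTable) -> str:
    """Map an expanded column name back to its covariate unit."""
    for s in cohort.specs:
        if column in s.columns or column == s.name:
            return s.name
    raise KeyError(column)


def select_candidates(cohort: CohortTable, seed: int = 0,
                      missing_threshold: float = 0.20, alpha: float = 0.05,
                      r_threshold: float = 0.60, n_folds: int = 10,
                      combine: str = "union"
                      ) -> tuple[list[str], SelectionReport]:
    """Full screening pipeline on a development cohort.

    Composition: missingness filter -> simple imputation -> univariate Cox
    and LASSO screens on expanded columns, combined by ``combine`` ("union"
    by default, "intersection" optional) -> collinearity thinning ->
    Z-score standardization parameters.  A time-varying covariate is a
    candidate when at least one of its slots survives; candidates are
    reported as covariate units in schema order so the recurrent model can
    consume them whole.
    """
    if combine not in ("union", "intersection"):
        raise ValueError("combine must be 'union' or 'intersection'")
    report = SelectionReport(input_covariates=list(cohort.covariate_names))

    filtered, report.dropped_missingness = filter_missingness(cohort, missing_threshold)
    imputed, report.imputation_values = simple_impute(filtered)

    report.univariate_results, uni_sig = univariate_cph_screen(imputed, alpha)
    report.univariate_significant = uni_sig
    report.lasso_selected = lasso_cox_screen(imputed, n_folds=n_folds, seed=seed)

    if combine == "union":
        chosen_cols = sorted(set(uni_sig) | set(report.lasso_selected))
    else:
        chosen_cols = sorted(set(uni_sig) & set(report.lasso_selected))

    chosen_units = {_unit_of(c, imputed) for c in chosen_cols}
    report.dropped_screening = [n for n in imputed.covariate_names
                                if n not in chosen_units]
    screened = imputed.select_covariates(chosen_units)

    pvals = {c: r["p"] for c, r in report.univariate_results.items()}
    kept_cols, report.dropped_collinear = collinearity_filter(
        screened, r_threshold, pvals)
    report.screened_columns = kept_cols
    kept_units = []
    for s in screened.specs:
        if any(c in kept_cols for c in s.columns):
            kept_units.append(s.name)
    final = screened.select_covariates(kept_units)

    _, report.zscore_params = zscore_standardize(final)
    report.candidates = final.covariate_names
    return report.candidates, report
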