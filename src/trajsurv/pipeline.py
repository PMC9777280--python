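"""Study orchestration: cross-validation, back-elimination, temporal validation.

The development protocol is: screen candidate predictors on the
development cohort, greedily back-eliminate predictors under 10-fold
event-stratified cross-validation (dropping whichever predictor's removal
most improves mean test C-index, until no removal helps), refit on all
development data, then evaluate once on the held-back temporal-validation
cohort.  Validation data never influences screening, imputation,
standardization, elimination or training; a checksum over all fitted state
taken before and after validation scoring guards this by construction.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .cohort import TIME_VARYING, CohortTable, expand_time_varying
from .evaluation import EvaluationReport, TimeGrid, evaluate_model
from .folds import stratified_fold_assignment
from .models import (
    CoxPHModel,
    NetworkConfig,
    TrainingConfig,
    fit_cph,
    fit_deepsurv,
    fit_rnnsurv,
)
from .selection import SelectionReport, select_candidates, simple_impute, zscore_standardize

__all__ = [
    "FoldSplit",
    "make_folds",
    "ModelRecipe",
    "FittedPipeline",
    "CVResult",
    "cross_validate",
    "EliminationTrace",
    "backward_eliminate",
    "StudyConfig",
    "StudyReport",
    "run_study",
]

MODEL_KINDS = ("rnnsurv", "deepsurv", "cph")


@dataclass(frozen=True)
class FoldSplit:
    """Per-patient fold assignment in [0, k)."""

    assignments: np.ndarray
    k: int
    seed: int

    def __post_init__(self):
        a = np.asarray(self.assignments, dtype=int)
        object.__setattr__(self, "assignments", a)
        sizes = np.bincount(a, minlength=self.k)
        if len(sizes) != self.k or sizes.max() - sizes.min() > 1:
            raise ValueError("folds must partition patients with sizes differing by <= 1")


def make_folds(cohort: CohortTable, k: int = 10, seed: int = 0) -> FoldSplit:
    """Event-stratified folds: per-fold event counts differ by at most 1."""
    return FoldSplit(stratified_fold_assignment(cohort.event, k, seed), k, seed)


# -- model recipes -----------------------------------------------------------

@dataclass
class ModelRecipe:
    """How to turn a (raw, possibly missing-valued) training cohort into a
    fitted risk model: simple imputation + Z-scoring learned on the
    training data, followed by one of the three model fits.  Static kinds
    ("cph", "deepsurv") expand time-varying covariates into independent
    columns; the recurrent kind consumes them as sequences.
    """

    kind: str
    l2_penalty: float = 0.05
    net: NetworkConfig = field(default_factory=NetworkConfig)
    train: TrainingConfig = field(default_factory=TrainingConfig)

    def __post_init__(self):
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")

    def fit(self, cohort: CohortTable, seed: int | None = None) -> "FittedPipeline":
        imputed, imp_values = simple_impute(cohort)
        standardized, z_params = zscore_standardize(imputed)
        if self.kind == "rnnsurv":
            model_input = standardized
        else:
            model_input = expand_time_varying(standardized)
        if self.kind == "cph":
            model = fit_cph(model_input, l2_penalty=self.l2_penalty)
        else:
            train_cfg = self.train if seed is None else \
                TrainingConfig(**{**self.train.__dict__, "seed": seed})
            if self.kind == "deepsurv":
                model = fit_deepsurv(model_input, self.net, train_cfg)
            else:
                model = fit_rnnsurv(model_input, self.net, train_cfg)
        return FittedPipeline(kind=self.kind, covariates=cohort.covariate_names,
                              imputation_values=imp_values,
                              zscore_params=z_params, model=model)


@dataclass
class FittedPipeline:
    """A fitted preprocessing + model stack, applicable to new cohorts."""

    kind: str
    covariates: list[str]
    imputation_values: dict[str, float]
    zscore_params: dict[str, tuple[float, float]]
    model: object

    def _prepare(self, cohort: CohortTable) -> CohortTable:
        sub = cohort.select_covariates(self.covariates)
        imputed, _ = simple_impute(sub, values=dict(self.imputation_values))
        if imputed.mask.any():
            # cells with no stored fill (never missing in training): fall back
            imputed, _ = simple_impute(imputed)
        standardized, _ = zscore_standardize(imputed, params=self.zscore_params)
        if self.kind == "rnnsurv":
            return standardized
        return expand_time_varying(standardized)

    def risk_score(self, cohort: CohortTable) -> np.ndarray:
        return self.model.risk_score(self._prepare(cohort))

    def survival_curve(self, cohort: CohortTable, time_grid) -> np.ndarray:
        return self.model.survival_curve(self._prepare(cohort), time_grid)

    def state_checksum(self) -> str:
        """SHA-256 over every piece of fitted state (leakage guard)."""
        h = hashlib.sha256()
        h.update(json.dumps(self.imputation_values, sort_keys=True).encode())
        h.update(json.dumps({k: list(v) for k, v in self.zscore_params.items()},
                            sort_keys=True).encode())
        m = self.model
        if isinstance(m, CoxPHModel):
            h.update(np.ascontiguousarray(m.beta_).tobytes())
        else:
            for p in m.net_.params():
                h.update(np.ascontiguousarray(p).tobytes())
            # batch-norm running statistics are fitted state too
            for layer_list in _bn_layers(m.net_):
                h.update(np.ascontiguousarray(layer_list.running_mean).tobytes())
                h.update(np.ascontiguousarray(layer_list.running_var).tobytes())
        if m.baseline_ is not None:
            h.update(np.ascontiguousarray(m.baseline_.event_times).tobytes())
            h.update(np.ascontiguousarray(m.baseline_.cumulative_hazard).tobytes())
        return h.hexdigest()


def _bn_layers(net):
    from .models.nn import BatchNorm, Sequential
    found = []

    def walk(obj):
        if isinstance(obj, BatchNorm):
            found.append(obj)
        elif isinstance(obj, Sequential):
            for l in obj.layers:
                walk(l)
        else:
            for attr in ("branch", "fc", "rnn", "head"):
                if hasattr(obj, attr):
                    walk(getattr(obj, attr))
    walk(net)
    return found


# -- cross-validation --------------------------------------------------------

@dataclass
class CVResult:
    per_fold: list[dict]
    skipped_folds: list[int]

    @property
    def test_c_indexes(self) -> np.ndarray:
        return np.array([f["test_c_index"] for f in self.per_fold])

    @property
    def train_c_indexes(self) -> np.ndarray:
        return np.array([f["train_c_index"] for f in self.per_fold])

    @property
    def mean_test(self) -> float:
        return float(self.test_c_indexes.mean())

    @property
    def sd_test(self) -> float:
        return float(self.test_c_indexes.std(ddof=1)) if len(self.per_fold) > 1 else 0.0

    @property
    def mean_train(self) -> float:
        return float(self.train_c_indexes.mean())


def cross_validate(cohort: CohortTable, recipe: ModelRecipe,
                   folds: FoldSplit) -> CVResult:
    """K-fold cross-validation of a recipe; per-fold train/test C-index.

    Preprocessing (imputation, standardization) is re-learned inside each
    training fold.  Folds whose held-out patients have no events cannot be
    scored and are skipped with a flag.
    """
    from .evaluation import harrell_cindex

    per_fold = []
    skipped = []
    for f in range(folds.k):
        te = folds.assignments == f
        tr = ~te
        if cohort.event[te].sum() == 0 or cohort.event[tr].sum() < 2:
            skipped.append(f)
            continue
        train_cohort = cohort.subset_rows(np.flatnonzero(tr))
        test_cohort = cohort.subset_rows(np.flatnonzero(te))
        fitted = recipe.fit(train_cohort, seed=recipe.train.seed + f)
        per_fold.append({
            "fold": f,
            "train_c_index": harrell_cindex(fitted.risk_score(train_cohort),
                                            train_cohort.time, train_cohort.event),
            "test_c_index": harrell_cindex(fitted.risk_score(test_cohort),
                                           test_cohort.time, test_cohort.event),
            "n_test": int(te.sum()),
            "n_test_events": int(cohort.event[te].sum()),
        })
    if not per_fold:
        raise ValueError("every fold was skipped; too few events")
    return CVResult(per_fold, skipped)


# -- backward elimination ----------------------------------------------------

@dataclass
class EliminationTrace:
    steps: list[tuple[str, float, float]]
    final_predictors: list[str]
    initial_c_index: float
    final_c_index: float


def backward_eliminate(cohort: CohortTable, recipe: ModelRecipe,
                       candidates: list[str], folds: FoldSplit,
                       parsimony_tol: float = 1e-3) -> EliminationTrace:
    """Greedy back-elimination on mean cross-validated test C-index.

    Each round re-evaluates removing every remaining predictor and deletes
    the one whose removal yields the best score; the loop stops when every
    removal would cost more than ``parsimony_tol`` in mean test C-index.
    Removals within the tolerance are treated as performance-neutral and
    accepted, preferring the smaller model — at 10-fold resolution a cost
    of well under one cross-validation standard error is indistinguishable
    from zero, and a strict improvement rule would keep uninformative
    predictors on such noise.  Set ``parsimony_tol=0`` for the strict rule.

    Predictor granularity follows the cohort view: pass an expanded cohort
    to eliminate per-slot columns, or a raw two-time-step cohort to
    eliminate time-varying covariates whole.
    """
    if len(candidates) < 2:
        raise ValueError("need at least two candidate predictors")
    remaining = list(candidates)
    current = cross_validate(cohort.select_covariates(remaining), recipe,
                             folds).mean_test
    initial = current
    steps: list[tuple[str, float, float]] = []
    while len(remaining) > 1:
        best_name, best_score = None, -np.inf
        for name in remaining:
            trial = [c for c in remaining if c != name]
            score = cross_validate(cohort.select_covariates(trial), recipe,
                                   folds).mean_test
            if score > best_score:
                best_name, best_score = name, score
        if best_score - current < -parsimony_tol:
            break
        steps.append((best_name, current, best_score))
        remaining.remove(best_name)
        current = best_score
    return EliminationTrace(steps, remaining, initial, current)


# -- full study --------------------------------------------------------------

@dataclass
class StudyConfig:
    seed: int = 0
    k_folds: int = 10
    models: tuple[str, ...] = MODEL_KINDS
    l2_penalty: float = 0.05
    net: NetworkConfig = field(default_factory=NetworkConfig)
    train: TrainingConfig = field(default_factory=TrainingConfig)
    back_elimination: bool = True
    dev_grid_cap: float = 48.0
    val_grid_cap: float = 24.0
    calibration_horizons: tuple[float, ...] = (12.0, 24.0)
    selection_alpha: float = 0.05
    missing_threshold: float = 0.20
    r_threshold: float = 0.60


@dataclass
class StudyReport:
    config: StudyConfig
    selection: SelectionReport
    candidates: list[str]
    models: dict[str, dict]

    def validation_c_indexes(self) -> dict[str, float]:
        return {k: v["validation"].c_index for k, v in self.models.items()}

    def to_dict(self) -> dict:
        return {
            "seed": self.config.seed,
            "candidates": self.candidates,
            "models": {
                k: {
                    "final_predictors": v["trace"].final_predictors,
                    "eliminated": [s[0] for s in v["trace"].steps],
                    "cv_mean_test_c_index": v["cv"].mean_test,
                    "cv_sd_test_c_index": v["cv"].sd_test,
                    "cv_mean_train_c_index": v["cv"].mean_train,
                    "development": v["development"].to_dict(),
                    "validation": v["validation"].to_dict(),
                    "leakage_checksum_ok": v["checksum_before"] == v["checksum_after"],
                }
                for k, v in self.models.items()
            },
        }


def _check_schema(dev: CohortTable, val: CohortTable) -> None:
    if dev.specs != val.specs:
        d, v = set(dev.covariate_names), set(val.covariate_names)
        diff = sorted(d.symmetric_difference(v)) or sorted(
            s.name for s in dev.specs if s not in val.specs)
        raise ValueError(f"development and validation schemas differ: {diff}")


def run_study(dev: CohortTable, val: CohortTable,
              config: StudyConfig | None = None) -> StudyReport:
    """Run the full development + temporal-validation protocol.

    Per model: candidate screening (shared) -> back-elimination under
    k-fold CV -> refit on all development data -> evaluation on both
    cohorts with a leakage checksum around validation scoring.
    """
    config = config or StudyConfig()
    _check_schema(dev, val)

    candidates, sel_report = select_candidates(
        dev, seed=config.seed, missing_threshold=config.missing_threshold,
        alpha=config.selection_alpha, r_threshold=config.r_threshold,
        n_folds=config.k_folds)
    if not candidates:
        raise ValueError("screening selected no candidate predictors")
    dev_c = dev.select_covariates(candidates)
    val_c = val.select_covariates(candidates)
    folds = make_folds(dev_c, config.k_folds, config.seed)

    results: dict[str, dict] = {}
    for kind in config.models:
        recipe = ModelRecipe(
            kind=kind, l2_penalty=config.l2_penalty, net=config.net,
            train=TrainingConfig(**{**config.train.__dict__, "seed": config.seed}))
        if kind == "rnnsurv":
            view_dev, view_val = dev_c, val_c
            names = view_dev.covariate_names
            if not any(s.timing == TIME_VARYING for s in view_dev.specs):
                raise ValueError("recurrent model requires time-varying candidates")
        else:
            view_dev, view_val = expand_time_varying(dev_c), expand_time_varying(val_c)
            names = view_dev.covariate_names

        if config.back_elimination and len(names) > 1:
            trace = backward_eliminate(view_dev, recipe, names, folds)
        else:
            trace = EliminationTrace([], list(names), float("nan"), float("nan"))

        final_dev = view_dev.select_covariates(trace.final_predictors)
        final_val = view_val.select_covariates(trace.final_predictors)
        cv = cross_validate(final_dev, recipe, folds)
        fitted = recipe.fit(final_dev)

        dev_report = evaluate_model(
            fitted, final_dev, TimeGrid.every_3_months(config.dev_grid_cap),
            config.calibration_horizons)
        checksum_before = fitted.state_checksum()
        val_report = evaluate_model(
            fitted, final_val, TimeGrid.every_3_months(config.val_grid_cap),
            config.calibration_horizons)
        checksum_after = fitted.state_checksum()

        results[kind] = {
            "trace": trace, "cv": cv, "fitted": fitted,
            "development": dev_report, "validation": val_report,
            "checksum_before": checksum_before,
            "checksum_after": checksum_after,
        }
    return StudyReport(config, sel_report, candidates, results)
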