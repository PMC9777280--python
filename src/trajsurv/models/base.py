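"""Common contract for the three risk models."""

from __future__ import annotations

import abc

import numpy as np

from ..cohort import CohortTable
from .baseline import BaselineHazard, breslow_baseline, predict_survival

__all__ = ["RiskModel"]


class RiskModel(abc.ABC):
    """A survival risk model under the proportional-hazards contract.

    ``fit`` trains on a cohort and estimates the Breslow baseline hazard
    from the training scores; ``risk_score`` returns the per-patient
    log-risk eta (deterministic after fitting); ``survival_curve`` maps
    scores through S(t|x) = exp(-H0(t) exp(eta)).
    """

    baseline_: BaselineHazard | None = None

    @abc.abstractmethod
    def fit(self, cohort: CohortTable) -> "RiskModel":
        ...

    @abc.abstractmethod
    def risk_score(self, cohort: CohortTable) -> np.ndarray:
        ...

    def _fit_baseline(self, cohort: CohortTable) -> None:
        self.baseline_ = breslow_baseline(self.risk_score(cohort),
                                          cohort.time, cohort.event)

    def survival_curve(self, cohort: CohortTable, time_grid) -> np.ndarray:
        if self.baseline_ is None:
            raise RuntimeError("model must be fitted before predicting survival")
        return predict_survival(self.risk_score(cohort), self.baseline_, time_grid)
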