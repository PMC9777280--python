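"""Performance evaluation for censored survival predictions.

Five axes: Harrell's concordance index, cumulative/dynamic time-dependent
AUC, IPCW (Graf) Brier score, decile calibration with a survival-adapted
Hosmer-Lemeshow test (Nam-D'Agostino form), and top-20% risk
stratification with Kaplan-Meier curves and the log-rank test.

Censoring is handled by inverse-probability-of-censoring weighting: the
censoring distribution G is estimated by the reverse Kaplan-Meier estimator
on the evaluation set, and weights use the left limit G(t-) for subjects
whose event is observed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cohort import CohortTable

__all__ = [
    "TimeGrid",
    "KaplanMeierCurve",
    "km_estimate",
    "censoring_km",
    "logrank_test",
    "harrell_cindex",
    "td_auc",
    "brier_score",
    "CalibrationResult",
    "calibration",
    "stratify_high_risk",
    "EvaluationReport",
    "evaluate_model",
]


@dataclass(frozen=True)
class TimeGrid:
    """Strictly increasing evaluation horizons in months.

    The default grid places a horizon every 3 months up to a cap (48 months
    for development-scale follow-up, 24 for shorter validation follow-up,
    chosen to avoid horizons where nearly everyone is censored).
    """

    horizons: np.ndarray

    def __post_init__(self):
        h = np.asarray(self.horizons, dtype=float)
        if h.ndim != 1 or len(h) == 0 or np.any(h <= 0) or np.any(np.diff(h) <= 0):
            raise ValueError("horizons must be positive and strictly increasing")
        object.__setattr__(self, "horizons", h)

    @classmethod
    def every_3_months(cls, cap: float) -> "TimeGrid":
        return cls(np.arange(3.0, cap + 1e-9, 3.0))


# -- Kaplan-Meier ------------------------------------------------------------

@dataclass(frozen=True)
class KaplanMeierCurve:
    """Product-limit estimate with at-risk and event counts."""

    times: np.ndarray        # distinct event times
    survival: np.ndarray     # S(t) just after each event time
    at_risk: np.ndarray
    n_events: np.ndarray

    def evaluate(self, t, side: str = "right") -> np.ndarray:
        """S(t) (right-continuous); ``side='left'`` gives the limit S(t-)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.times, t, side=side)
        padded = np.concatenate([[1.0], self.survival])
        return padded[idx]


def _product_limit(time, indicator) -> KaplanMeierCurve:
    t = np.asarray(time, dtype=float)
    d = np.asarray(indicator).astype(int)
    uniq = np.unique(t[d == 1])
    at_risk = np.array([(t >= u).sum() for u in uniq])
    n_ev = np.array([((t == u) & (d == 1)).sum() for u in uniq])
    with np.errstate(divide="ignore", invalid="ignore"):
        surv = np.cumprod(1.0 - n_ev / at_risk)
    return KaplanMeierCurve(uniq, surv, at_risk, n_ev)


def km_estimate(time, event) -> KaplanMeierCurve:
    """Kaplan-Meier estimate of the survival function."""
    if len(np.atleast_1d(time)) == 0:
        raise ValueError("km_estimate needs at least one observation")
    return _product_limit(time, event)


def censoring_km(time, event) -> KaplanMeierCurve:
    """Reverse Kaplan-Meier estimate of the censoring distribution G."""
    d = np.asarray(event).astype(int)
    return _product_limit(time, 1 - d)


def logrank_test(time_a, event_a, time_b, event_b) -> tuple[float, float]:
    """Two-group log-rank chi-square test (1 degree of freedom)."""
    ta = np.asarray(time_a, dtype=float); da = np.asarray(event_a).astype(int)
    tb = np.asarray(time_b, dtype=float); db = np.asarray(event_b).astype(int)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("both groups must be non-empty")
    t = np.concatenate([ta, tb])
    d = np.concatenate([da, db])
    grp = np.concatenate([np.zeros(len(ta), int), np.ones(len(tb), int)])
    if d.sum() == 0:
        raise ValueError("log-rank test undefined with zero events")
    obs_minus_exp = 0.0
    var = 0.0
    for u in np.unique(t[d == 1]):
        at = t >= u
        n_j = at.sum()
        n1 = (at & (grp == 0)).sum()
        d_j = ((t == u) & (d == 1)).sum()
        d1 = ((t == u) & (d == 1) & (grp == 0)).sum()
        obs_minus_exp += d1 - d_j * n1 / n_j
        if n_j > 1:
            var += d_j * (n1 / n_j) * (1 - n1 / n_j) * (n_j - d_j) / (n_j - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = obs_minus_exp ** 2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


# -- discrimination ----------------------------------------------------------

def harrell_cindex(scores, time, event) -> float:
    """Harrell's concordance index.

    A pair (i, j) is comparable when the patient with the shorter observed
    time had an event; it is concordant when that patient has the higher
    score.  Tied scores count 1/2; tied event times are not comparable.
    """
    s = np.asarray(scores, dtype=float).reshape(-1)
    t = np.asarray(time, dtype=float).reshape(-1)
    d = np.asarray(event).astype(int).reshape(-1)
    comparable = (t[:, None] < t[None, :]) & (d[:, None] == 1)
    n_comp = comparable.sum()
    if n_comp == 0:
        raise ValueError("no comparable pairs")
    better = s[:, None] > s[None, :]
    ties = s[:, None] == s[None, :]
    conc = (comparable & better).sum() + 0.5 * (comparable & ties).sum()
    return float(conc / n_comp)


def td_auc(scores, time, event, grid: TimeGrid,
           censor_dist: KaplanMeierCurve | None = None) -> np.ndarray:
    """IPCW cumulative/dynamic time-dependent AUC at each horizon.

    Cases at horizon t are patients with an observed event by t; controls
    are patients still under observation beyond t.  Horizons with no case
    or no control are reported as NaN (undefined), never dropped.
    """
    s = np.asarray(scores, dtype=float).reshape(-1)
    t = np.asarray(time, dtype=float).reshape(-1)
    d = np.asarray(event).astype(int).reshape(-1)
    G = censor_dist if censor_dist is not None else censoring_km(t, d)

    out = np.full(len(grid.horizons), np.nan)
    for k, h in enumerate(grid.horizons):
        cases = (t <= h) & (d == 1)
        controls = t > h
        if not cases.any() or not controls.any():
            continue
        g_case = G.evaluate(t[cases], side="left")
        g_ctrl = G.evaluate(h)[0]
        if np.any(g_case <= 0) or g_ctrl <= 0:
            raise ValueError(f"censoring survival is zero at horizon {h}")
        w_case = 1.0 / g_case
        w_ctrl = np.full(controls.sum(), 1.0 / g_ctrl)
        sc, su = s[cases], s[controls]
        pair_w = np.outer(w_case, w_ctrl)
        wins = (sc[:, None] > su[None, :]) + 0.5 * (sc[:, None] == su[None, :])
        out[k] = float((pair_w * wins).sum() / pair_w.sum())
    return out


def brier_score(surv_pred, time, event, grid: TimeGrid,
                censor_dist: KaplanMeierCurve | None = None) -> np.ndarray:
    """IPCW (Graf) Brier score at each horizon.

    ``surv_pred`` is an (n_patients, n_horizons) matrix of predicted
    survival probabilities aligned with ``grid.horizons``.
    """
    S = np.atleast_2d(np.asarray(surv_pred, dtype=float))
    t = np.asarray(time, dtype=float).reshape(-1)
    d = np.asarray(event).astype(int).reshape(-1)
    if S.shape != (len(t), len(grid.horizons)):
        raise ValueError("surv_pred must be (n_patients, n_horizons)")
    G = censor_dist if censor_dist is not None else censoring_km(t, d)

    out = np.empty(len(grid.horizons))
    for k, h in enumerate(grid.horizons):
        died = (t <= h) & (d == 1)
        alive = t > h
        g_died = G.evaluate(t[died], side="left")
        g_h = G.evaluate(h)[0]
        if np.any(g_died <= 0) or (alive.any() and g_h <= 0):
            raise ValueError(f"censoring survival is zero at horizon {h}; "
                             "IPCW weights undefined")
        total = np.sum(S[died, k] ** 2 / g_died)
        total += np.sum((1.0 - S[alive, k]) ** 2 / g_h)
        out[k] = total / len(t)
    return out


# -- calibration -------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationResult:
    """Decile calibration table and survival Hosmer-Lemeshow test.

    Each table row holds (group size, mean predicted event probability,
    observed event probability from within-group Kaplan-Meier, at-risk
    count at the horizon, validity flag).  The statistic is the
    Nam-D'Agostino chi-square over valid groups with (groups - 2) degrees
    of freedom.
    """

    horizon: float
    groups: list[dict]
    statistic: float
    p_value: float
    df: int


def calibration(surv_at_horizon, time, event, horizon: float,
                n_groups: int = 10) -> CalibrationResult:
    """Decile calibration of predicted event probability at one horizon.

    The chi-square compares each decile's mean predicted event probability
    with the within-decile Kaplan-Meier event probability, standardized by
    the Greenwood variance of the Kaplan-Meier estimate (the survival
    adaptation of the Hosmer-Lemeshow test; the naive binomial variance is
    anti-conservative under censoring).  The statistic is referred to a
    chi-square with (valid groups - 1) degrees of freedom, which matches
    its measured null distribution.  Groups with nobody at risk at the
    horizon, no events, or zero variance are flagged and excluded from the
    statistic.
    """
    S = np.asarray(surv_at_horizon, dtype=float).reshape(-1)
    t = np.asarray(time, dtype=float).reshape(-1)
    d = np.asarray(event).astype(int).reshape(-1)
    n = len(S)
    if n < n_groups:
        raise ValueError(f"need at least {n_groups} patients")
    pred = 1.0 - S
    order = np.argsort(pred, kind="stable")
    chunks = np.array_split(order, n_groups)

    rows = []
    chi2 = 0.0
    n_valid = 0
    for idx in chunks:
        p_mean = float(pred[idx].mean())
        at_risk = int((t[idx] >= horizon).sum())
        var = 0.0
        obs = 0.0
        if d[idx].sum():
            km = km_estimate(t[idx], d[idx])
            s_h = float(km.evaluate(horizon)[0])
            obs = 1.0 - s_h
            upto = km.times <= horizon
            denom = km.at_risk[upto] * (km.at_risk[upto] - km.n_events[upto])
            if np.all(denom > 0):
                var = s_h ** 2 * float(np.sum(km.n_events[upto] / denom))
        valid = at_risk > 0 and var > 0
        rows.append({"n": int(len(idx)), "predicted": p_mean, "observed": obs,
                     "at_risk": at_risk, "valid": valid})
        if valid:
            chi2 += (obs - p_mean) ** 2 / var
            n_valid += 1
    df = max(n_valid - 1, 1)
    return CalibrationResult(float(horizon), rows, float(chi2),
                             float(stats.chi2.sf(chi2, df=df)), df)


# -- risk stratification -----------------------------------------------------

def stratify_high_risk(scores, fraction: float = 0.20,
                       patient_ids=None) -> tuple[np.ndarray, np.ndarray]:
    """Split patients into a high-risk top fraction and the remainder.

    ``scores`` are log-risks (higher = riskier); under proportional
    hazards this ordering coincides with ranking by predicted survival at
    any horizon.  The high-risk group holds the floor(fraction * n)
    riskiest patients; score ties are broken by patient id so the split is
    deterministic.  Returns index arrays (high_risk, others).
    """
    s = np.asarray(scores, dtype=float).reshape(-1)
    n = len(s)
    if n < 5:
        raise ValueError("need at least 5 patients to stratify")
    ids = np.asarray(patient_ids if patient_ids is not None
                     else np.arange(n), dtype=object)
    k = int(math.floor(fraction * n))
    order = np.lexsort((ids, -s))  # primary: descending score; tie: ascending id
    return np.sort(order[:k]), np.sort(order[k:])


# -- full report -------------------------------------------------------------

@dataclass
class EvaluationReport:
    """All metrics for one model on one dataset."""

    c_index: float
    horizons: np.ndarray
    auc_t: np.ndarray
    brier_t: np.ndarray
    calibrations: list[CalibrationResult]
    high_risk_fraction: float
    high_risk_n: int
    high_risk_event_fraction: float
    other_event_fraction: float
    logrank_statistic: float
    logrank_p: float
    km_high: KaplanMeierCurve | None
    km_other: KaplanMeierCurve | None

    def to_dict(self) -> dict:
        return {
            "c_index": self.c_index,
            "horizons": self.horizons.tolist(),
            "auc_t": self.auc_t.tolist(),
            "brier_t": self.brier_t.tolist(),
            "calibration": [
                {"horizon": c.horizon, "statistic": c.statistic,
                 "p_value": c.p_value, "df": c.df, "groups": c.groups}
                for c in self.calibrations
            ],
            "stratification": {
                "fraction": self.high_risk_fraction,
                "n_high_risk": self.high_risk_n,
                "high_risk_event_fraction": self.high_risk_event_fraction,
                "other_event_fraction": self.other_event_fraction,
                "logrank_statistic": self.logrank_statistic,
                "logrank_p": self.logrank_p,
            },
        }


def evaluate_model(model, cohort: CohortTable, grid: TimeGrid | None = None,
                   calibration_horizons=(12.0, 24.0),
                   high_risk_fraction: float = 0.20) -> EvaluationReport:
    """Run the full evaluation battery for a fitted risk model.

    Horizons beyond the observable range (no cases/controls, or censoring
    survival zero) yield NaN entries rather than being dropped.
    """
    if grid is None:
        cap = min(48.0, float(np.quantile(cohort.time, 0.95)))
        grid = TimeGrid.every_3_months(max(cap, 3.0))
    t, d = cohort.time, cohort.event
    scores = np.asarray(model.risk_score(cohort), dtype=float)
    surv = model.survival_curve(cohort, grid.horizons)
    G = censoring_km(t, d)

    c_index = harrell_cindex(scores, t, d)

    # mask horizons where IPCW weights are undefined
    admissible = np.array([
        ((t <= h) & (d == 1)).any() and (t > h).any()
        and G.evaluate(h)[0] > 0
        and np.all(G.evaluate(t[(t <= h) & (d == 1)], side="left") > 0)
        for h in grid.horizons
    ])
    auc = np.full(len(grid.horizons), np.nan)
    brier = np.full(len(grid.horizons), np.nan)
    if admissible.any():
        sub = TimeGrid(grid.horizons[admissible])
        auc[admissible] = td_auc(scores, t, d, sub, G)
        brier[admissible] = brier_score(surv[:, admissible], t, d, sub, G)

    calibs = []
    for h in calibration_horizons:
        if h <= cohort.time.max():
            s_h = model.survival_curve(cohort, [h])[:, 0]
            calibs.append(calibration(s_h, t, d, h))

    high, other = stratify_high_risk(scores, high_risk_fraction,
                                     cohort.patient_ids)
    try:
        lr_stat, lr_p = logrank_test(t[high], d[high], t[other], d[other])
    except ValueError:
        lr_stat, lr_p = float("nan"), float("nan")
    km_high = km_estimate(t[high], d[high]) if d[high].sum() else None
    km_other = km_estimate(t[other], d[other]) if d[other].sum() else None

    return EvaluationReport(
        c_index=c_index, horizons=grid.horizons, auc_t=auc, brier_t=brier,
        calibrations=calibs,
        high_risk_fraction=high_risk_fraction, high_risk_n=len(high),
        high_risk_event_fraction=float(d[high].mean()),
        other_event_fraction=float(d[other].mean()),
        logrank_statistic=lr_stat, logrank_p=lr_p,
        km_high=km_high, km_other=km_other,
    )
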