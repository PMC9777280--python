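"""Breslow baseline cumulative hazard and survival-curve prediction.

Under proportional hazards, S(t|x) = exp(-H0(t) * exp(eta(x))).  H0 is the
Breslow step-function estimator fitted on training scores: it increments at
each distinct event time t by d_t / sum_{j at risk at t} exp(eta_j).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BaselineHazard", "breslow_baseline", "predict_survival"]


@dataclass(frozen=True)
class BaselineHazard:
    """Step-function cumulative baseline hazard H0(t).

    ``event_times`` are the sorted distinct event times of the training
    data; ``cumulative_hazard`` the non-decreasing step values.  H0 is 0
    before the first event time and right-continuous.
    """

    event_times: np.ndarray
    cumulative_hazard: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.event_times, dtype=float)
        h = np.asarray(self.cumulative_hazard, dtype=float)
        if t.shape != h.shape or t.ndim != 1:
            raise ValueError("event_times and cumulative_hazard must be 1-D and aligned")
        if np.any(np.diff(t) <= 0):
            raise ValueError("event_times must be strictly increasing")
        if np.any(h < 0) or np.any(np.diff(h) < 0):
            raise ValueError("cumulative hazard must be non-negative and non-decreasing")
        object.__setattr__(self, "event_times", t)
        object.__setattr__(self, "cumulative_hazard", h)

    def cumulative(self, times) -> np.ndarray:
        """H0 evaluated at arbitrary times (0 before the first event)."""
        times = np.atleast_1d(np.asarray(times, dtype=float))
        idx = np.searchsorted(self.event_times, times, side="right")
        padded = np.concatenate([[0.0], self.cumulative_hazard])
        return padded[idx]


def breslow_baseline(scores, time, event) -> BaselineHazard:
    """Breslow estimate of the cumulative baseline hazard.

    With all scores zero this reduces to the Nelson-Aalen estimator.
    """
    eta = np.asarray(scores, dtype=float).reshape(-1)
    t = np.asarray(time, dtype=float).reshape(-1)
    d = np.asarray(event).reshape(-1).astype(int)
    if d.sum() < 1:
        raise ValueError("breslow_baseline requires at least one event")

    order = np.argsort(t, kind="stable")
    ts, ds = t[order], d[order]
    w = np.exp(eta[order] - eta.max())

    # suffix sums of risk weights: risk set of t is {j: t_j >= t}
    suffix = np.concatenate([np.cumsum(w[::-1])[::-1], [0.0]])
    uniq, counts = np.unique(ts[ds == 1], return_counts=True)
    left = np.searchsorted(ts, uniq, side="left")
    increments = counts / (suffix[left] * np.exp(eta.max()))
    return BaselineHazard(uniq, np.cumsum(increments))


def predict_survival(scores, baseline: BaselineHazard, time_grid) -> np.ndarray:
    """Per-patient survival curves S(t|x) = exp(-H0(t) exp(eta)).

    Returns an (n_patients, n_times) matrix, non-increasing along the time
    axis with S(0) = 1.
    """
    eta = np.asarray(scores, dtype=float).reshape(-1)
    h0 = baseline.cumulative(time_grid)
    return np.exp(-np.outer(np.exp(eta), h0))
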