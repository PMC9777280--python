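"""L2-penalized Cox proportional-hazards model fitted by Newton's method.

The fitter maximizes the log partial likelihood minus a ridge term
``penalty/2 * ||beta||^2``.  Breslow tie handling is the default (matching
the training loss of the neural models); Efron is available for the
classical fitter.  Wald statistics from the inverse penalized Hessian back
the univariate screening step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ..cohort import TIME_VARYING, CohortTable
from .base import RiskModel

__all__ = ["CoxPHModel", "fit_cph", "cph_objective", "ConvergenceError"]


class ConvergenceError(RuntimeError):
    """Newton iterations failed to reach the gradient tolerance."""

    def __init__(self, msg: str, grad_norm: float):
        super().__init__(msg)
        self.grad_norm = grad_norm


def _breslow_derivatives(X, ts, ds, eta):
    """Summed negative log partial likelihood, gradient and Hessian in beta.

    Inputs are sorted ascending by time.  Risk set of an event at t is
    {j : t_j >= t}; tied events share the full risk set.
    """
    n, p = X.shape
    shift = eta.max()
    w = np.exp(eta - shift)
    # suffix sums over risk sets
    s0 = np.concatenate([np.cumsum(w[::-1])[::-1], [0.0]])
    s1 = np.concatenate([np.cumsum((w[:, None] * X)[::-1], axis=0)[::-1],
                         np.zeros((1, p))])
    xxw = np.einsum("i,ij,ik->ijk", w, X, X)
    s2 = np.concatenate([np.cumsum(xxw[::-1], axis=0)[::-1],
                         np.zeros((1, p, p))])

    uniq, counts = np.unique(ts[ds == 1], return_counts=True)
    left = np.searchsorted(ts, uniq, side="left")

    ev = ds == 1
    loglik = float(eta[ev].sum() - np.sum(counts * (np.log(s0[left]) + shift)))
    grad = -X[ev].sum(axis=0)
    hess = np.zeros((p, p))
    for k, li in enumerate(left):
        d_t = counts[k]
        m1 = s1[li] / s0[li]
        grad += d_t * m1
        hess += d_t * (s2[li] / s0[li] - np.outer(m1, m1))
    return -loglik, grad, hess


def _efron_derivatives(X, ts, ds, eta):
    """Efron tie correction: tied events progressively leave the risk set."""
    n, p = X.shape
    shift = eta.max()
    w = np.exp(eta - shift)
    s0 = np.concatenate([np.cumsum(w[::-1])[::-1], [0.0]])
    s1 = np.concatenate([np.cumsum((w[:, None] * X)[::-1], axis=0)[::-1],
                         np.zeros((1, p))])
    xxw = np.einsum("i,ij,ik->ijk", w, X, X)
    s2 = np.concatenate([np.cumsum(xxw[::-1], axis=0)[::-1],
                         np.zeros((1, p, p))])

    uniq = np.unique(ts[ds == 1])
    ev = ds == 1
    neg_loglik = -float(eta[ev].sum())
    grad = -X[ev].sum(axis=0)
    hess = np.zeros((p, p))
    for tt in uniq:
        li = np.searchsorted(ts, tt, side="left")
        members = np.flatnonzero((ts == tt) & ev)
        d_t = len(members)
        e0 = w[members].sum()
        e1 = (w[members, None] * X[members]).sum(axis=0)
        e2 = np.einsum("i,ij,ik->jk", w[members], X[members], X[members])
        for l in range(d_t):
            f = l / d_t
            a0 = s0[li] - f * e0
            a1 = s1[li] - f * e1
            a2 = s2[li] - f * e2
            neg_loglik += np.log(a0) + shift
            m1 = a1 / a0
            grad += m1
            hess += a2 / a0 - np.outer(m1, m1)
    return neg_loglik, grad, hess


def cph_objective(X, time, event, beta, l2_penalty: float = 0.0,
                  ties: str = "breslow"):
    """Penalized negative log partial likelihood, gradient and Hessian.

    The objective is summed over events (not averaged) plus
    ``l2_penalty/2 * ||beta||^2``.
    """
    X = np.asarray(X, dtype=float)
    t = np.asarray(time, dtype=float).reshape(-1)
    d = np.asarray(event).reshape(-1).astype(int)
    beta = np.asarray(beta, dtype=float).reshape(-1)
    order = np.argsort(t, kind="stable")
    Xs, ts, ds = X[order], t[order], d[order]
    eta = Xs @ beta
    deriv = _breslow_derivatives if ties == "breslow" else _efron_derivatives
    value, grad, hess = deriv(Xs, ts, ds, eta)
    value += 0.5 * l2_penalty * float(beta @ beta)
    grad = grad + l2_penalty * beta
    hess = hess + l2_penalty * np.eye(len(beta))
    return value, grad, hess


@dataclass
class CoxPHModel(RiskModel):
    """Fitted penalized Cox model with Wald inference."""

    column_names: list[str] | None = None
    beta_: np.ndarray | None = None
    cov_: np.ndarray | None = None
    l2_penalty: float = 0.05
    ties: str = "breslow"
    max_iter: int = 100
    tol: float = 1e-6
    n_iter_: int = 0

    def _design(self, cohort: CohortTable) -> np.ndarray:
        if any(s.timing == TIME_VARYING for s in cohort.specs):
            raise ValueError(
                "Cox model needs an expanded cohort; apply expand_time_varying first"
            )
        return cohort.complete_values()

    def fit(self, cohort: CohortTable) -> "CoxPHModel":
        if cohort.n_events < 2:
            raise ValueError("fit_cph requires at least two events")
        X = self._design(cohort)
        self.column_names = cohort.columns
        p = X.shape[1]
        beta = np.zeros(p)
        value, grad, hess = cph_objective(X, cohort.time, cohort.event, beta,
                                          self.l2_penalty, self.ties)
        converged = bool(np.linalg.norm(grad) < self.tol)
        for it in range(1, self.max_iter + 1):
            if converged:
                break
            try:
                step = np.linalg.solve(hess, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(hess, grad, rcond=None)[0]
            # backtracking line search on the penalized objective
            alpha = 1.0
            for _ in range(30):
                candidate = beta - alpha * step
                new_value, new_grad, new_hess = cph_objective(
                    X, cohort.time, cohort.event, candidate,
                    self.l2_penalty, self.ties)
                if new_value <= value + 1e-12:
                    break
                alpha *= 0.5
            beta, value, grad, hess = candidate, new_value, new_grad, new_hess
            self.n_iter_ = it
            if np.linalg.norm(grad) < self.tol:
                converged = True
                break
        if not converged:
            raise ConvergenceError(
                f"Cox Newton solver did not converge in {self.max_iter} "
                f"iterations (|grad| = {np.linalg.norm(grad):.3e})",
                float(np.linalg.norm(grad)),
            )
        self.beta_ = beta
        self.cov_ = np.linalg.inv(hess)
        self._fit_baseline(cohort)
        return self

    def risk_score(self, cohort: CohortTable) -> np.ndarray:
        if self.beta_ is None:
            raise RuntimeError("model is not fitted")
        if cohort.columns != self.column_names:
            raise ValueError("cohort columns do not match the fitted design")
        return self._design(cohort) @ self.beta_

    def summary(self) -> dict[str, dict[str, float]]:
        """Per-covariate hazard ratio, Wald 95% CI and p-value."""
        if self.beta_ is None:
            raise RuntimeError("model is not fitted")
        se = np.sqrt(np.diag(self.cov_))
        out = {}
        for name, b, s in zip(self.column_names, self.beta_, se):
            z = b / s if s > 0 else np.inf * np.sign(b) if b else 0.0
            out[name] = {
                "coef": float(b),
                "hazard_ratio": float(np.exp(b)),
                "se": float(s),
                "ci_lower": float(np.exp(b - 1.959963984540054 * s)),
                "ci_upper": float(np.exp(b + 1.959963984540054 * s)),
                "p": float(2.0 * stats.norm.sf(abs(z))),
            }
        return out


def fit_cph(cohort: CohortTable, l2_penalty: float = 0.05,
            max_iter: int = 100, tol: float = 1e-6,
            ties: str = "breslow") -> CoxPHModel:
    """Fit the penalized Cox model on an expanded cohort."""
    model = CoxPHModel(l2_penalty=l2_penalty, max_iter=max_iter,
                       tol=tol, ties=ties)
    return model.fit(cohort)
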