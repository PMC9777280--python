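"""Cox partial likelihood with Breslow tie handling.

This is the training loss shared by all three risk models: for scores
``eta`` and right-censored outcomes, the (event-averaged) negative log
partial likelihood is

    L = -(1/D) * sum_{i: event} [ eta_i - log sum_{j: t_j >= t_i} exp(eta_j) ]

where D is the number of events and tied event times share the full risk
set (Breslow convention).  The analytic gradient with respect to the scores
is provided for backpropagation through the neural models.
"""

from __future__ import annotations

import numpy as np

__all__ = ["neg_log_partial_likelihood", "partial_likelihood_gradient",
           "partial_likelihood_value_and_grad"]


def _suffix_logsumexp(x: np.ndarray) -> np.ndarray:
    """s[k] = logsumexp(x[k:]) computed stably in one backward pass."""
    out = np.empty_like(x)
    running = -np.inf
    for k in range(len(x) - 1, -1, -1):
        running = np.logaddexp(running, x[k])
        out[k] = running
    return out


def _prepare(scores, time, event):
    eta = np.asarray(scores, dtype=float).reshape(-1)
    t = np.asarray(time, dtype=float).reshape(-1)
    d = np.asarray(event).reshape(-1).astype(int)
    if not (len(eta) == len(t) == len(d)):
        raise ValueError("scores, time and event must have equal length")
    if d.sum() < 1:
        raise ValueError("partial likelihood undefined with zero events")
    return eta, t, d


def partial_likelihood_value_and_grad(scores, time, event):
    """Event-averaged negative log partial likelihood and its score gradient.

    Returns
    -------
    loss : float
    grad : ndarray, d loss / d eta_k, same length as ``scores``.
    """
    eta, t, d = _prepare(scores, time, event)
    n = len(eta)
    order = np.argsort(t, kind="stable")
    ts, es, ds = t[order], eta[order], d[order]

    lse = _suffix_logsumexp(es)
    # leftmost index of each patient's (tied) event time
    left = np.searchsorted(ts, ts, side="left")
    n_events = int(ds.sum())

    ev = np.flatnonzero(ds == 1)
    loss = float(np.sum(lse[left[ev]] - es[ev]) / n_events)

    # grad_k = (exp(eta_k) * sum_{events i: t_i <= t_k} exp(-lse_i) - d_k) / D
    bump = np.zeros(n)
    np.add.at(bump, left[ev], np.exp(-lse[left[ev]]))
    cum = np.cumsum(bump)
    grad_sorted = (np.exp(es) * cum - ds) / n_events
    grad = np.empty(n)
    grad[order] = grad_sorted
    return loss, grad


def neg_log_partial_likelihood(scores, time, event) -> float:
    """Breslow-tie negative log partial likelihood, averaged over events."""
    loss, _ = partial_likelihood_value_and_grad(scores, time, event)
    return loss


def partial_likelihood_gradient(scores, time, event) -> np.ndarray:
    """Gradient of :func:`neg_log_partial_likelihood` w.r.t. the scores."""
    _, grad = partial_likelihood_value_and_grad(scores, time, event)
    return grad
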