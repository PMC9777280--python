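"""Event-stratified fold assignment shared by screening and cross-validation."""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["stratified_fold_assignment"]


def stratified_fold_assignment(event, k: int, seed: int) -> np.ndarray:
    """Assign each patient a fold in [0, k) balancing events across folds.

    Events and censored patients are shuffled separately and dealt in one
    continuous round-robin, so both each fold's event count and its total
    size differ from the ideal by at most one.  With fewer events than
    folds a warning is issued and assignment degenerates to plain random
    folds (some folds will be event-free).
    """
    event = np.asarray(event).astype(int).reshape(-1)
    n = len(event)
    if n < k:
        raise ValueError(f"cannot make {k} folds from {n} patients")
    if 0 < event.sum() < k:
        warnings.warn(f"only {event.sum()} events for {k} folds; "
                      "some folds will have no events", stacklevel=2)
    rng = np.random.default_rng(seed)
    ev_idx = rng.permutation(np.flatnonzero(event == 1))
    cen_idx = rng.permutation(np.flatnonzero(event == 0))
    ordering = np.concatenate([ev_idx, cen_idx])
    folds = np.empty(n, dtype=int)
    folds[ordering] = np.arange(n) % k
    return folds
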