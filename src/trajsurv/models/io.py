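"""Versioned save/load of fitted model stacks.

The archive is a single JSON document: model kind, covariate list,
preprocessing parameters, architecture config, flattened weight arrays
(including batch-normalization running statistics) or Cox coefficients,
and the Breslow baseline hazard.  JSON keeps the archive text-only and
diff-friendly; the arrays are small for every model in this package.
"""

from __future__ import annotations

import json

import numpy as np

from .baseline import BaselineHazard
from .cph import CoxPHModel
from .networks import (
    DeepSurvModel,
    NetworkConfig,
    RNNSurvModel,
    TrainingConfig,
    _DeepSurvNet,
    _RNNSurvNet,
)
from .nn import BatchNorm, Sequential

ARCHIVE_VERSION = 1

__all__ = ["save_pipeline", "load_pipeline"]


def _walk_bn(obj, found):
    if isinstance(obj, BatchNorm):
        found.append(obj)
    elif isinstance(obj, Sequential):
        for l in obj.layers:
            _walk_bn(l, found)
    else:
        for attr in ("rnn", "branch", "fc", "head"):
            if hasattr(obj, attr):
                _walk_bn(getattr(obj, attr), found)


def _net_state(net) -> list[np.ndarray]:
    bn: list[BatchNorm] = []
    _walk_bn(net, bn)
    return list(net.params()) + [a for l in bn for a in (l.running_mean, l.running_var)]


def _set_net_state(net, arrays: list[np.ndarray]) -> None:
    state = _net_state(net)
    if len(state) != len(arrays):
        raise ValueError("archive does not match network architecture")
    for dst, src in zip(state, arrays):
        dst[...] = np.asarray(src, dtype=float).reshape(dst.shape)


def _model_payload(model) -> dict:
    base = {
        "baseline": None if model.baseline_ is None else {
            "event_times": model.baseline_.event_times.tolist(),
            "cumulative_hazard": model.baseline_.cumulative_hazard.tolist(),
        },
    }
    if isinstance(model, CoxPHModel):
        base.update({
            "model_kind": "cph",
            "columns": model.column_names,
            "beta": model.beta_.tolist(),
            "cov": model.cov_.tolist(),
            "l2_penalty": model.l2_penalty,
            "ties": model.ties,
        })
    else:
        kind = "rnnsurv" if isinstance(model, RNNSurvModel) else "deepsurv"
        base.update({
            "model_kind": kind,
            "columns": model.columns_,
            "net_config": model.net_config.__dict__ | {
                "fc_widths": list(model.net_config.fc_widths)},
            "train_config": dict(model.train_config.__dict__),
            "weights": [a.tolist() for a in _net_state(model.net_)],
            "n_inv": getattr(model.net_, "_n_inv", None),
            "n_seq": getattr(model.net_, "_n_seq", None),
            "n_in": getattr(model.net_, "_n_in", None),
        })
    return base


def _restore_model(payload: dict):
    kind = payload["model_kind"]
    baseline = None
    if payload["baseline"] is not None:
        baseline = BaselineHazard(np.asarray(payload["baseline"]["event_times"]),
                                  np.asarray(payload["baseline"]["cumulative_hazard"]))
    if kind == "cph":
        model = CoxPHModel(l2_penalty=payload["l2_penalty"], ties=payload["ties"])
        model.column_names = payload["columns"]
        model.beta_ = np.asarray(payload["beta"], dtype=float)
        model.cov_ = np.asarray(payload["cov"], dtype=float)
        model.baseline_ = baseline
        return model
    net_cfg = NetworkConfig(rnn_hidden=payload["net_config"]["rnn_hidden"],
                            fc_widths=tuple(payload["net_config"]["fc_widths"]),
                            dropout=payload["net_config"]["dropout"],
                            cell=payload["net_config"]["cell"])
    train_cfg = TrainingConfig(**payload["train_config"])
    rng = np.random.default_rng(0)  # weights are overwritten below
    if kind == "deepsurv":
        model = DeepSurvModel(net_cfg, train_cfg)
        model.net_ = _DeepSurvNet(payload["n_in"], net_cfg, rng)
    else:
        model = RNNSurvModel(net_cfg, train_cfg)
        model.net_ = _RNNSurvNet(payload["n_inv"], payload["n_seq"], net_cfg, rng)
    _set_net_state(model.net_, payload["weights"])
    model.columns_ = payload["columns"]
    model.baseline_ = baseline
    return model


def save_pipeline(fitted, path) -> None:
    """Write a fitted preprocessing + model stack to a JSON archive."""
    payload = {
        "version": ARCHIVE_VERSION,
        "kind": fitted.kind,
        "covariates": fitted.covariates,
        "imputation_values": fitted.imputation_values,
        "zscore_params": {k: list(v) for k, v in fitted.zscore_params.items()},
        "model": _model_payload(fitted.model),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_pipeline(path):
    """Read an archive written by :func:`save_pipeline`."""
    from ..pipeline import FittedPipeline

    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("version") != ARCHIVE_VERSION:
        raise ValueError(f"unsupported archive version {payload.get('version')!r}")
    return FittedPipeline(
        kind=payload["kind"],
        covariates=payload["covariates"],
        imputation_values=payload["imputation_values"],
        zscore_params={k: tuple(v) for k, v in payload["zscore_params"].items()},
        model=_restore_model(payload["model"]),
    )
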