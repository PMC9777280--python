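"""The two neural survival models.

Both are trained on the event-averaged Cox partial likelihood with
within-batch risk sets, an adaptive-moment optimiser (learning rate 0.05,
batch size 64 by default) and early termination when the full-training-set
loss stops improving for 20 consecutive epochs.

* The feed-forward model ("DeepSurv-style") is a shallow stack — one hidden
  fully connected layer with rectified-linear activation, batch
  normalization and dropout, then a linear output unit — applied to an
  *expanded* cohort in which each time-varying covariate contributes two
  independent columns.

* The recurrent model ("RNNSurv-style") has two branches: a recurrent
  layer that consumes the length-2 (admission, discharge) sequence of the
  time-varying covariates and emits its final hidden state, and a fully
  connected branch for the invariant covariates.  The branch outputs are
  concatenated and mapped to the log-risk by a linear output layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..cohort import TIME_VARYING, CohortTable
from .base import RiskModel
from .loss import neg_log_partial_likelihood, partial_likelihood_value_and_grad
from .nn import GRU, Adam, BatchNorm, Dense, Dropout, ElmanRNN, ReLU, Sequential

__all__ = ["NetworkConfig", "TrainingConfig", "DeepSurvModel", "RNNSurvModel",
           "fit_deepsurv", "fit_rnnsurv"]


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture knobs shared by the two networks.

    ``rnn_hidden`` is the recurrent branch width (recurrent model only);
    ``fc_widths`` the hidden widths of the fully connected branch;
    ``cell`` selects the recurrent cell (simple tanh cell or GRU).
    """

    rnn_hidden: int = 16
    fc_widths: tuple[int, ...] = (32,)
    dropout: float = 0.3
    cell: str = "simple_rnn"

    def validate(self) -> None:
        if self.rnn_hidden <= 0 or any(w <= 0 for w in self.fc_widths):
            raise ValueError("layer widths must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.cell not in ("simple_rnn", "gru"):
            raise ValueError(f"unknown cell {self.cell!r}")


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 0.05
    batch_size: int = 64
    max_epochs: int = 1000
    patience: int = 20
    seed: int = 0
    min_improvement: float = 1e-6

    def validate(self) -> None:
        if min(self.learning_rate, self.batch_size, self.max_epochs,
               self.patience) <= 0:
            raise ValueError("training config values must be positive")
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")


def _mlp(n_in: int, widths: tuple[int, ...], dropout: float,
         rng: np.random.Generator) -> tuple[Sequential, int]:
    layers: list = []
    width = n_in
    for w in widths:
        layers += [Dense(width, w, rng), ReLU(), BatchNorm(w), Dropout(dropout, rng)]
        width = w
    return Sequential(layers), width


class _DeepSurvNet:
    def __init__(self, n_in: int, cfg: NetworkConfig, rng: np.random.Generator):
        self._n_in = n_in
        self.branch, width = _mlp(n_in, cfg.fc_widths, cfg.dropout, rng)
        self.head = Dense(width, 1, rng)

    def params(self):
        return self.branch.params() + self.head.params()

    def grads(self):
        return self.branch.grads() + self.head.grads()

    def zero_grads(self):
        for g in self.grads():
            g[...] = 0.0

    def forward(self, inputs, train: bool) -> np.ndarray:
        (x,) = inputs
        return self.head.forward(self.branch.forward(x, train), train)[:, 0]

    def backward(self, deta: np.ndarray) -> None:
        self.branch.backward(self.head.backward(deta[:, None]))


class _RNNSurvNet:
    def __init__(self, n_inv: int, n_seq: int, cfg: NetworkConfig,
                 rng: np.random.Generator):
        self._n_inv, self._n_seq = n_inv, n_seq
        cell_cls = ElmanRNN if cfg.cell == "simple_rnn" else GRU
        self.rnn = cell_cls(n_seq, cfg.rnn_hidden, rng)
        self.has_inv = n_inv > 0
        width = cfg.rnn_hidden
        if self.has_inv:
            self.fc, fc_width = _mlp(n_inv, cfg.fc_widths, cfg.dropout, rng)
            width += fc_width
        self.head = Dense(width, 1, rng)

    def params(self):
        p = self.rnn.params() + (self.fc.params() if self.has_inv else [])
        return p + self.head.params()

    def grads(self):
        g = self.rnn.grads() + (self.fc.grads() if self.has_inv else [])
        return g + self.head.grads()

    def zero_grads(self):
        for g in self.grads():
            g[...] = 0.0

    def forward(self, inputs, train: bool) -> np.ndarray:
        x_inv, x_seq = inputs
        h = self.rnn.forward(x_seq, train)
        if self.has_inv:
            h = np.concatenate([h, self.fc.forward(x_inv, train)], axis=1)
        self._rnn_width = self.rnn.params()[-1].size  # hidden width via bias
        return self.head.forward(h, train)[:, 0]

    def backward(self, deta: np.ndarray) -> None:
        g = self.head.backward(deta[:, None])
        k = self._rnn_width
        self.rnn.backward(g[:, :k])
        if self.has_inv:
            self.fc.backward(g[:, k:])


def _take(inputs: tuple[np.ndarray, ...], idx) -> tuple[np.ndarray, ...]:
    return tuple(a[idx] for a in inputs)


def _train_network(net, inputs: tuple[np.ndarray, ...], time, event,
                   cfg: TrainingConfig, rng: np.random.Generator) -> list[float]:
    """Minibatch partial-likelihood training with early termination.

    Batches with zero events carry no partial-likelihood information and
    are skipped.  The monitored quantity is the full-training-set loss in
    evaluation mode; the parameters from the best epoch are kept.
    """
    n = len(time)
    opt = Adam(cfg.learning_rate, net.params())
    best = np.inf
    best_state = [p.copy() for p in net.params()]
    stall = 0
    history: list[float] = []
    for _ in range(cfg.max_epochs):
        perm = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = perm[start:start + cfg.batch_size]
            if event[idx].sum() == 0:
                continue
            eta = net.forward(_take(inputs, idx), train=True)
            _, deta = partial_likelihood_value_and_grad(eta, time[idx], event[idx])
            net.zero_grads()
            net.backward(deta)
            opt.step(net.grads())
        full = net.forward(inputs, train=False)
        loss = neg_log_partial_likelihood(full, time, event)
        history.append(loss)
        if loss < best - cfg.min_improvement:
            best = loss
            best_state = [p.copy() for p in net.params()]
            stall = 0
        else:
            stall += 1
            if stall >= cfg.patience:
                break
    for p, s in zip(net.params(), best_state):
        p[...] = s
    return history


class DeepSurvModel(RiskModel):
    """Shallow feed-forward Cox network on expanded covariate columns."""

    def __init__(self, net: NetworkConfig | None = None,
                 train: TrainingConfig | None = None):
        self.net_config = net or NetworkConfig()
        self.train_config = train or TrainingConfig()
        self.net_config.validate()
        self.train_config.validate()
        self.net_: _DeepSurvNet | None = None
        self.loss_history_: list[float] = []
        self.columns_: list[str] | None = None

    def _design(self, cohort: CohortTable) -> np.ndarray:
        if any(s.timing == TIME_VARYING for s in cohort.specs):
            raise ValueError("feed-forward model needs an expanded cohort; "
                             "apply expand_time_varying first")
        return cohort.complete_values()

    def fit(self, cohort: CohortTable) -> "DeepSurvModel":
        if cohort.n_events < 2:
            raise ValueError("training requires at least two events")
        X = self._design(cohort)
        self.columns_ = cohort.columns
        rng = np.random.default_rng(self.train_config.seed)
        self.net_ = _DeepSurvNet(X.shape[1], self.net_config, rng)
        self.loss_history_ = _train_network(
            self.net_, (X,), cohort.time, cohort.event, self.train_config, rng)
        self._fit_baseline(cohort)
        return self

    def risk_score(self, cohort: CohortTable) -> np.ndarray:
        if self.net_ is None:
            raise RuntimeError("model is not fitted")
        if cohort.columns != self.columns_:
            raise ValueError("cohort columns do not match the fitted design")
        return self.net_.forward((self._design(cohort),), train=False)


class RNNSurvModel(RiskModel):
    """Two-branch recurrent survival network for two-time-step cohorts."""

    def __init__(self, net: NetworkConfig | None = None,
                 train: TrainingConfig | None = None):
        self.net_config = net or NetworkConfig()
        self.train_config = train or TrainingConfig()
        self.net_config.validate()
        self.train_config.validate()
        self.net_: _RNNSurvNet | None = None
        self.loss_history_: list[float] = []
        self.columns_: list[str] | None = None

    def _design(self, cohort: CohortTable) -> tuple[np.ndarray, np.ndarray]:
        tv = [s for s in cohort.specs if s.timing == TIME_VARYING]
        if not tv:
            raise ValueError("cohort has no time-varying covariates; "
                             "use the feed-forward model (fit_deepsurv) instead")
        values = cohort.complete_values()
        inv_cols = [cohort.column_index(c) for s in cohort.specs
                    if s.timing != TIME_VARYING for c in s.columns]
        x_inv = values[:, inv_cols]
        adm = [cohort.column_index(s.columns[0]) for s in tv]
        dis = [cohort.column_index(s.columns[1]) for s in tv]
        x_seq = np.stack([values[:, adm], values[:, dis]], axis=1)
        return x_inv, x_seq

    def fit(self, cohort: CohortTable) -> "RNNSurvModel":
        if cohort.n_events < 2:
            raise ValueError("training requires at least two events")
        x_inv, x_seq = self._design(cohort)
        self.columns_ = cohort.columns
        rng = np.random.default_rng(self.train_config.seed)
        self.net_ = _RNNSurvNet(x_inv.shape[1], x_seq.shape[2],
                                self.net_config, rng)
        self.loss_history_ = _train_network(
            self.net_, (x_inv, x_seq), cohort.time, cohort.event,
            self.train_config, rng)
        self._fit_baseline(cohort)
        return self

    def risk_score(self, cohort: CohortTable) -> np.ndarray:
        if self.net_ is None:
            raise RuntimeError("model is not fitted")
        if cohort.columns != self.columns_:
            raise ValueError("cohort columns do not match the fitted design")
        return self.net_.forward(self._design(cohort), train=False)


def fit_deepsurv(cohort: CohortTable, net: NetworkConfig | None = None,
                 train: TrainingConfig | None = None) -> DeepSurvModel:
    """Train the feed-forward survival network on an expanded cohort."""
    return DeepSurvModel(net, train).fit(cohort)


def fit_rnnsurv(cohort: CohortTable, net: NetworkConfig | None = None,
                train: TrainingConfig | None = None) -> RNNSurvModel:
    """Train the recurrent survival network on a two-time-step cohort."""
    return RNNSurvModel(net, train).fit(cohort)
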