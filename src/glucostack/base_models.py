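"""The three recurrent base learners and their uniform predictor contract.

Architectures (widths and activations per the fixed hyperparameter table):

* ``bilstm`` — one bidirectional layer, 128 units per direction, relu cell
  activation; forward and backward final hidden states are concatenated into
  the linear dense head.
* ``stacklstm`` — three stacked layers of 128, 64 and 32 units, linear cell
  activation; the last layer's final hidden state feeds the dense head.
* ``vlstm`` — one 128-unit layer with peephole connections, linear cell
  activation.

All are trained with Adam (lr 0.001) on mean squared error, batches of 32,
up to 500 epochs with early stopping on validation loss (patience 10) and
best-weight restoration.  A reduced ``fast`` profile (smaller widths, fewer
epochs) is provided for desk-scale experiments and CI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from . import nn
from .windowing import SupervisedDataset

logger = logging.getLogger(__name__)

ARCHITECTURES = ("bilstm", "stacklstm", "vlstm")

_DEFAULT_UNITS = {"bilstm": [128], "stacklstm": [128, 64, 32], "vlstm": [128]}
_DEFAULT_ACTIVATION = {"bilstm": "relu", "stacklstm": "linear", "vlstm": "linear"}
_FAST_UNITS = {"bilstm": [32], "stacklstm": [32, 16, 8], "vlstm": [32]}


@dataclass(frozen=True)
class PredictionMatrix:
    """Per-model predictions, samples × horizon steps, with a scale flag."""

    values: np.ndarray
    scale: str = "normalized"   # or "mg_dl"
    model: str = ""

    def __post_init__(self):
        if self.values.ndim != 2:
            raise ValueError("PredictionMatrix requires a 2-D array")

    @property
    def shape(self):
        return self.values.shape


@dataclass(frozen=True)
class BaseModelConfig:
    """Hyperparameters of one base learner."""

    architecture: str
    output_dim: int = 6
    layer_units: tuple = ()
    activation: str = ""
    peepholes: bool | None = None
    learning_rate: float = 0.001
    batch_size: int = 32
    max_epochs: int = 500
    early_stop_patience: int | None = 10
    shuffle_batches: bool = True
    seed: int = 0

    def resolved(self) -> "BaseModelConfig":
        """Fill architecture-dependent defaults."""
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}; "
                             f"expected one of {ARCHITECTURES}")
        units = tuple(self.layer_units) or tuple(_DEFAULT_UNITS[self.architecture])
        act = self.activation or _DEFAULT_ACTIVATION[self.architecture]
        peep = self.peepholes
        if peep is None:
            peep = self.architecture == "vlstm"
        if self.architecture == "vlstm" and not peep:
            logger.warning("vlstm requested without peepholes: standard cell used")
        if self.output_dim not in (6, 9, 12):
            raise ValueError("output_dim must be one of 6, 9, 12")
        return replace(self, layer_units=units, activation=act, peepholes=peep)


def default_config(architecture: str, output_dim: int, *, seed: int = 0) -> BaseModelConfig:
    """Full-size configuration for one of the three architectures."""
    return BaseModelConfig(architecture=architecture, output_dim=output_dim,
                           seed=seed).resolved()


def fast_config(architecture: str, output_dim: int, *, seed: int = 0) -> BaseModelConfig:
    """Desk-scale profile: reduced widths, 12 epochs, patience 3, batch 64."""
    return BaseModelConfig(
        architecture=architecture, output_dim=output_dim,
        layer_units=tuple(_FAST_UNITS[architecture]),
        max_epochs=12, early_stop_patience=3, batch_size=64, seed=seed,
    ).resolved()


class LSTMForecaster(BaseEstimator, RegressorMixin):
    """A multi-step recurrent forecaster with the sklearn estimator contract.

    ``fit(X, y, X_val=..., y_val=...)`` trains on normalized windows; the
    optional validation set drives early stopping.  ``predict`` is
    deterministic given the trained weights.
    """

    def __init__(self, architecture="bilstm", output_dim=6, layer_units=None,
                 activation=None, peepholes=None, learning_rate=0.001,
                 batch_size=32, max_epochs=500, early_stop_patience=10,
                 shuffle_batches=True, seed=0):
        self.architecture = architecture
        self.output_dim = output_dim
        self.layer_units = layer_units
        self.activation = activation
        self.peepholes = peepholes
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.early_stop_patience = early_stop_patience
        self.shuffle_batches = shuffle_batches
        self.seed = seed

    def _config(self) -> BaseModelConfig:
        return BaseModelConfig(
            architecture=self.architecture,
            output_dim=self.output_dim,
            layer_units=tuple(self.layer_units) if self.layer_units else (),
            activation=self.activation or "",
            peepholes=self.peepholes,
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            early_stop_patience=self.early_stop_patience,
            shuffle_batches=self.shuffle_batches,
            seed=self.seed,
        ).resolved()

    def _build(self, input_dim: int) -> nn.LSTMNet:
        cfg = self._config()
        bidir = cfg.architecture == "bilstm"
        specs = [
            dict(units=u, activation=cfg.activation, peephole=cfg.peepholes,
                 bidirectional=bidir)
            for u in cfg.layer_units
        ]
        return nn.LSTMNet(1, specs, cfg.output_dim, seed=cfg.seed)

    def fit(self, X, y, *, X_val=None, y_val=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        cfg = self._config()
        if y.shape[1] != cfg.output_dim:
            raise ValueError(f"y has {y.shape[1]} outputs; config expects {cfg.output_dim}")
        self.config_ = cfg
        self.net_ = self._build(X.shape[1])
        self.history_ = nn.fit(
            self.net_, X, y, X_val=X_val, y_val=y_val,
            lr=cfg.learning_rate, batch_size=cfg.batch_size,
            max_epochs=cfg.max_epochs, patience=cfg.early_stop_patience,
            shuffle=cfg.shuffle_batches, seed=cfg.seed,
        )
        self.epochs_run_ = self.history_["epochs_run"]
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        if not hasattr(self, "net_"):
            raise RuntimeError("forecaster is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X must be 2-D with {self.n_features_in_} history columns, "
                f"got shape {X.shape}"
            )
        return self.net_.forward(X).astype(np.float64)

    def layer_summary(self) -> list[dict]:
        """Describe the recurrent stack (for inspection and tests)."""
        cfg = self._config()
        return [
            dict(kind="bilstm" if cfg.architecture == "bilstm" else "lstm",
                 units=u, activation=cfg.activation, peephole=cfg.peepholes)
            for u in cfg.layer_units
        ] + [dict(kind="dense", units=cfg.output_dim, activation="linear")]


# ---------------------------------------------------------------------------
# Functional wrappers matching the module's operation contract
# ---------------------------------------------------------------------------

def build_base_model(config: BaseModelConfig) -> LSTMForecaster:
    cfg = config.resolved()
    return LSTMForecaster(
        architecture=cfg.architecture, output_dim=cfg.output_dim,
        layer_units=list(cfg.layer_units), activation=cfg.activation,
        peepholes=cfg.peepholes, learning_rate=cfg.learning_rate,
        batch_size=cfg.batch_size, max_epochs=cfg.max_epochs,
        early_stop_patience=cfg.early_stop_patience,
        shuffle_batches=cfg.shuffle_batches, seed=cfg.seed,
    )


def train_base_model(model: LSTMForecaster, train: SupervisedDataset,
                     val: SupervisedDataset | None) -> LSTMForecaster:
    if val is not None and val.spec != train.spec:
        raise ValueError("train and validation datasets have different window specs")
    model.fit(train.X, train.Y,
              X_val=None if val is None else val.X,
              y_val=None if val is None else val.Y)
    return model


def predict(model: LSTMForecaster, X) -> PredictionMatrix:
    return PredictionMatrix(values=model.predict(X), scale="normalized",
                            model=model.architecture)
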