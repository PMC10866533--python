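"""The adaptively weighted stacking ensemble.

For each of the four history windows at a given prediction horizon:

1. the preprocessed, normalized training series is windowed and split
   chronologically 80/20 into a training subset and a validation subset;
2. each base architecture is trained in 5-fold cross-validation over the
   training subset (contiguous, non-shuffled folds), producing exactly one
   out-of-fold (OOF) prediction per training sample per architecture, with
   the validation subset driving early stopping;
3. the fold models predict the validation subset; those predictions (one
   coordinate per base model, final horizon step) are clustered by weighted
   affinity propagation to produce the adaptive base-model weights;
4. a linear (OLS) meta-model is fitted on the concatenation
   [base OOF predictions | weighted combination | original history window]
   against the training-subset targets;
5. at test time each architecture's five fold models predict the test
   windows and are averaged; the same weights and meta-model produce the
   stacked forecast, which is denormalized and scored.

The final report carries per-window metrics and their mean across the four
history windows.  Test targets never enter base-model training, normalizer
fitting, weight estimation or meta-model fitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import LinearRegression

from .ap_weighting import APWeighter, combine_predictions
from .base_models import ARCHITECTURES, LSTMForecaster, default_config, fast_config
from .evaluation import MetricsReport, evaluate
from .preprocessing import (
    KalmanConfig,
    MinMaxNormalizer,
    SmoothingConfig,
    preprocess_series,
    split_train_val,
)
from .series import GlucoseSeries, InsufficientDataError
from .windowing import enumerate_window_specs, make_supervised

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StackingPlan:
    """Configuration of one AWD-stacking run."""

    n_folds: int = 5
    profile: str = "paper"              # "paper" (full size) or "fast" (desk scale)
    val_fraction: float = 0.2
    similarity_alpha: float = 0.5
    damping: float = 0.5
    sample_cap: int = 500
    invert_flag: bool = False
    include_original_features: bool = True
    include_weighted_combo: bool = True
    metric_step: str = "final"          # "final": score the value PH minutes ahead
    seed: int = 0
    base_factory: object = None         # callable(arch, output_dim, seed) -> estimator

    def __post_init__(self):
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.profile not in ("paper", "fast"):
            raise ValueError("profile must be 'paper' or 'fast'")

    def make_base(self, arch: str, output_dim: int, seed: int):
        if self.base_factory is not None:
            return self.base_factory(arch, output_dim, seed)
        cfg = (fast_config if self.profile == "fast" else default_config)(
            arch, output_dim, seed=seed)
        return LSTMForecaster(
            architecture=cfg.architecture, output_dim=cfg.output_dim,
            layer_units=list(cfg.layer_units), activation=cfg.activation,
            peepholes=cfg.peepholes, learning_rate=cfg.learning_rate,
            batch_size=cfg.batch_size, max_epochs=cfg.max_epochs,
            early_stop_patience=cfg.early_stop_patience, seed=cfg.seed,
        )


def kfold_slices(n: int, k: int) -> list[slice]:
    """Contiguous near-equal folds; the remainder goes to the earliest folds."""
    if n < k:
        raise InsufficientDataError(f"need at least {k} samples for {k}-fold CV, got {n}")
    base, rem = divmod(n, k)
    sizes = [base + (1 if i < rem else 0) for i in range(k)]
    edges = np.cumsum([0] + sizes)
    return [slice(int(edges[i]), int(edges[i + 1])) for i in range(k)]


def _spawn_seeds(master: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def kfold_oof(X, Y, plan: StackingPlan, *, X_val=None, y_val=None,
              architectures=ARCHITECTURES):
    """5-fold out-of-fold predictions and fold models per architecture.

    Returns ``(oof, fold_models)``: ``oof[arch]`` has one prediction row per
    training sample from the fold model that did not see it; ``fold_models``
    keeps all n_folds × n_architectures fitted models.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    folds = kfold_slices(len(X), plan.n_folds)
    output_dim = Y.shape[1]
    seeds = _spawn_seeds(plan.seed, len(architectures) * plan.n_folds)
    oof = {}
    fold_models = {}
    si = 0
    for arch in architectures:
        preds = np.full_like(Y, np.nan, dtype=float)
        models = []
        for fold in folds:
            mask = np.ones(len(X), dtype=bool)
            mask[fold] = False
            model = plan.make_base(arch, output_dim, seeds[si])
            si += 1
            model.fit(X[mask], Y[mask], X_val=X_val, y_val=y_val)
            preds[fold] = model.predict(X[fold])
            models.append(model)
        if np.isnan(preds).any():
            raise RuntimeError("incomplete OOF coverage")  # defensive; folds partition
        oof[arch] = preds
        fold_models[arch] = models
    return oof, fold_models


def test_predictions(fold_models: dict, X) -> dict:
    """Average each architecture's fold models over the test inputs."""
    X = np.asarray(X, dtype=float)
    return {arch: np.mean([m.predict(X) for m in models], axis=0)
            for arch, models in fold_models.items()}


def assemble_meta_features(base_preds: list, weighted_pred, original_X):
    """Concatenate meta features in the fixed block order.

    ``base_preds`` is a list of (name, matrix) pairs; ``weighted_pred`` and
    ``original_X`` may be None when a block is disabled.  Returns
    ``(F, block_map)`` where block_map maps block name → (start, stop).
    """
    blocks, block_map, col = [], {}, 0
    n_rows = None
    parts = [(name, np.asarray(m, dtype=float)) for name, m in base_preds]
    if weighted_pred is not None:
        parts.append(("weighted", np.asarray(weighted_pred, dtype=float)))
    if original_X is not None:
        parts.append(("original", np.asarray(original_X, dtype=float)))
    for name, m in parts:
        if n_rows is None:
            n_rows = len(m)
        elif len(m) != n_rows:
            raise ValueError(f"meta-feature block {name!r} has {len(m)} rows, expected {n_rows}")
        blocks.append(m)
        block_map[name] = (col, col + m.shape[1])
        col += m.shape[1]
    return np.hstack(blocks), block_map


def extract_block(F: np.ndarray, block_map: dict, name: str) -> np.ndarray:
    start, stop = block_map[name]
    return F[:, start:stop]


def fit_meta(F, Y) -> LinearRegression:
    """Ordinary least squares with intercept, one linear map per horizon output."""
    F = np.asarray(F, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if F.shape[0] < F.shape[1]:
        logger.warning("meta design has fewer rows (%d) than columns (%d); "
                       "solution via least-squares pseudoinverse", *F.shape)
    return LinearRegression().fit(F, Y)


def meta_predict(model: LinearRegression, F) -> np.ndarray:
    pred = model.predict(np.asarray(F, dtype=float))
    return pred if pred.ndim == 2 else pred[:, None]


class AWDStackingRegressor(BaseEstimator, RegressorMixin):
    """AWD stacking for a single history window, as a sklearn estimator.

    ``fit(X, Y)`` consumes normalized supervised windows (X: n × history,
    Y: n × horizon) and performs the chronological train/validation split,
    the 5-fold OOF stage, affinity-propagation weighting and the meta fit.
    ``predict(X)`` returns the stacked forecast on the normalized scale.

    Fitted attributes: ``fold_models_``, ``oof_``, ``weights_``,
    ``weighter_``, ``meta_``, ``block_map_``.
    """

    def __init__(self, plan: StackingPlan | None = None):
        self.plan = plan

    def _plan(self) -> StackingPlan:
        return self.plan if self.plan is not None else StackingPlan()

    def fit(self, X, Y):
        plan = self._plan()
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        (X_tr, Y_tr), (X_val, Y_val) = split_train_val(X, Y, plan.val_fraction)
        self.oof_, self.fold_models_ = kfold_oof(
            X_tr, Y_tr, plan, X_val=X_val, y_val=Y_val)
        self.architectures_ = list(self.fold_models_)

        # weights from validation samples in base-model prediction space
        val_preds = test_predictions(self.fold_models_, X_val)
        points = np.column_stack([val_preds[a][:, -1] for a in self.architectures_])
        self.weighter_ = APWeighter(
            similarity_alpha=plan.similarity_alpha, damping=plan.damping,
            sample_cap=plan.sample_cap, invert_flag=plan.invert_flag,
            seed=plan.seed,
        ).fit(points)
        self.weights_ = self.weighter_.weights_

        F, self.block_map_ = self._features(
            {a: self.oof_[a] for a in self.architectures_}, X_tr)
        self.meta_ = fit_meta(F, Y_tr)
        self.n_features_in_ = X.shape[1]
        return self

    def _features(self, preds_by_arch: dict, original_X):
        plan = self._plan()
        base_preds = [(a, preds_by_arch[a]) for a in self.architectures_]
        weighted = None
        if plan.include_weighted_combo:
            weighted = combine_predictions(
                [preds_by_arch[a] for a in self.architectures_], self.weights_).values
        original = original_X if plan.include_original_features else None
        return assemble_meta_features(base_preds, weighted, original)

    def base_predictions(self, X) -> dict:
        """Fold-averaged predictions per architecture (normalized scale)."""
        if not hasattr(self, "fold_models_"):
            raise RuntimeError("estimator is not fitted")
        return test_predictions(self.fold_models_, X)

    def predict(self, X):
        preds = self.base_predictions(np.asarray(X, dtype=float))
        F, _ = self._features(preds, np.asarray(X, dtype=float))
        return meta_predict(self.meta_, F)


# ---------------------------------------------------------------------------
# Full multi-window pipeline
# ---------------------------------------------------------------------------

@dataclass
class WindowResult:
    history_points: int
    stacked: MetricsReport
    base: dict                      # arch -> MetricsReport
    weights: dict                   # arch -> float
    y_true: np.ndarray              # mg/dL, scored horizon step(s)
    y_pred: np.ndarray


@dataclass
class RunResult:
    """Everything a run produced: per-window metrics, their mean, fitted stats."""

    ph_minutes: int
    seed: int
    windows: list = field(default_factory=list)
    mean_metrics: dict = field(default_factory=dict)
    norm_params: tuple = ()
    fitted: dict = field(default_factory=dict)   # leakage-auditable statistics

    def to_manifest(self) -> dict:
        return {
            "ph_minutes": self.ph_minutes,
            "seed": self.seed,
            "norm_params": list(self.norm_params),
            "windows": [
                {
                    "history_points": w.history_points,
                    "stacked": w.stacked.to_dict(),
                    "base": {a: r.to_dict() for a, r in w.base.items()},
                    "weights": {a: float(v) for a, v in w.weights.items()},
                }
                for w in self.windows
            ],
            "mean_metrics": self.mean_metrics,
        }


def run_awd_stacking(train_series: GlucoseSeries, test_series: GlucoseSeries,
                     ph_minutes: int, plan: StackingPlan = StackingPlan(),
                     *, kalman: KalmanConfig = KalmanConfig(),
                     smoothing: SmoothingConfig = SmoothingConfig()) -> RunResult:
    """Run the full pipeline over the four history windows at one horizon."""
    train_p = preprocess_series(train_series, kalman, smoothing)
    test_p = preprocess_series(test_series, kalman, smoothing)

    scaler = MinMaxNormalizer().fit(train_p.values)
    train_n = train_p.with_values(scaler.transform(train_p.values), stage="normalize")
    test_n = test_p.with_values(scaler.transform(test_p.values), stage="normalize")

    result = RunResult(ph_minutes=ph_minutes, seed=plan.seed,
                       norm_params=(scaler.vmin_, scaler.vmax_))
    result.fitted["norm_params"] = (scaler.vmin_, scaler.vmax_)
    step = -1 if plan.metric_step == "final" else slice(None)

    for spec in enumerate_window_specs(ph_minutes):
        train_ds = make_supervised(train_n, spec)
        test_ds = make_supervised(test_n, spec)
        reg = AWDStackingRegressor(plan=plan).fit(train_ds.X, train_ds.Y)

        y_true = scaler.inverse_transform(test_ds.Y[:, step])
        stacked_pred = scaler.inverse_transform(reg.predict(test_ds.X)[:, step])
        ctx = {"ph_minutes": ph_minutes, "history_points": spec.history_points,
               "seed": plan.seed}
        stacked_report = evaluate(np.ravel(y_true), np.ravel(stacked_pred),
                                  context=dict(ctx, model="awd-stacking"))
        base_reports = {}
        for arch, pred in reg.base_predictions(test_ds.X).items():
            base_pred = scaler.inverse_transform(pred[:, step])
            base_reports[arch] = evaluate(np.ravel(y_true), np.ravel(base_pred),
                                          context=dict(ctx, model=arch))
        result.windows.append(WindowResult(
            history_points=spec.history_points,
            stacked=stacked_report,
            base=base_reports,
            weights=dict(zip(reg.architectures_, map(float, reg.weights_))),
            y_true=np.ravel(y_true),
            y_pred=np.ravel(stacked_pred),
        ))
        result.fitted[f"h{spec.history_points}"] = {
            "weights": dict(zip(reg.architectures_, map(float, reg.weights_))),
            "meta_coef": reg.meta_.coef_.copy(),
            "meta_intercept": np.atleast_1d(reg.meta_.intercept_).copy(),
        }

    for key in ("rmse", "mae", "mcc", "band10", "band20"):
        result.mean_metrics[key] = float(np.mean(
            [getattr(w.stacked, key) for w in result.windows]))
    result.mean_metrics["ega_zone_a"] = float(np.mean(
        [w.stacked.ega_zone_fractions["A"] for w in result.windows]))
    for arch in ARCHITECTURES:
        result.mean_metrics[f"rmse_{arch}"] = float(np.mean(
            [w.base[arch].rmse for w in result.windows]))
    return result
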