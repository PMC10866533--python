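"""CGM preprocessing: gap-filling, Kalman filtering, double exponential
smoothing, min–max normalization, chronological train/validation split.

The pipeline order is fixed — gap-fill → Kalman → smoothing → normalize →
split — and enforced via provenance stamps on :class:`GlucoseSeries` when
``strict=True``.

Gap-filling is role-dependent: training series may use information from both
sides of a gap (linear interpolation), whereas test series must remain causal,
so each missing point is linearly extrapolated from the two most recent
observed-or-filled points.

The Kalman filter is the scalar forward filter.  For each observation z_k:

    predict:  x̄ = A·x̂ + B·u          P̄ = A·P·A + Q
    gain:     K = P̄·H / (H·P̄·H + R)
    update:   x̂ = x̄ + K·(z − H·x̄)    P = (1 − K·H)·P̄

Double (Holt) exponential smoothing tracks a level L and trend T:

    L_t = α·Y_t + (1−α)·(L_{t−1} + T_{t−1})
    T_t = β·(L_t − L_{t−1}) + (1−β)·T_{t−1}
    Y'_t = L_t + T_t

with L_1 = Y_1, T_1 = Y_2 − Y_1 (which makes a linear ramp exactly
invariant up to the implied one-step-ahead shift of Y' = L + T).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .series import (
    STEP_MINUTES,
    GlucoseSeries,
    InsufficientDataError,
    snap_to_grid,
)


class ConfigurationError(ValueError):
    """Invalid preprocessing configuration."""


# ---------------------------------------------------------------------------
# Gap filling
# ---------------------------------------------------------------------------

def fill_gaps(series: GlucoseSeries) -> GlucoseSeries:
    """Return the series on an exact 5-minute grid with no missing values.

    Training series: interior gaps are linearly interpolated between the
    nearest observed neighbours (leading gaps are back-filled).  Test series:
    every missing point is extrapolated from the two most recent
    observed-or-filled values, so no future value is ever consulted.
    """
    data = series.data.copy()
    data.index = snap_to_grid(data.index)
    data = data[~data.index.duplicated(keep="first")]
    full_index = pd.date_range(data.index[0], data.index[-1], freq=f"{STEP_MINUTES}min")
    data = data.reindex(full_index)

    if data.notna().sum() < 2:
        raise InsufficientDataError("gap filling needs at least 2 observed points")

    if series.role == "train":
        filled = data.interpolate(method="time", limit_direction="both")
    else:
        values = data.to_numpy(dtype=float)
        first = int(np.flatnonzero(~np.isnan(values))[0])
        values[:first] = values[first]  # leading gap: no past exists, hold level
        for i in range(max(first + 1, 2), len(values)):
            if np.isnan(values[i]):
                values[i] = 2 * values[i - 1] - values[i - 2]
        if len(values) > 1 and np.isnan(values[1]):
            values[1] = values[0]
        filled = pd.Series(values, index=data.index)

    out = GlucoseSeries(
        data=filled,
        patient_id=series.patient_id,
        role=series.role,
        provenance=series.provenance + ("fill_gaps",),
    )
    out.require_gap_free()
    return out


# ---------------------------------------------------------------------------
# Kalman filter
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KalmanConfig:
    """Scalar Kalman filter parameters.

    Defaults model CGM sensor noise of ~2 mg/dL SD (R = 4 (mg/dL)²) with a
    small process noise Q = 0.1 allowing slow physiological drift.  ``x0``
    defaults to the first observation and ``P0`` to R.
    """

    A: float = 1.0
    B: float = 0.0
    u: float = 0.0
    H: float = 1.0
    Q: float = 0.1
    R: float = 4.0
    x0: float | None = None
    P0: float | None = None

    def validate(self) -> None:
        if self.Q < 0 or self.R < 0:
            raise ConfigurationError("Q and R must be nonnegative")
        if self.P0 is not None and self.P0 <= 0:
            raise ConfigurationError("P0 must be positive")


def kalman_filter_values(values: np.ndarray, config: KalmanConfig = KalmanConfig()) -> np.ndarray:
    """Run the scalar forward Kalman recursion over ``values``."""
    config.validate()
    values = np.asarray(values, dtype=float)
    A, B, u, H, Q, R = config.A, config.B, config.u, config.H, config.Q, config.R
    x = float(values[0]) if config.x0 is None else config.x0
    P = config.R if config.P0 is None else config.P0
    if P <= 0:
        P = 1.0
    out = np.empty_like(values)
    for k, z in enumerate(values):
        x_pred = A * x + B * u
        P_pred = A * P * A + Q
        K = P_pred * H / (H * P_pred * H + R)
        x = x_pred + K * (z - H * x_pred)
        P = (1 - K * H) * P_pred
        out[k] = x
    return out


def kalman_smooth(series: GlucoseSeries, config: KalmanConfig = KalmanConfig(),
                  *, strict: bool = False) -> GlucoseSeries:
    """Kalman-filter a gap-free series (same length out)."""
    series.require_stage("fill_gaps", strict=strict)
    series.require_gap_free()
    return series.with_values(kalman_filter_values(series.values, config), stage="kalman")


# ---------------------------------------------------------------------------
# Double exponential smoothing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SmoothingConfig:
    """Holt smoothing coefficients; level α = 0.1, trend β = 0.5 by default."""

    level_alpha: float = 0.1
    trend_beta: float = 0.5

    def validate(self) -> None:
        if not 0 < self.level_alpha < 1:
            raise ConfigurationError("level_alpha must lie strictly in (0, 1)")
        if not 0 < self.trend_beta < 1:
            raise ConfigurationError("trend_beta must lie strictly in (0, 1)")


def double_exp_smooth_values(values: np.ndarray,
                             config: SmoothingConfig = SmoothingConfig()) -> np.ndarray:
    """Holt double exponential smoothing; output Y'_t = L_t + T_t."""
    config.validate()
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise InsufficientDataError("double exponential smoothing needs >= 2 points")
    a, b = config.level_alpha, config.trend_beta
    L = values[0]
    T = values[1] - values[0]
    out = np.empty_like(values)
    out[0] = L + T
    for t in range(1, len(values)):
        L_prev = L
        L = a * values[t] + (1 - a) * (L + T)
        T = b * (L - L_prev) + (1 - b) * T
        out[t] = L + T
    return out


def double_exp_smooth(series: GlucoseSeries, config: SmoothingConfig = SmoothingConfig(),
                      *, strict: bool = False) -> GlucoseSeries:
    """Smooth a gap-free series (same length out)."""
    series.require_stage("kalman", strict=strict)
    series.require_gap_free()
    return series.with_values(double_exp_smooth_values(series.values, config), stage="smooth")


# ---------------------------------------------------------------------------
# Min–max normalization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NormalizationParams:
    """Bounds learned from training data only; vmax must exceed vmin."""

    vmin: float
    vmax: float

    def validate(self) -> None:
        if not self.vmax > self.vmin:
            raise ConfigurationError("degenerate normalization range: vmax must exceed vmin")


def fit_normalizer(train: GlucoseSeries) -> NormalizationParams:
    """Learn min–max bounds from a (training) series."""
    if train.role != "train":
        raise ValueError("normalizer must be fitted on training data")
    params = NormalizationParams(float(np.nanmin(train.values)), float(np.nanmax(train.values)))
    params.validate()
    return params


def normalize(values, params: NormalizationParams) -> np.ndarray:
    """Map mg/dL to (v − vmin)/(vmax − vmin); out-of-range values pass through unclipped."""
    params.validate()
    return (np.asarray(values, dtype=float) - params.vmin) / (params.vmax - params.vmin)


def denormalize(values, params: NormalizationParams) -> np.ndarray:
    params.validate()
    return np.asarray(values, dtype=float) * (params.vmax - params.vmin) + params.vmin


def normalize_series(series: GlucoseSeries, params: NormalizationParams) -> GlucoseSeries:
    return series.with_values(normalize(series.values, params), stage="normalize")


# ---------------------------------------------------------------------------
# Train/validation split (chronological)
# ---------------------------------------------------------------------------

def split_train_val(X: np.ndarray, Y: np.ndarray, val_fraction: float = 0.2):
    """Split windowed samples chronologically; the last 20% become validation.

    Returns ``(X_tr, Y_tr), (X_val, Y_val)``.  The validation size is
    ``floor(val_fraction * n)``.
    """
    n = len(X)
    if len(Y) != n:
        raise ValueError("X and Y row counts differ")
    if n < 10:
        raise InsufficientDataError(f"need at least 10 samples to split, got {n}")
    n_val = int(np.floor(val_fraction * n))
    cut = n - n_val
    return (X[:cut], Y[:cut]), (X[cut:], Y[cut:])


# ---------------------------------------------------------------------------
# sklearn-style transformers and the full series pipeline
# ---------------------------------------------------------------------------

class KalmanSmoother(BaseEstimator, TransformerMixin):
    """Stateless scalar Kalman filter as a sklearn transformer.

    ``transform`` treats each column of X as one time-ordered series.
    """

    def __init__(self, A=1.0, B=0.0, u=0.0, H=1.0, Q=0.1, R=4.0, x0=None, P0=None):
        self.A, self.B, self.u, self.H = A, B, u, H
        self.Q, self.R, self.x0, self.P0 = Q, R, x0, P0

    def _config(self) -> KalmanConfig:
        return KalmanConfig(self.A, self.B, self.u, self.H, self.Q, self.R, self.x0, self.P0)

    def fit(self, X, y=None):
        self._config().validate()
        self.n_features_in_ = 1 if np.ndim(X) == 1 else np.shape(X)[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            return kalman_filter_values(X, self._config())
        return np.column_stack([kalman_filter_values(X[:, j], self._config())
                                for j in range(X.shape[1])])


class DoubleExponentialSmoother(BaseEstimator, TransformerMixin):
    """Holt smoothing as a sklearn transformer (columns = time-ordered series)."""

    def __init__(self, level_alpha=0.1, trend_beta=0.5):
        self.level_alpha = level_alpha
        self.trend_beta = trend_beta

    def _config(self) -> SmoothingConfig:
        return SmoothingConfig(self.level_alpha, self.trend_beta)

    def fit(self, X, y=None):
        self._config().validate()
        self.n_features_in_ = 1 if np.ndim(X) == 1 else np.shape(X)[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            return double_exp_smooth_values(X, self._config())
        return np.column_stack([double_exp_smooth_values(X[:, j], self._config())
                                for j in range(X.shape[1])])


class MinMaxNormalizer(BaseEstimator, TransformerMixin):
    """Min–max scaling fitted on training data; never clips at transform time."""

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.vmin_ = float(np.nanmin(X))
        self.vmax_ = float(np.nanmax(X))
        NormalizationParams(self.vmin_, self.vmax_).validate()
        return self

    @property
    def params_(self) -> NormalizationParams:
        return NormalizationParams(self.vmin_, self.vmax_)

    def transform(self, X):
        return normalize(X, self.params_)

    def inverse_transform(self, X):
        return denormalize(X, self.params_)


def preprocess_series(series: GlucoseSeries,
                      kalman: KalmanConfig = KalmanConfig(),
                      smoothing: SmoothingConfig = SmoothingConfig(),
                      *, strict: bool = True) -> GlucoseSeries:
    """Apply gap-fill → Kalman → double exponential smoothing, in order.

    Normalization is deliberately not part of this helper: its bounds must be
    fitted on the training series and then applied to both splits.
    """
    out = fill_gaps(series)
    out = kalman_smooth(out, kalman, strict=strict)
    out = double_exp_smooth(out, smoothing, strict=strict)
    return out
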