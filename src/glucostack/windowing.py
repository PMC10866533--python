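"""Sliding-window supervised framing.

A preprocessed series of length N becomes N − h − p + 1 stride-1 samples,
each pairing h lagged observations (the history window) with the next p
observations (the forecast horizon).  Supported history lengths are 6, 9, 12
and 18 points (30–90 min at 5-minute cadence) and horizons 6, 9 and 12 points
(prediction horizons of 30, 45 and 60 min).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series import STEP_MINUTES, GlucoseSeries, InsufficientDataError

HISTORY_POINTS = (6, 9, 12, 18)
HORIZON_POINTS = (6, 9, 12)
SUPPORTED_PH_MINUTES = tuple(p * STEP_MINUTES for p in HORIZON_POINTS)  # 30, 45, 60


@dataclass(frozen=True)
class WindowSpec:
    history_points: int
    horizon_points: int
    step_minutes: int = STEP_MINUTES
    stride: int = 1

    def __post_init__(self):
        if self.history_points not in HISTORY_POINTS:
            raise ValueError(f"history_points must be one of {HISTORY_POINTS}")
        if self.horizon_points not in HORIZON_POINTS:
            raise ValueError(f"horizon_points must be one of {HORIZON_POINTS}")
        if self.stride != 1 or self.step_minutes != STEP_MINUTES:
            raise ValueError("only stride 1 at 5-minute cadence is supported")

    @property
    def history_minutes(self) -> int:
        return self.history_points * self.step_minutes

    @property
    def ph_minutes(self) -> int:
        return self.horizon_points * self.step_minutes


@dataclass(frozen=True)
class SupervisedDataset:
    """Windowed sample matrices tied to a :class:`WindowSpec`.

    ``X`` is n_samples × history_points, ``Y`` is n_samples × horizon_points;
    row i of X ends immediately before row i of Y begins.
    """

    X: np.ndarray
    Y: np.ndarray
    spec: WindowSpec
    scale: str = "normalized"   # or "mg_dl"
    origin: str = ""
    role: str = "train"

    def __post_init__(self):
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError("X and Y sample counts differ")
        if self.X.shape[1] != self.spec.history_points:
            raise ValueError("X width does not match spec.history_points")
        if self.Y.shape[1] != self.spec.horizon_points:
            raise ValueError("Y width does not match spec.horizon_points")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]


def sliding_windows(values: np.ndarray, history: int, horizon: int):
    """Return (X, Y) stride-1 window matrices over a 1-D array."""
    values = np.asarray(values, dtype=float)
    n = len(values) - history - horizon + 1
    if n < 1:
        raise InsufficientDataError(
            f"series of length {len(values)} too short for history {history} + "
            f"horizon {horizon}; need at least {history + horizon}"
        )
    window = np.lib.stride_tricks.sliding_window_view(values, history + horizon)[:n]
    return window[:, :history].copy(), window[:, history:].copy()


def make_supervised(series: GlucoseSeries, spec: WindowSpec,
                    *, scale: str = "normalized") -> SupervisedDataset:
    """Frame a gap-free preprocessed series as supervised samples."""
    series.require_gap_free()
    X, Y = sliding_windows(series.values, spec.history_points, spec.horizon_points)
    return SupervisedDataset(X=X, Y=Y, spec=spec, scale=scale,
                             origin=series.patient_id, role=series.role)


def enumerate_window_specs(ph_minutes: int) -> list[WindowSpec]:
    """The four history-window specs used at a given prediction horizon."""
    if ph_minutes not in SUPPORTED_PH_MINUTES:
        raise ValueError(
            f"unsupported prediction horizon {ph_minutes} min; "
            f"supported: {sorted(SUPPORTED_PH_MINUTES)}"
        )
    horizon = ph_minutes // STEP_MINUTES
    return [WindowSpec(h, horizon) for h in HISTORY_POINTS]
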