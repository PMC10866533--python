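"""Timestamped univariate glucose traces.

A :class:`GlucoseSeries` wraps a pandas Series of glucose concentrations
(mg/dL) indexed by timestamps at a nominal 5-minute cadence.  Missing sensor
readings are represented as NaN until gap-filling.  Each series carries a
``role`` (``"train"`` or ``"test"``) because several preprocessing steps are
role-dependent (interpolation vs. causal extrapolation), and a provenance
trail recording which pipeline stages have been applied, in order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

STEP_MINUTES = 5
ROLES = ("train", "test")


class PipelineOrderError(RuntimeError):
    """Raised in strict mode when preprocessing stages are applied out of order."""


class InsufficientDataError(ValueError):
    """Raised when a series is too short for the requested operation."""


@dataclass(frozen=True)
class GlucoseSeries:
    """A univariate CGM trace.

    Parameters
    ----------
    data : pandas.Series
        Glucose values in mg/dL indexed by a DatetimeIndex.  NaN marks a
        missing reading.
    patient_id : str
        Identifier of the subject (synthetic series use ``"synthetic"``).
    role : {"train", "test"}
        Which split the trace belongs to; controls gap-filling semantics.
    provenance : tuple of str
        Ordered names of the preprocessing stages already applied.
    """

    data: pd.Series
    patient_id: str = "synthetic"
    role: str = "train"
    provenance: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        if not isinstance(self.data.index, pd.DatetimeIndex):
            raise TypeError("GlucoseSeries requires a DatetimeIndex")
        if not self.data.index.is_monotonic_increasing or self.data.index.has_duplicates:
            raise ValueError("timestamps must be strictly increasing")

    # -- convenience accessors -------------------------------------------------
    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.data.index

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().sum())

    def with_values(self, values, stage: str | None = None) -> "GlucoseSeries":
        """Return a copy with new values (same index) and an appended stage stamp."""
        values = np.asarray(values, dtype=float)
        if values.shape != (len(self.data),):
            raise ValueError("replacement values must match series length")
        prov = self.provenance + (stage,) if stage else self.provenance
        return replace(self, data=pd.Series(values, index=self.data.index), provenance=prov)

    def require_stage(self, *stages: str, strict: bool = True) -> None:
        """Assert that ``stages`` have already been applied (strict mode only)."""
        if not strict:
            return
        missing = [s for s in stages if s not in self.provenance]
        if missing:
            raise PipelineOrderError(
                f"stages {missing} must run before this operation; "
                f"applied so far: {list(self.provenance)}"
            )

    def require_gap_free(self) -> None:
        if self.data.isna().any():
            raise ValueError("operation requires a gap-free series; run fill_gaps first")


def regular_grid(start: pd.Timestamp, n_points: int) -> pd.DatetimeIndex:
    """A 5-minute grid of ``n_points`` instants anchored at ``start``."""
    return pd.date_range(start=start, periods=n_points, freq=f"{STEP_MINUTES}min")


def snap_to_grid(index: pd.DatetimeIndex) -> pd.DatetimeIndex:
    """Snap timestamps to the 5-minute grid anchored at the first instant.

    Real CGM timestamps jitter by seconds; the pipeline operates on an exact
    grid so that window adjacency is well defined.
    """
    start = index[0]
    offsets = (index - start).total_seconds()
    steps = np.round(offsets / (STEP_MINUTES * 60)).astype(int)
    return start + pd.to_timedelta(steps * STEP_MINUTES, unit="min")
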