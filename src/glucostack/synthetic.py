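"""Synthetic CGM trace generator.

Emulates the gross statistical features of continuous glucose monitoring data
from a type-1-diabetes subject: a 5-minute sampling grid over days to weeks, a
baseline with a circadian oscillation, postprandial excursions at random meal
times, autocorrelated sensor noise, sensor-range clipping, and missing-value
gaps from dropped transmissions.  It makes every downstream stage of the
forecasting pipeline testable without access to clinical data; it does not
model insulin kinetics or any physiological feedback.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .series import STEP_MINUTES, GlucoseSeries, regular_grid

POINTS_PER_DAY = 24 * 60 // STEP_MINUTES  # 288

#: CGM sensor dynamic range, mg/dL.
SENSOR_RANGE = (40.0, 400.0)


class SynthConfigError(ValueError):
    """An invalid synthetic-generator configuration field."""


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic CGM model.

    Defaults describe a plausibly controlled T1D subject: baseline 120 mg/dL,
    a 15 mg/dL circadian swing, three meals a day peaking ~80 mg/dL above
    baseline with a 20-minute rise and 90-minute decay, ~5 mg/dL sensor noise
    with lag-1 autocorrelation 0.5, and 2% dropped readings.  The trace
    regularly crosses the 126 mg/dL glycemic-band boundary, as clinical CGM
    data does.
    """

    duration_days: float = 7.0
    baseline: float = 120.0
    circadian_amplitude: float = 15.0
    meal_rate: float = 3.0          # meals/day (Poisson)
    meal_peak: float = 80.0         # mg/dL above baseline at excursion maximum
    meal_rise_tau: float = 20.0     # minutes
    meal_decay_tau: float = 90.0    # minutes
    noise_sd: float = 5.0           # mg/dL
    noise_ar1: float = 0.5          # lag-1 autocorrelation, in [0, 1)
    missing_fraction: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.duration_days < 1:
            raise SynthConfigError("duration_days: must be >= 1 day")
        nonneg = ("baseline", "circadian_amplitude", "meal_rate", "meal_peak",
                  "meal_rise_tau", "meal_decay_tau", "noise_sd")
        for name in nonneg:
            if getattr(self, name) < 0:
                raise SynthConfigError(f"{name}: must be nonnegative")
        if not 0 <= self.noise_ar1 < 1:
            raise SynthConfigError("noise_ar1: must lie in [0, 1)")
        if not 0 <= self.missing_fraction < 1:
            raise SynthConfigError("missing_fraction: must lie in [0, 1)")
        for f in fields(self):
            if not np.isfinite(getattr(self, f.name)):
                raise SynthConfigError(f"{f.name}: must be finite")


def _meal_impulse(t_min: np.ndarray, rise_tau: float, decay_tau: float) -> np.ndarray:
    """Difference-of-exponentials excursion, normalized to unit peak.

    The shape ``exp(-t/decay) - exp(-t/rise)`` (for decay_tau > rise_tau)
    rises on the fast time constant and decays on the slow one, a standard
    phenomenological stand-in for a postprandial glucose pulse.
    """
    t = np.maximum(t_min, 0.0)
    if rise_tau == decay_tau:  # degenerate: gamma-like t*exp(-t/tau)
        shape = t / decay_tau * np.exp(1.0 - t / decay_tau)
        return np.where(t_min >= 0, shape, 0.0)
    shape = np.exp(-t / decay_tau) - np.exp(-t / rise_tau)
    t_peak = (np.log(decay_tau) - np.log(rise_tau)) / (1 / rise_tau - 1 / decay_tau)
    peak = np.exp(-t_peak / decay_tau) - np.exp(-t_peak / rise_tau)
    return np.where(t_min >= 0, shape / peak, 0.0)


def generate_cgm(
    config: SynthConfig = SynthConfig(),
    *,
    patient_id: str = "synthetic",
    role: str = "train",
    start: str | pd.Timestamp = "2024-01-01 00:00:00",
) -> GlucoseSeries:
    """Generate a seeded synthetic CGM series on an exact 5-minute grid.

    value(t) = baseline
             + circadian_amplitude * sin(2*pi*(hour - 10)/24)   (peak ~16:00)
             + sum of meal excursions at Poisson-process meal times
             + AR(1) sensor noise with stationary SD ``noise_sd``

    clipped to the sensor range [40, 400] mg/dL, after which a Bernoulli
    ``missing_fraction`` of points (never the first two, which gap-filling
    needs as anchors) are blanked to NaN.  The same config and seed always
    produce the identical series.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration_days * POINTS_PER_DAY))
    index = regular_grid(pd.Timestamp(start), n)
    t_min = np.arange(n) * STEP_MINUTES
    hours = (index.hour + index.minute / 60).to_numpy()

    values = np.full(n, config.baseline, dtype=float)
    values += config.circadian_amplitude * np.sin(2 * np.pi * (hours - 10.0) / 24.0)

    # Poisson meal process over the whole duration
    total_minutes = config.duration_days * 24 * 60
    n_meals = rng.poisson(config.meal_rate * config.duration_days)
    meal_times = np.sort(rng.uniform(0, total_minutes, size=n_meals))
    for mt in meal_times:
        values += config.meal_peak * _meal_impulse(
            t_min - mt, config.meal_rise_tau, config.meal_decay_tau
        )

    # AR(1) noise with stationary variance noise_sd**2
    if config.noise_sd > 0:
        innov_sd = config.noise_sd * np.sqrt(1 - config.noise_ar1**2)
        eps = rng.normal(0.0, 1.0, size=n)
        noise = np.empty(n)
        noise[0] = eps[0] * config.noise_sd
        for i in range(1, n):
            noise[i] = config.noise_ar1 * noise[i - 1] + innov_sd * eps[i]
        values += noise

    values = np.clip(values, *SENSOR_RANGE)

    if config.missing_fraction > 0:
        mask = rng.random(n) < config.missing_fraction
        mask[:2] = False  # keep anchors for interpolation/extrapolation
        values = np.where(mask, np.nan, values)

    return GlucoseSeries(
        data=pd.Series(values, index=index),
        patient_id=patient_id,
        role=role,
        provenance=("synthetic",),
    )
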