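"""Shared fixtures: tiny glucose series and a cheap linear base-model factory.

The linear factory stands in for the recurrent base learners in structural
tests (fold bookkeeping, meta-feature assembly, leakage audits) where the
learner's capacity is irrelevant and speed matters.
"""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LinearRegression

from glucostack.series import GlucoseSeries, regular_grid


class LinearBase:
    """Minimal base learner with the fit(X, y, X_val, y_val)/predict contract."""

    def __init__(self, seed=0, jitter=0.0):
        self.seed = seed
        self.jitter = jitter

    def fit(self, X, y, *, X_val=None, y_val=None):
        self._lr = LinearRegression().fit(X, y)
        return self

    def predict(self, X):
        pred = self._lr.predict(np.asarray(X, dtype=float))
        if self.jitter:
            rng = np.random.default_rng(self.seed)
            pred = pred + rng.normal(0, self.jitter, size=pred.shape)
        return pred


@pytest.fixture
def linear_factory():
    def factory(arch, output_dim, seed):
        return LinearBase(seed=seed)
    return factory


def make_series(values, *, role="train", provenance=()):
    values = np.asarray(values, dtype=float)
    index = regular_grid(pd.Timestamp("2024-01-01"), len(values))
    return GlucoseSeries(data=pd.Series(values, index=index), role=role,
                        provenance=tuple(provenance))


@pytest.fixture
def series_factory():
    return make_series
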