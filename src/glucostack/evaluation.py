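"""Clinical evaluation of glucose forecasts.

Numeric accuracy: RMSE and MAE in mg/dL.  Clinical classification accuracy:
the Matthews correlation coefficient over glycemic adverse events, using the
IDF bands low (<70), normal (70–<126) and high (≥126 mg/dL), where low and
high both count as "adverse".  Clinical risk: Clarke error-grid analysis,
which assigns every (reference, predicted) pair to one of five zones A–E by
treatment risk, plus the fraction of predictions inside ±10% and ±20%
relative error bands.

The Clarke zone geometry follows the canonical 1987 rule set; the exact
predicate table ships as JSON (``data/clarke_zones.json``) so variants can
be substituted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

BAND_LOW = 70.0     # mg/dL, exclusive upper bound of hypoglycemia
BAND_HIGH = 126.0   # mg/dL, inclusive lower bound of hyperglycemia


# ---------------------------------------------------------------------------
# Regression errors
# ---------------------------------------------------------------------------

def _paired(y, y_hat):
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if len(y) != len(y_hat):
        raise ValueError(f"length mismatch: {len(y)} vs {len(y_hat)}")
    if len(y) == 0:
        raise ValueError("empty input")
    return y, y_hat


def rmse(y, y_hat) -> float:
    """Root mean square error, mg/dL."""
    y, y_hat = _paired(y, y_hat)
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


def mae(y, y_hat) -> float:
    """Mean absolute error, mg/dL."""
    y, y_hat = _paired(y, y_hat)
    return float(np.mean(np.abs(y - y_hat)))


# ---------------------------------------------------------------------------
# Glycemic bands and MCC
# ---------------------------------------------------------------------------

def classify_bands(values) -> np.ndarray:
    """Map mg/dL values to 'low' (<70), 'normal' (70–<126) or 'high' (>=126)."""
    v = np.asarray(values, dtype=float)
    out = np.where(v < BAND_LOW, "low", np.where(v < BAND_HIGH, "normal", "high"))
    return out if v.ndim else out[()]


def confusion_counts(y, y_hat) -> dict:
    """2×2 confusion over adverse (low or high band) vs normal events."""
    y, y_hat = _paired(y, y_hat)
    actual_adverse = classify_bands(y) != "normal"
    pred_adverse = classify_bands(y_hat) != "normal"
    return {
        "TP": int(np.sum(pred_adverse & actual_adverse)),
        "TN": int(np.sum(~pred_adverse & ~actual_adverse)),
        "FP": int(np.sum(pred_adverse & ~actual_adverse)),
        "FN": int(np.sum(~pred_adverse & actual_adverse)),
    }


def mcc(y, y_hat) -> float:
    """Matthews correlation coefficient over adverse-event classification.

    A zero factor in the denominator (one class absent in either vector)
    yields 0 by the standard convention.
    """
    c = confusion_counts(y, y_hat)
    tp, tn, fp, fn = c["TP"], c["TN"], c["FP"], c["FN"]
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom))


# ---------------------------------------------------------------------------
# Clarke error grid
# ---------------------------------------------------------------------------

def _load_zone_table() -> dict:
    with resources.files("glucostack.data").joinpath("clarke_zones.json").open() as fh:
        return json.load(fh)


_ZONE_TABLE = _load_zone_table()
EGA_ZONES = tuple(_ZONE_TABLE["precedence"])  # ("A", "E", "C", "D", "B")


def _predicate_holds(pred: dict, r: float, p: float) -> bool:
    for key, val in pred.items():
        if key == "ref_min" and not r >= val:
            return False
        elif key == "ref_max" and not r <= val:
            return False
        elif key == "pred_min" and not p >= val:
            return False
        elif key == "pred_max" and not p <= val:
            return False
        elif key == "rel_error_max" and not abs(p - r) <= val * r:
            return False
        elif key == "pred_min_line" and not p >= val["slope"] * r + val["intercept"]:
            return False
        elif key == "pred_max_line" and not p <= val["slope"] * r + val["intercept"]:
            return False
    return True


def clarke_zone(reference: float, predicted: float, *, table: dict | None = None) -> str:
    """Assign one (reference, predicted) mg/dL pair to a Clarke zone."""
    table = table or _ZONE_TABLE
    if reference <= 0 or predicted <= 0:
        raise ValueError("glucose values must be positive")
    for zone in table["precedence"]:
        rules = table["zones"][zone]
        if rules == "otherwise":
            return zone
        if any(_predicate_holds(rule, reference, predicted) for rule in rules):
            return zone
    raise RuntimeError("zone table is not total")  # unreachable with a catch-all


def clarke_ega(reference, predicted, *, table: dict | None = None):
    """Zone labels and zone fractions for paired mg/dL vectors.

    Returns ``(labels, fractions)`` where fractions is a dict over zones A–E
    summing to 1.
    """
    reference, predicted = _paired(reference, predicted)
    labels = np.array([clarke_zone(r, p, table=table)
                       for r, p in zip(reference, predicted)])
    fractions = {z: float(np.mean(labels == z)) for z in sorted(EGA_ZONES)}
    return labels, fractions


def error_band_fraction(reference, predicted, pct: float) -> float:
    """Fraction of pairs with |predicted − reference| ≤ pct% of reference."""
    if pct <= 0:
        raise ValueError("pct must be positive")
    reference, predicted = _paired(reference, predicted)
    return float(np.mean(np.abs(predicted - reference) <= pct / 100.0 * reference))


# ---------------------------------------------------------------------------
# Aggregate report
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetricsReport:
    """All evaluation metrics for one (PH, history-window) cell."""

    rmse: float
    mae: float
    mcc: float
    ega_zone_fractions: dict
    band10: float
    band20: float
    context: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "rmse": self.rmse, "mae": self.mae, "mcc": self.mcc,
            "ega_zone_fractions": dict(self.ega_zone_fractions),
            "band10": self.band10, "band20": self.band20,
            "context": dict(self.context),
        }


def evaluate(reference, predicted, *, context: dict | None = None) -> MetricsReport:
    """Compute the full metrics report on denormalized (mg/dL) values."""
    _, fractions = clarke_ega(reference, predicted)
    return MetricsReport(
        rmse=rmse(reference, predicted),
        mae=mae(reference, predicted),
        mcc=mcc(reference, predicted),
        ega_zone_fractions=fractions,
        band10=error_band_fraction(reference, predicted, 10),
        band20=error_band_fraction(reference, predicted, 20),
        context=context or {},
    )


def plot_ega(reference, predicted, path) -> None:
    """Scatter the error grid and save to ``path`` (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels, fractions = clarke_ega(reference, predicted)
    fig, ax = plt.subplots(figsize=(5, 5))
    for zone, color in zip("ABCDE", ["#2a9d2a", "#7fba7f", "#e0a800", "#e06c00", "#c01414"]):
        mask = labels == zone
        if mask.any():
            ax.scatter(np.asarray(reference)[mask], np.asarray(predicted)[mask],
                       s=6, color=color, label=f"{zone} ({fractions[zone]:.1%})")
    lim = max(400.0, float(np.max(reference)), float(np.max(predicted)))
    ax.plot([0, lim], [0, lim], "k--", lw=0.5)
    ax.set_xlabel("reference glucose (mg/dL)")
    ax.set_ylabel("predicted glucose (mg/dL)")
    ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
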