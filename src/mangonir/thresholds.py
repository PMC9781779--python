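"""Indirect maturity grading by per-parameter threshold intervals.

Each quality parameter carries five intervals, one per maturity index.  TA,
firmness and starch decrease with ripening, SSC increases, so the interval
order along the value axis is reversed between the two groups.  Intervals are
half-open on the value axis, ``(lo, hi]``: a shared printed bound (e.g. TA
0.8, on the edge between the 80% and 85% intervals) belongs to the interval
whose *upper* bound it is, which makes the table a partition of the universe.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from mangonir.data import (
    MATURITY_CLASSES,
    PARAMETER_UNIVERSE,
    PARAMETERS,
)
from mangonir.chemometrics import accuracy_from_confusion, confusion_matrix

# Published cut points between adjacent maturity grades, per parameter.
# For the decreasing parameters the first interval on the value axis is the
# ripest grade (100%); for SSC it is the least ripe (80%).
_CUTS: dict[str, tuple[float, ...]] = {
    "TA": (0.37, 0.45, 0.55, 0.8),
    "SSC": (9.5, 13.5, 19.0, 19.6),
    "firmness": (1.8, 2.9, 3.4, 3.6),
    "starch": (1.95, 3.5, 5.0, 7.2),
}
_DECREASING = ("TA", "firmness", "starch")


@dataclass(frozen=True)
class ThresholdTable:
    """Per-parameter (class, lower, upper] intervals covering the universe."""

    intervals: dict[str, tuple[tuple[int, float, float], ...]] = field(default=None)

    def __post_init__(self) -> None:
        if self.intervals is None:
            object.__setattr__(self, "intervals", _default_intervals())
        for name, rows in self.intervals.items():
            lo_u, hi_u = PARAMETER_UNIVERSE[name]
            bounds = [(lo, hi) for _, lo, hi in rows]
            if bounds[0][0] != lo_u or bounds[-1][1] != hi_u:
                raise ValueError(f"{name} intervals do not span the universe")
            for (_, hi_prev), (lo_next, _) in zip(bounds, bounds[1:]):
                if hi_prev != lo_next:
                    raise ValueError(f"{name} intervals are not contiguous")

    @classmethod
    def default(cls) -> "ThresholdTable":
        return cls()

    def to_json(self) -> str:
        return json.dumps(
            {
                name: [
                    {"class": c, "lower": lo, "upper": hi} for c, lo, hi in rows
                ]
                for name, rows in self.intervals.items()
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ThresholdTable":
        obj = json.loads(text)
        return cls(
            {
                name: tuple(
                    (int(r["class"]), float(r["lower"]), float(r["upper"]))
                    for r in rows
                )
                for name, rows in obj.items()
            }
        )


def _default_intervals() -> dict[str, tuple[tuple[int, float, float], ...]]:
    table = {}
    for name, cuts in _CUTS.items():
        lo_u, hi_u = PARAMETER_UNIVERSE[name]
        edges = (lo_u, *cuts, hi_u)
        classes = (
            tuple(reversed(MATURITY_CLASSES)) if name in _DECREASING else MATURITY_CLASSES
        )
        table[name] = tuple(
            (cls, edges[i], edges[i + 1]) for i, cls in enumerate(classes)
        )
    return table


def classify_by_threshold(
    value: float, parameter: str, table: ThresholdTable | None = None
) -> int:
    """Maturity index whose interval contains ``value`` for this parameter."""
    table = table or ThresholdTable.default()
    if parameter not in table.intervals:
        raise ValueError(f"unknown parameter {parameter!r}")
    lo_u, hi_u = PARAMETER_UNIVERSE[parameter]
    if not np.isfinite(value) or value < lo_u or value > hi_u:
        raise ValueError(f"{parameter}={value} outside universe [{lo_u}, {hi_u}]")
    rows = table.intervals[parameter]
    if value == lo_u:  # bottom edge belongs to the first interval
        return rows[0][0]
    for cls, lo, hi in rows:
        if lo < value <= hi:
            return cls
    raise AssertionError("interval partition must cover the universe")


def evaluate_threshold_route(
    predictions: dict[str, np.ndarray],
    truth: np.ndarray,
    table: ThresholdTable | None = None,
) -> dict[str, dict]:
    """Grade each parameter's predictions and score them against true classes.

    Returns, per parameter, the predicted classes, the 5x5 confusion matrix
    (rows = actual) and the accuracy in percent.
    """
    table = table or ThresholdTable.default()
    truth = np.asarray(truth, dtype=int)
    if truth.size == 0:
        raise ValueError("empty evaluation set")
    out: dict[str, dict] = {}
    for name in PARAMETERS:
        if name not in predictions:
            continue
        values = np.asarray(predictions[name], dtype=float)
        if values.shape != truth.shape:
            raise ValueError(f"{name}: prediction/truth length mismatch")
        lo_u, hi_u = PARAMETER_UNIVERSE[name]
        clipped = np.clip(values, lo_u, hi_u)  # regression can overshoot slightly
        pred_cls = np.array(
            [classify_by_threshold(v, name, table) for v in clipped], dtype=int
        )
        cm = confusion_matrix(truth, pred_cls)
        out[name] = {
            "predicted_classes": pred_cls,
            "confusion": cm,
            "accuracy": accuracy_from_confusion(cm),
        }
    return out
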