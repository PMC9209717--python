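"""Overlap metrics and curve-to-data distance.

Contours are rasterized to binary masks with a pixel-center even-odd
inclusion rule (a pixel at row r, column c is set when its center
(c + 0.5, r + 0.5) falls inside the polygon), then compared pixelwise:
Dice DSC = 2TP/(2TP + FP + FN), Jaccard = TP/(TP + FP + FN), accuracy
ACC = (TP + TN)/all.  The curve-to-data distance delta_f is the mean
squared Euclidean distance from a point set to the (closed) sampled
contour polyline, used to quantify how closely a fitted curve hugs the
data it was built from.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from matplotlib.path import Path

from .ccps import ClosedPolyline, PointSet, _element_distances
from .contour import ContourFunction

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "UndefinedMetricError",
    "rasterize",
    "confusion",
    "dsc",
    "jaccard",
    "accuracy",
    "delta_f",
    "report",
]


class UndefinedMetricError(ZeroDivisionError):
    """Raised when a metric's denominator is zero (e.g. both masks empty)."""


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        for name in ("TP", "FP", "FN", "TN"):
            if getattr(self, name) < 0:
                raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclass(frozen=True)
class MetricsReport:
    dsc: float
    jaccard: float
    acc: float
    delta_f: float | None = None

    def as_dict(self) -> dict:
        out = {"dsc": self.dsc, "jaccard": self.jaccard, "acc": self.acc}
        if self.delta_f is not None:
            out["delta_f"] = self.delta_f
        return out


def _as_bool_mask(mask: np.ndarray) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValueError("mask must be 2-D")
    return arr.astype(bool)


def rasterize(polygon: ClosedPolyline, height: int, width: int) -> np.ndarray:
    """Rasterize a closed polygon to a (height, width) boolean mask with the
    pixel-center inclusion rule (x = column, y = row, 0-based)."""
    if height < 1 or width < 1:
        raise ValueError("frame dimensions must be >= 1")
    cols, rows = np.meshgrid(np.arange(width) + 0.5, np.arange(height) + 0.5)
    centers = np.column_stack([cols.ravel(), rows.ravel()])
    path = Path(polygon.vertices, closed=False)
    inside = path.contains_points(centers).reshape(height, width)
    if not inside.any():
        warnings.warn("polygon does not cover any pixel center", stacklevel=2)
    return inside


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    p = _as_bool_mask(pred)
    g = _as_bool_mask(truth)
    if p.shape != g.shape:
        raise ValueError(f"mask shapes differ: {p.shape} vs {g.shape}")
    return ConfusionCounts(
        TP=int(np.sum(p & g)),
        FP=int(np.sum(p & ~g)),
        FN=int(np.sum(~p & g)),
        TN=int(np.sum(~p & ~g)),
    )


def dsc(c: ConfusionCounts) -> float:
    denom = 2 * c.TP + c.FP + c.FN
    if denom == 0:
        raise UndefinedMetricError("DSC undefined: both masks empty")
    return 2 * c.TP / denom


def jaccard(c: ConfusionCounts) -> float:
    denom = c.TP + c.FP + c.FN
    if denom == 0:
        raise UndefinedMetricError("Jaccard undefined: both masks empty")
    return c.TP / denom


def accuracy(c: ConfusionCounts) -> float:
    if c.total == 0:
        raise UndefinedMetricError("accuracy undefined: empty frame")
    return (c.TP + c.TN) / c.total


def _point_to_polyline_sq(points: np.ndarray, polyline: ClosedPolyline) -> np.ndarray:
    d2 = _element_distances(points, polyline)
    return d2.min(axis=1)


def delta_f(
    fn: ContourFunction | ClosedPolyline,
    points: PointSet,
    samples: int = 360,
) -> float:
    """Mean squared Euclidean distance from the points to the contour.

    ``fn`` may be a fitted contour function (sampled at ``samples``
    parameter values and measured point-to-polyline) or an explicit closed
    polyline.  Distances are taken in whatever coordinate frame the inputs
    share; the pipeline reports it in normalized units.
    """
    if isinstance(fn, ClosedPolyline):
        poly = fn
    else:
        if samples < 32:
            raise ValueError("need at least 32 samples")
        t = np.arange(samples) / samples
        pts = np.atleast_2d(fn.evaluate_normalized(t))
        # drop coincident consecutive samples to keep the polyline valid
        keep = np.ones(pts.shape[0], dtype=bool)
        keep[1:] = np.any(pts[1:] != pts[:-1], axis=1)
        poly = ClosedPolyline(pts[keep])
    return float(_point_to_polyline_sq(points.xy, poly).mean())


def report(
    pred_mask: np.ndarray,
    truth_mask: np.ndarray,
    delta_f_value: float | None = None,
) -> MetricsReport:
    c = confusion(pred_mask, truth_mask)
    return MetricsReport(dsc(c), jaccard(c), accuracy(c), delta_f_value)
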