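"""Closed-form parametric contour assembled from trained network weights.

The trained network gives outputs g_x(t), g_y(t) in (-1, 1); the contour
map sends each through the output transform (algebraically (1 + g)/2, the
removable-singularity simplification of the printed rational form), then
inverts the min-max target scaling and the Z-score normalization, yielding
pixel coordinates.  Because every step is an explicit formula in the
4q + 2 network coefficients, the whole contour is a human-readable
parametric expression f(t) = (x(t), y(t)) that can be exported as text and
re-evaluated independently of this package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ccps import ClosedPolyline, NormalizationParams, VertexSequence, denormalize
from .network import ABPNNParams, forward

__all__ = [
    "CoordinateScaler",
    "ContourFunction",
    "map_output",
    "sample_closed_contour",
    "expression_text",
    "DegenerateContourError",
]


class DegenerateContourError(RuntimeError):
    """Raised when a sampled contour collapses to fewer than 3 distinct points."""


@dataclass(frozen=True)
class CoordinateScaler:
    """Min-max map between normalized coordinates and the trainable range.

    Targets are squeezed into [margin, 1 - margin] per axis so they stay
    strictly reachable by the mapped network output (1 + tanh)/2 in (0, 1).
    Carries the Z-score parameters so a contour can be pushed all the way
    back to pixels.
    """

    x_min: float
    x_max: float
    y_min: float
    y_max: float
    margin: float = 0.1
    norm_params: NormalizationParams | None = None

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError("scaler needs max > min on both axes")
        if not 0 <= self.margin < 0.5:
            raise ValueError("margin must lie in [0, 0.5)")

    @classmethod
    def from_sequence(cls, seq: VertexSequence, margin: float = 0.1) -> "CoordinateScaler":
        xy = seq.xy
        return cls(
            float(xy[:, 0].min()),
            float(xy[:, 0].max()),
            float(xy[:, 1].min()),
            float(xy[:, 1].max()),
            margin,
            seq.norm_params,
        )

    @property
    def _mins(self) -> np.ndarray:
        return np.array([self.x_min, self.y_min])

    @property
    def _spans(self) -> np.ndarray:
        return np.array([self.x_max - self.x_min, self.y_max - self.y_min])

    def scale(self, xy: np.ndarray) -> np.ndarray:
        """Normalized coordinates -> [margin, 1 - margin]^2."""
        unit = (np.asarray(xy, dtype=float) - self._mins) / self._spans
        return self.margin + unit * (1.0 - 2.0 * self.margin)

    def inverse(self, mapped: np.ndarray) -> np.ndarray:
        """[margin, 1 - margin]^2 (or anywhere in (0,1)) -> normalized."""
        unit = (np.asarray(mapped, dtype=float) - self.margin) / (1.0 - 2.0 * self.margin)
        return self._mins + unit * self._spans

    def to_pixels(self, mapped: np.ndarray) -> np.ndarray:
        norm = self.inverse(mapped)
        if self.norm_params is None:
            return norm
        return denormalize(norm, self.norm_params)

    def pixel_affine(self) -> tuple[np.ndarray, np.ndarray]:
        """Coefficients (scale, offset) of the affine map from the network's
        mapped output in (0, 1) straight to pixels: pixel = scale*u + offset."""
        span = self._spans / (1.0 - 2.0 * self.margin)
        offset = self._mins - span * self.margin
        if self.norm_params is not None:
            sigma = self.norm_params.sigma
            mu = self.norm_params.mu
            return span * sigma, offset * sigma + mu
        return span, np.array(offset)


def map_output(g) -> np.ndarray:
    """Output transform taking the tanh output in (-1, 1) to a coordinate in
    (0, 1).  The rational closed form (g + 1 - (1 - g^2)) / (2 g) simplifies
    to (1 + g)/2, removing the singularity at g = 0."""
    g_arr = np.asarray(g, dtype=float)
    if np.any(np.abs(g_arr) >= 1):
        raise ValueError("|g| must be < 1")
    return (1.0 + g_arr) / 2.0


@dataclass(frozen=True)
class ContourFunction:
    """The fitted parametric contour f(t) = (x(t), y(t)) in pixel space."""

    params: ABPNNParams
    scaler: CoordinateScaler
    resolution: int = 360

    def evaluate_mapped(self, t) -> np.ndarray:
        """Network output pushed through the (1 + g)/2 map; stays in (0,1)."""
        return map_output(forward(self.params, t))

    def evaluate_normalized(self, t) -> np.ndarray:
        return self.scaler.inverse(self.evaluate_mapped(t))

    def evaluate(self, t) -> np.ndarray:
        """Pixel coordinates of the contour at parameter t (scalar or array)."""
        return self.scaler.to_pixels(self.evaluate_mapped(t))

    def __call__(self, t) -> np.ndarray:
        return self.evaluate(t)


def sample_closed_contour(fn: ContourFunction, N: int | None = None) -> ClosedPolyline:
    """Sample the contour at t = 0, 1/N, ..., (N-1)/N into a closed polygon
    with canonical (counterclockwise) orientation.  Coincident consecutive
    samples are dropped."""
    N = N or fn.resolution
    if N < 8:
        raise ValueError("need at least 8 samples")
    t = np.arange(N) / N
    pts = np.atleast_2d(fn.evaluate(t))
    keep = np.ones(N, dtype=bool)
    keep[1:] = np.any(pts[1:] != pts[:-1], axis=1)
    pts = pts[keep]
    if pts.shape[0] > 1 and np.all(pts[-1] == pts[0]):
        pts = pts[:-1]
    if np.unique(pts, axis=0).shape[0] < 3:
        raise DegenerateContourError("sampled contour has fewer than 3 distinct points")
    poly = ClosedPolyline(pts)
    if not poly.is_ccw():
        poly = ClosedPolyline(pts[::-1])
    return poly


def _fmt(value: float) -> str:
    return repr(float(value))


def _axis_expression(params: ABPNNParams, k: int) -> str:
    """Fully inlined expression of the k-th mapped output as a function of t."""
    terms = []
    for i in range(params.q):
        w = _fmt(params.omega[i])
        T = _fmt(params.T[i])
        a = _fmt(params.A[i, k])
        terms.append(f"{a}/(1 + exp(-({w}*t - {T})))")
    inner = " + ".join(terms)
    b = _fmt(params.b[k])
    return f"(1 + tanh({inner} - {b}))/2"


def expression_text(params: ABPNNParams, scaler: CoordinateScaler | None = None) -> str:
    """Render the contour as a human-readable parametric expression.

    The core lines inline all 4q + 2 network coefficients; when a scaler is
    given, two further affine lines map the unit-square coordinates to
    pixels so the text reproduces ``ContourFunction.evaluate`` exactly.
    """
    lines = [
        "# Parametric closed contour, t in [0, 1]",
        f"x(t) = {_axis_expression(params, 0)}",
        f"y(t) = {_axis_expression(params, 1)}",
    ]
    if scaler is not None:
        scale, offset = scaler.pixel_affine()
        lines += [
            "# Pixel coordinates",
            f"X(t) = {_fmt(scale[0])}*x(t) + {_fmt(offset[0])}",
            f"Y(t) = {_fmt(scale[1])}*y(t) + {_fmt(offset[1])}",
        ]
    return "\n".join(lines) + "\n"


def parse_expression(text: str):
    """Re-build callables from an exported expression (the dual path used in
    tests and by the ``express`` CLI round-trip).

    Returns a dict mapping names ('x', 'y' and, when present, 'X', 'Y') to
    functions of t.
    """
    env = {"exp": np.exp, "tanh": np.tanh, "__builtins__": {}}
    fns: dict = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, rhs = line.split("=", 1)
        name = name.split("(")[0].strip()
        rhs = rhs.strip()
        if name in ("x", "y"):
            fns[name] = _make_fn(rhs, env)
        elif name in ("X", "Y"):
            base = fns[name.lower()]
            fns[name] = _make_affine_fn(rhs, env, name.lower(), base)
    return fns


def _make_fn(rhs: str, env: dict):
    code = compile(rhs, "<contour-expression>", "eval")
    return lambda t: eval(code, dict(env), {"t": np.asarray(t, dtype=float)})


def _make_affine_fn(rhs: str, env: dict, varname: str, base):
    rhs = rhs.replace(f"{varname}(t)", "_base")
    code = compile(rhs, "<contour-expression>", "eval")
    return lambda t: eval(code, dict(env), {"t": np.asarray(t, dtype=float), "_base": base(t)})
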