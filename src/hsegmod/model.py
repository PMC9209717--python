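"""Model/Results front end for the two-stage contour segmentation.

``HSegMod`` is constructed from seed points (plus an optional image frame)
and ``fit()`` runs both stages — the closed polygonal principal-curve fit
and the evolution-initialized network training — returning an
``HSegModResults`` that carries the fitted contour, its closed-form
expression, the fit traces, and evaluation helpers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import metrics as _metrics
from .ccps import (
    CCPSConfig,
    ClosedPolyline,
    FitTrace,
    PointSet,
    VertexSequence,
    fit_ccps,
)
from .contour import (
    ContourFunction,
    CoordinateScaler,
    expression_text,
    sample_closed_contour,
)
from .network import ABPNNParams, TrainConfig, TrainingTrace, train

__all__ = ["HSegMod", "HSegModResults"]


class HSegMod:
    """Semi-automatic closed-contour segmentation model.

    Parameters
    ----------
    points : PointSet or (n, 2) array
        Unordered boundary seed points in pixel coordinates (n >= 8).
    frame_shape : (height, width), optional
        Pixel grid of the source image; required for mask-based evaluation.
    ccps_config, train_config : optional stage configurations.
    """

    def __init__(
        self,
        points,
        frame_shape: tuple[int, int] | None = None,
        ccps_config: CCPSConfig | None = None,
        train_config: TrainConfig | None = None,
    ) -> None:
        self.points = points if isinstance(points, PointSet) else PointSet(np.asarray(points, dtype=float))
        if self.points.n < 8:
            raise ValueError("need at least 8 seed points")
        self.frame_shape = frame_shape
        self.ccps_config = ccps_config or CCPSConfig()
        self.train_config = train_config or TrainConfig()

    @classmethod
    def from_dataframe(cls, df, **kwargs) -> "HSegMod":
        """Build from a DataFrame with columns 'x' and 'y' (pixel units)."""
        return cls(df[["x", "y"]].to_numpy(dtype=float), **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "HSegMod":
        from .io import read_seed_points

        return cls(read_seed_points(path), **kwargs)

    def fit(self, seed: int | None = None) -> "HSegModResults":
        """Run both stages and return the results object.

        ``seed`` overrides the seed of the training configuration and makes
        the whole pipeline bit-reproducible.
        """
        rng = np.random.default_rng(seed if seed is not None else self.train_config.seed)
        curve, sequence, ccps_trace = fit_ccps(self.points, self.ccps_config, rng)
        scaler = CoordinateScaler.from_sequence(sequence)
        params, training_trace = train(sequence, self.train_config, rng, scaler)
        contour = ContourFunction(params, scaler)
        return HSegModResults(
            model=self,
            params=params,
            scaler=scaler,
            contour=contour,
            vertex_sequence=sequence,
            ccps_curve=curve,
            ccps_trace=ccps_trace,
            training_trace=training_trace,
            seed=seed,
        )


@dataclass
class HSegModResults:
    """Fitted contour plus diagnostics."""

    model: HSegMod
    params: ABPNNParams
    scaler: CoordinateScaler
    contour: ContourFunction
    vertex_sequence: VertexSequence
    ccps_curve: ClosedPolyline
    ccps_trace: FitTrace
    training_trace: TrainingTrace
    seed: int | None = None

    def predict(self, t) -> np.ndarray:
        """Pixel coordinates of the fitted contour at parameter t."""
        return self.contour.evaluate(t)

    def sample(self, N: int = 360) -> ClosedPolyline:
        """Closed pixel-space polygon sampled from the fitted contour."""
        return sample_closed_contour(self.contour, N)

    def expression(self) -> str:
        """Closed-form parametric expression of the contour."""
        return expression_text(self.params, self.scaler)

    def delta_f(self, points: PointSet | None = None, samples: int = 360) -> float:
        """Mean squared distance (normalized units) from the seed points
        (or any supplied pixel-space point set) to the fitted contour."""
        pts = points or self.model.points
        norm = self.vertex_sequence.norm_params
        normalized = PointSet((pts.xy - norm.mu) / norm.sigma)
        return _metrics.delta_f(self.contour, normalized, samples)

    def predicted_mask(self, frame_shape: tuple[int, int] | None = None) -> np.ndarray:
        shape = frame_shape or self.model.frame_shape
        if shape is None:
            raise ValueError("no frame shape available; pass frame_shape")
        return _metrics.rasterize(self.sample(), *shape)

    def evaluate(
        self,
        truth,
        frame_shape: tuple[int, int] | None = None,
    ) -> _metrics.MetricsReport:
        """Overlap metrics against a truth mask (2-D array) or contour."""
        shape = frame_shape or self.model.frame_shape
        if isinstance(truth, ClosedPolyline):
            if shape is None:
                raise ValueError("evaluating against a contour needs a frame shape")
            truth_mask = _metrics.rasterize(truth, *shape)
        else:
            truth_mask = np.asarray(truth).astype(bool)
            shape = truth_mask.shape
        pred = _metrics.rasterize(self.sample(), *shape)
        return _metrics.report(pred, truth_mask, self.delta_f())

    def summary(self) -> str:
        tr = self.training_trace
        cc = self.ccps_trace
        final_delta_n = cc.iterations[-1][2] if cc.iterations else float("nan")
        rows = [
            ("Seed points", self.model.points.n),
            ("Curve vertices", self.ccps_curve.n_vertices),
            ("Outer iterations", len(cc.iterations)),
            ("Final mean sq proj dist", f"{final_delta_n:.6g}"),
            ("Stop reason", cc.stop_reason),
            ("Hidden neurons", self.params.q),
            ("Init error (evolutionary search)", f"{tr.init_fitness:.6g}"),
            ("Final training error", f"{tr.final_error:.6g}"),
            ("Best epoch", tr.best_epoch),
            ("Delta_f (seed points, normalized)", f"{self.delta_f():.6g}"),
            ("Seed", self.seed),
        ]
        width = max(len(str(k)) for k, _ in rows)
        lines = ["Closed-contour segmentation results", "=" * 46]
        lines += [f"{str(k):<{width}}  {v}" for k, v in rows]
        return "\n".join(lines)

    def plot(self, ax=None, image: np.ndarray | None = None, truth: ClosedPolyline | None = None):
        """Overlay of seed points, stage-1 vertices, and the fitted contour."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if image is not None:
            ax.imshow(image, cmap="gray")
        pts = self.model.points.xy
        ax.scatter(pts[:, 0], pts[:, 1], s=12, c="tab:orange", label="seed points")
        verts = self.vertex_sequence.pixel_xy()
        ax.plot(verts[:, 0], verts[:, 1], "g.--", lw=0.8, label="principal curve")
        poly = self.sample().vertices
        closed = np.vstack([poly, poly[:1]])
        ax.plot(closed[:, 0], closed[:, 1], "b-", lw=1.5, label="fitted contour")
        if truth is not None:
            tv = np.vstack([truth.vertices, truth.vertices[:1]])
            ax.plot(tv[:, 0], tv[:, 1], "r-", lw=1.0, label="truth")
        ax.set_aspect("equal")
        ax.invert_yaxis()
        ax.legend(loc="best", fontsize=8)
        return ax

    def save(self, path) -> None:
        from .io import write_model

        write_model(path, self.params, self.scaler, {"seed": self.seed})
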