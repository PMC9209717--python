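"""Synthetic closed organ-like contours, masks, and seed points.

Ground truth is a star-shaped radial-harmonic contour
``r(theta) = r0 * (1 + sum_k eps_k cos(k*theta + phi_k))``, k = 2..5, which
mimics the smooth but non-elliptical cross-sections of soft organs in
ultrasound while the bound ``sum |eps_k| <= 0.3`` keeps the polygon simple.
Radiologist-like seed points are a sparse subsample of the dense truth
contour with Gaussian jitter; the "near-contour" placement jitters
isotropically, the "offset" placement additionally pushes points outward
(three times the jitter scale, half-normal) the way picks drift toward
bright shadow boundaries.  Everything is reproducible from a seed, so the
whole pipeline is testable without any imaging data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon

from .ccps import ClosedPolyline, PointSet
from .metrics import rasterize

__all__ = [
    "ShapeSpec",
    "make_truth_contour",
    "sample_seed_points",
    "make_mask",
    "make_fixture",
    "random_spec",
    "InvalidSpecError",
]

PLACEMENTS = ("near-contour", "offset")


class InvalidSpecError(ValueError):
    """Raised when a shape specification yields a non-simple contour."""


@dataclass(frozen=True)
class ShapeSpec:
    """Radial-harmonic shape: center and base radius in pixels, harmonic
    amplitudes eps[k] and phases phi[k] for k = 2..5, frame size."""

    center: tuple[float, float] = (128.0, 128.0)
    r0: float = 80.0
    eps: tuple[float, float, float, float] = (0.1, 0.0, 0.0, 0.0)
    phases: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    height: int = 256
    width: int = 256

    def __post_init__(self) -> None:
        if len(self.eps) != 4 or len(self.phases) != 4:
            raise ValueError("eps and phases must cover harmonics k = 2..5")
        if sum(abs(e) for e in self.eps) > 0.3:
            raise InvalidSpecError("sum of |eps_k| must not exceed 0.3")
        if self.r0 < 20:
            raise ValueError("base radius must be at least 20 px")
        r_max = self.r0 * (1 + sum(abs(e) for e in self.eps))
        cx, cy = self.center
        if (cx - r_max < 0 or cy - r_max < 0
                or cx + r_max > self.width or cy + r_max > self.height):
            raise ValueError("contour does not fit inside the frame")


def make_truth_contour(spec: ShapeSpec, n_vertices: int = 512) -> ClosedPolyline:
    """Dense counterclockwise polygon of the radial-harmonic shape."""
    if n_vertices < 512:
        raise ValueError("truth contour must have at least 512 vertices")
    theta = 2 * np.pi * np.arange(n_vertices) / n_vertices
    r = np.full_like(theta, spec.r0)
    for k, (eps_k, phi_k) in enumerate(zip(spec.eps, spec.phases), start=2):
        r = r + spec.r0 * eps_k * np.cos(k * theta + phi_k)
    x = spec.center[0] + r * np.cos(theta)
    y = spec.center[1] + r * np.sin(theta)
    poly = ClosedPolyline(np.column_stack([x, y]))
    if not Polygon(poly.vertices).is_valid:
        raise InvalidSpecError("shape specification produced a self-intersecting contour")
    return poly


def sample_seed_points(
    contour: ClosedPolyline,
    fraction: float,
    jitter_sigma: float,
    placement: str = "near-contour",
    rng: np.random.Generator | int | None = None,
) -> PointSet:
    """Subsample ceil(fraction * V) contour points and jitter them.

    ``near-contour``: isotropic Gaussian jitter of jitter_sigma pixels.
    ``offset``: the same isotropic jitter plus an outward half-normal shift
    of scale 3 * jitter_sigma along the radial direction.
    """
    if not 0 < fraction <= 0.5:
        raise ValueError("fraction must lie in (0, 0.5]")
    if placement not in PLACEMENTS:
        raise ValueError(f"placement must be one of {PLACEMENTS}")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    V = contour.n_vertices
    k = math.ceil(fraction * V)
    if k < 8:
        raise ValueError(f"fraction {fraction} yields only {k} points; need >= 8")
    idx = (np.arange(k) * V // k).astype(int)
    pts = contour.vertices[idx].copy()
    pts += rng.normal(0.0, jitter_sigma, size=pts.shape) if jitter_sigma > 0 else 0.0
    if placement == "offset":
        center = contour.vertices.mean(axis=0)
        radial = pts - center
        norms = np.linalg.norm(radial, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        outward = radial / norms
        shift = np.abs(rng.normal(0.0, 3.0 * jitter_sigma, size=(k, 1)))
        pts = pts + shift * outward
    return PointSet(pts)


def make_mask(contour: ClosedPolyline, height: int, width: int) -> np.ndarray:
    """Ground-truth mask via the canonical pixel-center rasterization."""
    return rasterize(contour, height, width)


def make_fixture(
    spec: ShapeSpec | None = None,
    fraction: float = 0.08,
    jitter_sigma: float = 1.0,
    placement: str = "near-contour",
    rng: np.random.Generator | int | None = None,
) -> tuple[PointSet, ClosedPolyline, np.ndarray]:
    """Bundle: (seed points, truth contour, truth mask), reproducible per seed."""
    spec = spec or ShapeSpec()
    contour = make_truth_contour(spec)
    seeds = sample_seed_points(contour, fraction, jitter_sigma, placement, rng)
    mask = make_mask(contour, spec.height, spec.width)
    return seeds, contour, mask


def random_spec(rng: np.random.Generator | int | None = None,
                height: int = 256, width: int = 256) -> ShapeSpec:
    """Draw a random valid organ-like shape.

    Base radius 60-90 px, centered with slack inside the frame.  Harmonic
    amplitudes decay as k^-2 (the Fourier spectrum of a smooth closed
    curve), with a random total amplitude in [0.08, 0.22] distributed with
    random sign and phase — mostly ellipticity plus mild higher-order
    asymmetry, like soft-organ cross-sections, never multi-lobed flowers.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    r0 = float(rng.uniform(60, 90))
    k = np.arange(2, 6)
    amps = rng.uniform(0.5, 1.0, size=4) / k**2
    amps = amps / amps.sum() * rng.uniform(0.08, 0.22)
    signs = rng.choice([-1.0, 1.0], size=4)
    eps = tuple(float(a * s) for a, s in zip(amps, signs))
    phases = tuple(float(p) for p in rng.uniform(0, 2 * np.pi, size=4))
    r_max = r0 * (1 + sum(abs(e) for e in eps))
    cx = float(rng.uniform(r_max + 2, width - r_max - 2))
    cy = float(rng.uniform(r_max + 2, height - r_max - 2))
    return ShapeSpec((cx, cy), r0, eps, phases, height, width)
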