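"""Constrained closed polygonal principal-curve fitting (CCPS).

Stage 1 of the segmentation pipeline: an unordered cloud of boundary seed
points is summarized by a *closed* polygonal principal curve.  The fitter
alternates point-to-curve projection, local vertex optimization, vertex
filtering, and vertex insertion, starting from a small closed square in
Z-score-normalized coordinates, until a segment-count bound or a
distance-improvement tolerance stops it.  The ordered vertices are then
emitted as a (t, x, y) sequence that the network stage consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PointSet",
    "NormalizationParams",
    "ClosedPolyline",
    "Projection",
    "CCPSConfig",
    "VertexSequence",
    "DegenerateVarianceError",
    "NoSplittableSegmentError",
    "zscore_normalize",
    "denormalize",
    "init_square",
    "project_points",
    "data_radius",
    "optimize_vertices",
    "insert_vertex",
    "filter_vertices",
    "stop_whole_loop",
    "fit_ccps",
    "to_vertex_sequence",
]


class DegenerateVarianceError(ValueError):
    """Raised when a coordinate axis has zero spread and cannot be Z-scored."""


class NoSplittableSegmentError(RuntimeError):
    """Raised when no segment has enough projected points to host a new vertex."""


@dataclass(frozen=True)
class PointSet:
    """Unordered 2-D points in pixel (or normalized) coordinates.

    ``xy`` is an (n, 2) float array; column 0 is x (image column), column 1
    is y (image row).
    """

    xy: np.ndarray

    def __post_init__(self) -> None:
        xy = np.asarray(self.xy, dtype=float)
        if xy.ndim != 2 or xy.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        if not np.all(np.isfinite(xy)):
            raise ValueError("points contain non-finite coordinates")
        object.__setattr__(self, "xy", xy)

    @property
    def n(self) -> int:
        return self.xy.shape[0]

    def centroid(self) -> np.ndarray:
        return self.xy.mean(axis=0)


@dataclass(frozen=True)
class NormalizationParams:
    """Per-axis mean and population standard deviation of a Z-score map."""

    mu_x: float
    mu_y: float
    sigma_x: float
    sigma_y: float

    def __post_init__(self) -> None:
        if not (self.sigma_x > 0 and self.sigma_y > 0):
            raise DegenerateVarianceError("standard deviations must be positive")

    @property
    def mu(self) -> np.ndarray:
        return np.array([self.mu_x, self.mu_y])

    @property
    def sigma(self) -> np.ndarray:
        return np.array([self.sigma_x, self.sigma_y])


@dataclass(frozen=True)
class ClosedPolyline:
    """Ordered polygon vertices; the edge from the last vertex back to the
    first is implicit, so the curve is always closed."""

    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValueError("vertices must be an (m, 2) array")
        if v.shape[0] < 3:
            raise ValueError("a closed polyline needs at least 3 vertices")
        if not np.all(np.isfinite(v)):
            raise ValueError("vertices contain non-finite coordinates")
        nxt = np.roll(v, -1, axis=0)
        if np.any(np.all(v == nxt, axis=1)):
            raise ValueError("consecutive vertices must be distinct")
        object.__setattr__(self, "vertices", v)

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_segments(self) -> int:
        return self.vertices.shape[0]

    def signed_area(self) -> float:
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    def is_ccw(self) -> bool:
        return self.signed_area() > 0

    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.roll(self.vertices, -1, axis=0) - self.vertices, axis=1)


@dataclass(frozen=True)
class Projection:
    """Nearest-element assignment of every point to a vertex or segment.

    ``kind[i]`` is 0 if point i projects onto a vertex, 1 if onto a segment
    interior; ``index[i]`` is the vertex/segment index.  Ties between
    elements break toward the lower element index (all vertices precede all
    segments in the element ordering).
    """

    kind: np.ndarray
    index: np.ndarray
    sqdist: np.ndarray
    vertex_counts: np.ndarray
    segment_counts: np.ndarray
    points: np.ndarray

    @property
    def delta_n(self) -> float:
        """Mean squared projection distance over all points."""
        return float(self.sqdist.mean())

    @property
    def total(self) -> float:
        return float(self.sqdist.sum())


@dataclass(frozen=True)
class CCPSConfig:
    """Tuning constants of the fitter.

    beta_stop is the whole-loop constant of the segment-count bound;
    delta_s the maximum distance deviation for inner/outer convergence;
    min_projected_points the vertex-filter count threshold; max_segments a
    safety cap on the vertex count.
    """

    beta_stop: float = 0.3
    delta_s: float = 0.002
    min_projected_points: int = 5
    max_segments: int = 50
    max_inner_sweeps: int = 100

    def __post_init__(self) -> None:
        if self.beta_stop <= 0 or self.delta_s <= 0:
            raise ValueError("beta_stop and delta_s must be positive")
        if self.min_projected_points < 1:
            raise ValueError("min_projected_points must be >= 1")


@dataclass(frozen=True)
class VertexSequence:
    """Ordered (t, x, y) training triples in normalized coordinates.

    t is strictly increasing on [0, 1]; the last entry duplicates the first
    vertex at t = 1 so the closure is part of the training target.
    """

    t: np.ndarray
    xy: np.ndarray
    norm_params: NormalizationParams

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        xy = np.asarray(self.xy, dtype=float)
        if t.ndim != 1 or xy.shape != (t.size, 2):
            raise ValueError("t must be (m,) and xy (m, 2)")
        if t.size < 4:
            raise ValueError("a vertex sequence needs at least 4 entries")
        if not (t[0] == 0.0 and t[-1] == 1.0):
            raise ValueError("t must start at 0 and end at 1")
        if np.any(np.diff(t) <= 0):
            raise ValueError("t must be strictly increasing")
        if not np.allclose(xy[0], xy[-1]):
            raise ValueError("last entry must duplicate the first (closure)")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "xy", xy)

    @property
    def n_entries(self) -> int:
        return self.t.size

    def pixel_xy(self) -> np.ndarray:
        return denormalize(self.xy, self.norm_params)


@dataclass
class FitTrace:
    """Per-outer-iteration record of the fit: vertex count and mean squared
    projection distance, plus any vertex-filter warnings."""

    iterations: list = field(default_factory=list)
    warnings: list = field(default_factory=list)
    stop_reason: str = ""

    def log(self, iteration: int, n_vertices: int, delta_n: float) -> None:
        self.iterations.append((iteration, n_vertices, delta_n))

    def delta_n_history(self) -> np.ndarray:
        return np.array([row[2] for row in self.iterations])

    def lines(self) -> list:
        return [f"{i}, {m}, {d:.6g}" for i, m, d in self.iterations]


def zscore_normalize(points: PointSet) -> tuple[PointSet, NormalizationParams]:
    """Z-score each axis to mean 0 and population standard deviation 1."""
    if points.n < 8:
        raise ValueError(f"need at least 8 seed points, got {points.n}")
    mu = points.xy.mean(axis=0)
    sigma = points.xy.std(axis=0)  # population SD (ddof=0)
    if sigma[0] <= 0 or sigma[1] <= 0:
        raise DegenerateVarianceError(
            "seed points have zero spread on at least one axis"
        )
    params = NormalizationParams(mu[0], mu[1], sigma[0], sigma[1])
    return PointSet((points.xy - mu) / sigma), params


def denormalize(xy: np.ndarray, params: NormalizationParams) -> np.ndarray:
    """Map Z-scored coordinates back to pixel coordinates."""
    return np.asarray(xy, dtype=float) * params.sigma + params.mu


def init_square() -> ClosedPolyline:
    """The initial principal curve: a small closed square about the origin
    of the normalized coordinate frame, traversed counterclockwise."""
    return ClosedPolyline(
        np.array([[0.1, 0.1], [-0.1, 0.1], [-0.1, -0.1], [0.1, -0.1]])
    )


def _element_distances(points: np.ndarray, curve: ClosedPolyline) -> np.ndarray:
    """Squared distances from every point to every element.

    Returns an (n, 2m) array: columns 0..m-1 are vertices, m..2m-1 are
    segment *interiors* (inf where the perpendicular foot falls outside the
    open segment, so endpoints are claimed by the vertex columns).
    """
    v = curve.vertices
    m = v.shape[0]
    diff = points[:, None, :] - v[None, :, :]
    d2_vertex = np.einsum("ijk,ijk->ij", diff, diff)

    a = v
    b = np.roll(v, -1, axis=0)
    ab = b - a  # (m, 2)
    ab2 = np.einsum("ij,ij->i", ab, ab)
    ap = points[:, None, :] - a[None, :, :]  # (n, m, 2)
    u = np.einsum("ijk,jk->ij", ap, ab) / ab2[None, :]
    interior = (u > 0.0) & (u < 1.0)
    foot = a[None, :, :] + u[..., None] * ab[None, :, :]
    res = points[:, None, :] - foot
    d2_seg = np.einsum("ijk,ijk->ij", res, res)
    d2_seg = np.where(interior, d2_seg, np.inf)
    return np.concatenate([d2_vertex, d2_seg], axis=1)


def project_points(points: PointSet, curve: ClosedPolyline) -> Projection:
    """Assign every point to its nearest curve element (vertex or segment)."""
    m = curve.n_vertices
    d2 = _element_distances(points.xy, curve)
    elem = np.argmin(d2, axis=1)  # ties -> lower element index
    sq = d2[np.arange(points.n), elem]
    kind = (elem >= m).astype(int)
    index = np.where(kind == 0, elem, elem - m)
    vertex_counts = np.bincount(index[kind == 0], minlength=m)
    segment_counts = np.bincount(index[kind == 1], minlength=m)
    return Projection(kind, index, sq, vertex_counts, segment_counts, points.xy)


def data_radius(points: PointSet) -> float:
    """Greatest Euclidean distance from any point to the point centroid."""
    if points.n < 1:
        raise ValueError("need at least one point")
    return float(np.linalg.norm(points.xy - points.centroid(), axis=1).max())


def _neighborhood_mask(proj: Projection, j: int, m: int) -> np.ndarray:
    """Points assigned to vertex j or to its two adjacent segments
    (segment j-1 ends at vertex j; segment j starts at it)."""
    on_vertex = (proj.kind == 0) & (proj.index == j)
    on_prev = (proj.kind == 1) & (proj.index == (j - 1) % m)
    on_next = (proj.kind == 1) & (proj.index == j)
    return on_vertex | on_prev | on_next


def optimize_vertices(
    curve: ClosedPolyline, points: PointSet, config: CCPSConfig
) -> ClosedPolyline:
    """Vertex optimization: sweep the vertices, locally minimizing the total
    squared projection distance as a function of each vertex position.

    Each vertex is refined by a deterministic Nelder-Mead search of the
    global distance function (started from the current position and from
    the centroid of the points assigned to the vertex and its two adjacent
    segments), with candidate positions confined to the data disk — the
    circle of the data radius about the point centroid — so the curve never
    grows abnormal vertices that the vertex filter would have to remove.
    A move is accepted only if the distance function decreases; sweeping
    stops when a full sweep improves by less than delta_s.  The returned
    curve is never worse than the input.
    """
    from scipy.optimize import minimize as _nm_minimize

    vertices = curve.vertices.copy()
    m = vertices.shape[0]
    pts = points.xy
    c0 = pts.mean(axis=0)
    # strictly inside the radius so the vertex filter's "> r" never trips
    # on boundary vertices by floating-point noise
    r_in = 0.999 * data_radius(points)

    def clip(v: np.ndarray) -> np.ndarray:
        d = np.linalg.norm(v - c0)
        return v if d <= r_in else c0 + (v - c0) * (r_in / d)

    def seg_col(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        ab = b - a
        ab2 = float(ab @ ab)
        if ab2 == 0:
            return np.full(pts.shape[0], np.inf)
        u = (pts - a) @ ab / ab2
        res = pts - a - u[:, None] * ab
        d2 = np.einsum("ij,ij->i", res, res)
        return np.where((u > 0.0) & (u < 1.0), d2, np.inf)

    # cached (n, 2m) point-to-element squared distances; moving vertex j
    # only touches columns {vertex j, segment j-1, segment j}
    D = _element_distances(pts, ClosedPolyline(vertices))

    def patched_cols(vj: np.ndarray, j: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        prev_v = vertices[(j - 1) % m]
        next_v = vertices[(j + 1) % m]
        diff = pts - vj
        return (
            np.einsum("ij,ij->i", diff, diff),
            seg_col(prev_v, vj),
            seg_col(vj, next_v),
        )

    def trial_total(vj_raw: np.ndarray, j: int) -> float:
        vj = clip(vj_raw)
        if np.all(vj == vertices[(j - 1) % m]) or np.all(vj == vertices[(j + 1) % m]):
            return np.inf  # would collapse an edge
        col_v, col_sp, col_s = patched_cols(vj, j)
        Dt = D.copy()
        Dt[:, j] = col_v
        Dt[:, m + (j - 1) % m] = col_sp
        Dt[:, m + j] = col_s
        return float(Dt.min(axis=1).sum())

    total = float(D.min(axis=1).sum())
    for _ in range(config.max_inner_sweeps):
        sweep_start = total
        for j in range(m):
            elem = np.argmin(D, axis=1)
            nbhd = (elem == j) | (elem == m + (j - 1) % m) | (elem == m + j)
            starts = [vertices[j]]
            if nbhd.any():
                starts.append(pts[nbhd].mean(axis=0))
            best_c, best_t = None, total
            for s0 in starts:
                res = _nm_minimize(
                    trial_total,
                    s0,
                    args=(j,),
                    method="Nelder-Mead",
                    options={"maxiter": 50, "xatol": 1e-5, "fatol": 1e-10},
                )
                if res.fun < best_t:
                    best_c, best_t = clip(res.x), res.fun
            if best_c is not None:
                vertices[j] = best_c
                total = best_t
                col_v, col_sp, col_s = patched_cols(best_c, j)
                D[:, j] = col_v
                D[:, m + (j - 1) % m] = col_sp
                D[:, m + j] = col_s
        if sweep_start - total < config.delta_s:
            break
    return ClosedPolyline(vertices)


def insert_vertex(curve: ClosedPolyline, projection: Projection) -> ClosedPolyline:
    """Split the segment carrying the greatest total squared projection
    distance, placing the new vertex at the centroid of its points."""
    m = curve.n_vertices
    seg_mask = projection.kind == 1
    seg_sq = np.bincount(
        projection.index[seg_mask], weights=projection.sqdist[seg_mask], minlength=m
    )
    eligible = projection.segment_counts >= 2
    if not eligible.any():
        raise NoSplittableSegmentError(
            "every segment has fewer than 2 projected points"
        )
    seg_sq = np.where(eligible, seg_sq, -np.inf)
    target = int(np.argmax(seg_sq))
    pts_mask = seg_mask & (projection.index == target)
    new_vertex = projection.points[pts_mask].mean(axis=0)
    vertices = np.insert(curve.vertices, target + 1, new_vertex, axis=0)
    return ClosedPolyline(vertices)


def filter_vertices(
    curve: ClosedPolyline,
    projection: Projection,
    r: float,
    config: CCPSConfig,
    centroid: np.ndarray | None = None,
) -> tuple[ClosedPolyline, list]:
    """Remove abnormal vertices: any vertex lying farther than the data
    radius r from the data centroid, or whose neighborhood (the vertex plus
    its two adjacent segments) captures fewer than min_projected_points
    points.  Endpoints of the longest segment are retained, the curve stays
    closed, and the vertex count never drops below 3."""
    m = curve.n_vertices
    if m < 4:
        return curve, []
    c = np.zeros(2) if centroid is None else np.asarray(centroid, dtype=float)
    dist_c = np.linalg.norm(curve.vertices - c, axis=1)
    neigh_counts = np.array(
        [
            projection.vertex_counts[j]
            + projection.segment_counts[(j - 1) % m]
            + projection.segment_counts[j]
            for j in range(m)
        ]
    )
    # endpoints of the longest segment are exempt from the starvation rule
    # (the longest segment is retained so it can keep collecting projection
    # points) but not from the radius rule, which targets distorted vertices
    longest = int(np.argmax(curve.segment_lengths()))
    protected = {longest, (longest + 1) % m}
    removals = []
    for j in range(m):
        if dist_c[j] > r:
            removals.append((j, "outside data radius"))
        elif j not in protected and neigh_counts[j] < config.min_projected_points:
            removals.append((j, f"fewer than {config.min_projected_points} projected points"))
    warnings: list = []
    keep = np.ones(m, dtype=bool)
    for j, reason in removals:
        if keep.sum() <= 3:
            warnings.append((j, "removal skipped: would drop below 3 vertices"))
            continue
        keep[j] = False
        warnings.append((j, reason))
    if keep.all():
        return curve, warnings
    vertices = curve.vertices[keep]
    # removing vertices can merge duplicated neighbors; drop exact repeats
    nxt = np.roll(vertices, -1, axis=0)
    distinct = ~np.all(vertices == nxt, axis=1)
    vertices = vertices[distinct] if distinct.sum() >= 3 else vertices
    return ClosedPolyline(vertices), warnings


def stop_whole_loop(
    num_segments: int, n: int, delta_n: float, r: float, config: CCPSConfig
) -> bool:
    """Segment-count stop bound: stop once the number of segments exceeds
    beta * n^(1/3) * delta_n^(-1/2) * r.  A perfect fit (delta_n = 0) stops
    immediately."""
    if delta_n < 0:
        raise ValueError("delta_n must be non-negative")
    if delta_n == 0:
        return True
    threshold = config.beta_stop * n ** (1.0 / 3.0) * delta_n ** (-0.5) * r
    return num_segments > threshold


def fit_ccps(
    points: PointSet,
    config: CCPSConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[ClosedPolyline, VertexSequence, FitTrace]:
    """Fit the closed polygonal principal curve to a seed-point cloud.

    The pipeline is normalize -> init square -> repeat {project, optimize
    vertices, filter vertices, stop checks, insert vertex}.  The fit is
    deterministic; ``rng`` is accepted for interface symmetry with the
    stochastic stages but is not consumed.
    """
    config = config or CCPSConfig()
    normalized, norm_params = zscore_normalize(points)
    n = normalized.n
    r = data_radius(normalized)
    centroid = normalized.centroid()
    curve = init_square()
    trace = FitTrace()
    prev_total = math.inf
    iteration = 0
    # The segment-count bound is spuriously exceeded at the coarse
    # initialization (large delta_n makes the bound tiny); it is armed once
    # the growing curve first satisfies it, and stops the loop when the
    # segment count outgrows it again at the fitted delta_n.
    bound_armed = False
    while True:
        iteration += 1
        curve = optimize_vertices(curve, normalized, config)
        proj = project_points(normalized, curve)
        filtered, warn = filter_vertices(curve, proj, r, config, centroid)
        if warn:
            trace.warnings.extend((iteration, j, reason) for j, reason in warn)
        if filtered.n_vertices != curve.n_vertices:
            # removals leave the survivors positioned for the old geometry;
            # re-spread them before judging convergence
            curve = optimize_vertices(filtered, normalized, config)
            proj = project_points(normalized, curve)
        trace.log(iteration, curve.n_vertices, proj.delta_n)
        exceeded = stop_whole_loop(curve.n_segments, n, proj.delta_n, r, config)
        if not exceeded:
            bound_armed = True
        if exceeded and bound_armed:
            trace.stop_reason = "segment-count bound"
            break
        if prev_total - proj.total < config.delta_s:
            trace.stop_reason = "outer-loop improvement below delta_s"
            break
        if curve.n_vertices >= config.max_segments:
            trace.stop_reason = "max_segments cap reached"
            break
        prev_total = proj.total
        try:
            curve = insert_vertex(curve, proj)
        except NoSplittableSegmentError:
            trace.stop_reason = "no splittable segment"
            break
    sequence = to_vertex_sequence(curve, norm_params)
    return curve, sequence, trace


def to_vertex_sequence(
    curve: ClosedPolyline, params: NormalizationParams
) -> VertexSequence:
    """Canonically order the curve vertices and parameterize them on [0, 1].

    Orientation is made counterclockwise; the start vertex is the one with
    the largest x (tie: largest y).  Vertex i of m gets t = i/m and the
    first vertex is repeated at t = 1 to encode closure.
    """
    vertices = curve.vertices
    if not curve.is_ccw():
        vertices = vertices[::-1]
    m = vertices.shape[0]
    order = np.lexsort((vertices[:, 1], vertices[:, 0]))
    start = order[-1]  # max x, then max y
    vertices = np.roll(vertices, -start, axis=0)
    t = np.arange(m + 1) / m
    xy = np.vstack([vertices, vertices[:1]])
    return VertexSequence(t, xy, params)
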