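"""Reproducible study-condition experiments.

These drive the whole pipeline under the synthetic study conditions:
radial-harmonic organ shapes, seed points subsampled at a given fraction of
the dense truth contour with Gaussian jitter proportional to the base
radius, and mask-based evaluation.  They are used by the acceptance script
and the test suite alike.
"""

from __future__ import annotations

import numpy as np

from .ccps import PointSet, init_square
from .de import DEConfig, minimize
from .metrics import delta_f, rasterize, report
from .model import HSegMod
from .synthetic import make_mask, make_truth_contour, random_spec, sample_seed_points

__all__ = ["fit_fixture", "recovery_experiment", "seed_fraction_trend", "sphere_benchmark"]


def fit_fixture(
    spec_seed: int,
    fraction: float = 0.08,
    jitter_frac: float = 0.01,
    placement: str = "near-contour",
    fit_seed: int | None = None,
) -> dict:
    """Generate one fixture, run the full pipeline, and evaluate it.

    Returns overlap metrics against the truth mask plus the curve-to-data
    distance of the final contour and of the initial (pre-fit) curve, both
    measured from the seed points in normalized units: the fit's whole
    point is to drive that distance down from its initialization.
    """
    spec = random_spec(spec_seed)
    truth = make_truth_contour(spec)
    seeds = sample_seed_points(
        truth, fraction, jitter_frac * spec.r0, placement, np.random.default_rng(spec_seed)
    )
    mask = make_mask(truth, spec.height, spec.width)
    model = HSegMod(seeds, frame_shape=mask.shape)
    results = model.fit(seed=fit_seed if fit_seed is not None else spec_seed)

    rep = report(rasterize(results.sample(), *mask.shape), mask)
    norm = results.vertex_sequence.norm_params
    seeds_norm = PointSet((seeds.xy - norm.mu) / norm.sigma)
    return {
        "dsc": rep.dsc,
        "jaccard": rep.jaccard,
        "acc": rep.acc,
        "delta_f_fit": results.delta_f(),
        "delta_f_initial": delta_f(init_square(), seeds_norm),
        "n_seeds": seeds.n,
        "n_vertices": results.ccps_curve.n_vertices,
    }


def recovery_experiment(
    spec_seeds=range(10),
    fraction: float = 0.08,
    jitter_frac: float = 0.01,
    placement: str = "near-contour",
    fit_seed_offset: int = 0,
) -> list[dict]:
    """End-to-end recovery on a batch of random shapes (the synthetic
    analogue of evaluating the method across patients)."""
    return [
        fit_fixture(s, fraction, jitter_frac, placement, fit_seed=s + fit_seed_offset)
        for s in spec_seeds
    ]


def seed_fraction_trend(
    spec_seeds=(0, 1, 2),
    fractions=(0.04, 0.07, 0.10),
    placements=("near-contour", "offset"),
    jitter_frac: float = 0.01,
    fit_seed_offset: int = 0,
) -> dict:
    """Median DSC per (placement, fraction): the synthetic analogue of the
    seed-count/placement study."""
    out: dict = {}
    for placement in placements:
        for fraction in fractions:
            rows = recovery_experiment(
                spec_seeds, fraction, jitter_frac, placement, fit_seed_offset
            )
            out[(placement, fraction)] = float(np.median([r["dsc"] for r in rows]))
    return out


def sphere_benchmark(
    n_seeds: int = 21, dim: int = 10, S: int = 30, GMax: int = 200, seed_offset: int = 0
) -> dict:
    """Median final fitness of classic DE (F=0.5, CR=0.9) and IAMCDE on the
    sphere objective, matched budgets."""

    def sphere(x):
        return float(np.sum(x * x))

    finals = {"DE": [], "IAMCDE": []}
    for s in range(n_seeds):
        for variant in finals:
            cfg = DEConfig(variant=variant, S=S, GMax=GMax, F=0.5, CR=0.9,
                           seed=s + seed_offset)
            finals[variant].append(minimize(sphere, dim, cfg).fun)
    return {k: float(np.median(v)) for k, v in finals.items()}
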