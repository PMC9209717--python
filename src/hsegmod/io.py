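"""File formats: images (PNG/DICOM), point CSV/JSON, contour CSV, mask PNG,
model JSON, and run manifests.

Conventions used everywhere: coordinates are 0-based with x = column and
y = row; pixel centers sit at half-integers; masks are PNGs with values
{0, 255}; contours are CSV with header ``t,x,y`` in pixel units.
"""

from __future__ import annotations

import json
from pathlib import Path as _Path

import numpy as np
import pandas as pd
from PIL import Image

from .ccps import ClosedPolyline, NormalizationParams, PointSet
from .contour import ContourFunction, CoordinateScaler
from .network import ABPNNParams

__all__ = [
    "MalformedRowError",
    "read_image",
    "read_seed_points",
    "write_seed_points",
    "read_contour",
    "write_contour",
    "read_mask",
    "write_mask",
    "write_model",
    "read_model",
    "write_manifest",
]


class MalformedRowError(ValueError):
    """A CSV row could not be parsed; the message names the line."""


def read_image(path) -> tuple[int, int, np.ndarray]:
    """Read a PNG or DICOM frame; returns (height, width, pixel array).

    Pixels are used only for framing and overlays, never by the fit.
    """
    path = _Path(path)
    suffix = path.suffix.lower()
    if suffix in (".dcm", ".dicom", ""):
        import pydicom

        try:
            ds = pydicom.dcmread(str(path))
            pixels = ds.pixel_array
        except Exception as exc:  # noqa: BLE001 - normalize reader errors
            raise ValueError(f"unreadable DICOM file {path}: {exc}") from exc
    elif suffix == ".png":
        try:
            with Image.open(path) as img:
                pixels = np.asarray(img.convert("L"))
        except Exception as exc:  # noqa: BLE001
            raise ValueError(f"unreadable PNG file {path}: {exc}") from exc
    else:
        raise ValueError(f"unsupported image format: {path}")
    if pixels.ndim == 3:
        pixels = pixels[..., 0]
    h, w = pixels.shape
    return h, w, pixels


def _parse_float(cell, path, line_no, column) -> float:
    try:
        return float(cell)
    except (TypeError, ValueError):
        raise MalformedRowError(
            f"{path}: line {line_no}: column '{column}' is not numeric: {cell!r}"
        ) from None


def read_seed_points(path) -> PointSet:
    """Seed points from CSV (header ``x,y``) or a JSON list of [x, y]."""
    path = _Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        return PointSet(np.asarray(data, dtype=float))
    df = pd.read_csv(path, dtype=str)
    cols = [c.strip().lower() for c in df.columns]
    if cols[:2] != ["x", "y"]:
        raise MalformedRowError(f"{path}: expected header 'x,y', got {list(df.columns)}")
    xy = np.empty((len(df), 2))
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # header is line 1
        xy[i, 0] = _parse_float(row[0], path, line_no, "x")
        xy[i, 1] = _parse_float(row[1], path, line_no, "y")
    return PointSet(xy)


def write_seed_points(path, points: PointSet) -> None:
    pd.DataFrame(points.xy, columns=["x", "y"]).to_csv(path, index=False)


def write_contour(path, polyline: ClosedPolyline, t: np.ndarray | None = None) -> None:
    """Contour CSV with header ``t,x,y`` (pixel coordinates)."""
    v = polyline.vertices
    if t is None:
        t = np.arange(v.shape[0]) / v.shape[0]
    df = pd.DataFrame({"t": t, "x": v[:, 0], "y": v[:, 1]})
    df.to_csv(path, index=False, float_format="%.9f")


def read_contour(path) -> tuple[np.ndarray, ClosedPolyline]:
    path = _Path(path)
    df = pd.read_csv(path, dtype=str)
    cols = [c.strip().lower() for c in df.columns]
    if cols[:3] != ["t", "x", "y"]:
        raise MalformedRowError(f"{path}: expected header 't,x,y', got {list(df.columns)}")
    arr = np.empty((len(df), 3))
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2
        for j, col in enumerate(("t", "x", "y")):
            arr[i, j] = _parse_float(row[j], path, line_no, col)
    return arr[:, 0], ClosedPolyline(arr[:, 1:])


def write_mask(path, mask: np.ndarray) -> None:
    img = Image.fromarray((np.asarray(mask, dtype=bool) * 255).astype(np.uint8))
    img.save(path)


def read_mask(path) -> np.ndarray:
    with Image.open(path) as img:
        arr = np.asarray(img.convert("L"))
    return arr >= 128


def write_model(path, params: ABPNNParams, scaler: CoordinateScaler, metadata: dict | None = None) -> None:
    """Save a fitted contour model as flat JSON."""
    norm = scaler.norm_params
    doc = {
        "q": params.q,
        "omega": params.omega.tolist(),
        "T": params.T.tolist(),
        "A": params.A.tolist(),
        "b": params.b.tolist(),
        "scaler": {
            "x_min": scaler.x_min,
            "x_max": scaler.x_max,
            "y_min": scaler.y_min,
            "y_max": scaler.y_max,
            "margin": scaler.margin,
            "norm_params": None
            if norm is None
            else {
                "mu_x": norm.mu_x,
                "mu_y": norm.mu_y,
                "sigma_x": norm.sigma_x,
                "sigma_y": norm.sigma_y,
            },
        },
        "metadata": metadata or {},
    }
    _Path(path).write_text(json.dumps(doc, indent=2))


def read_model(path) -> ContourFunction:
    doc = json.loads(_Path(path).read_text())
    params = ABPNNParams(
        np.asarray(doc["omega"], dtype=float),
        np.asarray(doc["T"], dtype=float),
        np.asarray(doc["A"], dtype=float),
        np.asarray(doc["b"], dtype=float),
    )
    s = doc["scaler"]
    norm = s.get("norm_params")
    norm_params = None if norm is None else NormalizationParams(
        norm["mu_x"], norm["mu_y"], norm["sigma_x"], norm["sigma_y"]
    )
    scaler = CoordinateScaler(
        s["x_min"], s["x_max"], s["y_min"], s["y_max"], s["margin"], norm_params
    )
    return ContourFunction(params, scaler)


def write_manifest(path, configs: dict, seed: int | None, outputs: dict) -> None:
    """Machine-readable record of a CLI run sufficient to reproduce it."""
    import hsegmod

    doc = {
        "package": "hsegmod",
        "version": getattr(hsegmod, "__version__", "unknown"),
        "seed": seed,
        "configs": configs,
        "outputs": outputs,
    }
    _Path(path).write_text(json.dumps(doc, indent=2, default=str))
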