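"""AOI polygons, fixation-to-AOI assignment, AOI metrics and density maps.

AOIs are named closed polygons (the first vertex repeated last). They can be
flat — one set for all trials — or nested per trial. Boundary points count as
inside; overlapping AOIs are resolved by declaration order (first wins).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "AOIError",
    "validate_aois",
    "point_in_polygon",
    "points_in_polygon",
    "assign_aoi",
    "compute_aoi_statistics",
    "fixation_density",
    "load_aois",
    "save_aois",
]

OUTSIDE = "outside"

Vertex = tuple[float, float]
FlatAOIs = dict[str, list[Vertex]]

_BOUNDARY_TOL = 1e-9


class AOIError(ValueError):
    pass


def _is_nested(aois: Mapping[str, Any]) -> bool:
    return any(isinstance(v, Mapping) for v in aois.values())


def _check_polygon(name: str, vertices: Sequence[Sequence[float]]) -> list[Vertex]:
    verts = [(float(x), float(y)) for x, y in vertices]
    if len(verts) < 4 or verts[0] != verts[-1]:
        raise AOIError(
            f"AOI {name!r}: polygon must be closed (first vertex repeated last, >= 4 points)"
        )
    return verts


def validate_aois(aois: Mapping[str, Any]) -> dict:
    """Validate a flat or nested AOI mapping; returns a normalized copy."""
    if _is_nested(aois):
        return {
            str(trial): {name: _check_polygon(f"{trial}/{name}", poly)
                         for name, poly in sub.items()}
            for trial, sub in aois.items()
        }
    return {name: _check_polygon(name, poly) for name, poly in aois.items()}


def point_in_polygon(point: Sequence[float], polygon: Sequence[Sequence[float]]) -> bool:
    """Even-odd point-in-polygon test; points on the boundary count as inside."""
    verts = _check_polygon("<polygon>", polygon)
    res = points_in_polygon(np.array([point[0]]), np.array([point[1]]), verts)
    return bool(res[0])


def points_in_polygon(x: np.ndarray, y: np.ndarray, polygon: Sequence[Vertex]) -> np.ndarray:
    """Vectorized even-odd containment test (boundary inclusive)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    inside = np.zeros(x.shape, dtype=bool)
    boundary = np.zeros(x.shape, dtype=bool)
    verts = np.asarray(polygon, dtype=float)
    for (x1, y1), (x2, y2) in zip(verts[:-1], verts[1:]):
        # on-segment check: zero cross product and within the bounding box
        cross = (x2 - x1) * (y - y1) - (y2 - y1) * (x - x1)
        seg_len = max(np.hypot(x2 - x1, y2 - y1), _BOUNDARY_TOL)
        on = (np.abs(cross) / seg_len <= _BOUNDARY_TOL) \
            & (x >= min(x1, x2) - _BOUNDARY_TOL) & (x <= max(x1, x2) + _BOUNDARY_TOL) \
            & (y >= min(y1, y2) - _BOUNDARY_TOL) & (y <= max(y1, y2) + _BOUNDARY_TOL)
        boundary |= on
        crosses = (y1 > y) != (y2 > y)
        if np.any(crosses):
            with np.errstate(invalid="ignore", divide="ignore"):
                xint = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            inside ^= crosses & (x < xint)
    return inside | boundary


def assign_aoi(
    fixations: pd.DataFrame,
    aois: Mapping[str, Any],
    x_col: str = "x",
    y_col: str = "y",
    trial_cols: str | Sequence[str] | None = None,
    out_col: str = "aoi",
) -> pd.DataFrame:
    """Label each fixation with the first AOI containing it, else "outside".

    With nested AOIs, ``trial_cols`` must name the identifier column(s); each
    fixation is tested against its own trial's AOIs (trial keys are the
    stringified identifier tuple, joined by "|" for compound identifiers).
    """
    aois = validate_aois(aois)
    out = fixations.copy()
    x = np.asarray(out[x_col], dtype=float)
    y = np.asarray(out[y_col], dtype=float)
    labels = np.full(len(out), OUTSIDE, dtype=object)

    if _is_nested(aois):
        if trial_cols is None:
            raise AOIError("nested AOIs require trial_cols")
        if isinstance(trial_cols, str):
            trial_cols = [trial_cols]
        keys = out[list(trial_cols)].astype(str).agg("|".join, axis=1)
        for key in keys.unique():
            if key not in aois:
                raise AOIError(f"no AOIs defined for trial {key!r}")
            sel = (keys == key).to_numpy()
            labels[sel] = _assign_flat(x[sel], y[sel], aois[key])
    else:
        labels[:] = _assign_flat(x, y, aois)
    out[out_col] = labels
    return out


def _assign_flat(x: np.ndarray, y: np.ndarray, aois: FlatAOIs) -> np.ndarray:
    labels = np.full(x.shape, OUTSIDE, dtype=object)
    unassigned = np.ones(x.shape, dtype=bool)
    for name, poly in aois.items():  # declaration order: first containing AOI wins
        hit = unassigned & points_in_polygon(x, y, poly)
        labels[hit] = name
        unassigned &= ~hit
    return labels


def compute_aoi_statistics(
    fixations: pd.DataFrame,
    aois: Mapping[str, Any],
    x_col: str = "x",
    y_col: str = "y",
    duration_col: str = "duration",
    trial_cols: str | Sequence[str] = "trial",
) -> pd.DataFrame:
    """Fixation count and total duration per (trial, AOI), zero rows included.

    "outside" is reported as its own AOI row. When the duration column is
    absent only counts are reported.
    """
    if isinstance(trial_cols, str):
        trial_cols = [trial_cols]
    trial_cols = list(trial_cols)
    aois_v = validate_aois(aois)
    nested = _is_nested(aois_v)
    assigned = assign_aoi(fixations, aois_v, x_col=x_col, y_col=y_col,
                          trial_cols=trial_cols if nested else None)
    has_dur = duration_col in assigned.columns
    rows = []
    for key, g in assigned.groupby(trial_cols, sort=False):
        key_t = key if isinstance(key, tuple) else (key,)
        if nested:
            names = list(aois_v["|".join(map(str, key_t))])
        else:
            names = list(aois_v)
        for name in names + [OUTSIDE]:
            sub = g[g["aoi"] == name]
            row = dict(zip(trial_cols, key_t))
            row["aoi"] = name
            row["n_fixations"] = int(len(sub))
            if has_dur:
                row["total_duration"] = float(sub[duration_col].sum())
            rows.append(row)
    cols = trial_cols + ["aoi", "n_fixations"] + (["total_duration"] if has_dur else [])
    return pd.DataFrame(rows, columns=cols)


def fixation_density(
    fixations: pd.DataFrame,
    canvas: tuple[int, int],
    bandwidth: float | None = None,
    x_col: str = "x",
    y_col: str = "y",
    duration_col: str = "duration",
) -> np.ndarray:
    """Duration-weighted Gaussian fixation density on the pixel grid.

    Returns a ``(height, width)`` array whose integral equals the total
    weight (fixation durations, or fixation count when no duration column is
    present), up to edge clipping. Default bandwidth: 2% of the canvas
    diagonal.
    """
    width, height = int(canvas[0]), int(canvas[1])
    if width <= 0 or height <= 0:
        raise ValueError("canvas dimensions must be positive")
    if bandwidth is None:
        bandwidth = 0.02 * float(np.hypot(width, height))
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    grid = np.zeros((height, width))
    if len(fixations) == 0:
        return grid
    x = np.clip(np.round(np.asarray(fixations[x_col], dtype=float)).astype(int), 0, width - 1)
    y = np.clip(np.round(np.asarray(fixations[y_col], dtype=float)).astype(int), 0, height - 1)
    if duration_col in fixations.columns:
        w = np.asarray(fixations[duration_col], dtype=float)
    else:
        w = np.ones(len(fixations))
    np.add.at(grid, (y, x), w)
    return gaussian_filter(grid, sigma=bandwidth, mode="constant", truncate=6.0)


def save_aois(aois: Mapping[str, Any], path: str | Path) -> None:
    """Write a flat or nested AOI mapping to JSON (round-trippable)."""
    aois = validate_aois(aois)
    Path(path).write_text(json.dumps(aois, indent=2))


def load_aois(path: str | Path) -> dict:
    """Load and validate an AOI JSON file (flat or nested)."""
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise AOIError(f"malformed AOI JSON in {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise AOIError(f"{path}: AOI file must contain a JSON object")
    return validate_aois(raw)
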