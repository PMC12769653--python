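"""Shared numeric helpers."""

from __future__ import annotations

import numpy as np

__all__ = ["mad", "contiguous_runs", "nan_runs"]


def mad(values: np.ndarray) -> float:
    """Raw median absolute deviation (no consistency scaling).

    ``median(|x - median(x)|)`` over finite values.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return float("nan")
    med = np.median(v)
    return float(np.median(np.abs(v - med)))


def contiguous_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Return [start, stop) index pairs of True runs in a boolean mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return [(int(edges[i]), int(edges[i + 1])) for i in range(0, len(edges), 2)]


def nan_runs(values: np.ndarray) -> list[tuple[int, int]]:
    """Return [start, stop) runs of non-finite entries."""
    return contiguous_runs(~np.isfinite(np.asarray(values, dtype=float)))
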