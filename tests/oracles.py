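"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the library's code paths (and, where practical, its
dependencies' high-level APIs) so that agreement is a real check.
"""

from __future__ import annotations

import numpy as np


def median(vals):
    s = sorted(vals)
    n = len(s)
    mid = n // 2
    return s[mid] if n % 2 else (s[mid - 1] + s[mid]) / 2.0


def raw_mad(vals):
    m = median(vals)
    return median([abs(v - m) for v in vals])


def speed_reject_brute(trace, times, n=16.0):
    """Loop-based speed rejection: max of fwd/bwd difference over dt,
    threshold median + n*MAD (raw), strict >. Missing samples skipped."""
    trace = list(map(float, trace))
    times = list(map(float, times))
    idx = [i for i, v in enumerate(trace) if np.isfinite(v)]
    mask = [False] * len(trace)
    if len(idx) < 3:
        return mask
    speeds = []
    for pos, i in enumerate(idx):
        cands = []
        if pos > 0:
            j = idx[pos - 1]
            cands.append(abs(trace[i] - trace[j]) / (times[i] - times[j]))
        if pos < len(idx) - 1:
            j = idx[pos + 1]
            cands.append(abs(trace[j] - trace[i]) / (times[j] - times[i]))
        speeds.append(max(cands))
    thr = median(speeds) + n * raw_mad(speeds)
    for pos, i in enumerate(idx):
        if speeds[pos] > thr:
            mask[i] = True
    return mask


def zscore_reject_brute(trace, z_threshold=2.5, cv_threshold=0.1):
    trace = list(map(float, trace))
    vals = [v for v in trace if np.isfinite(v)]
    mask = [False] * len(trace)
    if len(vals) < 2:
        return mask
    mean = sum(vals) / len(vals)
    if mean == 0:
        return mask
    sd = (sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)) ** 0.5
    if sd / mean <= cv_threshold:
        return mask
    for i, v in enumerate(trace):
        if np.isfinite(v) and abs((v - mean) / sd) > z_threshold:
            mask[i] = True
    return mask


def natural_spline_eval(xk, yk, xq):
    """Natural cubic spline through (xk, yk), evaluated at xq.

    Solves the classic second-derivative tridiagonal system directly with a
    dense linear solve; independent of scipy.interpolate.
    """
    xk = np.asarray(xk, dtype=float)
    yk = np.asarray(yk, dtype=float)
    n = len(xk)
    h = np.diff(xk)
    A = np.zeros((n, n))
    b = np.zeros(n)
    A[0, 0] = A[-1, -1] = 1.0  # natural: second derivative zero at ends
    for i in range(1, n - 1):
        A[i, i - 1] = h[i - 1]
        A[i, i] = 2 * (h[i - 1] + h[i])
        A[i, i + 1] = h[i]
        b[i] = 3 * ((yk[i + 1] - yk[i]) / h[i] - (yk[i] - yk[i - 1]) / h[i - 1])
    c = np.linalg.solve(A, b)  # second-derivative/2 coefficients
    out = []
    for x in np.atleast_1d(np.asarray(xq, dtype=float)):
        i = int(np.clip(np.searchsorted(xk, x) - 1, 0, n - 2))
        dx = x - xk[i]
        bi = (yk[i + 1] - yk[i]) / h[i] - h[i] * (2 * c[i] + c[i + 1]) / 3
        di = (c[i + 1] - c[i]) / (3 * h[i])
        out.append(yk[i] + bi * dx + c[i] * dx ** 2 + di * dx ** 3)
    return np.array(out)


def masked_window_smooth_brute(trace, weights):
    """Centered renormalized windowed average within non-missing runs."""
    trace = np.asarray(trace, dtype=float)
    w = np.asarray(weights, dtype=float)
    half = (len(w) - 1) // 2  # matches np.convolve 'same' centering
    n = len(trace)
    out = np.full(n, np.nan)
    # identify run membership
    run_id = np.full(n, -1)
    rid = -1
    prev = False
    for i in range(n):
        if np.isfinite(trace[i]):
            if not prev:
                rid += 1
            run_id[i] = rid
            prev = True
        else:
            prev = False
    for i in range(n):
        if run_id[i] < 0:
            continue
        num = den = 0.0
        for k in range(len(w)):
            j = i + k - half
            if 0 <= j < n and run_id[j] == run_id[i]:
                num += w[k] * trace[j]
                den += w[k]
        out[i] = num / den
    return out


def ray_cast_contains(x, y, polygon):
    """matplotlib-based containment oracle (off-boundary points only)."""
    from matplotlib.path import Path

    p = Path(np.asarray(polygon, dtype=float))
    pts = np.column_stack([np.atleast_1d(x), np.atleast_1d(y)])
    return p.contains_points(pts)
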