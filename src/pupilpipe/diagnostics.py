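"""Outlier flagging, per-trial summaries and quality-check grids.

All flags produced here are advisory: they populate the trial summary but
never modify pupil columns. Exclusion happens only through
:meth:`pupilpipe.pipeline.PupilProcessor.validate_trials`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Hashable, Mapping

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from ._utils import mad  # noqa: E402
from .pipeline import PupilProcessor  # noqa: E402

__all__ = [
    "OutlierReport",
    "check_baseline_outliers",
    "check_trace_outliers",
    "summarize",
    "pupil_surface",
    "plot_baseline_histogram",
    "plot_spaghetti",
    "plot_pupil_surface",
]


@dataclass
class OutlierReport:
    """Advisory outlier flags with the thresholds that produced them.

    ``thresholds`` is a ``(lower, upper)`` pair, or a mapping group ->
    ``(lower, upper)`` when ``group_by`` was used. ``unevaluable`` lists
    trials that could not be assessed (e.g. no overlap with the time grid).
    """

    flags: dict[Hashable, bool]
    thresholds: tuple[float, float] | dict[Any, tuple[float, float]]
    n: float
    group_by: Mapping[Hashable, Any] | None = None
    deviations: dict[Hashable, float] = field(default_factory=dict)
    unevaluable: list[Hashable] = field(default_factory=list)


def check_baseline_outliers(
    baselines: Mapping[Hashable, float] | pd.Series,
    n: float = 4.0,
    group_by: Mapping[Hashable, Any] | None = None,
) -> OutlierReport:
    """Flag baselines outside ``[median - n*MAD, median + n*MAD]`` (inclusive).

    MAD is raw (unscaled). With ``group_by`` (a mapping trial -> group label)
    the band is computed within each group independently; empty groups are
    omitted with a warning.
    """
    if isinstance(baselines, pd.Series):
        baselines = baselines.to_dict()
    keys = list(baselines)
    if group_by is None:
        groups: dict[Any, list[Hashable]] = {None: keys}
    else:
        groups = {}
        for k in keys:
            groups.setdefault(group_by[k], []).append(k)

    flags: dict[Hashable, bool] = {}
    thresholds: dict[Any, tuple[float, float]] = {}
    for gname, members in groups.items():
        values = np.array([baselines[k] for k in members], dtype=float)
        finite = values[np.isfinite(values)]
        if finite.size == 0:
            warnings.warn(f"group {gname!r} has no finite baselines; omitted", stacklevel=2)
            for k in members:
                flags[k] = False
            continue
        med = float(np.median(finite))
        band = n * mad(finite)
        lo, hi = med - band, med + band
        thresholds[gname] = (lo, hi)
        for k, v in zip(members, values):
            flags[k] = bool(np.isfinite(v) and (v < lo or v > hi))
    thr = thresholds[None] if group_by is None and None in thresholds else thresholds
    return OutlierReport(flags=flags, thresholds=thr, n=n, group_by=group_by)


def _trace_matrix(proc: PupilProcessor, column: str) -> tuple[np.ndarray, pd.DataFrame]:
    """Pivot trial traces onto the shared trialtime grid (trials as columns)."""
    df = proc.data
    key = df[proc.trial_identifier].apply(tuple, axis=1) if len(proc.trial_identifier) > 1 \
        else df[proc.trial_identifier[0]]
    wide = df.assign(_trial=key).pivot_table(
        index=proc.time_col, columns="_trial", values=column, aggfunc="mean",
        dropna=False,
    )
    return np.asarray(wide.index, dtype=float), wide


def check_trace_outliers(
    proc: PupilProcessor,
    n: float = 4.0,
    column: str | None = None,
    mode: str = "pointwise",
) -> OutlierReport:
    """Flag whole traces that stray too far from the grand mean trace.

    Traces are aligned on the trial-time grid. For each trial the maximum
    absolute distance ``D_j`` from the grand mean (the pointwise mean over
    trials, missing ignored; ``mode="scalar"`` uses a single scalar mean
    instead) is computed; the band half-width is ``median(D) + n * MAD(D)``
    and a trial is flagged when its ``D_j`` strictly exceeds it. Trials with
    no non-missing overlap with the grid are reported as unevaluable.
    """
    if mode not in ("pointwise", "scalar"):
        raise ValueError(f"unknown mode {mode!r}")
    column = column or proc.current
    _, wide = _trace_matrix(proc, column)
    if wide.shape[1] < 2:
        raise ValueError("need at least 2 trials for trace outlier detection")
    values = wide.to_numpy(dtype=float)
    if mode == "pointwise":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            center = np.nanmean(values, axis=1, keepdims=True)
    else:
        center = np.full((values.shape[0], 1), np.nanmean(values))
    dev = np.abs(values - center)
    flags: dict[Hashable, bool] = {}
    deviations: dict[Hashable, float] = {}
    unevaluable: list[Hashable] = []
    d_list = []
    trials = list(wide.columns)
    for j, trial in enumerate(trials):
        col = dev[:, j]
        if not np.isfinite(col).any():
            unevaluable.append(trial)
            continue
        deviations[trial] = float(np.nanmax(col))
        d_list.append(deviations[trial])
    d_arr = np.array(d_list)
    half_width = float(np.median(d_arr) + n * mad(d_arr)) if d_arr.size else np.nan
    for trial in trials:
        if trial in deviations:
            flags[trial] = bool(deviations[trial] > half_width)
        else:
            flags[trial] = False
    return OutlierReport(
        flags=flags, thresholds=(-half_width, half_width), n=n,
        deviations=deviations, unevaluable=unevaluable,
    )


def summarize(
    proc: PupilProcessor,
    baseline_report: OutlierReport | None = None,
    trace_report: OutlierReport | None = None,
) -> pd.DataFrame:
    """One row per trial aggregating every step's statistics and outlier flags.

    Columns include, per executed step, the missing proportion after the step
    and a success flag; plus the interpolated flag, the stored baseline, and
    the baseline/trace outlier flags with their thresholds when reports are
    given.
    """
    keys = proc.trial_keys()
    norm = lambda k: k if isinstance(k, tuple) else (k,)  # noqa: E731
    rows = {norm(k): dict(zip(proc.trial_identifier, norm(k))) for k in keys}
    for step in proc.steps:
        for key, stats in step.trial_stats.items():
            row = rows.setdefault(norm(key), dict(zip(proc.trial_identifier, norm(key))))
            ns = stats.get("n_samples", np.nan)
            if ns and np.isfinite(ns) and "n_missing_after" in stats:
                row[f"{step.name}_missing_prop"] = stats["n_missing_after"] / ns
            row[f"{step.name}_ok"] = stats.get("succeeded", True)
            for extra in ("interpolated", "baseline", "speed_threshold", "cv", "prop_missing"):
                if extra in stats:
                    row[extra] = stats[extra]
    for report, label in ((baseline_report, "baseline_outlier"), (trace_report, "trace_outlier")):
        if report is None:
            continue
        for key, flag in report.flags.items():
            row = rows.setdefault(norm(key), dict(zip(proc.trial_identifier, norm(key))))
            row[label] = bool(flag)
            if isinstance(report.thresholds, tuple):
                row[f"{label}_lower"], row[f"{label}_upper"] = report.thresholds
    if not rows:
        return pd.DataFrame(columns=proc.trial_identifier)
    return pd.DataFrame(list(rows.values()))


def pupil_surface(
    proc: PupilProcessor,
    bins: tuple[int, int] = (64, 36),
    mode: str = "count",
    column: str | None = None,
    extent: tuple[float, float, float, float] | None = None,
) -> tuple[np.ndarray, tuple[float, float], tuple[np.ndarray, np.ndarray]]:
    """2D gaze histogram: per-cell sample counts or mean pupil size.

    Returns ``(grid, (mean_x, mean_y), (x_edges, y_edges))``; the grid is
    indexed ``[ix, iy]``. In count mode the grid total equals the number of
    non-missing gaze samples. ``extent`` is ``(x_min, x_max, y_min, y_max)``
    (default: the data range).
    """
    if mode not in ("count", "size"):
        raise ValueError(f"unknown mode {mode!r}")
    x = np.asarray(proc.data[proc.x_col], dtype=float)
    y = np.asarray(proc.data[proc.y_col], dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if mode == "size":
        p = np.asarray(proc.data[column or proc.current], dtype=float)
        ok &= np.isfinite(p)
    if not ok.any():
        raise ValueError("no non-missing samples for the pupil surface")
    rng = None
    if extent is not None:
        rng = [[extent[0], extent[1]], [extent[2], extent[3]]]
    counts, xe, ye = np.histogram2d(x[ok], y[ok], bins=list(bins), range=rng)
    if mode == "count":
        grid = counts
    else:
        sums, _, _ = np.histogram2d(x[ok], y[ok], bins=[xe, ye], weights=p[ok])
        with np.errstate(invalid="ignore"):
            grid = np.where(counts > 0, sums / np.where(counts > 0, counts, 1), np.nan)
    return grid, (float(np.mean(x[ok])), float(np.mean(y[ok]))), (xe, ye)


# --------------------------------------------------------------------- plots

def plot_baseline_histogram(report: OutlierReport, baselines: Mapping[Hashable, float],
                            path: str | None = None):
    """Histogram of baseline values with the outlier band as dashed lines."""
    values = np.array([v for v in baselines.values() if np.isfinite(v)])
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(values, bins="fd" if values.size > 3 else 5, color="steelblue", alpha=0.8)
    if isinstance(report.thresholds, tuple):
        for thr in report.thresholds:
            ax.axvline(thr, linestyle="--", color="crimson")
    ax.set_xlabel("baseline pupil size")
    ax.set_ylabel("trials")
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_spaghetti(proc: PupilProcessor, report: OutlierReport | None = None,
                   column: str | None = None, path: str | None = None):
    """All per-trial traces over trial time; outliers highlighted."""
    column = column or proc.current
    t, wide = _trace_matrix(proc, column)
    fig, ax = plt.subplots(figsize=(7, 4))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        center = np.nanmean(wide.to_numpy(dtype=float), axis=1)
    for trial in wide.columns:
        flagged = bool(report and report.flags.get(trial, False))
        ax.plot(t, wide[trial], color="crimson" if flagged else "grey",
                alpha=0.9 if flagged else 0.4, lw=1.2 if flagged else 0.8)
    if report is not None and isinstance(report.thresholds, tuple):
        hw = report.thresholds[1]
        ax.plot(t, center + hw, "--", color="black", lw=0.8)
        ax.plot(t, center - hw, "--", color="black", lw=0.8)
    ax.set_xlabel("trial time (ms)")
    ax.set_ylabel(column)
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_pupil_surface(grid: np.ndarray, mean_gaze: tuple[float, float],
                       edges: tuple[np.ndarray, np.ndarray], path: str | None = None):
    """Render a pupil-surface grid with the mean gaze point as a red cross."""
    xe, ye = edges
    fig, ax = plt.subplots(figsize=(6, 4))
    mesh = ax.pcolormesh(xe, ye, grid.T, cmap="viridis")
    ax.plot(*mean_gaze, "+", color="red", markersize=12, markeredgewidth=2)
    ax.invert_yaxis()  # screen coordinates: origin top-left
    fig.colorbar(mesh, ax=ax)
    ax.set_xlabel("x (px)")
    ax.set_ylabel("y (px)")
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
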