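"""Chainable per-trial pupil preprocessing.

Every step reads the latest pupil stage column and writes a new column with a
step-specific suffix (``pp`` -> ``pp_db`` -> ``pp_db_ar`` -> ...), so all
intermediate data are preserved. Statistics (missing counts, thresholds,
per-trial success) are logged in :class:`StepRecord` objects on the processor.

All computations are grouped by the trial identifier columns; trials never
influence each other.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field as dc_field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.signal import butter, sosfiltfilt
from scipy.signal.windows import hann as hann_window

from ._utils import contiguous_runs, mad

__all__ = [
    "PupilProcessor",
    "StepRecord",
    "ValidRegion",
    "PipelineError",
    "ChainError",
    "reject_speed",
    "reject_zscore",
    "SUFFIXES",
]

logger = logging.getLogger(__name__)

SUFFIXES = {
    "deblink": "db",
    "downsample": "ds",
    "upsample": "us",
    "artifact_rejection": "ar",
    "filter_position": "xy",
    "smooth": "sm",
    "interpolate": "ip",
    "baseline_correct": "bc",
}


class PipelineError(RuntimeError):
    pass


class ChainError(PipelineError):
    def __init__(self, step: str, cause: Exception):
        super().__init__(f"pipeline step {step!r} failed: {cause}")
        self.step = step
        self.cause = cause


@dataclass
class StepRecord:
    """Bookkeeping for one executed pipeline step."""

    name: str
    suffix: str
    column_in: str
    column_out: str
    params: dict[str, Any]
    trial_stats: dict[Any, dict[str, Any]] = dc_field(default_factory=dict)


@dataclass(frozen=True)
class ValidRegion:
    """Valid gaze region: a pixel rectangle or a closed polygon.

    Boundary points count as inside.
    """

    rect: tuple[float, float, float, float] | None = None  # x_min, x_max, y_min, y_max
    polygon: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if (self.rect is None) == (self.polygon is None):
            raise ValueError("specify exactly one of rect or polygon")
        if self.rect is not None:
            x0, x1, y0, y1 = self.rect
            if not (x0 < x1 and y0 < y1):
                raise ValueError("degenerate rectangle: need x_min < x_max and y_min < y_max")
        else:
            poly = tuple((float(x), float(y)) for x, y in self.polygon)
            if len(poly) < 4 or poly[0] != poly[-1]:
                raise ValueError("polygon must be closed (first vertex repeated last, >= 4 points)")
            object.__setattr__(self, "polygon", poly)

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        finite = np.isfinite(x) & np.isfinite(y)
        out = np.zeros(x.shape, dtype=bool)
        if self.rect is not None:
            x0, x1, y0, y1 = self.rect
            out[finite] = (
                (x[finite] >= x0) & (x[finite] <= x1)
                & (y[finite] >= y0) & (y[finite] <= y1)
            )
        else:
            from .fixation_aoi import points_in_polygon

            out[finite] = points_in_polygon(x[finite], y[finite], list(self.polygon))
        return out


def _as_float(series: pd.Series) -> np.ndarray:
    return np.asarray(series, dtype=float)


def reject_speed(
    trace: np.ndarray,
    times: np.ndarray,
    n: float = 16.0,
    *,
    return_threshold: bool = False,
):
    """Flag samples whose pupil speed exceeds ``median + n * MAD``.

    Speed at each point is the absolute maximum of the forward and backward
    differences, each normalized by its time difference; endpoints use their
    single available side. MAD is raw (unscaled) and the comparison is strict,
    so degenerate traces (constant, linear ramp) reject nothing. Missing
    samples are skipped: differences are taken between consecutive non-missing
    samples. Fewer than 3 non-missing samples yields an all-false mask.
    """
    p = np.asarray(trace, dtype=float)
    t = np.asarray(times, dtype=float)
    mask = np.zeros(p.shape, dtype=bool)
    valid = np.isfinite(p)
    idx = np.flatnonzero(valid)
    if idx.size < 3:
        return (mask, np.nan) if return_threshold else mask
    pv, tv = p[idx], t[idx]
    diffs = np.abs(np.diff(pv)) / np.diff(tv)
    speed = np.empty(idx.size)
    speed[0] = diffs[0]
    speed[-1] = diffs[-1]
    if idx.size > 2:
        speed[1:-1] = np.maximum(diffs[:-1], diffs[1:])
    threshold = float(np.median(speed) + n * mad(speed))
    mask[idx] = speed > threshold
    return (mask, threshold) if return_threshold else mask


def reject_zscore(
    trace: np.ndarray,
    z_threshold: float = 2.5,
    cv_threshold: float = 0.1,
    *,
    return_stats: bool = False,
):
    """Flag extreme pupil sizes by z-score, guarded by a CV gate.

    When the trace's coefficient of variation (sd / mean, sample sd) is at or
    below ``cv_threshold`` the trace is considered stable and nothing is
    flagged. A zero mean leaves the CV undefined; nothing is flagged.
    """
    p = np.asarray(trace, dtype=float)
    mask = np.zeros(p.shape, dtype=bool)
    valid = np.isfinite(p)
    idx = np.flatnonzero(valid)
    stats = {"cv": np.nan, "protected": True}
    if idx.size < 2:
        return (mask, stats) if return_stats else mask
    pv = p[idx]
    mean = float(np.mean(pv))
    if mean == 0.0:
        return (mask, stats) if return_stats else mask
    sd = float(np.std(pv, ddof=1))
    cv = sd / mean
    stats["cv"] = cv
    if cv <= cv_threshold:
        return (mask, stats) if return_stats else mask
    stats["protected"] = False
    z = (pv - mean) / sd
    mask[idx] = np.abs(z) > z_threshold
    return (mask, stats) if return_stats else mask


class PupilProcessor:
    """Per-trial pupil preprocessing over a long-format sample table.

    Parameters
    ----------
    data
        Long-format samples, one row per gaze sample.
    trial_identifier
        Column name(s) whose value tuple identifies a trial. All steps are
        applied independently within these groups.
    time_col, x_col, y_col, pupil_col
        Role bindings into ``data``.
    sampling_rate
        Hz. Inferred per recording as the reciprocal of the median
        inter-sample interval when omitted.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        trial_identifier: str | Sequence[str],
        time_col: str = "trialtime",
        x_col: str = "x",
        y_col: str = "y",
        pupil_col: str = "pp",
        sampling_rate: float | None = None,
    ):
        if isinstance(trial_identifier, str):
            trial_identifier = [trial_identifier]
        self.trial_identifier = list(trial_identifier)
        for col in self.trial_identifier + [time_col, x_col, y_col, pupil_col]:
            if col not in data.columns:
                raise ValueError(f"column {col!r} not in data")
        self.data = data.reset_index(drop=True).copy()
        self.time_col = time_col
        self.x_col = x_col
        self.y_col = y_col
        self.pupil_col = pupil_col
        self.current = pupil_col
        self.steps: list[StepRecord] = []
        if sampling_rate is None:
            sampling_rate = self._infer_rate()
        self.sampling_rate = float(sampling_rate)

    # ------------------------------------------------------------------ utils
    def _infer_rate(self) -> float:
        dts = []
        for _, g in self._groups():
            if len(g) > 1:
                dts.append(np.median(np.diff(_as_float(g[self.time_col]))))
        if not dts:
            raise ValueError("cannot infer sampling rate from single-sample trials")
        dt = float(np.median(dts))
        if dt <= 0:
            raise ValueError("non-positive median inter-sample interval")
        return 1000.0 / dt

    def _groups(self):
        by = self.trial_identifier[0] if len(self.trial_identifier) == 1 else self.trial_identifier
        return self.data.groupby(by, sort=False)

    def trial_keys(self) -> list[Any]:
        return [key for key, _ in self._groups()]

    def _out_column(self, step_name: str) -> str:
        out = f"{self.current}_{SUFFIXES[step_name]}"
        if out in self.data.columns:
            raise PipelineError(f"column {out!r} already exists; refusing to overwrite")
        return out

    def _record(self, record: StepRecord, out: str) -> "PupilProcessor":
        self.steps.append(record)
        self.current = out
        logger.info("step %s: created column %r from %r", record.name, out, record.column_in)
        return self

    @staticmethod
    def _miss_stats(before: np.ndarray, after: np.ndarray) -> dict[str, Any]:
        return {
            "n_missing_before": int(np.sum(~np.isfinite(before))),
            "n_missing_after": int(np.sum(~np.isfinite(after))),
            "n_samples": int(before.size),
        }

    # ---------------------------------------------------------------- deblink
    def deblink(
        self,
        smooth_window_ms: float = 10.0,
        merge_gap_ms: float = 100.0,
    ) -> "PupilProcessor":
        """Remove blink intervals, including eyelid closing/opening ramps.

        Noise-based detection: runs of zero or missing pupil samples are
        located, then each run is extended backward over the descending ramp
        (to the nearest non-decreasing -> decreasing transition of the lightly
        smoothed signal) and forward over the ascending recovery ramp (to the
        first non-increasing sample). Runs separated by less than
        ``merge_gap_ms`` are merged. All flagged samples are set missing in a
        new ``*_db`` column; zeros elsewhere are preserved as recorded.
        """
        out = self._out_column("deblink")
        record = StepRecord(
            "deblink", SUFFIXES["deblink"], self.current, out,
            {"smooth_window_ms": smooth_window_ms, "merge_gap_ms": merge_gap_ms},
        )
        win = max(1, int(round(smooth_window_ms * self.sampling_rate / 1000.0)))
        merge_gap = max(1, int(round(merge_gap_ms * self.sampling_rate / 1000.0)))
        result = np.full(len(self.data), np.nan)
        for key, g in self._groups():
            p = _as_float(g[self.current])
            blink_mask = _detect_blinks(p, smooth_window=win, merge_gap=merge_gap)
            cleaned = p.copy()
            cleaned[blink_mask] = np.nan
            result[g.index] = cleaned
            stats = self._miss_stats(p, cleaned)
            stats["succeeded"] = bool(np.isfinite(cleaned).any())
            record.trial_stats[key] = stats
        self.data[out] = result
        return self._record(record, out)

    # --------------------------------------------------------------- resample
    def downsample(self, target_hz: float) -> "PupilProcessor":
        """Aggregate fixed windows of ``rate / target_hz`` samples per trial.

        Numeric columns take the window mean ignoring missing values
        (all-missing windows stay missing); time and text columns take the
        window's first value. Trailing samples that do not fill a window are
        dropped. The aggregated input column is duplicated as ``*_ds``.
        """
        if target_hz >= self.sampling_rate:
            raise ValueError("downsample target must be below the current sampling rate")
        factor_f = self.sampling_rate / target_hz
        factor = int(round(factor_f))
        if abs(factor_f - factor) > 1e-9:
            near = self.sampling_rate / round(factor_f)
            raise ValueError(
                f"target {target_hz} Hz does not evenly divide {self.sampling_rate} Hz; "
                f"nearest divisor target is {near:g} Hz"
            )
        out = self._out_column("downsample")
        record = StepRecord("downsample", SUFFIXES["downsample"], self.current, out,
                            {"target_hz": target_hz, "factor": factor})
        first_cols = {self.time_col, "trackertime", "msgtime"} & set(self.data.columns)
        frames = []
        for key, g in self._groups():
            n_win = len(g) // factor
            if n_win == 0:
                record.trial_stats[key] = {"succeeded": False, "n_samples": len(g)}
                continue
            g = g.iloc[: n_win * factor]
            widx = np.arange(len(g)) // factor
            agg: dict[str, Any] = {}
            for col in g.columns:
                if col in first_cols or not pd.api.types.is_numeric_dtype(g[col]):
                    agg[col] = g[col].groupby(widx).first()
                else:
                    agg[col] = g[col].groupby(widx).mean()
            down = pd.DataFrame(agg)[list(g.columns)]
            down[out] = down[self.current]
            frames.append(down)
            before = _as_float(g[self.current])
            record.trial_stats[key] = {
                **self._miss_stats(before, _as_float(down[out])),
                "succeeded": True,
            }
        if not frames:
            raise PipelineError("downsampling left no complete windows in any trial")
        self.data = pd.concat(frames, ignore_index=True)
        self.sampling_rate = float(target_hz)
        return self._record(record, out)

    def upsample(self, target_hz: float) -> "PupilProcessor":
        """Re-grid each trial at a higher rate with linear interpolation.

        Gaps bounded by missing samples stay missing on the new grid; text
        columns are carried forward from the most recent original sample.
        """
        if target_hz <= self.sampling_rate:
            raise ValueError("upsample target must exceed the current sampling rate")
        out = self._out_column("upsample")
        record = StepRecord("upsample", SUFFIXES["upsample"], self.current, out,
                            {"target_hz": target_hz})
        new_dt = 1000.0 / target_hz
        frames = []
        for key, g in self._groups():
            if len(g) < 2:
                raise PipelineError(f"cannot upsample single-sample trial {key!r}")
            t_old = _as_float(g[self.time_col])
            n_new = int(np.floor((t_old[-1] - t_old[0]) / new_dt)) + 1
            t_new = t_old[0] + np.arange(n_new) * new_dt
            up = pd.DataFrame({self.time_col: t_new})
            exact = np.isclose(t_new[:, None], t_old[None, :], atol=1e-9).any(axis=1)
            right = np.searchsorted(t_old, t_new, side="right")
            left = np.clip(right - 1, 0, len(t_old) - 1)
            right = np.clip(right, 0, len(t_old) - 1)
            nearest_exact = np.clip(np.searchsorted(t_old, t_new + 1e-9) - 1, 0, len(t_old) - 1)
            frac = np.where(
                t_old[right] > t_old[left],
                (t_new - t_old[left]) / np.where(t_old[right] > t_old[left], t_old[right] - t_old[left], 1.0),
                0.0,
            )
            for col in g.columns:
                if col == self.time_col:
                    continue
                if pd.api.types.is_numeric_dtype(g[col]):
                    v = _as_float(g[col])
                    interp = v[left] + frac * (v[right] - v[left])
                    interp[exact] = v[nearest_exact][exact]
                    up[col] = interp
                else:
                    up[col] = g[col].to_numpy()[nearest_exact]
            up[out] = up[self.current]
            up = up[list(g.columns) + [out]]
            frames.append(up)
            record.trial_stats[key] = {
                **self._miss_stats(_as_float(g[self.current]), _as_float(up[out])),
                "succeeded": True,
            }
        self.data = pd.concat(frames, ignore_index=True)
        self.sampling_rate = float(target_hz)
        return self._record(record, out)

    # ----------------------------------------------------- artifact rejection
    def artifact_rejection(
        self,
        method: str = "both",
        n_speed: float = 16.0,
        z_threshold: float = 2.5,
        cv_threshold: float = 0.1,
    ) -> "PupilProcessor":
        """Set speed and/or z-score artifacts to missing in a ``*_ar`` column.

        ``method`` is "speed", "zscore" or "both" (the default); with "both"
        the two masks are computed on the same input column and unioned.
        """
        if method not in ("speed", "zscore", "both"):
            raise ValueError(f"unknown artifact rejection method {method!r}")
        out = self._out_column("artifact_rejection")
        record = StepRecord(
            "artifact_rejection", SUFFIXES["artifact_rejection"], self.current, out,
            {"method": method, "n_speed": n_speed,
             "z_threshold": z_threshold, "cv_threshold": cv_threshold},
        )
        result = np.full(len(self.data), np.nan)
        for key, g in self._groups():
            p = _as_float(g[self.current])
            t = _as_float(g[self.time_col])
            mask = np.zeros(p.shape, dtype=bool)
            stats: dict[str, Any] = {}
            if method in ("speed", "both"):
                m, thr = reject_speed(p, t, n=n_speed, return_threshold=True)
                mask |= m
                stats["speed_threshold"] = thr
                stats["n_speed_rejected"] = int(m.sum())
            if method in ("zscore", "both"):
                m, zstats = reject_zscore(p, z_threshold, cv_threshold, return_stats=True)
                mask |= m
                stats["cv"] = zstats["cv"]
                stats["n_zscore_rejected"] = int(m.sum())
            cleaned = p.copy()
            cleaned[mask] = np.nan
            result[g.index] = cleaned
            stats.update(self._miss_stats(p, cleaned))
            stats["succeeded"] = True
            record.trial_stats[key] = stats
        self.data[out] = result
        return self._record(record, out)

    # --------------------------------------------------------- position filter
    def filter_position(self, region: ValidRegion | tuple) -> "PupilProcessor":
        """Set pupil missing where gaze falls outside the valid region.

        ``region`` may be a :class:`ValidRegion` or an ``(x_min, x_max,
        y_min, y_max)`` tuple. Samples with missing x/y are also set missing.
        Boundary points are kept.
        """
        if not isinstance(region, ValidRegion):
            region = ValidRegion(rect=tuple(region))
        out = self._out_column("filter_position")
        record = StepRecord("filter_position", SUFFIXES["filter_position"], self.current, out,
                            {"region": region})
        result = np.full(len(self.data), np.nan)
        for key, g in self._groups():
            p = _as_float(g[self.current])
            inside = region.contains(_as_float(g[self.x_col]), _as_float(g[self.y_col]))
            cleaned = np.where(inside, p, np.nan)
            result[g.index] = cleaned
            stats = self._miss_stats(p, cleaned)
            stats["succeeded"] = True
            stats["n_outside"] = int(np.sum(~inside))
            record.trial_stats[key] = stats
        self.data[out] = result
        return self._record(record, out)

    # ---------------------------------------------------------------- smooth
    def smooth(
        self,
        method: str = "hann",
        window: int = 100,
        order: int = 3,
        cutoff_hz: float = 4.0,
    ) -> "PupilProcessor":
        """Low-pass the pupil trace into a ``*_sm`` column.

        hann (default) / rolling_mean: centered convolution with a
        unit-normalized window, computed within contiguous non-missing runs
        only (weights are renormalized near run edges; missing samples never
        shrink or bleed). butterworth: zero-phase low-pass applied per run;
        runs too short for the filter's padding are left unchanged.
        """
        if method not in ("hann", "rolling_mean", "butterworth"):
            raise ValueError(f"unknown smoothing method {method!r}")
        if method != "butterworth" and window < 3:
            raise ValueError("window must be >= 3 samples")
        if method == "butterworth":
            if cutoff_hz >= self.sampling_rate / 2:
                raise ValueError("cutoff must be below the Nyquist frequency")
            sos = butter(order, cutoff_hz, btype="low", fs=self.sampling_rate, output="sos")
        out = self._out_column("smooth")
        record = StepRecord("smooth", SUFFIXES["smooth"], self.current, out,
                            {"method": method, "window": window,
                             "order": order, "cutoff_hz": cutoff_hz})
        if method == "hann":
            weights = hann_window(window, sym=True)
        elif method == "rolling_mean":
            weights = np.ones(window)
        result = np.full(len(self.data), np.nan)
        for key, g in self._groups():
            p = _as_float(g[self.current])
            smoothed = np.full(p.shape, np.nan)
            runs = contiguous_runs(np.isfinite(p))
            succeeded = False
            for a, b in runs:
                seg = p[a:b]
                if method == "butterworth":
                    padlen = 3 * (2 * len(sos) + 1)
                    if len(seg) > padlen:
                        smoothed[a:b] = sosfiltfilt(sos, seg)
                    else:
                        smoothed[a:b] = seg
                    succeeded = True
                else:
                    # centered 'same' extraction that also works for runs
                    # shorter than the window
                    lo = (len(weights) - 1) // 2
                    num = np.convolve(seg, weights, mode="full")[lo:lo + len(seg)]
                    den = np.convolve(np.ones(len(seg)), weights, mode="full")[lo:lo + len(seg)]
                    smoothed[a:b] = num / den
            if method != "butterworth":
                longest = max((b - a for a, b in runs), default=0)
                if longest < window:
                    smoothed[:] = np.nan  # window longer than every run
                    succeeded = False
                else:
                    succeeded = True
            result[g.index] = smoothed
            stats = self._miss_stats(p, smoothed)
            stats["succeeded"] = succeeded
            record.trial_stats[key] = stats
        self.data[out] = result
        return self._record(record, out)

    # ----------------------------------------------------------- interpolate
    def interpolate(
        self,
        method: str = "linear",
        max_missing: float = 0.4,
    ) -> "PupilProcessor":
        """Fill interior missing gaps into a ``*_ip`` column.

        Trials whose missing proportion exceeds ``max_missing`` are copied
        unchanged and flagged as not interpolated. Leading and trailing
        missing runs are never extrapolated. ``cubic`` uses a natural cubic
        spline through the non-missing samples.
        """
        if method not in ("linear", "cubic"):
            raise ValueError(f"unknown interpolation method {method!r}")
        out = self._out_column("interpolate")
        record = StepRecord("interpolate", SUFFIXES["interpolate"], self.current, out,
                            {"method": method, "max_missing": max_missing})
        result = np.full(len(self.data), np.nan)
        for key, g in self._groups():
            p = _as_float(g[self.current])
            t = _as_float(g[self.time_col])
            valid = np.isfinite(p)
            prop_missing = 1.0 - valid.mean() if p.size else 1.0
            filled = p.copy()
            interpolated = False
            if prop_missing <= max_missing and valid.sum() >= 2:
                vi = np.flatnonzero(valid)
                interior = np.flatnonzero(~valid)
                interior = interior[(interior > vi[0]) & (interior < vi[-1])]
                if interior.size:
                    if method == "linear":
                        filled[interior] = np.interp(t[interior], t[vi], p[vi])
                    else:
                        spline = CubicSpline(t[vi], p[vi], bc_type="natural")
                        filled[interior] = spline(t[interior])
                interpolated = True
            result[g.index] = filled
            stats = self._miss_stats(p, filled)
            stats["succeeded"] = interpolated
            stats["interpolated"] = interpolated
            stats["prop_missing"] = float(prop_missing)
            record.trial_stats[key] = stats
        self.data[out] = result
        return self._record(record, out)

    # ------------------------------------------------------ baseline correct
    def baseline_correct(
        self,
        event: str | None = None,
        last_k: int = 100,
        time_range: tuple[float, float] | Mapping[Any, tuple[float, float]] | None = None,
        method: str = "subtractive",
        event_col: str = "event",
        min_valid_frac: float = 0.1,
    ) -> "PupilProcessor":
        """Express pupil size relative to a per-trial baseline (``*_bc``).

        The baseline window is either the rows whose ``event_col`` equals
        ``event`` — the baseline is the mean of the window's last ``last_k``
        samples, ignoring missing — or an explicit ``time_range`` (one
        ``(t0, t1)`` or a per-trial mapping), averaged over all non-missing
        samples. Subtractive: ``p - b``; divisive: ``p / b``. Trials whose
        window is entirely missing, has fewer than ``min_valid_frac * last_k``
        valid samples, or (divisive) a zero baseline are flagged and set
        missing.
        """
        if method not in ("subtractive", "divisive"):
            raise ValueError(f"unknown baseline method {method!r}")
        if (event is None) == (time_range is None):
            raise ValueError("specify exactly one of event= or time_range=")
        if event is not None and event_col not in self.data.columns:
            raise ValueError(f"event column {event_col!r} not in data")
        out = self._out_column("baseline_correct")
        record = StepRecord("baseline_correct", SUFFIXES["baseline_correct"], self.current, out,
                            {"event": event, "last_k": last_k, "time_range": time_range,
                             "method": method})
        result = np.full(len(self.data), np.nan)
        for key, g in self._groups():
            p = _as_float(g[self.current])
            t = _as_float(g[self.time_col])
            if event is not None:
                wmask = (g[event_col] == event).to_numpy()
                win = p[wmask][-last_k:]
                enough = np.isfinite(win).sum() >= max(1, min_valid_frac * last_k)
            else:
                rng = time_range[key] if isinstance(time_range, Mapping) else time_range
                t0, t1 = rng
                win = p[(t >= t0) & (t <= t1)]
                enough = np.isfinite(win).any()
            stats: dict[str, Any] = self._miss_stats(p, p)
            if win.size == 0 or not np.isfinite(win).any() or not enough:
                record.trial_stats[key] = {**stats, "succeeded": False, "baseline": np.nan}
                continue
            b = float(np.nanmean(win))
            if method == "divisive" and b == 0.0:
                record.trial_stats[key] = {**stats, "succeeded": False, "baseline": b}
                continue
            corrected = p - b if method == "subtractive" else p / b
            result[g.index] = corrected
            stats = self._miss_stats(p, corrected)
            record.trial_stats[key] = {**stats, "succeeded": True, "baseline": b}
        self.data[out] = result
        return self._record(record, out)

    # ------------------------------------------------------------------ chain
    def chain(self, steps: Sequence[tuple[str, Mapping[str, Any]]]) -> "PupilProcessor":
        """Apply an ordered list of ``(step_name, params)`` pairs.

        Equivalent to calling each step in sequence; the first failure aborts
        with a :class:`ChainError` naming the step, leaving the partial state
        intact.
        """
        allowed = set(SUFFIXES)
        for name, _ in steps:
            if name not in allowed:
                raise ChainError(name, ValueError(f"unknown operation {name!r}"))
        for name, params in steps:
            try:
                getattr(self, name)(**dict(params))
            except ChainError:
                raise
            except Exception as exc:
                raise ChainError(name, exc) from exc
        return self

    # --------------------------------------------------------------- validity
    def validate_trials(self, invalid: pd.DataFrame) -> "PupilProcessor":
        """Add/replace a boolean ``valid`` column on the sample table.

        Every sample of a trial listed in ``invalid`` (whose columns must be a
        subset of the trial identifier) is marked False; all others True.
        Identifier tuples absent from the data trigger a warning.
        """
        id_cols = [c for c in invalid.columns if c in self.trial_identifier]
        if len(invalid.columns) and not id_cols:
            raise ValueError("invalid table shares no columns with the trial identifier")
        valid = np.ones(len(self.data), dtype=bool)
        if len(invalid):
            listed = set(map(tuple, invalid[id_cols].itertuples(index=False, name=None)))
            present = set(map(tuple, self.data[id_cols].itertuples(index=False, name=None)))
            unmatched = listed - present
            if unmatched:
                warnings.warn(f"invalid trial tuple(s) not present in data: {sorted(unmatched)}",
                              stacklevel=2)
            keys = list(map(tuple, self.data[id_cols].itertuples(index=False, name=None)))
            valid = np.array([k not in listed for k in keys], dtype=bool)
        self.data["valid"] = valid
        return self


def _detect_blinks(p: np.ndarray, smooth_window: int, merge_gap: int) -> np.ndarray:
    """Boolean mask of blink samples (zero/missing runs plus ramps)."""
    n = p.size
    candidate = (~np.isfinite(p)) | (p == 0)
    runs = contiguous_runs(candidate)
    if not runs:
        return np.zeros(n, dtype=bool)
    filled = np.where(np.isfinite(p), p, 0.0)
    if smooth_window > 1:
        kernel = np.ones(smooth_window)
        s = np.convolve(filled, kernel, mode="same") / np.convolve(
            np.ones(n), kernel, mode="same"
        )
    else:
        s = filled
    d = np.diff(s)
    extended = []
    for a, b in runs:
        # a sample is contaminated if the signal fell into it (closing ramp)
        # or rises out of it (reopening ramp); the walk stops on the last
        # clean sample on each side, which stays intact.
        i = a
        while i > 0 and d[i - 1] < 0:
            i -= 1
        j = b - 1
        while j < n - 1 and d[j] > 0:
            j += 1
        extended.append((min(i + 1, a), max(j, b)))
    # merge runs separated by less than merge_gap samples
    merged = [extended[0]]
    for a, b in extended[1:]:
        pa, pb = merged[-1]
        if a - pb < merge_gap:
            merged[-1] = (pa, max(pb, b))
        else:
            merged.append((a, b))
    mask = np.zeros(n, dtype=bool)
    for a, b in merged:
        mask[a:b] = True
    return mask
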