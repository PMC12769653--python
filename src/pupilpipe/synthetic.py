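"""Ground-truth-annotated synthetic recordings for testing.

Generates pupil traces with injected blinks and spike artifacts, ASC files
exercising the marker grammar, and fixation sets with known AOI membership.
Every generator is a pure function of its spec and seed. The event-locked
dilation is a gamma-shaped bump — test scaffolding, not a physiological
model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .eyelink_io import MarkerSpec
from .fixation_aoi import points_in_polygon, validate_aois

__all__ = [
    "TraceSpec",
    "BlinkSpec",
    "GroundTruth",
    "TrialRecordingSpec",
    "RecordingTruth",
    "generate_trace",
    "generate_recording_asc",
    "generate_fixations",
]


@dataclass(frozen=True)
class BlinkSpec:
    """One injected blink: linear closing ramp, zero plateau, reopening ramp."""

    onset_ms: float
    ramp_down_ms: float = 20.0
    closed_ms: float = 60.0
    ramp_up_ms: float = 20.0


@dataclass(frozen=True)
class TraceSpec:
    """Parameters for one synthetic pupil trace."""

    duration_ms: float = 3000.0
    sampling_rate: float = 1000.0
    baseline: float = 1000.0
    bump_onset_ms: float = 1000.0
    bump_amplitude: float = 0.0
    bump_shape: float = 2.0
    bump_scale_ms: float = 300.0
    noise_sd: float = 0.0
    blinks: tuple[BlinkSpec, ...] = ()
    spikes: tuple[tuple[float, float], ...] = ()  # (time_ms, magnitude)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "blinks", tuple(self.blinks))
        object.__setattr__(self, "spikes", tuple(self.spikes))
        for b in self.blinks:
            if b.onset_ms < 0 or b.onset_ms + b.ramp_down_ms + b.closed_ms + b.ramp_up_ms > self.duration_ms:
                raise ValueError(f"blink at {b.onset_ms} ms extends outside the trace")
        for t, _ in self.spikes:
            if not (0 <= t < self.duration_ms):
                raise ValueError(f"spike at {t} ms outside the trace")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_ms * self.sampling_rate / 1000.0))


@dataclass
class GroundTruth:
    """What was injected into a generated trace, sample-for-sample."""

    clean: np.ndarray
    times_ms: np.ndarray
    blink_intervals: list[tuple[int, int]]  # [start, stop) sample indices incl. ramps
    artifact_indices: list[int]             # spike sample indices
    baseline: float
    noise_sd: float

    @property
    def blink_mask(self) -> np.ndarray:
        mask = np.zeros(self.clean.shape, dtype=bool)
        for a, b in self.blink_intervals:
            mask[a:b] = True
        return mask


def _to_samples(ms: float, rate: float) -> int:
    return int(round(ms * rate / 1000.0))


def generate_trace(spec: TraceSpec) -> tuple[np.ndarray, GroundTruth]:
    """Generate one pupil trace and its ground truth.

    Trace = baseline + gamma-shaped bump + Gaussian noise; injected blinks
    overwrite with a strictly-decreasing linear ramp to zero, a zero plateau
    (``closed_ms`` worth of exact zeros), and a ramp back up. Spikes add
    single-sample impulses. Same seed, same output.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    t = np.arange(n) * (1000.0 / spec.sampling_rate)
    clean = np.full(n, spec.baseline, dtype=float)
    if spec.bump_amplitude != 0.0:
        rel = (t - spec.bump_onset_ms) / spec.bump_scale_ms
        rel = np.where(rel > 0, rel, 0.0)
        peak = spec.bump_shape ** spec.bump_shape * np.exp(-spec.bump_shape)
        bump = np.where(rel > 0, rel ** spec.bump_shape * np.exp(-rel) / peak, 0.0)
        clean = clean + spec.bump_amplitude * bump
    trace = clean + (rng.normal(0.0, spec.noise_sd, n) if spec.noise_sd > 0 else 0.0)

    intervals: list[tuple[int, int]] = []
    for b in spec.blinks:
        i0 = _to_samples(b.onset_ms, spec.sampling_rate)
        rd = _to_samples(b.ramp_down_ms, spec.sampling_rate)
        nz = _to_samples(b.closed_ms, spec.sampling_rate)
        ru = _to_samples(b.ramp_up_ms, spec.sampling_rate)
        i1 = i0 + rd + nz + ru
        for a, bb in intervals:
            if i0 < bb and a < i1:
                raise ValueError("overlapping blinks in TraceSpec")
        pre = trace[i0 - 1] if i0 > 0 else spec.baseline
        post = trace[i1] if i1 < n else spec.baseline
        if rd:
            trace[i0:i0 + rd] = pre * (1.0 - (np.arange(1, rd + 1) / (rd + 1)))
        trace[i0 + rd:i0 + rd + nz] = 0.0
        if ru:
            trace[i0 + rd + nz:i1] = post * (np.arange(1, ru + 1) / (ru + 1))
        intervals.append((i0, i1))

    spike_idx = []
    for time_ms, magnitude in spec.spikes:
        i = _to_samples(time_ms, spec.sampling_rate)
        trace[i] += magnitude
        spike_idx.append(i)

    truth = GroundTruth(
        clean=clean, times_ms=t, blink_intervals=sorted(intervals),
        artifact_indices=sorted(spike_idx), baseline=spec.baseline,
        noise_sd=spec.noise_sd,
    )
    return trace, truth


@dataclass(frozen=True)
class TrialRecordingSpec:
    """One trial of an emitted ASC recording."""

    trace: TraceSpec
    start_text: str
    stop_text: str
    mid_messages: tuple[tuple[float, str], ...] = ()  # (offset_ms from trial start, text)

    def __post_init__(self) -> None:
        object.__setattr__(self, "mid_messages", tuple(self.mid_messages))


@dataclass
class RecordingTruth:
    """Exact structure of an emitted ASC file."""

    samples_per_trial: list[int]
    boundaries: list[tuple[int, int]]            # (start msgtime, stop msgtime)
    msg_per_sample: list[list[str]]              # expected msg column, per trial
    events: list[dict[str, Any]]                 # EFIX/EBLINK intervals per trial
    trace_truths: list[GroundTruth]
    dot_rows: list[list[int]]                    # per-trial sample indices with "." x/y


def generate_recording_asc(
    trials: Sequence[TrialRecordingSpec],
    spec: MarkerSpec,
    path: str | Path,
    gaze: tuple[float, float] = (960.0, 540.0),
    gaze_jitter: float = 2.0,
    intertrial_gap_ms: float = 200.0,
    t0: int = 1_000_000,
    seed: int = 0,
) -> RecordingTruth:
    """Write a synthetic ASC file and return its exact ground truth.

    The file interleaves MSG boundary rows, optional mid-trial MSG rows,
    tab-separated sample rows at integer-millisecond timestamps, plus EFIX
    and EBLINK event rows. Samples whose trace value is exactly zero (blink
    plateau) are emitted with "." gaze coordinates, as the recorder does
    during track loss. The sampling rate of every trial must divide 1000 Hz.
    """
    path = Path(path)
    rng = np.random.default_rng(seed)
    lines = ["** SYNTHETIC RECORDING", "** DATE: n/a"]
    truth = RecordingTruth([], [], [], [], [], [])
    clock = int(t0)
    for tr in trials:
        rate = tr.trace.sampling_rate
        dt = 1000.0 / rate
        if abs(dt - round(dt)) > 1e-9:
            raise ValueError("sampling rate must divide 1000 Hz for integer timestamps")
        dt = int(round(dt))
        trace, gt = generate_trace(tr.trace)
        n = trace.size
        start_time = clock
        sample_times = start_time + 1 + np.arange(n) * dt
        stop_time = int(sample_times[-1]) + 1

        mids = sorted(tr.mid_messages)
        for off, _ in mids:
            if not (0 <= off <= tr.trace.duration_ms):
                raise ValueError(f"mid message offset {off} outside trial")
        lines.append(f"MSG\t{start_time} {tr.start_text}")
        msgs: list[str] = []
        dot_rows: list[int] = []
        mid_i = 0
        current_msg = tr.start_text
        xs = gaze[0] + rng.normal(0, gaze_jitter, n)
        ys = gaze[1] + rng.normal(0, gaze_jitter, n)
        for i, st in enumerate(sample_times):
            while mid_i < len(mids) and start_time + 1 + mids[mid_i][0] <= st:
                mtime = int(start_time + 1 + mids[mid_i][0])
                lines.append(f"MSG\t{mtime} {mids[mid_i][1]}")
                current_msg = mids[mid_i][1]
                mid_i += 1
            if trace[i] == 0.0:
                lines.append(f"{int(st)}\t.\t.\t0.0\t...")
                dot_rows.append(i)
            else:
                lines.append(f"{int(st)}\t{xs[i]:.1f}\t{ys[i]:.1f}\t{trace[i]:.1f}\t...")
            msgs.append(current_msg)

        # recorder event rows: one fixation spanning the trial, one per blink
        efix = {
            "kind": "fixation",
            "start_time": int(sample_times[0]),
            "end_time": int(sample_times[-1]),
        }
        lines.append(
            f"EFIX R   {efix['start_time']}\t{efix['end_time']}\t"
            f"{efix['end_time'] - efix['start_time']}\t{gaze[0]:.1f}\t{gaze[1]:.1f}\t"
            f"{tr.trace.baseline:.0f}"
        )
        truth.events.append({**efix, "trial_index": len(truth.samples_per_trial)})
        for a, b in gt.blink_intervals:
            ev = {
                "kind": "blink",
                "start_time": int(sample_times[a]),
                "end_time": int(sample_times[b - 1]),
            }
            lines.append(f"SBLINK R {ev['start_time']}")
            lines.append(
                f"EBLINK R {ev['start_time']}\t{ev['end_time']}\t"
                f"{ev['end_time'] - ev['start_time']}"
            )
            truth.events.append({**ev, "trial_index": len(truth.samples_per_trial)})
        lines.append(f"MSG\t{stop_time} {tr.stop_text}")

        truth.samples_per_trial.append(n)
        truth.boundaries.append((start_time, stop_time))
        truth.msg_per_sample.append(msgs)
        truth.trace_truths.append(gt)
        truth.dot_rows.append(dot_rows)
        clock = stop_time + int(intertrial_gap_ms)

    path.write_text("\n".join(lines) + "\n")
    return truth


def generate_fixations(
    aois: Mapping[str, Any],
    per_aoi_counts: Mapping[str, int],
    outside_count: int = 0,
    duration_range: tuple[int, int] = (50, 500),
    canvas: tuple[int, int] = (1920, 1080),
    trial: Any = 1,
    seed: int = 0,
    max_attempts: int = 10_000,
) -> tuple[pd.DataFrame, list[str]]:
    """Sample fixations with known AOI membership.

    Fixations are drawn uniformly inside each named AOI by rejection sampling
    over its bounding box; "outside" fixations are drawn on the canvas,
    outside every AOI. Returns the fixation table (columns: trial, x, y,
    duration) and the true label list, row-aligned.
    """
    aois_v = validate_aois(aois)
    if any(isinstance(v, Mapping) for v in aois_v.values()):
        raise ValueError("generate_fixations expects a flat AOI mapping")
    rng = np.random.default_rng(seed)
    rows: list[dict[str, Any]] = []
    labels: list[str] = []

    def sample_in(poly: list, want_inside: bool, bbox: tuple[float, float, float, float]) -> tuple[float, float]:
        x0, x1, y0, y1 = bbox
        for _ in range(max_attempts):
            x = rng.uniform(x0, x1)
            y = rng.uniform(y0, y1)
            if want_inside:
                if points_in_polygon(np.array([x]), np.array([y]), poly)[0]:
                    return x, y
            else:
                if not any(points_in_polygon(np.array([x]), np.array([y]), p)[0]
                           for p in aois_v.values()):
                    return x, y
        raise ValueError("rejection sampling failed; AOI area too small?")

    for name, count in per_aoi_counts.items():
        if count < 0:
            raise ValueError("counts must be >= 0")
        poly = aois_v[name]
        vx = [v[0] for v in poly]
        vy = [v[1] for v in poly]
        for _ in range(count):
            x, y = sample_in(poly, True, (min(vx), max(vx), min(vy), max(vy)))
            rows.append({"trial": trial, "x": x, "y": y,
                         "duration": int(rng.integers(*duration_range))})
            labels.append(name)
    for _ in range(outside_count):
        x, y = sample_in(None, False, (0, canvas[0], 0, canvas[1]))
        rows.append({"trial": trial, "x": x, "y": y,
                     "duration": int(rng.integers(*duration_range))})
        labels.append("outside")
    df = pd.DataFrame(rows, columns=["trial", "x", "y", "duration"])
    return df, labels
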