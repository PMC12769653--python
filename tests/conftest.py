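import numpy as np
import pandas as pd
import pytest

from pupilpipe import MarkerSpec, PupilProcessor
from pupilpipe.synthetic import BlinkSpec, TraceSpec, TrialRecordingSpec, generate_recording_asc


@pytest.fixture
def marker_spec():
    return MarkerSpec(
        fields=(("marker", "str"), ("event", "str"), ("block", "str"), ("trial", "int")),
        start_message="start fixation",
        stop_message="end feedback",
    )


def make_trials(n_trials, duration_ms=1000.0, rate=1000.0, noise_sd=0.0,
                blinks=(), spikes=(), seed=0, mid_messages=True, **trace_kw):
    trials = []
    for i in range(n_trials):
        mids = ((duration_ms / 2, f"start letters A {i + 1}"),) if mid_messages else ()
        trials.append(TrialRecordingSpec(
            trace=TraceSpec(duration_ms=duration_ms, sampling_rate=rate,
                            noise_sd=noise_sd, blinks=tuple(blinks), spikes=tuple(spikes),
                            seed=seed + i, **trace_kw),
            start_text=f"start fixation A {i + 1}",
            stop_text=f"end feedback A {i + 1}",
            mid_messages=mids,
        ))
    return trials


@pytest.fixture
def asc_recording(tmp_path, marker_spec):
    """A 2-trial noiseless recording with one blink per trial."""
    path = tmp_path / "rec.asc"
    trials = make_trials(2, blinks=[BlinkSpec(onset_ms=400.0)], seed=3)
    truth = generate_recording_asc(trials, marker_spec, path, seed=11)
    return path, truth


def trial_frame(traces, rate=1000.0, extra_cols=None):
    """Build a long-format sample table from {trial_id: trace array}."""
    frames = []
    dt = 1000.0 / rate
    for trial, trace in traces.items():
        n = len(trace)
        df = pd.DataFrame({
            "trial": trial,
            "trialtime": np.arange(n) * dt,
            "x": 960.0,
            "y": 540.0,
            "pp": np.asarray(trace, dtype=float),
        })
        for col, val in (extra_cols or {}).items():
            df[col] = val
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def make_processor(traces, rate=1000.0, **kwargs):
    return PupilProcessor(trial_frame(traces, rate=rate), trial_identifier="trial",
                          sampling_rate=rate, **kwargs)


@pytest.fixture
def unit_square():
    return [(0.0, 0.0), (1.0, 0.0), (1.0, 1.0), (0.0, 1.0), (0.0, 0.0)]
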