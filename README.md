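# pupilpipe

Pupil-size preprocessing and fixation/AOI analysis for eye-tracking
recordings.

`pupilpipe` reads EyeLink ASC text exports (or any long-format sample table)
into tidy pandas data frames, runs a chainable per-trial preprocessing
pipeline over the pupil trace, computes robust quality-check diagnostics, and
summarizes fixations over polygonal areas of interest (AOIs). A synthetic
fixture generator with exact ground truth makes the whole stack testable
offline.

## Features

- **ASC reader with a marker grammar** — you declare how your MSG event
  markers are formatted (typed fields, delimiter, trial start/stop prefixes)
  and the reader segments samples into trials, pairs each sample with the
  most recent message, and collects EFIX/ESACC/EBLINK events.
- **Chainable pipeline** — `deblink`, `downsample` / `upsample`,
  `artifact_rejection` (speed threshold `median + 16×MAD` and/or CV-gated
  z-scores), `filter_position`, `smooth` (Hann over 100 samples by default,
  rolling mean, zero-phase Butterworth), `interpolate` (linear/cubic with a
  40 % missing cap), `baseline_correct` (subtractive/divisive). Every step
  writes a new suffixed column (`pp → pp_db → pp_db_ar → …`) so all
  intermediate data are preserved, and logs per-trial statistics.
- **Diagnostics** — MAD-band baseline outliers, grand-mean-distance trace
  outliers, a per-trial preprocessing summary, a `valid` column via
  `validate_trials`, and a gaze/pupil 2-D surface, with static figure export.
- **Fixations & AOIs** — boundary-inclusive point-in-polygon assignment
  (flat or per-trial nested AOIs, JSON persistence), fixation counts and
  dwell time per AOI, and duration-weighted density maps.
- **Synthetic fixtures** — seeded generators for pupil traces with injected
  blinks/spikes, full ASC recordings, and fixation sets with known AOI
  labels.

## Quick start

```python
from pupilpipe import MarkerSpec, PupilProcessor, read_asc

spec = MarkerSpec(
    fields=(("marker", "str"), ("event", "str"), ("block", "str"), ("trial", "int")),
    start_message="start fixation",
    stop_message="end feedback",
)
samples, events = read_asc("subject01.asc", spec)

proc = PupilProcessor(samples, trial_identifier=["block", "trial"])
(proc.deblink()
     .artifact_rejection()                      # speed + z-score, union
     .filter_position((0, 1920, 0, 1080))
     .smooth()                                  # Hann, 100 samples
     .interpolate(max_missing=0.4)
     .baseline_correct(event="fixation", last_k=100))

from pupilpipe import check_baseline_outliers, check_trace_outliers, summarize
baselines = {k: s["baseline"] for k, s in proc.steps[-1].trial_stats.items()}
summary = summarize(proc,
                    check_baseline_outliers(baselines, n=4),
                    check_trace_outliers(proc, n=4))
bad = summary[summary["baseline_outlier"] | ~summary["interpolated"].astype(bool)]
proc.validate_trials(bad[["block", "trial"]])   # adds the boolean `valid` column
```

AOIs:

```python
from pupilpipe import assign_aoi, compute_aoi_statistics, load_aois

aois = load_aois("aois.json")   # {"name": [[x, y], ...]} — closed polygons
stats = compute_aoi_statistics(fixations, aois, trial_cols="trial_id")
```

## CLI

```sh
pupilpipe read --asc s01.asc \
    --fields "marker:str,event:str,block:str,trial:int" \
    --start "start fixation" --stop "end feedback" --out samples.tsv
pupilpipe process --in samples.tsv --config pipeline.json --out processed.tsv
pupilpipe qc --in samples.tsv --config pipeline.json --out-dir qc/
pupilpipe aoi --fixations fix.tsv --aois aois.json --out aoi_stats.tsv
pupilpipe simulate --seed 7 --out-dir fixtures/
pupilpipe run --config run.json --out-dir results/
```

`pipeline.json` declares the ordered step list:

```json
{
  "trial_identifier": ["block", "trial"],
  "steps": [
    {"name": "deblink"},
    {"name": "artifact_rejection", "params": {"method": "both"}},
    {"name": "smooth", "params": {"window": 100}},
    {"name": "interpolate", "params": {"max_missing": 0.4}},
    {"name": "baseline_correct", "params": {"event": "fixation", "last_k": 100}}
  ]
}
```

## Tests and acceptance report

```sh
python -m pytest tests/                  # unit + property + acceptance suite
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script regenerates synthetic recordings from scratch, runs the
full pipeline, and verifies the package's behavioral contracts (round-trip
exactness, rejection oracles, artifact-removal and trace-recovery bounds,
AOI conservation); it exits non-zero if any check fails. There are no
numeric benchmark targets, so the JSON report is an empty object.

## Conventions and caveats

- Coordinates are screen pixels, origin top-left, y increasing downward; no
  rescaling is applied.
- Missing samples are NaN. Raw zeros recorded during signal loss are
  preserved in the input column and neutralized only by `deblink`.
- MAD is the raw median absolute deviation (no 1.4826 scaling); threshold
  comparisons are strict, so constant or linear traces reject nothing.
- Outlier flags are advisory: they never modify pupil columns. Exclusion
  happens only through `validate_trials`.
- Monocular analysis; for binocular ASC rows the reader takes one named eye
  (default left).
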