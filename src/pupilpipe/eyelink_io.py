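"""Read EyeLink ASC exports into tidy sample and event tables.

The reader is driven by a user-supplied marker grammar (:class:`MarkerSpec`)
that describes how MSG rows encode trial structure: an ordered list of typed
fields, a delimiter, and the message prefixes that open and close a trial.
Only samples recorded between a start message and the following stop message
are retained; each sample is paired with the most recent message preceding it.

Recorder-detected events (EFIX / ESACC / EBLINK rows) are collected into a
separate event table and assigned to the trial whose boundary fully contains
them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MarkerSpec",
    "MarkerParseError",
    "SchemaError",
    "ValidationError",
    "parse_marker",
    "read_asc",
    "read_many",
    "validate_generic",
]

logger = logging.getLogger(__name__)

#: canonical sample-table column names
SAMPLE_COLUMNS = ("trialtime", "trackertime", "x", "y", "pp", "msg", "msgtime")

_FIELD_TYPES: dict[str, Callable[[str], Any]] = {
    "str": str,
    "text": str,
    "int": int,
    "integer": int,
    "float": float,
    "decimal": float,
}

_EVENT_PREFIXES = ("EFIX", "ESACC", "EBLINK", "SFIX", "SSACC", "SBLINK")


class MarkerParseError(ValueError):
    """A MSG payload does not conform to the declared marker grammar."""


class SchemaError(ValueError):
    """Tables that should share a schema do not."""


class ValidationError(ValueError):
    """A generic sample table violates the canonical schema contract."""


@dataclass(frozen=True)
class MarkerSpec:
    """User-defined grammar for event-marker messages.

    Parameters
    ----------
    fields
        Ordered ``(name, type)`` pairs; type is one of ``str``/``text``,
        ``int``/``integer``, ``float``/``decimal``.
    start_message, stop_message
        Message prefixes that open and close a trial.
    delimiter
        Token separator inside a message (default: single space; runs of
        whitespace are collapsed in that case).
    constant_columns
        Optional mapping of extra column name -> constant value appended to
        every parsed sample row.
    """

    fields: tuple[tuple[str, str], ...]
    start_message: str
    stop_message: str
    delimiter: str = " "
    constant_columns: Mapping[str, Any] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "fields", tuple((str(n), str(t)) for n, t in self.fields))
        names = [n for n, _ in self.fields]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate marker field names: {names}")
        for name, ftype in self.fields:
            if ftype not in _FIELD_TYPES:
                raise ValueError(f"unknown field type {ftype!r} for field {name!r}")
        if not self.delimiter:
            raise ValueError("delimiter must be non-empty")
        for label, msg in (("start_message", self.start_message), ("stop_message", self.stop_message)):
            if len(self._tokenize(msg)) > len(self.fields):
                raise ValueError(
                    f"{label} {msg!r} has more tokens than the {len(self.fields)} declared fields"
                )

    def _tokenize(self, message: str) -> list[str]:
        if self.delimiter == " ":
            return message.split()
        return [t for t in message.split(self.delimiter)]

    @property
    def field_names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.fields)


def parse_marker(message: str, spec: MarkerSpec) -> dict[str, Any]:
    """Parse one marker message into typed field values.

    Raises
    ------
    MarkerParseError
        If the token count does not match the declared fields, or a token
        cannot be coerced to its declared type.
    """
    tokens = spec._tokenize(message)
    if len(tokens) != len(spec.fields):
        raise MarkerParseError(
            f"message {message!r} splits into {len(tokens)} tokens but "
            f"{len(spec.fields)} fields are declared"
        )
    out: dict[str, Any] = {}
    for (name, ftype), token in zip(spec.fields, tokens):
        try:
            out[name] = _FIELD_TYPES[ftype](token)
        except ValueError as exc:
            raise MarkerParseError(
                f"field {name!r}: cannot coerce token {token!r} to {ftype}"
            ) from exc
    return out


def format_marker(values: Mapping[str, Any], spec: MarkerSpec) -> str:
    """Inverse of :func:`parse_marker` on the grammar's message set."""
    delim = " " if spec.delimiter == " " else spec.delimiter
    return delim.join(str(values[name]) for name in spec.field_names)


def _parse_float(token: str) -> float:
    """Sample-row numeric token; '.' encodes track loss."""
    if token == ".":
        return np.nan
    return float(token)


@dataclass
class _TrialBuffer:
    values: dict[str, Any]
    start_time: int
    rows: list[tuple] = field(default_factory=list)


def read_asc(
    path: str | Path,
    spec: MarkerSpec,
    eye: str = "left",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Parse an ASC file into ``(samples, events)`` data frames.

    Sample rows (first token an integer timestamp) falling between a
    ``spec.start_message`` and the next ``spec.stop_message`` MSG are kept;
    everything outside trial boundaries is discarded. A start message with no
    matching stop before end-of-file drops the trial with a warning.
    Malformed sample rows are skipped and counted in a log message.

    For binocular sample rows (two x/y/pupil triplets) the requested ``eye``
    ("left" = first triplet, "right" = second) is taken.
    """
    path = Path(path)
    if eye not in ("left", "right"):
        raise ValueError(f"eye must be 'left' or 'right', got {eye!r}")

    trials: list[_TrialBuffer] = []
    current: _TrialBuffer | None = None
    boundaries: list[tuple[int, int]] = []  # (start msgtime, stop msgtime)
    msg_text = ""
    msg_time: int | None = None
    raw_events: list[dict[str, Any]] = []
    n_malformed = 0
    saw_start = False

    with path.open("r", errors="replace") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            tokens = line.split()
            head = tokens[0]

            if head == "MSG":
                parts = line.split(None, 2)
                if len(parts) < 3:
                    continue
                t = int(parts[1])
                text = parts[2].strip()
                if text.startswith(spec.start_message):
                    saw_start = True
                    if current is not None:
                        warnings.warn(
                            f"start message at {t} before stop for trial starting at "
                            f"{current.start_time}; dropping the unterminated trial",
                            stacklevel=2,
                        )
                    try:
                        values = parse_marker(text, spec)
                    except MarkerParseError as exc:
                        warnings.warn(f"unparseable start message {text!r}: {exc}", stacklevel=2)
                        current = None
                        continue
                    current = _TrialBuffer(values=values, start_time=t)
                    msg_text, msg_time = text, t
                elif text.startswith(spec.stop_message) and current is not None:
                    trials.append(current)
                    boundaries.append((current.start_time, t))
                    current = None
                    msg_text, msg_time = text, t
                else:
                    msg_text, msg_time = text, t
                    if current is not None:
                        try:
                            current.values = {**current.values, **parse_marker(text, spec)}
                        except MarkerParseError:
                            pass  # free-form message: pairs via msg column only
                continue

            if head.rstrip(":") in _EVENT_PREFIXES:
                ev = _parse_event_line(tokens)
                if ev is not None:
                    raw_events.append(ev)
                continue

            # sample rows: first token parses as an integer timestamp
            try:
                t = int(head)
            except ValueError:
                continue
            if current is None:
                continue
            try:
                nums = [_parse_float(tok) for tok in tokens[1:] if tok not in ("...", "I..", ".I.", "..I")]
                if len(nums) >= 6:  # binocular: xl yl ppl xr yr ppr
                    off = 0 if eye == "left" else 3
                    x, y, pp = nums[off], nums[off + 1], nums[off + 2]
                elif len(nums) >= 3:
                    x, y, pp = nums[0], nums[1], nums[2]
                else:
                    raise ValueError("too few numeric fields")
            except ValueError:
                n_malformed += 1
                continue
            current.rows.append(
                (t, x, y, pp, msg_text, msg_time)
                + tuple(current.values[n] for n in spec.field_names)
            )

    if current is not None:
        warnings.warn(
            f"trial starting at {current.start_time} has no stop message; dropped",
            stacklevel=2,
        )
    if not saw_start:
        warnings.warn(f"no '{spec.start_message}' / '{spec.stop_message}' pair found in {path}", stacklevel=2)
    if n_malformed:
        logger.warning("%s: skipped %d malformed sample row(s)", path, n_malformed)

    samples = _assemble_samples(trials, spec)
    events = _assemble_events(raw_events, trials, boundaries, spec)
    return samples, events


def _parse_event_line(tokens: Sequence[str]) -> dict[str, Any] | None:
    kind_map = {"EFIX": "fixation", "ESACC": "saccade", "EBLINK": "blink"}
    head = tokens[0]
    if head not in kind_map:
        return None  # SFIX/SSACC/SBLINK start markers carry no interval
    try:
        start, end = int(tokens[2]), int(tokens[3])
    except (IndexError, ValueError):
        return None
    ev: dict[str, Any] = {
        "kind": kind_map[head],
        "start_time": start,
        "end_time": end,
        "duration": end - start,
    }
    rest = [_parse_float(t) for t in tokens[4:] if _is_numeric(t)]
    if head == "EFIX" and len(rest) >= 3:
        ev.update(x=rest[1], y=rest[2])
    elif head == "ESACC" and len(rest) >= 5:
        ev.update(start_x=rest[1], start_y=rest[2], end_x=rest[3], end_y=rest[4])
        if len(rest) >= 6:
            ev.update(amplitude=rest[5])
    return ev


def _is_numeric(token: str) -> bool:
    if token == ".":
        return True
    try:
        float(token)
        return True
    except ValueError:
        return False


def _assemble_samples(trials: list[_TrialBuffer], spec: MarkerSpec) -> pd.DataFrame:
    field_cols = list(spec.field_names)
    const = dict(spec.constant_columns or {})
    columns = field_cols + list(SAMPLE_COLUMNS) + list(const)
    frames = []
    for tr in trials:
        if not tr.rows:
            continue
        arr = pd.DataFrame(
            tr.rows,
            columns=["trackertime", "x", "y", "pp", "msg", "msgtime"] + field_cols,
        )
        arr.insert(0, "trialtime", arr["trackertime"] - arr["trackertime"].iloc[0])
        for name, value in const.items():
            arr[name] = value
        frames.append(arr[columns])
    if not frames:
        return pd.DataFrame(columns=columns)
    return pd.concat(frames, ignore_index=True)


def _assemble_events(
    raw_events: list[dict[str, Any]],
    trials: list[_TrialBuffer],
    boundaries: list[tuple[int, int]],
    spec: MarkerSpec,
) -> pd.DataFrame:
    field_cols = list(spec.field_names)
    base_cols = ["kind", "start_time", "end_time", "duration",
                 "x", "y", "start_x", "start_y", "end_x", "end_y", "amplitude"]
    rows = []
    for ev in raw_events:
        for tr, (t0, t1) in zip(trials, boundaries):
            if t0 <= ev["start_time"] and ev["end_time"] <= t1:
                rows.append({**ev, **{n: tr.values[n] for n in field_cols}})
                break
    df = pd.DataFrame(rows, columns=base_cols + field_cols)
    return df


def read_many(
    paths: Iterable[str | Path],
    spec: MarkerSpec,
    id_from: Callable[[Path], Any] | None = None,
    eye: str = "left",
) -> pd.DataFrame:
    """Read several ASC files and concatenate their sample tables.

    ``id_from`` maps each path to a participant identifier stored in a
    ``participant`` column (default: the file stem).
    """
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValueError("read_many requires at least one path")
    if id_from is None:
        id_from = lambda p: p.stem  # noqa: E731
    frames = []
    ref_cols: list[str] | None = None
    for p in paths:
        samples, _ = read_asc(p, spec, eye=eye)
        samples = samples.copy()
        samples.insert(0, "participant", id_from(p))
        if ref_cols is None:
            ref_cols = list(samples.columns)
        elif list(samples.columns) != ref_cols:
            diff = set(samples.columns).symmetric_difference(ref_cols)
            raise SchemaError(f"column schema mismatch in {p}: {sorted(diff)}")
        frames.append(samples)
    return pd.concat(frames, ignore_index=True)


def validate_generic(table: pd.DataFrame, column_map: Mapping[str, Any]) -> pd.DataFrame:
    """Validate a generic long-format sample table and canonicalize its roles.

    ``column_map`` must map the roles ``trial`` (one column name or a list),
    ``time``, ``x``, ``y`` and ``pupil`` to columns of ``table``. Time must be
    strictly increasing within every trial. The returned copy renames the
    time/x/y/pupil columns to the canonical ``trialtime``/``x``/``y``/``pp``.
    """
    required = ("trial", "time", "x", "y", "pupil")
    for role in required:
        if role not in column_map or column_map[role] in (None, "", []):
            raise ValidationError(f"role {role!r} unmapped")
    trial_cols = column_map["trial"]
    if isinstance(trial_cols, str):
        trial_cols = [trial_cols]
    trial_cols = list(trial_cols)
    roles = {"time": column_map["time"], "x": column_map["x"],
             "y": column_map["y"], "pupil": column_map["pupil"]}
    missing = [c for c in trial_cols + list(roles.values()) if c not in table.columns]
    if missing:
        raise ValidationError(f"mapped column(s) not in table: {missing}")

    tcol = roles["time"]
    for key, group in table.groupby(trial_cols, sort=False):
        if isinstance(key, tuple) and len(key) == 1:
            key = key[0]
        t = np.asarray(group[tcol], dtype=float)
        dt = np.diff(t)
        if np.any(dt == 0):
            raise ValidationError(f"duplicate timestamps within trial {key!r}")
        if np.any(dt < 0):
            raise ValidationError(f"time not monotonically increasing in trial {key!r}")

    rename = {roles["time"]: "trialtime", roles["x"]: "x",
              roles["y"]: "y", roles["pupil"]: "pp"}
    rename = {k: v for k, v in rename.items() if k != v}
    clash = [v for v in rename.values() if v in table.columns]
    if clash:
        raise ValidationError(f"cannot canonicalize: column(s) {clash} already exist")
    out = table.copy().rename(columns=rename)
    out.attrs["trial_identifier"] = trial_cols
    return out
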