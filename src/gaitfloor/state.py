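"""Event-driven reconstruction of the floor's capacitance state.

The floor's modules emit a message only when at least one of their eight
field capacitances has changed by more than an internal threshold since the
last emission. Each message carries the module id and the *current* values of
all eight fields, so the full floor state at any time is the fold of all
messages received so far over an all-zero initial state: a discrete-time
dynamical system whose only input is the message stream.

A state snapshot holds, per sensor field: the field id, its centroid position
(global frame, metres), the time of its last measurement and its capacitance
in [0, 1]. Updating with a message replaces the eight entries of that
message's module and leaves every other entry untouched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyInputError, OutOfOrderError, ValidationError
from .geometry import FIELDS_PER_MODULE, FloorLayout


@dataclass(frozen=True)
class SensorMessage:
    """One module's report: timestamp, module id and its 8 field capacitances."""

    t: float
    module: str
    c: np.ndarray  # shape (8,), values in [0, 1]

    def __post_init__(self) -> None:
        c = np.asarray(self.c, dtype=float)
        if c.shape != (FIELDS_PER_MODULE,):
            raise ValidationError(f"message must carry 8 capacitances, got shape {c.shape}")
        if not np.all(np.isfinite(c)) or c.min() < 0.0 or c.max() > 1.0:
            raise ValidationError("capacitances must be finite and within [0, 1]")
        if not np.isfinite(self.t) or self.t < 0.0:
            raise ValidationError(f"message time must be >= 0, got {self.t}")
        c.setflags(write=False)
        object.__setattr__(self, "c", c)
        object.__setattr__(self, "t", float(self.t))


@dataclass(frozen=True)
class SensorState:
    """Snapshot of all field capacitances and last-measurement times at one instant.

    The entry set is fixed at initialisation: exactly 8 entries per module of
    the layout, forever. Arrays are read-only; updates produce new snapshots.
    """

    layout: FloorLayout
    t_f: np.ndarray  # (n_fields,) last measurement time per field, seconds
    c_f: np.ndarray  # (n_fields,) capacitance per field in [0, 1]

    def __post_init__(self) -> None:
        n = self.layout.n_fields
        if self.t_f.shape != (n,) or self.c_f.shape != (n,):
            raise ValidationError("state arrays must have one entry per field")
        self.t_f.setflags(write=False)
        self.c_f.setflags(write=False)

    def __len__(self) -> int:
        return self.layout.n_fields

    @property
    def positions(self) -> np.ndarray:
        return self.layout.positions


def init_state(layout: FloorLayout) -> SensorState:
    """All-zero initial state: every capacitance and measurement time is 0."""
    n = layout.n_fields
    return SensorState(layout, np.zeros(n), np.zeros(n))


def apply_message(state: SensorState, msg: SensorMessage) -> SensorState:
    """Fold one message into the state (replacement semantics).

    The 8 entries of the message's module take the message's values and
    timestamp; all other entries are unchanged bit-for-bit. Messages older
    than the module's newest entry are rejected: the stream is assumed
    ordered and reordering is out of scope.
    """
    sl = state.layout.module_slice(msg.module)
    if state.t_f[sl].size and msg.t < state.t_f[sl].max():
        raise OutOfOrderError(
            f"message for module {msg.module!r} at t={msg.t} precedes "
            f"existing entry time {state.t_f[sl].max()}"
        )
    t_f = state.t_f.copy()
    c_f = state.c_f.copy()
    t_f[sl] = msg.t
    c_f[sl] = msg.c
    return SensorState(state.layout, t_f, c_f)


def replay(
    layout: FloorLayout, messages: Sequence[SensorMessage]
) -> list[SensorState]:
    """Fold a time-ordered message stream into one state per message.

    Returns the post-update state after each message (the initial all-zero
    state is not included). Unsorted input raises; equal timestamps are
    applied in stream order (modules are disjoint, so ties commute).
    """
    times = [m.t for m in messages]
    if any(b < a for a, b in zip(times, times[1:])):
        raise OutOfOrderError("message stream is not sorted by timestamp")
    states: list[SensorState] = []
    state = init_state(layout)
    for msg in messages:
        state = apply_message(state, msg)
        states.append(state)
    return states


def iter_replay(
    layout: FloorLayout, messages: Iterable[SensorMessage]
) -> Iterator[SensorState]:
    """Streaming variant of :func:`replay` (constant memory)."""
    state = init_state(layout)
    last_t = -np.inf
    for msg in messages:
        if msg.t < last_t:
            raise OutOfOrderError("message stream is not sorted by timestamp")
        last_t = msg.t
        state = apply_message(state, msg)
        yield state


def footfall_map(states: Sequence[SensorState]) -> pd.DataFrame:
    """Per-field maximum capacitance over a recording.

    Clusters of neighbouring fields with a high maximum correspond to
    footfalls; this is the standard diagnostic plot of a recording. Returns a
    frame with columns (field_id, x, y, max_c).
    """
    if len(states) == 0:
        raise EmptyInputError("footfall map of an empty state series")
    layout = states[0].layout
    max_c = np.zeros(layout.n_fields)
    for s in states:
        np.maximum(max_c, s.c_f, out=max_c)
    pos = layout.positions
    return pd.DataFrame(
        {
            "field_id": layout.field_ids,
            "x": pos[:, 0],
            "y": pos[:, 1],
            "max_c": max_c,
        }
    )


# -- message log I/O --------------------------------------------------------
#
# Canonical log format is JSON-lines, one object per message:
#   {"t": <seconds>, "module": <id>, "c": [<8 floats>]}
# A CSV representation (columns t, module, c1..c8) is also supported.


def write_messages_jsonl(messages: Iterable[SensorMessage], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in messages:
            fh.write(
                json.dumps({"t": m.t, "module": m.module, "c": [round(v, 6) for v in m.c]})
                + "\n"
            )


def read_messages_jsonl(path: str | Path) -> list[SensorMessage]:
    out: list[SensorMessage] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            out.append(SensorMessage(obj["t"], obj["module"], np.asarray(obj["c"])))
    return out


_CSV_COLS = ["t", "module"] + [f"c{j}" for j in range(1, FIELDS_PER_MODULE + 1)]


def write_messages_csv(messages: Iterable[SensorMessage], path: str | Path) -> None:
    rows = [[m.t, m.module, *np.round(m.c, 6)] for m in messages]
    pd.DataFrame(rows, columns=_CSV_COLS).to_csv(path, index=False)


def read_messages_csv(path: str | Path) -> list[SensorMessage]:
    df = pd.read_csv(path)
    missing = set(_CSV_COLS) - set(df.columns)
    if missing:
        raise ValidationError(f"message CSV missing columns: {sorted(missing)}")
    cvals = df[[f"c{j}" for j in range(1, FIELDS_PER_MODULE + 1)]].to_numpy(float)
    return [
        SensorMessage(float(t), str(mod), c)
        for t, mod, c in zip(df["t"], df["module"], cvals)
    ]
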