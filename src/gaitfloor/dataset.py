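"""Walk segmentation, sliding windows and leave-one-out split plans.

A recording is one out-and-back pass over the floor; the analysis operates
on straight directed walks, so each recording is split at the turning point
and the states near the turn are discarded (turning gait is not straight
walking). The vector series of every walk is then cut into overlapping
windows of 30 consecutive event-driven vectors — the sequence samples the
network trains on — and walks are assembled into leave-one-out
cross-validation folds:

* idiosyncratic design — all walks of one participant, two classes; each
  fold tests on a single walk, validates on the next walk in a fixed
  rotation, trains on the rest;
* generalised design — each fold tests on all walks of one participant,
  validates on all walks of the next participant in a fixed rotation, trains
  on the rest, so no participant ever appears in two sets of a fold.

All windows of a walk stay in one set; splits are constructed so that no
window can leak between train, validation and test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ValidationError

WALKING_MODES = ("normal", "fast", "slow", "closed_eyes", "dual_task", "post_uhr")
DIRECTIONS = ("door_to_window", "window_to_door")
DEFAULT_WINDOW_LENGTH = 30
DEFAULT_TRIM_RADIUS = 0.5


@dataclass
class Walk:
    """One directed straight walk: its activation-vector series plus metadata."""

    walk_id: str
    participant: str
    mode: str
    direction: str
    vectors: np.ndarray  # (T, grid length)
    uhr_left: int | None = None
    uhr_right: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in WALKING_MODES:
            raise ValidationError(f"unknown walking mode {self.mode!r}")
        if self.direction not in DIRECTIONS:
            raise ValidationError(f"unknown direction {self.direction!r}")
        self.vectors = np.asarray(self.vectors)

    @property
    def n_vectors(self) -> int:
        return len(self.vectors)

    def n_windows(self, length: int = DEFAULT_WINDOW_LENGTH, stride: int = 1) -> int:
        return len(window_starts(self.n_vectors, length, stride))


def window_starts(n: int, length: int, stride: int) -> np.ndarray:
    if length < 1 or stride < 1:
        raise ValidationError("window length and stride must be >= 1")
    if n < length:
        return np.empty(0, dtype=int)
    return np.arange(0, n - length + 1, stride)


def window(series: np.ndarray, length: int = DEFAULT_WINDOW_LENGTH, stride: int = 1) -> np.ndarray:
    """Overlapping windows over a (T, d) series; shape (n_windows, length, d).

    With stride 1 a series of T rows yields ``max(0, T - length + 1)``
    windows; series shorter than the window yield none.
    """
    series = np.asarray(series)
    starts = window_starts(len(series), length, stride)
    if len(starts) == 0:
        return np.empty((0, length) + series.shape[1:], dtype=series.dtype)
    return np.stack([series[s : s + length] for s in starts])


def segment_walks(
    positions: np.ndarray, trim_radius: float = DEFAULT_TRIM_RADIUS
) -> list[np.ndarray]:
    """Split an out-and-back trajectory at the turning point.

    ``positions`` are the tracked positions per state (rows). The dominant
    axis is the one with the larger coordinate range; the turning point is
    the state farthest from the start along it. States within ``trim_radius``
    (metres, Euclidean) of the turning point are removed from both segments,
    because gait right before and after turning is not straight walking. A
    trajectory whose return leg travels less than ``trim_radius`` back is
    treated as a single pass: one segment, nothing trimmed. Segments with
    fewer than two remaining states are dropped.

    Returns index arrays into ``positions``, one per directed walk.
    """
    positions = np.asarray(positions, float)
    if len(positions) < 2:
        return []
    ranges = positions.max(axis=0) - positions.min(axis=0)
    axis = int(np.argmax(ranges))
    disp = positions[:, axis] - positions[0, axis]
    if np.allclose(disp, 0.0):
        return []
    i_turn = int(np.argmax(np.abs(disp)))
    turn_pos = positions[i_turn]
    back = np.abs(disp[i_turn] - disp[i_turn:])
    single_pass = len(back) == 0 or back.max() < trim_radius
    if single_pass:
        segments = [np.arange(len(positions))]
        return [s for s in segments if len(s) >= 2]
    dist_to_turn = np.linalg.norm(positions - turn_pos, axis=1)
    keep = dist_to_turn >= trim_radius
    out_leg = np.arange(0, i_turn + 1)
    back_leg = np.arange(i_turn + 1, len(positions))
    segments = [out_leg[keep[out_leg]], back_leg[keep[back_leg]]]
    return [s for s in segments if len(s) >= 2]


@dataclass(frozen=True)
class Fold:
    """One cross-validation fold: disjoint train/validation/test walk indices."""

    train: tuple[int, ...]
    validation: tuple[int, ...]
    test: tuple[int, ...]

    def __post_init__(self) -> None:
        tr, va, te = set(self.train), set(self.validation), set(self.test)
        if tr & te or tr & va or va & te:
            raise ValidationError("fold sets must be pairwise disjoint")


@dataclass(frozen=True)
class SplitPlan:
    """A leave-one-out design: list of folds over a fixed walk collection."""

    design: str  # "idiosyncratic" | "generalised"
    folds: tuple[Fold, ...]

    def to_json(self, path: str | Path) -> None:
        obj = {
            "design": self.design,
            "folds": [
                {"train": list(f.train), "validation": list(f.validation), "test": list(f.test)}
                for f in self.folds
            ],
        }
        Path(path).write_text(json.dumps(obj, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitPlan":
        obj = json.loads(Path(path).read_text())
        folds = tuple(
            Fold(tuple(f["train"]), tuple(f["validation"]), tuple(f["test"]))
            for f in obj["folds"]
        )
        return cls(obj["design"], folds)

    def class_balance(self, walks: Sequence[Walk]) -> pd.DataFrame:
        """Per-fold count of walks per mode in each set (for run logs)."""
        rows = []
        for i, f in enumerate(self.folds):
            for name, idx in (("train", f.train), ("validation", f.validation), ("test", f.test)):
                for j in idx:
                    rows.append({"fold": i, "set": name, "mode": walks[j].mode})
        return (
            pd.DataFrame(rows)
            .groupby(["fold", "set", "mode"])
            .size()
            .rename("n_walks")
            .reset_index()
        )


def make_splits(walks: Sequence[Walk], design: str) -> SplitPlan:
    """Build the leave-one-out folds for either analysis design.

    Idiosyncratic requires all walks from one participant and exactly two
    modes; generalised requires at least three participants. The validation
    unit is the next walk/participant in a fixed rotation, so folds are
    reproducible without randomness.
    """
    n = len(walks)
    if design == "idiosyncratic":
        participants = {w.participant for w in walks}
        if len(participants) != 1:
            raise ValidationError("idiosyncratic design requires walks of a single participant")
        if len({w.mode for w in walks}) != 2:
            raise ValidationError("idiosyncratic design requires exactly two walking modes")
        if n < 3:
            raise InsufficientDataError("need at least 3 walks for idiosyncratic folds")
        folds = []
        for i in range(n):
            val = (i + 1) % n
            train = tuple(j for j in range(n) if j not in (i, val))
            folds.append(Fold(train, (val,), (i,)))
        return SplitPlan(design, tuple(folds))
    if design == "generalised":
        participants = sorted({w.participant for w in walks})
        if len(participants) < 3:
            raise InsufficientDataError("need at least 3 participants for generalised folds")
        by_p = {p: [i for i, w in enumerate(walks) if w.participant == p] for p in participants}
        folds = []
        for k, p in enumerate(participants):
            q = participants[(k + 1) % len(participants)]
            test = tuple(by_p[p])
            val = tuple(by_p[q])
            train = tuple(i for i in range(n) if walks[i].participant not in (p, q))
            folds.append(Fold(train, val, test))
        return SplitPlan(design, tuple(folds))
    raise ValidationError(f"unknown design {design!r}")


def manifest(walks: Sequence[Walk], window_length: int = DEFAULT_WINDOW_LENGTH) -> pd.DataFrame:
    """Dataset manifest: one row per walk with its metadata and window count."""
    return pd.DataFrame(
        {
            "walk_id": [w.walk_id for w in walks],
            "participant": [w.participant for w in walks],
            "mode": [w.mode for w in walks],
            "direction": [w.direction for w in walks],
            "n_vectors": [w.n_vectors for w in walks],
            "n_windows": [w.n_windows(window_length) for w in walks],
            "uhr_left": [w.uhr_left for w in walks],
            "uhr_right": [w.uhr_right for w in walks],
        }
    )
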