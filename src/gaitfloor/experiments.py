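"""End-to-end experiment designs: preprocessing, training and evaluation.

Three designs mirror the study protocol:

* ``idio_mode`` — per-participant (idiosyncratic) walking-mode
  classification: one network per participant and interference mode,
  leave-one-walk-out.
* ``gen_mode`` — generalised walking-mode classification: one network per
  fold, leave-one-participant-out, asking whether a mode changes gait in a
  way common to all participants.
* ``gen_uhr`` — generalised regression of unilateral heel-rise repetitions
  from normal-pace walks, participants held out in folds.

Window-level metrics are the primary report (the classifier operates on
30-step windows); walk-level majority-vote metrics are reported separately.
Every fold logs its seed, epochs run and metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import (
    DEFAULT_TRIM_RADIUS,
    DEFAULT_WINDOW_LENGTH,
    SplitPlan,
    Walk,
    make_splits,
    segment_walks,
    window,
)
from .errors import ConfigError, DegenerateWalkError, InsufficientDataError
from .metrics import (
    EvalReport,
    aggregate_reports,
    classification_report,
    majority_vote,
    regression_report,
)
from .nn import NetworkConfig, SequenceNet, TrainingConfig
from .simulate import Recording
from .state import iter_replay
from .transform import (
    DEFAULT_C_THRESHOLD,
    GridSpec,
    preprocess_sparse_series,
    sparsify,
    track,
)

log = logging.getLogger("gaitfloor")


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the state-to-vector preprocessing chain."""

    c_threshold: float = DEFAULT_C_THRESHOLD
    grid: GridSpec = field(default_factory=GridSpec)
    trim_radius: float = DEFAULT_TRIM_RADIUS
    window_length: int = DEFAULT_WINDOW_LENGTH
    stride: int = 1


def preprocess_recording(
    recording: Recording,
    layout,
    cfg: PreprocessConfig | None = None,
) -> list[Walk]:
    """Replay one recording and cut it into preprocessed directed walks.

    The message stream is folded into states, the walker tracked, the
    trajectory split at the turning point (turn-adjacent states trimmed),
    and each segment localised with its own walking angle and resampled to
    the receptive-field grid. Segments too short to track are skipped.
    """
    cfg = cfg or PreprocessConfig()
    sparse = [sparsify(s, cfg.c_threshold) for s in iter_replay(layout, recording.messages)]
    traj = track(sparse)
    valid = np.flatnonzero(traj.valid)
    if len(valid) < 2:
        return []
    segments = segment_walks(traj.positions[valid], cfg.trim_radius)
    walks: list[Walk] = []
    for si, seg in enumerate(segments):
        idx = valid[seg]
        seg_sparse = [sparse[i] for i in idx]
        try:
            vectors, _, _ = preprocess_sparse_series(seg_sparse, grid=cfg.grid)
        except DegenerateWalkError:  # segment without definable direction
            continue
        direction = "door_to_window" if si == 0 else "window_to_door"
        walks.append(
            Walk(
                walk_id=f"{recording.recording_id}_{direction}",
                participant=recording.participant,
                mode=recording.mode,
                direction=direction,
                vectors=vectors,
                uhr_left=recording.uhr_left,
                uhr_right=recording.uhr_right,
            )
        )
    return walks


def preprocess_cohort(
    recordings: Sequence[Recording],
    layout,
    cfg: PreprocessConfig | None = None,
) -> tuple[list[Walk], int]:
    """Preprocess every recording; returns (walks, n_dropped_short).

    Walks shorter than the window length are dropped here and counted, so
    the run log can report them.
    """
    cfg = cfg or PreprocessConfig()
    walks: list[Walk] = []
    dropped = 0
    for rec in recordings:
        for w in preprocess_recording(rec, layout, cfg):
            if w.n_vectors >= cfg.window_length:
                walks.append(w)
            else:
                dropped += 1
    log.info("preprocessed %d walks (%d dropped below window length)", len(walks), dropped)
    return walks, dropped


# -- window assembly ---------------------------------------------------------


def _windows_for(
    walks: Sequence[Walk],
    idx: Sequence[int],
    label_fn,
    length: int,
    stride: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack windows of the selected walks: (X, y, walk_index_per_window)."""
    xs, ys, wi = [], [], []
    for i in idx:
        w = walks[i]
        win = window(w.vectors, length, stride)
        if len(win) == 0:
            continue
        xs.append(win)
        ys.append(np.full(len(win), label_fn(w)))
        wi.append(np.full(len(win), i))
    if not xs:
        d = walks[idx[0]].vectors.shape[1] if len(idx) else 0
        return np.empty((0, length, d)), np.empty(0), np.empty(0, int)
    return np.concatenate(xs), np.concatenate(ys), np.concatenate(wi)


@dataclass
class FoldResult:
    """Outcome of one cross-validation fold."""

    fold: int
    seed: int
    n_epochs: int
    best_epoch: int
    report: EvalReport
    walk_report: EvalReport | None = None
    test_participants: tuple[str, ...] = ()
    walk_predictions: pd.DataFrame | None = None


@dataclass
class ExperimentResult:
    """Per-fold results plus the aggregate over folds."""

    design: str
    folds: list[FoldResult]
    aggregate: dict

    def fold_frame(self) -> pd.DataFrame:
        rows = []
        for f in self.folds:
            row = {
                "fold": f.fold,
                "participants": "|".join(f.test_participants),
                "seed": f.seed,
                "epochs": f.n_epochs,
                "best_epoch": f.best_epoch,
            }
            row.update(f.report.as_dict())
            rows.append(row)
        return pd.DataFrame(rows)


def _mode_label_fn(positive_mode: str):
    def label(w: Walk) -> int:
        return 1 if w.mode == positive_mode else 0

    return label


def run_mode_classification(
    walks: Sequence[Walk],
    positive_mode: str,
    design: str = "generalised",
    ncfg: NetworkConfig | None = None,
    tcfg: TrainingConfig | None = None,
    window_length: int = DEFAULT_WINDOW_LENGTH,
    stride: int = 1,
    seed: int | None = None,
) -> ExperimentResult:
    """One leave-one-out classification run (normal vs. ``positive_mode``).

    ``design`` selects the fold structure ("idiosyncratic" requires walks of
    a single participant). ``seed`` drives both weight initialisation and
    batch shuffling per fold (fold k uses seed + k), so a run is exactly
    repeatable; pass different seeds for independent repeats.
    """
    walks = [w for w in walks if w.mode in ("normal", positive_mode)]
    if not walks:
        raise InsufficientDataError("no walks for the requested mode pair")
    split = make_splits(walks, design)
    label_fn = _mode_label_fn(positive_mode)
    d = walks[0].vectors.shape[1]
    ncfg = ncfg or NetworkConfig(input_size=d, window_length=window_length)
    if ncfg.task != "classification":
        raise ConfigError("mode classification needs a classification head")
    tcfg = tcfg or TrainingConfig()
    base_seed = seed if seed is not None else int(np.random.default_rng().integers(2**31 - 1))
    folds: list[FoldResult] = []
    for k, fold in enumerate(split.folds):
        fold_seed = base_seed + k
        Xtr, ytr, _ = _windows_for(walks, fold.train, label_fn, window_length, stride)
        Xva, yva, _ = _windows_for(walks, fold.validation, label_fn, window_length, stride)
        Xte, yte, wte = _windows_for(walks, fold.test, label_fn, window_length, stride)
        if len(Xtr) == 0 or len(Xva) == 0 or len(Xte) == 0:
            raise InsufficientDataError(f"fold {k}: a split set has no windows")
        net = SequenceNet(ncfg, seed=fold_seed, dtype=tcfg.dtype)
        hist = net.fit(Xtr, ytr, Xva, yva, replace(tcfg, seed=fold_seed))
        pred = net.predict(Xte)
        report = classification_report(yte, pred)
        # walk-level majority vote, reported separately from window metrics
        w_true, w_pred = [], []
        for wi in np.unique(wte):
            w_true.append(label_fn(walks[int(wi)]))
            w_pred.append(majority_vote(pred[wte == wi]))
        walk_report = classification_report(np.array(w_true), np.array(w_pred))
        parts = tuple(sorted({walks[i].participant for i in fold.test}))
        folds.append(
            FoldResult(
                fold=k, seed=fold_seed, n_epochs=hist["n_epochs"],
                best_epoch=hist["best_epoch"], report=report,
                walk_report=walk_report, test_participants=parts,
            )
        )
        log.info(
            "fold %d (%s): acc=%.3f epochs=%d", k, ",".join(parts),
            report.accuracy, hist["n_epochs"],
        )
    agg = aggregate_reports([f.report for f in folds])
    agg["walk_level"] = aggregate_reports([f.walk_report for f in folds])
    return ExperimentResult(design=design, folds=folds, aggregate=agg)


def run_idiosyncratic_mode(
    walks: Sequence[Walk],
    positive_mode: str,
    **kwargs,
) -> dict[str, ExperimentResult]:
    """Idiosyncratic design: one leave-one-walk-out run per participant."""
    out: dict[str, ExperimentResult] = {}
    for p in sorted({w.participant for w in walks}):
        pw = [w for w in walks if w.participant == p]
        out[p] = run_mode_classification(pw, positive_mode, design="idiosyncratic", **kwargs)
    return out


def run_uhr_regression(
    walks: Sequence[Walk],
    leg: str = "right",
    ncfg: NetworkConfig | None = None,
    tcfg: TrainingConfig | None = None,
    window_length: int = DEFAULT_WINDOW_LENGTH,
    stride: int = 1,
    seed: int | None = None,
    n_holdout: int = 1,
    n_model_seeds: int = 1,
) -> ExperimentResult:
    """Predict heel-rise repetitions from normal-pace walks, participants held out.

    ``n_holdout`` > 1 groups several participants per test fold (a coarser
    but cheaper variant of leave-one-participant-out). ``n_model_seeds`` > 1
    trains an ensemble of independently seeded networks per fold and
    averages their predictions, which damps the run-to-run variability of
    small-network training (the same reason the protocol repeats runs with
    fresh seeds). The aggregate reports both the pooled window-level metrics
    and participant-level metrics computed from each held-out participant's
    mean prediction.
    """
    if leg not in ("left", "right"):
        raise ConfigError("leg must be 'left' or 'right'")
    walks = [w for w in walks if w.mode == "normal"]
    participants = sorted({w.participant for w in walks})
    if len(participants) < 3 * n_holdout:
        raise InsufficientDataError("too few participants for the requested folds")

    def target(w: Walk) -> float:
        val = w.uhr_right if leg == "right" else w.uhr_left
        if val is None:
            raise InsufficientDataError(f"walk {w.walk_id} lacks a UHR count")
        return float(val)

    d = walks[0].vectors.shape[1]
    ncfg = ncfg or NetworkConfig(input_size=d, window_length=window_length, task="regression")
    if ncfg.task != "regression":
        raise ConfigError("UHR prediction needs a regression head")
    tcfg = tcfg or TrainingConfig()
    base_seed = seed if seed is not None else int(np.random.default_rng().integers(2**31 - 1))
    groups = [participants[i : i + n_holdout] for i in range(0, len(participants), n_holdout)]
    by_p = {p: [i for i, w in enumerate(walks) if w.participant == p] for p in participants}
    folds: list[FoldResult] = []
    part_rows = []
    for k, test_group in enumerate(groups):
        val_group = groups[(k + 1) % len(groups)]
        test_idx = [i for p in test_group for i in by_p[p]]
        val_idx = [i for p in val_group for i in by_p[p]]
        train_idx = [
            i for i, w in enumerate(walks)
            if w.participant not in set(test_group) | set(val_group)
        ]
        fold_seed = base_seed + k
        Xtr, ytr, _ = _windows_for(walks, train_idx, target, window_length, stride)
        Xva, yva, _ = _windows_for(walks, val_idx, target, window_length, stride)
        Xte, yte, wte = _windows_for(walks, test_idx, target, window_length, stride)
        if len(Xtr) == 0 or len(Xva) == 0 or len(Xte) == 0:
            raise InsufficientDataError(f"fold {k}: a split set has no windows")
        preds = []
        for j in range(n_model_seeds):
            member_seed = fold_seed + 1000 * j
            net = SequenceNet(ncfg, seed=member_seed, dtype=tcfg.dtype)
            hist = net.fit(Xtr, ytr, Xva, yva, replace(tcfg, seed=member_seed))
            preds.append(net.predict(Xte))
        pred = np.mean(preds, axis=0)
        report = regression_report(yte, pred)
        for p in test_group:
            mask = np.isin(wte, by_p[p])
            if mask.any():
                part_rows.append(
                    {
                        "participant": p,
                        "true": target(walks[by_p[p][0]]),
                        "predicted": float(pred[mask].mean()),
                        "fold": k,
                    }
                )
        folds.append(
            FoldResult(
                fold=k, seed=fold_seed, n_epochs=hist["n_epochs"],
                best_epoch=hist["best_epoch"], report=report,
                test_participants=tuple(test_group),
            )
        )
        log.info("uhr fold %d: rmse=%.2f epochs=%d", k, report.rmse, hist["n_epochs"])
    agg = aggregate_reports([f.report for f in folds])
    part_df = pd.DataFrame(part_rows)
    participant_report = regression_report(
        part_df["true"].to_numpy(), part_df["predicted"].to_numpy()
    )
    agg["participant_level"] = participant_report.as_dict()
    result = ExperimentResult(design="generalised", folds=folds, aggregate=agg)
    result.aggregate["participant_predictions"] = part_df.to_dict("records")
    return result


def run_experiment(
    design: str,
    walks: Sequence[Walk],
    positive_mode: str = "closed_eyes",
    leg: str = "right",
    repeats: int = 1,
    seed: int | None = None,
    **kwargs,
):
    """Dispatch one of the three study designs, optionally repeated.

    ``seed`` fixes the whole run; with ``seed=None`` each repeat draws a
    fresh random seed (logged in the per-fold results, mirroring the
    protocol of re-running with random seeds to rule out incidental
    results). Returns a list of one result per repeat (``idio_mode`` yields
    one dict of per-participant results per repeat).
    """
    rng = np.random.default_rng(seed)
    results = []
    for rep in range(repeats):
        rep_seed = int(rng.integers(2**31 - 1))
        if design == "idio_mode":
            results.append(run_idiosyncratic_mode(walks, positive_mode, seed=rep_seed, **kwargs))
        elif design == "gen_mode":
            results.append(
                run_mode_classification(walks, positive_mode, design="generalised",
                                        seed=rep_seed, **kwargs)
            )
        elif design == "gen_uhr":
            results.append(run_uhr_regression(walks, leg=leg, seed=rep_seed, **kwargs))
        else:
            raise ConfigError(f"unknown design {design!r}")
    return results
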