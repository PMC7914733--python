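"""Transformation of floor states into the walker-local receptive-field grid.

Gait is translation- and rotation-invariant: what matters is the pattern of
activations around the walker, not where on the floor it happens. Each state
snapshot is therefore

1. sparsified — only fields with capacitance strictly above ``c_threshold``
   are kept (default 0.03, i.e. 3% of the measuring range, which suppresses
   sensor fluctuations);
2. tracked — the walker position is the capacitance-weighted mean of the
   active field positions, like the centre of mass of a particle system;
3. localised — active fields are translated to the tracked position, rotated
   so the walking direction becomes the +y axis, and cut off at radius
   ``r_s``;
4. resampled — each remaining field centroid assigns its capacitance to the
   nearest point of a fixed square lattice with spacing ``l_s`` limited to
   radius ``r_s``;
5. unrolled — the lattice values are flattened, in a fixed meander order,
   into the activation vector fed to the sequence model.

The walking direction of a walk is the vector from the first to the last
tracked position; the walking angle theta is the *signed* angle that rotates
the unit direction onto (0, 1).

``l_s`` and ``r_s`` are free parameters of the method. Defaults: ``l_s``
0.10 m (below the ~0.13 m centroid spacing of the gait-resolution module
type, so distinct fields rarely collide on one lattice point) and ``r_s``
1.0 m (covers the current double support and the adjacent footfalls at an
ordinary ~0.7 m step length).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .errors import DegenerateWalkError, EmptyInputError, InvalidGridError, ValidationError
from .state import SensorState

DEFAULT_C_THRESHOLD = 0.03
DEFAULT_GRID_SPACING = 0.10
DEFAULT_GRID_RADIUS = 1.0

#: bump when the lattice enumeration/meander order changes; stored in sidecars
GRID_ORDERING_VERSION = 1


@dataclass(frozen=True)
class SparseState:
    """Active fields of one snapshot: positions, capacitances and the threshold used."""

    positions: np.ndarray  # (m, 2) global frame, metres
    c: np.ndarray  # (m,)
    threshold: float

    def __len__(self) -> int:
        return len(self.c)

    @property
    def total_capacitance(self) -> float:
        return float(self.c.sum())


@dataclass(frozen=True)
class LocalSparseState:
    """Active fields in the walker frame, cut off at radius ``r_s``."""

    positions: np.ndarray  # (m, 2) walker frame, metres
    c: np.ndarray  # (m,)
    r_s: float

    def __len__(self) -> int:
        return len(self.c)


def sparsify(state: SensorState, c_threshold: float = DEFAULT_C_THRESHOLD) -> SparseState:
    """Keep exactly the fields with capacitance strictly above the threshold."""
    if not 0.0 <= c_threshold < 1.0:
        raise ValidationError(f"c_threshold must be in [0, 1), got {c_threshold}")
    mask = state.c_f > c_threshold
    return SparseState(state.positions[mask].copy(), state.c_f[mask].copy(), c_threshold)


def tracked_position(sparse: SparseState) -> np.ndarray | None:
    """Capacitance-weighted mean position of the active fields.

    Returns ``None`` when no field is active (total capacitance zero); the
    caller carries the last known position forward in that case.
    """
    if len(sparse) == 0:
        return None
    total = sparse.c.sum()
    return (sparse.c[:, None] * sparse.positions).sum(axis=0) / total


def walking_angle(first: np.ndarray, last: np.ndarray) -> float:
    """Signed angle theta rotating the walk direction onto the +y axis.

    With direction ``d = last - first`` and unit ``d_hat``, theta satisfies
    ``R(theta) @ d_hat == (0, 1)`` where ``R`` is the standard
    counter-clockwise rotation matrix; ``|theta|`` agrees with
    ``arccos(d_hat . (0, 1))``.
    """
    d = np.asarray(last, float) - np.asarray(first, float)
    norm = float(np.hypot(d[0], d[1]))
    if norm == 0.0 or not np.isfinite(norm):
        raise DegenerateWalkError("walk has no net displacement; direction undefined")
    return math.atan2(d[0], d[1])


def rotation_matrix(theta: float) -> np.ndarray:
    """Counter-clockwise rotation by ``theta`` (radians)."""
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, -s], [s, c]])


def to_local(
    sparse: SparseState,
    x_p: np.ndarray,
    theta: float,
    r_s: float = DEFAULT_GRID_RADIUS,
) -> LocalSparseState:
    """Translate to the tracked position, rotate into the walking direction.

    Entries at distance >= ``r_s`` from ``x_p`` are removed (strictly closer
    entries are kept). The map is rigid, so pairwise distances among kept
    entries are preserved.
    """
    if r_s <= 0:
        raise InvalidGridError(f"r_s must be > 0, got {r_s}")
    rel = sparse.positions - np.asarray(x_p, float)
    keep = np.einsum("ij,ij->i", rel, rel) < r_s * r_s
    local = rel[keep] @ rotation_matrix(theta).T
    return LocalSparseState(local, sparse.c[keep].copy(), r_s)


@lru_cache(maxsize=32)
def _lattice(l_s: float, r_s: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Lattice for (l_s, r_s): meander-ordered points, lex-ordered points,
    and the lex->meander index map."""
    k_max = int(math.ceil(r_s / l_s))
    ks = np.arange(-k_max, k_max + 1)
    xx, yy = np.meshgrid(ks * l_s, ks * l_s)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    pts = pts[np.einsum("ij,ij->i", pts, pts) < r_s * r_s]
    # meander: rows from most negative y upward, x ascending on even rows,
    # descending on odd rows (the unroll order of the activation vector)
    order = np.lexsort((pts[:, 0], pts[:, 1]))
    pts = pts[order]
    rows = np.round(pts[:, 1] / l_s).astype(int)
    out = []
    for r in np.unique(rows):
        row_pts = pts[rows == r]
        if (r - rows.min()) % 2 == 1:
            row_pts = row_pts[::-1]
        out.append(row_pts)
    meander = np.concatenate(out, axis=0)
    lex = pts[np.lexsort((pts[:, 1], pts[:, 0]))]  # x-major for tie-breaking
    key = {
        (round(p[0] / l_s), round(p[1] / l_s)): i for i, p in enumerate(meander)
    }
    lex_to_meander = np.array(
        [key[(round(p[0] / l_s), round(p[1] / l_s))] for p in lex], dtype=np.intp
    )
    meander.setflags(write=False)
    lex.setflags(write=False)
    lex_to_meander.setflags(write=False)
    return meander, lex, lex_to_meander


@dataclass(frozen=True)
class GridSpec:
    """Receptive-field lattice: spacing ``l_s`` and radius ``r_s`` (metres)."""

    l_s: float = DEFAULT_GRID_SPACING
    r_s: float = DEFAULT_GRID_RADIUS

    def __post_init__(self) -> None:
        if self.l_s <= 0 or self.r_s <= 0:
            raise InvalidGridError(
                f"grid spacing and radius must be > 0, got l_s={self.l_s}, r_s={self.r_s}"
            )

    @property
    def points(self) -> np.ndarray:
        """Lattice points (k*l_s, m*l_s) with norm < r_s, in meander order."""
        return _lattice(self.l_s, self.r_s)[0]

    @property
    def n_points(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class LocalGrid:
    """A grid spec plus one capacitance value per lattice point."""

    spec: GridSpec
    values: np.ndarray  # (n_points,) aligned with spec.points (meander order)

    def __post_init__(self) -> None:
        if self.values.shape != (self.spec.n_points,):
            raise InvalidGridError("grid values must align with the lattice points")
        self.values.setflags(write=False)


def make_grid(
    l_s: float = DEFAULT_GRID_SPACING, r_s: float = DEFAULT_GRID_RADIUS
) -> LocalGrid:
    """Fresh all-zero grid for the given spacing and radius."""
    spec = GridSpec(l_s, r_s)
    return LocalGrid(spec, np.zeros(spec.n_points))


def resample(local: LocalSparseState, grid: LocalGrid) -> LocalGrid:
    """Nearest-lattice-point resampling of a local sparse state.

    Each entry's capacitance goes to the Euclidean-nearest lattice point;
    exact distance ties resolve to the point with the smaller x (then smaller
    y); when several entries land on one point the maximum capacitance wins,
    preserving the strongest activation. Points receiving nothing stay at the
    grid's existing value (zero for a fresh grid).
    """
    spec = grid.spec
    if abs(local.r_s - spec.r_s) > 1e-12:
        raise InvalidGridError(
            f"local state radius {local.r_s} does not match grid radius {spec.r_s}"
        )
    values = grid.values.copy()
    if len(local) > 0:
        _, lex, lex_to_meander = _lattice(spec.l_s, spec.r_s)
        # argmin over lex-ordered points returns the first (lowest-x, then
        # lowest-y) point among exact ties
        d2 = (
            np.einsum("ij,ij->i", local.positions, local.positions)[:, None]
            - 2.0 * local.positions @ lex.T
            + np.einsum("ij,ij->i", lex, lex)[None, :]
        )
        nearest = lex_to_meander[np.argmin(d2, axis=1)]
        np.maximum.at(values, nearest, local.c)
    return LocalGrid(spec, values)


def unroll(grid: LocalGrid) -> np.ndarray:
    """Activation vector: the grid values in the fixed meander order.

    Rows are traversed from the most negative y upward, alternating x
    direction. The order depends only on (l_s, r_s), so every grid built from
    one spec unrolls identically.
    """
    return grid.values.copy()


# -- whole-walk preprocessing ----------------------------------------------


@dataclass(frozen=True)
class TrackedTrajectory:
    """Tracked positions and total capacitance per state of a walk.

    ``valid`` marks states with a defined position (at or after the first
    non-empty sparse state); within the valid range, positions of empty
    states carry the last fix forward and ``fresh`` is False there.
    """

    positions: np.ndarray  # (T, 2) NaN before the first fix
    total_capacitance: np.ndarray  # (T,)
    valid: np.ndarray  # (T,) bool
    fresh: np.ndarray  # (T,) bool: position computed from this state itself


def track(sparse_states: list[SparseState]) -> TrackedTrajectory:
    """Track the walker through a series of sparse states (carry-forward rule)."""
    n = len(sparse_states)
    pos = np.full((n, 2), np.nan)
    total = np.zeros(n)
    valid = np.zeros(n, bool)
    fresh = np.zeros(n, bool)
    last: np.ndarray | None = None
    for i, sp in enumerate(sparse_states):
        total[i] = sp.total_capacitance
        p = tracked_position(sp)
        if p is not None:
            last = p
            fresh[i] = True
        if last is not None:
            pos[i] = last
            valid[i] = True
    return TrackedTrajectory(pos, total, valid, fresh)


def preprocess_sparse_series(
    sparse_states: list[SparseState],
    grid: GridSpec | None = None,
    theta: float | None = None,
) -> tuple[np.ndarray, TrackedTrajectory, float]:
    """Localise, resample and unroll a series of sparse states.

    The walk-level angle is computed from the first and last *fresh* tracked
    positions unless given explicitly. States before the first fix are
    dropped; empty states within the walk yield zero vectors at the
    carried-forward position. Returns (vectors, trajectory, theta) where
    ``vectors`` has one row per state with a defined position.
    """
    if grid is None:
        grid = GridSpec()
    traj = track(sparse_states)
    fresh_idx = np.flatnonzero(traj.fresh)
    if theta is None:
        if len(fresh_idx) < 2:
            raise DegenerateWalkError("need at least two trackable states")
        theta = walking_angle(traj.positions[fresh_idx[0]], traj.positions[fresh_idx[-1]])
    empty_grid = make_grid(grid.l_s, grid.r_s)
    rows = []
    for i in np.flatnonzero(traj.valid):
        sp = sparse_states[i]
        if len(sp) == 0:
            rows.append(np.zeros(grid.n_points))
            continue
        local = to_local(sp, traj.positions[i], theta, grid.r_s)
        rows.append(unroll(resample(local, empty_grid)))
    if not rows:
        raise DegenerateWalkError("no state has a defined position")
    return np.array(rows), traj, theta


def preprocess_walk(
    states: list[SensorState],
    c_threshold: float = DEFAULT_C_THRESHOLD,
    grid: GridSpec | None = None,
    theta: float | None = None,
) -> tuple[np.ndarray, TrackedTrajectory, float]:
    """Full per-walk preprocessing: sparsify, track, localise, resample, unroll.

    Returns (vectors, trajectory, theta); ``vectors`` is the time series of
    activation vectors fed to the sequence model, one row per state with a
    defined tracked position.
    """
    if len(states) == 0:
        raise EmptyInputError("cannot preprocess an empty state series")
    sparse = [sparsify(s, c_threshold) for s in states]
    return preprocess_sparse_series(sparse, grid=grid, theta=theta)
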