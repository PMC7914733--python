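"""Synthetic capacitive-floor gait recordings.

Generates event-based message streams with the statistical structure the
analysis pipeline assumes: a walker crossing a floor of triangular sensor
fields, capacitances sampled at 10 Hz, and change-triggered message emission
per module. The generator emulates the recording protocol of a straight
out-and-back walk repeated several times per participant and walking mode,
with mode-dependent shifts of the gait parameters, so every pipeline stage
and both cross-validation designs can be exercised end to end.

Generative model, briefly:

* Footfalls alternate left/right along the walking axis. Step length, step
  width and step timing carry configurable Gaussian/CV noise; stance
  intervals overlap by the double-support fraction of the stride.
* A foot on the floor is a 0.26 m x 0.10 m ellipse. A field's capacitance is
  ``gain x (overlap area / field area)``, clipped to [0, 1]; overlap is
  estimated by deterministic sub-sampling of the ellipse. Fields under both
  feet accumulate both contributions before clipping. Contact builds up and
  releases over a short load ramp (0.15 s) at stance start and end, which is
  what makes a footfall generate a handful of messages rather than two.
* Sensor noise is a per-field Ornstein-Uhlenbeck baseline fluctuation with
  stationary SD ``noise_sd`` (default 0.01) and a correlation time of a few
  seconds: capacitance readings wander slowly, as idle capacitive channels
  do, while tick-to-tick jumps stay small enough that the event-based
  emission is not flooded.
* At every 10 Hz tick, a module emits a message iff at least one of its 8
  fields differs from its last *emitted* value by more than
  ``emission_threshold`` (default 0.02, below the 0.03 analysis threshold so
  a step can never be silently invisible to the tracker).

Synthetic participants carry latent traits: a baseline gait-parameter draw
and a latent "strength" that determines their unilateral heel-rise (UHR)
capacity and — with configurable coupling — shifts their step length, so a
parameter-recovery experiment can ask whether UHR counts are predictable
from gait. None of the generator's magnitudes are measured device values;
they are documented defaults chosen to make footfalls activate a realistic
1-4 fields on the 0.38 m module type.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .geometry import FIELDS_PER_MODULE, FloorLayout, corridor_layout, field_triangles
from .state import SensorMessage, write_messages_jsonl


# -- gait parameters and walking modes --------------------------------------


@dataclass(frozen=True)
class GaitParams:
    """Generative spatio-temporal gait parameters of one walker.

    Units: metres, seconds, m/s. ``double_support`` is the fraction of the
    stride during which both feet are on the ground; ``step_time_cv`` is the
    coefficient of variation of the step interval; ``stance_asymmetry``
    lengthens left stance and shortens right stance by the given fraction.
    """

    speed: float = 1.25
    step_length: float = 0.70
    step_length_sd: float = 0.02
    step_width: float = 0.10
    step_width_sd: float = 0.015
    double_support: float = 0.10
    sway_amplitude: float = 0.01
    step_time_cv: float = 0.04
    stance_asymmetry: float = 0.0

    def __post_init__(self) -> None:
        if self.speed <= 0 or self.step_length <= 0 or self.step_width < 0:
            raise ConfigError("speed and step_length must be > 0, step_width >= 0")
        if self.step_length_sd < 0 or self.step_width_sd < 0 or self.step_time_cv < 0:
            raise ConfigError("spread parameters must be >= 0")
        if not 0.0 <= self.double_support < 1.0:
            raise ConfigError("double_support must be in [0, 1)")

    @property
    def step_time(self) -> float:
        """Interval between consecutive (alternating-foot) footfalls, s."""
        return self.step_length / self.speed

    @property
    def cadence(self) -> float:
        """Steps per minute."""
        return 60.0 / self.step_time

    def stance_time(self, foot: str) -> float:
        """Single-foot ground-contact duration, s.

        Stance occupies half the stride plus the double-support fraction;
        ``stance_asymmetry`` shifts left/right in opposite directions.
        """
        stride = 2.0 * self.step_time
        base = (0.5 + self.double_support) * stride
        sign = +1.0 if foot == "L" else -1.0
        return base * (1.0 + sign * self.stance_asymmetry)


@dataclass(frozen=True)
class ParamScale:
    """Multiplicative (and one additive) perturbation of GaitParams."""

    speed: float = 1.0
    step_length: float = 1.0
    step_length_sd: float = 1.0
    step_width: float = 1.0
    step_width_sd: float = 1.0
    step_time_cv: float = 1.0
    double_support: float = 1.0
    stance_asymmetry_add: float = 0.0

    def apply(self, base: GaitParams) -> GaitParams:
        return replace(
            base,
            speed=base.speed * self.speed,
            step_length=base.step_length * self.step_length,
            step_length_sd=base.step_length_sd * self.step_length_sd,
            step_width=base.step_width * self.step_width,
            step_width_sd=base.step_width_sd * self.step_width_sd,
            step_time_cv=base.step_time_cv * self.step_time_cv,
            double_support=min(base.double_support * self.double_support, 0.95),
            stance_asymmetry=base.stance_asymmetry + self.stance_asymmetry_add,
        )


@dataclass(frozen=True)
class ModeLibrary:
    """Map from walking mode to its gait-parameter perturbation.

    ``normal`` is always the unperturbed baseline. The default perturbations
    are qualitative knobs, not measured effects: closed eyes slows the walk
    and makes foot placement and timing more variable; a concurrent
    cognitive task mainly increases timing variability; walking after an
    exhausting unilateral heel-rise test leaves a stance-time asymmetry.
    """

    scales: dict[str, ParamScale] = field(
        default_factory=lambda: {
            "normal": ParamScale(),
            "closed_eyes": ParamScale(speed=0.85, step_width_sd=2.0, step_time_cv=2.0),
            "dual_task": ParamScale(step_time_cv=1.5),
            "post_uhr": ParamScale(stance_asymmetry_add=0.10),
        }
    )

    def __post_init__(self) -> None:
        if "normal" not in self.scales:
            raise ConfigError("ModeLibrary must contain the 'normal' baseline mode")
        if self.scales["normal"] != ParamScale():
            raise ConfigError("the 'normal' mode must be the unperturbed baseline")

    @property
    def modes(self) -> list[str]:
        return list(self.scales)

    def params_for(self, base: GaitParams, mode: str) -> GaitParams:
        try:
            return self.scales[mode].apply(base)
        except KeyError:
            raise ValidationError(f"mode {mode!r} not in mode library") from None


def strongly_separated_modes() -> ModeLibrary:
    """Mode library with a deliberately strong closed-eyes perturbation.

    Used for parameter-recovery experiments: the perturbation loads on cues
    the receptive-field grid resolves well — shorter steps, doubled step
    width, more placement/timing variability and longer double support (slow
    walking increases double support). With this separation a working
    pipeline must classify held-out participants far above chance.
    """
    return ModeLibrary(
        {
            "normal": ParamScale(),
            "closed_eyes": ParamScale(
                speed=0.7,
                step_length=0.75,
                step_width=2.0,
                step_width_sd=3.0,
                step_time_cv=3.0,
                double_support=1.4,
            ),
        }
    )


def null_modes(names: Iterable[str] = ("normal", "closed_eyes")) -> ModeLibrary:
    """All-identity mode library: labels carry no gait information at all.

    A classifier trained on such a cohort must land at chance level; used as
    the negative control of the recovery experiments.
    """
    return ModeLibrary({name: ParamScale() for name in names})


# -- footfalls ---------------------------------------------------------------


@dataclass(frozen=True)
class Footfall:
    """One ground contact: which foot, where, its heading and contact interval."""

    foot: str  # "L" | "R"
    center: np.ndarray  # (2,) global metres
    heading: float  # walking direction, radians (0 = +y)
    t_down: float
    t_up: float


def simulate_footfalls(
    params: GaitParams,
    path_length: float,
    rng: np.random.Generator,
    start: tuple[float, float] = (0.0, 0.0),
    heading: float = 0.0,
    t_start: float = 0.0,
) -> list[Footfall]:
    """Footfalls of one straight pass of the given length.

    The walk progresses along +y in its own frame (rotated by ``heading``
    into the global frame, clockwise positive to match the walking-angle
    convention). Feet alternate left/right with lateral offsets
    ``±step_width/2`` plus placement noise and a slow sinusoidal sway;
    longitudinal spacing is ``step_length`` plus noise; step intervals carry
    multiplicative timing jitter of CV ``step_time_cv``. With all spreads
    zero the gait is perfectly periodic.
    """
    if path_length <= 0:
        raise ConfigError("path length must be > 0")
    cos_h, sin_h = math.cos(heading), math.sin(heading)
    # inverse of the local-frame rotation: local (x, y) -> global
    rot = np.array([[cos_h, sin_h], [-sin_h, cos_h]])
    out: list[Footfall] = []
    t = t_start
    k = 0
    while True:
        y = k * params.step_length + (rng.normal(0.0, params.step_length_sd) if params.step_length_sd else 0.0)
        if y > path_length or k * params.step_length > path_length:
            break
        foot = "L" if k % 2 == 0 else "R"
        side = -1.0 if foot == "L" else 1.0
        x = side * params.step_width / 2.0
        if params.step_width_sd:
            x += rng.normal(0.0, params.step_width_sd)
        x += params.sway_amplitude * math.sin(2.0 * math.pi * k / 8.0)
        pos = np.asarray(start, float) + rot @ np.array([x, y])
        out.append(Footfall(foot, pos, heading, t, t + params.stance_time(foot)))
        jitter = 1.0 + (rng.normal(0.0, params.step_time_cv) if params.step_time_cv else 0.0)
        t += params.step_time * max(jitter, 0.1)
        k += 1
    return out


# -- foot-to-field capacitance ----------------------------------------------

_ELLIPSE_SAMPLES: dict[int, np.ndarray] = {}


def _unit_disc_samples(n_grid: int = 22) -> np.ndarray:
    """Deterministic sample points covering the unit disc (cell centres)."""
    if n_grid not in _ELLIPSE_SAMPLES:
        u = (np.arange(n_grid) + 0.5) / n_grid * 2.0 - 1.0
        xx, yy = np.meshgrid(u, u)
        pts = np.column_stack([xx.ravel(), yy.ravel()])
        pts = pts[np.einsum("ij,ij->i", pts, pts) <= 1.0]
        pts.setflags(write=False)
        _ELLIPSE_SAMPLES[n_grid] = pts
    return _ELLIPSE_SAMPLES[n_grid]


def _points_in_triangle(pts: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Boolean mask of points inside (or on) a triangle, vectorised."""
    a, b, c = tri
    v0, v1 = c - a, b - a
    v2 = pts - a
    den = v0[0] * v1[1] - v1[0] * v0[1]
    if den == 0.0:
        return np.zeros(len(pts), bool)
    u = (v2[:, 0] * v1[1] - v1[0] * v2[:, 1]) / den
    v = (v0[0] * v2[:, 1] - v2[:, 0] * v0[1]) / den
    return (u >= -1e-12) & (v >= -1e-12) & (u + v <= 1.0 + 1e-12)


def footprint_to_capacitance(
    footfall: Footfall,
    layout: FloorLayout,
    gain: float = 0.9,
    foot_length: float = 0.26,
    foot_width: float = 0.10,
    n_grid: int = 22,
) -> tuple[np.ndarray, np.ndarray]:
    """Static capacitance contribution of one foot on the floor.

    The foot is an ellipse (long axis along the heading). Each overlapped
    field receives ``gain x overlap_area / field_area``; overlap area is
    estimated from a deterministic grid of sample points inside the ellipse.
    Returns ``(field_indices, contributions)`` for the nonzero fields only.
    """
    a = foot_length / 2.0
    b = foot_width / 2.0
    unit = _unit_disc_samples(n_grid)
    cos_h, sin_h = math.cos(footfall.heading), math.sin(footfall.heading)
    rot = np.array([[cos_h, sin_h], [-sin_h, cos_h]])  # local -> global
    pts = footfall.center + (unit * np.array([b, a])) @ rot.T
    ellipse_area = math.pi * a * b
    area_per_pt = ellipse_area / len(unit)
    reach = a + 1e-9
    idx_out: list[int] = []
    c_out: list[float] = []
    for k, mod in enumerate(layout.modules):
        half_diag = mod.edge / math.sqrt(2.0)
        if np.linalg.norm(footfall.center - np.asarray(mod.center)) > reach + half_diag:
            continue
        tris = field_triangles(mod)
        tri_area = mod.edge * mod.edge / FIELDS_PER_MODULE
        for j in range(FIELDS_PER_MODULE):
            inside = _points_in_triangle(pts, tris[j])
            n_in = int(inside.sum())
            if n_in == 0:
                continue
            overlap = n_in * area_per_pt
            idx_out.append(FIELDS_PER_MODULE * k + j)
            c_out.append(min(gain * overlap / tri_area, 1.0))
    return np.asarray(idx_out, dtype=np.intp), np.asarray(c_out)


# -- sampling and event-based emission ---------------------------------------


@dataclass(frozen=True)
class SimConfig:
    """Sensor-side and protocol-side settings of the simulator."""

    sample_rate: float = 10.0  # Hz
    emission_threshold: float = 0.02
    gain: float = 0.9
    foot_length: float = 0.26
    foot_width: float = 0.10
    noise_sd: float = 0.01
    noise_corr_time: float = 5.0  # s, OU correlation time of the baseline drift
    load_ramp: float = 0.15  # s, linear build-up/release of foot contact
    turn_pause: float = 1.0  # s standing at the turning point
    n_participants: int = 12
    reps_per_mode: int = 5
    uhr_gait_coupling: float = 0.0  # step-length shift per SD of latent strength, x 0.08 m
    uhr_noise_sd: float = 2.0  # repetitions
    uhr_bounds: tuple[int, int] = (10, 45)

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ConfigError("sample_rate must be > 0")
        if self.emission_threshold < 0:
            raise ConfigError("emission_threshold must be >= 0")


def _contact_weight(t: float, ff: Footfall, ramp: float) -> float:
    """Load fraction of a footfall at time t: linear ramp up, plateau, ramp down."""
    if t < ff.t_down or t > ff.t_up:
        return 0.0
    if ramp <= 0:
        return 1.0
    up = min((t - ff.t_down) / ramp, 1.0)
    down = min((ff.t_up - t) / ramp, 1.0)
    return min(up, down)


def sample_capacitances(
    footfalls: list[Footfall],
    layout: FloorLayout,
    sim: SimConfig,
    rng: np.random.Generator,
    t_end: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-rate capacitance series of all fields.

    Returns ``(times, series)`` with ``series[k]`` the (n_fields,) clipped
    capacitances at tick k: footfall coverage (per-footfall static, scaled by
    the load ramp) summed over active feet, plus the OU baseline noise.
    """
    dt = 1.0 / sim.sample_rate
    if t_end is None:
        t_end = max((f.t_up for f in footfalls), default=0.0) + 2.0 * dt
    times = np.arange(0.0, t_end + dt / 2, dt)
    n = layout.n_fields
    coverage = [
        footprint_to_capacitance(
            f, layout, gain=sim.gain, foot_length=sim.foot_length, foot_width=sim.foot_width
        )
        for f in footfalls
    ]
    alpha = math.exp(-dt / sim.noise_corr_time) if sim.noise_corr_time > 0 else 0.0
    innov_sd = sim.noise_sd * math.sqrt(max(1.0 - alpha * alpha, 0.0))
    noise = rng.normal(0.0, sim.noise_sd, n) if sim.noise_sd else np.zeros(n)
    series = np.zeros((len(times), n))
    for k, t in enumerate(times):
        c = np.zeros(n)
        for ff, (idx, contrib) in zip(footfalls, coverage):
            w = _contact_weight(t, ff, sim.load_ramp)
            if w > 0.0:
                np.add.at(c, idx, w * contrib)
        if sim.noise_sd:
            c += noise
            noise = alpha * noise + rng.normal(0.0, innov_sd, n)
        series[k] = np.clip(c, 0.0, 1.0)
    return times, series


def emit_messages(
    times: np.ndarray,
    series: np.ndarray,
    layout: FloorLayout,
    emission_threshold: float = 0.02,
) -> list[SensorMessage]:
    """Change-triggered message emission from a fixed-rate series.

    A module emits at tick k iff any of its 8 fields differs from its last
    *emitted* values by strictly more than the threshold; the message carries
    all 8 current values. Last-emitted values start at zero, matching the
    receiver's all-zero initial state, so a replay of the emitted stream
    reconstructs the sampled series to within the threshold per field at
    every tick.
    """
    n_mod = layout.n_modules
    module_ids = [m.module_id for m in layout.modules]
    last = np.zeros((n_mod, FIELDS_PER_MODULE))
    out: list[SensorMessage] = []
    for k, t in enumerate(times):
        cur = series[k].reshape(n_mod, FIELDS_PER_MODULE)
        emit = np.abs(cur - last).max(axis=1) > emission_threshold
        for mi in np.flatnonzero(emit):
            out.append(SensorMessage(float(t), module_ids[mi], cur[mi].copy()))
            last[mi] = cur[mi]
    return out


def simulate_recording(
    layout: FloorLayout,
    params: GaitParams,
    sim: SimConfig,
    rng: np.random.Generator,
    path_length: float | None = None,
    margin: float = 0.45,
) -> list[SensorMessage]:
    """One out-and-back straight walk along the floor's long (y) axis.

    The walker goes out (+y), stands at the turning point for
    ``turn_pause`` seconds, and walks back. Returns the emitted message
    stream of the whole recording.
    """
    xs = layout.positions
    if len(xs) == 0:
        raise ConfigError("cannot simulate on an empty layout")
    y_min, y_max = xs[:, 1].min(), xs[:, 1].max()
    x_center = (xs[:, 0].min() + xs[:, 0].max()) / 2.0
    if path_length is None:
        path_length = (y_max - y_min) - 2.0 * margin
    if path_length <= 0:
        raise ConfigError("floor too short for the requested margins")
    start_out = (x_center, y_min + margin)
    start_back = (x_center, y_min + margin + path_length)
    out_ff = simulate_footfalls(params, path_length, rng, start=start_out, heading=0.0)
    t_turn = max(f.t_up for f in out_ff)
    # standing at the turn: both feet planted until the back pass starts
    stand = [
        Footfall("L", np.asarray(start_back) + np.array([-params.step_width / 2, 0.0]),
                 0.0, t_turn, t_turn + sim.turn_pause),
        Footfall("R", np.asarray(start_back) + np.array([params.step_width / 2, 0.0]),
                 0.0, t_turn, t_turn + sim.turn_pause),
    ]
    back_ff = simulate_footfalls(
        params, path_length, rng, start=start_back, heading=math.pi,
        t_start=t_turn + sim.turn_pause,
    )
    footfalls = out_ff + stand + back_ff
    times, series = sample_capacitances(footfalls, layout, sim, rng)
    return emit_messages(times, series, layout, sim.emission_threshold)


# -- cohort generation -------------------------------------------------------


@dataclass(frozen=True)
class ParticipantTraits:
    """Latent per-participant draws: baseline gait and heel-rise capacity."""

    participant: str
    baseline: GaitParams
    strength: float  # latent, ~N(0, 1) over the population
    uhr_left: int
    uhr_right: int


@dataclass
class Recording:
    """One simulated out-and-back recording with its labels."""

    recording_id: str
    participant: str
    mode: str
    repetition: int
    messages: list[SensorMessage]
    uhr_left: int
    uhr_right: int


# population distributions of the baseline gait (young healthy adults)
_POPULATION = dict(
    speed=(1.25, 0.10),
    step_length=(0.70, 0.04),
    step_width=(0.10, 0.02),
    step_width_sd=(0.015, 0.004),
    step_time_cv=(0.04, 0.01),
)
# cohort UHR statistics: mean, SD per leg; counts bounded by SimConfig.uhr_bounds
_UHR_POP = {"right": (25.7, 7.8), "left": (24.3, 7.9)}
_COUPLING_STEP_LENGTH = 0.08  # m shift per SD of latent strength at coupling 1.0


def draw_participant(
    name: str, sim: SimConfig, rng: np.random.Generator
) -> ParticipantTraits:
    """Draw one participant's latent traits from the population model."""
    def pos_normal(mean: float, sd: float, lo: float) -> float:
        return max(rng.normal(mean, sd), lo)

    strength = rng.normal()
    step_length = pos_normal(*_POPULATION["step_length"], 0.45)
    step_length += sim.uhr_gait_coupling * _COUPLING_STEP_LENGTH * strength
    base = GaitParams(
        speed=pos_normal(*_POPULATION["speed"], 0.6),
        step_length=max(step_length, 0.40),
        step_width=pos_normal(*_POPULATION["step_width"], 0.03),
        step_width_sd=pos_normal(*_POPULATION["step_width_sd"], 0.002),
        step_time_cv=pos_normal(*_POPULATION["step_time_cv"], 0.005),
    )
    lo, hi = sim.uhr_bounds
    uhr = {}
    for leg, (mean, sd) in _UHR_POP.items():
        raw = mean + sd * strength + rng.normal(0.0, sim.uhr_noise_sd)
        uhr[leg] = int(round(min(max(raw, lo), hi)))
    return ParticipantTraits(name, base, strength, uhr["left"], uhr["right"])


def generate_cohort(
    layout: FloorLayout | None = None,
    sim: SimConfig | None = None,
    modes: ModeLibrary | None = None,
    mode_subset: Iterable[str] | None = None,
    seed: int | None = None,
) -> tuple[list[Recording], list[ParticipantTraits]]:
    """Simulate a full study cohort.

    For each participant, each requested mode and each repetition, one
    out-and-back recording is generated. Identical seeds yield byte-identical
    datasets.
    """
    layout = layout if layout is not None else corridor_layout()
    sim = sim or SimConfig()
    modes = modes or ModeLibrary()
    mode_list = list(mode_subset) if mode_subset is not None else modes.modes
    for m in mode_list:
        if m not in modes.scales:
            raise ValidationError(f"mode {m!r} not in mode library")
    if sim.n_participants < 1:
        raise ConfigError("need at least one participant")
    rng = np.random.default_rng(seed)
    recordings: list[Recording] = []
    traits: list[ParticipantTraits] = []
    for pi in range(sim.n_participants):
        name = f"p{pi:02d}"
        tr = draw_participant(name, sim, rng)
        traits.append(tr)
        for mode in mode_list:
            gp = modes.params_for(tr.baseline, mode)
            for rep in range(sim.reps_per_mode):
                msgs = simulate_recording(layout, gp, sim, rng)
                recordings.append(
                    Recording(
                        recording_id=f"{name}_{mode}_r{rep}",
                        participant=name,
                        mode=mode,
                        repetition=rep,
                        messages=msgs,
                        uhr_left=tr.uhr_left,
                        uhr_right=tr.uhr_right,
                    )
                )
    return recordings, traits


def cohort_manifest(recordings: list[Recording]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "recording_id": [r.recording_id for r in recordings],
            "participant": [r.participant for r in recordings],
            "mode": [r.mode for r in recordings],
            "repetition": [r.repetition for r in recordings],
            "n_messages": [len(r.messages) for r in recordings],
            "uhr_left": [r.uhr_left for r in recordings],
            "uhr_right": [r.uhr_right for r in recordings],
        }
    )


def save_cohort(recordings: list[Recording], out_dir: str | Path) -> None:
    """Write one JSONL message log per recording plus a manifest CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for r in recordings:
        write_messages_jsonl(r.messages, out / f"{r.recording_id}.jsonl")
    cohort_manifest(recordings).to_csv(out / "manifest.csv", index=False)
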