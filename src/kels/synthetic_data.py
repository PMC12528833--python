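"""Synthetic multi-session reaching studies with known ground truth.

Emulates the sequential-reaching task: a central target plus six hexagon
targets, eight three-target sequences (19 unique submovements), sessions of
three 40-trial blocks (five trials per sequence), ~840 ms bell-speed
movements, endpoint scatter within the 1 cm logical radius, and
per-submovement deviation distributions that drift across sessions toward a
configurable target (e.g. each submovement's safe-range median).  Every draw
flows from one seed, and the generator records its ground truth so pipeline
estimates can be checked against it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .arm_model import ArmGeometry, inverse_kinematics
from .trajectory_synthesis import jitter_endpoint, simulate_path

__all__ = [
    "TaskLayout",
    "GeneratorConfig",
    "TrialRecord",
    "Study",
    "DEFAULT_SEQUENCES",
    "default_layout",
    "generate_trial",
    "generate_study",
]

# Reconstruction of the eight three-target sequences over hexagon vertices
# 1..6 (1 = top, numbered clockwise); chosen so the 24 sequence slots reduce
# to exactly 19 unique (start, end) pairs, matching the task's submovement
# count.  User-replaceable via TaskLayout(sequences=...).
DEFAULT_SEQUENCES: tuple[tuple[int, int, int], ...] = (
    (1, 4, 2),
    (2, 5, 3),
    (3, 6, 1),
    (4, 1, 5),
    (5, 2, 6),
    (6, 3, 1),
    (3, 5, 2),
    (4, 2, 5),
)

#: vertex label -> polar angle (deg) around the hexagon centre
_VERTEX_ANGLES = {1: 90.0, 2: 30.0, 3: -30.0, 4: -90.0, 5: -150.0, 6: 150.0}
#: vertices at the center-to-top distance (the others use center-to-side)
_TOP_BOTTOM = {1, 4}

# hexagon scale (m): center-to-top and center-to-side distances per profile
_PROFILE_SCALES = {"E": (0.036, 0.045), "J": (0.040, 0.050)}


@dataclass(frozen=True)
class TaskLayout:
    """Target geometry and sequence set of the reaching task.

    Targets are labelled 0 (centre) and 1..6 (hexagon vertices); the logical
    radius is the invisible 1 cm acceptance zone around each target, also used
    as the endpoint-scatter radius.
    """

    center: tuple[float, float]
    vertices: dict[int, tuple[float, float]]
    logical_radius: float = 0.01
    sequences: tuple[tuple[int, int, int], ...] = DEFAULT_SEQUENCES

    def __post_init__(self) -> None:
        if sorted(self.vertices) != [1, 2, 3, 4, 5, 6]:
            raise ValueError("vertices must be labelled 1..6")
        if len({tuple(v) for v in self.vertices.values()}) != 6:
            raise ValueError("vertices must be distinct")
        for seq in self.sequences:
            if not all(t in self.vertices for t in seq):
                raise ValueError(f"sequence {seq} references unknown targets")

    def target_position(self, label: int) -> np.ndarray:
        if label == 0:
            return np.asarray(self.center, dtype=float)
        return np.asarray(self.vertices[label], dtype=float)

    def submovement_catalog(self) -> list[str]:
        """Unique (start, end) pairs over all sequence slots, in first-seen order."""
        seen: list[str] = []
        for seq in self.sequences:
            chain = (0,) + tuple(seq)
            for a, b in zip(chain[:-1], chain[1:]):
                sid = f"{a}-{b}"
                if sid not in seen:
                    seen.append(sid)
        return seen


def default_layout(
    monkey_profile: str, center: tuple[float, float] = (0.06, 0.27)
) -> TaskLayout:
    """Hexagon layout for an E-like or J-like subject.

    The hexagon is irregular: top/bottom vertices sit at the center-to-top
    distance (3.6 cm E-like, 4 cm J-like) and the four oblique vertices at the
    center-to-side distance (4.5 cm E-like, 5 cm J-like).  ``center`` places
    the workspace relative to the shoulder origin.
    """
    if monkey_profile not in _PROFILE_SCALES:
        raise ValueError(f"unknown profile {monkey_profile!r}; expected 'E' or 'J'")
    d_top, d_side = _PROFILE_SCALES[monkey_profile]
    cx, cy = center
    vertices = {}
    for label, ang in _VERTEX_ANGLES.items():
        d = d_top if label in _TOP_BOTTOM else d_side
        rad = np.deg2rad(ang)
        vertices[label] = (cx + d * np.cos(rad), cy + d * np.sin(rad))
    return TaskLayout(center=center, vertices=vertices)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-level simulation parameters.

    Deviation law per submovement: session ``s`` draws trial deviations from
    ``Normal(mean_s, trial_dev_sd)`` truncated to ``[-dev_span, dev_span]``,
    where ``mean_s`` approaches ``target_dev`` from ``initial_dev``
    geometrically at ``drift_rate`` per session.  Durations are
    ``Normal(duration_mean, duration_sd)`` clipped below the 1.5 s task
    timeout.  ``initial_dev``/``target_dev`` may be scalars or dicts keyed by
    submovement id ("start-end").
    """

    n_sessions: int = 20
    trials_per_session: int = 120
    n_blocks: int = 3
    initial_dev: float | dict = 0.0
    target_dev: float | dict = 0.0
    drift_rate: float = 0.2
    trial_dev_sd: float = 0.05
    duration_mean: float = 0.84
    duration_sd: float = 0.08
    speed_noise_sd: float = 0.05
    center_hold_s: float = 0.25
    target_hold_range: tuple[float, float] = (0.15, 0.20)
    hold_noise_amp: float = 0.0003
    hold_noise_knot_s: float = 0.05
    onset_speed_threshold: float = 0.05
    speed_floor: float = 0.05
    dev_span: float = 0.5
    path_points: int = 501
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trials_per_session % (self.n_blocks) != 0:
            raise ValueError("trials_per_session must divide evenly into blocks")
        for name in ("trial_dev_sd", "duration_sd", "speed_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.drift_rate <= 1.0:
            raise ValueError("drift_rate must be in [0, 1]")
        if self.duration_mean + 4 * self.duration_sd >= 1.5:
            raise ValueError("duration law must stay below the 1.5 s task timeout")

    def dev_mean(self, submovement_id: str, session: int) -> float:
        """Per-session deviation mean under the geometric drift law."""

        def resolve(v):
            return v.get(submovement_id, 0.0) if isinstance(v, dict) else float(v)

        init = resolve(self.initial_dev)
        target = resolve(self.target_dev)
        return target + (init - target) * (1.0 - self.drift_rate) ** session


@dataclass
class TrialRecord:
    """One simulated trial: 1 kHz streams plus events and ground truth."""

    session_id: int
    trial_id: int
    sequence_id: int
    targets: list[int]  # [0, t1, t2, t3]
    reach_times: np.ndarray  # time each target was reached (s)
    t: np.ndarray
    hand_x: np.ndarray
    hand_y: np.ndarray
    theta_s: np.ndarray
    theta_e: np.ndarray
    omega_s: np.ndarray
    omega_e: np.ndarray
    speed: np.ndarray
    true_devs: np.ndarray  # drawn deviation per submovement
    true_durations: np.ndarray


@dataclass
class Study:
    """A generated study: sessions of trials plus recorded ground truth."""

    sessions: list[list[TrialRecord]]
    ground_truth: pd.DataFrame  # session_id, submovement_id, true_mean_dev, true_ke_J
    config: GeneratorConfig
    layout: TaskLayout
    geom: ArmGeometry

    def trials(self):
        for session in self.sessions:
            yield from session


def movement_intervals(n_points: int, duration: float, floor: float = 0.05) -> np.ndarray:
    """Inter-sample intervals giving a bell speed that vanishes at the ends.

    Speed along the (uniformly sampled) path follows ``sin^2(pi*s) + floor``,
    so movements start and stop from near rest — unlike the landscape model's
    canonical profile, whose edge speed is finite.  ``floor`` keeps the tails
    finite in time; smaller values give slower starts and a sharper peak.
    """
    s_mid = (np.arange(n_points - 1) + 0.5) / (n_points - 1)
    w = 1.0 / (np.sin(np.pi * s_mid) ** 2 + floor)
    return w / w.sum() * duration


def _hold_positions(
    t: np.ndarray,
    t0: float,
    duration: float,
    pos: np.ndarray,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Hold-period positions at the sample times ``t`` (relative to ``t0``):
    stationary hand plus slow, low-amplitude positional noise, zero at both
    ends so holds join movements smoothly."""
    n_knots = max(int(round(duration / cfg.hold_noise_knot_s)) + 1, 2)
    tk = np.linspace(0.0, duration, n_knots)
    noise = rng.normal(0.0, cfg.hold_noise_amp, size=(n_knots, 2))
    noise[0] = noise[-1] = 0.0
    out = np.empty((t.size, 2))
    out[:, 0] = pos[0] + np.interp(t - t0, tk, noise[:, 0])
    out[:, 1] = pos[1] + np.interp(t - t0, tk, noise[:, 1])
    return out


#: dense sub-steps per speed-noise segment when tabulating each leg's time warp
_FINE_PER_SEG = 8


#: number of speed-noise knots along one leg (noise is smooth, like a real
#: velocity trace, so onset detection is not defeated by sample-level jitter)
_NOISE_KNOTS = 9


def _leg_time_warp(
    n_points: int,
    duration: float,
    floor: float,
    speed_noise_sd: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Dense (t, s) table of a leg's path-parameter-vs-time warp.

    Integrates dt = ds / speed(s) on a fine grid so that 1 kHz sampling of the
    warp is smooth (no interpolation-knot artefacts in the speed stream).
    Multiplicative speed noise is drawn at a few knots along the leg and
    interpolated, modulating the interval durations smoothly; the total is
    renormalised to the drawn duration.
    """
    n_seg = n_points - 1
    s_fine = np.linspace(0.0, 1.0, n_seg * _FINE_PER_SEG + 1)
    s_mid = 0.5 * (s_fine[:-1] + s_fine[1:])
    v = np.sin(np.pi * s_mid) ** 2 + floor
    if speed_noise_sd > 0:
        knots = np.linspace(0.0, 1.0, _NOISE_KNOTS)
        factors = np.clip(1.0 + rng.normal(0.0, speed_noise_sd, _NOISE_KNOTS), 0.1, None)
        v = v / np.interp(s_mid, knots, factors)
    dt = np.diff(s_fine) / v
    t = np.concatenate([[0.0], np.cumsum(dt)])
    return t * (duration / t[-1]), s_fine


def generate_trial(
    layout: TaskLayout,
    geom: ArmGeometry,
    sequence: tuple[int, int, int],
    dev_means: np.ndarray,
    config: GeneratorConfig,
    rng: np.random.Generator,
    session_id: int = 0,
    trial_id: int = 0,
    sequence_id: int = 0,
) -> TrialRecord:
    """Simulate one trial of the three-submovement sequence at 1 kHz.

    Each leg jitters its end target within the logical radius, draws a
    deviation and duration, lays down a parabolic hand path re-timed with the
    bell-speed profile (interval durations perturbed multiplicatively by the
    speed noise and renormalised), and is preceded by a hold so that onset
    detection is non-trivial.  Joint streams come from the inverse kinematics;
    velocities and speed from finite differences of the 1 kHz streams.
    """
    start = jitter_endpoint(layout.target_position(0), layout.logical_radius, rng)
    segments = []  # (kind, t0, duration, payload)
    reach_times = [0.0]
    true_devs = np.empty(3)
    true_durations = np.empty(3)

    segments.append(("hold", 0.0, config.center_hold_s, (start,)))
    t_cursor = config.center_hold_s
    pos = start
    for i, label in enumerate(sequence):
        end = jitter_endpoint(layout.target_position(label), layout.logical_radius, rng)
        dev = float(
            np.clip(rng.normal(dev_means[i], config.trial_dev_sd), -config.dev_span, config.dev_span)
        )
        duration = float(np.clip(rng.normal(config.duration_mean, config.duration_sd), 0.3, 1.45))
        warp_t, warp_s = _leg_time_warp(
            config.path_points, duration, config.speed_floor, config.speed_noise_sd, rng
        )
        segments.append(("move", t_cursor, duration, (pos.copy(), end, dev, warp_t, warp_s)))
        t_cursor += duration
        reach_times.append(t_cursor)
        true_devs[i] = dev
        true_durations[i] = duration
        pos = end
        hold = float(rng.uniform(*config.target_hold_range)) if i < 2 else 0.15
        segments.append(("hold", t_cursor, hold, (pos.copy(),)))
        t_cursor += hold

    # sample the whole timeline on the uniform 1 kHz grid, segment by segment
    t = np.arange(0.0, t_cursor, 1e-3)
    bounds = np.array([t0 for _, t0, _, _ in segments][1:])
    seg_index = np.searchsorted(bounds, t, side="right")
    x = np.empty_like(t)
    y = np.empty_like(t)
    for k, (kind, t0, duration, payload) in enumerate(segments):
        mask = seg_index == k
        if not mask.any():
            continue
        tm = t[mask]
        if kind == "hold":
            xy = _hold_positions(tm, t0, duration, payload[0], config, rng)
        else:
            seg_start, seg_end, dev, warp_t, warp_s = payload
            s = np.interp(tm - t0, warp_t, warp_s)
            chord = seg_end - seg_start
            length = float(np.hypot(*chord))
            u = chord / length
            n_right = np.array([u[1], -u[0]])
            offset = 4.0 * dev * length * s * (1.0 - s)
            xy = seg_start[None, :] + (s * length)[:, None] * u[None, :] + offset[:, None] * n_right[None, :]
        x[mask] = xy[:, 0]
        y[mask] = xy[:, 1]
    theta_s, theta_e = inverse_kinematics(geom, x, y)
    # the grid is uniform at 1 ms, so differentiate with scalar spacing
    omega_s = np.gradient(theta_s, 1e-3)
    omega_e = np.gradient(theta_e, 1e-3)
    speed = np.hypot(np.gradient(x, 1e-3), np.gradient(y, 1e-3))
    return TrialRecord(
        session_id=session_id,
        trial_id=trial_id,
        sequence_id=sequence_id,
        targets=[0, *sequence],
        reach_times=np.asarray(reach_times),
        t=t,
        hand_x=x,
        hand_y=y,
        theta_s=theta_s,
        theta_e=theta_e,
        omega_s=omega_s,
        omega_e=omega_e,
        speed=speed,
        true_devs=true_devs,
        true_durations=true_durations,
    )


def _noiseless_ke(
    layout: TaskLayout,
    geom: ArmGeometry,
    submovement_id: str,
    dev: float,
    config: GeneratorConfig,
) -> float:
    """KE of the noiseless path (exact centres, mean duration, no speed noise)."""
    a, b = (int(s) for s in submovement_id.split("-"))
    path = simulate_path(
        layout.target_position(a), layout.target_position(b), dev, config.path_points
    )
    theta_s, theta_e = inverse_kinematics(geom, path[:, 0], path[:, 1])
    dt = movement_intervals(config.path_points, config.duration_mean, config.speed_floor)
    return float(
        0.5 * geom.Is * np.sum((np.diff(theta_s) / dt) ** 2)
        + 0.5 * geom.Ie * np.sum((np.diff(theta_e) / dt) ** 2)
    )


def generate_study(
    config: GeneratorConfig,
    layout: TaskLayout | None = None,
    geom: ArmGeometry | None = None,
) -> Study:
    """Generate a full multi-session study with ground truth.

    Trials are organised in blocks containing five shuffled repetitions of
    each sequence.  The ground-truth table records, per session and
    submovement, the drifting true mean deviation and the model KE of the
    corresponding noiseless trajectory.
    """
    layout = layout if layout is not None else default_layout("E")
    geom = geom if geom is not None else ArmGeometry()
    rng = np.random.default_rng(config.seed)
    trials_per_block = config.trials_per_session // config.n_blocks
    n_seq = len(layout.sequences)
    if trials_per_block % n_seq != 0:
        raise ValueError("block size must be a multiple of the number of sequences")
    reps = trials_per_block // n_seq

    sessions: list[list[TrialRecord]] = []
    gt_rows = []
    trial_counter = 0
    for s in range(config.n_sessions):
        dev_means = {
            sid: config.dev_mean(sid, s) for sid in layout.submovement_catalog()
        }
        for sid, m in dev_means.items():
            gt_rows.append(
                {
                    "session_id": s,
                    "submovement_id": sid,
                    "true_mean_dev": m,
                    "true_ke_J": _noiseless_ke(layout, geom, sid, m, config),
                }
            )
        session_trials: list[TrialRecord] = []
        for _ in range(config.n_blocks):
            order = np.repeat(np.arange(n_seq), reps)
            rng.shuffle(order)
            for seq_idx in order:
                seq = layout.sequences[seq_idx]
                chain = (0, *seq)
                means = np.array(
                    [dev_means[f"{a}-{b}"] for a, b in zip(chain[:-1], chain[1:])]
                )
                session_trials.append(
                    generate_trial(
                        layout,
                        geom,
                        seq,
                        means,
                        config,
                        rng,
                        session_id=s,
                        trial_id=trial_counter,
                        sequence_id=int(seq_idx),
                    )
                )
                trial_counter += 1
        sessions.append(session_trials)
    return Study(
        sessions=sessions,
        ground_truth=pd.DataFrame(gt_rows),
        config=config,
        layout=layout,
        geom=geom,
    )
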