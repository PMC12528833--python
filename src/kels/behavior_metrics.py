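"""Trial-stream metrics: onset detection, sectioning, deviation, variability,
observed KE, session trends, deviation ellipses, and submovement classes.

Works on 1 kHz kinematic streams of a sequential reaching task in which each
trial chains three point-to-point submovements.  A submovement is identified
by its (start target, end target) pair, so identical pairs occurring in
different sequences are pooled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .arm_model import ArmGeometry, JointVelocitySeries, Trajectory, kinetic_energy

__all__ = [
    "OnsetNotFoundError",
    "DegenerateChordError",
    "SubmovementSlice",
    "EllipseFit",
    "detect_movement_onset",
    "section_submovements",
    "trajectory_deviation",
    "spatial_variability",
    "observed_ke",
    "early_late_summary",
    "ke_session_trend",
    "fit_deviation_ellipse",
    "cluster_submovement_classes",
]


class OnsetNotFoundError(ValueError):
    """No supra-threshold speed segment of sufficient duration exists."""


class DegenerateChordError(ValueError):
    """Trajectory endpoints coincide; deviation is undefined."""


def detect_movement_onset(
    t: np.ndarray,
    speed: np.ndarray,
    threshold: float,
    min_supra_ms: float = 50.0,
) -> float:
    """Movement-onset time from a hand-speed stream.

    Finds the first segment that stays above ``threshold`` for at least
    ``min_supra_ms`` (shorter supra-threshold blips are rejected as noise),
    then walks backward from that segment's threshold crossing to the nearest
    preceding acceleration zero-crossing — the last sample before the crossing
    at which the finite-difference acceleration is still non-positive; onset
    is the sample after it.  Falls back to the stream's first sample with a
    warning if acceleration is positive all the way back.
    """
    t = np.asarray(t, dtype=float)
    speed = np.asarray(speed, dtype=float)
    if t.size != speed.size or t.size < 2:
        raise ValueError("t and speed must be equal-length with >= 2 samples")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    above = speed > threshold
    if not above.any():
        raise OnsetNotFoundError("speed never crosses the threshold")
    # boundaries of supra-threshold runs
    edges = np.flatnonzero(np.diff(above.astype(int)))
    starts = [0] if above[0] else []
    starts += [int(e) + 1 for e in edges if above[e + 1]]
    ends = [int(e) for e in edges if above[e]]  # inclusive run ends
    ends += [t.size - 1] if above[-1] else []
    crossing = None
    for s, e in zip(starts, ends):
        if (t[e] - t[s]) * 1e3 >= min_supra_ms:
            crossing = s
            break
    if crossing is None:
        raise OnsetNotFoundError(
            f"no supra-threshold segment lasting >= {min_supra_ms:g} ms"
        )
    accel = np.diff(speed) / np.diff(t)  # accel[j] spans samples j..j+1
    j = crossing - 1
    while j >= 0 and accel[j] > 0:
        j -= 1
    if j < 0:
        warnings.warn(
            "no acceleration zero-crossing before threshold crossing; "
            "falling back to the first sample",
            RuntimeWarning,
        )
        return float(t[0])
    return float(t[j + 1])


@dataclass
class SubmovementSlice:
    """One sectioned submovement: paths in both spaces plus joint velocities."""

    submovement_id: str
    hand: Trajectory
    joint: Trajectory
    velocities: JointVelocitySeries


def section_submovements(
    trial,
    speed_threshold: float,
    min_supra_ms: float = 50.0,
) -> list[SubmovementSlice]:
    """Cut a trial's streams into its three submovements.

    ``trial`` must expose 1 kHz arrays ``t, hand_x, hand_y, theta_s, theta_e,
    omega_s, omega_e, speed``, the ordered target labels ``targets`` (four:
    start plus the three sequence targets) and ``reach_times`` (four: the time
    the hand reached each target).  Each slice runs from the detected movement
    onset after the previous target reach to the next target reach; slices are
    keyed "start-end" so identical target pairs from different sequences share
    an id.
    """
    reach = np.asarray(trial.reach_times, dtype=float)
    targets = list(trial.targets)
    if len(reach) != 4 or len(targets) != 4:
        raise ValueError("trial must have 4 targets and 4 reach times")
    if np.any(np.diff(reach) <= 0):
        raise ValueError("reach times must be strictly increasing")
    t = np.asarray(trial.t, dtype=float)
    if reach[0] < t[0] - 1e-9 or reach[-1] > t[-1] + 1e-9:
        raise ValueError("reach times outside the stream's time range")
    out: list[SubmovementSlice] = []
    for i in range(3):
        w = (t >= reach[i]) & (t <= reach[i + 1])
        idx = np.flatnonzero(w)
        onset = detect_movement_onset(
            t[idx], np.asarray(trial.speed)[idx], speed_threshold, min_supra_ms
        )
        sl = idx[t[idx] >= onset]
        hand = Trajectory(
            space="hand",
            t=t[sl],
            u=np.asarray(trial.hand_x)[sl],
            v=np.asarray(trial.hand_y)[sl],
        )
        joint = Trajectory(
            space="joint",
            t=t[sl],
            u=np.asarray(trial.theta_s)[sl],
            v=np.asarray(trial.theta_e)[sl],
        )
        vel = JointVelocitySeries(
            t=t[sl],
            omega_s=np.asarray(trial.omega_s)[sl],
            omega_e=np.asarray(trial.omega_e)[sl],
        )
        out.append(
            SubmovementSlice(
                submovement_id=f"{targets[i]}-{targets[i + 1]}",
                hand=hand,
                joint=joint,
                velocities=vel,
            )
        )
    return out


def trajectory_deviation(traj: Trajectory) -> float:
    """Signed, chord-normalised maximum deviation of a path (a.u.).

    Magnitude: the maximum over samples of the perpendicular distance to the
    straight line joining the path's endpoints, divided by that line's length.
    Sign: negative when the maximising sample lies on the left of the chord in
    the direction of movement (ties go to the earlier sample).
    """
    pts = traj.points
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 samples to measure deviation")
    start, end = pts[0], pts[-1]
    chord = end - start
    length = float(np.hypot(*chord))
    if length < 1e-12:
        raise DegenerateChordError("trajectory endpoints coincide")
    u = chord / length
    rel = pts - start
    # positive cross product = left of the movement direction
    s = u[0] * rel[:, 1] - u[1] * rel[:, 0]
    imax = int(np.argmax(np.abs(s)))  # first maximiser on ties
    return float(-s[imax] / length)


def spatial_variability(trajs: list[Trajectory], step_ms: float = 10.0) -> pd.DataFrame:
    """Spread of repeated trajectories around their mean path.

    Trajectories are aligned at their own onsets, sampled on a common grid
    every ``step_ms``, truncated to the shortest trajectory's duration, and
    the RMS Euclidean distance of the paths to the pointwise mean path is
    reported at each grid time.  Returns a frame with columns ``time_s`` and
    ``sd`` (units of the input space).
    """
    if len(trajs) < 2:
        raise ValueError("need at least 2 trajectories")
    durations = [tr.t[-1] - tr.t[0] for tr in trajs]
    grid = np.arange(0.0, min(durations) + 1e-12, step_ms / 1e3)
    xs = np.empty((len(trajs), grid.size))
    ys = np.empty((len(trajs), grid.size))
    for i, tr in enumerate(trajs):
        tau = tr.t - tr.t[0]
        xs[i] = np.interp(grid, tau, tr.u)
        ys[i] = np.interp(grid, tau, tr.v)
    mx, my = xs.mean(axis=0), ys.mean(axis=0)
    sd = np.sqrt(np.mean((xs - mx) ** 2 + (ys - my) ** 2, axis=0))
    return pd.DataFrame({"time_s": grid, "sd": sd})


def observed_ke(vel: JointVelocitySeries, geom: ArmGeometry) -> float:
    """Summed KE of recorded joint velocities (delegates to the arm model)."""
    return kinetic_energy(vel, geom)


def early_late_summary(
    records: pd.DataFrame, n_edge: int = 10, field: str = "hand_dev"
) -> pd.DataFrame:
    """Early/late session means of a per-trial field, per submovement.

    ``records`` needs columns ``session_id``, ``submovement_id`` and ``field``.
    Sessions are ordered by their id; the early (late) value is the mean over
    the first (last) ``n_edge`` sessions of the per-session means, and
    ``difference = late - early``.
    """
    sessions = np.sort(records["session_id"].unique())
    if sessions.size < 2 * n_edge:
        raise ValueError(
            f"need >= {2 * n_edge} sessions, got {sessions.size}"
        )
    early_ids = set(sessions[:n_edge])
    late_ids = set(sessions[-n_edge:])
    per_session = (
        records.groupby(["submovement_id", "session_id"])[field].mean().reset_index()
    )
    rows = []
    for sm, grp in per_session.groupby("submovement_id"):
        early = grp.loc[grp["session_id"].isin(early_ids), field].mean()
        late = grp.loc[grp["session_id"].isin(late_ids), field].mean()
        rows.append(
            {
                "submovement_id": sm,
                "early_mean": early,
                "late_mean": late,
                "difference": late - early,
            }
        )
    return pd.DataFrame(rows)


def ke_session_trend(mean_ke_per_session: np.ndarray) -> tuple[float, float]:
    """OLS slope and Pearson r of per-session mean KE against session index."""
    y = np.asarray(mean_ke_per_session, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 sessions")
    x = np.arange(y.size, dtype=float)
    if np.ptp(y) == 0.0:
        warnings.warn("constant KE series; r defined as 0", RuntimeWarning)
        return 0.0, 0.0
    res = stats.linregress(x, y)
    return float(res.slope), float(res.rvalue)


@dataclass(frozen=True)
class EllipseFit:
    """1-SD covariance ellipse of a 2-D point cloud."""

    center: tuple[float, float]
    semi_major: float
    semi_minor: float
    major_axis_angle_deg: float  # vs the horizontal (first) axis, in [-90, 90)


def fit_deviation_ellipse(points: np.ndarray) -> EllipseFit:
    """Covariance ellipse of (joint_dev, hand_dev) pairs.

    Axes are the covariance eigenvectors, semi-axis lengths the square roots
    of the eigenvalues (1 SD).  Collinear clouds are returned with a zero
    minor axis and a degeneracy warning; identical points raise.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need an (n>=3, 2) array of points")
    cov = np.cov(pts.T)
    vals, vecs = np.linalg.eigh(cov)  # ascending
    if vals[1] <= 1e-30:
        raise ValueError("degenerate covariance: all points identical")
    if vals[0] < 1e-12 * vals[1]:
        warnings.warn("degenerate covariance: points are collinear", RuntimeWarning)
        vals = np.clip(vals, 0.0, None)
    major = vecs[:, 1]
    angle = np.degrees(np.arctan2(major[1], major[0]))
    angle = ((angle + 90.0) % 180.0) - 90.0
    center = pts.mean(axis=0)
    return EllipseFit(
        center=(float(center[0]), float(center[1])),
        semi_major=float(np.sqrt(vals[1])),
        semi_minor=float(np.sqrt(max(vals[0], 0.0))),
        major_axis_angle_deg=float(angle),
    )


def cluster_submovement_classes(
    X: np.ndarray,
    k: int = 2,
    rng: np.random.Generator | None = None,
    n_init: int = 10,
    max_iter: int = 100,
) -> np.ndarray:
    """k-means under cosine distance on (joint_dev, hand_dev) vectors.

    Distance is ``1 - cos(x, c)``, so labels depend only on each vector's
    direction (positive rescaling never changes them).  Runs ``n_init``
    seeded restarts of Lloyd's algorithm and keeps the lowest-inertia
    solution.  Labels are canonicalised so class 0 is the cluster whose
    centroid has the lowest joint-deviation (first) component.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < k:
        raise ValueError(f"need at least k={k} observations")
    norms = np.linalg.norm(X, axis=1)
    if np.any(norms == 0.0):
        raise ValueError("zero vectors have no direction under cosine distance")
    Xn = X / norms[:, None]
    if np.unique(np.round(Xn, 12), axis=0).shape[0] < k:
        warnings.warn(
            "fewer distinct directions than clusters; clustering is degenerate",
            RuntimeWarning,
        )
        return np.zeros(X.shape[0], dtype=int)
    rng = rng if rng is not None else np.random.default_rng(0)

    best_labels, best_inertia = None, np.inf
    for _ in range(n_init):
        centroids = Xn[rng.choice(X.shape[0], size=k, replace=False)]
        labels = np.zeros(X.shape[0], dtype=int)
        for _ in range(max_iter):
            sim = Xn @ centroids.T  # cosine similarity
            new_labels = np.argmax(sim, axis=1)
            for j in range(k):
                members = Xn[new_labels == j]
                if members.shape[0] == 0:
                    # reseed an empty cluster at the worst-fit point
                    worst = int(np.argmin(np.max(sim, axis=1)))
                    centroids[j] = Xn[worst]
                    new_labels[worst] = j
                    members = Xn[new_labels == j]
                c = members.mean(axis=0)
                n = np.linalg.norm(c)
                centroids[j] = c / n if n > 0 else members[0]
            if np.array_equal(new_labels, labels):
                labels = new_labels
                break
            labels = new_labels
        inertia = float(np.sum(1.0 - np.max(Xn @ centroids.T, axis=1)))
        if inertia < best_inertia - 1e-12:
            best_inertia, best_labels = inertia, labels.copy()
            best_centroids = centroids.copy()
    order = np.argsort(best_centroids[:, 0])
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    return remap[best_labels]
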