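"""Model trajectories and kinetic-energy landscapes.

Generates straight and parabolic point-to-point paths with a controlled,
signed, chord-normalised deviation, re-times them with an inverted-Gaussian
interval profile (bell-shaped speed), and sweeps a deviation grid to build a
kinetic-energy landscape (KE-LS) per submovement in hand or joint space.

Deviation convention: a path's deviation is its maximum perpendicular distance
from the start->end chord divided by the chord length, negative when the
extremum lies on the left of the chord in the movement direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .arm_model import (
    ArmGeometry,
    Trajectory,
    angular_velocities,
    inverse_kinematics,
    kinetic_energy,
)

__all__ = [
    "TimeProfile",
    "DeviationGrid",
    "KELandscape",
    "gaussian_bump",
    "make_time_profile",
    "simulate_path",
    "apply_time_profile",
    "jitter_endpoint",
    "build_ke_landscape",
    "estimate_ke_for_observed_shape",
]

DEFAULT_N_POINTS = 501
DEFAULT_MU = 250.0
DEFAULT_SIGMA = 75.0
DEFAULT_DURATION = 1.0


def gaussian_bump(k, mu: float, sigma: float):
    """The (unnormalised) Gaussian g(k) = exp(-0.5*((k-mu)/sigma)**2)."""
    k = np.asarray(k, dtype=float)
    return np.exp(-0.5 * ((k - mu) / sigma) ** 2)


@dataclass(frozen=True)
class TimeProfile:
    """Inverted-Gaussian sampling-time profile.

    ``timestamps`` has ``n_points`` strictly increasing times starting at 0
    and ending at the total duration; intervals are shortest at the movement
    middle, so a path sampled uniformly in space moves fastest there
    (bell-shaped speed).
    """

    n_points: int
    mu: float
    sigma: float
    C: float
    timestamps: np.ndarray

    @property
    def intervals(self) -> np.ndarray:
        return np.diff(self.timestamps)

    @property
    def total_duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])

    def scaled(self, total_duration: float) -> "TimeProfile":
        """Same shape, rescaled to a different total duration."""
        if total_duration <= 0:
            raise ValueError("total_duration must be positive")
        factor = total_duration / self.total_duration
        return TimeProfile(
            n_points=self.n_points,
            mu=self.mu,
            sigma=self.sigma,
            C=self.C,
            timestamps=self.timestamps * factor,
        )


def make_time_profile(
    n_points: int = DEFAULT_N_POINTS,
    mu: float | None = None,
    sigma: float = DEFAULT_SIGMA,
    total_duration: float = DEFAULT_DURATION,
) -> TimeProfile:
    """Build the inverted-Gaussian time profile.

    Inter-sample intervals are ``t(k) = (C - g(k)) / sum(C - g(k))`` scaled to
    ``total_duration``, with ``g(k) = exp(-0.5*((k-mu)/sigma)**2)`` and
    ``C = max(g(k)) + 0.1``.  ``g`` is evaluated at the interval midpoints
    ``k = j + 0.5`` (samples indexed 0..n_points-1), which makes the interval
    sequence exactly symmetric about the sample midpoint when ``mu`` is the
    midpoint (the default: ``(n_points-1)/2``, i.e. 250 for 501 points).
    """
    if n_points < 3:
        raise ValueError("n_points must be >= 3")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if total_duration <= 0:
        raise ValueError("total_duration must be positive")
    if mu is None:
        mu = (n_points - 1) / 2.0
    k_mid = np.arange(n_points - 1, dtype=float) + 0.5
    g = gaussian_bump(k_mid, mu, sigma)
    C = float(g.max()) + 0.1
    raw = C - g
    intervals = raw / raw.sum() * total_duration
    timestamps = np.concatenate([[0.0], np.cumsum(intervals)])
    return TimeProfile(n_points=n_points, mu=float(mu), sigma=float(sigma), C=C, timestamps=timestamps)


@dataclass(frozen=True)
class DeviationGrid:
    """Ordered signed deviation levels (a.u.), symmetric about a single 0."""

    levels: np.ndarray

    def __post_init__(self) -> None:
        levels = np.asarray(self.levels, dtype=float)
        object.__setattr__(self, "levels", levels)
        if np.any(np.diff(levels) <= 0):
            raise ValueError("levels must be strictly increasing")
        if np.count_nonzero(levels == 0.0) != 1:
            raise ValueError("levels must contain exactly one 0")
        if not np.allclose(levels, -levels[::-1]):
            raise ValueError("levels must be symmetric about 0")

    @classmethod
    def symmetric(cls, n_levels: int = 33, span: float = 0.5) -> "DeviationGrid":
        """Symmetric grid of ``n_levels`` (odd) values over [-span, span]."""
        if n_levels < 3 or n_levels % 2 == 0:
            raise ValueError("n_levels must be odd and >= 3")
        return cls(np.linspace(-span, span, n_levels))

    def __len__(self) -> int:
        return self.levels.size


@dataclass
class KELandscape:
    """Mean and SD of modelled KE per deviation level for one submovement."""

    submovement_id: str
    space: str
    levels: np.ndarray
    mean_ke: np.ndarray
    sd_ke: np.ndarray
    n_replicates: int

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        self.mean_ke = np.asarray(self.mean_ke, dtype=float)
        self.sd_ke = np.asarray(self.sd_ke, dtype=float)
        if not (self.levels.shape == self.mean_ke.shape == self.sd_ke.shape):
            raise ValueError("levels, mean_ke, sd_ke must align")
        if np.any(~np.isfinite(self.mean_ke)) or np.any(self.mean_ke < 0):
            raise ValueError("mean_ke must be finite and non-negative")


def _chord_frame(start: np.ndarray, end: np.ndarray):
    chord = end - start
    length = float(np.hypot(chord[0], chord[1]))
    if length == 0.0:
        raise ValueError("coincident endpoints: chord length is zero")
    u = chord / length
    # unit normal pointing to the RIGHT of the movement direction; positive
    # deviations curve rightward, matching the sign convention
    n_right = np.array([u[1], -u[0]])
    return length, u, n_right


def simulate_path(start, end, deviation: float, n_points: int = DEFAULT_N_POINTS) -> np.ndarray:
    """Parabolic (or straight) path between two points with a set deviation.

    In the chord frame the path is ``y(x) = 4*d*l*(x/l)*(1 - x/l)`` sampled at
    ``n_points`` equal steps in x, so the apex offset is ``d*l`` and the
    measured normalised deviation equals ``d`` exactly.  ``d = 0`` gives the
    straight segment.  Returns an (n_points, 2) untimed array of points.
    """
    if n_points < 3:
        raise ValueError("n_points must be >= 3")
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    length, u, n_right = _chord_frame(start, end)
    s = np.linspace(0.0, 1.0, n_points)
    y = 4.0 * deviation * length * s * (1.0 - s)
    return start[None, :] + (s * length)[:, None] * u[None, :] + y[:, None] * n_right[None, :]


def apply_time_profile(points: np.ndarray, profile: TimeProfile, space: str) -> Trajectory:
    """Attach a time profile's timestamps to an untimed path."""
    points = np.asarray(points, dtype=float)
    if points.shape[0] != profile.n_points:
        raise ValueError(
            f"path has {points.shape[0]} points but profile expects {profile.n_points}"
        )
    return Trajectory(space=space, t=profile.timestamps.copy(), u=points[:, 0], v=points[:, 1])


def jitter_endpoint(target, radius: float, rng: np.random.Generator) -> np.ndarray:
    """Uniform random point in the closed disk of ``radius`` around ``target``."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    target = np.asarray(target, dtype=float)
    r = radius * np.sqrt(rng.uniform())
    phi = rng.uniform(0.0, 2.0 * np.pi)
    return target + r * np.array([np.cos(phi), np.sin(phi)])


def _paths_to_ke(paths: np.ndarray, space: str, geom: ArmGeometry, profile: TimeProfile) -> np.ndarray:
    """KE of a batch of untimed paths, shape (R, n_points, 2).

    Hand-space paths are transformed point-wise to joint space; joint-space
    paths are used as-is.  All paths share the profile's timestamps.
    """
    if space == "hand":
        theta_s, theta_e = inverse_kinematics(geom, paths[..., 0], paths[..., 1])
    else:
        theta_s, theta_e = paths[..., 0], paths[..., 1]
    dt = profile.intervals  # (n_points-1,)
    omega_s = np.diff(theta_s, axis=-1) / dt
    omega_e = np.diff(theta_e, axis=-1) / dt
    return 0.5 * geom.Is * np.sum(omega_s**2, axis=-1) + 0.5 * geom.Ie * np.sum(
        omega_e**2, axis=-1
    )


def build_ke_landscape(
    submovement_id: str,
    start,
    end,
    space: str,
    geom: ArmGeometry,
    grid: DeviationGrid | None = None,
    n_replicates: int = 100,
    profile: TimeProfile | None = None,
    rng: np.random.Generator | None = None,
    jitter_radius: float = 0.01,
) -> KELandscape:
    """KE landscape over a deviation grid for one submovement.

    ``start``/``end`` are hand-space target centres (m).  For ``space="joint"``
    the endpoints are first transformed to joint coordinates and the parabola
    is drawn in the (theta_s, theta_e) plane; for ``space="hand"`` the parabola
    is drawn in hand space and every sampled point is transformed through the
    inverse kinematics.  With ``n_replicates > 0``, each level simulates that
    many paths whose endpoints are independently jittered uniformly within
    ``jitter_radius`` (the task's logical radius) of the targets, and the
    deviation is measured relative to the jittered chord; with
    ``n_replicates = 0`` a single noiseless path through the exact centres is
    used and the SD is zero.

    The same ``n_replicates`` endpoint draws are reused for every deviation
    level (common random numbers), so the Monte-Carlo noise is shared across
    levels and cancels from the landscape's finite-difference slope instead of
    polluting it.
    """
    if space not in ("hand", "joint"):
        raise ValueError(f"space must be 'hand' or 'joint', got {space!r}")
    grid = grid if grid is not None else DeviationGrid.symmetric()
    profile = profile if profile is not None else make_time_profile()
    if n_replicates > 0 and rng is None:
        raise ValueError("a seeded rng is required when endpoint jitter is on")
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)

    def endpoints_to_space(a: np.ndarray, b: np.ndarray):
        if space == "joint":
            ts, te = inverse_kinematics(geom, np.array([a[0], b[0]]), np.array([a[1], b[1]]))
            return np.array([ts[0], te[0]]), np.array([ts[1], te[1]])
        return a, b

    if n_replicates == 0:
        endpoint_pairs = [endpoints_to_space(start, end)]
    else:
        endpoint_pairs = []
        for _ in range(n_replicates):
            a = jitter_endpoint(start, jitter_radius, rng)
            b = jitter_endpoint(end, jitter_radius, rng)
            endpoint_pairs.append(endpoints_to_space(a, b))

    n_levels = len(grid)
    mean_ke = np.empty(n_levels)
    sd_ke = np.empty(n_levels)
    for i, level in enumerate(grid.levels):
        paths = np.empty((len(endpoint_pairs), profile.n_points, 2))
        for rep, (a, b) in enumerate(endpoint_pairs):
            paths[rep] = simulate_path(a, b, level, profile.n_points)
        try:
            kes = _paths_to_ke(paths, space, geom, profile)
        except Exception as exc:  # annotate which level failed
            raise type(exc)(f"submovement {submovement_id}, deviation {level:+.4g}: {exc}") from exc
        mean_ke[i] = kes.mean()
        sd_ke[i] = kes.std() if n_replicates > 0 else 0.0
    return KELandscape(
        submovement_id=submovement_id,
        space=space,
        levels=grid.levels.copy(),
        mean_ke=mean_ke,
        sd_ke=sd_ke,
        n_replicates=n_replicates,
    )


def resample_by_arclength(points: np.ndarray, n_points: int) -> np.ndarray:
    """Resample a polyline to ``n_points`` equally spaced in arclength.

    Linear interpolation between the input vertices.
    """
    points = np.asarray(points, dtype=float)
    if points.shape[0] < 2:
        raise ValueError("need at least 2 points")
    seg = np.hypot(*np.diff(points, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] == 0.0:
        raise ValueError("degenerate path: zero total arclength")
    s_new = np.linspace(0.0, s[-1], n_points)
    return np.column_stack([np.interp(s_new, s, points[:, 0]), np.interp(s_new, s, points[:, 1])])


def estimate_ke_for_observed_shape(
    hand_traj: Trajectory, geom: ArmGeometry, profile: TimeProfile | None = None
) -> float:
    """Model KE of an observed hand path with the canonical time profile.

    Discards the trajectory's own timing: the shape is resampled to the
    profile's point count uniformly in arclength, re-timed with the profile's
    inverted-Gaussian intervals, transformed to joint space, and its summed KE
    returned.  This is the standard-profile KE the landscape model assigns to
    that shape.
    """
    if hand_traj.space != "hand":
        raise ValueError("estimate_ke_for_observed_shape requires a hand-space trajectory")
    profile = profile if profile is not None else make_time_profile()
    shape = resample_by_arclength(hand_traj.points, profile.n_points)
    theta_s, theta_e = inverse_kinematics(geom, shape[:, 0], shape[:, 1])
    joint = Trajectory(space="joint", t=profile.timestamps.copy(), u=theta_s, v=theta_e)
    return kinetic_energy(angular_velocities(joint), geom)
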