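"""Two-link planar arm model: kinematics and kinetic energy.

The arm is the planar exoskeleton linkage: an upper arm of length ``L1``
rotating about a fixed shoulder and a lower arm of length ``L2`` attached at
the elbow.  Hand position follows the exoskeleton's angle convention

    Xh - Xs = L2*cos(theta_e - theta_s) + L1*cos(theta_s)
    Yh - Ys = L2*sin(theta_e - theta_s) + L1*sin(theta_s)

so ``theta_s`` is the direction of the upper-arm link and ``theta_e - theta_s``
the direction of the forearm link, both measured from the workspace x axis.
Kinetic energy treats each segment as a rigid rod with its mass concentrated
at the distal end (I = m*L**2) and is accumulated as a plain sum of
``0.5*I*omega**2`` over time samples, which makes it a sampled proxy for the
energetic cost of a movement rather than a time integral.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ArmGeometry",
    "JointState",
    "Trajectory",
    "JointVelocitySeries",
    "UnreachableTargetError",
    "forward_kinematics",
    "inverse_kinematics",
    "angular_velocities",
    "kinetic_energy",
]

#: slack (m) allowed when testing whether a point lies inside the reachable annulus
REACH_TOL = 1e-9
#: slack allowed on |cos| before clamping the acos argument
COS_CLAMP_TOL = 1e-12

# default segment parameters: exoskeleton lengths 0.13/0.23 m, approximate
# segment masses 220/90 g
DEFAULT_L1 = 0.13
DEFAULT_L2 = 0.23
DEFAULT_M1 = 0.220
DEFAULT_M2 = 0.090


class UnreachableTargetError(ValueError):
    """Hand position outside the annulus |L1-L2| <= r <= L1+L2."""


@dataclass(frozen=True)
class ArmGeometry:
    """Segment lengths, masses, moments of inertia and shoulder position.

    ``Is``/``Ie`` default to the rigid-rod values ``m1*L1**2`` / ``m2*L2**2``
    but may be overridden.  ``ik_branch`` selects the inverse-kinematics
    solution: ``"open"`` keeps ``theta_e - 2*theta_s`` in (0, pi), the elbow
    configuration of a right arm in the exoskeleton.
    """

    L1: float = DEFAULT_L1
    L2: float = DEFAULT_L2
    m1: float = DEFAULT_M1
    m2: float = DEFAULT_M2
    Is: float | None = None
    Ie: float | None = None
    shoulder_origin: tuple[float, float] = (0.0, 0.0)
    ik_branch: str = "open"

    def __post_init__(self) -> None:
        if not (self.L1 > 0 and self.L2 > 0):
            raise ValueError("segment lengths must be positive")
        if self.m1 < 0 or self.m2 < 0:
            raise ValueError("segment masses must be non-negative")
        if self.ik_branch not in ("open", "closed"):
            raise ValueError(f"unknown ik_branch {self.ik_branch!r}")
        if self.Is is None:
            object.__setattr__(self, "Is", self.m1 * self.L1**2)
        if self.Ie is None:
            object.__setattr__(self, "Ie", self.m2 * self.L2**2)

    @property
    def reach_min(self) -> float:
        return abs(self.L1 - self.L2)

    @property
    def reach_max(self) -> float:
        return self.L1 + self.L2


@dataclass(frozen=True)
class JointState:
    """Shoulder and elbow angles (rad) in the exoskeleton convention."""

    theta_s: float
    theta_e: float


@dataclass
class Trajectory:
    """Timestamped 2-D path in hand space (m) or joint space (rad).

    ``u``/``v`` are (x, y) for hand space, (theta_s, theta_e) for joint space.
    """

    space: str
    t: np.ndarray
    u: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        if self.space not in ("hand", "joint"):
            raise ValueError(f"space must be 'hand' or 'joint', got {self.space!r}")
        self.t = np.asarray(self.t, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if not (self.t.shape == self.u.shape == self.v.shape):
            raise ValueError("t, u, v must have identical shapes")
        if self.t.size < 2:
            raise ValueError("a trajectory needs at least 2 samples")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return self.t.size

    @property
    def points(self) -> np.ndarray:
        """(n, 2) array of path coordinates."""
        return np.column_stack([self.u, self.v])


@dataclass
class JointVelocitySeries:
    """Interval-centred angular velocities (rad/s).

    One entry per interval of the source trajectory; ``t`` holds interval
    midpoints.
    """

    t: np.ndarray
    omega_s: np.ndarray
    omega_e: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.omega_s = np.asarray(self.omega_s, dtype=float)
        self.omega_e = np.asarray(self.omega_e, dtype=float)
        if not (self.t.shape == self.omega_s.shape == self.omega_e.shape):
            raise ValueError("t, omega_s, omega_e must have identical shapes")


def forward_kinematics(geom: ArmGeometry, theta_s, theta_e):
    """Hand position for joint angles (vectorised; angles in rad).

    Returns ``(Xh, Yh)`` in metres.
    """
    theta_s = np.asarray(theta_s, dtype=float)
    theta_e = np.asarray(theta_e, dtype=float)
    xs, ys = geom.shoulder_origin
    xh = xs + geom.L2 * np.cos(theta_e - theta_s) + geom.L1 * np.cos(theta_s)
    yh = ys + geom.L2 * np.sin(theta_e - theta_s) + geom.L1 * np.sin(theta_s)
    return xh, yh


def inverse_kinematics(geom: ArmGeometry, x, y):
    """Joint angles reaching hand position ``(x, y)`` (vectorised).

    The two-link linkage admits two mirror solutions; the branch configured on
    ``geom`` is returned (``"open"``: ``theta_e - 2*theta_s`` in (0, pi)).

    Raises
    ------
    UnreachableTargetError
        If any point lies outside the reachable annulus beyond ``REACH_TOL``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xs, ys = geom.shoulder_origin
    dx = x - xs
    dy = y - ys
    r = np.hypot(dx, dy)
    if np.any(r > geom.reach_max + REACH_TOL) or np.any(r < geom.reach_min - REACH_TOL):
        bad = float(np.max(r)) if np.any(r > geom.reach_max + REACH_TOL) else float(np.min(r))
        raise UnreachableTargetError(
            f"hand distance {bad:.6g} m outside reachable annulus "
            f"[{geom.reach_min:.6g}, {geom.reach_max:.6g}] m"
        )
    # angle between the two link direction vectors
    cos_alpha = (r**2 - geom.L1**2 - geom.L2**2) / (2.0 * geom.L1 * geom.L2)
    if np.any(np.abs(cos_alpha) > 1.0 + COS_CLAMP_TOL):
        raise UnreachableTargetError("cosine argument outside [-1, 1] beyond tolerance")
    cos_alpha = np.clip(cos_alpha, -1.0, 1.0)
    alpha = np.arccos(cos_alpha)
    if geom.ik_branch == "closed":
        alpha = -alpha
    theta_s = np.arctan2(dy, dx) - np.arctan2(
        geom.L2 * np.sin(alpha), geom.L1 + geom.L2 * np.cos(alpha)
    )
    theta_e = 2.0 * theta_s + alpha
    return theta_s, theta_e


def angular_velocities(traj: Trajectory) -> JointVelocitySeries:
    """Finite-difference joint velocities of a joint-space trajectory.

    Velocities are attributed to interval midpoints, so the series is one
    sample shorter than the trajectory.  Non-uniform time steps are honoured.
    """
    if traj.space != "joint":
        raise ValueError("angular_velocities requires a joint-space trajectory")
    dt = np.diff(traj.t)
    # Trajectory validation already enforces strictly increasing t
    t_mid = traj.t[:-1] + 0.5 * dt
    omega_s = np.diff(traj.u) / dt
    omega_e = np.diff(traj.v) / dt
    return JointVelocitySeries(t=t_mid, omega_s=omega_s, omega_e=omega_e)


def kinetic_energy(vel: JointVelocitySeries, geom: ArmGeometry) -> float:
    """Summed kinetic energy (J) of a joint-velocity series.

    ``KE = sum_t (0.5*Is*omega_s**2 + 0.5*Ie*omega_e**2)`` over all samples;
    a sum, not an integral, so the value scales with the number of samples.
    """
    if not (np.all(np.isfinite(vel.omega_s)) and np.all(np.isfinite(vel.omega_e))):
        raise ValueError("velocities must be finite")
    return float(
        0.5 * geom.Is * np.sum(vel.omega_s**2) + 0.5 * geom.Ie * np.sum(vel.omega_e**2)
    )
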