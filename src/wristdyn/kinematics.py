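"""Modified Denavit-Hartenberg kinematics of the 4-joint exoskeleton.

Joints: {1} shoulder flexion-extension, {2} elbow flexion-extension,
{3} wrist flexion-extension / ulnar-radial deviation, {4} forearm
pronation-supination.  The chain uses the modified (Craig) convention with
elementary transform order ``Rx(alpha_prev) Tx(a_prev) Tz(d) Rz(theta)``
and parameter rows ``(0, 0, ds, th1), (0, 0, de, th2), (0, 0, dw, th3),
(pi/2, 0, 0, th4)`` where ``ds``, ``de``, ``dw`` are subject-adjustable link
offsets.

Single-axis exercise modes are configured by locking one wrist motor:
pronation-supination locks joint 3 (joint 4 sweeps +-85 deg);
flexion-extension locks joint 4 at 0 deg and ulnar-radial deviation locks
joint 4 at 90 deg, with joint 3 active in both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .protocol import MovementType

__all__ = [
    "DHRow",
    "JointLimits",
    "DEFAULT_LIMITS",
    "MovementMode",
    "dh_table",
    "dh_transform",
    "forward_kinematics",
    "check_joint_limits",
    "configure_movement_mode",
]


@dataclass(frozen=True)
class DHRow:
    """One modified-DH parameter row (angles rad, lengths m)."""

    alpha_prev: float
    a_prev: float
    d: float
    theta: float


@dataclass(frozen=True)
class JointLimits:
    """Per-joint angle bounds, degrees: {joint: (min, max)}."""

    limits: dict

    def __post_init__(self):
        for j, (lo, hi) in self.limits.items():
            if lo >= hi:
                raise ParameterError(f"joint {j}: min must be below max")


#: Exoskeleton workspace: shoulder and elbow flexion-extension, forearm
#: pronation-supination, wrist deviation and flexion-extension.
DEFAULT_LIMITS = JointLimits(
    {
        "shoulder_fe": (0.0, 140.0),
        "elbow_fe": (0.0, 120.0),
        "forearm_ps": (-85.0, 85.0),
        "wrist_rud": (-30.0, 20.0),
        "wrist_fe": (-50.0, 60.0),
    }
)


@dataclass(frozen=True)
class MovementMode:
    """Exercise configuration: one active joint, the others locked."""

    movement: MovementType
    active_joint: int
    locked_joints: dict          # {joint index: lock angle, degrees}
    active_range_deg: tuple


def dh_table(thetas, ds: float, de: float, dw: float) -> list:
    """The exoskeleton's 4-row modified-DH table at the given joint angles."""
    th = np.asarray(thetas, dtype=float).reshape(4)
    return [
        DHRow(0.0, 0.0, ds, th[0]),
        DHRow(0.0, 0.0, de, th[1]),
        DHRow(0.0, 0.0, dw, th[2]),
        DHRow(np.pi / 2, 0.0, 0.0, th[3]),
    ]


def dh_transform(row: DHRow) -> np.ndarray:
    """Elementary modified-DH transform Rx(alpha) Tx(a) Tz(d) Rz(theta)."""
    ca, sa = np.cos(row.alpha_prev), np.sin(row.alpha_prev)
    ct, st = np.cos(row.theta), np.sin(row.theta)
    return np.array(
        [
            [ct, -st, 0.0, row.a_prev],
            [st * ca, ct * ca, -sa, -sa * row.d],
            [st * sa, ct * sa, ca, ca * row.d],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )


def forward_kinematics(thetas, ds: float = 0.0, de: float = 0.0, dw: float = 0.0) -> np.ndarray:
    """End-effector pose (4x4 homogeneous transform) at joint angles ``thetas`` (rad)."""
    T = np.eye(4)
    for row in dh_table(thetas, ds, de, dw):
        T = T @ dh_transform(row)
    return T


def check_joint_limits(angles_deg: dict, limits: JointLimits = DEFAULT_LIMITS) -> dict:
    """Inclusive per-joint bound check; angles in degrees at this interface."""
    out = {}
    for joint, angle in angles_deg.items():
        if joint not in limits.limits:
            raise ParameterError(f"unknown joint {joint!r}")
        lo, hi = limits.limits[joint]
        out[joint] = bool(lo <= angle <= hi)
    return out


def configure_movement_mode(movement: MovementType | str) -> MovementMode:
    """Joint locking for a single-axis exercise movement.

    Joint indices follow the kinematic chain: 0 shoulder, 1 elbow, 2 wrist
    motor {3}, 3 forearm motor {4}.
    """
    movement = MovementType(movement)
    if movement is MovementType.pronation_supination:
        return MovementMode(
            movement=movement,
            active_joint=3,
            locked_joints={2: 0.0},
            active_range_deg=DEFAULT_LIMITS.limits["forearm_ps"],
        )
    if movement is MovementType.flexion_extension:
        return MovementMode(
            movement=movement,
            active_joint=2,
            locked_joints={3: 0.0},
            active_range_deg=DEFAULT_LIMITS.limits["wrist_fe"],
        )
    if movement is MovementType.ulnar_radial:
        return MovementMode(
            movement=movement,
            active_joint=2,
            locked_joints={3: 90.0},
            active_range_deg=DEFAULT_LIMITS.limits["wrist_rud"],
        )
    raise ParameterError(f"unknown movement {movement!r}")
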