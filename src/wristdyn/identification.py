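"""Passive/active parameter identification from session data.

Passive stiffness comes from quasi-static displacement-torque records by
multivariable linear regression of ``tau = K q (+ tau0)``; off-diagonal
symmetry of K is enforced by construction (6 free stiffness parameters).
Damping is scaled proportionally to stiffness with the flexion-extension
diagonal pinned to a literature value.  Session-level helpers run the
regression over repeated rounds until the estimate converges and extract the
active-torque/RoM summary from resisted-movement recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .biomech import AXIS_INDEX, DampingMatrix, StiffnessMatrix, Trajectory
from .errors import IdentifiabilityError, InputError, ParameterError

__all__ = [
    "QuasiStaticRecord",
    "StiffnessFit",
    "PassiveComponents",
    "ActiveComponents",
    "SessionResult",
    "fit_stiffness",
    "scale_damping",
    "extract_passive_components",
    "extract_active_components",
]

#: Default flexion-extension damping pin, Nms/rad. Measured passive wrist FE
#: damping lies in 0.02-0.03 Nms/rad; the upper value is used.
DEFAULT_B_FE = 0.03


@dataclass(frozen=True)
class QuasiStaticRecord:
    """Quasi-static displacement/torque pairs from a passive manipulation.

    ``displacements`` and ``torques`` are (n, 3) arrays (rad, Nm).
    """

    displacements: np.ndarray
    torques: np.ndarray
    movement_type: str | None = None

    def __post_init__(self):
        d = np.atleast_2d(np.asarray(self.displacements, dtype=float))
        tq = np.atleast_2d(np.asarray(self.torques, dtype=float))
        if d.shape != tq.shape or d.shape[1] != 3:
            raise InputError(
                f"displacements and torques must both be (n, 3); got {d.shape}, {tq.shape}"
            )
        object.__setattr__(self, "displacements", d)
        object.__setattr__(self, "torques", tq)

    @property
    def n_points(self) -> int:
        return self.displacements.shape[0]


@dataclass(frozen=True)
class StiffnessFit:
    """Stiffness regression result with diagnostics."""

    K: StiffnessMatrix
    offset: np.ndarray          # per-axis constant torque offset, Nm
    residual_rms: float         # RMS torque residual, Nm
    rank: int
    singular_values: np.ndarray


@dataclass(frozen=True)
class PassiveComponents:
    """Outcome of the iterative passive-identification stage."""

    K: StiffnessMatrix
    B: DampingMatrix
    per_round_K: list
    per_round_change: list      # relative Frobenius change between rounds
    converged: bool
    passive_torque_peak: float


@dataclass(frozen=True)
class ActiveComponents:
    """Outcome of the resisted-movement (active) stage."""

    max_active_torque: float    # Nm, on the movement axis
    achieved_rom: float         # degrees, max - min of the movement-axis angle
    movement_type: str


@dataclass(frozen=True)
class SessionResult:
    passive: PassiveComponents | None = None
    active: ActiveComponents | None = None
    movement_type: str | None = None


def _symmetric_design(q: np.ndarray, fit_offset: bool) -> np.ndarray:
    """Design matrix mapping [K11 K22 K33 K12 K13 K23 (t0a t0b t0g)] -> stacked torques."""
    n = q.shape[0]
    ncol = 9 if fit_offset else 6
    X = np.zeros((3 * n, ncol))
    a, b, g = q[:, 0], q[:, 1], q[:, 2]
    # tau_alpha = K11 a + K12 b + K13 g
    X[0::3, 0] = a
    X[0::3, 3] = b
    X[0::3, 4] = g
    # tau_beta = K12 a + K22 b + K23 g
    X[1::3, 3] = a
    X[1::3, 1] = b
    X[1::3, 5] = g
    # tau_gamma = K13 a + K23 b + K33 g
    X[2::3, 4] = a
    X[2::3, 5] = b
    X[2::3, 2] = g
    if fit_offset:
        X[0::3, 6] = 1.0
        X[1::3, 7] = 1.0
        X[2::3, 8] = 1.0
    return X


def fit_stiffness(
    record: QuasiStaticRecord,
    fit_offset: bool = False,
    symmetric: bool = True,
) -> StiffnessFit:
    """Least-squares stiffness fit ``tau = K q (+ tau0)``.

    With ``symmetric=True`` (default) K is parameterized by its 6 free
    entries so off-diagonal symmetry holds exactly by construction; the
    alternative fits all 9 entries and averages K[i,j] with K[j,i].
    ``fit_offset`` adds an estimable constant torque offset per axis
    (the per-session axis-offset term).

    Raises :class:`IdentifiabilityError` when the displacement set does not
    excite all parameters, naming the deficient direction(s).
    """
    q = record.displacements
    tau = record.torques
    n_par = (6 if symmetric else 9) + (3 if fit_offset else 0)
    if 3 * record.n_points < n_par:
        raise IdentifiabilityError(
            f"{record.n_points} points provide {3 * record.n_points} equations "
            f"for {n_par} parameters"
        )

    if symmetric:
        X = _symmetric_design(q, fit_offset)
    else:
        n = q.shape[0]
        ncol = 12 if fit_offset else 9
        X = np.zeros((3 * n, ncol))
        for row in range(3):
            X[row::3, 3 * row : 3 * row + 3] = q
            if fit_offset:
                X[row::3, 9 + row] = 1.0
    y = tau.reshape(-1)

    sol, _, rank, sv = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        # name the deficient parameter directions (right singular vectors
        # matching near-zero singular values)
        _, s, vt = np.linalg.svd(X, full_matrices=True)
        cutoff = s[0] * max(X.shape) * np.finfo(float).eps if s.size else 0.0
        deficient = vt[np.sum(s > cutoff):]
        raise IdentifiabilityError(
            f"rank-deficient design (rank {rank} < {X.shape[1]}); the "
            "displacement set does not excite "
            f"{X.shape[1] - rank} parameter direction(s)",
            deficient_directions=deficient,
        )

    if symmetric:
        k11, k22, k33, k12, k13, k23 = sol[:6]
        K = np.array([[k11, k12, k13], [k12, k22, k23], [k13, k23, k33]])
        offset = sol[6:9] if fit_offset else np.zeros(3)
    else:
        K9 = sol[:9].reshape(3, 3)
        K = (K9 + K9.T) / 2.0
        offset = sol[9:12] if fit_offset else np.zeros(3)

    resid = y - X @ sol
    return StiffnessFit(
        K=StiffnessMatrix(K),
        offset=np.asarray(offset),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        rank=int(rank),
        singular_values=sv,
    )


def scale_damping(
    K: StiffnessMatrix, b_fe: float = DEFAULT_B_FE, fe_axis: int = AXIS_INDEX["fe"]
) -> DampingMatrix:
    """Damping proportional to stiffness, pinned so B_FE equals ``b_fe``.

    ``B = c K`` with ``c = b_fe / K_FE``; the flexion-extension diagonal of
    the result is exactly ``b_fe`` Nms/rad.
    """
    Karr = np.asarray(K)
    k_fe = Karr[fe_axis, fe_axis]
    if k_fe <= 0:
        raise ParameterError(
            f"flexion-extension stiffness must be positive to scale damping; got {k_fe}"
        )
    return DampingMatrix(b_fe / k_fe * Karr)


def extract_passive_components(
    rounds: list[QuasiStaticRecord],
    tol: float = 1e-3,
    max_rounds: int = 12,
    b_fe: float = DEFAULT_B_FE,
    fit_offset: bool = False,
) -> PassiveComponents:
    """Iterative passive identification over repeated quasi-static rounds.

    Each round re-fits the stiffness on that round's data; convergence is
    declared once the relative Frobenius change between consecutive round
    estimates falls below ``tol``.  Non-convergence within ``max_rounds`` is
    flagged on the result, not raised.
    """
    if not rounds:
        raise InputError("at least one quasi-static round is required")
    rounds = rounds[:max_rounds]
    per_round_K: list[np.ndarray] = []
    changes: list[float] = []
    converged = False
    for rec in rounds:
        fit = fit_stiffness(rec, fit_offset=fit_offset)
        per_round_K.append(np.asarray(fit.K))
        if len(per_round_K) >= 2:
            prev, cur = per_round_K[-2], per_round_K[-1]
            denom = np.linalg.norm(prev, "fro")
            change = np.linalg.norm(cur - prev, "fro") / denom if denom > 0 else np.inf
            changes.append(float(change))
            if change < tol:
                converged = True
                break

    K = StiffnessMatrix(per_round_K[-1])
    B = scale_damping(K, b_fe=b_fe)
    # peak passive torque actually observed across the rounds used
    peak = max(
        float(np.max(np.linalg.norm(rec.torques, axis=1))) for rec in rounds[: len(per_round_K)]
    )
    return PassiveComponents(
        K=K,
        B=B,
        per_round_K=per_round_K,
        per_round_change=changes,
        converged=converged,
        passive_torque_peak=peak,
    )


def extract_active_components(
    traj: Trajectory,
    torque_series: np.ndarray,
    movement_type: str,
) -> ActiveComponents:
    """Active-stage summary: peak patient torque and achieved RoM.

    ``torque_series`` is the patient-attributed (n, 3) torque with the
    robot's resistive torque already subtracted upstream.  RoM is
    ``max - min`` of the movement-axis angle in degrees, so it is invariant
    to the axis sign convention.
    """
    key = movement_type.lower()
    aliases = {
        "pronation_supination": "ps",
        "flexion_extension": "fe",
        "ulnar_radial": "rud",
        "radial_ulnar": "rud",
    }
    key = aliases.get(key, key)
    if key not in AXIS_INDEX:
        raise InputError(f"unknown movement type {movement_type!r}")
    axis = AXIS_INDEX[key]

    torque_series = np.atleast_2d(np.asarray(torque_series, dtype=float))
    if torque_series.shape != (traj.n_samples, 3):
        raise InputError(
            f"torque series must be ({traj.n_samples}, 3); got {torque_series.shape}"
        )
    angles = traj.q[:, axis]
    rom = float(np.degrees(angles.max() - angles.min()))
    max_tau = float(np.max(np.abs(torque_series[:, axis])))
    return ActiveComponents(
        max_active_torque=max_tau, achieved_rom=rom, movement_type=movement_type
    )
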