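"""Second-order mechanical impedance model of coupled wrist-forearm rotations.

The wrist and forearm are modelled as a universal joint with three rotational
degrees of freedom: forearm pronation-supination (``alpha``, most proximal)
and the two wrist rotations flexion-extension (``beta``) and radial-ulnar
deviation (``gamma``).  The rotation sequence is proximal to distal:
``R = Ry(alpha) @ Rz(beta) @ Rx(gamma)`` with the lab ``y`` axis along the
forearm in the neutral posture.  Under this convention the body-frame angular
velocity of the hand is::

    w_x = gamma' + alpha' * sin(beta)
    w_y = beta' * sin(gamma) + alpha' * cos(beta) * cos(gamma)
    w_z = beta' * cos(gamma) - alpha' * cos(beta) * sin(gamma)

and the kinetic energy ``T = (IHx w_x^2 + IHy w_y^2 + IHz w_z^2
+ IAy alpha'^2) / 2`` yields the configuration-dependent inertia matrix and
centripetal/Coriolis terms implemented here.  The joint torque balance is

    tau_active = M(q) q'' + C(q, q') + B q' + K (q - q_rest) + g(q)

where ``B`` and ``K`` are the 3x3 passive damping and stiffness matrices
(stiffness is symmetric in the off-diagonals), and ``g(q)`` is the
gravitational torque of the hand treated as a point mass ``m`` at distance
``l`` from the wrist along the hand's long axis.

All angles are radians, torques Nm, times seconds.  Degrees appear only at
I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import InputError, NumericalError, ParameterError

__all__ = [
    "AnthropometricProfile",
    "InertialParameters",
    "StiffnessMatrix",
    "DampingMatrix",
    "JointState",
    "ImpedanceModel",
    "Trajectory",
    "DEFAULT_REGRESSION",
    "estimate_inertial_params",
    "inertia_matrix",
    "inertia_matrix_gradient",
    "coriolis_vector",
    "potential_energy",
    "gravity_torque",
    "inverse_dynamics",
    "forward_dynamics",
    "mechanical_energy",
]

#: Axis order used throughout: index 0 = pronation-supination (forearm),
#: index 1 = flexion-extension (wrist), index 2 = radial-ulnar deviation.
AXIS_LABELS = ("ps", "fe", "rud")

#: Default axis-label map from anatomical names to coordinate indices.
AXIS_INDEX = {"ps": 0, "fe": 1, "rud": 2, "alpha": 0, "beta": 1, "gamma": 2}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnthropometricProfile:
    """Raw subject measurements feeding the anthropometric regressions.

    Parameters
    ----------
    hand_length, forearm_length : float
        Segment lengths in metres.
    hand_mass : float
        Hand mass in kg.
    body_mass : float, optional
        Whole-body mass in kg; required only when a regression coefficient
        is expressed as a fraction of body mass (e.g. forearm mass).
    hand_com_fraction : float, optional
        Overrides the regression's centre-of-mass fraction (of hand length,
        measured from the wrist joint).
    """

    hand_length: float
    forearm_length: float
    hand_mass: float
    body_mass: float | None = None
    hand_com_fraction: float | None = None

    def __post_init__(self):
        if self.hand_length <= 0 or self.forearm_length <= 0:
            raise ParameterError("segment lengths must be positive")
        if self.hand_mass < 0:
            raise ParameterError("hand_mass must be non-negative")
        if self.body_mass is not None and self.body_mass <= 0:
            raise ParameterError("body_mass must be positive when given")
        if self.hand_com_fraction is not None and not (
            0 < self.hand_com_fraction < 1
        ):
            raise ParameterError("hand_com_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class InertialParameters:
    """Inertial constants of the hand + forearm system.

    ``IHx``, ``IHy``, ``IHz`` are the hand's principal moments of inertia
    about the wrist joint (``y`` is the hand's long axis, so ``IHy`` is the
    longitudinal moment), ``IAy`` the forearm moment about its long axis.
    ``m`` and ``l`` are the hand mass and wrist-to-hand-CoM distance used by
    the gravity term; ``g`` is gravitational acceleration.
    """

    IHx: float
    IHy: float
    IHz: float
    IAy: float
    m: float = 0.0
    l: float = 0.0
    g: float = 9.81

    def __post_init__(self):
        for name in ("IHx", "IHy", "IHz", "IAy", "m", "l", "g"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")


def _as_matrix(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.shape != (3, 3):
        raise ParameterError(f"expected a 3x3 matrix, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ParameterError("matrix entries must be finite")
    return arr


@dataclass(frozen=True)
class StiffnessMatrix:
    """3x3 passive stiffness matrix in Nm/rad, symmetric off-diagonals."""

    K: np.ndarray

    def __post_init__(self):
        arr = _as_matrix(self.K)
        if not np.allclose(arr, arr.T, rtol=0, atol=1e-9 * max(1.0, np.abs(arr).max())):
            raise ParameterError("stiffness off-diagonal terms must be symmetric")
        if np.any(np.diag(arr) < 0):
            raise ParameterError("stiffness diagonal entries must be non-negative")
        # store a symmetrized copy so downstream algebra sees exact symmetry
        object.__setattr__(self, "K", (arr + arr.T) / 2.0)

    def __array__(self, dtype=None, copy=None):
        return np.array(self.K, dtype=dtype)


@dataclass(frozen=True)
class DampingMatrix:
    """3x3 passive damping matrix in Nms/rad."""

    B: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "B", _as_matrix(self.B))

    def __array__(self, dtype=None, copy=None):
        return np.array(self.B, dtype=dtype)


@dataclass(frozen=True)
class JointState:
    """Joint angles, velocities and (optionally) accelerations.

    ``q = (alpha, beta, gamma)`` in radians; derivatives in rad/s, rad/s^2.
    """

    q: np.ndarray
    qdot: np.ndarray = field(default_factory=lambda: np.zeros(3))
    qddot: np.ndarray | None = None

    def __post_init__(self):
        q = np.asarray(self.q, dtype=float).reshape(3)
        qd = np.asarray(self.qdot, dtype=float).reshape(3)
        if not (np.all(np.isfinite(q)) and np.all(np.isfinite(qd))):
            raise InputError("joint state must be finite")
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "qdot", qd)
        if self.qddot is not None:
            qdd = np.asarray(self.qddot, dtype=float).reshape(3)
            if not np.all(np.isfinite(qdd)):
                raise InputError("joint accelerations must be finite")
            object.__setattr__(self, "qddot", qdd)


@dataclass(frozen=True)
class ImpedanceModel:
    """Assembled passive impedance model: inertia + damping + stiffness + gravity."""

    inertial: InertialParameters
    B: DampingMatrix
    K: StiffnessMatrix
    rest_posture: np.ndarray = field(default_factory=lambda: np.zeros(3))
    gravity_enabled: bool = True

    def __post_init__(self):
        rest = np.asarray(self.rest_posture, dtype=float).reshape(3)
        if not np.all(np.isfinite(rest)):
            raise ParameterError("rest_posture must be finite")
        object.__setattr__(self, "rest_posture", rest)


@dataclass(frozen=True)
class Trajectory:
    """Sampled joint motion: time grid plus per-sample angle arrays.

    ``q``/``qd``/``qdd`` have shape ``(n, 3)``; ``qdd`` may be ``None`` in
    which case consumers fill it with second-order central differences.
    """

    t: np.ndarray
    q: np.ndarray
    qd: np.ndarray | None = None
    qdd: np.ndarray | None = None

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float).reshape(-1)
        q = np.asarray(self.q, dtype=float)
        if t.size < 2:
            raise InputError("a trajectory needs at least 2 samples")
        if np.any(np.diff(t) <= 0):
            raise InputError("time grid must be strictly increasing")
        if q.shape != (t.size, 3):
            raise InputError(f"q must have shape ({t.size}, 3), got {q.shape}")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "q", q)
        for name in ("qd", "qdd"):
            val = getattr(self, name)
            if val is not None:
                val = np.asarray(val, dtype=float)
                if val.shape != q.shape:
                    raise InputError(f"{name} must match q's shape")
                object.__setattr__(self, name, val)

    @property
    def n_samples(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def with_derivatives(self) -> "Trajectory":
        """Return a copy with qd/qdd filled by central differences if absent."""
        qd = self.qd if self.qd is not None else np.gradient(self.q, self.t, axis=0)
        qdd = self.qdd if self.qdd is not None else np.gradient(qd, self.t, axis=0)
        return Trajectory(self.t, self.q, qd, qdd)

    def states(self):
        """Iterate over per-sample :class:`JointState` objects."""
        traj = self.with_derivatives()
        for i in range(traj.n_samples):
            yield JointState(traj.q[i], traj.qd[i], traj.qdd[i])


# ---------------------------------------------------------------------------
# anthropometric regression
# ---------------------------------------------------------------------------

#: Shipped anthropometric regression coefficients.  Mass fractions are of
#: whole-body mass, CoM fraction is of hand length from the wrist, and the
#: radii of gyration are fractions of the segment length about the hand's
#: body-fixed axes (x, z transverse; y longitudinal).  Values follow the
#: commonly used cadaver/gamma-scan segment-parameter tables.
DEFAULT_REGRESSION: dict = {
    "hand_mass_fraction": 0.0061,
    "hand_com_fraction": 0.3624,
    "hand_gyration_fraction_x": 0.288,
    "hand_gyration_fraction_y": 0.184,
    "hand_gyration_fraction_z": 0.235,
    "forearm_mass_fraction": 0.0162,
    "forearm_long_gyration_fraction": 0.121,
    "g": 9.81,
}


def estimate_inertial_params(
    profile: AnthropometricProfile,
    regression: dict | None = None,
) -> InertialParameters:
    """Estimate inertial parameters from anthropometrics via regression table.

    The hand is modelled as a rigid body whose principal moments about its
    own centre of mass are ``m * (c_i * hand_length)^2`` with per-axis
    radius-of-gyration fractions ``c_i`` from the table; transverse moments
    (x, z) are transported to the wrist joint with the parallel-axis theorem
    while the longitudinal moment (y) is unchanged.  The forearm contributes
    only its moment about its long axis, ``m_forearm * (c * forearm_length)^2``,
    with forearm mass taken as a body-mass fraction (so ``body_mass`` is
    required unless the forearm fraction is zero).

    An explicit ``hand_com_fraction`` on the profile overrides the table's.
    """
    table = dict(DEFAULT_REGRESSION)
    if regression:
        table.update(regression)

    com_frac = (
        profile.hand_com_fraction
        if profile.hand_com_fraction is not None
        else table["hand_com_fraction"]
    )
    l = com_frac * profile.hand_length
    m = profile.hand_mass

    Lh = profile.hand_length
    I_com = {
        ax: m * (table[f"hand_gyration_fraction_{ax}"] * Lh) ** 2
        for ax in ("x", "y", "z")
    }
    # transport transverse axes to the wrist joint
    IHx = I_com["x"] + m * l**2
    IHy = I_com["y"]
    IHz = I_com["z"] + m * l**2

    fa_frac = table["forearm_mass_fraction"]
    if fa_frac > 0:
        if profile.body_mass is None:
            raise ParameterError(
                "body_mass is required: the regression expresses forearm mass "
                "as a fraction of body mass"
            )
        m_forearm = fa_frac * profile.body_mass
    else:
        m_forearm = 0.0
    IAy = m_forearm * (table["forearm_long_gyration_fraction"] * profile.forearm_length) ** 2

    return InertialParameters(
        IHx=IHx, IHy=IHy, IHz=IHz, IAy=IAy, m=m, l=l, g=table.get("g", 9.81)
    )


# ---------------------------------------------------------------------------
# dynamics building blocks
# ---------------------------------------------------------------------------

def inertia_matrix(p: InertialParameters, state: JointState) -> np.ndarray:
    """Configuration-dependent 3x3 inertia matrix.

    Entries (with ``s = sin``, ``c = cos``)::

        A = IHx s(b)^2 + IHy c(b)^2 c(g)^2 + IHz s(g)^2 c(b)^2 + IAy
        B = c(g) c(b) s(g) (IHy - IHz)
        C = IHx s(b)
        D = IHy s(g)^2 + IHz c(g)^2
        E = 0
        F = IHx

    arranged as ``[[A, B, C], [B, D, E], [C, E, F]]`` — symmetric by
    construction.
    """
    _, b, g = state.q
    sb, cb = np.sin(b), np.cos(b)
    sg, cg = np.sin(g), np.cos(g)
    A = p.IHx * sb**2 + (p.IHy * cg**2 + p.IHz * sg**2) * cb**2 + p.IAy
    B = cb * sg * cg * (p.IHy - p.IHz)
    C = p.IHx * sb
    D = p.IHy * sg**2 + p.IHz * cg**2
    E = 0.0
    F = p.IHx
    return np.array([[A, B, C], [B, D, E], [C, E, F]])


def inertia_matrix_gradient(p: InertialParameters, state: JointState) -> np.ndarray:
    """Analytic gradient ``dM/dq`` with shape (3, 3, 3); ``[..., k]`` is dM/dq_k.

    M is independent of alpha, so the first slice is zero.
    """
    _, b, g = state.q
    sb, cb = np.sin(b), np.cos(b)
    sg, cg = np.sin(g), np.cos(g)
    dIyz = p.IHy - p.IHz

    dM = np.zeros((3, 3, 3))
    # d/d beta
    dA_db = np.sin(2 * b) * (p.IHx - p.IHy * cg**2 - p.IHz * sg**2)
    dB_db = -sb * sg * cg * dIyz
    dC_db = p.IHx * cb
    dM[0, 0, 1] = dA_db
    dM[0, 1, 1] = dM[1, 0, 1] = dB_db
    dM[0, 2, 1] = dM[2, 0, 1] = dC_db
    # d/d gamma
    dA_dg = cb**2 * np.sin(2 * g) * (p.IHz - p.IHy)
    dB_dg = cb * np.cos(2 * g) * dIyz
    dD_dg = np.sin(2 * g) * dIyz
    dM[0, 0, 2] = dA_dg
    dM[0, 1, 2] = dM[1, 0, 2] = dB_dg
    dM[1, 1, 2] = dD_dg
    return dM


def _coriolis_christoffel(p: InertialParameters, state: JointState) -> np.ndarray:
    """C(q, q') q' via Christoffel symbols of the first kind."""
    dM = inertia_matrix_gradient(p, state)
    qd = state.qdot
    # c_ijk = (dM_ij/dq_k + dM_ik/dq_j - dM_jk/dq_i) / 2
    c = (dM + dM.transpose(0, 2, 1) - dM.transpose(2, 0, 1)) / 2.0
    return np.einsum("ijk,j,k->i", c, qd, qd)


def _coriolis_closed_form(p: InertialParameters, state: JointState) -> np.ndarray:
    """Expanded closed-form centripetal/Coriolis torque vector (G, H, I).

    Obtained by symbolically expanding the Euler-Lagrange equations of the
    hand's rotational kinetic energy; this is the torque-table form of the
    same quantity the Christoffel route computes.
    """
    _, b, g = state.q
    ad, bd, gd = state.qdot
    sb, cb = np.sin(b), np.cos(b)
    sg, cg = np.sin(g), np.cos(g)
    dIyz = p.IHy - p.IHz

    G = (
        -2 * ad * bd * sb * cb * (p.IHy * cg**2 + p.IHz * sg**2 - p.IHx)
        - 2 * ad * gd * dIyz * sg * cg * cb**2
        - bd**2 * dIyz * sb * sg * cg
        + bd * gd * cb * (p.IHx + dIyz * np.cos(2 * g))
    )
    H = (
        ad**2 * sb * cb * (p.IHy * cg**2 + p.IHz * sg**2 - p.IHx)
        - ad * gd * cb * (p.IHx - dIyz * np.cos(2 * g))
        + bd * gd * dIyz * np.sin(2 * g)
    )
    I = (
        ad**2 * dIyz * sg * cg * cb**2
        + ad * bd * cb * (p.IHx - dIyz * np.cos(2 * g))
        - bd**2 * dIyz * np.sin(2 * g) / 2.0
    )
    return np.array([G, H, I])


def coriolis_vector(
    p: InertialParameters, state: JointState, method: str = "christoffel"
) -> np.ndarray:
    """Centripetal/Coriolis torque vector (G, H, I) in Nm.

    ``method='christoffel'`` (default, authoritative) builds the vector from
    the analytic inertia-matrix gradient; ``method='table'`` evaluates the
    expanded closed-form torque-table expressions.  Both derive from the same
    kinetic energy and agree to rounding.
    """
    if method == "christoffel":
        return _coriolis_christoffel(p, state)
    if method == "table":
        return _coriolis_closed_form(p, state)
    raise ParameterError(f"unknown coriolis method {method!r}")


#: Default gravity pull direction in the lab frame. The lab frame is chosen
#: with the gravitational field along +z (neutral forearm along y), which
#: reproduces the conventional closed-form gravity torque vector.
GRAVITY_DIRECTION = np.array([0.0, 0.0, 1.0])


def _hand_direction(q: np.ndarray) -> np.ndarray:
    """Unit vector of the hand's long axis in the lab frame: R(q) @ ey."""
    a, b, g = q
    sa, ca = np.sin(a), np.cos(a)
    sb, cb = np.sin(b), np.cos(b)
    sg, cg = np.sin(g), np.cos(g)
    # Ry(a) @ Rz(b) @ Rx(g) @ [0, 1, 0]
    return np.array(
        [
            -sb * cg * ca + sg * sa,
            cb * cg,
            sb * cg * sa + sg * ca,
        ]
    )


def potential_energy(p: InertialParameters, q: np.ndarray,
                     gravity_direction: np.ndarray = GRAVITY_DIRECTION) -> float:
    """Gravitational potential energy of the hand point mass, J.

    ``U = -m g l (g_hat . d_hat(q))`` where ``d_hat`` is the hand's long-axis
    direction and ``g_hat`` the unit gravity-pull direction.
    """
    return -p.m * p.g * p.l * float(np.dot(gravity_direction, _hand_direction(q)))


def gravity_torque(p: InertialParameters, state: JointState,
                   gravity_direction: np.ndarray = GRAVITY_DIRECTION) -> np.ndarray:
    """Gravity torque vector ``dU/dq`` in Nm (the term active torque must overcome).

    Closed form for the default gravity direction::

        g m l [ s(a) s(g) - c(a) s(b) c(g),
                -s(a) c(b) c(g),
                s(a) s(b) s(g) - c(a) c(g) ]
    """
    a, b, g_ = state.q
    k = p.g * p.l * p.m
    if k == 0.0:
        return np.zeros(3)
    if np.array_equal(gravity_direction, GRAVITY_DIRECTION):
        sa, ca = np.sin(a), np.cos(a)
        sb, cb = np.sin(b), np.cos(b)
        sg, cg = np.sin(g_), np.cos(g_)
        return k * np.array(
            [
                sa * sg - ca * sb * cg,
                -sa * cb * cg,
                sa * sb * sg - ca * cg,
            ]
        )
    # general direction: analytic gradient of -m g l (g_hat . d_hat)
    eps = 1e-7
    grad = np.empty(3)
    for i in range(3):
        qp = state.q.copy()
        qm = state.q.copy()
        qp[i] += eps
        qm[i] -= eps
        grad[i] = (
            potential_energy(p, qp, gravity_direction)
            - potential_energy(p, qm, gravity_direction)
        ) / (2 * eps)
    return grad


# ---------------------------------------------------------------------------
# inverse and forward dynamics
# ---------------------------------------------------------------------------

def inverse_dynamics(model: ImpedanceModel, traj: Trajectory) -> np.ndarray:
    """Per-sample torque required to produce the trajectory, shape (n, 3).

    Accelerations absent from the trajectory are filled by second-order
    central differences (one-sided at the ends).
    """
    traj = traj.with_derivatives()
    p = model.inertial
    B = np.asarray(model.B)
    K = np.asarray(model.K)
    tau = np.empty((traj.n_samples, 3))
    for i in range(traj.n_samples):
        state = JointState(traj.q[i], traj.qd[i], traj.qdd[i])
        M = inertia_matrix(p, state)
        tau[i] = (
            M @ traj.qdd[i]
            + coriolis_vector(p, state)
            + B @ traj.qd[i]
            + K @ (traj.q[i] - model.rest_posture)
        )
        if model.gravity_enabled:
            tau[i] += gravity_torque(p, state)
    return tau


#: Condition-number guard for the inertia matrix during integration.
_COND_LIMIT = 1e12


def _acceleration(model: ImpedanceModel, q, qd, tau_active) -> np.ndarray:
    p = model.inertial
    if not (np.all(np.isfinite(q)) and np.all(np.isfinite(qd))):
        raise NumericalError("forward dynamics diverged (non-finite state)")
    state = JointState(q, qd)
    M = inertia_matrix(p, state)
    if np.linalg.cond(M) > _COND_LIMIT:
        raise NumericalError(
            f"inertia matrix near-singular at q={np.array2string(q, precision=4)}"
        )
    rhs = (
        tau_active
        - coriolis_vector(p, state)
        - np.asarray(model.B) @ qd
        - np.asarray(model.K) @ (q - model.rest_posture)
    )
    if model.gravity_enabled:
        rhs = rhs - gravity_torque(p, state)
    return np.linalg.solve(M, rhs)


def forward_dynamics(
    model: ImpedanceModel,
    active_torque: Callable[[float], Sequence[float]],
    initial: JointState,
    duration: float,
    dt: float = 1e-3,
) -> Trajectory:
    """Integrate the equations of motion under an active torque input.

    Uses the classical fixed-step 4th-order Runge-Kutta scheme.  Returns a
    trajectory sampled at every step, including accelerations evaluated from
    the dynamics at the stored states.
    """
    if dt <= 0:
        raise ParameterError("dt must be positive")
    if duration <= 0:
        raise ParameterError("duration must be positive")

    n = int(round(duration / dt)) + 1
    t = np.arange(n) * dt
    q = np.empty((n, 3))
    qd = np.empty((n, 3))
    qdd = np.empty((n, 3))
    q[0] = initial.q
    qd[0] = initial.qdot

    def deriv(ti, qi, qdi):
        tau = np.asarray(active_torque(ti), dtype=float).reshape(3)
        return qdi, _acceleration(model, qi, qdi, tau)

    for i in range(n - 1):
        ti = t[i]
        k1q, k1v = deriv(ti, q[i], qd[i])
        k2q, k2v = deriv(ti + dt / 2, q[i] + dt / 2 * k1q, qd[i] + dt / 2 * k1v)
        k3q, k3v = deriv(ti + dt / 2, q[i] + dt / 2 * k2q, qd[i] + dt / 2 * k2v)
        k4q, k4v = deriv(ti + dt, q[i] + dt * k3q, qd[i] + dt * k3v)
        q[i + 1] = q[i] + dt / 6 * (k1q + 2 * k2q + 2 * k3q + k4q)
        qd[i + 1] = qd[i] + dt / 6 * (k1v + 2 * k2v + 2 * k3v + k4v)
        if not (np.all(np.isfinite(q[i + 1])) and np.all(np.isfinite(qd[i + 1]))):
            raise NumericalError(f"forward dynamics diverged at t={t[i + 1]:.4f} s")

    for i in range(n):
        tau = np.asarray(active_torque(t[i]), dtype=float).reshape(3)
        qdd[i] = _acceleration(model, q[i], qd[i], tau)

    return Trajectory(t, q, qd, qdd)


def mechanical_energy(model: ImpedanceModel, state: JointState) -> float:
    """Total mechanical energy: kinetic + elastic + gravitational, J."""
    p = model.inertial
    M = inertia_matrix(p, state)
    kin = 0.5 * state.qdot @ M @ state.qdot
    dq = state.q - model.rest_posture
    elastic = 0.5 * dq @ np.asarray(model.K) @ dq
    grav = potential_energy(p, state.q) if model.gravity_enabled else 0.0
    return float(kin + elastic + grav)
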