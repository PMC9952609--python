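"""Torque decomposition and inter-DOF coupling statistics.

The full joint torque splits by *source* (inertia, damping, stiffness,
gravity) and, within each matrix source, into a *main* part produced by the
diagonal matrix entries and an *interaction* part produced by the
off-diagonal entries.  The centripetal/Coriolis vector exists only through
inter-DOF velocity coupling and is classified as interaction by default
(configurable).  Gravity cannot be split and is reported separately.

The time-averaged magnitude of a per-source torque vector uses the
non-orthogonal metric

    Mj = (1/T) \\int sqrt(Ma^2 + Mb^2 + Mg^2 + 2 Ma Mg sin(beta)) dt

whose cross term accounts for the pronation-supination and deviation axes
becoming colinear at beta = +-pi/2.  The coupling ratio R is the interaction
magnitude over the main magnitude (gravity excluded), and Rj the same ratio
restricted to one source.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .biomech import (
    ImpedanceModel,
    JointState,
    Trajectory,
    coriolis_vector,
    gravity_torque,
    inertia_matrix,
)
from .errors import InputError, ParameterError, UndefinedRatioError

__all__ = [
    "TorqueComponents",
    "ImpedanceSummary",
    "decompose_torques",
    "impedance_magnitude",
    "interaction_ratio",
    "elementwise_interaction_ratio",
    "summarize_impedance",
]

MATRIX_SOURCES = ("inertia", "damping", "stiffness")
SOURCES = MATRIX_SOURCES + ("gravity",)


@dataclass(frozen=True)
class TorqueComponents:
    """Per-sample torque split by source and by main/interaction part.

    ``main[source]`` and ``interaction[source]`` are (n, 3) arrays for the
    matrix sources; ``gravity`` is a single (n, 3) array outside the split.
    ``beta`` carries the flexion-extension angle per sample for the magnitude
    metric, and ``t`` the shared time grid.
    """

    t: np.ndarray
    beta: np.ndarray
    main: dict = field(default_factory=dict)
    interaction: dict = field(default_factory=dict)
    gravity: np.ndarray | None = None

    def total(self) -> np.ndarray:
        """Reconstructed full torque (n, 3): sum of all parts plus gravity."""
        out = np.zeros_like(self.gravity)
        for src in MATRIX_SOURCES:
            out = out + self.main[src] + self.interaction[src]
        return out + self.gravity


@dataclass(frozen=True)
class ImpedanceSummary:
    """Scalar coupling summary over one movement of duration ``T``."""

    Mj: dict          # per source incl. gravity, Nm
    R: float          # interaction / main ratio, dimensionless
    Rj: dict          # per matrix source, dimensionless
    T: float          # movement duration, s


def decompose_torques(
    model: ImpedanceModel,
    traj: Trajectory,
    coriolis_as: str = "interaction",
) -> TorqueComponents:
    """Split the inverse-dynamics torque into per-source main/interaction parts.

    Main torques use only the diagonal entries of M, B, K; interaction
    torques the off-diagonal entries.  ``coriolis_as`` routes the
    centripetal/Coriolis vector to ``'interaction'`` (default), ``'main'``
    or ``'excluded'``.
    """
    if coriolis_as not in ("interaction", "main", "excluded"):
        raise ParameterError(f"invalid coriolis_as {coriolis_as!r}")

    traj = traj.with_derivatives()
    p = model.inertial
    B = np.asarray(model.B)
    K = np.asarray(model.K)
    n = traj.n_samples

    main = {src: np.zeros((n, 3)) for src in MATRIX_SOURCES}
    inter = {src: np.zeros((n, 3)) for src in MATRIX_SOURCES}
    grav = np.zeros((n, 3))

    B_diag, B_off = np.diag(np.diag(B)), B - np.diag(np.diag(B))
    K_diag, K_off = np.diag(np.diag(K)), K - np.diag(np.diag(K))

    for i in range(n):
        state = JointState(traj.q[i], traj.qd[i], traj.qdd[i])
        M = inertia_matrix(p, state)
        M_diag = np.diag(np.diag(M))
        main["inertia"][i] = M_diag @ traj.qdd[i]
        inter["inertia"][i] = (M - M_diag) @ traj.qdd[i]
        cor = coriolis_vector(p, state)
        if coriolis_as == "interaction":
            inter["inertia"][i] += cor
        elif coriolis_as == "main":
            main["inertia"][i] += cor
        dq = traj.q[i] - model.rest_posture
        main["damping"][i] = B_diag @ traj.qd[i]
        inter["damping"][i] = B_off @ traj.qd[i]
        main["stiffness"][i] = K_diag @ dq
        inter["stiffness"][i] = K_off @ dq
        if model.gravity_enabled:
            grav[i] = gravity_torque(p, state)

    return TorqueComponents(
        t=traj.t, beta=traj.q[:, 1], main=main, interaction=inter, gravity=grav
    )


def _magnitude_series(tau: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Pointwise torque-vector magnitude under the sin(beta) cross-term metric.

    The integrand equals ``(Ma + Mg sin b)^2 + Mb^2 + Mg^2 cos^2 b`` and is
    therefore non-negative; clipping only guards rounding.
    """
    ta, tb, tg = tau[:, 0], tau[:, 1], tau[:, 2]
    val = ta**2 + tb**2 + tg**2 + 2 * ta * tg * np.sin(beta)
    return np.sqrt(np.clip(val, 0.0, None))


def _time_average(series: np.ndarray, t: np.ndarray) -> float:
    T = t[-1] - t[0]
    if T <= 0:
        raise InputError("movement duration must be positive")
    return float(np.trapezoid(series, t) / T)


def impedance_magnitude(
    components: TorqueComponents, source: str, traj: Trajectory | None = None
) -> float:
    """Time-averaged magnitude Mj of the full torque from one source, Nm."""
    if source == "gravity":
        tau = components.gravity
    elif source in MATRIX_SOURCES:
        tau = components.main[source] + components.interaction[source]
    else:
        raise ParameterError(f"unknown source {source!r}")
    mag = _magnitude_series(tau, components.beta)
    return _time_average(mag, components.t)


def _part_magnitude(components: TorqueComponents, part: dict,
                    sources=MATRIX_SOURCES) -> float:
    tau = sum(part[src] for src in sources)
    return _time_average(_magnitude_series(tau, components.beta), components.t)


def interaction_ratio(components: TorqueComponents,
                      traj: Trajectory | None = None) -> float:
    """Coupling ratio R = averaged interaction magnitude / main magnitude.

    Both magnitudes use the cross-term metric; gravity is excluded from both.
    """
    denom = _part_magnitude(components, components.main)
    if denom <= 0:
        raise UndefinedRatioError("main-torque magnitude is zero; R undefined")
    return _part_magnitude(components, components.interaction) / denom


def elementwise_interaction_ratio(
    components: TorqueComponents, source: str, traj: Trajectory | None = None
) -> float:
    """Per-source coupling ratio Rj for j in {inertia, damping, stiffness}."""
    if source == "gravity":
        raise ParameterError("gravity has no main/interaction split; Rj undefined")
    if source not in MATRIX_SOURCES:
        raise ParameterError(f"unknown source {source!r}")
    denom = _part_magnitude(components, components.main, (source,))
    if denom <= 0:
        raise UndefinedRatioError(
            f"main-torque magnitude for {source} is zero; Rj undefined"
        )
    return _part_magnitude(components, components.interaction, (source,)) / denom


def summarize_impedance(
    model: ImpedanceModel, traj: Trajectory, coriolis_as: str = "interaction"
) -> ImpedanceSummary:
    """Full coupling summary: Mj per source (incl. gravity), R, Rj."""
    comps = decompose_torques(model, traj, coriolis_as=coriolis_as)
    Mj = {src: impedance_magnitude(comps, src) for src in SOURCES}
    try:
        R = interaction_ratio(comps)
    except UndefinedRatioError:
        R = float("nan")  # torque-free movement: the ratio has no meaning
    Rj = {}
    for src in MATRIX_SOURCES:
        try:
            Rj[src] = elementwise_interaction_ratio(comps, src)
        except UndefinedRatioError:
            Rj[src] = float("nan")
    return ImpedanceSummary(Mj=Mj, R=R, Rj=Rj, T=float(traj.t[-1] - traj.t[0]))
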