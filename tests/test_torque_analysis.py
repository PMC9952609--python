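"""Torque decomposition and coupling-ratio tests against brute-force oracles."""

import numpy as np
import pytest

from wristdyn.biomech import (
    DampingMatrix,
    ImpedanceModel,
    InertialParameters,
    StiffnessMatrix,
    Trajectory,
    inverse_dynamics,
)
from wristdyn.errors import ParameterError, UndefinedRatioError
from wristdyn.torque_analysis import (
    MATRIX_SOURCES,
    TorqueComponents,
    decompose_torques,
    elementwise_interaction_ratio,
    impedance_magnitude,
    interaction_ratio,
    summarize_impedance,
)


def brute_force_magnitude(tau, beta, t):
    """Independent dense-grid quadrature of the cross-term magnitude metric."""
    integrand = np.sqrt(
        tau[:, 0] ** 2
        + tau[:, 1] ** 2
        + tau[:, 2] ** 2
        + 2 * tau[:, 0] * tau[:, 2] * np.sin(beta)
    )
    total = 0.0
    for i in range(len(t) - 1):
        total += 0.5 * (integrand[i] + integrand[i + 1]) * (t[i + 1] - t[i])
    return total / (t[-1] - t[0])


def make_components(t, beta, main, inter, gravity=None):
    n = len(t)
    zeros = np.zeros((n, 3))
    return TorqueComponents(
        t=np.asarray(t, float),
        beta=np.asarray(beta, float),
        main={s: main.get(s, zeros.copy()) for s in MATRIX_SOURCES},
        interaction={s: inter.get(s, zeros.copy()) for s in MATRIX_SOURCES},
        gravity=gravity if gravity is not None else zeros.copy(),
    )


def rich_trajectory(n=1200, T=3.0):
    t = np.linspace(0, T, n)
    q = np.stack(
        [
            0.5 * np.sin(2 * np.pi * 0.4 * t),
            0.4 * np.sin(2 * np.pi * 0.55 * t + 0.3),
            0.3 * np.sin(2 * np.pi * 0.7 * t + 1.1),
        ],
        axis=1,
    )
    return Trajectory(t, q).with_derivatives()


@pytest.fixture
def coupled_model():
    K = StiffnessMatrix([[3.0, 0.5, 0.2], [0.5, 2.0, 0.1], [0.2, 0.1, 1.5]])
    B = DampingMatrix(0.01 * np.asarray(K))
    p = InertialParameters(0.003, 0.0008, 0.0025, 0.0015, m=0.45, l=0.07)
    return ImpedanceModel(inertial=p, B=B, K=K, gravity_enabled=True)


class TestDecomposition:
    def test_reconstructs_full_inverse_dynamics(self, coupled_model):
        traj = rich_trajectory()
        comps = decompose_torques(coupled_model, traj)
        np.testing.assert_allclose(
            comps.total(), inverse_dynamics(coupled_model, traj), atol=1e-9
        )

    @pytest.mark.parametrize("coriolis_as", ["interaction", "main", "excluded"])
    def test_reconstruction_up_to_coriolis_routing(self, coupled_model, coriolis_as):
        traj = rich_trajectory(n=400, T=1.0)
        comps = decompose_torques(coupled_model, traj, coriolis_as=coriolis_as)
        total = comps.total()
        full = inverse_dynamics(coupled_model, traj)
        if coriolis_as == "excluded":
            from wristdyn.biomech import JointState, coriolis_vector

            cor = np.array(
                [
                    coriolis_vector(coupled_model.inertial, s)
                    for s in traj.states()
                ]
            )
            np.testing.assert_allclose(total + cor, full, atol=1e-9)
        else:
            np.testing.assert_allclose(total, full, atol=1e-9)

    def test_planar_uncoupled_motion_has_no_interaction(self, coupled_model):
        # diagonal-only model and motion confined to beta = gamma = 0
        K = StiffnessMatrix(np.diag([3.0, 2.0, 1.5]))
        model = ImpedanceModel(
            inertial=coupled_model.inertial,
            B=DampingMatrix(np.diag([0.03, 0.02, 0.015])),
            K=K,
            gravity_enabled=False,
        )
        t = np.linspace(0, 2, 500)
        q = np.zeros((500, 3))
        q[:, 0] = 0.5 * np.sin(2 * np.pi * t)
        comps = decompose_torques(model, Trajectory(t, q))
        for src in MATRIX_SOURCES:
            np.testing.assert_allclose(comps.interaction[src], 0.0, atol=1e-12)
        assert interaction_ratio(comps) == pytest.approx(0.0, abs=1e-12)
        for src in MATRIX_SOURCES:
            assert elementwise_interaction_ratio(comps, src) == pytest.approx(0.0, abs=1e-12)

    def test_offdiagonal_stiffness_static_posture(self):
        # K with only off-diagonal terms, static displaced posture
        K = StiffnessMatrix([[0, 0.5, 0.2], [0.5, 0, 0.1], [0.2, 0.1, 0]])
        model = ImpedanceModel(
            inertial=InertialParameters(0.01, 0.01, 0.01, 0.01),
            B=DampingMatrix(np.zeros((3, 3))),
            K=K,
            gravity_enabled=False,
        )
        q0 = np.array([0.3, -0.2, 0.1])
        t = np.linspace(0, 1, 100)
        traj = Trajectory(t, np.tile(q0, (100, 1)),
                          np.zeros((100, 3)), np.zeros((100, 3)))
        comps = decompose_torques(model, traj)
        np.testing.assert_allclose(comps.main["stiffness"], 0.0, atol=1e-14)
        expected = np.asarray(K) @ q0
        np.testing.assert_allclose(comps.interaction["stiffness"][0], expected, atol=1e-12)

    def test_invalid_coriolis_routing_rejected(self, coupled_model):
        with pytest.raises(ParameterError):
            decompose_torques(coupled_model, rich_trajectory(100, 1.0), coriolis_as="no")


class TestMagnitude:
    def test_zero_torque_zero_magnitude(self):
        t = np.linspace(0, 1, 50)
        comps = make_components(t, np.zeros(50), {}, {})
        assert impedance_magnitude(comps, "stiffness") == 0.0

    def test_constant_unit_alpha_torque(self):
        t = np.linspace(0, 2, 100)
        tau = np.zeros((100, 3))
        tau[:, 0] = 1.0
        comps = make_components(t, np.sin(3 * t), {"inertia": tau}, {})
        assert impedance_magnitude(comps, "inertia") == pytest.approx(1.0, abs=1e-12)

    def test_colinear_axes_cross_term(self):
        # constant (1, 0, 1) with beta = pi/2: integrand sqrt(1+1+2) = 2
        t = np.linspace(0, 1, 80)
        tau = np.zeros((80, 3))
        tau[:, 0] = 1.0
        tau[:, 2] = 1.0
        comps = make_components(t, np.full(80, np.pi / 2), {"damping": tau}, {})
        assert impedance_magnitude(comps, "damping") == pytest.approx(2.0, abs=1e-12)

    def test_matches_brute_force_on_random_fixture(self, coupled_model):
        traj = rich_trajectory(n=1500, T=3.0)
        comps = decompose_torques(coupled_model, traj)
        for src in MATRIX_SOURCES + ("gravity",):
            if src == "gravity":
                tau = comps.gravity
            else:
                tau = comps.main[src] + comps.interaction[src]
            expected = brute_force_magnitude(tau, comps.beta, comps.t)
            got = impedance_magnitude(comps, src)
            assert got == pytest.approx(expected, rel=1e-3)


class TestRatios:
    def test_zero_interaction_gives_zero_ratio(self):
        t = np.linspace(0, 1, 60)
        tau = np.zeros((60, 3))
        tau[:, 0] = 0.5
        comps = make_components(t, np.zeros(60), {"stiffness": tau}, {})
        assert interaction_ratio(comps) == 0.0
        assert elementwise_interaction_ratio(comps, "stiffness") == 0.0

    def test_scale_invariance(self, coupled_model):
        traj = rich_trajectory(n=600, T=2.0)
        comps = decompose_torques(coupled_model, traj)
        R = interaction_ratio(comps)
        scaled = TorqueComponents(
            t=comps.t,
            beta=comps.beta,
            main={s: 3.7 * v for s, v in comps.main.items()},
            interaction={s: 3.7 * v for s, v in comps.interaction.items()},
            gravity=3.7 * comps.gravity,
        )
        assert interaction_ratio(scaled) == pytest.approx(R, rel=1e-12)

    def test_time_reparameterization_invariance(self, coupled_model):
        # same sampled torque path on a uniformly stretched time grid
        traj = rich_trajectory(n=800, T=2.0)
        comps = decompose_torques(coupled_model, traj)
        stretched = TorqueComponents(
            t=comps.t * 4.0,
            beta=comps.beta,
            main=comps.main,
            interaction=comps.interaction,
            gravity=comps.gravity,
        )
        assert interaction_ratio(stretched) == pytest.approx(
            interaction_ratio(comps), rel=1e-12
        )

    def test_matches_brute_force_ratio(self, coupled_model):
        traj = rich_trajectory(n=1500, T=3.0)
        comps = decompose_torques(coupled_model, traj)
        main = sum(comps.main[s] for s in MATRIX_SOURCES)
        inter = sum(comps.interaction[s] for s in MATRIX_SOURCES)
        expected = brute_force_magnitude(inter, comps.beta, comps.t) / brute_force_magnitude(
            main, comps.beta, comps.t
        )
        assert interaction_ratio(comps) == pytest.approx(expected, rel=1e-3)
        for src in MATRIX_SOURCES:
            expected_j = brute_force_magnitude(
                comps.interaction[src], comps.beta, comps.t
            ) / brute_force_magnitude(comps.main[src], comps.beta, comps.t)
            assert elementwise_interaction_ratio(comps, src) == pytest.approx(
                expected_j, rel=1e-3
            )

    def test_gravity_is_not_a_ratio_source(self, coupled_model):
        comps = decompose_torques(coupled_model, rich_trajectory(200, 1.0))
        with pytest.raises(ParameterError):
            elementwise_interaction_ratio(comps, "gravity")

    def test_summary_bundles_everything(self, coupled_model):
        traj = rich_trajectory(n=500, T=2.0)
        s = summarize_impedance(coupled_model, traj)
        assert set(s.Mj) == {"inertia", "damping", "stiffness", "gravity"}
        assert set(s.Rj) == {"inertia", "damping", "stiffness"}
        assert s.R >= 0 and all(v >= 0 for v in s.Mj.values())
        assert s.T == pytest.approx(traj.duration)
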