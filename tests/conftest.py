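import numpy as np
import pytest

from wristdyn.biomech import (
    DampingMatrix,
    ImpedanceModel,
    InertialParameters,
    StiffnessMatrix,
)
from wristdyn.identification import scale_damping

K_REF = np.array([[3.0, 0.5, 0.2], [0.5, 2.0, 0.1], [0.2, 0.1, 1.5]])


@pytest.fixture
def reference_stiffness():
    return StiffnessMatrix(K_REF)


@pytest.fixture
def hand_inertia():
    """Physiologically plausible hand/forearm inertial parameters."""
    return InertialParameters(IHx=0.003, IHy=0.0008, IHz=0.0025, IAy=0.0015,
                              m=0.45, l=0.07)


@pytest.fixture
def reference_model(hand_inertia, reference_stiffness):
    return ImpedanceModel(
        inertial=hand_inertia,
        B=scale_damping(reference_stiffness),
        K=reference_stiffness,
        gravity_enabled=False,
    )


@pytest.fixture
def undamped_model(hand_inertia):
    zeros = np.zeros((3, 3))
    return ImpedanceModel(
        inertial=hand_inertia,
        B=DampingMatrix(zeros),
        K=StiffnessMatrix(zeros),
        gravity_enabled=False,
    )


def random_inertial(rng):
    return InertialParameters(*rng.uniform(0.01, 2.0, size=4))
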