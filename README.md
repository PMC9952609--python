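# wristdyn

Computational toolkit for robot-assisted wrist–forearm rehabilitation:
a 3-DOF mechanical-impedance model of coupled wrist and forearm rotations,
torque decomposition statistics, passive-parameter identification,
surface-EMG muscle-fatigue estimation, and a three-stage rehabilitation
protocol with a quantitative progress score. It is aimed at researchers in
rehabilitation biomechanics and biomedical signal processing who need a
tested, scriptable reference implementation of this computation stack, with
seeded synthetic-data generators so everything runs without recorded data.

## The models

**Impedance dynamics.** The wrist–forearm complex is a universal joint with
angles q = (α, β, γ): forearm pronation–supination, wrist
flexion–extension, and radial–ulnar deviation. The joint torque balance is

    τ_active = M(q) q̈ + C(q, q̇) q̇ + B q̇ + K (q − q_rest) + g(q)

where M(q) is the configuration-dependent inertia matrix built from the
hand's principal moments (IHx, IHy, IHz) and the forearm's longitudinal
moment IAy, C collects the centripetal/Coriolis terms (implemented via
Christoffel symbols and cross-checked against a closed-form expansion),
B and K are the 3×3 passive damping and stiffness matrices, and g(q) is the
gravity torque of the hand treated as a point mass m at distance l from the
wrist. `wristdyn.biomech` provides the matrix builders, inverse dynamics,
and fixed-step 4th-order forward integration.

**Coupling statistics.** Torque in each DOF splits into a *main* part
(diagonal matrix entries) and an *interaction* part (off-diagonal entries).
Per impedance source j the time-averaged vector magnitude

    Mj = (1/T) ∫ √(Mαj² + Mβj² + Mγj² + 2 Mαj Mγj sin β) dt

and the interaction-to-main ratios R and Rj quantify how strongly the DOFs
are coupled (`wristdyn.torque_analysis`).

**Identification.** Passive stiffness is fitted from quasi-static
displacement–torque records by multivariable linear regression τ = K q with
off-diagonal symmetry enforced (6 free parameters); damping is scaled
proportionally to stiffness with the flexion–extension diagonal pinned at
0.03 Nms/rad (`wristdyn.identification`).

**EMG fatigue pipeline.** Raw sEMG is band-pass (2nd-order Butterworth,
10–2000 Hz) and 50 Hz notch filtered, cut into 2 s mid-term windows with
1 s step, and summarized per window by mean frequency MNF = Σfj·Pj / ΣPj,
mean power MNP = ΣPj / M, and median frequency (`wristdyn.emg`). A
standardized RBF-kernel SVM classifies windows as fatigue/nonfatigue and
maps detections to a torque decrement for the controller
(`wristdyn.fatigue`).

**Protocol and scoring.** The three-stage protocol (passive extraction →
active extraction → continuous fatigue-adjusted exercises) is orchestrated
by `wristdyn.protocol`, which also computes the Rehabilitation Progress
Factor

    RPF = current RoM / theoretical RoM × 10

displayed truncated to one decimal, and writes the per-subject evaluation
report as JSON. `wristdyn.kinematics` adds the exoskeleton's modified-DH
forward kinematics, joint limits, and movement-mode joint locking;
`wristdyn.synthetic` generates all the data the stack consumes.

## Worked example

```python
import numpy as np
from wristdyn import (ImpedanceModel, InertialParameters, StiffnessMatrix,
                      Trajectory, MovementType, compute_rpf)
from wristdyn.identification import scale_damping
from wristdyn.torque_analysis import summarize_impedance

K = StiffnessMatrix([[3.0, 0.5, 0.2], [0.5, 2.0, 0.1], [0.2, 0.1, 1.5]])
model = ImpedanceModel(
    inertial=InertialParameters(IHx=0.003, IHy=0.0008, IHz=0.0025,
                                IAy=0.0015, m=0.45, l=0.07),
    B=scale_damping(K),   # B = c·K with B_FE pinned to 0.03 Nms/rad
    K=K,
)
t = np.linspace(0, 3, 1500)
q = np.stack([0.5 * np.sin(2 * np.pi * 0.4 * t),
              0.4 * np.sin(2 * np.pi * 0.55 * t + 0.3),
              0.3 * np.sin(2 * np.pi * 0.7 * t + 1.1)], axis=1)
s = summarize_impedance(model, Trajectory(t, q))
print({k: round(v, 4) for k, v in s.Mj.items()})
print(round(s.R, 4), {k: round(v, 4) for k, v in s.Rj.items()})
print(compute_rpf(66.0, MovementType.pronation_supination).display)
```

prints

```
{'inertia': 0.0186, 'damping': 0.0516, 'stiffness': 1.1942, 'gravity': 0.3261}
0.1877 {'inertia': 0.3866, 'damping': 0.1795, 'stiffness': 0.1859}
7.3
```

Stiffness dominates the passive impedance of this movement (M_stiffness ≈
1.19 Nm vs 0.02 Nm for inertia); about 19 % of the torque magnitude comes
from inter-DOF coupling (R ≈ 0.19), with inertia the most strongly coupled
source (R_inertia ≈ 0.39). A final pronation–supination range of 66° scores
RPF 7.3 out of 10 against the 90° scoring range.

The same operations are available from the shell, e.g.:

```
wristdyn simulate --model model.yaml --torque torque.csv --duration 10 --out traj.csv
wristdyn analyze  --model model.yaml --traj traj.csv --out summary.json
wristdyn identify --session round1.csv --session round2.csv --out passive.json
wristdyn emg-features --in emg.csv --out features.csv
wristdyn protocol --seed 1 --out report.json
```

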