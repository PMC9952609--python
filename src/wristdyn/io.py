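"""File formats: trajectory/quasi-static/EMG CSV, model YAML/JSON.

Trajectory CSV: header ``t,alpha,beta,gamma[,dalpha,...[,ddalpha,...]]``,
SI units.  Model documents carry ``inertial``, ``stiffness`` (9 values,
symmetry validated), ``damping`` (9 values or ``proportional: {b_fe: ...}``)
and ``gravity_enabled``.  EMG CSV has a ``t`` column plus one ``ch_<name>``
column per channel with a JSON sidecar ``{"fs": ..., "gain": ..., "units": ...}``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .biomech import (
    DampingMatrix,
    ImpedanceModel,
    InertialParameters,
    StiffnessMatrix,
    Trajectory,
)
from .emg import EMGRecording
from .errors import InputError, ParameterError
from .identification import QuasiStaticRecord, scale_damping

__all__ = [
    "read_trajectory_csv",
    "write_trajectory_csv",
    "read_model",
    "read_quasistatic_csv",
    "write_quasistatic_csv",
    "read_emg_csv",
    "write_emg_csv",
    "read_torque_csv",
    "write_torque_csv",
]

_ANGLES = ["alpha", "beta", "gamma"]
_VEL = ["dalpha", "dbeta", "dgamma"]
_ACC = ["ddalpha", "ddbeta", "ddgamma"]


def read_trajectory_csv(path) -> Trajectory:
    df = pd.read_csv(path)
    missing = [c for c in ["t", *_ANGLES] if c not in df.columns]
    if missing:
        raise InputError(f"trajectory CSV missing columns: {missing}")
    qd = df[_VEL].to_numpy() if all(c in df.columns for c in _VEL) else None
    qdd = df[_ACC].to_numpy() if all(c in df.columns for c in _ACC) else None
    return Trajectory(df["t"].to_numpy(), df[_ANGLES].to_numpy(), qd, qdd)


def write_trajectory_csv(traj: Trajectory, path) -> None:
    data = {"t": traj.t}
    data.update(dict(zip(_ANGLES, traj.q.T)))
    if traj.qd is not None:
        data.update(dict(zip(_VEL, traj.qd.T)))
    if traj.qdd is not None:
        data.update(dict(zip(_ACC, traj.qdd.T)))
    pd.DataFrame(data).to_csv(path, index=False)


def read_torque_csv(path) -> np.ndarray:
    df = pd.read_csv(path)
    cols = ["tau_alpha", "tau_beta", "tau_gamma"]
    if not all(c in df.columns for c in cols):
        raise InputError(f"torque CSV must contain columns {cols}")
    return df[cols].to_numpy()


def write_torque_csv(t: np.ndarray, tau: np.ndarray, path) -> None:
    pd.DataFrame(
        {
            "t": t,
            "tau_alpha": tau[:, 0],
            "tau_beta": tau[:, 1],
            "tau_gamma": tau[:, 2],
        }
    ).to_csv(path, index=False)


def read_model(path) -> ImpedanceModel:
    """Load an impedance model from a YAML or JSON document."""
    text = Path(path).read_text()
    doc = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    try:
        inertial = InertialParameters(**doc["inertial"])
        K = StiffnessMatrix(np.asarray(doc["stiffness"], dtype=float).reshape(3, 3))
        damping = doc["damping"]
        if isinstance(damping, dict) and "proportional" in damping:
            B = scale_damping(K, **damping["proportional"])
        else:
            B = DampingMatrix(np.asarray(damping, dtype=float).reshape(3, 3))
    except KeyError as exc:
        raise InputError(f"model document missing key: {exc}") from exc
    except (TypeError, ValueError) as exc:
        raise ParameterError(f"invalid model document: {exc}") from exc
    return ImpedanceModel(
        inertial=inertial,
        B=B,
        K=K,
        rest_posture=np.asarray(doc.get("rest_posture", [0, 0, 0]), dtype=float),
        gravity_enabled=bool(doc.get("gravity_enabled", True)),
    )


def read_quasistatic_csv(path) -> QuasiStaticRecord:
    df = pd.read_csv(path)
    cols = ["alpha", "beta", "gamma", "tau_alpha", "tau_beta", "tau_gamma"]
    if not all(c in df.columns for c in cols):
        raise InputError(f"quasi-static CSV must contain columns {cols}")
    return QuasiStaticRecord(
        displacements=df[cols[:3]].to_numpy(), torques=df[cols[3:]].to_numpy()
    )


def write_quasistatic_csv(record: QuasiStaticRecord, path) -> None:
    pd.DataFrame(
        np.hstack([record.displacements, record.torques]),
        columns=["alpha", "beta", "gamma", "tau_alpha", "tau_beta", "tau_gamma"],
    ).to_csv(path, index=False)


def read_emg_csv(path, sidecar=None) -> EMGRecording:
    """Read an EMG CSV plus its JSON sidecar (default ``<path>.json``)."""
    df = pd.read_csv(path)
    sidecar = Path(sidecar) if sidecar else Path(str(path) + ".json")
    if not sidecar.exists():
        raise InputError(f"EMG sidecar not found: {sidecar}")
    meta = json.loads(sidecar.read_text())
    chan_cols = [c for c in df.columns if c.startswith("ch_")]
    if not chan_cols:
        raise InputError("EMG CSV has no ch_* channel columns")
    channels = {c[3:]: df[c].to_numpy() for c in chan_cols}
    return EMGRecording(fs=float(meta["fs"]), channels=channels, meta=meta)


def write_emg_csv(rec: EMGRecording, path, sidecar=None) -> None:
    n = rec.n_samples
    data = {"t": np.arange(n) / rec.fs}
    for name, x in rec.channels.items():
        data[f"ch_{name}"] = x
    pd.DataFrame(data).to_csv(path, index=False)
    sidecar = Path(sidecar) if sidecar else Path(str(path) + ".json")
    meta = {"fs": rec.fs, "units": "uV"}
    meta.update({k: v for k, v in rec.meta.items() if isinstance(v, (int, float, str))})
    sidecar.write_text(json.dumps(meta, indent=1))
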