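"""Synthetic fixtures: sEMG, impedance subjects, identification and protocol data.

Every generator here is a pure function of its parameters and a seed, so the
full pipeline is testable without any recorded data.

The sEMG generator shapes Gaussian noise with the classic two-corner
band-form power spectrum

    P(f) ~ f^2 fh^2 / ((f^2 + fl^2) (f^2 + fh^2)^2)

whose characteristic frequencies sit in the physiological 60-120 Hz band.
Muscle fatigue compresses the spectrum toward lower frequencies (corner
frequencies scaled down by ``fatigue_shift``) and raises the amplitude
(slower, larger motor-unit action potentials), so the mean frequency drops
and the pipeline's MNF/MNP features separate the two states — the
qualitative behaviour of fatigued surface EMG.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .biomech import StiffnessMatrix, Trajectory
from .emg import EMGRecording, WindowSpec, extract_feature_table, filter_emg
from .errors import ParameterError
from .fatigue import FATIGUE, NONFATIGUE
from .identification import QuasiStaticRecord
from .protocol import DaySession, MovementType, ProtocolConfig, SubjectStream

__all__ = [
    "EMGSpectrumParams",
    "SimulatedSubject",
    "emg_power_shape",
    "generate_emg",
    "generate_fatigue_dataset",
    "generate_quasistatic_dataset",
    "generate_protocol_stream",
]

DEFAULT_FS = 10_000.0


@dataclass(frozen=True)
class EMGSpectrumParams:
    """Parametric sEMG spectrum with a downward fatigue shift.

    ``amplitude`` is the RMS scale in microvolts; ``fatigue_shift`` the
    fractional reduction of both corner frequencies under fatigue;
    ``fatigue_amplitude_gain`` the RMS gain under fatigue (below 1, so the
    mean power drops alongside the mean frequency and both features sit
    higher in the fresh state); ``noise_floor`` a flat spectral floor
    relative to the peak; ``mains_amplitude`` an optional 50 Hz
    interference component (microvolts) for filter tests.
    """

    f_low: float = 60.0
    f_high: float = 120.0
    amplitude: float = 100.0
    fatigue_shift: float = 0.35
    fatigue_amplitude_gain: float = 0.8
    noise_floor: float = 1e-4
    mains_amplitude: float = 0.0

    def __post_init__(self):
        if not 0 < self.f_low < self.f_high:
            raise ParameterError("need 0 < f_low < f_high")
        if not 0 <= self.fatigue_shift < 1:
            raise ParameterError("fatigue_shift must lie in [0, 1)")
        if self.amplitude <= 0:
            raise ParameterError("amplitude must be positive")


def emg_power_shape(f: np.ndarray, f_low: float, f_high: float) -> np.ndarray:
    """Unnormalized band-form sEMG power spectrum shape."""
    f = np.asarray(f, dtype=float)
    return f**2 * f_high**2 / ((f**2 + f_low**2) * (f**2 + f_high**2) ** 2)


def generate_emg(
    params: EMGSpectrumParams,
    fs: float = DEFAULT_FS,
    duration: float = 5.0,
    state: int = NONFATIGUE,
    seed: int = 0,
    channels: tuple = ("FCU", "BR"),
) -> EMGRecording:
    """Seeded multichannel sEMG realization of the parametric spectrum.

    ``state`` is 0 (nonfatigue) or 1 (fatigue); fatigue applies the corner
    shift and the amplitude gain.  Channels carry independent noise drawn
    from one seeded generator, so the whole recording is reproducible.
    """
    f_low, f_high = params.f_low, params.f_high
    amplitude = params.amplitude
    if int(state) == FATIGUE:
        f_low *= 1.0 - params.fatigue_shift
        f_high *= 1.0 - params.fatigue_shift
        amplitude *= params.fatigue_amplitude_gain
    if f_high >= fs / 2:
        raise ParameterError(
            f"corner frequency {f_high} Hz must be below Nyquist ({fs / 2} Hz)"
        )

    n = int(round(fs * duration))
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = emg_power_shape(freqs, f_low, f_high)
    shape = shape + params.noise_floor * shape.max()
    gain = np.sqrt(shape)

    out = {}
    t = np.arange(n) / fs
    for name in channels:
        white = rng.standard_normal(n)
        x = np.fft.irfft(np.fft.rfft(white) * gain, n=n)
        rms = np.sqrt(np.mean(x**2))
        x = x * (amplitude / rms)
        if params.mains_amplitude > 0:
            x = x + params.mains_amplitude * np.sin(2 * np.pi * 50.0 * t)
        out[name] = x
    return EMGRecording(fs=fs, channels=out, meta={"state": int(state), "seed": seed})


def generate_fatigue_dataset(
    n_subjects: int = 57,
    windows_per_subject: int = 4,
    params: EMGSpectrumParams = EMGSpectrumParams(),
    fs: float = DEFAULT_FS,
    seed: int = 0,
    subject_sigma: float = 0.1,
    window_spec: WindowSpec = WindowSpec(),
) -> pd.DataFrame:
    """Grouped (MNF, MNP) feature dataset over simulated subjects.

    Each subject receives log-normal multipliers (sigma ``subject_sigma``)
    on the corner frequencies and amplitude — the between-subject
    variability — then contributes ``windows_per_subject`` mid-term windows
    per fatigue state, extracted through the real EMG pipeline (filtering
    included).  Labels are balanced by construction.

    Returns a DataFrame with columns ``subject, label, mnf_hz, mnp``.
    """
    if n_subjects < 2:
        raise ParameterError("need at least 2 subjects for grouped splitting")
    rng = np.random.default_rng(seed)
    duration = windows_per_subject + window_spec.mid_len - window_spec.mid_step
    rows = []
    for subject in range(n_subjects):
        mult_fl, mult_fh, mult_amp = np.exp(subject_sigma * rng.standard_normal(3))
        subj_params = replace(
            params,
            f_low=params.f_low * mult_fl,
            f_high=params.f_high * mult_fh,
            amplitude=params.amplitude * mult_amp,
        )
        for state in (NONFATIGUE, FATIGUE):
            rec_seed = int(rng.integers(0, 2**31 - 1))
            rec = generate_emg(
                subj_params, fs=fs, duration=duration, state=state,
                seed=rec_seed, channels=("FCU",),
            )
            feats = extract_feature_table(filter_emg(rec), window_spec)
            for _, row in feats.iterrows():
                rows.append(
                    {
                        "subject": subject,
                        "label": state,
                        "mnf_hz": row["mnf_hz"],
                        "mnp": row["mnp"],
                    }
                )
    return pd.DataFrame(rows)


def generate_quasistatic_dataset(
    K_true,
    noise_sd: float = 0.0,
    n_points: int = 50,
    seed: int = 0,
    max_disp: float = 0.2,
    movement_type: str | None = None,
) -> QuasiStaticRecord:
    """Noisy quasi-static torque-displacement record from a known stiffness.

    Displacements are uniform in ``[-max_disp, max_disp]`` rad per axis;
    torques are ``K_true @ q`` plus Gaussian noise of standard deviation
    ``noise_sd`` Nm.
    """
    K = np.asarray(StiffnessMatrix(np.asarray(K_true, dtype=float)))
    rng = np.random.default_rng(seed)
    q = rng.uniform(-max_disp, max_disp, size=(n_points, 3))
    tau = q @ K.T
    if noise_sd > 0:
        tau = tau + rng.normal(0.0, noise_sd, size=tau.shape)
    return QuasiStaticRecord(displacements=q, torques=tau, movement_type=movement_type)


# ---------------------------------------------------------------------------
# protocol-session streams
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulatedSubject:
    """Ground-truth subject for protocol simulations.

    Capability interpolates linearly from the initial to the final value
    across exercise days: ``rom`` ceilings in degrees, active-torque
    ceilings in Nm, and a multiplicative end-of-protocol scale on the
    passive stiffness (below 1 for an improving subject).
    """

    subject_id: str = "sim-01"
    K_true: np.ndarray = None
    rom_initial: float = 54.0
    rom_final: float = 84.0
    torque_initial: float = 0.5
    torque_final: float = 0.8
    stiffness_final_scale: float = 0.4
    emg_params: EMGSpectrumParams = EMGSpectrumParams()
    seed: int = 0

    def __post_init__(self):
        K = self.K_true
        if K is None:
            K = np.array([[2.0, 0.3, 0.1], [0.3, 3.0, 0.2], [0.1, 0.2, 1.5]])
        object.__setattr__(self, "K_true", np.asarray(K, dtype=float))


def _exercise_trajectory(rom_deg: float, axis: int, duration: float = 10.0,
                         fs: float = 100.0) -> Trajectory:
    """Sinusoidal single-axis sweep covering ``rom_deg`` peak-to-peak."""
    t = np.arange(int(duration * fs)) / fs
    amp = np.radians(rom_deg) / 2.0
    q = np.zeros((t.size, 3))
    q[:, axis] = amp * np.sin(2 * np.pi * 0.25 * t)
    return Trajectory(t, q)


def generate_protocol_stream(
    subject: SimulatedSubject,
    config: ProtocolConfig = ProtocolConfig(),
    movement: MovementType = MovementType.pronation_supination,
    rest_days: tuple = (5,),
    emg_duration: float = 3.0,
    emg_fs: float = 2000.0,
) -> SubjectStream:
    """Per-day stage inputs for a simulated protocol run.

    Emits three stage-1 quasi-static rounds with shrinking noise, then one
    exercise day per protocol day (rest days carry no stage-3 stream).
    Within each day the EMG starts fresh and ends fatigued; across days the
    RoM and active-torque ceilings rise while the passive stiffness falls —
    monotone ground truth for protocol-level tests.
    """
    rng = np.random.default_rng(subject.seed)
    axis = movement.axis

    rounds = [
        generate_quasistatic_dataset(
            subject.K_true, noise_sd=sd, n_points=60,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        for sd in (0.02, 0.01, 0.005)
    ]

    exercise_days = [d for d in range(config.n_days) if d not in rest_days]
    n_ex = max(len(exercise_days) - 1, 1)
    days = []
    for d in range(config.n_days):
        if d in rest_days:
            days.append(DaySession(day=d, rest=True))
            continue
        frac = exercise_days.index(d) / n_ex
        rom_d = subject.rom_initial + frac * (subject.rom_final - subject.rom_initial)
        tau_d = subject.torque_initial + frac * (subject.torque_final - subject.torque_initial)
        k_scale = 1.0 + frac * (subject.stiffness_final_scale - 1.0)

        traj = _exercise_trajectory(rom_d, axis)
        torque = np.zeros((traj.n_samples, 3))
        torque[:, axis] = tau_d * np.sin(2 * np.pi * 0.25 * traj.t)

        qs = generate_quasistatic_dataset(
            k_scale * subject.K_true, noise_sd=0.005, n_points=60,
            seed=int(rng.integers(0, 2**31 - 1)),
        )

        half = emg_duration
        fresh = generate_emg(
            subject.emg_params, fs=emg_fs, duration=half, state=NONFATIGUE,
            seed=int(rng.integers(0, 2**31 - 1)), channels=("FCU",),
        )
        tired = generate_emg(
            subject.emg_params, fs=emg_fs, duration=half, state=FATIGUE,
            seed=int(rng.integers(0, 2**31 - 1)), channels=("FCU",),
        )
        emg = EMGRecording(
            fs=emg_fs,
            channels={"FCU": np.concatenate([fresh.channels["FCU"], tired.channels["FCU"]])},
            meta={"day": d},
        )

        days.append(
            DaySession(
                day=d,
                quasistatic=qs,
                trajectory=traj,
                patient_torque=torque,
                emg=emg,
            )
        )

    return SubjectStream(
        subject_id=subject.subject_id,
        quasistatic_rounds=rounds,
        days=days,
        movement=movement,
    )
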