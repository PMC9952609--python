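"""Three-stage rehabilitation protocol orchestration and progress scoring.

Stage 1 identifies the subject's passive impedance (stiffness and damping)
from quasi-static rounds; stage 2 measures the active capability (peak
voluntary torque and achieved range of motion) against a resistive robot,
and is skipped for subjects unable to deliver a minimal legible torque;
stage 3 runs the continuous exercises, per exercise estimating fatigue from
EMG, converting it to a torque decrement, and logging the fatigue-adjusted
resultant torque alongside RoM and passive/active torque series.

Progress is scored with the Rehabilitation Progress Factor

    RPF = current RoM / theoretical RoM * 10

where the theoretical RoM is the healthy range for the selected movement.
The displayed score is truncated toward zero at one decimal; the raw value
is preserved.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

from .biomech import AXIS_INDEX, Trajectory
from .emg import EMGRecording, WindowSpec, extract_feature_table, filter_emg
from .errors import InputError, ParameterError
from .fatigue import FATIGUE, FatigueModel, estimate_fatigue_torque, predict_fatigue
from .identification import (
    ActiveComponents,
    PassiveComponents,
    QuasiStaticRecord,
    extract_active_components,
    extract_passive_components,
)

__all__ = [
    "MovementType",
    "ProtocolConfig",
    "SessionRecord",
    "DaySession",
    "SubjectStream",
    "RehabReport",
    "RPFScore",
    "resultant_torque",
    "compute_rpf",
    "run_protocol",
    "generate_report",
    "load_report",
    "progress_summary",
]


class MovementType(str, Enum):
    """Single-axis exercise movements with their healthy (theoretical) RoM."""

    pronation_supination = "pronation_supination"
    flexion_extension = "flexion_extension"
    ulnar_radial = "ulnar_radial"

    @property
    def axis(self) -> int:
        return {"pronation_supination": AXIS_INDEX["ps"],
                "flexion_extension": AXIS_INDEX["fe"],
                "ulnar_radial": AXIS_INDEX["rud"]}[self.value]

    @property
    def theoretical_rom(self) -> float:
        return DEFAULT_THEORETICAL_ROM[self]


#: Healthy-range defaults in degrees.  Flexion-extension is 70 + 60 and
#: ulnar-radial 30 + 20 from the standard wrist ranges.  The
#: pronation-supination scoring range is 90 deg, the value consistent with
#: the RPF worked examples; override per call if a 180 deg anatomical range
#: is preferred.
DEFAULT_THEORETICAL_ROM = {
    MovementType.pronation_supination: 90.0,
    MovementType.flexion_extension: 130.0,
    MovementType.ulnar_radial: 50.0,
}

#: Minimal legible active torque below which stage 2 is skipped, Nm.
MIN_LEGIBLE_TORQUE = 0.05


@dataclass(frozen=True)
class ProtocolConfig:
    """Protocol layout: days, sets, movement, fatigue mapping."""

    movement: MovementType = MovementType.pronation_supination
    n_days: int = 10
    repeats_per_exercise: int = 3
    total_sets: int = 12
    fatigue_delta: float = 0.3
    min_legible_torque: float = MIN_LEGIBLE_TORQUE
    theoretical_rom: float | None = None

    def __post_init__(self):
        if min(self.n_days, self.repeats_per_exercise, self.total_sets) <= 0:
            raise ParameterError("protocol counts must be positive")
        if not 0 <= self.fatigue_delta <= 1:
            raise ParameterError("fatigue_delta must lie in [0, 1]")


@dataclass(frozen=True)
class RPFScore:
    raw: float
    display: float


def compute_rpf(
    current_rom: float,
    movement: MovementType | str = MovementType.pronation_supination,
    theoretical_rom: float | None = None,
) -> RPFScore:
    """Rehabilitation Progress Factor: current RoM / theoretical RoM * 10.

    The raw score is capped at 10; the display value truncates toward zero
    at one decimal (66 deg pronation-supination -> 7.3, not 7.4).
    """
    if current_rom < 0:
        raise InputError("current_rom must be non-negative")
    movement = MovementType(movement)
    theo = theoretical_rom if theoretical_rom is not None else movement.theoretical_rom
    if theo <= 0:
        raise ParameterError("theoretical RoM must be positive")
    raw = min(current_rom / theo * 10.0, 10.0)
    display = math.trunc(raw * 10.0 + 1e-9) / 10.0
    return RPFScore(raw=raw, display=display)


def resultant_torque(
    model_torque: np.ndarray, fatigue_torque: float, axis: int
) -> np.ndarray:
    """Fatigue-adjusted resultant torque.

    The fatigue decrement acts on the active movement axis only; the axis
    torque magnitude is reduced by ``fatigue_torque`` and floored at zero
    (the sign of the model torque is preserved).
    """
    if fatigue_torque < 0:
        raise ParameterError("fatigue_torque must be non-negative")
    tau = np.asarray(model_torque, dtype=float).copy()
    scalar = tau.ndim == 1
    tau = np.atleast_2d(tau)
    vals = tau[:, axis]
    reduced = np.sign(vals) * np.maximum(np.abs(vals) - fatigue_torque, 0.0)
    tau[:, axis] = reduced
    return tau[0] if scalar else tau


# ---------------------------------------------------------------------------
# protocol inputs and outcomes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DaySession:
    """One day's inputs: optional passive probe, exercise data, EMG."""

    day: int
    rest: bool = False
    quasistatic: QuasiStaticRecord | None = None
    trajectory: Trajectory | None = None
    patient_torque: np.ndarray | None = None   # (n, 3), robot torque removed
    emg: EMGRecording | None = None
    date: str | None = None


@dataclass(frozen=True)
class SubjectStream:
    """All inputs for one subject's protocol run."""

    subject_id: str
    quasistatic_rounds: list
    days: list
    movement: MovementType = MovementType.pronation_supination


@dataclass(frozen=True)
class SessionRecord:
    day: int
    rom_deg: float
    active_torque: float
    passive_torque: float
    fatigue_fraction: float
    fatigue_torque: float
    date: str | None = None


@dataclass(frozen=True)
class RehabReport:
    """Per-subject protocol outcome mirroring the clinical evaluation report."""

    subject_id: str
    movement: MovementType
    total_exercises: int
    sessions: list
    passive: PassiveComponents | None
    initial_active: ActiveComponents | None
    fully_passive: bool
    last_date: str | None = None

    @property
    def rom_series(self):
        return [s.rom_deg for s in self.sessions]

    @property
    def active_torque_series(self):
        return [s.active_torque for s in self.sessions]

    @property
    def passive_torque_series(self):
        return [s.passive_torque for s in self.sessions]

    @property
    def final_rom(self) -> float:
        return self.sessions[-1].rom_deg if self.sessions else 0.0

    @property
    def rpf(self) -> RPFScore:
        return compute_rpf(self.final_rom, self.movement)


def _passive_torque_peak(passive: PassiveComponents, traj: Trajectory, axis: int) -> float:
    """Peak stiffness torque on the movement axis along the day's trajectory."""
    K = np.asarray(passive.K)
    tau = traj.q @ K.T
    return float(np.max(np.abs(tau[:, axis])))


def run_protocol(
    config: ProtocolConfig,
    stream: SubjectStream,
    classifier: FatigueModel | None = None,
    window_spec: WindowSpec = WindowSpec(),
) -> RehabReport:
    """Execute the three protocol stages over a subject's input stream.

    Stage 3 requires a fitted fatigue ``classifier`` consuming (MNF, MNP)
    rows; without one the fatigue decrement is zero (a logged limitation,
    not an error), which corresponds to a purely model-based controller.
    """
    movement = stream.movement
    axis = movement.axis

    # stage 1: passive identification
    if not stream.quasistatic_rounds:
        raise InputError("stage 1 requires quasi-static rounds")
    passive = extract_passive_components(stream.quasistatic_rounds)

    # stage 2: active capability on the first exercise day
    first_active = next(
        (d for d in stream.days if not d.rest and d.trajectory is not None), None
    )
    if first_active is None:
        raise InputError("stage 2 requires at least one exercise day")
    if first_active.patient_torque is None:
        raise InputError("stage 2 requires the patient-attributed torque series")
    initial_active = extract_active_components(
        first_active.trajectory, first_active.patient_torque, movement.value
    )
    fully_passive = initial_active.max_active_torque < config.min_legible_torque

    # stage 3: continuous exercises with fatigue-adjusted torque
    sessions: list[SessionRecord] = []
    last_date = None
    for day in stream.days:
        if day.rest:
            continue
        if day.trajectory is None or day.patient_torque is None:
            raise InputError(f"day {day.day}: missing exercise trajectory or torque")
        active = extract_active_components(
            day.trajectory, day.patient_torque, movement.value
        )

        fatigue_frac = 0.0
        if classifier is not None and day.emg is not None:
            rec = day.emg if day.emg.filtered else filter_emg(day.emg)
            feats = extract_feature_table(rec, window_spec)
            X = feats[["mnf_hz", "mnp"]].to_numpy()
            if len(X):
                labels, _ = predict_fatigue(classifier, X)
                fatigue_frac = float(np.mean(labels == FATIGUE))
        fatigue_tau = estimate_fatigue_torque(
            FATIGUE if fatigue_frac >= 0.5 else 0,
            active.max_active_torque,
            delta=config.fatigue_delta,
        )

        day_passive = (
            extract_passive_components([day.quasistatic]).K
            if day.quasistatic is not None
            else passive.K
        )
        passive_peak = _passive_torque_peak(
            PassiveComponents(
                K=day_passive, B=passive.B, per_round_K=[], per_round_change=[],
                converged=True, passive_torque_peak=0.0,
            ),
            day.trajectory,
            axis,
        )

        sessions.append(
            SessionRecord(
                day=day.day,
                rom_deg=active.achieved_rom,
                active_torque=active.max_active_torque,
                passive_torque=passive_peak,
                fatigue_fraction=fatigue_frac,
                fatigue_torque=fatigue_tau,
                date=day.date,
            )
        )
        if day.date is not None:
            last_date = day.date

    return RehabReport(
        subject_id=stream.subject_id,
        movement=movement,
        total_exercises=config.total_sets,
        sessions=sessions,
        passive=passive,
        initial_active=None if fully_passive else initial_active,
        fully_passive=fully_passive,
        last_date=last_date,
    )


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def generate_report(report: RehabReport, path) -> dict:
    """Write the evaluation report as JSON and return the document.

    The document carries the totals, the movement type, final RoM and
    torques, the three per-session series, the RPF score, and the last
    training date.  A report requires at least one completed session.
    """
    if not report.sessions:
        raise InputError("a report requires at least one completed session")
    doc = {
        "subject_id": report.subject_id,
        "movement": report.movement.value,
        "total_exercises": report.total_exercises,
        "fully_passive": report.fully_passive,
        "final_rom_deg": report.final_rom,
        "final_active_torque_nm": report.active_torque_series[-1],
        "final_passive_torque_nm": report.passive_torque_series[-1],
        "rpf": report.rpf.display,
        "rpf_raw": report.rpf.raw,
        "series": {
            "day": [s.day for s in report.sessions],
            "rom_deg": report.rom_series,
            "active_torque_nm": report.active_torque_series,
            "passive_torque_nm": report.passive_torque_series,
            "fatigue_fraction": [s.fatigue_fraction for s in report.sessions],
        },
        "last_date": report.last_date,
    }
    p = Path(path)
    try:
        p.write_text(json.dumps(doc, indent=1))
    except OSError as exc:
        raise InputError(f"cannot write report to {p}: {exc}") from exc
    return doc


def load_report(path) -> dict:
    """Read back a JSON report document."""
    return json.loads(Path(path).read_text())


def progress_summary(pairs: dict) -> dict:
    """Percent changes between initial and final parameter values.

    ``pairs`` maps a quantity name (e.g. ``rom``) to a list of
    ``(initial, final)`` tuples, one per subject.  Returns, per quantity,
    the per-subject percent changes and the pooled change
    ``(sum(final) - sum(initial)) / sum(initial) * 100``.
    """
    out = {}
    for name, values in pairs.items():
        per_subject = []
        tot_i = tot_f = 0.0
        for initial, final in values:
            if initial == 0:
                raise ParameterError(
                    f"{name}: zero initial value makes the percent change undefined"
                )
            per_subject.append((final - initial) / initial * 100.0)
            tot_i += initial
            tot_f += final
        out[name] = {
            "per_subject_pct": per_subject,
            "pooled_pct": (tot_f - tot_i) / tot_i * 100.0,
        }
    return out
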