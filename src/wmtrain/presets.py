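"""Protocol presets: thresholds, ladders, starting records, programs.

The defaults here are the conditions of the 8-week pilot protocol:

* validity thresholds 100% (Vs-WM), 80% (Op-NB), 75% (D-NB);
* rate-first ladders ending at 1 s/stimulus (Vs-WM) and 3 s/stimulus
  (Op-NB, D-NB); starting rates and step sizes are not fixed by the
  protocol and default to 2.0→1.0 s in 0.25 s steps for Vs-WM and
  4.5→3.0 s in 0.5 s steps for the n-back types;
* starting records equal for all patients: 3×3 grid / 3 stimuli for
  Vs-WM, N = 0 for Op-NB and D-NB, all at the slowest rate;
* the ``takeuchi-8w`` program: 8 weeks × 5 sessions/week (40 sessions),
  one 30-minute session per day, ~10 minutes per exercise, after the
  working-memory training schedule of Takeuchi and colleagues.

Everything is a plain value; build custom ladders/programs by constructing
the dataclasses directly or by editing a YAML config (see :func:`load_yaml`).
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .adaptive import DifficultyLadder, ExerciseRecord, ValidityThresholds
from .errors import ConfigError
from .exercises import DNbConfig, ExerciseType, OpNbConfig, VsWmConfig
from .scheduler import Program

__all__ = [
    "PROTOCOL_THRESHOLDS",
    "PROTOCOL_PROGRAM",
    "PROGRAMS",
    "protocol_ladder",
    "protocol_ladders",
    "starting_record",
    "protocol_starting_records",
    "load_yaml",
]

PROTOCOL_THRESHOLDS = ValidityThresholds(vs_wm=100.0, op_nb=80.0, d_nb=75.0)

_VSWM_RATE_STEPS = (2.0, 1.75, 1.5, 1.25, 1.0)
_NB_RATE_STEPS = (4.5, 4.0, 3.5, 3.0)

PROTOCOL_PROGRAM = Program(
    duration_weeks=8,
    sessions_per_week=5,
    max_training_days_per_week=5,
    session_minutes=30.0,
    per_exercise_daily_minutes={t: 10.0 for t in ExerciseType},
    max_sessions_per_day=1,
    name="takeuchi-8w",
)

PROGRAMS = {"takeuchi-8w": PROTOCOL_PROGRAM}


def protocol_ladder(exercise_type: ExerciseType, grow_grid: bool = False) -> DifficultyLadder:
    """The default difficulty ladder for one paradigm."""
    if exercise_type is ExerciseType.VS_WM:
        base = VsWmConfig(grid_rows=3, grid_cols=3, sequence_length=3, isi=_VSWM_RATE_STEPS[0])
        return DifficultyLadder(exercise_type, _VSWM_RATE_STEPS, base, grow_grid=grow_grid)
    if grow_grid:
        raise ConfigError("grow_grid applies to Vs-WM ladders only")
    if exercise_type is ExerciseType.OP_NB:
        base = OpNbConfig.protocol(n_back=0, isi=_NB_RATE_STEPS[0])
        return DifficultyLadder(exercise_type, _NB_RATE_STEPS, base)
    if exercise_type is ExerciseType.D_NB:
        base = DNbConfig.protocol(n_back=0, isi=_NB_RATE_STEPS[0])
        return DifficultyLadder(exercise_type, _NB_RATE_STEPS, base)
    raise ConfigError(f"unknown exercise type {exercise_type!r}")


def protocol_ladders() -> dict[ExerciseType, DifficultyLadder]:
    return {t: protocol_ladder(t) for t in ExerciseType}


def starting_record(
    exercise_type: ExerciseType,
    patient_id: str | None = None,
    record_id: str | None = None,
) -> ExerciseRecord:
    """The level-1 record all patients start from (slowest rate, base task)."""
    ladder = protocol_ladder(exercise_type)
    if record_id is None:
        suffix = patient_id if patient_id is not None else "unassigned"
        record_id = f"start-{exercise_type.value}-{suffix}"
    return ExerciseRecord(
        record_id=record_id,
        exercise_type=exercise_type,
        config=ladder.base_config,
        level=1,
        patient_id=patient_id,
        auto_generated=False,
    )


def protocol_starting_records(patient_id: str) -> dict[ExerciseType, ExerciseRecord]:
    return {t: starting_record(t, patient_id) for t in ExerciseType}


def load_yaml(path: str | Path) -> dict:
    """Load a structured-text (YAML) configuration file as a plain dict."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"configuration file {path} must hold a mapping")
    return data
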