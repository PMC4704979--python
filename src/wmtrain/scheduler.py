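"""Training-intensiveness settings, session eligibility and adherence.

A :class:`Program` captures the intensiveness of a home-based training
course: its total duration in weeks, how many sessions are trained per week
(and at most per day), how long a session lasts and how many minutes per day
each exercise type receives.  The study preset is 8 weeks × 5 sessions/week
(40 sessions), 30-minute sessions split as ~10 minutes per exercise, one
session per day.

Adherence is the share of scheduled sessions actually completed, reported as
an integer percent (half-up rounding, so a cohort mean of 33.4/40 prints as
84%).  Weeks are anchored on the ISO calendar.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from fractions import Fraction
from numbers import Rational
from typing import Iterable, Mapping

from .errors import ConfigError, InputError
from .exercises import BlockResult, ExerciseType

__all__ = [
    "Program",
    "SessionLog",
    "round_half_up",
    "scheduled_session_count",
    "session_allowed",
    "adherence_percent",
    "inclusion_threshold_sessions",
]


def round_half_up(x) -> int:
    """Round to the nearest integer, ties away from zero, exactly.

    Floats are interpreted through their decimal literal (``str``) so that
    e.g. ``83.5`` rounds to 84 rather than falling victim to binary
    representation error.
    """
    if isinstance(x, Rational):
        f = Fraction(x)
    else:
        f = Fraction(str(x))
    if f >= 0:
        return int((f + Fraction(1, 2)).__floor__())
    return -round_half_up(-f)


@dataclass(frozen=True)
class Program:
    """Intensiveness settings of one training course."""

    duration_weeks: int = 8
    sessions_per_week: int = 5
    max_training_days_per_week: int = 5
    session_minutes: float = 30.0
    per_exercise_daily_minutes: Mapping[ExerciseType, float] = field(
        default_factory=lambda: {t: 10.0 for t in ExerciseType}
    )
    max_sessions_per_day: int = 1
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.duration_weeks < 1:
            raise ConfigError("duration_weeks must be >= 1")
        if self.sessions_per_week < 1:
            raise ConfigError("sessions_per_week must be >= 1")
        if not self.sessions_per_week <= self.max_training_days_per_week <= 7:
            raise ConfigError(
                "need sessions_per_week <= max_training_days_per_week <= 7"
            )
        if self.session_minutes <= 0:
            raise ConfigError("session_minutes must be positive")
        if self.max_sessions_per_day < 1:
            raise ConfigError("max_sessions_per_day must be >= 1")
        if any(m < 0 for m in self.per_exercise_daily_minutes.values()):
            raise ConfigError("per-exercise minutes must be non-negative")


@dataclass
class SessionLog:
    """All blocks trained by one patient on one calendar day."""

    patient_id: str
    date: dt.date
    blocks: dict[ExerciseType, list[BlockResult]] = field(default_factory=dict)
    total_minutes: float = 0.0

    def n_blocks(self) -> int:
        return sum(len(v) for v in self.blocks.values())


def scheduled_session_count(program: Program) -> int:
    """Total sessions the program schedules (weeks × sessions/week)."""
    return program.duration_weeks * program.sessions_per_week


def session_allowed(
    history: Iterable[SessionLog],
    date: dt.date,
    program: Program,
    start_date: dt.date | None = None,
) -> bool:
    """Whether a new session may start on ``date`` given past sessions.

    Denied when the day already holds ``max_sessions_per_day`` sessions,
    when the ISO week of ``date`` already holds ``sessions_per_week``
    sessions, or when the program duration (counted from ``start_date``,
    defaulting to the earliest session in the history) has elapsed.
    """
    history = list(history)
    if any(log.date > date for log in history):
        raise InputError("history contains sessions later than the queried date")
    same_day = sum(1 for log in history if log.date == date)
    if same_day >= program.max_sessions_per_day:
        return False
    week = date.isocalendar()[:2]
    in_week = sum(1 for log in history if log.date.isocalendar()[:2] == week)
    if in_week >= program.sessions_per_week:
        return False
    anchor = start_date
    if anchor is None and history:
        anchor = min(log.date for log in history)
    if anchor is not None and (date - anchor).days >= program.duration_weeks * 7:
        return False
    return True


def adherence_percent(completed_sessions, program: Program) -> int:
    """Completed sessions as an integer percent of scheduled sessions.

    ``completed_sessions`` may be fractional (e.g. a cohort mean such as
    33.4) — the percentage is computed exactly and rounded half-up, so
    33.4/40 → 83.5% → 84.
    """
    scheduled = scheduled_session_count(program)
    if scheduled == 0:
        raise ConfigError("program schedules no sessions")
    if isinstance(completed_sessions, Rational):
        completed = Fraction(completed_sessions)
    else:
        completed = Fraction(str(completed_sessions))
    if completed < 0:
        raise InputError("completed session count cannot be negative")
    return round_half_up(Fraction(100) * completed / scheduled)


def inclusion_threshold_sessions(program: Program, fraction: float) -> int:
    """Smallest completed-session count whose adherence meets ``fraction``.

    With the study preset (40 scheduled sessions) an 80% inclusion cut-off
    corresponds to 32 sessions.
    """
    if not 0 < fraction <= 100:
        raise ConfigError("inclusion fraction must lie in (0, 100]")
    scheduled = scheduled_session_count(program)
    for count in range(scheduled + 1):
        if adherence_percent(count, program) >= fraction:
            return count
    return scheduled  # pragma: no cover - 100% always qualifies
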