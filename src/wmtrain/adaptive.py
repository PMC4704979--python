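"""Adaptive working-load staircase: validity, level updates, record spawning.

After every block ('trial') the percent of correct answers is compared with
an exercise-specific validity threshold (protocol preset: 100% for Vs-WM,
80% for Op-NB, 75% for D-NB).  Every *valid* block raises the difficulty
level by 1 and a new exercise record is generated for the patient; after the
first and second consecutive *invalid* blocks nothing changes and the last
record is reused; the third consecutive invalid block lowers the level by 1.
The level therefore never moves by more than 1 per block.

Levels map onto concrete exercise configurations through a
:class:`DifficultyLadder`: difficulty first increases by speeding up the
presentation rate until it reaches a per-paradigm rate threshold (1 s per
stimulus for Vs-WM, 3 s for the n-back types), and only then by growing the
task-specific parameter (sequence length for Vs-WM, N for Op-NB/D-NB, with
the n-back block length tied to N as (N+1)×5).  Consecutive levels differ in
exactly one independent parameter.

Auto-spawned records are bound to the patient whose performance produced
them and can never be assigned to another subject (enforced again by the
datastore on assignment).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import ClassVar

from .errors import ConfigError, StateError
from .exercises import (
    BlockResult,
    DNbConfig,
    ExerciseConfig,
    ExerciseType,
    OpNbConfig,
    VsWmConfig,
    required_stimulus_count,
)

__all__ = [
    "ValidityThresholds",
    "AdaptiveState",
    "DifficultyLadder",
    "ExerciseRecord",
    "NO_CHANGE",
    "evaluate_validity",
    "advance_state",
    "config_at_level",
    "spawn_record",
]


@dataclass(frozen=True)
class ValidityThresholds:
    """Percent-correct required for a block to count as valid.

    Defaults are the study protocol's thresholds.
    """

    vs_wm: float = 100.0
    op_nb: float = 80.0
    d_nb: float = 75.0

    def __post_init__(self) -> None:
        for name in ("vs_wm", "op_nb", "d_nb"):
            v = getattr(self, name)
            if not 0 < v <= 100:
                raise ConfigError(f"threshold {name} must lie in (0, 100], got {v}")

    def for_type(self, exercise_type: ExerciseType) -> float:
        try:
            return {
                ExerciseType.VS_WM: self.vs_wm,
                ExerciseType.OP_NB: self.op_nb,
                ExerciseType.D_NB: self.d_nb,
            }[exercise_type]
        except KeyError:
            raise ConfigError(f"unknown exercise type {exercise_type!r}") from None


@dataclass(frozen=True)
class AdaptiveState:
    """Current difficulty level and consecutive-invalid streak.

    The streak is always 0–2: the third consecutive invalid block triggers
    the decrement and resets the counter, so a streak of 3 is never stored.
    """

    level: int = 1
    invalid_streak: int = 0

    def __post_init__(self) -> None:
        if self.level < 1:
            raise ConfigError("level must be >= 1")
        if not 0 <= self.invalid_streak <= 2:
            raise ConfigError("invalid_streak must be 0..2")


def evaluate_validity(result: BlockResult, thresholds: ValidityThresholds) -> bool:
    """A block is valid iff its percent correct meets the paradigm threshold."""
    return result.pct_correct >= thresholds.for_type(result.exercise_type)


def advance_state(
    state: AdaptiveState,
    valid: bool,
    floor: int = 1,
    ceiling: int | None = None,
) -> AdaptiveState:
    """One staircase step: +1 on valid, −1 after the 3rd consecutive invalid.

    ``floor`` is the easiest ladder rung (difficulty never drops below it);
    ``ceiling``, when given, caps the level of a bounded ladder.  Both a
    valid block and a decrement reset the invalid streak.
    """
    if valid:
        new_level = state.level + 1
        if ceiling is not None:
            new_level = min(new_level, ceiling)
        return AdaptiveState(level=new_level, invalid_streak=0)
    if state.invalid_streak < 2:
        return AdaptiveState(level=state.level, invalid_streak=state.invalid_streak + 1)
    return AdaptiveState(level=max(state.level - 1, floor), invalid_streak=0)


@dataclass(frozen=True)
class DifficultyLadder:
    """Deterministic map from integer difficulty levels to exercise configs.

    Levels ``1..len(rate_steps)`` present the base configuration at
    successively faster rates (``rate_steps`` holds the inter-stimulus
    intervals in seconds, strictly decreasing, the last one being the rate
    threshold).  Levels beyond keep the threshold rate and grow the
    task-specific parameter by one per level: sequence length for Vs-WM,
    N for the n-back types (block length follows as (N+1)×5).

    With a fixed grid the Vs-WM ladder is bounded: cells are not revisited
    within a sequence, so the sequence cannot outgrow the grid and
    :attr:`max_level` is finite.  Setting ``grow_grid=True`` enlarges the
    grid minimally whenever the sequence no longer fits, making the ladder
    unbounded (an optional variant; the study protocol holds the grid fixed).
    """

    exercise_type: ExerciseType
    rate_steps: tuple[float, ...]
    base_config: ExerciseConfig
    grow_grid: bool = False

    def __post_init__(self) -> None:
        if len(self.rate_steps) < 1:
            raise ConfigError("rate_steps must contain at least one isi value")
        if any(s <= 0 for s in self.rate_steps):
            raise ConfigError("all rate steps must be positive")
        if any(a <= b for a, b in zip(self.rate_steps, self.rate_steps[1:])):
            raise ConfigError("rate_steps must be strictly decreasing (speeding up)")
        if self.base_config.exercise_type is not self.exercise_type:
            raise ConfigError("base_config paradigm does not match the ladder's")
        if self.base_config.isi != self.rate_steps[0]:
            raise ConfigError("base_config.isi must equal the first (slowest) rate step")
        if self.grow_grid and self.exercise_type is not ExerciseType.VS_WM:
            raise ConfigError("grow_grid applies to Vs-WM ladders only")

    @property
    def max_level(self) -> int | None:
        """Highest representable level, or None for an unbounded ladder."""
        if self.exercise_type is ExerciseType.VS_WM and not self.grow_grid:
            cfg: VsWmConfig = self.base_config
            capacity = cfg.grid_rows * cfg.grid_cols
            return len(self.rate_steps) + (capacity - cfg.sequence_length)
        return None


def config_at_level(ladder: DifficultyLadder, level: int) -> ExerciseConfig:
    """The exercise configuration presented at a given difficulty level."""
    if level < 1:
        raise ConfigError(f"level must be >= 1, got {level}")
    n_rate = len(ladder.rate_steps)
    if level <= n_rate:
        return replace(ladder.base_config, isi=ladder.rate_steps[level - 1])
    extra = level - n_rate
    isi = ladder.rate_steps[-1]
    base = ladder.base_config
    if isinstance(base, VsWmConfig):
        length = base.sequence_length + extra
        rows, cols = base.grid_rows, base.grid_cols
        if length > rows * cols:
            if not ladder.grow_grid:
                raise ConfigError(
                    f"level {level} needs a {length}-cell sequence but the fixed "
                    f"{rows}x{cols} grid holds only {rows * cols} cells "
                    f"(ladder ceiling is level {ladder.max_level})"
                )
            while length > rows * cols:
                if rows <= cols:
                    rows += 1
                else:
                    cols += 1
        return VsWmConfig(grid_rows=rows, grid_cols=cols, sequence_length=length, isi=isi)
    if isinstance(base, OpNbConfig):
        n = base.n_back + extra
        return OpNbConfig(
            n_back=n,
            digit_lo=base.digit_lo,
            digit_hi=base.digit_hi,
            isi=isi,
            stimulus_count=required_stimulus_count(n),
        )
    if isinstance(base, DNbConfig):
        n = base.n_back + extra
        return DNbConfig(n_back=n, isi=isi, stimulus_count=required_stimulus_count(n))
    raise ConfigError(f"unknown config type {type(base).__name__}")


@dataclass(frozen=True)
class ExerciseRecord:
    """One stored parameter configuration of one exercise type.

    Auto-generated records carry the id of the record they were spawned from
    and are bound to a single patient.  ``patient_id=None`` denotes an
    administrator-created record not yet assigned (UNASSIGNED).
    """

    record_id: str
    exercise_type: ExerciseType
    config: ExerciseConfig
    level: int
    patient_id: str | None = None
    auto_generated: bool = False
    parent_record_id: str | None = None

    def __post_init__(self) -> None:
        if self.level < 1:
            raise ConfigError("record level must be >= 1")
        if self.config.exercise_type is not self.exercise_type:
            raise ConfigError("record config paradigm does not match exercise_type")
        if self.auto_generated and self.patient_id is None:
            raise ConfigError("auto-generated records must be bound to a patient")


class _NoChangeType:
    _singleton: ClassVar["_NoChangeType | None"] = None

    def __new__(cls) -> "_NoChangeType":
        if cls._singleton is None:
            cls._singleton = super().__new__(cls)
        return cls._singleton

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "NO_CHANGE"


#: Returned by :func:`spawn_record` when the level did not move and the
#: previous record is to be reused for the next block.
NO_CHANGE = _NoChangeType()


def spawn_record(
    previous: ExerciseRecord,
    new_state: AdaptiveState,
    ladder: DifficultyLadder,
    record_id: str | None = None,
):
    """Create the next patient-bound record, or NO_CHANGE if the level held.

    A new record is generated only when the staircase actually moved; after
    the first and second consecutive invalid blocks the previous record is
    reused unchanged.
    """
    if previous.patient_id is None:
        raise StateError("cannot spawn from a record that is not assigned to a patient")
    if new_state.level == previous.level:
        return NO_CHANGE
    if record_id is None:
        record_id = f"{previous.record_id}>L{new_state.level}"
    return ExerciseRecord(
        record_id=record_id,
        exercise_type=previous.exercise_type,
        config=config_at_level(ladder, new_state.level),
        level=new_state.level,
        patient_id=previous.patient_id,
        auto_generated=True,
        parent_record_id=previous.record_id,
    )
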