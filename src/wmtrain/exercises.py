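"""Stimulus generation and scoring for three working-memory paradigms.

The trainer implements three touch-screen working-memory exercises:

* **Vs-WM** (visuospatial working memory) — a random sequence of circles is
  lit one at a time on an ``R × C`` grid; the subject reproduces the sequence
  by touching the cells in the presented order.
* **Op-NB** (operation n-back) — pairs of digits are shown (e.g. ``1+4``);
  the subject answers the *sum* of the pair shown ``N`` stimuli earlier
  (``N = 0`` means the current pair).
* **D-NB** (dual n-back) — a digit from 1–4 appears in one of 4 cells placed
  in a row; the subject answers both the digit (buttons 1–4) and the cell
  (buttons 5–8, 5 = left-most cell, 8 = right-most cell) of the stimulus
  ``N`` back.

This module is purely in-memory and time-free: streams are generated from an
explicit integer seed (recorded in the raw log so a block can be replayed),
and a missed answer is represented by the :data:`MISSED` sentinel rather than
by a real-time timeout.

Scoring conventions
-------------------
For the n-back types the first ``N`` stimuli are memorise-only; scored
positions start at the ``(N+1)``-th stimulus, so a block of ``S`` stimuli has
``S − N`` scored positions.  A dual n-back answer is correct only when *both*
the digit button and the cell button match; a half-right answer counts as a
single incorrect answer.  Vs-WM reproduction is order-sensitive with no
partial credit.  Every scorer conserves counts:
``n_correct + n_incorrect + n_missed`` equals the number of scored positions
and ``pct_correct = 100 · n_correct / scored``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from datetime import datetime
from typing import ClassVar, Sequence, Union

import numpy as np

from .errors import ConfigError, InputError

__all__ = [
    "ExerciseType",
    "MISSED",
    "VsWmConfig",
    "OpNbConfig",
    "DNbConfig",
    "ExerciseConfig",
    "StimulusStream",
    "BlockResult",
    "required_stimulus_count",
    "generate_vswm_stream",
    "generate_opnb_stream",
    "generate_dnb_stream",
    "generate_stream",
    "score_vswm",
    "score_opnb",
    "score_dnb",
    "config_to_dict",
    "config_from_dict",
]


class ExerciseType(str, enum.Enum):
    """The three working-memory paradigms."""

    VS_WM = "vs-wm"
    OP_NB = "op-nb"
    D_NB = "d-nb"

    @property
    def description(self) -> str:
        return {
            ExerciseType.VS_WM: "visuospatial working-memory sequence reproduction",
            ExerciseType.OP_NB: "operation n-back (sum of the digit pair N stimuli ago)",
            ExerciseType.D_NB: "dual n-back (digit identity and cell position N stimuli ago)",
        }[self]


class _MissedType:
    """Singleton sentinel for an answer the subject never gave."""

    _singleton: ClassVar["_MissedType | None"] = None

    def __new__(cls) -> "_MissedType":
        if cls._singleton is None:
            cls._singleton = super().__new__(cls)
        return cls._singleton

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "MISSED"

    def __deepcopy__(self, memo):  # sentinel identity must survive copying
        return self

    def __copy__(self):
        return self


MISSED = _MissedType()


def required_stimulus_count(n_back: int) -> int:
    """Number of stimuli per n-back block under the study protocol.

    The protocol scales block length with difficulty as
    ``stimuli = (N + 1) × 5``, so e.g. a 2-back block presents 15 stimuli.
    """
    if n_back < 0:
        raise ConfigError(f"n_back must be >= 0, got {n_back}")
    return (n_back + 1) * 5


@dataclass(frozen=True)
class VsWmConfig:
    """Parameters of one visuospatial sequence-reproduction block.

    ``isi`` is the inter-stimulus interval in seconds (the inverse of the
    presentation rate).  Cells within one sequence are sampled without
    replacement, hence ``sequence_length`` may not exceed the grid size.
    """

    grid_rows: int = 3
    grid_cols: int = 3
    sequence_length: int = 3
    isi: float = 2.0

    exercise_type: ClassVar[ExerciseType] = ExerciseType.VS_WM

    def __post_init__(self) -> None:
        if self.grid_rows < 2 or self.grid_cols < 2:
            raise ConfigError(f"grid must be at least 2x2, got {self.grid_rows}x{self.grid_cols}")
        if self.sequence_length < 1:
            raise ConfigError("sequence_length must be >= 1")
        if self.isi <= 0:
            raise ConfigError("isi must be positive")
        if self.sequence_length > self.grid_rows * self.grid_cols:
            raise ConfigError(
                f"sequence_length {self.sequence_length} exceeds the "
                f"{self.grid_rows * self.grid_cols} grid cells (cells are not revisited)"
            )

    @property
    def n_scored(self) -> int:
        return self.sequence_length

    @property
    def block_seconds(self) -> float:
        """Simulated duration of one block (stimuli × isi)."""
        return self.sequence_length * self.isi


@dataclass(frozen=True)
class OpNbConfig:
    """Parameters of one operation n-back block.

    Digits are drawn uniformly and independently from the inclusive span
    ``[digit_lo, digit_hi]``; with the full 1–9 span the pair sums range
    from 2 to 18.
    """

    n_back: int = 0
    digit_lo: int = 1
    digit_hi: int = 9
    isi: float = 4.5
    stimulus_count: int = 5

    exercise_type: ClassVar[ExerciseType] = ExerciseType.OP_NB

    def __post_init__(self) -> None:
        if self.n_back < 0:
            raise ConfigError("n_back must be >= 0")
        if not (1 <= self.digit_lo <= self.digit_hi <= 9):
            raise ConfigError(
                f"digit span must satisfy 1 <= lo <= hi <= 9, got [{self.digit_lo}, {self.digit_hi}]"
            )
        if self.isi <= 0:
            raise ConfigError("isi must be positive")
        if self.stimulus_count < 1:
            raise ConfigError("stimulus_count must be >= 1")
        if self.n_back >= self.stimulus_count:
            raise ConfigError(
                f"n_back {self.n_back} leaves no scorable position in a block of "
                f"{self.stimulus_count} stimuli"
            )

    @classmethod
    def protocol(cls, n_back: int, isi: float, digit_lo: int = 1, digit_hi: int = 9) -> "OpNbConfig":
        """Build a config with the protocol's (N+1)×5 stimulus count."""
        return cls(
            n_back=n_back,
            digit_lo=digit_lo,
            digit_hi=digit_hi,
            isi=isi,
            stimulus_count=required_stimulus_count(n_back),
        )

    @property
    def n_scored(self) -> int:
        return self.stimulus_count - self.n_back

    @property
    def block_seconds(self) -> float:
        return self.stimulus_count * self.isi


@dataclass(frozen=True)
class DNbConfig:
    """Parameters of one dual n-back block.

    The stimulus space is fixed by the paradigm: digits 1–4 shown in one of
    4 adjacent cells (numbered 1 = left-most to 4 = right-most).
    """

    n_back: int = 0
    isi: float = 4.5
    stimulus_count: int = 5

    exercise_type: ClassVar[ExerciseType] = ExerciseType.D_NB
    n_digits: ClassVar[int] = 4
    n_cells: ClassVar[int] = 4

    def __post_init__(self) -> None:
        if self.n_back < 0:
            raise ConfigError("n_back must be >= 0")
        if self.isi <= 0:
            raise ConfigError("isi must be positive")
        if self.stimulus_count < 1:
            raise ConfigError("stimulus_count must be >= 1")
        if self.n_back >= self.stimulus_count:
            raise ConfigError(
                f"n_back {self.n_back} leaves no scorable position in a block of "
                f"{self.stimulus_count} stimuli"
            )

    @classmethod
    def protocol(cls, n_back: int, isi: float) -> "DNbConfig":
        return cls(n_back=n_back, isi=isi, stimulus_count=required_stimulus_count(n_back))

    @property
    def n_scored(self) -> int:
        return self.stimulus_count - self.n_back

    @property
    def block_seconds(self) -> float:
        return self.stimulus_count * self.isi


ExerciseConfig = Union[VsWmConfig, OpNbConfig, DNbConfig]


@dataclass(frozen=True)
class StimulusStream:
    """An ordered stimulus sequence generated from one explicit seed.

    ``items`` holds ``(row, col)`` cells for Vs-WM, ``(a, b)`` digit pairs
    for Op-NB and ``(digit, cell)`` pairs for D-NB.
    """

    exercise_type: ExerciseType
    items: tuple
    seed: int
    config: ExerciseConfig

    def __post_init__(self) -> None:
        expected = (
            self.config.sequence_length
            if isinstance(self.config, VsWmConfig)
            else self.config.stimulus_count
        )
        if len(self.items) != expected:
            raise ConfigError(
                f"stream holds {len(self.items)} items but the config requires {expected}"
            )


@dataclass(frozen=True)
class BlockResult:
    """Outcome of executing one exercise record once (one 'trial')."""

    exercise_type: ExerciseType
    n_correct: int
    n_incorrect: int
    n_missed: int
    pct_correct: float
    level: int = 1
    timestamp: datetime | None = None

    @classmethod
    def from_counts(
        cls,
        exercise_type: ExerciseType,
        n_correct: int,
        n_incorrect: int,
        n_missed: int,
        level: int = 1,
        timestamp: datetime | None = None,
    ) -> "BlockResult":
        total = n_correct + n_incorrect + n_missed
        if total <= 0:
            raise InputError("a block must contain at least one scored position")
        return cls(
            exercise_type=exercise_type,
            n_correct=n_correct,
            n_incorrect=n_incorrect,
            n_missed=n_missed,
            pct_correct=100.0 * n_correct / total,
            level=level,
            timestamp=timestamp,
        )

    @property
    def n_scored(self) -> int:
        return self.n_correct + self.n_incorrect + self.n_missed


# ---------------------------------------------------------------------------
# generators


def generate_vswm_stream(config: VsWmConfig, seed: int) -> StimulusStream:
    """Draw a cell sequence uniformly *without replacement* from the grid."""
    rng = np.random.default_rng(seed)
    cells = [(r, c) for r in range(config.grid_rows) for c in range(config.grid_cols)]
    idx = rng.choice(len(cells), size=config.sequence_length, replace=False)
    items = tuple(cells[i] for i in idx)
    return StimulusStream(ExerciseType.VS_WM, items, int(seed), config)


def generate_opnb_stream(config: OpNbConfig, seed: int) -> StimulusStream:
    """Draw digit pairs uniformly and independently on the digit span."""
    rng = np.random.default_rng(seed)
    arr = rng.integers(config.digit_lo, config.digit_hi + 1, size=(config.stimulus_count, 2))
    items = tuple((int(a), int(b)) for a, b in arr)
    return StimulusStream(ExerciseType.OP_NB, items, int(seed), config)


def generate_dnb_stream(config: DNbConfig, seed: int) -> StimulusStream:
    """Draw (digit, cell) stimuli, digit and cell independently uniform on 1–4."""
    rng = np.random.default_rng(seed)
    digits = rng.integers(1, config.n_digits + 1, size=config.stimulus_count)
    cells = rng.integers(1, config.n_cells + 1, size=config.stimulus_count)
    items = tuple((int(d), int(c)) for d, c in zip(digits, cells))
    return StimulusStream(ExerciseType.D_NB, items, int(seed), config)


def generate_stream(config: ExerciseConfig, seed: int) -> StimulusStream:
    """Dispatch to the generator matching the config type."""
    if isinstance(config, VsWmConfig):
        return generate_vswm_stream(config, seed)
    if isinstance(config, OpNbConfig):
        return generate_opnb_stream(config, seed)
    if isinstance(config, DNbConfig):
        return generate_dnb_stream(config, seed)
    raise ConfigError(f"unknown config type {type(config).__name__}")


# ---------------------------------------------------------------------------
# scorers


def _check_stream_type(stream: StimulusStream, expected: ExerciseType) -> None:
    if stream.exercise_type is not expected:
        raise InputError(
            f"expected a {expected.value} stream, got {stream.exercise_type.value}"
        )


def score_vswm(
    stream: StimulusStream,
    responses: Sequence,
    *,
    level: int = 1,
    timestamp: datetime | None = None,
) -> BlockResult:
    """Order-sensitive, position-by-position scoring of a reproduced sequence.

    Position ``i`` is correct iff the touched cell equals the ``i``-th
    presented cell; a right cell touched at the wrong position is incorrect.
    """
    _check_stream_type(stream, ExerciseType.VS_WM)
    if len(responses) != len(stream.items):
        raise InputError(
            f"expected {len(stream.items)} responses, got {len(responses)}"
        )
    n_correct = n_incorrect = n_missed = 0
    for item, answer in zip(stream.items, responses):
        if answer is MISSED:
            n_missed += 1
        elif tuple(answer) == item:
            n_correct += 1
        else:
            n_incorrect += 1
    return BlockResult.from_counts(
        ExerciseType.VS_WM, n_correct, n_incorrect, n_missed, level, timestamp
    )


def score_opnb(
    stream: StimulusStream,
    responses: Sequence,
    n_back: int | None = None,
    *,
    level: int = 1,
    timestamp: datetime | None = None,
) -> BlockResult:
    """Score sum answers; scored position ``j`` refers to stimulus ``j``
    (given while stimulus ``j + N`` is on screen)."""
    _check_stream_type(stream, ExerciseType.OP_NB)
    if n_back is None:
        n_back = stream.config.n_back
    n_scored = len(stream.items) - n_back
    if n_scored <= 0:
        raise ConfigError(
            f"n_back {n_back} leaves no scorable position in {len(stream.items)} stimuli"
        )
    if len(responses) != n_scored:
        raise InputError(f"expected {n_scored} responses, got {len(responses)}")
    n_correct = n_incorrect = n_missed = 0
    for j, answer in enumerate(responses):
        a, b = stream.items[j]
        if answer is MISSED:
            n_missed += 1
        elif answer == a + b:
            n_correct += 1
        else:
            n_incorrect += 1
    return BlockResult.from_counts(
        ExerciseType.OP_NB, n_correct, n_incorrect, n_missed, level, timestamp
    )


def score_dnb(
    stream: StimulusStream,
    responses: Sequence,
    n_back: int | None = None,
    *,
    level: int = 1,
    timestamp: datetime | None = None,
) -> BlockResult:
    """Score (digit-button, cell-button) answers against the stimulus N back.

    Digit buttons are 1–4; cell buttons are 5–8 and map left-to-right onto
    the 4 cells (button 5 = cell 1).  An answer is correct only when both
    buttons match; a partial match is one incorrect answer.
    """
    _check_stream_type(stream, ExerciseType.D_NB)
    if n_back is None:
        n_back = stream.config.n_back
    n_scored = len(stream.items) - n_back
    if n_scored <= 0:
        raise ConfigError(
            f"n_back {n_back} leaves no scorable position in {len(stream.items)} stimuli"
        )
    if len(responses) != n_scored:
        raise InputError(f"expected {n_scored} responses, got {len(responses)}")
    n_correct = n_incorrect = n_missed = 0
    for j, answer in enumerate(responses):
        if answer is MISSED:
            n_missed += 1
            continue
        digit_button, cell_button = answer
        if digit_button not in (1, 2, 3, 4):
            raise InputError(f"digit button must be in 1..4, got {digit_button}")
        if cell_button not in (5, 6, 7, 8):
            raise InputError(f"cell button must be in 5..8, got {cell_button}")
        digit, cell = stream.items[j]
        if digit_button == digit and cell_button - 4 == cell:
            n_correct += 1
        else:
            n_incorrect += 1
    return BlockResult.from_counts(
        ExerciseType.D_NB, n_correct, n_incorrect, n_missed, level, timestamp
    )


# ---------------------------------------------------------------------------
# config (de)serialisation — used by the datastore raw log and report


_CONFIG_CLASSES = {
    ExerciseType.VS_WM.value: VsWmConfig,
    ExerciseType.OP_NB.value: OpNbConfig,
    ExerciseType.D_NB.value: DNbConfig,
}


def config_to_dict(config: ExerciseConfig) -> dict:
    import dataclasses

    d = {"type": config.exercise_type.value}
    for f in dataclasses.fields(config):
        d[f.name] = getattr(config, f.name)
    return d


def config_from_dict(d: dict) -> ExerciseConfig:
    d = dict(d)
    try:
        cls = _CONFIG_CLASSES[d.pop("type")]
    except KeyError as exc:
        raise InputError(f"unknown exercise config type: {exc}") from None
    return cls(**d)
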