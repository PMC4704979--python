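"""Parametric simulated patients and closed-loop program execution.

No human sits at the desk, so the whole system is exercised end-to-end by a
:class:`ResponderModel`: a stylised psychometric observer that answers each
scored position independently.  At or below its per-exercise *capacity
level* it answers correctly with probability ``p_high``; above capacity the
probability degrades linearly with ``slope`` per level down to ``p_floor``.
Independently of correctness, each answer is missed (never given within the
response window) with probability ``miss_rate``.

The same module provides the analytic counterpart used to validate the
staircase: the adaptive algorithm with a level-dependent validity
probability is an explicit Markov chain on states ``(level,
invalid_streak)``, whose exact stationary distribution
(:func:`exact_stationary_levels`) can be compared against the empirical
level frequencies of a long closed-loop run
(:func:`stationary_level_distribution`).

:func:`run_program` executes a full training course — scheduler-eligible
sessions, per-exercise daily time budgets, staircase updates, record
spawning and raw logging — deterministically from one integer seed.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from fractions import Fraction
from typing import Mapping

import numpy as np
from scipy import stats

from .adaptive import (
    AdaptiveState,
    DifficultyLadder,
    ExerciseRecord,
    NO_CHANGE,
    ValidityThresholds,
    advance_state,
    evaluate_validity,
    spawn_record,
)
from .datastore import RawLogLine, Store
from .errors import ConfigError, StateError
from .exercises import (
    BlockResult,
    ExerciseConfig,
    ExerciseType,
    MISSED,
    OpNbConfig,
    VsWmConfig,
    generate_stream,
    score_dnb,
    score_opnb,
    score_vswm,
)
from .presets import PROTOCOL_THRESHOLDS, protocol_ladder, protocol_ladders
from .scheduler import Program, SessionLog, scheduled_session_count, session_allowed

__all__ = [
    "ResponderModel",
    "answer_probability",
    "valid_probability",
    "run_block",
    "run_program",
    "History",
    "stationary_level_distribution",
    "level_valid_probabilities",
    "exact_stationary_levels",
]

# decorrelates the response draws from the stimulus stream, which is
# generated from the raw block seed
_RESPONSE_STREAM_KEY = 0x5DEECE66


@dataclass(frozen=True)
class ResponderModel:
    """Stylised observer: step-then-linear-decay psychometric profile.

    ``capacity_level`` may be a single integer (same capacity in every
    paradigm) or a per-exercise mapping.  Defaults describe a competent but
    imperfect responder whose performance collapses quickly above capacity,
    which keeps the staircase oscillating near the capacity level.
    """

    capacity_level: int | Mapping[ExerciseType, int] = 4
    p_high: float = 0.95
    p_floor: float = 0.05
    slope: float = 0.45
    miss_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.p_floor <= self.p_high <= 1:
            raise ConfigError("need 0 <= p_floor <= p_high <= 1")
        if self.slope < 0:
            raise ConfigError("slope must be >= 0")
        if not 0 <= self.miss_rate < 1:
            raise ConfigError("miss_rate must lie in [0, 1)")

    def capacity_for(self, exercise_type: ExerciseType) -> int:
        if isinstance(self.capacity_level, Mapping):
            try:
                return int(self.capacity_level[exercise_type])
            except KeyError:
                raise ConfigError(
                    f"responder has no capacity for {exercise_type.value}"
                ) from None
        return int(self.capacity_level)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ResponderModel":
        d = dict(d)
        cap = d.get("capacity_level", 4)
        if isinstance(cap, Mapping):
            d["capacity_level"] = {ExerciseType(k): int(v) for k, v in cap.items()}
        return cls(**d)


def answer_probability(
    model: ResponderModel, level: int, exercise_type: ExerciseType | None = None
) -> float:
    """Per-answer correctness probability at a difficulty level."""
    if level < 1:
        raise ConfigError("level must be >= 1")
    if exercise_type is not None:
        capacity = model.capacity_for(exercise_type)
    elif isinstance(model.capacity_level, Mapping):
        raise ConfigError("exercise_type required for a per-exercise capacity map")
    else:
        capacity = int(model.capacity_level)
    if level <= capacity:
        return model.p_high
    return max(model.p_floor, model.p_high - model.slope * (level - capacity))


def _min_correct_for_valid(n_scored: int, threshold_pct: float) -> int:
    """Smallest correct count whose percentage meets the threshold, exactly."""
    t = Fraction(str(threshold_pct))
    return math.ceil(t * n_scored / 100)


def valid_probability(
    model: ResponderModel,
    level: int,
    config: ExerciseConfig,
    thresholds: ValidityThresholds = PROTOCOL_THRESHOLDS,
) -> float:
    """Exact probability that one block at ``level`` comes out valid.

    Each scored position is independently answered (probability
    ``1 − miss_rate``) and then correct with the level's answer
    probability, so the correct count is binomial.
    """
    extype = config.exercise_type
    p = (1.0 - model.miss_rate) * answer_probability(model, level, extype)
    n = config.n_scored
    k_min = _min_correct_for_valid(n, thresholds.for_type(extype))
    if k_min <= 0:
        return 1.0
    return float(stats.binom.sf(k_min - 1, n, p))


# ---------------------------------------------------------------------------
# single block


def _simulate_responses(model, stream, level, rng):
    config = stream.config
    extype = stream.exercise_type
    n_back = 0 if isinstance(config, VsWmConfig) else config.n_back
    scored_refs = stream.items[: len(stream.items) - n_back] if n_back else stream.items
    n = len(scored_refs)
    p = answer_probability(model, level, extype)
    missed = rng.random(n) < model.miss_rate
    correct = rng.random(n) < p
    responses = []
    for j, ref in enumerate(scored_refs):
        if missed[j]:
            responses.append(MISSED)
            continue
        if isinstance(config, VsWmConfig):
            truth = ref
            if correct[j]:
                responses.append(truth)
            else:
                while True:
                    cand = (
                        int(rng.integers(config.grid_rows)),
                        int(rng.integers(config.grid_cols)),
                    )
                    if cand != truth:
                        break
                responses.append(cand)
        elif isinstance(config, OpNbConfig):
            truth = ref[0] + ref[1]
            if correct[j]:
                responses.append(truth)
            else:
                lo, hi = 2 * config.digit_lo, 2 * config.digit_hi
                if lo == hi:  # degenerate span: the only wrong move is e.g. truth±1
                    responses.append(truth + 1)
                else:
                    while True:
                        cand = int(rng.integers(lo, hi + 1))
                        if cand != truth:
                            break
                    responses.append(cand)
        else:  # DNbConfig — answer is (digit button 1-4, cell button 5-8)
            truth = (ref[0], ref[1] + 4)
            if correct[j]:
                responses.append(truth)
            else:
                while True:
                    cand = (int(rng.integers(1, 5)), int(rng.integers(5, 9)))
                    if cand != truth:
                        break
                responses.append(cand)
    return responses


def run_block(
    model: ResponderModel,
    record: ExerciseRecord,
    seed: int,
    timestamp: datetime | None = None,
) -> BlockResult:
    """Execute one record once: generate, answer and *score* the block.

    The result always comes from the exercise scorers, never from counting
    the simulated draws directly.
    """
    config = record.config
    stream = generate_stream(config, seed)
    rng = np.random.default_rng([int(seed), _RESPONSE_STREAM_KEY])
    responses = _simulate_responses(model, stream, record.level, rng)
    kwargs = dict(level=record.level, timestamp=timestamp)
    if isinstance(config, VsWmConfig):
        return score_vswm(stream, responses, **kwargs)
    if isinstance(config, OpNbConfig):
        return score_opnb(stream, responses, config.n_back, **kwargs)
    return score_dnb(stream, responses, config.n_back, **kwargs)


# ---------------------------------------------------------------------------
# closed loop


@dataclass
class History:
    """Everything produced by one simulated training course."""

    patient_id: str
    program: Program
    sessions: list[SessionLog] = field(default_factory=list)
    records: list[ExerciseRecord] = field(default_factory=list)
    raw_lines: list[RawLogLine] = field(default_factory=list)
    final_states: dict[ExerciseType, AdaptiveState] = field(default_factory=dict)

    def max_levels(self) -> dict[ExerciseType, int]:
        out: dict[ExerciseType, int] = {}
        for line in self.raw_lines:
            cur = out.get(line.exercise_type)
            if cur is None or line.level > cur:
                out[line.exercise_type] = line.level
        return out


def run_program(
    model: ResponderModel,
    program: Program,
    starting_records: Mapping[ExerciseType, ExerciseRecord],
    ladders: Mapping[ExerciseType, DifficultyLadder] | None = None,
    thresholds: ValidityThresholds = PROTOCOL_THRESHOLDS,
    seed: int | None = None,
    start_date: date | None = None,
    store: Store | None = None,
) -> History:
    """Run a full training course closed-loop; reproducible from ``seed``.

    Sessions are taken greedily on the first eligible calendar days (the
    default start date is a Monday, so a 5-session week fills Monday to
    Friday).  Within a session each exercise runs blocks until its daily
    time budget is exhausted, counting simulated block time (stimuli × isi);
    at least one block of every exercise is run per session.  The staircase
    is updated after each block and new records are spawned on every level
    change.
    """
    if not starting_records:
        raise ConfigError("starting_records must contain at least one exercise type")
    patient_ids = {r.patient_id for r in starting_records.values()}
    if len(patient_ids) != 1 or None in patient_ids:
        raise StateError("all starting records must be bound to one patient")
    patient_id = patient_ids.pop()
    if ladders is None:
        ladders = protocol_ladders()
    if seed is None:
        seed = model.seed
    if start_date is None:
        start_date = date(2026, 1, 5)  # a Monday: ISO weeks align with program weeks
    master = np.random.default_rng(seed)

    order = [t for t in ExerciseType if t in starting_records]
    states = {t: AdaptiveState(level=starting_records[t].level) for t in order}
    current = dict(starting_records)
    history = History(patient_id=patient_id, program=program,
                      records=list(starting_records.values()))
    if store is not None:
        for rec in starting_records.values():
            store.upsert(rec)
    spawn_counter = 0

    n_scheduled = scheduled_session_count(program)
    day = start_date
    last_day = start_date + timedelta(days=7 * program.duration_weeks)
    while len(history.sessions) < n_scheduled and day < last_day:
        if not session_allowed(history.sessions, day, program, start_date=start_date):
            day += timedelta(days=1)
            continue
        session = SessionLog(patient_id=patient_id, date=day)
        session_offset = 0.0
        for extype in order:
            ladder = ladders[extype]
            budget = program.per_exercise_daily_minutes.get(extype, 0.0) * 60.0
            elapsed = 0.0
            blocks: list[BlockResult] = []
            while not blocks or elapsed + current[extype].config.block_seconds <= budget:
                record = current[extype]
                block_seed = int(master.integers(0, 2**31))
                ts = datetime.combine(day, time(9, 0)) + timedelta(
                    seconds=session_offset + elapsed
                )
                result = run_block(model, record, block_seed, timestamp=ts)
                valid = evaluate_validity(result, thresholds)
                line_args = dict(seed=block_seed, valid=valid, timestamp=ts)
                if store is not None:
                    line = store.log_block(result, record, **line_args)
                else:
                    line = RawLogLine(
                        timestamp=ts.isoformat(),
                        patient_id=patient_id,
                        exercise_type=extype,
                        level=record.level,
                        config=record.config,
                        seed=block_seed,
                        n_correct=result.n_correct,
                        n_incorrect=result.n_incorrect,
                        n_missed=result.n_missed,
                        pct_correct=result.pct_correct,
                        valid=valid,
                    )
                history.raw_lines.append(line)
                blocks.append(result)
                elapsed += record.config.block_seconds

                states[extype] = advance_state(
                    states[extype], valid, floor=1, ceiling=ladder.max_level
                )
                spawned = spawn_record(
                    record,
                    states[extype],
                    ladder,
                    record_id=f"{patient_id}-{extype.value}-auto{spawn_counter:05d}",
                )
                if spawned is not NO_CHANGE:
                    spawn_counter += 1
                    current[extype] = spawned
                    history.records.append(spawned)
                    if store is not None:
                        store.upsert(spawned)
            session.blocks[extype] = blocks
            session_offset += elapsed
        session.total_minutes = session_offset / 60.0
        history.sessions.append(session)
        day += timedelta(days=1)
    history.final_states = dict(states)
    return history


def stationary_level_distribution(
    model: ResponderModel,
    exercise_type: ExerciseType,
    n_blocks: int,
    seed: int,
    ladder: DifficultyLadder | None = None,
    thresholds: ValidityThresholds = PROTOCOL_THRESHOLDS,
    burn_in_fraction: float = 0.1,
):
    """Empirical level occupancy of a long closed-loop run.

    Returns ``(freqs, levels)`` where ``freqs`` maps level → relative
    frequency over the blocks after burn-in (first 10% by default) and
    ``levels`` is the full post-burn-in level trajectory (useful for
    Monte-Carlo error estimates that respect autocorrelation).
    """
    if n_blocks < 1:
        raise ConfigError("n_blocks must be >= 1")
    if ladder is None:
        ladder = protocol_ladder(exercise_type)
    master = np.random.default_rng(seed)
    state = AdaptiveState(level=1)
    record = ExerciseRecord(
        record_id="sim-start",
        exercise_type=exercise_type,
        config=ladder.base_config,
        level=1,
        patient_id="sim",
    )
    trajectory = np.empty(n_blocks, dtype=int)
    for i in range(n_blocks):
        block_seed = int(master.integers(0, 2**31))
        result = run_block(model, record, block_seed)
        valid = evaluate_validity(result, thresholds)
        trajectory[i] = record.level
        state = advance_state(state, valid, floor=1, ceiling=ladder.max_level)
        spawned = spawn_record(record, state, ladder, record_id="sim")
        if spawned is not NO_CHANGE:
            record = spawned
    burn = int(n_blocks * burn_in_fraction)
    tail = trajectory[burn:]
    counts = Counter(tail.tolist())
    total = len(tail)
    freqs = {lvl: c / total for lvl, c in sorted(counts.items())}
    return freqs, tail


# ---------------------------------------------------------------------------
# exact (level, streak) Markov chain


def level_valid_probabilities(
    model: ResponderModel,
    ladder: DifficultyLadder,
    thresholds: ValidityThresholds = PROTOCOL_THRESHOLDS,
    max_level: int | None = None,
) -> np.ndarray:
    """P(valid) at each ladder level 1..L for a responder model."""
    from .adaptive import config_at_level

    if max_level is None:
        max_level = ladder.max_level
    if max_level is None:
        raise ConfigError("max_level required for an unbounded ladder")
    return np.array(
        [
            valid_probability(model, lvl, config_at_level(ladder, lvl), thresholds)
            for lvl in range(1, max_level + 1)
        ]
    )


def exact_stationary_levels(p_valid: np.ndarray) -> np.ndarray:
    """Exact stationary level distribution of the staircase Markov chain.

    The chain's states are ``(level, invalid_streak)`` with levels 1..L
    (``L = len(p_valid)``, a reflecting ceiling) and streaks 0..2.  A valid
    block (probability ``p_valid[level-1]``) moves to ``(min(level+1, L),
    0)``; an invalid block raises the streak, and from streak 2 drops to
    ``(max(level-1, 1), 0)``.  The stationary vector solves ``πP = π``; the
    returned array is the level marginal (index 0 ↔ level 1).
    """
    p_valid = np.asarray(p_valid, dtype=float)
    L = len(p_valid)
    if L < 1:
        raise ConfigError("need at least one level")
    if np.any((p_valid < 0) | (p_valid > 1)):
        raise ConfigError("probabilities must lie in [0, 1]")
    n = 3 * L

    def idx(level: int, streak: int) -> int:
        return 3 * (level - 1) + streak

    P = np.zeros((n, n))
    for level in range(1, L + 1):
        p = p_valid[level - 1]
        up = min(level + 1, L)
        down = max(level - 1, 1)
        for streak in range(3):
            i = idx(level, streak)
            P[i, idx(up, 0)] += p
            if streak < 2:
                P[i, idx(level, streak + 1)] += 1.0 - p
            else:
                P[i, idx(down, 0)] += 1.0 - p
    # solve pi (P - I) = 0 with sum(pi) = 1
    A = np.vstack([(P - np.eye(n)).T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    return pi.reshape(L, 3).sum(axis=1)
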