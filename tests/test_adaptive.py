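"""Tests for the validity staircase and the difficulty ladder."""

import itertools

import numpy as np
import pytest

from wmtrain import (
    AdaptiveState,
    BlockResult,
    ConfigError,
    ExerciseType,
    NO_CHANGE,
    StateError,
    ValidityThresholds,
    advance_state,
    config_at_level,
    evaluate_validity,
    protocol_ladder,
    spawn_record,
    starting_record,
)
from wmtrain.responder import exact_stationary_levels


def _result(extype, pct):
    """A BlockResult carrying an arbitrary percent (validity reads only pct)."""
    return BlockResult(
        exercise_type=extype, n_correct=1, n_incorrect=0, n_missed=0,
        pct_correct=pct, level=1,
    )


@pytest.mark.parametrize(
    "extype,pct,expected",
    [
        (ExerciseType.VS_WM, 100.0, True),
        (ExerciseType.VS_WM, 99.9, False),
        (ExerciseType.OP_NB, 80.0, True),
        (ExerciseType.OP_NB, 79.9, False),
        (ExerciseType.D_NB, 75.0, True),
        (ExerciseType.D_NB, 0.0, False),
    ],
)
def test_validity_thresholds(extype, pct, expected, protocol_thresholds):
    assert evaluate_validity(_result(extype, pct), protocol_thresholds) is expected


def test_threshold_invariants():
    with pytest.raises(ConfigError):
        ValidityThresholds(vs_wm=0.0)
    with pytest.raises(ConfigError):
        ValidityThresholds(op_nb=101.0)


def test_advance_state_rules():
    assert advance_state(AdaptiveState(3, 0), True) == AdaptiveState(4, 0)
    assert advance_state(AdaptiveState(3, 0), False) == AdaptiveState(3, 1)
    assert advance_state(AdaptiveState(3, 1), False) == AdaptiveState(3, 2)
    assert advance_state(AdaptiveState(3, 2), False) == AdaptiveState(2, 0)
    # valid resets the invalid streak
    assert advance_state(AdaptiveState(3, 2), True) == AdaptiveState(4, 0)
    # floor: difficulty never drops below the easiest rung
    assert advance_state(AdaptiveState(1, 2), False) == AdaptiveState(1, 0)
    # ceiling clamps a bounded ladder
    assert advance_state(AdaptiveState(11, 0), True, ceiling=11) == AdaptiveState(11, 0)


def _replay(outcomes, start_level=1):
    state = AdaptiveState(level=start_level)
    levels = []
    for valid in outcomes:
        state = advance_state(state, valid)
        levels.append(state.level)
    return levels


def _oracle_level(outcomes, start_level):
    """Closed-form level: +1 per valid, -1 per completed triple of a
    maximal run of consecutive invalids (floor not binding)."""
    level = start_level + sum(outcomes)
    run = 0
    for valid in outcomes:
        if valid:
            run = 0
        else:
            run += 1
            if run == 3:
                level -= 1
                run = 0
    return level


def test_staircase_replay_matches_brute_force_oracle():
    """All valid/invalid strings of length <= 12, away from the floor."""
    start = 20  # floor can never bind within 12 steps
    for length in range(1, 13):
        for outcomes in itertools.product([True, False], repeat=length):
            levels = _replay(outcomes, start)
            for t in range(length):
                assert levels[t] == _oracle_level(outcomes[: t + 1], start)
            # trajectory moves by at most one level per block
            path = [start] + levels
            assert all(abs(b - a) <= 1 for a, b in zip(path, path[1:]))


def test_staircase_floor_pins_all_invalid_runs():
    levels = _replay([False] * 9, start_level=2)
    assert levels == [2, 2, 1, 1, 1, 1, 1, 1, 1]
    assert min(levels) >= 1


def test_constant_p_chain_matches_exact_stationary_distribution():
    """Direct staircase simulation with P(valid)=p agrees with the exact
    (level, streak) Markov chain within 3 SD of the batch-means MC error."""
    p, n_levels, n_steps = 0.3, 5, 20_000
    rng = np.random.default_rng(42)
    state = AdaptiveState(1, 0)
    levels = np.empty(n_steps, dtype=int)
    for i in range(n_steps):
        state = advance_state(state, bool(rng.random() < p), ceiling=n_levels)
        levels[i] = state.level
    tail = levels[n_steps // 10:]
    pi = exact_stationary_levels(np.full(n_levels, p))
    batches = tail[: len(tail) // 100 * 100].reshape(-1, 100)
    for lvl in range(1, n_levels + 1):
        freq = np.mean(tail == lvl)
        batch_means = (batches == lvl).mean(axis=1)
        se = batch_means.std(ddof=1) / np.sqrt(len(batch_means))
        assert abs(freq - pi[lvl - 1]) <= 3 * se + 1e-3


# ---------------------------------------------------------------------------
# ladder


def test_vswm_ladder_rate_then_length():
    ladder = protocol_ladder(ExerciseType.VS_WM)
    c5 = config_at_level(ladder, 5)
    assert (c5.isi, c5.sequence_length) == (1.0, 3)
    c6 = config_at_level(ladder, 6)
    assert (c6.isi, c6.sequence_length) == (1.0, 4)
    c1 = config_at_level(ladder, 1)
    assert (c1.isi, c1.sequence_length, c1.grid_rows) == (2.0, 3, 3)


def test_opnb_ladder_rate_then_nback_with_protocol_block_length():
    ladder = protocol_ladder(ExerciseType.OP_NB)
    c4 = config_at_level(ladder, 4)
    assert (c4.isi, c4.n_back, c4.stimulus_count) == (3.0, 0, 5)
    c5 = config_at_level(ladder, 5)
    assert (c5.isi, c5.n_back, c5.stimulus_count) == (3.0, 1, 10)


def test_successive_levels_differ_in_exactly_one_independent_parameter():
    """Only isi or the task parameter moves per level; n-back block length
    is derived from N and does not count."""
    for extype in ExerciseType:
        ladder = protocol_ladder(extype)
        top = ladder.max_level or 10
        for lvl in range(1, top):
            a = config_at_level(ladder, lvl)
            b = config_at_level(ladder, lvl + 1)
            if extype is ExerciseType.VS_WM:
                fields = ("isi", "sequence_length", "grid_rows", "grid_cols")
            elif extype is ExerciseType.OP_NB:
                fields = ("isi", "n_back", "digit_lo", "digit_hi")
            else:
                fields = ("isi", "n_back")
            changed = [f for f in fields if getattr(a, f) != getattr(b, f)]
            assert len(changed) == 1, (extype, lvl, changed)


def test_vswm_ladder_is_bounded_by_the_fixed_grid():
    ladder = protocol_ladder(ExerciseType.VS_WM)
    assert ladder.max_level == 11  # 5 rate steps + (9 - 3) extra stimuli
    top = config_at_level(ladder, 11)
    assert top.sequence_length == 9
    with pytest.raises(ConfigError):
        config_at_level(ladder, 12)


def test_vswm_grow_grid_variant_is_unbounded():
    ladder = protocol_ladder(ExerciseType.VS_WM, grow_grid=True)
    assert ladder.max_level is None
    c12 = config_at_level(ladder, 12)
    assert c12.sequence_length == 10
    assert c12.grid_rows * c12.grid_cols >= 10


def test_config_at_level_rejects_levels_below_one():
    ladder = protocol_ladder(ExerciseType.D_NB)
    with pytest.raises(ConfigError):
        config_at_level(ladder, 0)


# ---------------------------------------------------------------------------
# record spawning


def test_spawn_record_on_level_change_binds_patient_and_parent():
    ladder = protocol_ladder(ExerciseType.OP_NB)
    prev = starting_record(ExerciseType.OP_NB, patient_id="p1")
    rec = spawn_record(prev, AdaptiveState(level=2), ladder)
    assert rec is not NO_CHANGE
    assert rec.patient_id == "p1"
    assert rec.auto_generated
    assert rec.parent_record_id == prev.record_id
    assert rec.config == config_at_level(ladder, 2)


def test_spawn_record_reuses_previous_when_level_holds():
    ladder = protocol_ladder(ExerciseType.D_NB)
    prev = starting_record(ExerciseType.D_NB, patient_id="p1")
    assert spawn_record(prev, AdaptiveState(level=1, invalid_streak=1), ladder) is NO_CHANGE


def test_spawn_record_requires_an_assigned_record():
    ladder = protocol_ladder(ExerciseType.VS_WM)
    prev = starting_record(ExerciseType.VS_WM, patient_id=None)
    with pytest.raises(StateError):
        spawn_record(prev, AdaptiveState(level=2), ladder)
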