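"""Unit and property tests for stimulus generation and scoring."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from wmtrain import (
    ConfigError,
    DNbConfig,
    ExerciseType,
    InputError,
    MISSED,
    OpNbConfig,
    VsWmConfig,
    generate_dnb_stream,
    generate_opnb_stream,
    generate_stream,
    generate_vswm_stream,
    required_stimulus_count,
    score_dnb,
    score_opnb,
    score_vswm,
)

# ---------------------------------------------------------------------------
# configs


def test_vswm_config_rejects_sequences_longer_than_the_grid():
    with pytest.raises(ConfigError):
        VsWmConfig(grid_rows=2, grid_cols=2, sequence_length=5)


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(grid_rows=1),
        dict(sequence_length=0),
        dict(isi=0.0),
        dict(isi=-1.0),
    ],
)
def test_vswm_config_invariants(kwargs):
    with pytest.raises(ConfigError):
        VsWmConfig(**kwargs)


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(digit_lo=0),
        dict(digit_hi=10),
        dict(digit_lo=5, digit_hi=3),
        dict(n_back=-1),
        dict(n_back=5, stimulus_count=5),  # no scorable position
    ],
)
def test_opnb_config_invariants(kwargs):
    with pytest.raises(ConfigError):
        OpNbConfig(**kwargs)


def test_nback_protocol_stimulus_counts():
    assert required_stimulus_count(2) == 15
    assert required_stimulus_count(0) == 5
    assert required_stimulus_count(4) == 25
    with pytest.raises(ConfigError):
        required_stimulus_count(-1)
    assert OpNbConfig.protocol(n_back=2, isi=3.0).stimulus_count == 15
    assert DNbConfig.protocol(n_back=1, isi=3.0).stimulus_count == 10


# ---------------------------------------------------------------------------
# generators


@pytest.mark.parametrize(
    "config",
    [
        VsWmConfig(grid_rows=3, grid_cols=3, sequence_length=5, isi=1.5),
        OpNbConfig(n_back=1, stimulus_count=10, isi=3.0),
        DNbConfig(n_back=2, stimulus_count=15, isi=3.0),
    ],
)
def test_generators_are_deterministic_under_a_fixed_seed(config):
    a = generate_stream(config, 7)
    b = generate_stream(config, 7)
    c = generate_stream(config, 8)
    assert a.items == b.items
    assert a.items != c.items


def test_vswm_full_grid_sequence_is_a_permutation():
    config = VsWmConfig(grid_rows=2, grid_cols=2, sequence_length=4)
    for seed in range(20):
        stream = generate_vswm_stream(config, seed)
        assert sorted(stream.items) == [(0, 0), (0, 1), (1, 0), (1, 1)]


def test_vswm_cells_are_not_repeated_within_a_sequence():
    config = VsWmConfig(grid_rows=3, grid_cols=3, sequence_length=7)
    for seed in range(20):
        stream = generate_vswm_stream(config, seed)
        assert len(set(stream.items)) == len(stream.items)


def test_vswm_single_stimulus_frequencies_are_uniform():
    """Each of the 9 cells appears with frequency within 3 SD of 1/9."""
    config = VsWmConfig(grid_rows=3, grid_cols=3, sequence_length=1)
    n = 10_000
    counts = {}
    for seed in range(n):
        (cell,) = generate_vswm_stream(config, seed).items
        counts[cell] = counts.get(cell, 0) + 1
    p = 1 / 9
    sd = np.sqrt(p * (1 - p) / n)
    for cell in [(r, c) for r in range(3) for c in range(3)]:
        assert abs(counts.get(cell, 0) / n - p) < 3 * sd


def test_dnb_item_frequencies_are_uniform():
    """Digits and cells each uniform on 1..4 over ~10,000 generated items."""
    config = DNbConfig(n_back=0, stimulus_count=100, isi=3.0)
    digits = []
    cells = []
    for seed in range(100):
        for d, c in generate_dnb_stream(config, seed).items:
            digits.append(d)
            cells.append(c)
    n = len(digits)
    assert n == 10_000
    p = 0.25
    sd = np.sqrt(p * (1 - p) / n)
    for v in (1, 2, 3, 4):
        assert abs(digits.count(v) / n - p) < 3 * sd
        assert abs(cells.count(v) / n - p) < 3 * sd


def test_dnb_items_lie_in_the_stimulus_space():
    config = DNbConfig(n_back=1, stimulus_count=10, isi=3.0)
    for seed in range(10):
        for digit, cell in generate_dnb_stream(config, seed).items:
            assert digit in (1, 2, 3, 4)
            assert cell in (1, 2, 3, 4)


def test_opnb_full_span_sums_lie_in_2_to_18():
    config = OpNbConfig(n_back=0, stimulus_count=50, isi=3.0)
    sums = [a + b for seed in range(20) for a, b in generate_opnb_stream(config, seed).items]
    assert min(sums) >= 2
    assert max(sums) <= 18


def test_opnb_degenerate_span_yields_constant_pairs():
    config = OpNbConfig(n_back=0, digit_lo=3, digit_hi=3, stimulus_count=10, isi=3.0)
    stream = generate_opnb_stream(config, 1)
    assert set(stream.items) == {(3, 3)}
    assert {a + b for a, b in stream.items} == {6}


# ---------------------------------------------------------------------------
# scorers


def _vswm_stream(items, grid=(3, 3)):
    config = VsWmConfig(grid_rows=grid[0], grid_cols=grid[1], sequence_length=len(items))
    stream = generate_vswm_stream(config, 0)
    return type(stream)(ExerciseType.VS_WM, tuple(items), 0, config)


def test_vswm_scoring_identity_and_mixed_and_missed():
    a, b, c, d, x = (0, 0), (0, 1), (1, 0), (1, 1), (2, 2)
    r = score_vswm(_vswm_stream([a, b]), [a, b])
    assert (r.n_correct, r.n_incorrect, r.n_missed, r.pct_correct) == (2, 0, 0, 100.0)
    r = score_vswm(_vswm_stream([a, b, c, d]), [a, b, x, MISSED])
    assert (r.n_correct, r.n_incorrect, r.n_missed, r.pct_correct) == (2, 1, 1, 50.0)
    r = score_vswm(_vswm_stream([a]), [MISSED])
    assert (r.n_correct, r.n_missed, r.pct_correct) == (0, 1, 0.0)


def test_vswm_right_cell_wrong_order_is_incorrect():
    a, b = (0, 0), (0, 1)
    r = score_vswm(_vswm_stream([a, b]), [b, a])
    assert (r.n_correct, r.n_incorrect) == (0, 2)


def test_vswm_scoring_rejects_mismatched_lengths():
    with pytest.raises(InputError):
        score_vswm(_vswm_stream([(0, 0), (0, 1)]), [(0, 0)])


def _opnb_stream(pairs, n_back):
    config = OpNbConfig(n_back=n_back, stimulus_count=len(pairs), isi=3.0)
    stream = generate_opnb_stream(config, 0)
    return type(stream)(ExerciseType.OP_NB, tuple(pairs), 0, config)


def test_opnb_scoring_examples():
    r = score_opnb(_opnb_stream([(1, 4)], 0), [5], 0)
    assert (r.n_correct, r.pct_correct) == (1, 100.0)
    # N=1: answers refer to the stimulus one back
    r = score_opnb(_opnb_stream([(1, 4), (2, 3), (5, 2)], 1), [5, 5], 1)
    assert (r.n_correct, r.pct_correct) == (2, 100.0)
    r = score_opnb(_opnb_stream([(1, 4), (2, 3)], 1), [MISSED], 1)
    assert (r.n_correct, r.n_missed, r.pct_correct) == (0, 1, 0.0)


def test_opnb_scoring_rejects_unscorable_nback():
    stream = _opnb_stream([(1, 4), (2, 3)], 1)
    with pytest.raises(ConfigError):
        score_opnb(stream, [], 2)


def _dnb_stream(items, n_back):
    config = DNbConfig(n_back=n_back, stimulus_count=len(items), isi=3.0)
    stream = generate_dnb_stream(config, 0)
    return type(stream)(ExerciseType.D_NB, tuple(items), 0, config)


def test_dnb_both_buttons_must_match():
    # stimulus: digit 3 in the 2nd cell; cell button 6 is the 2nd cell
    r = score_dnb(_dnb_stream([(3, 2)], 0), [(3, 6)], 0)
    assert (r.n_correct, r.pct_correct) == (1, 100.0)
    r = score_dnb(_dnb_stream([(3, 2)], 0), [(3, 7)], 0)  # cell wrong
    assert (r.n_correct, r.n_incorrect) == (0, 1)
    r = score_dnb(_dnb_stream([(3, 2)], 0), [(2, 6)], 0)  # digit wrong
    assert (r.n_correct, r.n_incorrect) == (0, 1)


def test_dnb_one_back_example():
    r = score_dnb(_dnb_stream([(1, 1), (2, 2)], 1), [(1, 5)], 1)
    assert (r.n_correct, r.pct_correct) == (1, 100.0)


@pytest.mark.parametrize("answer", [(0, 5), (5, 5), (1, 4), (1, 9)])
def test_dnb_rejects_buttons_outside_their_legal_sets(answer):
    with pytest.raises(InputError):
        score_dnb(_dnb_stream([(1, 1)], 0), [answer], 0)


# ---------------------------------------------------------------------------
# properties


@given(st.data())
def test_scorers_conserve_counts_and_recompute_pct(data):
    """n_correct + n_incorrect + n_missed = scored positions, pct exact."""
    extype = data.draw(st.sampled_from(list(ExerciseType)))
    if extype is ExerciseType.VS_WM:
        rows = data.draw(st.integers(2, 3))
        cols = data.draw(st.integers(2, 3))
        seq = data.draw(st.integers(1, rows * cols))
        config = VsWmConfig(grid_rows=rows, grid_cols=cols, sequence_length=seq)
        stream = generate_vswm_stream(config, data.draw(st.integers(0, 10**6)))
        cell = st.tuples(st.integers(0, rows - 1), st.integers(0, cols - 1))
        responses = data.draw(
            st.lists(st.one_of(st.just(MISSED), cell), min_size=seq, max_size=seq)
        )
        result = score_vswm(stream, responses)
        scored = seq
    elif extype is ExerciseType.OP_NB:
        count = data.draw(st.integers(2, 8))
        n_back = data.draw(st.integers(0, count - 1))
        config = OpNbConfig(n_back=n_back, stimulus_count=count, isi=3.0)
        stream = generate_opnb_stream(config, data.draw(st.integers(0, 10**6)))
        scored = count - n_back
        responses = data.draw(
            st.lists(
                st.one_of(st.just(MISSED), st.integers(2, 18)),
                min_size=scored,
                max_size=scored,
            )
        )
        result = score_opnb(stream, responses, n_back)
    else:
        count = data.draw(st.integers(2, 8))
        n_back = data.draw(st.integers(0, count - 1))
        config = DNbConfig(n_back=n_back, stimulus_count=count, isi=3.0)
        stream = generate_dnb_stream(config, data.draw(st.integers(0, 10**6)))
        scored = count - n_back
        answer = st.tuples(st.integers(1, 4), st.integers(5, 8))
        responses = data.draw(
            st.lists(st.one_of(st.just(MISSED), answer), min_size=scored, max_size=scored)
        )
        result = score_dnb(stream, responses, n_back)
    assert result.n_correct + result.n_incorrect + result.n_missed == scored
    assert result.pct_correct == 100.0 * result.n_correct / scored
    assert 0.0 <= result.pct_correct <= 100.0


def test_opnb_sum_domain_is_exhaustively_2_to_18():
    sums = {a + b for a, b in itertools.product(range(1, 10), repeat=2)}
    assert min(sums) == 2
    assert max(sums) == 18
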