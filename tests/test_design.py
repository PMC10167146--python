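"""Design-generator contracts: timing grid, sequence constraints, balance."""

from collections import Counter

import numpy as np
import pytest

from pdec.design import (BLOCK_LENGTHS, OPPOSITE, STEP, generate_arithmetic_block,
                         generate_design, generate_visuospatial_block,
                         sample_isi, simulate_behavioral_responses)


def test_isi_on_grid_and_mean_4s(rng):
    draws = np.array([sample_isi(rng) for _ in range(100_000)])
    assert draws.min() >= 3600 and draws.max() <= 4400
    assert (draws % 100 == 0).all()
    assert abs(draws.mean() - 4000) < 10


def test_isi_deterministic_under_seed():
    a = [sample_isi(np.random.default_rng(3)) for _ in range(50)]
    b = [sample_isi(np.random.default_rng(3)) for _ in range(50)]
    assert a == b


def _replay_arithmetic(start, cues, load):
    value = start
    for c in cues:
        value = value + int(c) if load == "low" else value - int(c)
        assert 10 < value < 100
    return value


@pytest.mark.parametrize("load,ops,start_range", [
    ("low", {1, 2}, range(10, 41)),
    ("high", {3, 4}, range(65, 100)),
])
def test_arithmetic_blocks_obey_constraints(rng, load, ops, start_range):
    """Independent replay of 300 dual blocks: ranges, operand sets, answers."""
    for _ in range(300):
        n = int(rng.integers(9, 12))
        blk = generate_arithmetic_block(load, rng, n_trials=n)
        start = int(blk.starting_stimulus)
        assert start in start_range
        cues = [t.cue_label for t in blk.trials]
        assert {int(c) for c in cues} <= ops
        assert _replay_arithmetic(start, cues, load) == blk.correct_final_answer
        onsets = [t.cue_onset_ms for t in blk.trials]
        assert all(b > a for a, b in zip(onsets, onsets[1:]))
        assert all(3600 <= t.isi_ms <= 4400 and t.operation_period_ms >= 3000
                   for t in blk.trials)


def test_arithmetic_single_block_has_no_answer(rng):
    blk = generate_arithmetic_block("single", rng)
    assert blk.starting_stimulus == "XX"
    assert blk.correct_final_answer is None


def _replay_visuospatial(start, cues, size):
    cell, prev = start, None
    for c in cues:
        assert prev is None or c != OPPOSITE[prev]
        cell = (cell[0] + STEP[c][0], cell[1] + STEP[c][1])
        assert 0 <= cell[0] < size and 0 <= cell[1] < size
        prev = c
    return cell


@pytest.mark.parametrize("load,size", [("low", 3), ("high", 4)])
def test_visuospatial_blocks_obey_constraints(rng, load, size):
    """Independent replay of 300 blocks: border, reversal, final cell."""
    for _ in range(300):
        blk = generate_visuospatial_block(load, rng,
                                          n_trials=int(rng.integers(9, 12)))
        assert blk.matrix_size == size
        r, c = int(blk.starting_stimulus[1]), int(blk.starting_stimulus[3])
        cues = [t.cue_label for t in blk.trials]
        assert _replay_visuospatial((r, c), cues, size) == blk.correct_final_answer


def test_visuospatial_single_blocks_split_matrix_sizes(rng):
    sizes = [generate_visuospatial_block("single", rng, single_size=s).matrix_size
             for s in (3, 4, 3, 4)]
    assert sizes == [3, 4, 3, 4]
    blk = generate_visuospatial_block("single", rng, single_size=3)
    assert blk.starting_stimulus == "empty"
    assert blk.correct_final_answer is None


def test_design_balance_and_totals():
    design = generate_design(participant_id=1, seed=11)
    cells = Counter((b.modality, b.load) for b in design.blocks)
    assert all(v == 10 for v in cells.values()) and len(cells) == 6
    assert design.n_trials == 600
    per_modality = Counter()
    for b in design.blocks:
        per_modality[b.modality] += b.n_trials
    assert per_modality == {"arithmetic": 300, "visuospatial": 300}
    assert sum(BLOCK_LENGTHS) == 100


def test_design_deterministic_and_counterbalanced():
    d1 = generate_design(0, 42)
    d2 = generate_design(0, 42)
    assert [b.block_id for b in d1.blocks] == [b.block_id for b in d2.blocks]
    assert [t.cue_label for b in d1.blocks for t in b.trials] == \
           [t.cue_label for b in d2.blocks for t in b.trials]
    assert generate_design(0, 1).task_order != generate_design(1, 1).task_order


def test_behavioral_responses_match_binomial_rates(rng):
    design = generate_design(0, 5)
    rates = {(m, l): r for m in ("arithmetic", "visuospatial")
             for l, r in (("low", 0.0), ("high", 1.0))}
    ans = simulate_behavioral_responses(design, rates, rng)
    assert ans.loc[ans["load"] == "low", "correct"].all()
    assert not ans.loc[ans["load"] == "high", "correct"].any()
    # stochastic rate: pool many independent response draws
    rates = {(m, l): 0.2 for m in ("arithmetic", "visuospatial")
             for l in ("low", "high")}
    outcomes = []
    for _ in range(250):
        outcomes.append(simulate_behavioral_responses(design, rates, rng)["correct"])
    acc = np.concatenate(outcomes).mean()
    assert abs(acc - 0.8) < 0.01
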