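"""Experimental-design generation for the dual-task pursuit paradigm.

The schedule is a 2 (internal-task modality: arithmetic, visuospatial) x 3
(workload: single, low, high) within-subject design. Each modality comprises
30 blocks (10 per workload level) of 9-11 trials; a trial is one internal
operation, announced by a 600-ms auditory cue and followed by a 3-3.8-s
operation period, so trial onsets are spaced 3.6-4.4 s apart (0.1-s grid,
4 s on average).

Arithmetic blocks present numeric cues: low workload starts at 10-40 and adds
1 or 2 per trial, high workload starts at 65-99 and subtracts 3 or 4, with
every running result kept strictly between 10 and 100. Visuospatial blocks
move a patch through a 3x3 (low) or 4x4 (high) matrix with direction cues that
never cross the border and never immediately reverse the previous cue.
Single-task (control) blocks present the same cue streams but they are to be
ignored: arithmetic control replaces the starting number with "XX",
visuospatial control shows an empty matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CUE_DURATION_MS = 600
ISI_GRID_MS = np.arange(3600, 4401, 100)
DIRECTIONS = ("left", "right", "up", "down")
OPPOSITE = {"left": "right", "right": "left", "up": "down", "down": "up"}
#: (drow, dcol) with 'up' decreasing the row index (rows counted from the top).
STEP = {"left": (0, -1), "right": (0, 1), "up": (-1, 0), "down": (1, 0)}

#: Block lengths for the 10 blocks of one workload level; sums to 100 trials
#: so that the 3 levels x 10 blocks of a modality total exactly 300 trials.
BLOCK_LENGTHS = (9, 9, 9, 10, 10, 10, 10, 11, 11, 11)

_MAX_RETRIES = 1000


class GenerationError(RuntimeError):
    """Raised when a block satisfying the constraints cannot be sampled."""


@dataclass
class TrialSpec:
    trial_index: int
    cue_label: str
    cue_onset_ms: int
    isi_ms: int
    cue_duration_ms: int = CUE_DURATION_MS

    @property
    def operation_period_ms(self) -> int:
        return self.isi_ms - self.cue_duration_ms


@dataclass
class BlockSpec:
    block_id: str
    modality: str                      # 'arithmetic' | 'visuospatial'
    load: str                          # 'single' | 'low' | 'high'
    starting_stimulus: str
    trials: list[TrialSpec]
    matrix_size: int | None = None     # visuospatial only
    correct_final_answer: int | tuple[int, int] | None = None  # dual only

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def duration_ms(self) -> int:
        last = self.trials[-1]
        return last.cue_onset_ms + last.isi_ms


@dataclass
class ExperimentDesign:
    participant_id: int
    seed: int
    task_order: tuple[str, str]
    blocks: list[BlockSpec] = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return sum(b.n_trials for b in self.blocks)


def sample_isi(rng: np.random.Generator) -> int:
    """One inter-trial-onset interval: uniform over {3600, 3700, ..., 4400} ms."""
    return int(rng.choice(ISI_GRID_MS))


def _timed_trials(cue_labels: list[str], rng: np.random.Generator) -> list[TrialSpec]:
    trials, onset = [], 0
    for i, label in enumerate(cue_labels):
        isi = sample_isi(rng)
        trials.append(TrialSpec(trial_index=i, cue_label=str(label),
                                cue_onset_ms=onset, isi_ms=isi))
        onset += isi
    return trials


def _arithmetic_cues(style: str, n_trials: int, rng: np.random.Generator):
    """Sample a start number and operand sequence obeying the 10 < result < 100
    running constraint; returns (start, cues, final)."""
    lo, hi, ops = ((10, 40), None, (1, 2)) if style == "low" else (None, (65, 99), (3, 4))
    for _ in range(_MAX_RETRIES):
        start = int(rng.integers(10, 41)) if style == "low" else int(rng.integers(65, 100))
        value, cues, ok = start, [], True
        for _ in range(n_trials):
            for _ in range(_MAX_RETRIES):
                op = int(rng.choice(ops))
                nxt = value + op if style == "low" else value - op
                if 10 < nxt < 100:
                    break
            else:
                ok = False
                break
            cues.append(str(op))
            value = nxt
        if ok:
            return start, cues, value
    raise GenerationError(f"could not build a valid {style} arithmetic block")


def generate_arithmetic_block(load: str, rng: np.random.Generator,
                              n_trials: int = 10, block_id: str = "a0",
                              single_style: str | None = None) -> BlockSpec:
    """One arithmetic block. Dual blocks carry the running result as the
    correct final answer; control blocks reuse a low- or high-style cue stream
    (``single_style``) with starting stimulus "XX" and no answer."""
    if load not in ("single", "low", "high"):
        raise ValueError(f"unknown load {load!r}")
    if load == "single":
        style = single_style or ("low", "high")[int(rng.integers(2))]
        _, cues, _ = _arithmetic_cues(style, n_trials, rng)
        return BlockSpec(block_id, "arithmetic", "single", "XX",
                         _timed_trials(cues, rng))
    start, cues, final = _arithmetic_cues(load, n_trials, rng)
    return BlockSpec(block_id, "arithmetic", load, str(start),
                     _timed_trials(cues, rng), correct_final_answer=final)


def _legal_moves(cell: tuple[int, int], prev: str | None, size: int) -> list[str]:
    moves = []
    for d in DIRECTIONS:
        if prev is not None and d == OPPOSITE[prev]:
            continue
        r, c = cell[0] + STEP[d][0], cell[1] + STEP[d][1]
        if 0 <= r < size and 0 <= c < size:
            moves.append(d)
    return moves


def _visuospatial_cues(size: int, n_trials: int, rng: np.random.Generator):
    for _ in range(_MAX_RETRIES):
        cell = (int(rng.integers(size)), int(rng.integers(size)))
        start, cues, prev = cell, [], None
        for _ in range(n_trials):
            moves = _legal_moves(cell, prev, size)
            if not moves:        # dead end: resample the whole block
                break
            d = str(rng.choice(moves))
            cues.append(d)
            cell = (cell[0] + STEP[d][0], cell[1] + STEP[d][1])
            prev = d
        else:
            return start, cues, cell
    raise GenerationError("could not build a valid visuospatial cue sequence")


def generate_visuospatial_block(load: str, rng: np.random.Generator,
                                n_trials: int = 10, block_id: str = "v0",
                                single_size: int | None = None) -> BlockSpec:
    """One visuospatial block: 3x3 matrix under low, 4x4 under high workload.
    Control blocks show an empty matrix (``single_size`` 3 or 4) with cues to
    be ignored. Dual blocks carry the end cell as the correct final answer."""
    if load not in ("single", "low", "high"):
        raise ValueError(f"unknown load {load!r}")
    size = {"low": 3, "high": 4}.get(load) or single_size or (3, 4)[int(rng.integers(2))]
    start, cues, end = _visuospatial_cues(size, n_trials, rng)
    if load == "single":
        return BlockSpec(block_id, "visuospatial", "single", "empty",
                         _timed_trials(cues, rng), matrix_size=size)
    return BlockSpec(block_id, "visuospatial", load, f"r{start[0]}c{start[1]}",
                     _timed_trials(cues, rng), matrix_size=size,
                     correct_final_answer=end)


def generate_design(participant_id: int, seed: int) -> ExperimentDesign:
    """The full 2 x 3 within-subject schedule for one participant.

    Per modality: 10 blocks per workload level, block lengths drawn from
    :data:`BLOCK_LENGTHS` (balanced to 100 trials per level, hence 300 per
    modality and 600 overall), block order randomized within modality, trial
    order fixed within block. Task order alternates by participant parity.
    Control blocks split evenly: arithmetic controls reuse 5 low-style and 5
    high-style cue streams; visuospatial controls show 5 empty 3x3 and 5
    empty 4x4 matrices.
    """
    rng = np.random.default_rng(seed)
    order = ("arithmetic", "visuospatial") if participant_id % 2 == 0 else \
            ("visuospatial", "arithmetic")
    design = ExperimentDesign(participant_id, seed, order)
    for modality in order:
        blocks = []
        for load in ("single", "low", "high"):
            lengths = list(BLOCK_LENGTHS)
            rng.shuffle(lengths)
            for j, n in enumerate(lengths):
                bid = f"p{participant_id}_{modality[0]}_{load}_{j}"
                style_or_size = ("low", "high")[j % 2] if modality == "arithmetic" else (3, 4)[j % 2]
                if modality == "arithmetic":
                    blk = generate_arithmetic_block(
                        load, rng, n_trials=n, block_id=bid,
                        single_style=style_or_size if load == "single" else None)
                else:
                    blk = generate_visuospatial_block(
                        load, rng, n_trials=n, block_id=bid,
                        single_size=style_or_size if load == "single" else None)
                blocks.append(blk)
        idx = rng.permutation(len(blocks))
        design.blocks.extend(blocks[i] for i in idx)
    return design


def simulate_behavioral_responses(design: ExperimentDesign,
                                  error_rate_by_condition: dict[tuple[str, str], float],
                                  rng: np.random.Generator,
                                  missing_if_wrong: float = 0.3) -> pd.DataFrame:
    """Draw a final-answer outcome for every dual block.

    Each dual block is answered correctly with probability ``1 - error_rate``
    for its (modality, load) cell; an incorrect block receives either a
    perturbed answer or (with probability ``missing_if_wrong``) no answer at
    all, emulating participants who lost track and skipped. Returns a frame
    with columns ``block_id, modality, load, answer_given, correct``.
    """
    rows = []
    for block in design.blocks:
        if block.load == "single":
            continue
        rate = error_rate_by_condition.get((block.modality, block.load), 0.0)
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"error rate out of [0,1]: {rate}")
        correct = bool(rng.random() >= rate)
        truth = block.correct_final_answer
        if correct:
            answer = str(truth)
        elif rng.random() < missing_if_wrong:
            answer = None
        elif block.modality == "arithmetic":
            answer = str(truth + int(rng.choice([-2, -1, 1, 2])))
        else:
            size = block.matrix_size
            r, c = truth
            answer = f"r{(r + 1) % size}c{c}"
        rows.append({"block_id": block.block_id, "modality": block.modality,
                     "load": block.load, "answer_given": answer,
                     "correct": correct and answer is not None})
    return pd.DataFrame(rows)
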