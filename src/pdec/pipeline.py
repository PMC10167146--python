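"""End-to-end orchestration: samples in, binned metrics out.

Glue between the stage modules, used by the CLI and by simulation studies:
detect events, clean the pupil trace, compute per-sample pursuit metrics,
classify saccades, and aggregate everything into the long binned table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .binning import aggregate_bin_metrics
from .design import BlockSpec, ExperimentDesign
from .events import (PreprocessThresholds, compute_kinematics, detect_blinks,
                     detect_saccades, label_microsaccades, label_samples)
from .io_formats import SampleTable
from .metrics import classify_saccades, compute_sample_metrics
from .pupil import clean_pupil
from .simulate import SimulationConfig, TargetTrajectory, simulate_block


def preprocess_block(series: SampleTable,
                     thresholds: PreprocessThresholds = PreprocessThresholds(),
                     traj: TargetTrajectory | None = None):
    """Events, labels, cleaned pupil and per-sample metrics for one block.

    Returns a dict with keys ``blinks, saccades, labels, kinematics,
    sample_metrics, pupil``.
    """
    traj = traj or TargetTrajectory()
    blinks = detect_blinks(series, thresholds)
    kin = compute_kinematics(series)
    saccades = label_microsaccades(detect_saccades(kin, thresholds, blinks),
                                   thresholds)
    labels = label_samples(series, blinks, saccades)
    saccades = classify_saccades(saccades, traj, t0_s=0.0)
    sample_metrics = compute_sample_metrics(series, labels, kin, traj,
                                            t0_s=0.0, thresholds=thresholds)
    pupil = clean_pupil(series, blinks, labels, thresholds)
    return {"blinks": blinks, "saccades": saccades, "labels": labels,
            "kinematics": kin, "sample_metrics": sample_metrics, "pupil": pupil}


def bin_block(block: BlockSpec, pre: dict, participant: int) -> pd.DataFrame:
    """Aggregate one preprocessed block into binned-metric rows."""
    frames = []
    for trial in block.trials:
        meta = {"participant": participant, "modality": block.modality,
                "load": block.load, "block": block.block_id,
                "trial": trial.trial_index}
        frames.append(aggregate_bin_metrics(
            pre["sample_metrics"], pre["pupil"]["pd_mm"].to_numpy(),
            pre["saccades"], trial.cue_onset_ms, meta))
    return pd.concat(frames, ignore_index=True)


def simulate_and_bin(design: ExperimentDesign,
                     config: SimulationConfig | None = None,
                     thresholds: PreprocessThresholds = PreprocessThresholds(),
                     blocks: list[BlockSpec] | None = None) -> pd.DataFrame:
    """Simulate (a subset of) a design and run the full pipeline to bins."""
    config = config or SimulationConfig()
    traj = TargetTrajectory()
    rng = np.random.default_rng(config.seed)
    out = []
    for block in (blocks if blocks is not None else design.blocks):
        series, _ = simulate_block(block, config, traj, rng)
        pre = preprocess_block(series, thresholds, traj)
        out.append(bin_block(block, pre, design.participant_id))
    return pd.concat(out, ignore_index=True)
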