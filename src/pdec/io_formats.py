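"""Tabular I/O and run configuration.

All other modules operate on in-memory containers defined here: gaze/pupil
samples are a :class:`SampleTable` (a pandas DataFrame plus a pupil-unit
declaration), trial events are a plain DataFrame with the :data:`EVENT_COLUMNS`
schema, and a :class:`RunConfig` carries every numeric threshold and simulator
parameter plus the random seed.

Conventions shared by the whole package:

* gaze coordinates are screen-centered degrees of visual angle (dva), +y up;
* time is integer milliseconds from block start, sampled at 1000 Hz;
* all event intervals are half-open ``[onset, offset)`` in milliseconds.
"""

from __future__ import annotations

import dataclasses
import io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: Mandatory columns of a sample CSV, in canonical order.
SAMPLE_COLUMNS = [
    "time_ms", "xl", "yl", "xr", "yr", "pdl", "pdr", "valid_l", "valid_r",
]

#: Canonical columns of a trial/block event table.
EVENT_COLUMNS = [
    "block_id", "modality", "load", "trial_index", "cue_onset_ms",
    "cue_label", "block_answer_given", "block_answer_correct",
]

#: Canonical columns of the binned long-format metrics table.
BINNED_COLUMNS = [
    "participant", "modality", "load", "block", "trial", "bin_index",
    "median_pd_mm", "median_vg_percent", "median_gtd_dva",
    "cus_rate_hz", "as_rate_hz",
    "missing_spem", "missing_saccade", "missing_pd",
]


class FormatError(ValueError):
    """Raised when an input table violates the documented schema."""


@dataclass
class SampleTable:
    """Time-indexed binocular gaze + pupil samples.

    ``data`` holds one row per 1-ms sample with columns ``time_ms`` (int,
    strictly increasing), ``xl yl xr yr`` (dva, NaN only where the matching
    validity flag is False), ``pdl pdr`` (pupil size in ``pupil_units``) and
    boolean ``valid_l valid_r`` tracker flags.
    """

    data: pd.DataFrame
    pupil_units: str = "mm"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        missing = [c for c in SAMPLE_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"sample table missing mandatory columns: {missing}")
        t = self.data["time_ms"].to_numpy()
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            bad = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
            raise FormatError(f"time_ms not strictly increasing at row {bad}")

    def __len__(self) -> int:
        return len(self.data)


def read_samples(path: str | Path) -> SampleTable:
    """Read a sample CSV written by :func:`write_samples`.

    The file may start with ``# key: value`` comment lines; a
    ``# pupil_units:`` line declares the pupil unit (default ``mm``).
    Unknown columns are preserved but ignored by the pipeline. Monotonic
    time is validated; a non-monotonic file raises :class:`FormatError`.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = 0
        for line in fh:
            if not line.startswith("#"):
                break
            pos += len(line)
            key, _, value = line.lstrip("# ").partition(":")
            meta[key.strip()] = value.strip()
        fh.seek(pos)
        df = pd.read_csv(fh)
    n_in = len(df)
    df["valid_l"] = df["valid_l"].astype(bool) if "valid_l" in df else True
    df["valid_r"] = df["valid_r"].astype(bool) if "valid_r" in df else True
    table = SampleTable(df, pupil_units=meta.get("pupil_units", "mm"))
    logger.info("read_samples: %s rows in, %s rows out, 0 rejected", n_in, len(df))
    return table


def write_samples(table: SampleTable, path: str | Path) -> None:
    """Write a SampleTable to CSV with a pupil-unit header comment."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# pupil_units: {table.pupil_units}\n")
        table.data.to_csv(fh, index=False, float_format="%.10g")


def read_events(path: str | Path) -> pd.DataFrame:
    """Read a trial/block event table, validating the schema and cue order."""
    df = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS[:6] if c not in df.columns]
    if missing:
        raise FormatError(f"event table missing mandatory columns: {missing}")
    for _, grp in df.groupby("block_id"):
        onsets = grp["cue_onset_ms"].to_numpy()
        if len(onsets) > 1 and not np.all(np.diff(onsets) > 0):
            raise FormatError(f"cue onsets not strictly increasing in block {grp['block_id'].iloc[0]}")
    return df


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    events.to_csv(path, index=False)


def write_binned(metrics: pd.DataFrame, path: str | Path) -> None:
    """Write the binned long-format metrics table.

    Raises ``ValueError`` on an empty collection: an empty binned table means
    the pipeline upstream produced nothing, which is never a valid output.
    """
    if metrics is None or len(metrics) == 0:
        raise ValueError("refusing to write an empty binned-metrics table")
    metrics.to_csv(path, index=False, float_format="%.12g")


def read_binned(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in BINNED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"binned table missing columns: {missing}")
    return df


@dataclass
class RunConfig:
    """Everything a pipeline run needs: thresholds, simulator parameters, seed.

    The seed is recorded in every output the CLI writes so that a run can be
    reproduced from its artifacts alone.
    """

    seed: int = 0
    out_dir: str = "pdec_out"
    thresholds: dict = field(default_factory=dict)   # PreprocessThresholds overrides
    simulation: dict = field(default_factory=dict)   # SimulationConfig overrides

    def __post_init__(self) -> None:
        for name, value in {**self.thresholds, **self.simulation}.items():
            if isinstance(value, (int, float)) and not isinstance(value, bool) and value < 0:
                raise ValueError(f"config value {name} must be non-negative, got {value}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def design_to_event_table(design, answers: pd.DataFrame | None = None) -> pd.DataFrame:
    """Flatten an ExperimentDesign (and optional behavioral answers) to the
    canonical event-table schema."""
    rows = []
    for block in design.blocks:
        for trial in block.trials:
            rows.append({
                "block_id": block.block_id,
                "modality": block.modality,
                "load": block.load,
                "trial_index": trial.trial_index,
                "cue_onset_ms": trial.cue_onset_ms,
                "cue_label": trial.cue_label,
                "block_answer_given": None,
                "block_answer_correct": None,
            })
    df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    if answers is not None:
        amap = answers.set_index("block_id")
        df["block_answer_given"] = df["block_id"].map(amap["answer_given"])
        df["block_answer_correct"] = df["block_id"].map(amap["correct"])
    return df


def write_ground_truth(log, path: str | Path) -> None:
    """Serialize a GroundTruthLog (or a dict of them) to JSON."""
    def _default(obj):
        if dataclasses.is_dataclass(obj):
            return dataclasses.asdict(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        raise TypeError(type(obj))
    with open(path, "w") as fh:
        json.dump(log, fh, default=_default)
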