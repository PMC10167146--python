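"""Sample labelling: blink, saccade, microsaccade or smooth pursuit.

Saccades are detected on the average binocular gaze with a two-threshold
velocity-acceleration criterion (speed > 22 dva/s opening only where the
acceleration also exceeds 4000 dva/s^2, minimum duration 6 ms); saccades
smaller than 1 dva (straight-line start-to-end amplitude, strict boundary)
are microsaccades. Blinks are maximal runs of tracker-invalid samples,
extended by 100 ms on both sides to swallow partial lid closure; padded
blinks take precedence over saccades. Everything else is SPEM.

Velocity and acceleration use a 5-point central difference (the estimator is
configurable in principle; this is the package's documented choice, since
tracker-side parsers do not publish their filter).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .io_formats import SampleTable


@dataclass(frozen=True)
class PreprocessThresholds:
    """Every numeric threshold of the preprocessing pipeline (canonical defaults)."""

    saccade_vel: float = 22.0        # dva/s
    saccade_acc: float = 4000.0      # dva/s^2
    saccade_min_dur: float = 6.0     # ms
    micro_amp: float = 1.0           # dva, strict <
    blink_pad: float = 100.0         # ms each side
    fixation_vel: float = 0.5        # dva/s, below = fixation, excluded from VG
    gtd_max: float = 6.8             # dva, above = lost the target
    pd_outlier_sd: float = 3.0
    disparity_sd: float = 3.0
    disparity_max_mm: float = 60.0   # on-screen mm, conjunctive with the SD rule
    missing_frac: float = 0.5        # strict >, at every hierarchy level
    smooth_n: int = 20               # pupil moving-average window, samples

    def __post_init__(self) -> None:
        for f in self.__dataclass_fields__:
            if getattr(self, f) <= 0:
                raise ValueError(f"threshold {f} must be positive")


@dataclass
class SaccadeEvent:
    onset_ms: int
    offset_ms: int                   # half-open [onset, offset)
    amplitude_dva: float
    peak_velocity: float
    x_on: float
    y_on: float
    x_off: float
    y_off: float
    category: str = "unclassified"   # catchup | anticipatory | micro | unclassified


@dataclass
class BlinkEvent:
    raw_onset_ms: int
    raw_offset_ms: int
    padded_onset_ms: int
    padded_offset_ms: int


@dataclass
class Kinematics:
    """Per-sample kinematics of the binocular-average gaze."""

    time_ms: np.ndarray
    x: np.ndarray                    # mean-eye position, dva
    y: np.ndarray
    speed: np.ndarray                # dva/s, NaN at gaps/edges
    acc: np.ndarray                  # dva/s^2, derivative of speed


@dataclass
class SampleLabels:
    labels: np.ndarray               # 'blink' | 'saccade' | 'microsaccade' | 'spem'
    speed: np.ndarray
    acc: np.ndarray

    def counts(self) -> dict[str, int]:
        vals, cnt = np.unique(self.labels, return_counts=True)
        return dict(zip(vals.tolist(), cnt.tolist()))


def _central_diff5(values: np.ndarray, dt: float) -> np.ndarray:
    """5-point central difference; NaN wherever the window touches a NaN."""
    n = len(values)
    out = np.full(n, np.nan)
    if n >= 5:
        out[2:-2] = (values[4:] + values[3:-1] - values[1:-3] - values[:-4]) / (6 * dt)
    return out


def binocular_mean(series: SampleTable) -> tuple[np.ndarray, np.ndarray]:
    """Average of the two eyes; one eye alone where the other is invalid."""
    df = series.data
    xl, yl = df["xl"].to_numpy(float), df["yl"].to_numpy(float)
    xr, yr = df["xr"].to_numpy(float), df["yr"].to_numpy(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN blink rows
        x = np.nanmean(np.column_stack([xl, xr]), axis=1)
        y = np.nanmean(np.column_stack([yl, yr]), axis=1)
    return x, y


def compute_kinematics(series: SampleTable) -> Kinematics:
    """Speed and acceleration of the binocular-average gaze at 1000 Hz.

    Speed is the norm of the 5-point central-difference velocity of the mean
    eye position; acceleration is the same operator applied to speed.
    Undefined (NaN) at invalid gaps and the first/last two samples.
    """
    t = series.data["time_ms"].to_numpy()
    x, y = binocular_mean(series)
    dt = 1e-3 * (np.median(np.diff(t)) if len(t) > 1 else 1.0)
    vx = _central_diff5(x, dt)
    vy = _central_diff5(y, dt)
    speed = np.hypot(vx, vy)
    acc = _central_diff5(speed, dt)
    return Kinematics(time_ms=t, x=x, y=y, speed=speed, acc=acc)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs as half-open index pairs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        ends = np.r_[ends, len(mask)]
    return list(zip(starts.tolist(), ends.tolist()))


def detect_blinks(series: SampleTable,
                  thresholds: PreprocessThresholds = PreprocessThresholds()
                  ) -> list[BlinkEvent]:
    """Maximal runs of tracker-invalid (or pupil-missing) samples, padded by
    ``blink_pad`` ms on each side; overlapping padded blinks are merged.

    A merged event keeps the raw span from the first raw onset to the last
    raw offset, so the padded interval still extends the raw one by exactly
    the pad on each side. Padded bounds may extend beyond the series; they
    are clipped only when samples are labelled.
    """
    df = series.data
    invalid = (~df["valid_l"].to_numpy(bool)) & (~df["valid_r"].to_numpy(bool))
    pupil_gone = df["pdl"].isna().to_numpy() & df["pdr"].isna().to_numpy()
    t = df["time_ms"].to_numpy()
    pad = int(thresholds.blink_pad)
    events: list[BlinkEvent] = []
    for i0, i1 in _runs(invalid | pupil_gone):
        raw_on, raw_off = int(t[i0]), int(t[i1 - 1]) + 1
        if events and raw_on - pad <= events[-1].padded_offset_ms:
            last = events[-1]
            events[-1] = BlinkEvent(last.raw_onset_ms, raw_off,
                                    last.padded_onset_ms, raw_off + pad)
        else:
            events.append(BlinkEvent(raw_on, raw_off, raw_on - pad, raw_off + pad))
    return events


def detect_saccades(kin: Kinematics,
                    thresholds: PreprocessThresholds = PreprocessThresholds(),
                    blinks: list[BlinkEvent] = ()) -> list[SaccadeEvent]:
    """Two-threshold saccade detection outside padded blinks.

    Candidate events are maximal runs of speed above ``saccade_vel``; a run
    is kept only if the acceleration magnitude also exceeds ``saccade_acc``
    within it (the opening criterion) and it lasts at least
    ``saccade_min_dur`` ms. Amplitude is the straight-line start-to-end
    distance of the mean-eye position.
    """
    t = kin.time_ms
    in_blink = np.zeros(len(t), dtype=bool)
    for b in blinks:
        in_blink |= (t >= b.padded_onset_ms) & (t < b.padded_offset_ms)
    with np.errstate(invalid="ignore"):
        supra = (kin.speed > thresholds.saccade_vel) & ~in_blink
    supra &= ~np.isnan(kin.speed)
    step = float(np.median(np.diff(t))) if len(t) > 1 else 1.0
    min_len = int(np.ceil(thresholds.saccade_min_dur / step))
    events = []
    for i0, i1 in _runs(supra):
        if i1 - i0 < min_len:
            continue
        acc_run = kin.acc[i0:i1]
        with np.errstate(invalid="ignore"):
            if not (np.abs(acc_run[~np.isnan(acc_run)]) > thresholds.saccade_acc).any():
                continue
        j1 = min(i1, len(t) - 1)
        events.append(SaccadeEvent(
            onset_ms=int(t[i0]), offset_ms=int(t[i1 - 1]) + 1,
            amplitude_dva=float(np.hypot(kin.x[j1] - kin.x[i0],
                                         kin.y[j1] - kin.y[i0])),
            peak_velocity=float(np.nanmax(kin.speed[i0:i1])),
            x_on=float(kin.x[i0]), y_on=float(kin.y[i0]),
            x_off=float(kin.x[j1]), y_off=float(kin.y[j1])))
    return events


def label_microsaccades(saccades: list[SaccadeEvent],
                        thresholds: PreprocessThresholds = PreprocessThresholds()
                        ) -> list[SaccadeEvent]:
    """Mark saccades with amplitude strictly below ``micro_amp`` as micro."""
    return [replace(s, category="micro") if s.amplitude_dva < thresholds.micro_amp
            else s for s in saccades]


def label_samples(series: SampleTable, blinks: list[BlinkEvent],
                  saccades: list[SaccadeEvent]) -> SampleLabels:
    """Per-sample labels with precedence blink > saccade/micro > SPEM."""
    kin = compute_kinematics(series)
    t = kin.time_ms
    labels = np.full(len(t), "spem", dtype=object)
    for s in saccades:
        inside = (t >= s.onset_ms) & (t < s.offset_ms)
        labels[inside] = "microsaccade" if s.category == "micro" else "saccade"
    for b in blinks:
        labels[(t >= b.padded_onset_ms) & (t < b.padded_offset_ms)] = "blink"
    return SampleLabels(labels=labels, speed=kin.speed, acc=kin.acc)
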