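"""Per-sample pursuit metrics and saccade categorization.

Gaze-to-target distance (GTD) is the Euclidean distance between the
binocular-average gaze and the target; samples farther than 6.8 dva (the
distance the target travels in one second) are treated as "lost the target"
and excluded. Velocity gain (VG) is gaze path speed over the constant target
speed, in percent, defined only on SPEM-labelled samples moving at least
0.5 dva/s (slower samples are fixations). Binocular fixation disparity is
excluded by a conjunctive rule: beyond the participant's mean + 3 SD AND
larger than 60 mm on screen (~3.9 dva at the 88-cm viewing distance).

Non-micro saccades are catch-up (CUS) if they end nearer the target than
they started, otherwise anticipatory (AS); distances are evaluated against
the target position at the saccade's own onset and offset times, since the
target keeps moving during the saccade. The exact tie goes to anticipatory.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import replace

import numpy as np
import pandas as pd

from .events import Kinematics, PreprocessThresholds, SaccadeEvent, SampleLabels
from .io_formats import SampleTable
from .simulate import TargetTrajectory, target_position

logger = logging.getLogger(__name__)

VIEWING_DISTANCE_CM = 88.0

#: Exclusion reasons in priority order (first matching wins).
EXCLUSION_PRIORITY = ["blink", "saccade", "disparity", "gtd_gt_max", "fixation"]


def dva_to_screen_mm(dva: np.ndarray,
                     viewing_distance_cm: float = VIEWING_DISTANCE_CM) -> np.ndarray:
    """Visual angle to on-screen extent in mm at the given viewing distance."""
    return 2.0 * viewing_distance_cm * 10.0 * np.tan(np.deg2rad(dva) / 2.0)


def gaze_to_target_distance(series: SampleTable, traj: TargetTrajectory,
                            t0_s: float = 0.0,
                            thresholds: PreprocessThresholds = PreprocessThresholds()
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample GTD (dva) and a mask of samples beyond ``gtd_max``.

    ``t0_s`` places the series on the block clock for the target phase.
    Invalid gaze gives NaN.
    """
    from .events import binocular_mean
    t = series.data["time_ms"].to_numpy() / 1000.0 + t0_s
    x, y = binocular_mean(series)
    tx, ty = target_position(t, traj)
    gtd = np.hypot(x - tx, y - ty)
    with np.errstate(invalid="ignore"):
        lost = gtd > thresholds.gtd_max
    return gtd, lost


def fixation_disparity_exclusion(series: SampleTable,
                                 thresholds: PreprocessThresholds = PreprocessThresholds(),
                                 viewing_distance_cm: float = VIEWING_DISTANCE_CM,
                                 mean: float | None = None,
                                 sd: float | None = None) -> np.ndarray:
    """Conjunctive disparity exclusion mask.

    A sample is excluded only when the left-right gaze distance is both more
    than 3 SD above the participant's mean disparity AND larger than 60 mm
    on screen. Monocular data (one eye entirely missing) yields an all-false
    mask with a warning.
    """
    df = series.data
    disp = np.hypot(df["xl"].to_numpy(float) - df["xr"].to_numpy(float),
                    df["yl"].to_numpy(float) - df["yr"].to_numpy(float))
    if np.isnan(disp).all():
        warnings.warn("monocular data: disparity exclusion skipped")
        return np.zeros(len(disp), dtype=bool)
    if mean is None:
        mean = float(np.nanmean(disp))
    if sd is None:
        sd = float(np.nanstd(disp))
    disp_mm = dva_to_screen_mm(disp, viewing_distance_cm)
    with np.errstate(invalid="ignore"):
        mask = (disp > mean + thresholds.disparity_sd * sd) \
            & (disp_mm > thresholds.disparity_max_mm)
    return np.where(np.isnan(disp), False, mask)


def velocity_gain(kin: Kinematics, labels: SampleLabels,
                  thresholds: PreprocessThresholds = PreprocessThresholds(),
                  target_speed: float = 6.8) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample VG in percent on SPEM samples, plus a fixation mask.

    VG = 100 * gaze speed / target speed; samples slower than
    ``fixation_vel`` are fixations and excluded from VG.
    """
    vg = np.full(len(kin.speed), np.nan)
    with np.errstate(invalid="ignore"):
        fixation = (kin.speed < thresholds.fixation_vel) & (labels.labels == "spem")
        ok = (labels.labels == "spem") & (kin.speed >= thresholds.fixation_vel)
    vg[ok] = 100.0 * kin.speed[ok] / target_speed
    return vg, fixation


def classify_pursuit_saccade(saccade: SaccadeEvent, traj: TargetTrajectory,
                             t0_s: float = 0.0) -> SaccadeEvent:
    """Categorize a non-micro saccade as catch-up or anticipatory.

    Compares gaze-to-target distance at the saccade's onset and offset, with
    the target evaluated at those same times. Distance decreased -> catch-up;
    otherwise (including the measure-zero tie) -> anticipatory. Micro
    saccades pass through unchanged; missing boundary gaze -> unclassified.
    """
    if saccade.category == "micro":
        return saccade
    if any(math.isnan(v) for v in (saccade.x_on, saccade.y_on,
                                   saccade.x_off, saccade.y_off)):
        logger.info("saccade at %s ms has missing boundary gaze; unclassified",
                    saccade.onset_ms)
        return replace(saccade, category="unclassified")
    tx0, ty0 = target_position(t0_s + saccade.onset_ms / 1000.0, traj)
    tx1, ty1 = target_position(t0_s + saccade.offset_ms / 1000.0, traj)
    d_on = math.hypot(saccade.x_on - tx0, saccade.y_on - ty0)
    d_off = math.hypot(saccade.x_off - tx1, saccade.y_off - ty1)
    return replace(saccade, category="catchup" if d_off < d_on else "anticipatory")


def classify_saccades(saccades: list[SaccadeEvent], traj: TargetTrajectory,
                      t0_s: float = 0.0) -> list[SaccadeEvent]:
    return [classify_pursuit_saccade(s, traj, t0_s) for s in saccades]


_CUE_VECTORS = {"right": (1.0, 0.0), "left": (-1.0, 0.0),
                "up": (0.0, 1.0), "down": (0.0, -1.0)}


def saccade_direction_sector(saccade: SaccadeEvent, cue_direction: str) -> float:
    """Angle sector (deg) of the saccade displacement relative to the cued
    direction: 0 means within +/-22.5 deg of the cue, sectors are 45 deg wide
    in (-180, 180]. Zero displacement is undefined."""
    dx = saccade.x_off - saccade.x_on
    dy = saccade.y_off - saccade.y_on
    if dx == 0 and dy == 0:
        raise ValueError("zero-displacement saccade has no direction")
    cx, cy = _CUE_VECTORS[cue_direction]
    rel = math.degrees(math.atan2(dy, dx) - math.atan2(cy, cx))
    rel = (rel + 180.0) % 360.0 - 180.0
    sector = round(rel / 45.0) * 45.0
    return 180.0 if sector == -180.0 else sector


def compute_sample_metrics(series: SampleTable, labels: SampleLabels,
                           kin: Kinematics, traj: TargetTrajectory,
                           t0_s: float = 0.0,
                           thresholds: PreprocessThresholds = PreprocessThresholds()
                           ) -> pd.DataFrame:
    """Assemble the per-sample metric table with exclusion reasons.

    Columns: ``time_ms, gtd_dva, vg_percent, exclusion_reason``. GTD and VG
    are reported only where no exclusion applies; ``exclusion_reason`` holds
    the highest-priority reason (blink > saccade > disparity > gtd_gt_max >
    fixation) or 'none'.
    """
    t = series.data["time_ms"].to_numpy()
    gtd, lost = gaze_to_target_distance(series, traj, t0_s, thresholds)
    disparity = fixation_disparity_exclusion(series, thresholds)
    vg, fixation = velocity_gain(kin, labels, thresholds, traj.speed)

    reason = np.full(len(t), "none", dtype=object)
    masks = {
        "blink": labels.labels == "blink",
        "saccade": np.isin(labels.labels, ["saccade", "microsaccade"]),
        "disparity": disparity,
        "gtd_gt_max": np.where(np.isnan(gtd), False, lost),
        "fixation": fixation,
    }
    for name in reversed(EXCLUSION_PRIORITY):
        reason[masks[name]] = name

    excluded = reason != "none"
    gtd_out = np.where(excluded | np.isnan(gtd), np.nan, gtd)
    vg_out = np.where(excluded, np.nan, vg)
    return pd.DataFrame({"time_ms": t, "gtd_dva": gtd_out,
                         "vg_percent": vg_out, "exclusion_reason": reason})
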