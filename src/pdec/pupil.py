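"""Pupil-diameter preprocessing.

The cleaning order is fixed: unit conversion, 20-sample centered moving
average, linear interpolation across padded blink gaps, then exclusion of
3-SD outliers (relative to the participant's own mean) and of samples
recorded during saccades, where pupil size cannot be measured reliably.
The binocular trace is the mean of the two eyes where both are valid and the
single valid eye otherwise. Every step leaves a provenance flag so that an
excluded sample can never silently re-enter an analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import BlinkEvent, PreprocessThresholds, SampleLabels, _runs
from .io_formats import SampleTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PupilCalibration:
    """Linear artificial-pupil calibration: mm = (au - intercept) / slope.

    The slope (arbitrary units per mm) is rig-specific and must be supplied;
    there is no meaningful universal default.
    """

    au_per_mm: float
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if self.au_per_mm <= 0:
            raise ValueError("calibration slope must be positive")


def au_to_mm(raw_au: np.ndarray, calibration: PupilCalibration) -> np.ndarray:
    """Arbitrary tracker units to millimeters via the linear calibration."""
    return (np.asarray(raw_au, dtype=float) - calibration.intercept) / calibration.au_per_mm


def binocular_pd(series: SampleTable) -> np.ndarray:
    """Mean of both eyes' pupil sizes; one eye alone where the other is missing."""
    df = series.data
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(np.column_stack(
            [df["pdl"].to_numpy(float), df["pdr"].to_numpy(float)]), axis=1)


def smooth_pd(pd_values: np.ndarray, n: int = 20) -> np.ndarray:
    """Centered ``n``-sample moving average, truncated at edges and gaps.

    Each contiguous valid (non-NaN) run is smoothed independently, so the
    window never averages across a missing-data gap. For even ``n`` the
    window covers ``n//2`` samples back and ``n//2 - 1`` forward.
    """
    values = np.asarray(pd_values, dtype=float)
    out = np.full_like(values, np.nan)
    for i0, i1 in _runs(~np.isnan(values)):
        seg = pd.Series(values[i0:i1])
        out[i0:i1] = seg.rolling(n, center=True, min_periods=1).mean().to_numpy()
    return out


def interpolate_blinks(pd_values: np.ndarray, blinks: list[BlinkEvent],
                       time_ms: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Linearly bridge every padded blink interval.

    Samples inside a padded blink are replaced by the straight line between
    the nearest valid samples on either side. A blink touching the series
    edge has no boundary on that side and is left missing (no extrapolation).
    Returns (interpolated series, boolean flag of interpolated samples).
    """
    values = np.asarray(pd_values, dtype=float).copy()
    flag = np.zeros(len(values), dtype=bool)
    for b in blinks:
        inside = np.flatnonzero((time_ms >= b.padded_onset_ms)
                                & (time_ms < b.padded_offset_ms))
        if len(inside) == 0:
            continue
        left = inside[0] - 1
        right = inside[-1] + 1
        while left >= 0 and np.isnan(values[left]):
            left -= 1
        while right < len(values) and np.isnan(values[right]):
            right += 1
        if left < 0 or right >= len(values):
            logger.info("blink at series edge left uninterpolated: [%s, %s)",
                        b.padded_onset_ms, b.padded_offset_ms)
            continue
        values[inside] = np.interp(inside, [left, right],
                                   [values[left], values[right]])
        flag[inside] = True
    return values, flag


def exclude_pd_outliers(pd_values: np.ndarray, labels: SampleLabels,
                        thresholds: PreprocessThresholds = PreprocessThresholds(),
                        mean: float | None = None, sd: float | None = None
                        ) -> tuple[np.ndarray, pd.DataFrame]:
    """Drop 3-SD outliers and saccade-contaminated pupil samples.

    The reference mean and SD default to this series' own valid samples but
    can be supplied (e.g. computed once over all of a participant's data).
    A zero SD (constant series) disables the outlier rule with a warning.
    Returns the cleaned series (NaN at exclusions) and a per-sample flag frame.
    """
    values = np.asarray(pd_values, dtype=float).copy()
    valid = ~np.isnan(values)
    if mean is None:
        mean = float(np.nanmean(values)) if valid.any() else np.nan
    if sd is None:
        sd = float(np.nanstd(values)) if valid.any() else np.nan
    if not np.isnan(sd) and sd == 0:
        warnings.warn("pupil SD is zero; outlier exclusion disabled")
        outlier = np.zeros(len(values), dtype=bool)
    else:
        with np.errstate(invalid="ignore"):
            outlier = np.abs(values - mean) > thresholds.pd_outlier_sd * sd
        outlier &= valid
    in_saccade = np.isin(labels.labels, ["saccade", "microsaccade"]) & valid
    excluded = outlier | in_saccade
    values[excluded] = np.nan
    flags = pd.DataFrame({"excluded_outlier": outlier,
                          "excluded_saccade": in_saccade})
    logger.info("pupil exclusions: %.4f outlier, %.4f saccade",
                outlier.mean() if len(values) else 0.0,
                in_saccade.mean() if len(values) else 0.0)
    return values, flags


def clean_pupil(series: SampleTable, blinks: list[BlinkEvent],
                labels: SampleLabels,
                thresholds: PreprocessThresholds = PreprocessThresholds(),
                calibration: PupilCalibration | None = None,
                mean: float | None = None, sd: float | None = None
                ) -> pd.DataFrame:
    """Full pipeline: (au->mm) -> smooth -> interpolate blinks -> exclude.

    Returns a frame with ``time_ms``, the cleaned ``pd_mm`` and provenance
    flags (``interpolated``, ``excluded_outlier``, ``excluded_saccade``).
    """
    t = series.data["time_ms"].to_numpy()
    raw = binocular_pd(series)
    if calibration is not None:
        raw = au_to_mm(raw, calibration)
    elif series.pupil_units not in ("mm",):
        raise ValueError(f"pupil in {series.pupil_units!r} but no calibration given")
    smoothed = smooth_pd(raw, thresholds.smooth_n)
    interpolated, interp_flag = interpolate_blinks(smoothed, blinks, t)
    cleaned, flags = exclude_pd_outliers(interpolated, labels, thresholds,
                                         mean=mean, sd=sd)
    out = pd.DataFrame({"time_ms": t, "pd_mm": cleaned,
                        "interpolated": interp_flag})
    return pd.concat([out, flags], axis=1)
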