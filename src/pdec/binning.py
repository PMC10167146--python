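"""Time-binning and hierarchical missing-data exclusion.

Every trial is split into seven 0.5-s bins covering [0, 3.5) s from cue
onset; later samples are discarded (the shortest inter-trial interval is
3.6 s, so all trials cover the seven bins). Per bin we report median pupil
diameter, median VG, median GTD, and catch-up / anticipatory saccade rates
(onset-in-bin counts per second, microsaccades excluded).

Missingness is tracked per metric family — SPEM (GTD/VG), saccade, and
pupil — and exclusion cascades bottom-up with a strict >50% rule at every
level: bins with >50% missing samples, trials with >50% excluded bins,
blocks with >50% excluded trials (within participant x modality), and
participants with >50% excluded blocks (pooled over modalities). Dual-task
blocks without a reported final answer are removed from the eye-metric
tables entirely (a missing answer means the participant lost track, so the
eye record does not reflect the intended internal task); blocks answered
incorrectly are retained.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_formats import BINNED_COLUMNS

BIN_WIDTH_MS = 500
N_BINS = 7

FAMILY_VALUE_COLUMNS = {
    "spem": ["median_vg_percent", "median_gtd_dva"],
    "saccade": ["cus_rate_hz", "as_rate_hz"],
    "pd": ["median_pd_mm"],
}
FAMILY_MISSING_COLUMNS = {"spem": "missing_spem", "saccade": "missing_saccade",
                          "pd": "missing_pd"}


def assign_bins(time_ms: np.ndarray, cue_onset_ms: int,
                bin_width_ms: int = BIN_WIDTH_MS, n_bins: int = N_BINS
                ) -> np.ndarray:
    """Bin index 1..n_bins for each sample; 0 marks discarded samples.

    Bin k covers [(k-1), k) * bin width after cue onset; samples before the
    cue or at/after ``n_bins * bin_width`` are discarded (index 0).
    """
    rel = np.asarray(time_ms) - cue_onset_ms
    idx = rel // bin_width_ms + 1
    idx = np.where((rel < 0) | (rel >= n_bins * bin_width_ms), 0, idx)
    return idx.astype(int)


def aggregate_bin_metrics(sample_metrics: pd.DataFrame,
                          pd_mm: np.ndarray,
                          saccades: list,
                          cue_onset_ms: int,
                          meta: dict | None = None) -> pd.DataFrame:
    """One trial's seven binned-metric rows.

    ``sample_metrics`` is the per-sample table from
    :func:`pdec.metrics.compute_sample_metrics` (block-clock ``time_ms``),
    ``pd_mm`` the cleaned pupil trace aligned to it, and ``saccades`` the
    classified saccade events (block clock). Medians are taken over
    non-excluded samples; a bin with no usable sample in a family gets an
    absent median and missing fraction 1. Saccade rates count non-micro
    onsets in the bin divided by the bin width.
    """
    t = sample_metrics["time_ms"].to_numpy()
    bins = assign_bins(t, cue_onset_ms)
    reason = sample_metrics["exclusion_reason"].to_numpy()
    gtd = sample_metrics["gtd_dva"].to_numpy()
    vg = sample_metrics["vg_percent"].to_numpy()
    pd_mm = np.asarray(pd_mm, dtype=float)

    rows = []
    for k in range(1, N_BINS + 1):
        sel = bins == k
        n = int(sel.sum())
        row = dict(meta or {})
        row["bin_index"] = k
        if n == 0:
            row.update({c: np.nan for cols in FAMILY_VALUE_COLUMNS.values()
                        for c in cols})
            row.update({c: 1.0 for c in FAMILY_MISSING_COLUMNS.values()})
            rows.append(row)
            continue
        spem_missing = reason[sel] != "none"
        row["missing_spem"] = float(spem_missing.mean())
        row["median_gtd_dva"] = float(np.nanmedian(gtd[sel])) \
            if np.isfinite(gtd[sel]).any() else np.nan
        row["median_vg_percent"] = float(np.nanmedian(vg[sel])) \
            if np.isfinite(vg[sel]).any() else np.nan
        row["missing_saccade"] = float((reason[sel] == "blink").mean())
        row["missing_pd"] = float(np.isnan(pd_mm[sel]).mean())
        row["median_pd_mm"] = float(np.nanmedian(pd_mm[sel])) \
            if np.isfinite(pd_mm[sel]).any() else np.nan
        lo = cue_onset_ms + (k - 1) * BIN_WIDTH_MS
        hi = lo + BIN_WIDTH_MS
        cus = sum(1 for s in saccades
                  if s.category == "catchup" and lo <= s.onset_ms < hi)
        ant = sum(1 for s in saccades
                  if s.category == "anticipatory" and lo <= s.onset_ms < hi)
        row["cus_rate_hz"] = cus / (BIN_WIDTH_MS / 1000.0)
        row["as_rate_hz"] = ant / (BIN_WIDTH_MS / 1000.0)
        rows.append(row)
    return pd.DataFrame(rows)


def _level_fraction(excluded: pd.Series, by: list[str]) -> pd.Series:
    return excluded.groupby([excluded.index.get_level_values(c) for c in by]).mean()


def hierarchical_exclusion(binned: pd.DataFrame, threshold: float = 0.5
                           ) -> tuple[pd.DataFrame, dict]:
    """Bottom-up >50% missing-data exclusion, per metric family.

    Returns the table with excluded values set to NaN (missing-fraction
    columns are left untouched, so the operation is idempotent) and a report
    of exclusion counts per level and family.
    """
    out = binned.copy()
    report: dict[str, dict[str, int]] = {}
    for family, miss_col in FAMILY_MISSING_COLUMNS.items():
        bin_excl = out[miss_col] > threshold

        key_trial = ["participant", "modality", "block", "trial"]
        trial_frac = bin_excl.groupby([out[c] for c in key_trial]).transform("mean")
        trial_excl = trial_frac > threshold

        key_block = ["participant", "modality", "block"]
        trial_level = pd.DataFrame({
            "excl": trial_excl.groupby([out[c] for c in key_trial]).first()})
        block_frac_map = trial_level["excl"].groupby(
            [trial_level.index.get_level_values(c) for c in key_block]).mean()
        block_excl = pd.MultiIndex.from_frame(out[key_block]).map(block_frac_map) > threshold
        block_excl = pd.Series(np.asarray(block_excl), index=out.index)

        block_level = pd.DataFrame({"excl": block_excl.groupby(
            [out[c] for c in key_block]).first()})
        part_frac_map = block_level["excl"].groupby(
            block_level.index.get_level_values("participant")).mean()
        part_excl = out["participant"].map(part_frac_map) > threshold

        excluded = bin_excl | trial_excl | block_excl | part_excl
        for col in FAMILY_VALUE_COLUMNS[family]:
            out.loc[excluded, col] = np.nan
        report[family] = {
            "bins": int(bin_excl.sum()),
            "trials": int(trial_level["excl"].sum()),
            "blocks": int(block_level["excl"].sum()),
            "participants": int((part_frac_map > threshold).sum()),
        }
    return out, report


def drop_unanswered_blocks(binned: pd.DataFrame,
                           answers: pd.DataFrame) -> pd.DataFrame:
    """Remove dual blocks with no reported final answer from eye analyses.

    ``answers`` has one row per dual block (``block_id``, ``answer_given``).
    Single-task blocks and answered (even incorrectly answered) dual blocks
    are retained. Behavioral accuracy tables are unaffected by design: they
    are computed upstream of this filter.
    """
    missing = answers.loc[answers["answer_given"].isna(), "block_id"]
    unanswered = set(missing)
    mask = (binned["load"] != "single") & binned["block"].isin(unanswered)
    return binned.loc[~mask].reset_index(drop=True)
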