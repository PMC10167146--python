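"""Manipulation-check ANOVA, planned workload contrasts, Bayes factors, power.

The contrast layer is a two-stage participant-aggregate analysis: each
participant's trial-level medians are first averaged to one value per
workload level and time-bin, then the three planned comparisons
(single-low, single-high, low-high) are run per bin as paired t-tests with
Bonferroni correction over the bin's family of tests, a paired-difference
Cohen's d_z, and a default-Cauchy (JZS, scale sqrt(2)/2) Bayes factor.
This deliberately replaces mixed-model marginal-means machinery with a
transparent aggregate analysis; it recovers the same qualitative contrasts
but makes no claim of numerical agreement with model-based estimates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, stats

logger = logging.getLogger(__name__)

JZS_SCALE = math.sqrt(2) / 2

#: Evidence-strength boundaries for Bayes factors: below 3 weak, 3-20
#: moderate, 20-150 strong, above 150 very strong.
BF_BANDS = (3.0, 20.0, 150.0)

COMPARISONS = [("single", "low"), ("single", "high"), ("low", "high")]


@dataclass
class AnovaResult:
    effect: str            # 'task' | 'workload' | 'interaction'
    F: float
    df_num: int
    df_den: int
    p: float
    eta_squared: float


def block_accuracy(answers: pd.DataFrame) -> pd.DataFrame:
    """Percent correct blocks per participant x modality x load.

    ``answers`` must carry ``participant, modality, load, correct`` with one
    row per dual block; a missing answer counts as incorrect (``correct`` is
    False for it).
    """
    dual = answers[answers["load"] != "single"]
    if dual.empty:
        raise ValueError("no dual blocks in answers")
    acc = (dual.groupby(["participant", "modality", "load"], observed=True)["correct"]
           .mean().mul(100.0).rename("percent_correct").reset_index())
    return acc


def rm_anova_2x2(accuracy: pd.DataFrame) -> list[AnovaResult]:
    """2 (modality) x 2 (load) within-subject ANOVA on percent correct.

    Classical repeated-measures sums-of-squares decomposition: each effect is
    tested against its own subject-by-effect interaction. Effect size is the
    classical eta squared (SS_effect / SS_total). Participants missing any
    cell are removed listwise.
    """
    wide = accuracy.pivot_table(index="participant", columns=["modality", "load"],
                                values="percent_correct")
    complete = wide.dropna()
    dropped = len(wide) - len(complete)
    if dropped:
        logger.info("rm_anova_2x2: %d participants removed listwise", dropped)
    y = complete.to_numpy(float)          # subjects x 4 cells
    modal = np.array([c[0] for c in complete.columns])
    load = np.array([c[1] for c in complete.columns])
    n = y.shape[0]
    if n < 2:
        raise ValueError("need at least two complete participants")

    grand = y.mean()
    subj_mean = y.mean(axis=1)
    a_levels, b_levels = np.unique(modal), np.unique(load)
    a_mean = {a: y[:, modal == a].mean() for a in a_levels}
    b_mean = {b: y[:, load == b].mean() for b in b_levels}
    cell_mean = {(a, b): y[:, (modal == a) & (load == b)].mean()
                 for a in a_levels for b in b_levels}

    ss_total = ((y - grand) ** 2).sum()
    # each factor level spans n subjects x 2 cells of the other factor
    ss_a = 2 * n * sum((a_mean[a] - grand) ** 2 for a in a_levels)
    ss_b = 2 * n * sum((b_mean[b] - grand) ** 2 for b in b_levels)
    ss_ab = n * sum((cell_mean[a, b] - a_mean[a] - b_mean[b] + grand) ** 2
                    for a in a_levels for b in b_levels)

    sa = {a: y[:, modal == a].mean(axis=1) for a in a_levels}
    sb = {b: y[:, load == b].mean(axis=1) for b in b_levels}
    ss_as = 2 * sum(((sa[a] - subj_mean - a_mean[a] + grand) ** 2).sum()
                    for a in a_levels)
    ss_bs = 2 * sum(((sb[b] - subj_mean - b_mean[b] + grand) ** 2).sum()
                    for b in b_levels)
    ss_subj = 4 * ((subj_mean - grand) ** 2).sum()
    ss_abs = ss_total - ss_subj - ss_a - ss_b - ss_ab - ss_as - ss_bs

    df_err = n - 1
    results = []
    for effect, ss_eff, ss_err in (("task", ss_a, ss_as),
                                   ("workload", ss_b, ss_bs),
                                   ("interaction", ss_ab, ss_abs)):
        ms_eff, ms_err = ss_eff / 1, ss_err / df_err
        # degenerate flat data: no effect variance and no error variance
        F = ms_eff / ms_err if ms_err > 0 else (0.0 if ms_eff < 1e-12 else np.inf)
        p = float(stats.f.sf(F, 1, df_err))
        results.append(AnovaResult(effect, float(F), 1, df_err, p,
                                   float(ss_eff / ss_total)))
    return results


def jzs_bayes_factor(t: float, n: int, scale: float = JZS_SCALE) -> float:
    """JZS Bayes factor (BF10) for a one-sample / paired t statistic.

    Marginalizes the noncentral-t likelihood over a Cauchy(0, ``scale``)
    prior on the standardized effect size by adaptive quadrature; the null
    likelihood is the central t density.
    """
    if not np.isfinite(t):
        raise ValueError("t must be finite")
    if n < 2:
        raise ValueError("need n >= 2")
    df = n - 1
    sqrt_n = math.sqrt(n)

    def integrand(delta):
        return stats.nct.pdf(t, df, delta * sqrt_n) * stats.cauchy.pdf(delta, 0, scale)

    num = 0.0
    for lo, hi in ((-np.inf, 0.0), (0.0, np.inf)):
        val, _ = integrate.quad(integrand, lo, hi, limit=200)
        num += val
    return float(num / stats.t.pdf(t, df))


def bf_band(bf10: float) -> str:
    """Interpretation band for a BF10 value."""
    if bf10 < BF_BANDS[0]:
        return "weak"
    if bf10 < BF_BANDS[1]:
        return "moderate"
    if bf10 < BF_BANDS[2]:
        return "strong"
    return "very strong"


def pairwise_workload_contrasts(binned: pd.DataFrame, metric: str,
                                modality: str, alpha: float = 0.05,
                                bayes: bool = True) -> pd.DataFrame:
    """Planned per-bin workload contrasts on participant aggregates.

    For each time-bin: aggregate ``metric`` to one value per participant and
    load (mean of trial-level values), then run the three paired comparisons.
    ``p_bonferroni`` is the raw p times the number of tests actually run in
    that bin's family, capped at 1. Contrasts with fewer than 3 complete
    pairs are skipped with a log message.
    """
    sub = binned[binned["modality"] == modality]
    agg = (sub.groupby(["participant", "load", "bin_index"], observed=True)[metric]
           .mean().reset_index())
    rows = []
    for bin_index, grp in agg.groupby("bin_index"):
        wide = grp.pivot(index="participant", columns="load", values=metric)
        candidates = []
        for a, b in COMPARISONS:
            if a not in wide.columns or b not in wide.columns:
                logger.info("bin %s: %s-%s skipped (missing condition)", bin_index, a, b)
                continue
            pair = wide[[a, b]].dropna()
            if len(pair) < 3:
                logger.info("bin %s: %s-%s skipped (<3 complete pairs)", bin_index, a, b)
                continue
            candidates.append((a, b, pair))
        n_family = len(candidates)
        for a, b, pair in candidates:
            diff = pair[a].to_numpy() - pair[b].to_numpy()
            n = len(diff)
            tstat, p_raw = stats.ttest_rel(pair[a], pair[b])
            sd = diff.std(ddof=1)
            d = diff.mean() / sd if sd > 0 else np.nan
            rows.append({
                "modality": modality, "metric": metric, "bin_index": bin_index,
                "comparison": f"{a}-{b}", "estimate": float(diff.mean()),
                "t": float(tstat), "df": n - 1, "n": n,
                "p_raw": float(p_raw),
                "p_bonferroni": float(min(1.0, p_raw * n_family)),
                "cohen_d": float(d),
                "bf10": jzs_bayes_factor(float(tstat), n) if bayes else np.nan,
            })
    out = pd.DataFrame(rows)
    if bayes and len(out):
        out["bf_band"] = out["bf10"].map(bf_band)
    return out


def required_n_paired_t(dz: float, alpha: float = 0.05, power: float = 0.80,
                        tails: int = 1, n_max: int = 1_000_000) -> int:
    """Smallest paired-t sample size reaching the requested power.

    Power is computed exactly from the noncentral t distribution with
    noncentrality ``dz * sqrt(n)`` and ``n - 1`` degrees of freedom.
    """
    if dz <= 0:
        raise ValueError("dz must be positive")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    for n in range(2, n_max + 1):
        df = n - 1
        ncp = dz * math.sqrt(n)
        if tails == 1:
            achieved = stats.nct.sf(stats.t.isf(alpha, df), df, ncp)
        else:
            crit = stats.t.isf(alpha / 2, df)
            achieved = stats.nct.sf(crit, df, ncp) + stats.nct.cdf(-crit, df, ncp)
        if achieved >= power:
            return n
    raise ValueError(f"requested power not reachable below n = {n_max}")
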