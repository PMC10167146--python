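"""Accuracy ANOVA, planned contrasts, JZS Bayes factors, power analysis."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats as sps

from pdec.stats import (bf_band, block_accuracy, jzs_bayes_factor,
                        pairwise_workload_contrasts, required_n_paired_t,
                        rm_anova_2x2)


def _answers(correct_flags, participant=0, modality="arithmetic", load="low"):
    return pd.DataFrame({"participant": participant, "modality": modality,
                         "load": load, "block_id": range(len(correct_flags)),
                         "correct": correct_flags})


def test_block_accuracy_percentages():
    acc = block_accuracy(_answers([True] * 9 + [False]))
    assert acc["percent_correct"].iloc[0] == 90.0
    acc = block_accuracy(_answers([True] * 10))
    assert acc["percent_correct"].iloc[0] == 100.0


def test_block_accuracy_recovers_simulated_rates(rng):
    frames = []
    for load, rate in (("low", 0.14), ("high", 0.18)):
        frames.append(_answers(rng.random(10_000) >= rate, load=load))
    acc = block_accuracy(pd.concat(frames, ignore_index=True))
    by_load = acc.set_index("load")["percent_correct"]
    assert abs(by_load["low"] - 86.0) < 1.0
    assert abs(by_load["high"] - 82.0) < 1.0


def _acc_frame(values: dict) -> pd.DataFrame:
    rows = [{"participant": p, "modality": m, "load": l, "percent_correct": v}
            for (p, m, l), v in values.items()]
    return pd.DataFrame(rows)


def test_anova_flat_data_gives_zero_f():
    values = {(p, m, l): 80.0 + p for p in range(4)
              for m in ("arithmetic", "visuospatial") for l in ("low", "high")}
    for res in rm_anova_2x2(_acc_frame(values)):
        assert res.F == pytest.approx(0.0, abs=1e-9)


def test_anova_matches_hand_computed_fixture():
    """Three-participant fixture; expected F/p frozen from an independent
    repeated-measures sums-of-squares computation."""
    values = {
        (0, "arithmetic", "low"): 90, (0, "arithmetic", "high"): 80,
        (0, "visuospatial", "low"): 92, (0, "visuospatial", "high"): 78,
        (1, "arithmetic", "low"): 85, (1, "arithmetic", "high"): 82,
        (1, "visuospatial", "low"): 88, (1, "visuospatial", "high"): 80,
        (2, "arithmetic", "low"): 95, (2, "arithmetic", "high"): 85,
        (2, "visuospatial", "low"): 90, (2, "visuospatial", "high"): 84,
    }
    res = {r.effect: r for r in rm_anova_2x2(_acc_frame(values))}
    assert res["task"].F == pytest.approx(0.5813953488, abs=1e-6)
    assert res["workload"].F == pytest.approx(20.1627906977, abs=1e-6)
    assert res["workload"].p == pytest.approx(0.0461873051, abs=1e-6)
    assert res["interaction"].F == pytest.approx(0.3424657534, abs=1e-6)
    assert (res["task"].df_num, res["task"].df_den) == (1, 2)


def test_anova_matches_brute_force_ss_oracle(rng):
    """Random data vs an independent cell-mean sums-of-squares decomposition."""
    values = {(p, m, l): float(rng.normal(85, 6)) for p in range(10)
              for m in ("arithmetic", "visuospatial") for l in ("low", "high")}
    df = _acc_frame(values)
    res = {r.effect: r for r in rm_anova_2x2(df)}

    y = df.pivot_table(index="participant", columns=["modality", "load"],
                       values="percent_correct").to_numpy()
    n = y.shape[0]
    grand = y.mean()
    A = np.stack([y[:, :2].mean(1), y[:, 2:].mean(1)])     # modality x subj
    B = np.stack([y[:, [0, 2]].mean(1), y[:, [1, 3]].mean(1)])  # load x subj
    subj = y.mean(1)
    for effect, per_subj in (("task", A), ("workload", B)):
        eff = per_subj.mean(1)
        ss_eff = 2 * n * ((eff - grand) ** 2).sum()
        resid = per_subj - subj - eff[:, None] + grand
        ss_err = 2 * (resid ** 2).sum()
        F = ss_eff / (ss_err / (n - 1))
        assert res[effect].F == pytest.approx(F, abs=1e-9)


def _binned_pd(n_part, means, noise_sd, rng, bins=range(1, 8)):
    rows = []
    for p in range(n_part):
        base = rng.normal(0, 0.3)
        for load, mu in means.items():
            for b in bins:
                for trial in range(3):
                    rows.append({
                        "participant": p, "modality": "arithmetic",
                        "load": load, "block": f"{load}0", "trial": trial,
                        "bin_index": b,
                        "median_pd_mm": 4.0 + base + mu + rng.normal(0, noise_sd)})
    return pd.DataFrame(rows)


def test_identical_conditions_give_null_contrasts(rng):
    binned = _binned_pd(8, {"single": 0, "low": 0, "high": 0}, 0.0, rng)
    out = pairwise_workload_contrasts(binned, "median_pd_mm", "arithmetic",
                                      bayes=False)
    assert (out["estimate"].abs() < 1e-12).all()
    assert (out["p_bonferroni"] == 1.0).all()


def test_bonferroni_multiplies_by_family_size(rng):
    binned = _binned_pd(10, {"single": 0, "low": 0.05, "high": 0.1}, 0.05, rng)
    out = pairwise_workload_contrasts(binned, "median_pd_mm", "arithmetic",
                                      bayes=False)
    np.testing.assert_allclose(out["p_bonferroni"],
                               np.minimum(1.0, out["p_raw"] * 3))
    assert set(out["comparison"]) == {"single-low", "single-high", "low-high"}


def test_localized_effect_detected_in_its_bins_only(rng):
    """A GTD-like shift confined to bins 2-4 must come out significant there
    and not in the late bins."""
    rows = []
    for p in range(30):
        for load in ("single", "low"):
            for b in range(1, 8):
                shift = 0.3 if (load == "low" and b in (2, 3, 4)) else 0.0
                rows.append({"participant": p, "modality": "arithmetic",
                             "load": load, "block": "b", "trial": 0,
                             "bin_index": b,
                             "median_gtd_dva": 0.6 + shift + rng.normal(0, 0.15)})
    out = pairwise_workload_contrasts(pd.DataFrame(rows), "median_gtd_dva",
                                      "arithmetic", bayes=False)
    sig = out.set_index("bin_index")["p_bonferroni"] < 0.05
    assert sig.loc[[2, 3, 4]].all()
    assert not sig.loc[[6, 7]].any()


def _bf_g_quadrature(t, n, r=math.sqrt(2) / 2):
    """Independent oracle: inverse-gamma mixture representation of the JZS BF."""
    df = n - 1

    def integrand(g):
        return ((1 + n * g) ** -0.5
                * (1 + t ** 2 / ((1 + n * g) * df)) ** (-(df + 1) / 2)
                * (r / math.sqrt(2 * math.pi)) * g ** -1.5
                * math.exp(-r ** 2 / (2 * g)))

    num, _ = integrate.quad(integrand, 0, np.inf, limit=200)
    return num / (1 + t ** 2 / df) ** (-(df + 1) / 2)


def test_jzs_bf_matches_independent_quadrature():
    for t in (0.0, 0.5, 2.0, 4.0, 6.0):
        for n in (10, 20, 50):
            assert jzs_bayes_factor(t, n) == pytest.approx(
                _bf_g_quadrature(t, n), rel=0.01)


def test_jzs_bf_null_support_and_monotonicity():
    assert jzs_bayes_factor(0.0, 25) < 1.0
    grid = [jzs_bayes_factor(t, 25) for t in np.linspace(0, 6, 13)]
    assert all(b > a for a, b in zip(grid, grid[1:]))
    with pytest.raises(ValueError):
        jzs_bayes_factor(float("nan"), 10)


def test_bf_interpretation_bands():
    assert bf_band(1.0) == "weak"
    assert bf_band(10.0) == "moderate"
    assert bf_band(50.0) == "strong"
    assert bf_band(200.0) == "very strong"


def test_power_analysis_sample_sizes():
    assert required_n_paired_t(0.4, alpha=0.05, power=0.80, tails=1) == 41
    # monotone decreasing in effect size
    ns = [required_n_paired_t(dz, tails=2) for dz in (0.2, 0.4, 0.8)]
    assert ns[0] > ns[1] > ns[2]
    # normal approximation: doubling dz roughly quarters n
    approx = [((sps.norm.isf(0.05) + sps.norm.isf(0.2)) / dz) ** 2
              for dz in (0.2, 0.4)]
    assert ns[0] / ns[1] == pytest.approx(approx[0] / approx[1], rel=0.25)
    with pytest.raises(ValueError):
        required_n_paired_t(-0.1)
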