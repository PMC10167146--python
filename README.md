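# pdec — smooth-pursuit perceptual-decoupling analysis

When attention turns inward — doing mental arithmetic, navigating an
imagined map — processing of the visual world is attenuated (*perceptual
decoupling*), and smooth pursuit eye movements (SPEM) degrade in measurable
ways: the eye falls behind the target, slows down, and compensates with
catch-up saccades, while pupil diameter indexes the internal workload.
`pdec` is a toolkit for quantifying these effects in dual-task pursuit
experiments. It is aimed at eye-movement and pupillometry researchers who
want a tested, reproducible pipeline from raw 1000-Hz binocular samples to
per-time-bin statistics — plus a synthetic-data generator with ground-truth
event logs, so every pipeline stage can be validated against a known
answer.

## What it computes

The external task is circular pursuit (radius 5.4°, 6.8 °/s,
counterclockwise) performed alone (single-task control) or together with an
arithmetic or visuospatial internal task at low or high workload. For each
trial, split into seven 0.5-s bins from the operation-cue onset, the
pipeline yields:

* **GTD** — gaze-to-target distance `‖gaze − target‖` (dva); samples with
  GTD > 6.8° (the target's 1-s travel) are excluded as "target lost";
* **VG** — velocity gain `100 · ‖dgaze/dt‖ / 6.8` (%) on SPEM samples
  moving ≥ 0.5 °/s;
* **CUS / AS rates** — catch-up saccades (distance-decreasing) and
  anticipatory saccades (distance-increasing) per second, from a
  two-threshold detector (velocity > 22 °/s, acceleration > 4000 °/s²,
  ≥ 6 ms; amplitudes < 1° are microsaccades);
* **PD** — median pupil diameter after smoothing (20-sample moving
  average), blink interpolation (blinks padded ±100 ms), and 3-SD/saccade
  exclusions.

Bins/trials/blocks/participants with more than 50% missing data are
excluded bottom-up, per metric family. The statistics layer runs the
manipulation-check 2×2 within-subject ANOVA on block accuracy and, per bin,
the three planned workload contrasts (paired t, Bonferroni within bin,
Cohen's d_z, JZS Bayes factor with Cauchy(0, √2/2) prior), plus the exact
noncentral-t power computation for paired designs.

See `docs/methods.md` for the models, defaults, and design decisions.

## Worked example

```python
import numpy as np
from pdec import generate_design, SimulationConfig, required_n_paired_t, jzs_bayes_factor
from pdec.pipeline import simulate_and_bin

design = generate_design(participant_id=0, seed=1)
print("trials:", design.n_trials, "| task order:", design.task_order)

# simulate one control and one high-load arithmetic block, run the pipeline
picks = [next(b for b in design.blocks
              if b.modality == "arithmetic" and b.load == l)
         for l in ("single", "high")]
binned = simulate_and_bin(design, SimulationConfig(seed=1), blocks=picks)
print(binned.groupby(["load", "bin_index"])[
    ["median_gtd_dva", "median_vg_percent", "cus_rate_hz", "median_pd_mm"]]
    .mean().round(3).loc[("high", slice(1, 4)), :])

print("a-priori n for dz=0.4:", required_n_paired_t(0.4, tails=1))
print("BF10 for t=3.2, n=40:", round(jzs_bayes_factor(3.2, 40), 1))
```

prints

```
trials: 600 | task order: ('arithmetic', 'visuospatial')
                median_gtd_dva  median_vg_percent  cus_rate_hz  median_pd_mm
load bin_index
high 1                   0.789             92.147        0.000         4.201
     2                   0.194             92.245        1.818         4.258
     3                   0.320             92.187        0.182         4.341
     4                   0.577             92.336        0.182         4.279
a-priori n for dz=0.4: 41
BF10 for t=3.2, n=40: 12.6
```

The design always totals 600 trials (300 per modality, 100 per workload
level and modality). The simulated block was generated with pursuit gain
0.92 and 100-ms lag, and the pipeline reads both back: median VG sits at
~92% and GTD fluctuates around the lag chord (≈ 0.68 dva) as catch-up
saccades (bin-2 rate above) repeatedly re-capture the target. Pupil
diameter peaks in bin 3, 1.25 s after the cue, as configured. The power
routine reproduces the canonical n = 41 for dz = 0.4 at 80% power
(one-tailed, α = .05), and the Bayes factor lands in the 3–20 "moderate
evidence" band.

## Command line

```bash
pdec simulate   --seed 1 --out run/            # design + synthetic recordings
pdec preprocess --seed 1 --samples run/samples_b0.csv --out run/pre/
pdec metrics    --seed 1 --samples run/samples_b0.csv \
                --events run/events.csv --block-id b0 --out run/met/
pdec analyze    --seed 1 --binned run/met/binned.csv --out run/an/
```

Every exclusion is logged with counts; the seed is recorded in all outputs.

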