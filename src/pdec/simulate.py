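"""Synthetic binocular gaze and pupil recordings during circular pursuit.

The generative model is deliberately phase-based: the pursuit target moves
counterclockwise on a circle (radius 5.4 dva) at 6.8 dva/s starting at
12 o'clock, and the eye is a point on the same circle whose phase advances at
``gain`` times the target's angular velocity, starting ``lag_ms`` behind.
Velocity gain and positional lag are therefore independently controllable,
which is what makes parameter-recovery testing possible: between saccades the
eye's path speed is exactly ``gain * 6.8`` dva/s, and under gain 1 the
gaze-to-target distance is the constant chord ``2 * r * sin(omega * lag / 2)``.

Catch-up saccades are triggered endogenously whenever the (noise-free)
gaze-to-target distance exceeds ``catchup_trigger_dva`` and land on the
target; anticipatory saccades occur at a Poisson rate and land ahead of the
target along its path; microsaccades are small random phase jumps. All
saccades follow a raised-cosine velocity profile (peak velocity
``2 * amplitude / duration``). Blinks blank both eyes and the pupil, with
20-ms partial-occlusion pupil ramps at their edges. Every injected event is
recorded in a :class:`GroundTruthLog`, the known-answer oracle for the
detection and classification stages. Saccades are scheduled outside
blink-padded zones so that injected events are detectable by design.

Pupil diameter is baseline + a load-dependent tonic offset + a phasic
dilation kernel peaking ``phasic_peak_s`` after the operation cue (absent in
the single-task control) + slow noise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .design import BlockSpec, ExperimentDesign, TrialSpec
from .io_formats import SAMPLE_COLUMNS, SampleTable


@dataclass
class TargetTrajectory:
    """Parametric circular pursuit target.

    Defaults describe the canonical stimulus: radius 5.4 dva, path speed
    6.8 dva/s, counterclockwise (direction +1), starting at the top of the
    circle (phase pi/2 under the screen-centered, +y-up convention).
    """

    radius: float = 5.4
    speed: float = 6.8
    direction: int = 1
    phase0: float = math.pi / 2
    center: tuple[float, float] = (0.0, 0.0)

    @property
    def omega(self) -> float:
        """Signed angular velocity in rad/s."""
        return self.direction * self.speed / self.radius

    def phase(self, t):
        return self.phase0 + self.omega * np.asarray(t, dtype=float)


def target_position(t, traj: TargetTrajectory | None = None):
    """Target (x, y) in dva at time ``t`` seconds (scalar or array)."""
    traj = traj or TargetTrajectory()
    ang = traj.phase(t)
    x = traj.center[0] + traj.radius * np.cos(ang)
    y = traj.center[1] + traj.radius * np.sin(ang)
    return (x, y) if np.ndim(t) else (float(x), float(y))


@dataclass
class SimulationConfig:
    """Generative parameters; defaults are the package's standard conditions.

    Tonic pupil offsets are ordered single < low < high and the phasic
    dilation peaks 1.25 s after cue onset, emulating a workload-sensitive
    pupil response. Positional noise is temporally correlated (Gaussian
    kernel, ``noise_corr_ms``) to mimic slow drift rather than white sensor
    noise.
    """

    sampling_rate: int = 1000
    gain: float = 0.92
    lag_ms: float = 100.0
    pos_noise_sd: float = 0.02          # dva, per eye
    noise_corr_ms: float = 20.0
    catchup_trigger_dva: float = 1.0
    anticipatory_rate_hz: float = 0.10
    anticipatory_lead_dva: float = 0.9
    micro_rate_hz: float = 0.10
    micro_amp_dva: tuple[float, float] = (0.2, 0.8)
    saccade_duration_ms: float = 25.0
    saccade_refractory_ms: float = 150.0
    blink_rate_hz: float = 0.10
    blink_duration_ms: float = 150.0
    pupil_baseline_mm: float = 4.0
    tonic_offset_mm: dict = field(default_factory=lambda: {
        "single": 0.0, "low": 0.10, "high": 0.20})
    phasic_amp_mm: float = 0.15
    phasic_peak_s: float = 1.25
    phasic_width_s: float = 1.0
    pupil_noise_sd: float = 0.02
    interocular_offset_dva: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        for name in ("anticipatory_rate_hz", "micro_rate_hz", "blink_rate_hz"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class InjectedSaccade:
    onset_ms: int
    offset_ms: int
    category: str          # 'catchup' | 'anticipatory' | 'micro'
    amplitude_dva: float
    dx: float
    dy: float


@dataclass
class GroundTruthLog:
    """Record of every injected event plus per-sample true labels."""

    saccades: list[InjectedSaccade] = field(default_factory=list)
    blinks: list[tuple[int, int]] = field(default_factory=list)  # raw, pre-pad
    labels: np.ndarray | None = None   # 'spem'|'saccade'|'micro'|'blink'
    gain: float = 1.0
    lag_ms: float = 0.0
    rejected: list[dict] = field(default_factory=list)


def _correlated_noise(n: int, sd: float, corr_ms: float, fs: int,
                      rng: np.random.Generator) -> np.ndarray:
    if sd == 0 or n == 0:
        return np.zeros(n)
    sigma = corr_ms * fs / 1000.0
    raw = gaussian_filter1d(rng.standard_normal(n + int(8 * sigma) + 8),
                            sigma)[4 + int(4 * sigma):][:n]
    # analytic sd of Gaussian-filtered unit white noise
    theoretical_sd = math.sqrt(1.0 / (2.0 * sigma * math.sqrt(math.pi)))
    return raw * (sd / theoretical_sd)


def _raised_cosine_progress(k: int) -> np.ndarray:
    """Position progress S(tau) of a raised-cosine velocity profile over k
    samples: S'(tau) ~ 1 - cos(2 pi tau), S(0)=0, S(1)=1."""
    tau = np.arange(k) / k
    return tau - np.sin(2 * np.pi * tau) / (2 * np.pi)


def phasic_kernel(t_s: np.ndarray, peak_s: float, width_s: float) -> np.ndarray:
    """Unimodal dilation kernel, unit peak at ``peak_s``, FWHM ~ ``width_s``.

    Gamma-shaped ``(t/tp)^a exp(a (1 - t/tp))`` with the shape parameter set
    from the requested width; zero for t < 0.
    """
    a = (2.355 * peak_s / width_s) ** 2
    t = np.maximum(np.asarray(t_s, dtype=float), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        k = np.where(t > 0, np.exp(a * (np.log(t / peak_s) + 1 - t / peak_s)), 0.0)
    return k


def pupil_timecourse(trial: TrialSpec, load: str, config: SimulationConfig,
                     n_samples: int | None = None) -> np.ndarray:
    """Deterministic pupil trace (mm) for one trial, cue onset at t = 0.

    baseline + tonic offset for the workload level + phasic kernel; the
    single-task control has no phasic component (cues are ignored).
    """
    n = n_samples if n_samples is not None else trial.isi_ms
    t = np.arange(n) / config.sampling_rate
    pd_mm = np.full(n, config.pupil_baseline_mm + config.tonic_offset_mm[load])
    if load != "single" and config.phasic_amp_mm > 0:
        pd_mm = pd_mm + config.phasic_amp_mm * phasic_kernel(
            t, config.phasic_peak_s, config.phasic_width_s)
    return pd_mm


def _poisson_times(rate_hz: float, n: int, fs: int,
                   rng: np.random.Generator) -> np.ndarray:
    if rate_hz <= 0:
        return np.array([], dtype=int)
    count = rng.poisson(rate_hz * n / fs)
    return np.sort(rng.integers(0, n, size=count))


def simulate_trial(trial: TrialSpec, config: SimulationConfig,
                   traj: TargetTrajectory, rng: np.random.Generator,
                   t0_s: float = 0.0, load: str = "single"
                   ) -> tuple[SampleTable, GroundTruthLog]:
    """Synthesize one trial (cue onset to next cue onset) of binocular samples.

    ``t0_s`` is the trial's cue onset on the block clock, so the target phase
    is continuous across the trials of a block. Returns the samples (with
    trial-local ``time_ms``) and the ground-truth log.
    """
    fs = config.sampling_rate
    n = trial.isi_ms * fs // 1000
    dt = 1.0 / fs
    omega, r = traj.omega, traj.radius
    g = config.gain
    if config.pos_noise_sd > 0 and config.catchup_trigger_dva <= 3 * config.pos_noise_sd:
        warnings.warn("catchup_trigger_dva is at the noise floor: expect a saccade storm")

    log = GroundTruthLog(gain=g, lag_ms=config.lag_ms)
    labels = np.full(n, "spem", dtype=object)

    # --- blinks first: they define zones where no saccade may be scheduled
    blink_len = int(round(config.blink_duration_ms * fs / 1000))
    blink_mask = np.zeros(n, dtype=bool)
    forbidden = np.zeros(n, dtype=bool)
    sac_len = int(round(config.saccade_duration_ms * fs / 1000))
    guard = 100 * fs // 1000 + sac_len + 5   # blink pad + saccade length + margin
    for b0 in _poisson_times(config.blink_rate_hz, n, fs, rng):
        b1 = min(int(b0) + blink_len, n)
        if blink_mask[max(0, b0 - guard):min(n, b1 + guard)].any():
            continue
        blink_mask[b0:b1] = True
        log.blinks.append((int(b0), int(b1)))
        forbidden[max(0, b0 - guard):min(n, b1 + guard)] = True

    # --- scheduled (exogenous) saccade onsets: anticipatory + micro
    scheduled: list[tuple[int, str]] = \
        [(int(i), "anticipatory") for i in
         _poisson_times(config.anticipatory_rate_hz, n, fs, rng)] + \
        [(int(i), "micro") for i in
         _poisson_times(config.micro_rate_hz, n, fs, rng)]
    scheduled = sorted((i, c) for i, c in scheduled if not forbidden[i])

    delta_trig = 2 * math.asin(min(config.catchup_trigger_dva / (2 * r), 1.0))
    drift = (1 - g) * omega          # d(phase deficit)/dt

    phases = np.empty(n)
    sacc_xy: list[tuple[int, np.ndarray, np.ndarray]] = []  # (start, x, y)
    theta = traj.phase0 + omega * (t0_s - config.lag_ms / 1000.0)
    i = 0
    min_next = 0                     # refractory: earliest allowed next onset
    refr = int(round(config.saccade_refractory_ms * fs / 1000))
    sched_pos = 0
    while i < n:
        delta_i = (traj.phase0 + omega * (t0_s + i * dt)) - theta
        # endogenous catch-up: first sample where |deficit| reaches threshold.
        # The deficit evolves linearly, delta(t) = delta_i + drift*t, so the
        # crossing of the threshold on the drift side is solved analytically.
        if abs(delta_i) >= delta_trig and config.catchup_trigger_dva < 2 * r:
            j_catch = i
        elif drift != 0:
            t_cross = (math.copysign(delta_trig, drift) - delta_i) / drift
            j_catch = i + int(math.ceil(t_cross / dt))
        else:
            j_catch = n
        j_catch = max(j_catch, min_next)
        while j_catch < n and forbidden[j_catch]:
            j_catch += 1
        while sched_pos < len(scheduled) and scheduled[sched_pos][0] < max(i, min_next):
            sched_pos += 1
        j_sched, cat_sched = (scheduled[sched_pos]
                              if sched_pos < len(scheduled) else (n, ""))
        j, category = (j_catch, "catchup") if j_catch <= j_sched else (j_sched, cat_sched)
        j = min(j, n)
        k = np.arange(j - i)
        phases[i:j] = theta + g * omega * k * dt
        if j >= n or j + sac_len > n:
            if j < n:
                k = np.arange(n - i)
                phases[i:n] = theta + g * omega * k * dt
            break
        theta_pre = theta + g * omega * (j - i) * dt
        off = j + sac_len
        if category != "catchup":
            sched_pos += 1           # consume the scheduled event
        if category == "catchup":
            theta_post = traj.phase0 + omega * (t0_s + off * dt)
        elif category == "anticipatory":
            # anticipatory saccades occur when pursuit is still close to the
            # target (as in real pursuit); a lagging eye gets catch-ups instead
            delta_pre = (traj.phase0 + omega * (t0_s + j * dt)) - theta_pre
            if 2 * r * math.sin(abs(delta_pre) / 2) > 0.6 * config.anticipatory_lead_dva:
                continue
            theta_post = (traj.phase0 + omega * (t0_s + off * dt)
                          + np.sign(omega) * config.anticipatory_lead_dva / r)
        else:  # micro: small phase jump, random direction
            amp = rng.uniform(*config.micro_amp_dva)
            theta_post = theta_pre + rng.choice([-1, 1]) * amp / r
        p0 = np.array([traj.center[0] + r * math.cos(theta_pre),
                       traj.center[1] + r * math.sin(theta_pre)])
        p1 = np.array([traj.center[0] + r * math.cos(theta_post),
                       traj.center[1] + r * math.sin(theta_post)])
        disp = p1 - p0
        amp_dva = float(np.hypot(*disp))
        if amp_dva > 1e-12:
            s = _raised_cosine_progress(sac_len)
            sacc_xy.append((j, p0[0] + s * disp[0], p0[1] + s * disp[1]))
            # the logged category follows the operational definitions: by
            # amplitude for micro, else by the distance change the saccade
            # actually produces (the scheduling mechanism is not the label)
            ton = np.array(target_position(t0_s + j * dt, traj))
            toff = np.array(target_position(t0_s + off * dt, traj))
            d_on = float(np.hypot(*(p0 - ton)))
            d_off = float(np.hypot(*(p1 - toff)))
            true_cat = "micro" if amp_dva < 1.0 else (
                "catchup" if d_off < d_on else "anticipatory")
            labels[j:off] = "micro" if true_cat == "micro" else "saccade"
            log.saccades.append(InjectedSaccade(
                onset_ms=int(j * 1000 / fs), offset_ms=int(off * 1000 / fs),
                category=true_cat, amplitude_dva=amp_dva,
                dx=float(disp[0]), dy=float(disp[1])))
        theta = theta_post
        i = off
        min_next = off + refr

    x = traj.center[0] + r * np.cos(phases)
    y = traj.center[1] + r * np.sin(phases)
    for start, sx, sy in sacc_xy:
        x[start:start + len(sx)] = sx
        y[start:start + len(sy)] = sy

    # binocular channels: cyclopean +/- half the interocular offset, plus
    # per-eye correlated positional noise
    half = config.interocular_offset_dva / 2.0
    xl = x - half + _correlated_noise(n, config.pos_noise_sd, config.noise_corr_ms, fs, rng)
    yl = y + _correlated_noise(n, config.pos_noise_sd, config.noise_corr_ms, fs, rng)
    xr = x + half + _correlated_noise(n, config.pos_noise_sd, config.noise_corr_ms, fs, rng)
    yr = y + _correlated_noise(n, config.pos_noise_sd, config.noise_corr_ms, fs, rng)

    pd_mm = pupil_timecourse(trial, load, config, n_samples=n)
    if config.pupil_noise_sd > 0:
        pd_mm = pd_mm + _correlated_noise(n, config.pupil_noise_sd, 50.0, fs, rng)
    pdl = pd_mm.copy()
    pdr = pd_mm.copy()

    valid = np.ones(n, dtype=bool)
    ramp_len = 20 * fs // 1000
    for b0, b1 in log.blinks:
        valid[b0:b1] = False
        labels[b0:b1] = "blink"
        for arr in (xl, yl, xr, yr, pdl, pdr):
            arr[b0:b1] = np.nan
        # partial lid occlusion: pupil dips on the shoulders of the blink
        lo = max(0, b0 - ramp_len)
        if lo < b0:
            ramp = np.linspace(1.0, 0.4, b0 - lo)
            pdl[lo:b0] *= ramp
            pdr[lo:b0] *= ramp
        hi = min(n, b1 + ramp_len)
        if b1 < hi:
            ramp = np.linspace(0.4, 1.0, hi - b1)
            pdl[b1:hi] *= ramp
            pdr[b1:hi] *= ramp

    log.labels = labels
    df = pd.DataFrame({
        "time_ms": np.arange(n) * 1000 // fs,
        "xl": xl, "yl": yl, "xr": xr, "yr": yr,
        "pdl": pdl, "pdr": pdr,
        "valid_l": valid, "valid_r": valid.copy(),
    }, columns=SAMPLE_COLUMNS)
    return SampleTable(df), log


def inject_saccade(series: SampleTable, onset_ms: int,
                   displacement: tuple[float, float], duration_ms: int,
                   log: GroundTruthLog | None = None) -> SampleTable:
    """Add a ballistic raised-cosine saccade to an existing sample series.

    The displacement is added to both eyes from ``onset_ms`` over
    ``duration_ms`` (and persists afterwards). Zero displacement returns the
    series unchanged. An injection overlapping a saccade already in ``log``
    is rejected and recorded in ``log.rejected``.
    """
    if duration_ms < 10:
        raise ValueError("saccade duration must be >= 10 ms")
    dx, dy = displacement
    if dx == 0 and dy == 0:
        return series
    df = series.data
    t = df["time_ms"].to_numpy()
    if onset_ms < t[0] or onset_ms + duration_ms > t[-1] + 1:
        raise ValueError("saccade interval outside the series")
    if log is not None:
        for s in log.saccades:
            if onset_ms < s.offset_ms and onset_ms + duration_ms > s.onset_ms:
                log.rejected.append({"onset_ms": onset_ms,
                                     "reason": "overlaps existing saccade"})
                return series
    out = df.copy()
    inside = (t >= onset_ms) & (t < onset_ms + duration_ms)
    after = t >= onset_ms + duration_ms
    k = int(inside.sum())
    s = _raised_cosine_progress(k)
    amp = math.hypot(dx, dy)
    for col, d in (("xl", dx), ("yl", dy), ("xr", dx), ("yr", dy)):
        vals = out[col].to_numpy(dtype=float)
        vals[inside] += s * d
        vals[after] += d
        out[col] = vals
    if log is not None:
        log.saccades.append(InjectedSaccade(
            onset_ms=int(onset_ms), offset_ms=int(onset_ms + duration_ms),
            category="micro" if amp < 1.0 else "unlabelled",
            amplitude_dva=amp, dx=dx, dy=dy))
    return SampleTable(out, pupil_units=series.pupil_units)


def simulate_block(block: BlockSpec, config: SimulationConfig,
                   traj: TargetTrajectory, rng: np.random.Generator
                   ) -> tuple[SampleTable, GroundTruthLog]:
    """Simulate all trials of a block on a common block clock.

    Trial traces are concatenated; ground-truth event times are shifted to
    block time. The target phase is continuous across the block.
    """
    frames, log = [], GroundTruthLog(gain=config.gain, lag_ms=config.lag_ms)
    labels = []
    for trial in block.trials:
        table, tlog = simulate_trial(trial, config, traj, rng,
                                     t0_s=trial.cue_onset_ms / 1000.0,
                                     load=block.load)
        df = table.data.copy()
        df["time_ms"] = df["time_ms"] + trial.cue_onset_ms
        frames.append(df)
        off = trial.cue_onset_ms
        log.saccades.extend(InjectedSaccade(
            s.onset_ms + off, s.offset_ms + off, s.category,
            s.amplitude_dva, s.dx, s.dy) for s in tlog.saccades)
        log.blinks.extend((b0 + off, b1 + off) for b0, b1 in tlog.blinks)
        labels.append(tlog.labels)
    log.labels = np.concatenate(labels) if labels else None
    data = pd.concat(frames, ignore_index=True)
    return SampleTable(data), log
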