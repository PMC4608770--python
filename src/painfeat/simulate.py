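"""Seeded synthetic-data generator for the heat-pain protocol.

Emulates the structure of the experimental dataset: per subject, 20
applications of each of four calibrated temperature levels (T1 pain
threshold .. T4 pain tolerance) in randomized order with 4 s plateaus and
8-12 s randomized pauses, plus stimulus-free baseline stretches, recorded on
five channels (zygomaticus / corrugator / trapezius EMG, skin conductance
level, ECG).

The generative model is intentionally simple — it reproduces the statistical
structure the downstream features measure, not biophysical morphology:

* EMG: zero-mean band-limited (20-250 Hz) Gaussian noise whose scale is
  multiplied by a level-dependent burst gain during each stimulus, with a
  smooth on/off envelope.  Facial muscles respond more strongly than the
  trapezius.
* SCL: per-subject tonic level with slow drift plus, per stimulus, a phasic
  response of level-dependent amplitude after a 1-3 s onset latency
  (exponential rise/decay kernel).
* ECG: narrow QRS-like impulse train; RR intervals are Gaussian with an
  AR(1) successive-difference structure, and the mean RR is shortened by a
  level-dependent amount while a stimulus is active.

Per-subject baseline scales are randomized (log-normal) so that per-person
z-normalization downstream is non-trivial.  A single root seed fans out into
independent per-subject streams, so any subject is reproducible in
isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal as sps

from painfeat.core import (
    PAIN_LEVELS,
    Recording,
    StimulusEvent,
    StimulusSchedule,
    ConfigError,
)


def _level_map(values) -> dict[str, float]:
    return dict(zip(PAIN_LEVELS, values))


@dataclass
class SimConfig:
    """Simulation parameters (defaults follow the standard protocol).

    Effect-size vectors are indexed T1..T4 and must be monotone
    non-decreasing: higher temperature, stronger response.
    """

    n_subjects: int = 85
    reps_per_level: int = 20
    n_levels: int = 4
    plateau_s: float = 4.0
    pause_range_s: tuple[float, float] = (8.0, 12.0)
    window_s: float = 5.5
    fs: float = 512.0
    lead_in_s: float = 10.0
    lead_out_s: float = 10.0

    #: probability that a stimulus elicits any measurable EMG/SCL response;
    #: near threshold many trials are non-responses, at tolerance all respond
    response_prob: tuple[float, ...] = (0.6, 0.75, 0.9, 1.0)

    # EMG: multiplicative noise-scale gain per level during a stimulus
    emg_burst_gain: tuple[float, ...] = (1.10, 1.30, 1.70, 2.50)
    #: trapezius responds less than the facial muscles: gain_tra = 1 + f*(g-1)
    trapezius_gain_fraction: float = 0.6
    emg_sigma0: float = 10e-6  # baseline EMG scale, volts (10 uV RMS)
    #: trial-to-trial log-normal jitter of the gain excess (g-1)
    emg_gain_jitter_sigma: float = 0.25
    #: spontaneous (stimulus-unrelated) EMG activity bursts
    emg_spont_rate_per_min: float = 2.0
    emg_spont_gain: float = 1.6
    emg_spont_dur_s: tuple[float, float] = (0.3, 1.5)

    # SCL: phasic response amplitude per level, microsiemens
    scl_phasic_amp: tuple[float, ...] = (0.05, 0.12, 0.25, 0.50)
    scl_level_uS: float = 5.0
    scl_drift_amp: float = 0.10      # uS, slow tonic drift scale
    scl_noise_uS: float = 0.02
    scl_latency_range_s: tuple[float, float] = (1.0, 3.0)
    scl_rise_s: float = 0.8
    scl_decay_s: float = 3.0
    #: trial-to-trial log-normal jitter of phasic amplitudes
    scl_amp_jitter_sigma: float = 0.5
    #: spontaneous (non-specific) skin-conductance responses
    scl_spont_rate_per_min: float = 3.0
    scl_spont_amp_uS: float = 0.04
    scl_spont_amp_sigma: float = 0.7

    # ECG: mean RR shortening per level during a stimulus, milliseconds
    rr_shortening_ms: tuple[float, ...] = (5.0, 12.0, 30.0, 60.0)
    mean_rr_ms: float = 800.0
    sdnn_ms: float = 40.0
    rr_ar1: float = 0.8              # lag-1 coefficient of RR deviations
    ecg_noise: float = 0.02          # additive noise on the 1 mV QRS train

    #: log-normal sigma of per-subject baseline-scale randomization
    subject_scale_sigma: float = 0.25

    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.reps_per_level < 1:
            raise ConfigError("reps_per_level must be >= 1")
        if self.fs <= 0:
            raise ConfigError("fs must be positive")
        for name in ("emg_burst_gain", "scl_phasic_amp", "rr_shortening_ms",
                     "response_prob"):
            v = np.asarray(getattr(self, name), dtype=float)
            if len(v) != self.n_levels:
                raise ConfigError(f"{name} must have {self.n_levels} entries")
            if np.any(np.diff(v) < 0):
                raise ConfigError(f"{name} must be monotone non-decreasing in level")
        if np.any(np.asarray(self.emg_burst_gain) < 1.0):
            raise ConfigError("emg_burst_gain entries must be >= 1")

    def gain_map(self, role: str) -> dict[str, float]:
        g = np.asarray(self.emg_burst_gain, dtype=float)
        if role == "emg_tra":
            g = 1.0 + self.trapezius_gain_fraction * (g - 1.0)
        return _level_map(g)

    def to_dict(self) -> dict:
        return asdict(self)


def generate_schedule(cfg: SimConfig, rng: np.random.Generator) -> StimulusSchedule:
    """Random stimulus order with uniform pauses and mid-pause baselines.

    Each level appears ``reps_per_level`` times in a random permutation;
    pauses between plateau end and the next onset are i.i.d. uniform on
    ``pause_range_s``.  ``reps_per_level`` baseline windows are placed inside
    pauses (2 s after the plateau ends) on an evenly spaced subset of pauses,
    so the class counts are balanced (standard protocol: 80 stimuli + 20
    baseline windows).
    """
    levels = np.repeat(PAIN_LEVELS[: cfg.n_levels], cfg.reps_per_level)
    order = rng.permutation(len(levels))
    levels = [levels[i] for i in order]

    events: list[StimulusEvent] = []
    pause_starts: list[float] = []
    t = cfg.lead_in_s
    lo, hi = cfg.pause_range_s
    for lv in levels:
        events.append(StimulusEvent(level=lv, onset_s=round(t, 6), plateau_s=cfg.plateau_s))
        t += cfg.plateau_s
        pause_starts.append(t)
        t += rng.uniform(lo, hi)

    n_b = cfg.reps_per_level
    idx = np.unique(np.linspace(0, len(pause_starts) - 1, n_b).round().astype(int))
    baselines = [round(pause_starts[i] + 2.0, 6) for i in idx]

    return StimulusSchedule(events=events, baseline_windows=baselines,
                            pause_range_s=cfg.pause_range_s)


def schedule_duration_s(schedule: StimulusSchedule, cfg: SimConfig) -> float:
    """Recording length needed to contain all events, windows and lead-out."""
    t = cfg.lead_in_s
    for ev in schedule.events:
        t = max(t, ev.onset_s + max(ev.plateau_s, cfg.window_s))
    for b in schedule.baseline_windows:
        t = max(t, b + cfg.window_s)
    return t + cfg.lead_out_s


def _gain_envelope(n: int, fs: float, spans: list[tuple[float, float, float]],
                   ramp_s: float = 0.5) -> np.ndarray:
    """Multiplicative scale envelope: 1 at rest, span gain during activity.

    ``spans`` are (start_s, end_s, gain) intervals; the transition in/out of
    each interval is a raised-cosine ramp of ``ramp_s`` seconds, so bursts
    switch on and off smoothly.  Overlaps take the maximum.
    """
    env = np.ones(n)
    t = np.arange(n) / fs
    for a, b, g in spans:
        if g <= 1.0:
            continue
        m = (t > a - ramp_s) & (t < b + ramp_s)
        tt = t[m]
        shape = np.ones_like(tt)
        rise = tt < a
        fall = tt > b
        shape[rise] = 0.5 * (1 + np.cos(np.pi * (a - tt[rise]) / ramp_s))
        shape[fall] = 0.5 * (1 + np.cos(np.pi * (tt[fall] - b) / ramp_s))
        env[m] = np.maximum(env[m], 1.0 + (g - 1.0) * shape)
    return env


def synth_emg(schedule: StimulusSchedule, channel_role: str, cfg: SimConfig,
              rng: np.random.Generator, n_samples: int | None = None,
              sigma0: float | None = None) -> np.ndarray:
    """Band-limited EMG noise with level-dependent burst gains.

    Stimulus bursts carry trial-to-trial log-normal jitter of the gain
    excess; spontaneous short activity bursts occur at
    ``emg_spont_rate_per_min`` independently of the stimuli, so baseline
    stretches are not perfectly quiet.
    """
    if n_samples is None:
        n_samples = int(round(schedule_duration_s(schedule, cfg) * cfg.fs))
    sigma0 = cfg.emg_sigma0 if sigma0 is None else sigma0
    white = rng.standard_normal(n_samples)
    hi = min(250.0, 0.99 * cfg.fs / 2)
    sos = sps.butter(4, [20.0, hi], btype="bandpass", fs=cfg.fs, output="sos")
    x = sps.sosfiltfilt(sos, white)
    x *= sigma0 / max(np.std(x), 1e-30)

    gains = cfg.gain_map(channel_role)
    resp = _level_map(cfg.response_prob)
    spans: list[tuple[float, float, float]] = []
    for ev in schedule.events:
        g = gains[ev.level]
        if rng.uniform() > resp[ev.level]:
            g = 1.0  # non-response trial
        if cfg.emg_gain_jitter_sigma > 0 and g > 1.0:
            g = 1.0 + (g - 1.0) * np.exp(cfg.emg_gain_jitter_sigma * rng.standard_normal())
        spans.append((ev.onset_s, ev.onset_s + ev.plateau_s, g))
    duration = n_samples / cfg.fs
    n_spont = rng.poisson(cfg.emg_spont_rate_per_min * duration / 60.0)
    lo_d, hi_d = cfg.emg_spont_dur_s
    for _ in range(n_spont):
        t0 = rng.uniform(0, duration)
        spans.append((t0, t0 + rng.uniform(lo_d, hi_d), cfg.emg_spont_gain))
    env = _gain_envelope(n_samples, cfg.fs, spans)
    return x * env


def _scr_kernel(fs: float, rise_s: float, decay_s: float) -> np.ndarray:
    """Phasic skin-conductance response kernel, normalized to unit peak."""
    t = np.arange(0, rise_s + 6 * decay_s, 1 / fs)
    k = (1 - np.exp(-t / rise_s)) * np.exp(-t / decay_s)
    return k / k.max()


def synth_scl(schedule: StimulusSchedule, cfg: SimConfig, rng: np.random.Generator,
              n_samples: int | None = None, level_uS: float | None = None) -> np.ndarray:
    """Tonic skin conductance with per-stimulus phasic responses.

    Each stimulus elicits a response with onset latency uniform on
    ``scl_latency_range_s`` and amplitude ``scl_phasic_amp[level]``.
    """
    if n_samples is None:
        n_samples = int(round(schedule_duration_s(schedule, cfg) * cfg.fs))
    level_uS = cfg.scl_level_uS if level_uS is None else level_uS

    # slow tonic drift: random-phase low-frequency sinusoids, unit RMS.
    # Peak amplitude is bounded by sqrt(2 k) x scale, so the tonic-only
    # trace stays within a deterministic envelope of the drift scale.
    drift = np.zeros(n_samples)
    if cfg.scl_drift_amp > 0:
        k_sin = 8
        t = np.arange(n_samples) / cfg.fs
        freqs = rng.uniform(0.003, 0.03, k_sin)
        phases = rng.uniform(0, 2 * np.pi, k_sin)
        slow = np.sum([np.sin(2 * np.pi * f * t + p)
                       for f, p in zip(freqs, phases)], axis=0)
        drift = cfg.scl_drift_amp * slow / np.sqrt(k_sin / 2.0)

    x = level_uS + drift
    amp = _level_map(cfg.scl_phasic_amp)
    kern = _scr_kernel(cfg.fs, cfg.scl_rise_s, cfg.scl_decay_s)
    lo, hi = cfg.scl_latency_range_s

    def _add_scr(onset_s: float, a: float) -> None:
        i0 = int(round(onset_s * cfg.fs))
        if i0 >= n_samples or a <= 0:
            return
        j = min(n_samples, i0 + len(kern))
        x[i0:j] += a * kern[: j - i0]

    resp = _level_map(cfg.response_prob)
    for ev in schedule.events:
        a = amp[ev.level]
        if rng.uniform() > resp[ev.level]:
            a = 0.0  # non-response trial
        if cfg.scl_amp_jitter_sigma > 0 and a > 0:
            a *= np.exp(cfg.scl_amp_jitter_sigma * rng.standard_normal())
        _add_scr(ev.onset_s + rng.uniform(lo, hi), a)

    # spontaneous (non-specific) SCRs, uniform over the recording
    duration = n_samples / cfg.fs
    n_spont = rng.poisson(cfg.scl_spont_rate_per_min * duration / 60.0)
    for _ in range(n_spont):
        a = cfg.scl_spont_amp_uS * np.exp(cfg.scl_spont_amp_sigma * rng.standard_normal())
        _add_scr(rng.uniform(0, duration), a)

    if cfg.scl_noise_uS > 0:
        x = x + cfg.scl_noise_uS * rng.standard_normal(n_samples)
    return x


def _qrs_template(fs: float) -> np.ndarray:
    """Narrow biphasic spike standing in for the QRS complex (peak 1.0)."""
    n = int(round(0.08 * fs)) | 1
    t = (np.arange(n) - n // 2) / fs
    a = 0.012  # width parameter ~12 ms, QRS-like
    w = (1 - (t / a) ** 2) * np.exp(-(t ** 2) / (2 * a ** 2))
    return w / np.abs(w).max()


def simulate_rr_sequence(schedule: StimulusSchedule, cfg: SimConfig,
                         rng: np.random.Generator, duration_s: float,
                         response_lag_s: float = 1.0) -> np.ndarray:
    """Beat times (seconds) with AR(1) RR variability and stimulus shortening."""
    shorten = _level_map(np.asarray(cfg.rr_shortening_ms) / 1000.0)
    mean_rr = cfg.mean_rr_ms / 1000.0
    sd_innov = (cfg.sdnn_ms / 1000.0) * np.sqrt(max(1 - cfg.rr_ar1 ** 2, 1e-12))

    # active-level lookup per time
    spans = [(ev.onset_s + response_lag_s, ev.onset_s + cfg.window_s + response_lag_s,
              shorten[ev.level]) for ev in schedule.events]

    beats = [0.0]
    dev = 0.0
    t = 0.0
    while t < duration_s:
        s = 0.0
        for a, b, sh in spans:
            if a <= t <= b:
                s = sh
                break
        if cfg.sdnn_ms > 0:
            dev = cfg.rr_ar1 * dev + sd_innov * rng.standard_normal()
        rr = max(mean_rr - s + dev, 0.25)
        t += rr
        beats.append(t)
    return np.asarray(beats[:-1])


def synth_ecg(schedule: StimulusSchedule, cfg: SimConfig, rng: np.random.Generator,
              n_samples: int | None = None) -> np.ndarray:
    """QRS-like impulse train with modulated RR intervals."""
    if n_samples is None:
        n_samples = int(round(schedule_duration_s(schedule, cfg) * cfg.fs))
    duration = n_samples / cfg.fs
    beats = simulate_rr_sequence(schedule, cfg, rng, duration)
    x = np.zeros(n_samples)
    tmpl = _qrs_template(cfg.fs)
    half = len(tmpl) // 2
    for tb in beats:
        i = int(round(tb * cfg.fs)) - half
        a, b = max(i, 0), min(i + len(tmpl), n_samples)
        if b <= a:
            continue
        x[a:b] += tmpl[a - i: b - i]
    if cfg.ecg_noise > 0:
        x = x + cfg.ecg_noise * rng.standard_normal(n_samples)
    return x


def simulate_subject(cfg: SimConfig, subject_index: int,
                     seed_seq: np.random.SeedSequence | None = None
                     ) -> tuple[Recording, StimulusSchedule]:
    """One subject's recording + schedule, reproducible in isolation."""
    if seed_seq is None:
        seed_seq = np.random.SeedSequence(cfg.rng_seed).spawn(cfg.n_subjects)[subject_index]
    rng = np.random.default_rng(seed_seq)
    schedule = generate_schedule(cfg, rng)
    n = int(round(schedule_duration_s(schedule, cfg) * cfg.fs))

    # per-subject baseline-scale randomization (log-normal, median 1)
    s = cfg.subject_scale_sigma
    emg_scale, scl_scale = np.exp(s * rng.standard_normal(2)) if s > 0 else (1.0, 1.0)

    channels = {
        "emg_zyg": synth_emg(schedule, "emg_zyg", cfg, rng, n, cfg.emg_sigma0 * emg_scale),
        "emg_cor": synth_emg(schedule, "emg_cor", cfg, rng, n, cfg.emg_sigma0 * emg_scale),
        "emg_tra": synth_emg(schedule, "emg_tra", cfg, rng, n, cfg.emg_sigma0 * emg_scale),
        "scl": synth_scl(schedule, cfg, rng, n, cfg.scl_level_uS * scl_scale),
        "ecg": synth_ecg(schedule, cfg, rng, n),
    }
    rec = Recording(
        subject_id=f"S{subject_index:03d}",
        fs=cfg.fs,
        channels=channels,
        channel_role={k: k for k in channels},
    )
    return rec, schedule


def generate_dataset(cfg: SimConfig) -> list[tuple[Recording, StimulusSchedule]]:
    """All subjects' recordings; same config (incl. seed) -> identical data."""
    seqs = np.random.SeedSequence(cfg.rng_seed).spawn(cfg.n_subjects)
    return [simulate_subject(cfg, i, seqs[i]) for i in range(cfg.n_subjects)]


def iter_dataset(cfg: SimConfig):
    """Generator variant of :func:`generate_dataset` (memory-friendly)."""
    seqs = np.random.SeedSequence(cfg.rng_seed).spawn(cfg.n_subjects)
    for i in range(cfg.n_subjects):
        yield simulate_subject(cfg, i, seqs[i])
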