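"""Synthetic eyewear EOG + accelerometer sessions with ground truth.

Emulates a stress-induction protocol: a resting baseline followed by four
stress-inducing tasks interspersed with two-minute relaxation intervals,
recorded at 50 Hz by glasses-mounted EOG electrodes and a 3-axis
accelerometer. Blink rate, duration and amplitude are modulated by the
(latent) stress state of each segment so that downstream detection,
feature-extraction and classification stages have a known signal to recover.

Every session carries a :class:`GroundTruth` with the true blink apices,
durations, artifact times and per-sample state labels, so detector and
masking stages can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .blinks import blink_template_waveform

# Latent stress states used throughout: 0 = no stress, 1 = stress level 1,
# 2 = stress level 2. Tasks map deterministically to a self-reported Likert
# rating (0-4 scale) consistent with their state.
STATE_TO_RATING = {0: 0, 1: 2, 2: 4}


@dataclass(frozen=True)
class Segment:
    """One annotated phase of a session."""

    name: str
    duration_s: float
    state: int  # 0 rest, 1 stress level 1, 2 stress level 2

    @property
    def is_rest(self) -> bool:
        return self.state == 0 and self.name.startswith("rest")


@dataclass(frozen=True)
class BlinkStateParams:
    """Blink statistics for one stress state."""

    rate_per_min: float
    mean_duration_s: float
    mean_amplitude_uv: float

    def __post_init__(self):
        if self.rate_per_min < 0:
            raise ValueError("blink rate must be >= 0")
        if self.mean_duration_s <= 0 or self.mean_amplitude_uv <= 0:
            raise ValueError("blink duration and amplitude must be > 0")


def default_segment_plan() -> list[Segment]:
    """Baseline rest + four 2 min tasks with 2 min relaxation intervals,
    trimmed to 884 s.

    The nominal plan (120 s rest + 4 x (120 s task + 120 s rest) = 1080 s)
    is truncated at 884 s — the session length a 3 s / 1 s-step sliding
    window segments into exactly 882 windows per subject — so the final
    task is cut to 44 s and the closing rest dropped. Task 1 (Stroop
    colour-word test) is the mildest stressor; the arithmetic-under-time-
    pressure and memory tasks are stronger.
    """
    return [
        Segment("rest0", 120.0, 0),
        Segment("task1", 120.0, 1),
        Segment("rest1", 120.0, 0),
        Segment("task2", 120.0, 1),
        Segment("rest2", 120.0, 0),
        Segment("task3", 120.0, 2),
        Segment("rest3", 120.0, 0),
        Segment("task4", 44.0, 2),
    ]


# Stress multipliers relative to rest: under load blinks become more
# frequent, longer, and smaller.
_STRESS_RATE_MULT = {0: 1.0, 1: 1.4, 2: 1.8}
_STRESS_DUR_MULT = {0: 1.0, 1: 1.2, 2: 1.4}
_STRESS_AMP_MULT = {0: 1.0, 1: 0.85, 2: 0.7}


@dataclass(frozen=True)
class SynthConfig:
    """Generator configuration; identical configs yield identical cohorts."""

    n_subjects: int = 12
    sampling_rate: float = 50.0
    segment_plan: tuple[Segment, ...] = field(
        default_factory=lambda: tuple(default_segment_plan())
    )
    # rest-state blink statistics; stressed states are derived from these
    # via the multiplicative modulation above unless overridden
    blink_params: dict[int, BlinkStateParams] | None = None
    rest_blink_rate_per_min: float = 15.0
    rest_blink_duration_s: float = 0.28
    rest_blink_amplitude_uv: float = 150.0
    # between-subject variability: log-normal sd of multiplicative factors
    subject_rate_sd: float = 0.15
    subject_duration_sd: float = 0.10
    subject_amplitude_sd: float = 0.15
    # saccades: piecewise-constant gaze level, renewed at each event
    saccade_rate_per_min: float = 12.0
    saccade_step_uv: float = 50.0
    vertical_saccade_fraction: float = 0.3
    # slow baseline drift (electrode/skin potential wander)
    drift_amplitude_uv: float = 30.0
    drift_period_s: float = 60.0
    noise_sd_uv: float = 10.0
    # motion artifacts: coincident EOG spike + acceleration burst
    artifact_rate_per_min: float = 1.0
    artifact_count: int | None = None  # exact event count overriding the rate
    artifact_eog_uv: float = 300.0
    artifact_accel_g: float = 0.6
    artifact_duration_s: float = 0.3
    accel_noise_sd_g: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.sampling_rate <= 2 * 7.5:
            raise ValueError("sampling_rate must exceed twice the 7.5 Hz band edge")
        for name in (
            "rest_blink_rate_per_min", "saccade_rate_per_min",
            "drift_amplitude_uv", "noise_sd_uv", "artifact_rate_per_min",
            "artifact_eog_uv", "artifact_accel_g", "accel_noise_sd_g",
            "saccade_step_uv",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.segment_plan:
            raise ValueError("segment_plan must be non-empty")

    @property
    def duration_s(self) -> float:
        return float(sum(s.duration_s for s in self.segment_plan))

    def state_params(self, state: int) -> BlinkStateParams:
        """Blink statistics for a stress state (0, 1 or 2)."""
        if self.blink_params is not None and state in self.blink_params:
            return self.blink_params[state]
        return BlinkStateParams(
            rate_per_min=self.rest_blink_rate_per_min * _STRESS_RATE_MULT[state],
            mean_duration_s=self.rest_blink_duration_s * _STRESS_DUR_MULT[state],
            mean_amplitude_uv=self.rest_blink_amplitude_uv * _STRESS_AMP_MULT[state],
        )


@dataclass
class GroundTruth:
    """Oracle annotations for one synthetic session."""

    true_blink_apices: np.ndarray  # s, strictly increasing
    true_blink_durations: np.ndarray  # s
    true_blink_amplitudes: np.ndarray  # µV
    true_artifact_times: np.ndarray  # s (burst centers)
    state_labels: np.ndarray  # per-sample int state


@dataclass
class SessionRecording:
    """Multichannel timed signals plus protocol annotations for one subject."""

    subject_id: str
    sampling_rate: float
    time_s: np.ndarray
    eog_v: np.ndarray  # µV, vertical component (blinks dominate here)
    eog_h: np.ndarray  # µV, horizontal component (saccades)
    acc_x: np.ndarray  # g
    acc_y: np.ndarray
    acc_z: np.ndarray  # gravity axis
    segments: list[tuple[str, float, float, int]]  # (name, start_s, end_s, state)
    ratings: dict[str, int]  # task name -> Likert 0-4

    @property
    def n_samples(self) -> int:
        return len(self.time_s)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate


def sample_blink_train(
    state_params: BlinkStateParams,
    duration_s: float,
    rng: np.random.Generator,
    duration_jitter_sd: float = 0.15,
    amplitude_jitter_sd: float = 0.20,
) -> list[tuple[float, float, float]]:
    """Draw blink events (apex_time_s, duration_s, amplitude_uv) on [0, duration_s).

    Inter-blink intervals follow a Gamma(shape=2) renewal process with the
    state's mean rate: blinks have a refractory period, so near-zero
    intervals of a Poisson process would be unphysiological. Per-blink
    duration and amplitude are log-normal around the state means.
    Consecutive apices are kept at least the sum of half-durations apart so
    rendered waveforms never overlap.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    rate = state_params.rate_per_min / 60.0  # blinks per second
    if rate == 0:
        return []
    mean_interval = 1.0 / rate
    shape = 2.0
    scale = mean_interval / shape

    events: list[tuple[float, float, float]] = []
    t = 0.0
    prev_half = 0.0
    while True:
        gap = rng.gamma(shape, scale)
        dur = state_params.mean_duration_s * rng.lognormal(0.0, duration_jitter_sd)
        amp = state_params.mean_amplitude_uv * rng.lognormal(0.0, amplitude_jitter_sd)
        # refractory floor: no overlap between consecutive blink waveforms
        gap = max(gap, prev_half + dur / 2.0 + 0.02)
        t += gap
        if t + dur / 2.0 >= duration_s:
            break
        events.append((t, dur, amp))
        prev_half = dur / 2.0
    return events


def _hann_pulse(n: int) -> np.ndarray:
    # odd-length raised-cosine pulse, exact unit peak, zero endpoints
    if n % 2 == 0:
        n += 1
    k = np.arange(n)
    return 0.5 - 0.5 * np.cos(2 * np.pi * k / (n - 1))


def _add_pulse(signal: np.ndarray, center_idx: int, pulse: np.ndarray, amp: float):
    half = len(pulse) // 2
    lo = center_idx - half
    hi = lo + len(pulse)
    plo = max(0, -lo)
    phi = len(pulse) - max(0, hi - len(signal))
    lo = max(lo, 0)
    hi = min(hi, len(signal))
    if hi > lo:
        signal[lo:hi] += amp * pulse[plo:phi]


def _subject_factors(cfg: SynthConfig, rng: np.random.Generator) -> tuple[float, float, float]:
    return (
        rng.lognormal(0.0, cfg.subject_rate_sd),
        rng.lognormal(0.0, cfg.subject_duration_sd),
        rng.lognormal(0.0, cfg.subject_amplitude_sd),
    )


def render_session(
    config: SynthConfig, subject_index: int = 0
) -> tuple[SessionRecording, GroundTruth]:
    """Render one subject's session from the generative model.

    Vertical EOG = blink pulses (raised-cosine waveforms at the sampled
    amplitudes/durations) + attenuated saccade steps + sinusoidal drift +
    white noise + motion-artifact spikes. Horizontal EOG carries the full
    saccade step process. Acceleration = 1 g gravity on z + sensor noise,
    with a burst at every artifact time — so every EOG artifact spike has a
    coincident acceleration signature.
    """
    fs = config.sampling_rate
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, subject_index)))
    n = int(round(config.duration_s * fs))
    t = np.arange(n) / fs

    rate_f, dur_f, amp_f = _subject_factors(config, rng)

    # per-sample state labels and segment table
    state_labels = np.zeros(n, dtype=np.int64)
    segments: list[tuple[str, float, float, int]] = []
    ratings: dict[str, int] = {}
    cursor = 0.0
    for seg in config.segment_plan:
        i0 = int(round(cursor * fs))
        i1 = int(round((cursor + seg.duration_s) * fs))
        state_labels[i0:i1] = seg.state
        segments.append((seg.name, cursor, cursor + seg.duration_s, seg.state))
        if not seg.is_rest:
            ratings[seg.name] = STATE_TO_RATING[seg.state]
        cursor += seg.duration_s

    eog_v = np.zeros(n)
    eog_h = np.zeros(n)

    # blinks, segment by segment (state-dependent statistics)
    apices: list[float] = []
    durations: list[float] = []
    amplitudes: list[float] = []
    for name, start, end, state in segments:
        base = config.state_params(state)
        params = BlinkStateParams(
            rate_per_min=base.rate_per_min * rate_f,
            mean_duration_s=base.mean_duration_s * dur_f,
            mean_amplitude_uv=base.mean_amplitude_uv * amp_f,
        )
        for apex, dur, amp in sample_blink_train(params, end - start, rng):
            apices.append(start + apex)
            durations.append(dur)
            amplitudes.append(amp)
    order = np.argsort(apices)
    apices_arr = np.asarray(apices)[order] if apices else np.empty(0)
    durations_arr = np.asarray(durations)[order] if apices else np.empty(0)
    amplitudes_arr = np.asarray(amplitudes)[order] if apices else np.empty(0)
    for apex, dur, amp in zip(apices_arr, durations_arr, amplitudes_arr):
        wav = blink_template_waveform(dur, fs)
        _add_pulse(eog_v, int(round(apex * fs)), wav, amp)

    # saccades: gaze level renewed at each event (bounded, not a random walk)
    if config.saccade_rate_per_min > 0 and config.saccade_step_uv > 0:
        sacc_rate = config.saccade_rate_per_min / 60.0
        n_sacc = rng.poisson(sacc_rate * config.duration_s)
        sacc_times = np.sort(rng.uniform(0, config.duration_s, size=n_sacc))
        level = 0.0
        prev_idx = 0
        gaze = np.zeros(n)
        for st in sacc_times:
            idx = int(st * fs)
            gaze[prev_idx:idx] = level
            level = rng.choice([-1.0, 1.0]) * config.saccade_step_uv * rng.uniform(0.3, 1.0)
            prev_idx = idx
        gaze[prev_idx:] = level
        eog_h += gaze
        eog_v += config.vertical_saccade_fraction * gaze

    # slow drift
    if config.drift_amplitude_uv > 0:
        phase = rng.uniform(0, 2 * np.pi)
        drift = config.drift_amplitude_uv * np.sin(
            2 * np.pi * t / config.drift_period_s + phase
        )
        eog_v += drift
        eog_h += drift

    # measurement noise
    if config.noise_sd_uv > 0:
        eog_v += rng.normal(0, config.noise_sd_uv, n)
        eog_h += rng.normal(0, config.noise_sd_uv, n)

    # acceleration channels
    acc_x = rng.normal(0, config.accel_noise_sd_g, n) if config.accel_noise_sd_g else np.zeros(n)
    acc_y = rng.normal(0, config.accel_noise_sd_g, n) if config.accel_noise_sd_g else np.zeros(n)
    acc_z = 1.0 + (rng.normal(0, config.accel_noise_sd_g, n) if config.accel_noise_sd_g else 0.0)
    acc_z = np.asarray(acc_z) if np.ndim(acc_z) else np.full(n, 1.0)

    # motion artifacts: EOG spike + acceleration burst at the same instant
    artifact_times = np.empty(0)
    if config.artifact_count is not None or config.artifact_rate_per_min > 0:
        if config.artifact_count is not None:
            n_art = config.artifact_count
        else:
            n_art = rng.poisson(config.artifact_rate_per_min / 60.0 * config.duration_s)
        candidates: list[float] = []
        margin = 2.0
        attempts = 0
        while len(candidates) < n_art and attempts < 50 * max(n_art, 1):
            c = rng.uniform(margin, config.duration_s - margin)
            if all(abs(c - o) > 3.0 for o in candidates):
                candidates.append(c)
            attempts += 1
        artifact_times = np.sort(np.asarray(candidates))
        burst = _hann_pulse(int(round(config.artifact_duration_s * fs)) | 1)
        for at in artifact_times:
            idx = int(round(at * fs))
            _add_pulse(eog_v, idx, burst, config.artifact_eog_uv)
            _add_pulse(acc_z, idx, burst, config.artifact_accel_g)
            _add_pulse(acc_x, idx, burst, 0.5 * config.artifact_accel_g * rng.choice([-1.0, 1.0]))
            _add_pulse(acc_y, idx, burst, 0.5 * config.artifact_accel_g * rng.choice([-1.0, 1.0]))

    recording = SessionRecording(
        subject_id=f"S{subject_index:02d}",
        sampling_rate=fs,
        time_s=t,
        eog_v=eog_v,
        eog_h=eog_h,
        acc_x=acc_x,
        acc_y=acc_y,
        acc_z=acc_z,
        segments=segments,
        ratings=ratings,
    )
    truth = GroundTruth(
        true_blink_apices=apices_arr,
        true_blink_durations=durations_arr,
        true_blink_amplitudes=amplitudes_arr,
        true_artifact_times=artifact_times,
        state_labels=state_labels,
    )
    return recording, truth


def generate_cohort(config: SynthConfig) -> list[tuple[SessionRecording, GroundTruth]]:
    """One session per subject, with between-subject blink variability."""
    if config.n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    return [render_session(config, i) for i in range(config.n_subjects)]
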