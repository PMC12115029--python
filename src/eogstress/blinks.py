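"""Blink detection on the vertical EOG channel by template matching.

Candidate peaks are located by prominence, each candidate is scored by the
root-mean-square error of a least-squares fit of a canonical blink pulse to
the apex-centred excerpt, and candidates are accepted when their normalized
RMSE falls under an adaptive, per-session threshold (a Tukey upper fence on
the score distribution, capped at an absolute maximum).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

ABSOLUTE_RMSE_CAP = 0.5  # dimensionless normalized-RMSE ceiling for acceptance
DEFAULT_TEMPLATE_DURATION_S = 0.3
DEFAULT_MIN_SEPARATION_S = 0.2  # physiological blink refractory


def blink_template_waveform(duration_s: float, sampling_rate: float) -> np.ndarray:
    """Unit-amplitude raised-cosine (Hann) blink pulse.

    Odd sample count so the apex sample is exactly 1; endpoints are 0.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    n = int(round(duration_s * sampling_rate))
    n = max(n, 3)
    if n % 2 == 0:
        n += 1
    k = np.arange(n)
    return 0.5 - 0.5 * np.cos(2 * np.pi * k / (n - 1))


@dataclass(frozen=True)
class BlinkTemplate:
    """Canonical blink waveform sampled at the session rate.

    When ``prefilter_sos`` is set (second-order sections of the session's
    bandpass), rescaled template shapes are passed through the same
    zero-phase filter as the signal, so the fit is not penalized for the
    filter's own distortion of the pulse.
    """

    duration_s: float
    sampling_rate: float
    shape: np.ndarray
    prefilter_sos: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return len(self.shape)

    @classmethod
    def default(cls, sampling_rate: float,
                duration_s: float = DEFAULT_TEMPLATE_DURATION_S,
                filter_spec=None) -> "BlinkTemplate":
        sos = filter_spec.butter_sos() if filter_spec is not None else None
        return cls(duration_s, sampling_rate,
                   blink_template_waveform(duration_s, sampling_rate),
                   prefilter_sos=sos)

    def shape_for_duration(self, duration_s: float) -> np.ndarray:
        """Unit-input template rescaled to ``duration_s`` (odd length)."""
        pulse = blink_template_waveform(duration_s, self.sampling_rate)
        if self.prefilter_sos is None:
            return pulse
        from scipy.signal import sosfiltfilt

        pad = int(4 * self.sampling_rate)  # let filter transients die out
        padded = np.concatenate([np.zeros(pad), pulse, np.zeros(pad)])
        return sosfiltfilt(self.prefilter_sos, padded)[pad: pad + len(pulse)]


@dataclass
class BlinkEvent:
    apex_time_s: float
    onset_s: float
    offset_s: float
    amplitude: float  # µV, least-squares template scale
    duration_s: float  # half-amplitude-width based estimate
    rmse_norm: float  # RMSE of scaled-template fit / amplitude
    accepted: bool = False


def robust_noise_sd(signal: np.ndarray) -> float:
    """Noise scale via the median absolute deviation (Gaussian-consistent)."""
    med = np.median(signal)
    return 1.4826 * float(np.median(np.abs(signal - med)))


def detect_candidates(
    eog_v: np.ndarray,
    sampling_rate: float,
    min_prominence: float | None = None,
    min_separation_s: float = DEFAULT_MIN_SEPARATION_S,
) -> np.ndarray:
    """Candidate blink apices: local maxima by prominence.

    Returns sample indices. ``min_prominence`` defaults to three times the
    MAD-based noise sd of the signal.
    """
    eog_v = np.asarray(eog_v, dtype=float)
    if min_prominence is None:
        min_prominence = 3.0 * robust_noise_sd(eog_v)
        if min_prominence == 0:
            # noise-free signal: MAD collapses; scale to the largest deflection
            peak = float(np.max(np.abs(eog_v))) if eog_v.size else 0.0
            if peak == 0:
                return np.empty(0, dtype=int)
            min_prominence = 0.05 * peak
    if min_prominence <= 0:
        raise ValueError("min_prominence must be > 0")
    distance = max(1, int(round(min_separation_s * sampling_rate)))
    peaks, _ = find_peaks(eog_v, prominence=min_prominence, distance=distance)
    return peaks


MIN_BLINK_DURATION_S = 0.08
MAX_BLINK_DURATION_S = 0.8


def score_candidate(
    eog_v: np.ndarray,
    apex_idx: int,
    template: BlinkTemplate,
) -> BlinkEvent | None:
    """Fit a duration-rescaled template to the apex-centred excerpt.

    The template duration is first rescaled to the excerpt's half-amplitude
    width (for the raised-cosine shape the half-amplitude width is exactly
    half the duration) and then refined over a small multiplicative grid,
    keeping the duration whose fit minimizes the normalized RMSE — the
    half-amplitude estimate alone is biased when neighbouring deflections
    overlap the pulse. The amplitude is the least-squares scale of the
    rescaled template onto the excerpt; rmse_norm = residual RMSE /
    amplitude is invariant to rescaling the signal. Returns None when no
    full excerpt exists around the apex (boundary) or the apex is
    non-positive.
    """
    eog_v = np.asarray(eog_v, dtype=float)
    fs = template.sampling_rate
    peak = eog_v[apex_idx]
    if peak <= 0:
        return None
    width = _half_amplitude_width(eog_v, apex_idx, peak,
                                  max_radius=int(MAX_BLINK_DURATION_S * fs))
    d_est = 2.0 * width / fs

    best = None
    for factor in (0.7, 0.85, 1.0, 1.2, 1.45):
        duration = float(np.clip(d_est * factor,
                                 MIN_BLINK_DURATION_S, MAX_BLINK_DURATION_S))
        tpl = template.shape_for_duration(duration)
        n = len(tpl)
        half = n // 2
        lo, hi = apex_idx - half, apex_idx + half + 1
        if lo < 0 or hi > len(eog_v):
            continue  # boundary: no full excerpt at this duration
        excerpt = eog_v[lo:hi]
        # LS scale of the template plus a linear baseline nuisance term:
        # blinks ride on the slow undershoot the high-pass leaves behind
        design = np.column_stack([tpl, np.ones(n), np.linspace(-1, 1, n)])
        coef, *_ = np.linalg.lstsq(design, excerpt, rcond=None)
        amp = float(coef[0])
        if amp <= 0:
            continue
        resid = excerpt - design @ coef
        rmse_norm = float(np.sqrt(np.mean(resid**2))) / amp
        if best is None or rmse_norm < best[0]:
            best = (rmse_norm, amp, duration)
    if best is None:
        return None
    rmse_norm, amp, duration = best

    apex_time = apex_idx / fs
    return BlinkEvent(
        apex_time_s=apex_time,
        onset_s=apex_time - duration / 2.0,
        offset_s=apex_time + duration / 2.0,
        amplitude=amp,
        duration_s=duration,
        rmse_norm=rmse_norm,
    )


def _half_amplitude_width(signal: np.ndarray, center: int, peak: float,
                          max_radius: int) -> float:
    """Width (in samples) of the region around ``center`` above peak/2."""
    level = peak / 2.0
    left = float(min(center, max_radius))
    for i in range(center, max(center - max_radius, 0), -1):
        if signal[i - 1] < level <= signal[i]:
            frac = (signal[i] - level) / (signal[i] - signal[i - 1])
            left = center - (i - frac)
            break
    right = float(min(len(signal) - 1 - center, max_radius))
    m = len(signal)
    for i in range(center, min(center + max_radius, m - 1)):
        if signal[i + 1] < level <= signal[i]:
            frac = (signal[i] - level) / (signal[i] - signal[i + 1])
            right = (i + frac) - center
            break
    return max(left + right, 1.0)


def adaptive_accept(
    events: list[BlinkEvent], absolute_cap: float = ABSOLUTE_RMSE_CAP
) -> list[BlinkEvent]:
    """Accept events whose normalized RMSE is under the session's fence.

    The threshold adapts to the session: min(absolute_cap,
    Q3 + 1.5 * IQR of the rmse_norm distribution). Flags are set in place;
    the accepted sublist is returned in original order.
    """
    if not events:
        return []
    scores = np.array([e.rmse_norm for e in events])
    q1, q3 = np.percentile(scores, [25, 75])
    fence = q3 + 1.5 * (q3 - q1)
    threshold = min(absolute_cap, fence)
    for e in events:
        e.accepted = bool(e.rmse_norm <= threshold)
    return [e for e in events if e.accepted]


def detect_blinks(
    eog_v: np.ndarray,
    sampling_rate: float,
    template: BlinkTemplate | None = None,
    min_prominence: float | None = None,
    min_separation_s: float = DEFAULT_MIN_SEPARATION_S,
    filter_spec=None,
) -> list[BlinkEvent]:
    """Full detector: candidates -> template scoring -> adaptive acceptance.

    Intended for bandpassed vertical EOG; by default the template is
    prefiltered with the standard session bandpass so the score reflects
    waveform shape rather than filter distortion. Returns all scored events
    with their ``accepted`` flags set.
    """
    if template is None:
        if filter_spec is None:
            from .preprocessing import FilterSpec

            filter_spec = FilterSpec(sampling_rate=sampling_rate)
        template = BlinkTemplate.default(sampling_rate, filter_spec=filter_spec)
    eog_v = np.asarray(eog_v, dtype=float)
    if min_prominence is None:
        min_prominence = 3.0 * robust_noise_sd(eog_v)
        if min_prominence == 0:
            peak = float(np.max(np.abs(eog_v))) if eog_v.size else 0.0
            if peak == 0:
                return []
            min_prominence = 0.05 * peak
    apices = detect_candidates(eog_v, sampling_rate, min_prominence, min_separation_s)
    events = []
    for idx in apices:
        ev = score_candidate(eog_v, int(idx), template)
        # the fitted amplitude is a denoised peak estimate; hold it to the
        # same floor as the raw peak prominence
        if ev is not None and ev.amplitude >= min_prominence:
            events.append(ev)
    _refit_overlapping(eog_v, events, template)
    adaptive_accept(events)
    return events


def _refit_overlapping(eog_v: np.ndarray, events: list[BlinkEvent],
                       template: BlinkTemplate, passes: int = 1) -> None:
    """Rescore each event with its fitted neighbours subtracted.

    Blinks in rapid succession distort each other's excerpts; one pass of
    subtract-neighbours-and-refit removes that interference so the score
    reflects each pulse's own shape.
    """
    fs = template.sampling_rate
    n = len(eog_v)
    radius = int(2 * MAX_BLINK_DURATION_S * fs)
    for _ in range(passes):
        recon = np.zeros(n)
        pulses = []
        for ev in events:
            tpl = ev.amplitude * template.shape_for_duration(ev.duration_s)
            idx = int(round(ev.apex_time_s * fs))
            pulses.append((idx, tpl))
            _add_centered(recon, idx, tpl)
        residual = eog_v - recon
        for ev, (idx, tpl) in zip(events, pulses):
            lo = max(0, idx - radius)
            hi = min(n, idx + radius + 1)
            local = residual[lo:hi].copy()
            _add_centered(local, idx - lo, tpl)
            refit = score_candidate(local, idx - lo, template)
            if refit is not None:
                ev.amplitude = refit.amplitude
                ev.duration_s = refit.duration_s
                ev.onset_s = ev.apex_time_s - refit.duration_s / 2.0
                ev.offset_s = ev.apex_time_s + refit.duration_s / 2.0
                ev.rmse_norm = refit.rmse_norm


def _add_centered(signal: np.ndarray, center: int, pulse: np.ndarray) -> None:
    half = len(pulse) // 2
    lo = center - half
    hi = lo + len(pulse)
    plo = max(0, -lo)
    phi = len(pulse) - max(0, hi - len(signal))
    lo = max(lo, 0)
    hi = min(hi, len(signal))
    if hi > lo:
        signal[lo:hi] += pulse[plo:phi]


def events_to_rows(events: list[BlinkEvent]) -> list[dict]:
    """Serializable rows (CSV columns: apex_s,onset_s,offset_s,amplitude_uV,duration_s,rmse_norm,accepted)."""
    return [
        {
            "apex_s": e.apex_time_s,
            "onset_s": e.onset_s,
            "offset_s": e.offset_s,
            "amplitude_uV": e.amplitude,
            "duration_s": e.duration_s,
            "rmse_norm": e.rmse_norm,
            "accepted": e.accepted,
        }
        for e in events
    ]
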