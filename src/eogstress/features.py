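"""Sliding-window feature extraction and Lasso feature selection.

Sessions are segmented into 3 s windows advanced by 1 s. Each window yields
nine features of the vertical and "total" (vertical + horizontal) EOG
signals, is labelled by the self-reported stress rating of its segment, and
the resulting table feeds an L1-penalized (Lasso) selector that zeroes out
uninformative features on the training split.

Conventions fixed here (and mirrored by the test oracles): population
(divide-by-n) variance/sd; blink-dependent features are 0 in blink-free
windows; windows crossing a segment boundary are dropped before labelling.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, LassoCV

from .blinks import BlinkEvent

WINDOW_S = 3.0
STEP_S = 1.0

FEATURE_NAMES = [
    "blink_freq",   # accepted blinks per second in the window
    "mean_p2p_v",   # mean peak-to-peak amplitude of in-window blinks (µV)
    "var_v",        # variance of the vertical component (µV²)
    "cov_v",        # covariance of vertical with the total signal (µV²)
    "sd_peaks",     # sd of in-window blink amplitudes (µV)
    "rms_signal",   # root mean square of the total signal (µV)
    "max_v",        # max of the vertical component (µV)
    "mean_total",   # mean of the total signal (µV)
    "sd_total",     # sd of the total signal (µV)
]

LABEL_COLUMNS = ["subject_id", "start_s", "phase", "label2", "label3"]


def segment_windows(
    session_duration_s: float, window_s: float = WINDOW_S, step_s: float = STEP_S
) -> np.ndarray:
    """Window start times: 0, step, 2*step, ... while start + window <= duration.

    Count = floor((duration - window) / step) + 1; an 884 s session at
    3 s / 1 s yields 882 windows.
    """
    if session_duration_s < window_s:
        warnings.warn("session shorter than one window; no windows produced")
        return np.empty(0)
    # small epsilon guards the floating-point boundary (e.g. duration 10.0)
    count = int(math.floor((session_duration_s - window_s) / step_s + 1e-9)) + 1
    return np.arange(count) * step_s


def compute_window_features(
    eog_v: np.ndarray,
    eog_h: np.ndarray,
    blinks: list[BlinkEvent],
    window_start_s: float,
    sampling_rate: float,
    window_s: float = WINDOW_S,
) -> dict[str, float]:
    """Nine features for one window; ``blinks`` are the accepted events whose
    apex falls in [start, start + window)."""
    v = np.asarray(eog_v, dtype=float)
    h = np.asarray(eog_h, dtype=float)
    if v.shape != h.shape:
        raise ValueError("vertical and horizontal windows must match in length")
    if not (np.all(np.isfinite(v)) and np.all(np.isfinite(h))):
        raise ValueError("window contains non-finite samples")
    total = v + h

    n_blinks = len(blinks)
    if n_blinks:
        p2ps = []
        for b in blinks:
            i0 = max(0, int(round((b.onset_s - window_start_s) * sampling_rate)))
            i1 = min(len(v), int(round((b.offset_s - window_start_s) * sampling_rate)) + 1)
            seg = v[i0:i1] if i1 > i0 else v[min(i0, len(v) - 1): min(i0, len(v) - 1) + 1]
            p2ps.append(float(np.max(seg) - np.min(seg)))
        mean_p2p = float(np.mean(p2ps))
        amps = np.array([b.amplitude for b in blinks])
        sd_peaks = float(np.std(amps)) if n_blinks >= 2 else 0.0
    else:
        mean_p2p = 0.0
        sd_peaks = 0.0

    return {
        "blink_freq": n_blinks / window_s,
        "mean_p2p_v": mean_p2p,
        "var_v": float(np.var(v)),
        "cov_v": float(np.mean((v - v.mean()) * (total - total.mean()))),
        "sd_peaks": sd_peaks,
        "rms_signal": float(np.sqrt(np.mean(total**2))),
        "max_v": float(np.max(v)),
        "mean_total": float(np.mean(total)),
        "sd_total": float(np.std(total)),
    }


def assign_labels(is_rest: bool, rating: int | None) -> tuple[str, str]:
    """Map a window's segment type and Likert rating to class labels.

    Rest segments are no-stress in both schemes. Task segments split on the
    0-4 rating: two-class stress at rating >= 2; three-class no_stress for
    ratings 0-1, stress1 for 2-3, stress2 for 4.
    """
    if is_rest:
        return "no_stress", "no_stress"
    if rating is None:
        raise ValueError("task segment without a Likert rating")
    if not 0 <= rating <= 4:
        raise ValueError("Likert rating must be in 0..4")
    label2 = "stress" if rating >= 2 else "no_stress"
    if rating <= 1:
        label3 = "no_stress"
    elif rating <= 3:
        label3 = "stress1"
    else:
        label3 = "stress2"
    return label2, label3


def build_feature_table(
    session,
    preprocessed,
    events: list[BlinkEvent],
    window_s: float = WINDOW_S,
    step_s: float = STEP_S,
) -> pd.DataFrame:
    """Feature rows for one session: one row per fully-in-segment window."""
    fs = session.sampling_rate
    accepted = [e for e in events if e.accepted]
    apex_times = np.array([e.apex_time_s for e in accepted])
    starts = segment_windows(session.duration_s, window_s, step_s)

    rows = []
    for start in starts:
        seg = _segment_containing(session.segments, start, start + window_s)
        if seg is None:
            continue  # window crosses a segment boundary: no single true label
        name, _, _, state = seg
        is_rest = name.startswith("rest")
        rating = None if is_rest else session.ratings[name]
        label2, label3 = assign_labels(is_rest, rating)

        i0 = int(round(start * fs))
        i1 = i0 + int(round(window_s * fs))
        in_win = (
            [accepted[k] for k in np.flatnonzero(
                (apex_times >= start) & (apex_times < start + window_s))]
            if len(apex_times)
            else []
        )
        feats = compute_window_features(
            preprocessed.eog_v[i0:i1],
            preprocessed.eog_h[i0:i1],
            in_win,
            start,
            fs,
            window_s,
        )
        rows.append(
            {
                "subject_id": session.subject_id,
                "start_s": float(start),
                "phase": name,
                "label2": label2,
                "label3": label3,
                **feats,
            }
        )
    return pd.DataFrame(rows, columns=LABEL_COLUMNS + FEATURE_NAMES)


def _segment_containing(segments, start: float, end: float):
    eps = 1e-9
    for seg in segments:
        if seg[1] - eps <= start and end <= seg[2] + eps:
            return seg
    return None


@dataclass
class LassoSelection:
    """Outcome of L1 feature selection on a training split."""

    mask: np.ndarray  # True = feature kept
    coefficients: np.ndarray  # on standardized features
    alpha: float
    dropped_constant: list[str]
    feature_names: list[str]

    @property
    def selected(self) -> list[str]:
        return [n for n, m in zip(self.feature_names, self.mask) if m]


def lasso_select(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    alpha: float | None = None,
    seed: int = 0,
    cv: int = 5,
) -> LassoSelection:
    """Select features by the Lasso at a cross-validated penalty.

    Features are z-scored (training statistics) and the class labels encoded
    as consecutive integers; features with exactly-zero coefficients are
    excluded. When ``alpha`` is not supplied it is chosen by internal CV with
    the one-standard-error rule (the largest penalty whose CV error is within
    one standard error of the minimum), which favours sparse supports.
    Constant feature columns cannot be standardized and are dropped.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        names = [f"f{i}" for i in range(Xv.shape[1])]
    if alpha is not None and alpha < 0:
        raise ValueError("alpha must be >= 0")

    y_codes = pd.Categorical(np.asarray(y)).codes.astype(float)

    sd = Xv.std(axis=0)
    constant = sd == 0
    keep = ~constant
    Z = (Xv[:, keep] - Xv[:, keep].mean(axis=0)) / sd[keep]

    if alpha is None:
        cv_model = LassoCV(cv=cv, random_state=seed, alphas=100)
        cv_model.fit(Z, y_codes)
        # one-standard-error rule over the CV error path
        mse = cv_model.mse_path_.mean(axis=1)
        se = cv_model.mse_path_.std(axis=1) / np.sqrt(cv_model.mse_path_.shape[1])
        limit = mse.min() + se[np.argmin(mse)]
        alphas = cv_model.alphas_
        alpha = float(np.max(alphas[mse <= limit]))

    if alpha == 0:
        coef_kept = np.linalg.lstsq(
            np.column_stack([Z, np.ones(len(Z))]), y_codes, rcond=None
        )[0][:-1]
    else:
        model = Lasso(alpha=alpha, max_iter=50_000)
        model.fit(Z, y_codes)
        coef_kept = model.coef_

    coefs = np.zeros(Xv.shape[1])
    coefs[keep] = coef_kept
    mask = coefs != 0
    return LassoSelection(
        mask=mask,
        coefficients=coefs,
        alpha=float(alpha),
        dropped_constant=[n for n, c in zip(names, constant) if c],
        feature_names=names,
    )
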