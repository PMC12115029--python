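"""Session CSV + JSON-sidecar serialization.

One CSV per session with the fixed header
``time_s,eog_v,eog_h,acc_x,acc_y,acc_z`` (9 significant digits), and a JSON
sidecar carrying segment annotations, Likert ratings, and — for synthetic
sessions — the ground truth.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import GroundTruth, SessionRecording

SESSION_COLUMNS = ["time_s", "eog_v", "eog_h", "acc_x", "acc_y", "acc_z"]


def write_session_csv(
    session: SessionRecording,
    path: str | Path,
    truth: GroundTruth | None = None,
) -> Path:
    """Write the session CSV and its JSON sidecar; returns the CSV path."""
    path = Path(path)
    frame = pd.DataFrame(
        {
            "time_s": session.time_s,
            "eog_v": session.eog_v,
            "eog_h": session.eog_h,
            "acc_x": session.acc_x,
            "acc_y": session.acc_y,
            "acc_z": session.acc_z,
        }
    )
    frame.to_csv(path, index=False, float_format="%.9g")
    sidecar = {
        "subject_id": session.subject_id,
        "sampling_rate": session.sampling_rate,
        "segments": [
            {"name": n, "start_s": s, "end_s": e, "state": st}
            for n, s, e, st in session.segments
        ],
        "ratings": session.ratings,
    }
    if truth is not None:
        sidecar["ground_truth"] = {
            "true_blink_apices": truth.true_blink_apices.tolist(),
            "true_blink_durations": truth.true_blink_durations.tolist(),
            "true_blink_amplitudes": truth.true_blink_amplitudes.tolist(),
            "true_artifact_times": truth.true_artifact_times.tolist(),
        }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


class SessionFormatError(ValueError):
    """Malformed session CSV (bad header, time base, or rate)."""


def read_session_csv(path: str | Path) -> tuple[SessionRecording, GroundTruth | None]:
    """Read a session CSV + sidecar; validates header and time base."""
    path = Path(path)
    frame = pd.read_csv(path)
    if list(frame.columns) != SESSION_COLUMNS:
        missing = [c for c in SESSION_COLUMNS if c not in frame.columns]
        raise SessionFormatError(
            f"bad header in {path.name}: expected {SESSION_COLUMNS}, "
            f"missing {missing or 'none'} (line 1)"
        )
    t = frame["time_s"].to_numpy()
    dt = np.diff(t)
    bad = np.flatnonzero(dt <= 0)
    if bad.size:
        raise SessionFormatError(
            f"non-monotone time in {path.name} at line {bad[0] + 3}"
        )

    sidecar_path = path.with_suffix(".json")
    sidecar = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    fs = sidecar.get("sampling_rate")
    if fs is None:
        fs = 1.0 / float(np.median(dt))
    elif len(t) > 1 and abs(np.median(dt) - 1.0 / fs) > 1e-6 / fs:
        raise SessionFormatError(
            f"time step in {path.name} does not match declared rate {fs} Hz"
        )

    session = SessionRecording(
        subject_id=sidecar.get("subject_id", path.stem),
        sampling_rate=float(fs),
        time_s=t,
        eog_v=frame["eog_v"].to_numpy(),
        eog_h=frame["eog_h"].to_numpy(),
        acc_x=frame["acc_x"].to_numpy(),
        acc_y=frame["acc_y"].to_numpy(),
        acc_z=frame["acc_z"].to_numpy(),
        segments=[
            (s["name"], s["start_s"], s["end_s"], s["state"])
            for s in sidecar.get("segments", [])
        ],
        ratings={k: int(v) for k, v in sidecar.get("ratings", {}).items()},
    )
    truth = None
    if "ground_truth" in sidecar:
        gt = sidecar["ground_truth"]
        n = len(t)
        truth = GroundTruth(
            true_blink_apices=np.asarray(gt["true_blink_apices"]),
            true_blink_durations=np.asarray(gt["true_blink_durations"]),
            true_blink_amplitudes=np.asarray(gt["true_blink_amplitudes"]),
            true_artifact_times=np.asarray(gt["true_artifact_times"]),
            state_labels=_states_from_segments(session.segments, n, session.sampling_rate),
        )
    return session, truth


def _states_from_segments(segments, n: int, fs: float) -> np.ndarray:
    states = np.zeros(n, dtype=np.int64)
    for _, start, end, state in segments:
        states[int(round(start * fs)): int(round(end * fs))] = state
    return states
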