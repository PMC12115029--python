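import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import eogstress as eog

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

FS = 50.0


def noise_free_config(**overrides) -> eog.SynthConfig:
    """Blinks only: every other signal source switched off."""
    base = dict(
        noise_sd_uv=0.0,
        saccade_rate_per_min=0.0,
        drift_amplitude_uv=0.0,
        artifact_rate_per_min=0.0,
        accel_noise_sd_g=0.0,
        n_subjects=1,
    )
    base.update(overrides)
    return dataclasses.replace(eog.SynthConfig(), **base)


@pytest.fixture(scope="session")
def default_sessions():
    """12 default-config sessions (seeds 0-11) with preprocessing and blinks."""
    out = []
    for seed in range(12):
        session, truth = eog.render_session(eog.SynthConfig(seed=seed), 0)
        prep = eog.preprocess_session(session)
        events = eog.detect_blinks(prep.eog_v, session.sampling_rate)
        out.append({"session": session, "truth": truth, "prep": prep,
                    "events": events})
    return out


@pytest.fixture(scope="session")
def cohort_table():
    """Feature table of the default 12-subject stress-modulated cohort."""
    tables = []
    for session, _ in eog.generate_cohort(eog.SynthConfig(seed=0)):
        prep = eog.preprocess_session(session)
        events = eog.detect_blinks(prep.eog_v, session.sampling_rate)
        tables.append(eog.build_feature_table(session, prep, events))
    return pd.concat(tables, ignore_index=True)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def match_blinks(true_apices, detected_apices, tol_s: float = 0.1):
    """Greedy one-to-one matching; returns (tp, fp, fn)."""
    det = np.asarray(detected_apices, dtype=float)
    used = np.zeros(len(det), dtype=bool)
    tp = 0
    for ta in true_apices:
        if not len(det):
            break
        d = np.abs(det - ta)
        d[used] = np.inf
        j = int(np.argmin(d))
        if d[j] <= tol_s:
            used[j] = True
            tp += 1
    return tp, len(det) - tp, len(true_apices) - tp
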