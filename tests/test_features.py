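"""Windowing, the nine window features (vs a brute-force oracle), labels, Lasso."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import eogstress as eog
from eogstress.blinks import BlinkEvent
from eogstress.features import (
    FEATURE_NAMES,
    assign_labels,
    compute_window_features,
    lasso_select,
    segment_windows,
)

FS = 50.0


def oracle_window_features(v, h, blinks, start, fs, win=3.0):
    """Naive from-first-principles recomputation of the nine features."""
    v = list(map(float, v))
    h = list(map(float, h))
    total = [a + b for a, b in zip(v, h)]
    n = len(v)

    def mean(xs):
        return sum(xs) / len(xs)

    def pvar(xs):
        m = mean(xs)
        return sum((x - m) ** 2 for x in xs) / len(xs)

    mv, mt = mean(v), mean(total)
    out = {}
    out["blink_freq"] = len(blinks) / win
    p2ps = []
    for b in blinks:
        i0 = max(0, int(round((b.onset_s - start) * fs)))
        i1 = min(n, int(round((b.offset_s - start) * fs)) + 1)
        if i1 <= i0:
            i0 = min(i0, n - 1)
            i1 = i0 + 1
        seg = v[i0:i1]
        p2ps.append(max(seg) - min(seg))
    out["mean_p2p_v"] = mean(p2ps) if p2ps else 0.0
    out["var_v"] = pvar(v)
    out["cov_v"] = sum((a - mv) * (b - mt) for a, b in zip(v, total)) / n
    amps = [b.amplitude for b in blinks]
    out["sd_peaks"] = math.sqrt(pvar(amps)) if len(amps) >= 2 else 0.0
    out["rms_signal"] = math.sqrt(mean([x * x for x in total]))
    out["max_v"] = max(v)
    out["mean_total"] = mt
    out["sd_total"] = math.sqrt(pvar(total))
    return out


def random_window(rng, with_blinks=True):
    n = int(3.0 * FS)
    v = rng.normal(0, 20, n)
    h = rng.normal(0, 15, n)
    blinks = []
    if with_blinks:
        for _ in range(rng.integers(0, 4)):
            apex = rng.uniform(0.3, 2.7)
            dur = rng.uniform(0.15, 0.5)
            blinks.append(BlinkEvent(
                apex_time_s=apex, onset_s=apex - dur / 2, offset_s=apex + dur / 2,
                amplitude=rng.uniform(50, 300), duration_s=dur,
                rmse_norm=0.05, accepted=True))
    return v, h, blinks


class TestSegmentWindows:
    @pytest.mark.parametrize("duration,expected", [(884.0, 882), (3.0, 1), (10.0, 8)])
    def test_window_counts(self, duration, expected):
        starts = segment_windows(duration)
        assert len(starts) == expected
        assert starts[0] == 0.0
        if expected > 1:
            assert np.allclose(np.diff(starts), 1.0)

    def test_too_short_session_warns_and_is_empty(self):
        with pytest.warns(UserWarning):
            assert len(segment_windows(2.0)) == 0

    @given(st.integers(3, 400), st.integers(1, 10), st.integers(1, 5))
    def test_count_formula(self, duration, window, step):
        if duration < window:
            return
        starts = segment_windows(float(duration), float(window), float(step))
        assert len(starts) == math.floor((duration - window) / step) + 1
        assert all(s + window <= duration + 1e-9 for s in starts)


class TestWindowFeatures:
    def test_zero_window_all_features_zero(self):
        n = int(3 * FS)
        feats = compute_window_features(np.zeros(n), np.zeros(n), [], 0.0, FS)
        assert all(value == 0.0 for value in feats.values())

    def test_population_variance_convention(self):
        # toy check at 1 Hz equivalent: population (divide-by-n) variance
        v = np.array([1.0, 2.0, 3.0])
        feats = compute_window_features(v, np.zeros(3), [], 0.0, 1.0, window_s=3.0)
        assert feats["var_v"] == pytest.approx(2.0 / 3.0)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            v, h, blinks = random_window(rng)
            got = compute_window_features(v, h, blinks, 0.0, FS)
            expected = oracle_window_features(v, h, blinks, 0.0, FS)
            for name in FEATURE_NAMES:
                assert got[name] == pytest.approx(expected[name], abs=1e-9), name

    def test_position_invariance(self, rng):
        """Features are pure functions of the samples, not the window position."""
        v, h, blinks = random_window(rng, with_blinks=False)
        a = compute_window_features(v, h, [], 0.0, FS)
        b = compute_window_features(v, h, [], 120.0, FS)
        assert a == b

    def test_nan_sample_rejected(self):
        n = int(3 * FS)
        v = np.zeros(n)
        v[5] = np.nan
        with pytest.raises(ValueError):
            compute_window_features(v, np.zeros(n), [], 0.0, FS)


class TestLabels:
    @pytest.mark.parametrize("rating,expected", [
        (0, ("no_stress", "no_stress")),
        (1, ("no_stress", "no_stress")),
        (2, ("stress", "stress1")),
        (3, ("stress", "stress1")),
        (4, ("stress", "stress2")),
    ])
    def test_task_rating_mapping(self, rating, expected):
        assert assign_labels(False, rating) == expected

    def test_rest_is_no_stress(self):
        assert assign_labels(True, None) == ("no_stress", "no_stress")

    def test_missing_rating_rejected(self):
        with pytest.raises(ValueError):
            assign_labels(False, None)


class TestFeatureTable:
    @pytest.fixture(scope="class")
    def small_bundle(self):
        import dataclasses
        plan = (
            eog.Segment("rest0", 20.0, 0),
            eog.Segment("task1", 15.0, 2),
            eog.Segment("rest1", 20.0, 0),
        )
        cfg = dataclasses.replace(eog.SynthConfig(seed=4, n_subjects=1),
                                  segment_plan=plan)
        session, truth = eog.render_session(cfg, 0)
        prep = eog.preprocess_session(session)
        events = eog.detect_blinks(prep.eog_v, session.sampling_rate)
        return session, prep, events

    def test_boundary_windows_dropped(self, small_bundle):
        session, prep, events = small_bundle
        table = eog.build_feature_table(session, prep, events)
        # fully-contained windows: 18 + 13 + 18; boundary-crossing ones dropped
        assert len(table) == 18 + 13 + 18
        assert set(table["phase"]) == {"rest0", "task1", "rest1"}
        assert (table[table["phase"] == "task1"]["label3"] == "stress2").all()

    def test_blink_conservation_across_windows(self, small_bundle):
        """Each accepted blink lands in exactly the windows that contain it."""
        session, prep, events = small_bundle
        accepted = [ev for ev in events if ev.accepted]
        starts = segment_windows(session.duration_s)
        by_enumeration = sum(
            1 for ev in accepted for s in starts if s <= ev.apex_time_s < s + 3.0
        )
        table = eog.build_feature_table(session, prep, events)
        # restrict enumeration to windows that survived boundary filtering
        kept = set(table["start_s"])
        kept_count = sum(
            1 for ev in accepted for s in starts
            if s in kept and s <= ev.apex_time_s < s + 3.0
        )
        assert table["blink_freq"].sum() * 3.0 == pytest.approx(kept_count)
        assert kept_count <= by_enumeration


class TestLassoSelect:
    def test_huge_penalty_empty_selection(self, rng):
        X = rng.normal(size=(80, 5))
        y = rng.integers(0, 2, 80)
        sel = lasso_select(X, y, alpha=1e6)
        assert not sel.mask.any()

    def test_zero_penalty_keeps_full_rank_features(self, rng):
        X = rng.normal(size=(100, 4))
        beta = np.array([1.0, -2.0, 0.5, 3.0])
        y = X @ beta + rng.normal(0, 0.1, 100)
        sel = lasso_select(X, (y > np.median(y)).astype(int), alpha=0.0)
        assert sel.mask.all()

    def test_constant_feature_dropped(self, rng):
        X = pd.DataFrame({
            "informative": rng.normal(size=60),
            "constant": np.ones(60),
        })
        y = (X["informative"] > 0).astype(int).to_numpy()
        sel = lasso_select(X, y, alpha=0.01)
        assert "constant" in sel.dropped_constant
        assert not sel.mask[1]

    def test_support_recovery_smoke(self):
        """Noise features zeroed at the CV-chosen penalty (small replicate)."""
        hits = 0
        for seed in range(5):
            r = np.random.default_rng(seed)
            n = 500
            informative = r.normal(size=(n, 2))
            y = (informative.sum(axis=1) + 0.3 * r.normal(size=n) > 0).astype(int)
            X = np.column_stack([informative, r.normal(size=(n, 7))])
            sel = lasso_select(X, y, seed=seed)
            if not sel.mask[2:].any() and sel.mask[:2].all():
                hits += 1
        assert hits >= 4

    def test_negative_penalty_rejected(self, rng):
        with pytest.raises(ValueError):
            lasso_select(rng.normal(size=(20, 3)), rng.integers(0, 2, 20), alpha=-1.0)
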