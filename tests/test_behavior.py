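"""Behavioral inference: change points, approach likelihood, surrogates,
drink detection, session metrics and phenotype rules."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from twocap import behavior as beh
from twocap.behavior import (
    ApproachLikelihoodSet,
    BehaviorError,
    TrackingTrace,
    approach_likelihood,
    assign_surrogate_times,
    classify_session_phenotype,
    cs_sensitivity,
    detect_approach_initiation,
    detect_drink_initiation,
    session_change_point,
    session_metrics,
)


def brute_force_split(x, min_seg=2):
    """Independent oracle: naive loop over splits, naive mean/RSS."""
    x = list(map(float, x))
    n = len(x)
    all_rss = []
    for k in range(min_seg, n - min_seg + 1):
        pre, post = x[:k], x[k:]
        mp = sum(pre) / len(pre)
        mq = sum(post) / len(post)
        all_rss.append(sum((v - mp) ** 2 for v in pre)
                       + sum((v - mq) ** 2 for v in post))
    tol = 1e-9 * max(1.0, sum(v * v for v in x))
    best = min(all_rss)
    for i, r in enumerate(all_rss):
        if r <= best + tol:
            return i + min_seg + 1  # 1-based first post element
    raise AssertionError("unreachable")


class TestSessionChangePoint:
    def test_clean_step(self):
        cp = session_change_point([1, 1, 1, 1, 0, 0, 0, 0])
        assert cp.index == 5 and cp.magnitude == 1.0

    def test_constant_sequence_has_no_change_point(self):
        cp = session_change_point([1] * 10)
        assert cp.index is None and cp.magnitude == 0.0

    def test_too_short_raises(self):
        with pytest.raises(BehaviorError):
            session_change_point([1, 0, 1])

    def test_matches_brute_force_on_all_short_binary_sequences(self):
        for n in range(4, 11):
            for bits in itertools.product((0, 1), repeat=n):
                if len(set(bits)) == 1:
                    continue
                assert session_change_point(bits).index == brute_force_split(bits), bits

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-5, 5).map(lambda v: round(v, 3)),
                    min_size=4, max_size=48))
    def test_matches_brute_force_on_real_sequences(self, xs):
        if np.ptp(xs) == 0:
            assert session_change_point(xs).index is None
        else:
            assert session_change_point(xs).index == brute_force_split(xs)

    def test_ties_break_to_earliest_split(self):
        # symmetric bump: splits at 3 and 5 tie; earliest wins
        seq = [0, 0, 1, 1, 0, 0]
        assert session_change_point(seq).index == brute_force_split(seq)


def _constant_position_tracking(positions, onsets, duration=14.0, rate=30.0):
    """Trace that holds a constant position inside each trial's window."""
    t_end = max(onsets) + duration + 5.0
    t = np.arange(0.0, t_end, 1.0 / rate)
    x = np.zeros_like(t)
    y = np.full_like(t, 100.0)
    for (px, _), onset in zip(positions, onsets):
        x[(t >= onset - 1) & (t <= onset + duration)] = px
    return TrackingTrace(time=t, x=x, y=y,
                         sippers={"left": (0.0, 0.0), "right": (500.0, 0.0)},
                         frame_rate=rate)


def _trials(onsets, approach, cs_type="plus", side="left"):
    return pd.DataFrame({
        "trial": np.arange(1, len(onsets) + 1),
        "cs_type": cs_type, "side": side, "cs_onset": onsets,
        "approach": approach,
        "correct": approach, "drink": approach,
    })


class TestApproachLikelihood:
    def test_all_approach_statuses_one_gives_q_one(self):
        onsets = [20.0, 60.0, 100.0]
        trials = _trials(onsets, [True, True, True])
        trace = _constant_position_tracking([(10, 0), (80, 0), (200, 0)], onsets)
        q = approach_likelihood(trials, trace)
        assert np.allclose(q.q, 1.0)

    def test_all_zero_gives_q_zero(self):
        onsets = [20.0, 60.0, 100.0]
        trials = _trials(onsets, [False, False, False])
        trace = _constant_position_tracking([(10, 0), (80, 0), (200, 0)], onsets)
        q = approach_likelihood(trials, trace)
        assert np.allclose(q.q, 0.0)

    def test_hand_computed_inverse_distance_weights(self):
        """Distances 1:2 from trial 1 with p=[.,1,0] give q_1 = 2/3."""
        onsets = [20.0, 60.0, 100.0]
        trials = _trials(onsets, [True, True, False])
        # constant positions: trial 2 at distance d, trial 3 at 2d from trial 1
        trace = _constant_position_tracking([(0, 0), (100, 0), (200, 0)], onsets)
        q = approach_likelihood(trials, trace)
        assert np.allclose(q.q[0], 2.0 / 3.0, atol=1e-4)

    def test_q_is_convex_combination_of_statuses(self, session_small):
        trials, trace = session_small.trials, session_small.tracking
        q = approach_likelihood(trials, trace)
        p = trials.set_index("trial").loc[q.trial_index, "approach"].astype(float)
        assert q.q.min() >= p.min() - 1e-9 and q.q.max() <= p.max() + 1e-9
        assert np.allclose(q.weights.sum(axis=1), 1.0)


class TestApproachInitiation:
    def _qset(self, q_rows, approach):
        n, T = np.asarray(q_rows).shape
        return ApproachLikelihoodSet(
            q=np.asarray(q_rows, dtype=float),
            weights=np.zeros((n, n, T)),
            trial_index=np.arange(1, n + 1),
            rel_times=np.arange(T) * 0.1,
            bin_width=0.1,
        ), _trials(20.0 + 40.0 * np.arange(n), approach)

    def test_step_trace_detected_at_first_post_bin(self):
        row = [0.1] * 20 + [0.9] * 20
        qset, trials = self._qset([row, row], [True, True])
        out = detect_approach_initiation(qset, trials)
        assert np.allclose(out["approach_init"], 2.0)

    def test_flat_trace_flagged(self):
        qset, trials = self._qset([[0.5] * 30, [0.5] * 30], [True, True])
        out = detect_approach_initiation(qset, trials)
        assert out["flat"].all() and out["approach_init"].isna().all()

    def test_recovers_planted_initiation_times(self):
        from twocap.synth import SimConfig, generate_session

        sess = generate_session(SimConfig(n_neurons=2), seed=3)
        trials, trace = sess.trials, sess.tracking
        q = approach_likelihood(trials, trace)
        out = detect_approach_initiation(q, trials)
        truth = sess.truth.trials.set_index("trial")["approach_init_true"]
        err = (out.set_index("trial")["approach_init"] - truth).abs().dropna()
        assert err.median() <= 0.5


class TestSurrogates:
    def test_surrogates_drawn_from_real_support(self):
        trials = _trials([20.0, 60.0, 100.0, 140.0], [True, True, False, False])
        trials["approach_init"] = [1.2, 3.4, np.nan, np.nan]
        out = assign_surrogate_times(trials, "approach", seed=0)
        surr = out.loc[out["surrogate_approach"], "approach_init"]
        assert set(surr).issubset({1.2, 3.4})

    def test_real_event_trials_untouched(self):
        trials = _trials([20.0, 60.0, 100.0], [True, True, False])
        trials["approach_init"] = [1.2, 3.4, np.nan]
        out = assign_surrogate_times(trials, "approach", seed=1)
        assert out.loc[0, "approach_init"] == 1.2
        assert out.loc[1, "approach_init"] == 3.4
        assert not out.loc[0:1, "surrogate_approach"].any()

    def test_draws_are_uniform_over_real_times(self):
        n_fake = 9_999
        onsets = 20.0 + 40.0 * np.arange(n_fake + 3)
        approach = [True] * 3 + [False] * n_fake
        trials = _trials(onsets, approach)
        trials["approach_init"] = [1.0, 2.0, 3.0] + [np.nan] * n_fake
        out = assign_surrogate_times(trials, "approach", seed=2)
        counts = out.loc[out["surrogate_approach"], "approach_init"].value_counts()
        expected = n_fake / 3
        se = np.sqrt(n_fake * (1 / 3) * (2 / 3))
        assert all(abs(c - expected) < 3 * se for c in counts)

    def test_no_real_events_raises(self):
        trials = _trials([20.0, 60.0], [False, False])
        trials["approach_init"] = np.nan
        with pytest.raises(BehaviorError):
            assign_surrogate_times(trials, "approach", seed=0)


class TestDrinkDetection:
    def _crossing_trace(self, cross_time, onset=20.0, rate=30.0):
        """Snout moves from far away, crossing into the radius at cross_time."""
        t = np.arange(0.0, onset + 20.0, 1.0 / rate)
        # linear move: distance to sipper = 200 - 50*(t - onset), crossing 9 px
        d = np.maximum(200.0 - 50.0 * (t - onset), 0.0)
        return TrackingTrace(time=t, x=d, y=np.zeros_like(t),
                             sippers={"left": (0.0, 0.0), "right": (500.0, 0.0)},
                             frame_rate=rate)

    def test_first_crossing_returned(self):
        # d(t) = 200 - 50*(t-onset) <= 9  =>  t-onset >= 3.82
        trials = _trials([20.0], [True])
        trace = self._crossing_trace(23.82)
        out = detect_drink_initiation(trials, trace)
        grid = np.arange(0.0, 40.0, 1 / 30.0) - 20.0
        expected = grid[(grid >= 4.0) & (200.0 - 50.0 * grid <= 9.0)][0]
        assert np.isclose(out.loc[1], expected)

    def test_never_within_radius_gives_nan(self):
        trials = _trials([20.0], [False])
        t = np.arange(0.0, 40.0, 1 / 30.0)
        trace = TrackingTrace(time=t, x=np.full_like(t, 300.0), y=np.zeros_like(t),
                              sippers={"left": (0.0, 0.0), "right": (500.0, 0.0)},
                              frame_rate=30.0)
        assert np.isnan(detect_drink_initiation(trials, trace).loc[1])

    def test_detection_radius_boundary(self):
        """A snout parked at 8.9 px is drinking; at 9.1 px it is not."""
        t = np.arange(0.0, 40.0, 1 / 30.0)
        for dist, is_hit in ((8.9, True), (9.1, False)):
            trace = TrackingTrace(time=t, x=np.full_like(t, dist), y=np.zeros_like(t),
                                  sippers={"left": (0.0, 0.0), "right": (500.0, 0.0)},
                                  frame_rate=30.0)
            out = detect_drink_initiation(_trials([20.0], [True]), trace)
            assert np.isfinite(out.loc[1]) == is_hit


class TestSessionSummaries:
    def test_cs_sensitivity_ratio(self):
        onsets = 20.0 + 40.0 * np.arange(40)
        cs_type = ["plus"] * 30 + ["minus"] * 10
        trials = pd.DataFrame({
            "trial": np.arange(1, 41), "cs_type": cs_type, "side": "left",
            "cs_onset": onsets, "approach": True, "correct": False, "drink": False,
        })
        assert cs_sensitivity(trials) == 0.75

    def test_cs_sensitivity_undefined_without_approaches(self):
        trials = _trials([20.0, 60.0], [False, False])
        with pytest.raises(BehaviorError):
            cs_sensitivity(trials)

    def test_time_at_sipper_full_access(self):
        t = np.arange(0.0, 40.0, 1 / 30.0)
        trace = TrackingTrace(time=t, x=np.zeros_like(t), y=np.zeros_like(t),
                              sippers={"left": (0.0, 0.0), "right": (500.0, 0.0)},
                              frame_rate=30.0)
        m = session_metrics(_trials([10.0], [True]), trace)
        assert np.isclose(m.time_at_sipper.loc[1], 8.0, atol=2 / 30.0)

    def test_occupancy_zero_without_approaches(self):
        t = np.arange(0.0, 60.0, 1 / 30.0)
        trace = TrackingTrace(time=t, x=np.full_like(t, 250.0), y=np.zeros_like(t),
                              sippers={"left": (0.0, 0.0), "right": (500.0, 0.0)},
                              frame_rate=30.0)
        m = session_metrics(_trials([15.0, 45.0], [False, False]), trace)
        assert np.all(m.occupancy == 0.0)


class TestPhenotype:
    def _records(self):
        return pd.DataFrame({
            "session_id": [f"s{i}" for i in range(10)],
            "strain": ["P"] * 5 + ["Wistar"] * 5,
            "alcohol_consumption": [10.0] * 5 + [10.0] * 5,
            "quinine_consumption": [10, 10, 10, 10, 2.0] + [5, 5, 5, 5, 9.0],
        })

    def test_p_rat_reclassified_non_compulsive(self):
        out = classify_session_phenotype(self._records())
        row = out[out["session_id"] == "s4"].iloc[0]
        assert row["z"] < -1.4 and row["percent_decrease"] > 50
        assert row["label"] == "non-compulsive" and row["reclassified"]

    def test_wistar_reclassified_compulsive(self):
        out = classify_session_phenotype(self._records())
        row = out[out["session_id"] == "s9"].iloc[0]
        assert row["z"] > 1.4 and row["percent_decrease"] < 50
        assert row["label"] == "compulsive" and row["reclassified"]

    def test_typical_sessions_keep_strain_default(self):
        out = classify_session_phenotype(self._records())
        kept = out[~out["session_id"].isin(["s4", "s9"])]
        assert not kept["reclassified"].any()
        assert (kept.loc[kept["strain"] == "P", "label"] == "compulsive").all()

    def test_single_session_strain_raises(self):
        records = self._records().iloc[[0, 5, 6]]
        with pytest.raises(BehaviorError):
            classify_session_phenotype(records)
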