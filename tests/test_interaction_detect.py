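import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flysin.errors import ParameterError
from flysin.interaction_detect import (
    InteractionCriteria,
    InteractionEvent,
    detect_events,
    events_summary,
    merge_events,
)

from conftest import make_traj, random_traj
from oracles import oracle_detect_events


def as_tuples(events):
    return [(e.fly_a, e.fly_b, e.start_frame, e.end_frame) for e in events]


class TestDetectEvents:
    def test_continuous_proximity_one_event(self, two_fly_traj):
        events = detect_events(two_fly_traj)
        assert as_tuples(events) == [("a", "b", 0, 24)]
        assert events[0].duration_s == pytest.approx(1.0)

    def test_below_min_duration_no_event(self):
        traj = make_traj({"a": [(0, 0)] * 10, "b": [(3, 0)] * 10})
        assert detect_events(traj) == []

    def test_above_distance_threshold_no_event(self):
        traj = make_traj({"a": [(0, 0)] * 50, "b": [(4.5, 0)] * 50})
        assert detect_events(traj) == []

    def test_boundary_duration_inclusive(self):
        # exactly 12 frames = 0.5 s at 24 fps counts (inclusive minimum)
        traj = make_traj({"a": [(0, 0)] * 12, "b": [(3, 0)] * 12})
        assert len(detect_events(traj)) == 1

    def test_gap_split_and_fused(self):
        """Distance dips above threshold for 2 frames mid-episode: split at
        tolerance 0, fused into one span at tolerance 2."""
        close, far = (3.0, 0.0), (9.0, 0.0)
        b = [close] * 20 + [far] * 2 + [close] * 21
        traj = make_traj({"a": [(0, 0)] * 43, "b": b})
        split = detect_events(traj, InteractionCriteria())
        assert as_tuples(split) == [("a", "b", 0, 20), ("a", "b", 22, 43)]
        fused = detect_events(traj, InteractionCriteria(gap_tolerance_frames=2))
        assert as_tuples(fused) == [("a", "b", 0, 43)]

    def test_missing_frames_break_runs(self):
        b = [(3.0, 0.0)] * 20 + [None] * 2 + [(3.0, 0.0)] * 20
        traj = make_traj({"a": [(0, 0)] * 42, "b": b})
        events = detect_events(traj)
        assert as_tuples(events) == [("a", "b", 0, 20), ("a", "b", 22, 42)]
        # a missing gap is never bridged, even with tolerance
        events = detect_events(traj, InteractionCriteria(gap_tolerance_frames=5))
        assert len(events) == 2

    def test_per_fly_body_length_overrides(self):
        # pair mean body length 3 mm -> threshold 6 mm, so 5 mm apart counts
        traj = make_traj(
            {"a": [(0, 0)] * 24, "b": [(5.0, 0)] * 24},
            body_length={"a": 2.0, "b": 4.0},
        )
        assert len(detect_events(traj)) == 1

    def test_invalid_criteria(self):
        with pytest.raises(ParameterError):
            InteractionCriteria(min_duration_s=0)
        with pytest.raises(ParameterError):
            InteractionCriteria(gap_tolerance_frames=-1)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize(
        "criteria",
        [
            InteractionCriteria(),
            InteractionCriteria(gap_tolerance_frames=3),
            InteractionCriteria(min_duration_s=0.25),
        ],
    )
    def test_matches_frame_scan_oracle(self, seed, criteria):
        rng = np.random.default_rng(seed)
        traj = random_traj(rng, n_flies=5, n_frames=200, missing_prob=0.03)
        assert as_tuples(detect_events(traj, criteria)) == oracle_detect_events(
            traj, criteria
        )


class TestProperties:
    @given(seed=st.integers(0, 10**6))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_monotone_in_thresholds(self, seed):
        """Loosening either criterion never removes events."""
        rng = np.random.default_rng(seed)
        traj = random_traj(rng, n_flies=4, n_frames=120)
        base = len(detect_events(traj, InteractionCriteria()))
        wider = len(
            detect_events(traj, InteractionCriteria(distance_threshold_bl=3.0))
        )
        shorter = len(
            detect_events(traj, InteractionCriteria(min_duration_s=0.25))
        )
        assert wider >= base
        assert shorter >= base

    @given(seed=st.integers(0, 10**6))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_time_reversal_preserves_durations(self, seed):
        rng = np.random.default_rng(seed)
        traj = random_traj(rng, n_flies=4, n_frames=120)
        fwd = sorted(e.duration_s for e in detect_events(traj))
        rev_data = traj.data.copy()
        rev_data["frame"] = traj.n_frames - 1 - rev_data["frame"]
        rev = traj.__class__(data=rev_data, arena=traj.arena, n_frames=traj.n_frames)
        bwd = sorted(e.duration_s for e in detect_events(rev))
        assert fwd == pytest.approx(bwd)

    @given(seed=st.integers(0, 10**6))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_all_events_meet_minimum_duration(self, seed):
        rng = np.random.default_rng(seed)
        traj = random_traj(rng, n_flies=5, n_frames=150, missing_prob=0.05)
        criteria = InteractionCriteria()
        for e in detect_events(traj, criteria):
            assert e.duration_s >= criteria.min_duration_s
            assert e.end_frame > e.start_frame


class TestMergeEvents:
    def _ev(self, s, e, fps=24.0):
        return InteractionEvent("a", "b", s, e, (e - s) / fps)

    def test_fuses_within_tolerance(self):
        merged = merge_events([self._ev(0, 20), self._ev(22, 40)], 2)
        assert as_tuples(merged) == [("a", "b", 0, 40)]
        assert merged[0].duration_s == pytest.approx(40 / 24)

    def test_zero_tolerance_identity(self):
        events = [self._ev(0, 20), self._ev(22, 40)]
        assert merge_events(events, 0) == events

    def test_idempotent(self):
        events = [self._ev(0, 20), self._ev(22, 40), self._ev(50, 70)]
        once = merge_events(events, 2)
        assert merge_events(once, 2) == once

    def test_empty(self):
        assert merge_events([], 3) == []


class TestEventsSummary:
    def test_per_pair_counts_and_durations(self):
        events = [
            InteractionEvent("A", "B", 0, 24, 1.0),
            InteractionEvent("A", "B", 50, 98, 2.0),
            InteractionEvent("A", "C", 0, 15, 0.6),
        ]
        table, totals = events_summary(events)
        ab = table[(table.fly_a == "A") & (table.fly_b == "B")].iloc[0]
        assert ab.n_events == 2
        assert ab.total_duration_s == pytest.approx(3.0)
        assert totals == {"n_events": 3, "total_duration_s": pytest.approx(3.6)}

    def test_empty(self):
        table, totals = events_summary([])
        assert len(table) == 0
        assert totals["n_events"] == 0
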