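"""EAR computation, baseline filters and blink detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drowsekit.ear_blink import (
    AdaptiveThresholdParams,
    EyeLandmarks,
    adaptive_threshold,
    compute_ear,
    detect_blinks,
    ear_from_landmarks,
    frozen_baseline_threshold,
    median_filter,
    moving_average,
)
from drowsekit.io_formats import EarTrace

OPEN_EYE = np.array(
    [[0.0, 3.0], [1.0, 4.0], [3.0, 4.0], [4.0, 3.0], [3.0, 2.0], [1.0, 2.0]]
)


class TestComputeEar:
    def test_worked_example(self):
        # vertical distances 2 and 2, width 4 -> (2+2)/(2*4) = 0.5
        assert compute_ear(OPEN_EYE) == pytest.approx(0.5)

    def test_closed_eye_is_zero(self):
        closed = OPEN_EYE.copy()
        closed[5] = closed[1]  # p6 = p2
        closed[4] = closed[2]  # p5 = p3
        assert compute_ear(closed) == pytest.approx(0.0)

    @pytest.mark.parametrize("scale", [0.1, 7.0, 123.4])
    def test_scale_invariance(self, scale):
        assert compute_ear(OPEN_EYE * scale) == pytest.approx(compute_ear(OPEN_EYE))

    def test_rotation_translation_invariance(self):
        theta = 0.83
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        moved = OPEN_EYE @ rot.T + np.array([12.0, -3.5])
        assert compute_ear(moved) == pytest.approx(compute_ear(OPEN_EYE))

    def test_degenerate_width_raises(self):
        bad = OPEN_EYE.copy()
        bad[3] = bad[0]  # p4 = p1
        with pytest.raises(ValueError, match="degenerate"):
            compute_ear(bad)

    def test_two_eyes_average(self):
        wide = OPEN_EYE.copy()
        wide[:, 0] *= 2  # halves the EAR
        both = ear_from_landmarks(left=OPEN_EYE, right=wide)
        assert both == pytest.approx((0.5 + 0.25) / 2)
        with pytest.raises(ValueError):
            ear_from_landmarks()

    def test_landmarks_dataclass(self):
        lm = EyeLandmarks.from_array(OPEN_EYE)
        assert compute_ear(lm) == pytest.approx(0.5)


class TestFilters:
    def test_median_constant(self):
        out = median_filter(np.full(40, 0.3), 17)
        assert np.allclose(out, 0.3)

    def test_median_removes_single_dip(self):
        values = np.full(60, 0.3)
        values[30] = 0.1
        assert np.allclose(median_filter(values, 17), 0.3)

    def test_median_matches_bruteforce(self, rng):
        """Oracle: explicit sort of each truncated window (statistics.median)."""
        import statistics

        values = rng.uniform(0, 1, 25)
        for length in (1, 3, 5, 17):
            half = length // 2
            expected = [
                statistics.median(sorted(values[max(0, i - half) : min(25, i + half + 1)]))
                for i in range(25)
            ]
            assert np.allclose(median_filter(values, length), expected)

    @pytest.mark.parametrize("length", [0, 2, 16, -3])
    def test_median_rejects_even_or_nonpositive(self, length):
        with pytest.raises(ValueError):
            median_filter(np.ones(5), length)

    def test_moving_average_constant(self):
        assert np.allclose(moving_average(np.full(20, 0.4), 5), 0.4)

    def test_moving_average_alternating_length_two(self):
        values = np.array([0.0, 1.0, 0.0, 1.0, 0.0, 1.0])
        out = moving_average(values, 2)
        assert out[0] == pytest.approx(0.0)  # truncated single-sample window
        assert np.allclose(out[1:], 0.5)

    def test_moving_average_matches_bruteforce(self, rng):
        values = rng.normal(size=30)
        for length in (1, 2, 5, 9):
            left, right = length // 2, (length - 1) // 2
            expected = [
                np.mean(values[max(0, i - left) : min(30, i + right + 1)])
                for i in range(30)
            ]
            assert np.allclose(moving_average(values, length), expected)

    def test_moving_average_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            moving_average(np.ones(5), 0)


class TestAdaptiveThreshold:
    def test_constant_trace(self):
        trace = EarTrace(30.0, np.full(100, 0.30))
        assert np.allclose(adaptive_threshold(trace), 0.26)

    def test_short_dip_does_not_move_threshold(self):
        # 7-frame dip: removed by the length-17 median, so the threshold
        # stays at baseline - offset across the dip
        values = np.full(120, 0.30)
        values[60:67] = 0.05
        thr = adaptive_threshold(EarTrace(30.0, values))
        assert np.allclose(thr[55:75], 0.26, atol=1e-9)

    def test_empty_trace(self):
        assert adaptive_threshold(EarTrace(30.0, np.empty(0))).size == 0


def _dip_trace(dips, n=400, baseline=0.30, level=0.10):
    values = np.full(n, baseline)
    for start, end in dips:
        values[start : end + 1] = level
    return EarTrace(30.0, values)


class TestDetectBlinks:
    @pytest.mark.parametrize("baseline", ["frozen", "tracking"])
    def test_flat_trace_has_no_blinks(self, baseline):
        events, state = detect_blinks(_dip_trace([]), baseline=baseline)
        assert events == []
        assert not state.closed.any()

    @pytest.mark.parametrize("baseline", ["frozen", "tracking"])
    def test_single_dip_single_event(self, baseline):
        events, state = detect_blinks(_dip_trace([(100, 106)]), baseline=baseline)
        assert len(events) == 1
        assert (events[0].start_frame, events[0].end_frame) == (100, 106)
        assert events[0].duration == pytest.approx(7 / 30.0)
        assert state.closed[100:107].all()

    @pytest.mark.parametrize("baseline", ["frozen", "tracking"])
    def test_two_separated_dips_two_events(self, baseline):
        events, _ = detect_blinks(_dip_trace([(100, 104), (110, 113)]), baseline=baseline)
        assert [(e.start_frame, e.end_frame) for e in events] == [(100, 104), (110, 113)]

    def test_min_blink_frames_rejects_single_frame(self):
        events, state = detect_blinks(_dip_trace([(100, 100)]))
        assert events == []
        assert not state.closed.any()

    def test_events_disjoint_ordered_and_long_enough(self, rng):
        params = AdaptiveThresholdParams(min_blink_frames=3)
        for _ in range(10):
            values = np.clip(0.3 + 0.08 * rng.standard_normal(500), 0, None)
            trace = EarTrace(30.0, values)
            events, _ = detect_blinks(trace, params)
            for a, b in zip(events, events[1:]):
                assert a.end_frame < b.start_frame
            assert all(e.n_frames >= 3 for e in events)

    @pytest.mark.parametrize("baseline", ["frozen", "tracking"])
    def test_shift_invariance(self, rng, baseline):
        """Adding a constant to the whole trace shifts the threshold equally
        and leaves detections unchanged."""
        values = np.clip(0.3 + 0.05 * rng.standard_normal(400), 0, None)
        values[200:206] = 0.05
        base, _ = detect_blinks(EarTrace(30.0, values), baseline=baseline)
        shifted, _ = detect_blinks(EarTrace(30.0, values + 0.2), baseline=baseline)
        assert [(e.start_frame, e.end_frame) for e in base] == [
            (e.start_frame, e.end_frame) for e in shifted
        ]

    def test_adaptive_finds_shallow_dips_fixed_misses(self):
        """On a high baseline, dips to 0.25 never cross the fixed 0.2 cut-off
        but do cross the adaptive baseline-tracking threshold."""
        values = np.full(300, 0.45)
        values[100:105] = 0.25
        values[200:205] = 0.25
        trace = EarTrace(30.0, values)
        fixed_events, _ = detect_blinks(trace, fixed_threshold=0.2)
        adaptive_events, _ = detect_blinks(trace)
        assert fixed_events == []
        assert len(adaptive_events) == 2

    def test_fixed_threshold_finds_every_deep_dip(self):
        trace = _dip_trace([(50, 55), (120, 128)], baseline=0.30, level=0.10)
        events, _ = detect_blinks(trace, fixed_threshold=0.2)
        assert [(e.start_frame, e.end_frame) for e in events] == [(50, 55), (120, 128)]

    def test_frozen_baseline_tracks_through_long_closure(self):
        """A 5 s closure stays below the frozen-baseline threshold for its
        whole duration; the plain tracking composition loses it after the
        median window adapts."""
        values = np.full(600, 0.32)
        values[150:300] = 0.05
        trace = EarTrace(30.0, values)
        _, frozen_state = detect_blinks(trace, baseline="frozen")
        assert frozen_state.closed[150:300].mean() > 0.99
        _, tracking_state = detect_blinks(trace, baseline="tracking")
        assert tracking_state.closed[150:300].mean() < 0.2

    def test_threshold_series_matches_composition(self, rng):
        values = np.clip(0.3 + 0.02 * rng.standard_normal(200), 0, None)
        params = AdaptiveThresholdParams()
        below, thr = frozen_baseline_threshold(values, params)
        assert below.shape == thr.shape == values.shape
        assert np.array_equal(below, values < thr)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    offset=st.floats(min_value=0.01, max_value=0.1),
    n=st.integers(min_value=20, max_value=120),
)
def test_threshold_offset_is_exact_on_constant_traces(offset, n):
    params = AdaptiveThresholdParams(offset=offset)
    thr = adaptive_threshold(EarTrace(30.0, np.full(n, 0.3)), params)
    assert np.allclose(thr, 0.3 - offset)
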