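"""Eye-aspect-ratio computation and adaptive-threshold blink detection.

The eye aspect ratio (EAR) of six eye landmarks P1..P6 (P1/P4 the horizontal
corners, P2/P6 and P3/P5 the two vertical pairs) is

    EAR = (|P2-P6| + |P3-P5|) / (2 |P1-P4|),

a dimensionless quantity that is stable while the eye is open and collapses
toward zero as the lid closes.  A fixed EAR cut-off (0.16-0.28 in the
literature) transfers poorly across subjects, eyewear and lighting, so the
detector here derives a per-frame threshold from the trace itself: a median
filter (default length 17 frames) removes the blinks, a moving average
(default length 5) smooths the residual baseline, and a constant offset
(default 0.04 EAR units) is subtracted.  A frame counts as closed when the
*raw* EAR falls below this slowly varying threshold; the smoothed signal only
serves as the baseline tracker, since a 17-frame median (~0.57 s at 30 fps)
would erase ordinary 100-400 ms blinks from the signal it is compared with.

Maximal runs of closed frames of at least ``min_blink_frames`` (default 2,
~67 ms, rejecting single-frame noise) become blink/closure events.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .episode_scoring import EyeStateSeries
from .io_formats import EarTrace

logger = logging.getLogger("drowsekit.ear")

#: Fixed threshold used for comparison with the adaptive detector.
DEFAULT_FIXED_THRESHOLD = 0.2


@dataclass
class EyeLandmarks:
    """Six 2-D landmark points (pixels) around one eye."""

    p1: np.ndarray
    p2: np.ndarray
    p3: np.ndarray
    p4: np.ndarray
    p5: np.ndarray
    p6: np.ndarray

    def __post_init__(self) -> None:
        for name in ("p1", "p2", "p3", "p4", "p5", "p6"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))

    @classmethod
    def from_array(cls, points: np.ndarray) -> "EyeLandmarks":
        points = np.asarray(points, dtype=float)
        if points.shape != (6, 2):
            raise ValueError(f"expected (6, 2) landmark array, got {points.shape}")
        return cls(*points)


@dataclass
class AdaptiveThresholdParams:
    """Adaptive-threshold parameters.

    ``median_length`` and ``ma_length`` are in frames; ``offset`` is in EAR
    units and is subtracted from the smoothed baseline.
    """

    median_length: int = 17
    ma_length: int = 5
    offset: float = 0.04
    min_blink_frames: int = 2

    def __post_init__(self) -> None:
        if self.median_length < 1 or self.median_length % 2 == 0:
            raise ValueError("median_length must be odd and >= 1")
        if self.ma_length < 1:
            raise ValueError("ma_length must be >= 1")
        if self.offset <= 0:
            raise ValueError("offset must be positive")
        if self.min_blink_frames < 1:
            raise ValueError("min_blink_frames must be >= 1")


@dataclass
class BlinkEvent:
    """A maximal run of closed frames (inclusive frame indices)."""

    start_frame: int
    end_frame: int
    duration: float

    def __post_init__(self) -> None:
        if self.end_frame < self.start_frame:
            raise ValueError("end_frame must be >= start_frame")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


def compute_ear(landmarks: EyeLandmarks | np.ndarray) -> float:
    """EAR of one eye; invariant to translation, rotation and uniform scale."""
    if not isinstance(landmarks, EyeLandmarks):
        landmarks = EyeLandmarks.from_array(landmarks)
    width = np.linalg.norm(landmarks.p1 - landmarks.p4)
    if width < 1e-12:
        raise ValueError("degenerate eye: P1 equals P4")
    v1 = np.linalg.norm(landmarks.p2 - landmarks.p6)
    v2 = np.linalg.norm(landmarks.p3 - landmarks.p5)
    return float((v1 + v2) / (2.0 * width))


def ear_from_landmarks(
    left: EyeLandmarks | np.ndarray | None = None,
    right: EyeLandmarks | np.ndarray | None = None,
) -> float:
    """EAR from one or both eyes; with both present, the mean of the two."""
    values = [compute_ear(e) for e in (left, right) if e is not None]
    if not values:
        raise ValueError("at least one eye's landmarks are required")
    return float(np.mean(values))


def median_filter(values: np.ndarray, length: int) -> np.ndarray:
    """Centered median filter with truncated (shrinking) edge windows.

    No padding is applied: near the boundaries the window is clipped to the
    available samples, so no data is fabricated at session edges.
    """
    if length < 1 or length % 2 == 0:
        raise ValueError("median filter length must be odd and >= 1")
    values = np.asarray(values, dtype=float)
    n = values.size
    if n == 0:
        return values.copy()
    half = length // 2
    out = np.empty(n)
    if n >= length:
        windows = sliding_window_view(values, length)
        out[half : n - half] = np.median(windows, axis=1)
        edge = half
    else:
        edge = n
    for i in range(min(edge, n)):
        out[i] = np.median(values[: min(n, i + half + 1)])
        j = n - 1 - i
        if j >= edge or n < length:
            out[j] = np.median(values[max(0, j - half) :])
    return out


def moving_average(values: np.ndarray, length: int) -> np.ndarray:
    """Centered moving average with truncated edge windows (cumsum based)."""
    if length < 1:
        raise ValueError("moving average length must be >= 1")
    values = np.asarray(values, dtype=float)
    n = values.size
    if n == 0:
        return values.copy()
    # centered window; for even lengths the extra sample comes from the past
    left = length // 2
    right = (length - 1) // 2
    csum = np.concatenate([[0.0], np.cumsum(values)])
    idx = np.arange(n)
    lo = np.maximum(0, idx - left)
    hi = np.minimum(n, idx + right + 1)
    return (csum[hi] - csum[lo]) / (hi - lo)


def adaptive_threshold(
    trace: EarTrace | np.ndarray, params: AdaptiveThresholdParams | None = None
) -> np.ndarray:
    """Per-frame threshold: moving_average(median_filter(EAR)) - offset."""
    params = params or AdaptiveThresholdParams()
    values = trace.values if isinstance(trace, EarTrace) else np.asarray(trace, float)
    smoothed = moving_average(median_filter(values, params.median_length), params.ma_length)
    return smoothed - params.offset


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs as (start, end) inclusive index pairs."""
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2] - 1
    return list(zip(starts.tolist(), ends.tolist()))


def frozen_baseline_threshold(
    values: np.ndarray, params: AdaptiveThresholdParams
) -> tuple[np.ndarray, np.ndarray]:
    """Causal adaptive threshold whose baseline ignores closed frames.

    The plain filter composition tracks the baseline *into* any closure
    longer than about half the median window (~0.3 s at 30 fps with the
    default length 17), after which the raw EAR is no longer below the
    threshold — sustained closures, the very signal PERCLOS/CLOSDUR scoring
    needs, would end after a fraction of a second.  Here the baseline is a
    trailing median (length ``median_length``) followed by a trailing moving
    average (length ``ma_length``) over *held* values: a frame classified
    closed contributes the last open baseline sample instead of its own EAR,
    so the threshold stays put until the eye reopens.  Each frame is
    classified against the threshold derived from frames before it, making
    the rule causal (usable on a live stream).

    Returns ``(below, threshold)`` where ``below[t]`` is the raw comparison
    ``EAR(t) < threshold(t)`` and ``threshold[0]`` is ``EAR(0) - offset``.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    below = np.zeros(n, dtype=bool)
    threshold = np.empty(n)
    held = np.empty(n)
    meds = np.empty(n)
    ml, al = params.median_length, params.ma_length
    baseline = values[0] if n else 0.0
    for t in range(n):
        threshold[t] = baseline - params.offset
        below[t] = values[t] < threshold[t]
        held[t] = values[t] if not below[t] else (held[t - 1] if t else values[t])
        meds[t] = np.median(held[max(0, t - ml + 1) : t + 1])
        baseline = float(np.mean(meds[max(0, t - al + 1) : t + 1]))
    return below, threshold


def detect_blinks(
    trace: EarTrace,
    params: AdaptiveThresholdParams | None = None,
    fixed_threshold: float | None = None,
    baseline: str = "frozen",
    perclos_window: float = 60.0,
) -> tuple[list[BlinkEvent], EyeStateSeries]:
    """Detect blinks/closures and derive the per-frame eye-state series.

    A frame is closed when the raw EAR is strictly below the threshold.
    ``baseline="frozen"`` (default) uses :func:`frozen_baseline_threshold`,
    which detects both brief blinks and sustained closures;
    ``baseline="tracking"`` compares against the plain centered composition
    :func:`adaptive_threshold` (blinks only — the baseline follows longer
    closures).  A numeric ``fixed_threshold`` overrides both.  Maximal
    closed runs of at least ``min_blink_frames`` become :class:`BlinkEvent`
    objects; shorter runs are treated as detector noise and left open in the
    returned state series.
    """
    params = params or AdaptiveThresholdParams()
    n = len(trace)
    if 0 < n <= params.median_length:
        logger.warning(
            "trace of %d frames is no longer than the median filter (%d); "
            "the adaptive baseline will be poorly defined",
            n,
            params.median_length,
        )
    if fixed_threshold is not None:
        threshold = np.full(n, float(fixed_threshold))
        below = trace.values < threshold
    elif baseline == "frozen":
        below, threshold = frozen_baseline_threshold(trace.values, params)
    elif baseline == "tracking":
        threshold = adaptive_threshold(trace, params)
        below = trace.values < threshold
    else:
        raise ValueError(f"unknown baseline mode {baseline!r}")
    closed = np.zeros(n, dtype=bool)
    events: list[BlinkEvent] = []
    for start, end in _runs(below):
        if end - start + 1 >= params.min_blink_frames:
            closed[start : end + 1] = True
            events.append(
                BlinkEvent(start, end, (end - start + 1) / trace.frame_rate)
            )
    state = EyeStateSeries.from_closed(closed, trace.frame_rate, perclos_window)
    return events, state
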