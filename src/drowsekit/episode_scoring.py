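"""PERCLOS/CLOSDUR tracks and wake/drowsy episode segmentation.

Two classic oculometric drowsiness measures are derived from the per-frame
closed/open series produced by the blink detector:

* **PERCLOS** — the fraction of closed frames within a trailing evaluation
  window (default 60 s, following the regulatory "percentage of eye closure
  within a minute" definition), truncated at the session start.
* **CLOSDUR** — the duration in seconds of the ongoing eye closure at each
  frame, resetting to zero whenever the eye opens.

A frame is flagged drowsy when the trailing-window PERCLOS reaches the
threshold (default 0.3) **or** it belongs to a closure run whose eventual
length reaches the closure threshold (default 2 s).  The closure rule is
retroactive: the whole run is flagged from its first frame, which is the
natural choice for offline scoring and avoids splitting one closure across
two episodes.  Maximal same-flag runs become episodes that tile the session
contiguously with alternating labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import DROWSY, WAKE, EpisodeRecord, EpisodeTable


@dataclass
class EyeStateSeries:
    """Per-frame eye state plus derived PERCLOS and closure-duration tracks."""

    frame_rate: float
    closed: np.ndarray
    perclos: np.ndarray
    closdur: np.ndarray

    def __post_init__(self) -> None:
        self.closed = np.asarray(self.closed, dtype=bool)
        self.perclos = np.asarray(self.perclos, dtype=float)
        self.closdur = np.asarray(self.closdur, dtype=float)
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if not (self.closed.size == self.perclos.size == self.closdur.size):
            raise ValueError("closed/perclos/closdur must have equal length")
        if self.perclos.size and (self.perclos.min() < 0 or self.perclos.max() > 1):
            raise ValueError("perclos must lie in [0, 1]")
        if self.closdur.size and self.closdur.min() < 0:
            raise ValueError("closdur must be non-negative")

    def __len__(self) -> int:
        return self.closed.size

    @classmethod
    def from_closed(
        cls, closed: np.ndarray, frame_rate: float, perclos_window: float = 60.0
    ) -> "EyeStateSeries":
        closed = np.asarray(closed, dtype=bool)
        return cls(
            frame_rate=frame_rate,
            closed=closed,
            perclos=perclos_track(closed, frame_rate, perclos_window),
            closdur=closdur_track(closed, frame_rate),
        )


@dataclass
class ScoringParams:
    """Episode-scoring parameters.

    ``perclos_window`` (s) is the trailing evaluation window;
    ``perclos_threshold`` (fraction) and ``closdur_threshold`` (s) define
    drowsiness; flag runs shorter than ``min_episode`` (s, 0 disables) are
    merged into the preceding episode.
    """

    perclos_window: float = 60.0
    perclos_threshold: float = 0.3
    closdur_threshold: float = 2.0
    min_episode: float = 0.0

    def __post_init__(self) -> None:
        if self.perclos_window <= 0:
            raise ValueError("perclos_window must be positive")
        if self.perclos_threshold <= 0 or self.closdur_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.min_episode < 0:
            raise ValueError("min_episode must be non-negative")


def perclos(closed: np.ndarray) -> float:
    """Fraction of closed frames in a window (closed / all frames)."""
    closed = np.asarray(closed, dtype=bool)
    if closed.size == 0:
        raise ValueError("PERCLOS of an empty window is undefined")
    return float(np.count_nonzero(closed) / closed.size)


def perclos_track(
    closed: np.ndarray, frame_rate: float, window: float = 60.0
) -> np.ndarray:
    """Trailing-window PERCLOS at every frame.

    The denominator is always the nominal window length; before a full
    window has elapsed the unseen frames count as open.  Normalizing by the
    truncated length instead would let a single ordinary blink in the first
    seconds of a session exceed the drowsiness threshold.
    """
    closed = np.asarray(closed, dtype=bool)
    n = closed.size
    if n == 0:
        return np.empty(0)
    w = max(1, int(round(window * frame_rate)))
    csum = np.concatenate([[0], np.cumsum(closed)])
    idx = np.arange(n)
    lo = np.maximum(0, idx - w + 1)
    return (csum[idx + 1] - csum[lo]) / w


def closdur_track(closed: np.ndarray, frame_rate: float) -> np.ndarray:
    """Seconds of ongoing closure up to and including each frame (0 if open)."""
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    closed = np.asarray(closed, dtype=bool)
    n = closed.size
    if n == 0:
        return np.empty(0)
    idx = np.arange(n)
    last_open = np.maximum.accumulate(np.where(~closed, idx, -1))
    frames_closed = np.where(closed, idx - last_open, 0)
    return frames_closed / frame_rate


def drowsy_flags(state: EyeStateSeries, params: ScoringParams | None = None) -> np.ndarray:
    """Per-frame drowsy flag from the PERCLOS and retroactive CLOSDUR rules."""
    params = params or ScoringParams()
    flags = state.perclos >= params.perclos_threshold
    # retroactive closure rule: flag the entire run once it reaches threshold
    min_frames = params.closdur_threshold * state.frame_rate
    n = len(state)
    start = None
    closed = state.closed
    for i in range(n + 1):
        if i < n and closed[i]:
            if start is None:
                start = i
        elif start is not None:
            if i - start >= min_frames:
                flags[start:i] = True
            start = None
    return flags


def _flag_runs(flags: np.ndarray) -> list[tuple[int, int, bool]]:
    """Maximal runs as (start, end_exclusive, value)."""
    n = flags.size
    runs = []
    start = 0
    for i in range(1, n + 1):
        if i == n or flags[i] != flags[start]:
            runs.append((start, i, bool(flags[start])))
            start = i
    return runs


def segment_episodes(
    state: EyeStateSeries,
    params: ScoringParams | None = None,
    origin=None,
) -> EpisodeTable:
    """Segment the session into alternating wake/drowsy episodes.

    The returned table tiles ``[0, n_frames / frame_rate]`` with no gaps or
    overlaps; adjacent episodes share their boundary time.  Runs shorter than
    ``min_episode`` are merged into the preceding episode (the first run, into
    the following one).
    """
    params = params or ScoringParams()
    if len(state) == 0:
        raise ValueError("cannot segment an empty state series")
    flags = drowsy_flags(state, params)
    runs = _flag_runs(flags)

    if params.min_episode > 0 and len(runs) > 1:
        min_frames = params.min_episode * state.frame_rate
        merged: list[list] = []
        for start, end, value in runs:
            if merged and (end - start) < min_frames:
                merged[-1][1] = end  # absorb into previous episode
            elif merged and merged[-1][2] == value:
                merged[-1][1] = end  # coalesce same-label neighbors
            else:
                merged.append([start, end, value])
        if len(merged) > 1 and (merged[0][1] - merged[0][0]) < min_frames:
            merged[1][0] = merged[0][0]
            merged = merged[1:]
        # a merge can leave same-label neighbors; coalesce once more
        runs = []
        for start, end, value in merged:
            if runs and runs[-1][2] == value:
                runs[-1] = (runs[-1][0], end, value)
            else:
                runs.append((start, end, value))

    fr = state.frame_rate
    episodes = [
        EpisodeRecord(
            index=k + 1,
            label=DROWSY if value else WAKE,
            start=start / fr,
            end=end / fr,
        )
        for k, (start, end, value) in enumerate(runs)
    ]
    return EpisodeTable(episodes=episodes, origin=origin)
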