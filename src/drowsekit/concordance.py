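"""Per-episode agreement between visual scoring and EEG features.

Each of the ten features carries an expected direction of change with
drowsiness: the theta/delta powers, the three band ratios and the spectral
spread increase, while alpha power, spectral entropy, centroid and rolloff
decrease.  A drowsy episode *i* agrees with a feature on a channel when its
value exceeds (for increasing features; is below, for decreasing ones) the
values of **both** neighboring wake episodes *i-1* and *i+1*; at a session
boundary the single available neighbor decides.

A wake episode has no printed rule of its own, so the mirrored form is used:
wake *j* agrees when, on some channel, its value sits on the wake side of
*every* adjacent drowsy episode (below each adjacent drowsy value for
increasing features, above it for decreasing ones).  For a channel *set*, an
episode agrees when the rule holds on at least one member (union rule).

Across subjects, the association between the number of scored episodes and
the number of agreeing episodes is summarized with Spearman's rank
correlation (tie-corrected average ranks, two-sided p from the t
approximation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .eeg_features import FEATURE_NAMES
from .io_formats import DROWSY, WAKE

#: Direction of change with increasing drowsiness: +1 increases, -1 decreases.
FEATURE_DIRECTIONS: dict[str, int] = {
    "theta_alpha": +1,
    "delta_alpha": +1,
    "delta_theta": +1,
    "psd_alpha": -1,
    "psd_theta": +1,
    "psd_delta": +1,
    "spectral_entropy": -1,
    "spectral_spread": +1,
    "spectral_centroid": -1,
    "spectral_rolloff": -1,
}
assert set(FEATURE_DIRECTIONS) == set(FEATURE_NAMES)


@dataclass(frozen=True)
class FeatureCriterion:
    """A feature name with its drowsiness trend."""

    feature: str
    direction: int  # +1 increases with drowsiness, -1 decreases

    def __post_init__(self) -> None:
        if self.direction not in (+1, -1):
            raise ValueError("direction must be +1 or -1")


#: The ten agreement criteria, one per feature.
CRITERIA: dict[str, FeatureCriterion] = {
    name: FeatureCriterion(name, direction)
    for name, direction in FEATURE_DIRECTIONS.items()
}


@dataclass
class EpisodeCorrelationLabels:
    """Per-episode agreement flags for one feature.

    ``per_channel`` is indexed by 1-based episode with one boolean column per
    channel; ``correlated`` is the union over the channel set; ``labels``
    holds the wake/drowsy label per episode.
    """

    feature: str
    per_channel: pd.DataFrame
    labels: pd.Series
    channels: list[str] = field(default_factory=list)

    @property
    def correlated(self) -> pd.Series:
        return self.per_channel[self.channels].any(axis=1)

    @property
    def total(self) -> int:
        return len(self.per_channel)

    @property
    def n_correlated(self) -> int:
        return int(self.correlated.sum())

    def counts(self, label: str | None = None) -> tuple[int, int]:
        """(total, correlated) episode counts, optionally for one class."""
        mask = slice(None) if label is None else (self.labels == label).to_numpy()
        flags = self.correlated.to_numpy()[mask]
        return int(np.size(flags)), int(np.sum(flags))


def _pivot(features: pd.DataFrame, feature: str) -> tuple[pd.DataFrame, pd.Series]:
    """(episode x channel) value matrix plus per-episode labels, episode-sorted."""
    values = features.pivot(index="episode", columns="channel", values=feature).sort_index()
    labels = (
        features.drop_duplicates("episode").set_index("episode")["label"].sort_index()
    )
    return values, labels


def _drowsy_ok(values: np.ndarray, i: int, direction: int) -> bool:
    """Strict comparison of drowsy episode i against its wake neighbors."""
    neighbors = [j for j in (i - 1, i + 1) if 0 <= j < values.size]
    comparisons = [
        values[i] > values[j] if direction > 0 else values[i] < values[j]
        for j in neighbors
    ]
    return bool(comparisons) and all(comparisons)


def _wake_ok(values: np.ndarray, labels: np.ndarray, j: int, direction: int) -> bool:
    """Mirrored rule: wake j on the wake side of every adjacent drowsy value."""
    adjacent = [
        k for k in (j - 1, j + 1) if 0 <= k < values.size and labels[k] == DROWSY
    ]
    if not adjacent:
        return False
    return all(
        values[j] < values[k] if direction > 0 else values[j] > values[k]
        for k in adjacent
    )


def evaluate_criterion(
    features: pd.DataFrame,
    drowsy_index: int,
    channel: str,
    criterion: FeatureCriterion,
) -> bool:
    """Does drowsy episode ``drowsy_index`` (1-based) meet the criterion on
    ``channel``?  Comparisons involving missing feature values are false."""
    values, labels = _pivot(features, criterion.feature)
    if labels.loc[drowsy_index] != DROWSY:
        raise ValueError(f"episode {drowsy_index} is not a drowsy episode")
    col = values[channel].to_numpy()
    pos = values.index.get_loc(drowsy_index)
    return _drowsy_ok(col, pos, criterion.direction)


def label_episodes(
    features: pd.DataFrame,
    channels: list[str],
    criterion: FeatureCriterion,
) -> EpisodeCorrelationLabels:
    """Agreement flags for every episode on every channel in ``channels``."""
    if not channels:
        raise ValueError("channel set must be non-empty")
    values, labels = _pivot(features, criterion.feature)
    label_arr = labels.to_numpy()
    flags = pd.DataFrame(False, index=values.index, columns=list(channels))
    for channel in channels:
        col = values[channel].to_numpy()
        out = np.zeros(col.size, dtype=bool)
        for pos in range(col.size):
            if label_arr[pos] == DROWSY:
                out[pos] = _drowsy_ok(col, pos, criterion.direction)
            else:
                out[pos] = _wake_ok(col, label_arr, pos, criterion.direction)
        flags[channel] = out
    return EpisodeCorrelationLabels(
        feature=criterion.feature,
        per_channel=flags,
        labels=labels,
        channels=list(channels),
    )


def label_all(
    features: pd.DataFrame, channels: list[str]
) -> dict[str, EpisodeCorrelationLabels]:
    """Agreement labels for all ten criteria."""
    return {name: label_episodes(features, channels, crit) for name, crit in CRITERIA.items()}


def spearman_association(
    per_subject_counts: list[tuple[int, int]],
) -> tuple[float, float]:
    """Spearman's rho between per-subject totals and agreeing counts.

    Requires at least three subjects and non-constant values on both sides.
    """
    counts = np.asarray(per_subject_counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 3:
        raise ValueError("need at least three (total, correlated) pairs")
    totals, matched = counts[:, 0], counts[:, 1]
    if np.ptp(totals) == 0 or np.ptp(matched) == 0:
        raise ValueError("zero variance in totals or matched counts")
    rho, p = stats.spearmanr(totals, matched)
    return float(rho), float(p)
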