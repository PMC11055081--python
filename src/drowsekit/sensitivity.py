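"""Channel, region and all-channel sensitivity of the EEG agreement.

Sensitivity of a channel is the percentage of scored episodes (wake and
drowsy alike) whose EEG feature agrees with the visual scoring on that
channel.  For a set of channels the *combine* sensitivity counts an episode
as agreeing when it agrees on at least one member, so it can only grow as
channels are added:

    sensitivity(ch)       = 100 * agreeing(ch) / total
    combine(set)          = 100 * (1 - missed_by_union / total)

Cross-subject values are plain arithmetic means.  Regions are the montage's
electrode pairs: frontal F3/F4, central C3/C4, occipital O1/O2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .concordance import EpisodeCorrelationLabels
from .eeg_features import FEATURE_NAMES
from .io_formats import DROWSY, EXPECTED_CHANNELS, WAKE

#: Electrode pairs per scalp region.
REGIONS: dict[str, tuple[str, str]] = {
    "frontal": ("F3", "F4"),
    "central": ("C3", "C4"),
    "occipital": ("O1", "O2"),
}


def channel_sensitivity(labels: EpisodeCorrelationLabels, channel: str) -> float:
    """Percent of episodes agreeing on one channel."""
    return combine_sensitivity(labels, [channel])


def combine_sensitivity(labels: EpisodeCorrelationLabels, channel_set: list[str]) -> float:
    """Percent of episodes agreeing on at least one channel of the set."""
    if not channel_set:
        raise ValueError("channel set must be non-empty")
    flags = labels.per_channel[list(channel_set)].to_numpy()
    total = flags.shape[0]
    if total == 0:
        raise ValueError("no episodes to score")
    missed = int(np.sum(~flags.any(axis=1)))
    return 100.0 * (1.0 - missed / total)


def average_sensitivity(per_subject: list[float]) -> float:
    """Arithmetic mean of per-subject sensitivities."""
    values = np.asarray(per_subject, dtype=float)
    if values.size == 0:
        raise ValueError("no per-subject sensitivities to average")
    return float(np.mean(values))


def match_percentages(
    drowsy_total: int, drowsy_matched: int, wake_total: int, wake_matched: int
) -> dict[str, float]:
    """Matched-episode percentages by class and overall, to one decimal."""
    for total in (drowsy_total, wake_total):
        if total <= 0:
            raise ValueError("episode totals must be positive")
    return {
        "drowsy_pct": round(100.0 * drowsy_matched / drowsy_total, 1),
        "wake_pct": round(100.0 * wake_matched / wake_total, 1),
        "total_pct": round(
            100.0 * (drowsy_matched + wake_matched) / (drowsy_total + wake_total), 1
        ),
    }


@dataclass
class SensitivityReport:
    """Cross-subject sensitivity summary.

    ``table`` has one row per (feature, scope) with the subject-averaged
    percentage and the per-subject vector; ``best_channel`` / ``best_region``
    give, per feature, the single channel / region pair with the highest
    average; ``class_counts`` aggregates matched/total episodes by class for
    the union of all channels.
    """

    table: pd.DataFrame
    best_channel: pd.DataFrame
    best_region: pd.DataFrame
    class_counts: pd.DataFrame

    def lookup(self, feature: str, scope: str) -> float:
        row = self.table[(self.table.feature == feature) & (self.table.scope == scope)]
        if row.empty:
            raise KeyError(f"no entry for ({feature}, {scope})")
        return float(row.mean_pct.iloc[0])


def build_report(
    all_labels: dict[object, dict[str, EpisodeCorrelationLabels]],
    channels: list[str] | None = None,
) -> SensitivityReport:
    """Assemble the sensitivity report from per-subject agreement labels.

    ``all_labels`` maps subject -> feature -> labels.  A subject missing a
    feature contributes NaN to that feature's per-subject vectors — the gap
    stays visible, nothing is imputed.
    """
    channels = list(channels or EXPECTED_CHANNELS)
    subjects = list(all_labels)
    if not subjects:
        raise ValueError("no subjects")

    scopes: list[tuple[str, list[str]]] = [(ch, [ch]) for ch in channels]
    scopes += [
        (region, [c for c in members if c in channels])
        for region, members in REGIONS.items()
        if all(c in channels for c in members)
    ]
    scopes.append(("all", channels))

    rows = []
    for feature in FEATURE_NAMES:
        for scope, members in scopes:
            per_subject = []
            for subject in subjects:
                labels = all_labels[subject].get(feature)
                per_subject.append(
                    combine_sensitivity(labels, members) if labels is not None else np.nan
                )
            vec = np.asarray(per_subject, dtype=float)
            rows.append(
                {
                    "feature": feature,
                    "scope": scope,
                    "scope_members": "|".join(members),
                    "mean_pct": float(np.nanmean(vec)) if np.any(~np.isnan(vec)) else np.nan,
                    "n_subjects": int(np.sum(~np.isnan(vec))),
                    "per_subject": per_subject,
                }
            )
    table = pd.DataFrame(rows)

    def _best(scopes_in: list[str], column: str) -> pd.DataFrame:
        block = table[table.scope.isin(scopes_in)].dropna(subset=["mean_pct"])
        if block.empty:
            return pd.DataFrame(columns=["feature", column, "mean_pct"])
        return (
            block.loc[block.groupby("feature").mean_pct.idxmax()][
                ["feature", "scope", "mean_pct"]
            ].rename(columns={"scope": column})
        )

    best_channel = _best(channels, "channel")
    best_region = _best(list(REGIONS), "region")

    class_rows = []
    for feature in FEATURE_NAMES:
        agg = {lab: [0, 0] for lab in (DROWSY, WAKE)}
        complete = True
        for subject in subjects:
            labels = all_labels[subject].get(feature)
            if labels is None:
                complete = False
                continue
            for lab in (DROWSY, WAKE):
                total, matched = labels.counts(lab)
                agg[lab][0] += total
                agg[lab][1] += matched
        class_rows.append(
            {
                "feature": feature,
                "drowsy_total": agg[DROWSY][0],
                "drowsy_matched": agg[DROWSY][1],
                "wake_total": agg[WAKE][0],
                "wake_matched": agg[WAKE][1],
                "complete": complete,
                **(
                    match_percentages(
                        agg[DROWSY][0], agg[DROWSY][1], agg[WAKE][0], agg[WAKE][1]
                    )
                    if agg[DROWSY][0] and agg[WAKE][0]
                    else {"drowsy_pct": np.nan, "wake_pct": np.nan, "total_pct": np.nan}
                ),
            }
        )
    class_counts = pd.DataFrame(class_rows)

    return SensitivityReport(
        table=table,
        best_channel=best_channel.reset_index(drop=True),
        best_region=best_region.reset_index(drop=True),
        class_counts=class_counts,
    )
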