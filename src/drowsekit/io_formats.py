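"""Readers and writers for the pipeline's external representations.

Covered formats:

* EEG recordings — standard 16-bit EDF (read through :mod:`mne`, written by a
  minimal writer in this module) or delimited text with a ``t`` column and one
  column per channel.
* EAR traces — two-column ``(time, ear)`` CSV, or one-column CSV with a
  declared frame rate.
* Episode tables — CSV with 1-based index, ``wake``/``drowsy`` label and
  start/end timestamps (ISO-8601 with millisecond precision when the session
  origin is known, otherwise seconds from session start).
* Feature matrices and sensitivity reports — delimited text.
* Run configuration — a flat YAML mapping of sections to keyword arguments.

All delimited files are comma-separated with a mandatory header row and ``.``
as the decimal mark.  Internally every timestamp is seconds from the start of
the session (float); absolute times are reconciled once, at load.
"""

from __future__ import annotations

import datetime as dt
import io
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("drowsekit.io")

#: Channel labels of the six-electrode montage (10-20 system) this pipeline
#: expects: frontal F3/F4, central C3/C4, occipital O1/O2.  M1/M2 are
#: reference electrodes and are stripped from labels such as ``F4-M1``.
EXPECTED_CHANNELS: tuple[str, ...] = ("F3", "F4", "C3", "C4", "O1", "O2")

WAKE = "wake"
DROWSY = "drowsy"

_ISO_MS = "%Y-%m-%dT%H:%M:%S.%f"


def normalize_channel_label(label: str) -> str:
    """Canonical channel name: case-folded, reference suffix removed.

    ``"f4-M1"`` and ``"F4"`` both normalize to ``"F4"``.
    """
    head = label.strip().split("-")[0].strip()
    return head.upper()


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class EegRecording:
    """A multichannel EEG recording with a shared sampling rate.

    Parameters
    ----------
    channel_labels
        Ordered channel names; unique after normalization.
    sampling_rate
        Sampling frequency in Hz (nominally 200).
    data
        Array of shape ``(n_channels, n_samples)`` in microvolts.
    start_time
        Absolute start of the recording, or ``None`` when unknown.
    """

    channel_labels: list[str]
    sampling_rate: float
    data: np.ndarray
    start_time: dt.datetime | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} rows"
            )
        norm = [normalize_channel_label(c) for c in self.channel_labels]
        if len(set(norm)) != len(norm):
            raise ValueError(f"duplicate channel labels: {self.channel_labels}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate

    def channel(self, label: str) -> np.ndarray:
        """Return one channel's samples; the label match ignores case and
        reference suffixes."""
        want = normalize_channel_label(label)
        for i, lab in enumerate(self.channel_labels):
            if normalize_channel_label(lab) == want:
                return self.data[i]
        raise KeyError(f"channel {label!r} not in {self.channel_labels}")

    def select(self, labels: Sequence[str]) -> "EegRecording":
        rows = np.stack([self.channel(lab) for lab in labels])
        return EegRecording(
            [normalize_channel_label(lab) for lab in labels],
            self.sampling_rate,
            rows,
            self.start_time,
        )


@dataclass
class EarTrace:
    """Per-frame eye-aspect-ratio samples at a fixed frame rate."""

    frame_rate: float
    values: np.ndarray
    start_time: dt.datetime | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("EAR values must be finite")
        if self.values.size and np.any(self.values < 0):
            raise ValueError("EAR values must be non-negative")

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self)) / self.frame_rate


@dataclass
class EpisodeRecord:
    """One wake or drowsy episode; times are seconds from session start."""

    index: int
    label: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.label not in (WAKE, DROWSY):
            raise ValueError(f"label must be {WAKE!r} or {DROWSY!r}, got {self.label!r}")
        if not self.end > self.start:
            raise ValueError(
                f"episode {self.index}: end ({self.end}) must exceed start ({self.start})"
            )

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class EpisodeTable:
    """Ordered, non-overlapping episodes tiling a session.

    ``origin`` is the absolute time of session second 0; when present the CSV
    form carries ISO-8601 timestamps at millisecond resolution.
    """

    episodes: list[EpisodeRecord] = field(default_factory=list)
    origin: dt.datetime | None = None

    def __post_init__(self) -> None:
        for prev, cur in zip(self.episodes, self.episodes[1:]):
            if cur.start < prev.end - 1e-9:
                raise ValueError(
                    f"episodes {prev.index} and {cur.index} overlap "
                    f"({prev.end:.3f} > {cur.start:.3f})"
                )

    def __len__(self) -> int:
        return len(self.episodes)

    def __iter__(self) -> Iterator[EpisodeRecord]:
        return iter(self.episodes)

    def __getitem__(self, i: int) -> EpisodeRecord:
        return self.episodes[i]

    @property
    def labels(self) -> list[str]:
        return [e.label for e in self.episodes]

    @property
    def session_end(self) -> float:
        return self.episodes[-1].end if self.episodes else 0.0

    def alternates(self) -> bool:
        return all(a.label != b.label for a, b in zip(self.episodes, self.episodes[1:]))


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------


def write_edf(recording: EegRecording, path: str | Path) -> None:
    """Write a recording as a standard 16-bit EDF file.

    One-second data records; per-channel physical scaling spans the observed
    range, so the quantization step is range/65535.  Values are stored in
    microvolts with the ``uV`` physical dimension.
    """
    path = Path(path)
    data = np.asarray(recording.data, dtype=float)
    if not float(recording.sampling_rate).is_integer():
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(recording.sampling_rate)  # samples per 1-s record
    n_ch = data.shape[0]
    n_rec = math.ceil(data.shape[1] / spr) if data.shape[1] else 0
    if n_rec * spr > data.shape[1]:
        data = np.pad(data, ((0, 0), (0, n_rec * spr - data.shape[1])), mode="edge")

    pmin = data.min(axis=1) if data.size else np.zeros(n_ch)
    pmax = data.max(axis=1) if data.size else np.ones(n_ch)
    span = np.where(pmax - pmin < 1e-9, 1.0, pmax - pmin)
    # widen by half a quantum so printed 8-char limits always bracket the data
    pmin = pmin - 1e-4 * span
    pmax = pmin + span * (1 + 2e-4)
    pmin = np.array([float("%.6g" % v) for v in pmin])
    pmax = np.array([float("%.6g" % v) for v in pmax])
    pmax = np.where(pmax - pmin < 1e-9, pmin + 1.0, pmax)
    dmin, dmax = -32768, 32767

    start = recording.start_time or dt.datetime(2000, 1, 1, 0, 0, 0)

    def fixed(value: object, width: int) -> bytes:
        raw = str(value)[:width].encode("ascii")
        return raw + b" " * (width - len(raw))

    hdr = io.BytesIO()
    hdr.write(fixed("0", 8))
    hdr.write(fixed("X X X X", 80))
    hdr.write(fixed("Startdate X X X X", 80))
    hdr.write(fixed(start.strftime("%d.%m.%y"), 8))
    hdr.write(fixed(start.strftime("%H.%M.%S"), 8))
    hdr.write(fixed(256 * (n_ch + 1), 8))
    hdr.write(fixed("", 44))
    hdr.write(fixed(n_rec, 8))
    hdr.write(fixed("1", 8))
    hdr.write(fixed(n_ch, 4))
    for lab in recording.channel_labels:
        hdr.write(fixed(f"EEG {lab}", 16))
    for _ in range(n_ch):
        hdr.write(fixed("AgAgCl electrode", 80))
    for _ in range(n_ch):
        hdr.write(fixed("uV", 8))
    for v in pmin:
        hdr.write(fixed("%.6g" % v, 8))
    for v in pmax:
        hdr.write(fixed("%.6g" % v, 8))
    for _ in range(n_ch):
        hdr.write(fixed(dmin, 8))
    for _ in range(n_ch):
        hdr.write(fixed(dmax, 8))
    for _ in range(n_ch):
        hdr.write(fixed("", 80))
    for _ in range(n_ch):
        hdr.write(fixed(spr, 8))
    for _ in range(n_ch):
        hdr.write(fixed("", 32))

    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.rint((data - pmin[:, None]) * scale[:, None] + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(hdr.getvalue())
        for rec in range(n_rec):
            fh.write(digital[:, rec * spr : (rec + 1) * spr].tobytes())


def _read_edf(path: Path, channels: Sequence[str] | None) -> EegRecording:
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    labels = [normalize_channel_label(c.removeprefix("EEG ")) for c in raw.ch_names]
    data = raw.get_data(units="uV")
    meas = raw.info.get("meas_date")
    start = meas.replace(tzinfo=None) if meas is not None else None
    rec = EegRecording(labels, float(raw.info["sfreq"]), data, start)
    if channels is None:
        return rec
    wanted = {normalize_channel_label(c) for c in channels}
    extra = [c for c in labels if c not in wanted]
    if extra:
        logger.info("EDF %s: ignoring channels not requested: %s", path.name, extra)
    return rec.select(list(channels))


def _read_delimited_eeg(path: Path, channels: Sequence[str] | None) -> EegRecording:
    frame = pd.read_csv(path)
    if "t" not in frame.columns:
        raise ValueError(f"{path}: delimited EEG needs a 't' time column")
    if frame.isna().any().any():
        raise ValueError(f"{path}: channels have unequal lengths (missing cells)")
    t = frame["t"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError(f"{path}: need at least two samples")
    steps = np.diff(t)
    if np.any(steps <= 0):
        raise ValueError(f"{path}: time column must be strictly increasing")
    step = float(np.median(steps))
    if np.max(np.abs(steps - step)) > 1e-3 * step:
        raise ValueError(f"{path}: non-uniform sample spacing")
    labels = [c for c in frame.columns if c != "t"]
    rec = EegRecording(labels, 1.0 / step, frame[labels].to_numpy(dtype=float).T)
    if channels is None:
        return rec
    return rec.select(list(channels))


def read_eeg(
    path: str | Path,
    format: str | None = None,
    channels: Sequence[str] | None = None,
) -> EegRecording:
    """Read an EEG recording from EDF or delimited text.

    ``format`` is ``"edf"`` or ``"delimited"``; when ``None`` it is inferred
    from the file extension.  ``channels`` restricts and orders the output;
    channels present in the file but not requested are logged, never silently
    dropped; a requested channel that is absent raises ``KeyError``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "delimited"
    if format == "edf":
        return _read_edf(path, channels)
    if format == "delimited":
        return _read_delimited_eeg(path, channels)
    raise ValueError(f"unknown EEG format {format!r}")


def write_eeg(recording: EegRecording, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "delimited"
    if format == "edf":
        write_edf(recording, path)
        return
    t = np.arange(recording.n_samples) / recording.sampling_rate
    frame = pd.DataFrame({"t": t})
    for lab, row in zip(recording.channel_labels, recording.data):
        frame[lab] = row
    frame.to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# EAR traces
# ---------------------------------------------------------------------------


def write_ear_trace(trace: EarTrace, path: str | Path) -> None:
    frame = pd.DataFrame({"time": trace.times, "ear": trace.values})
    frame.to_csv(path, index=False, float_format="%.6f")


def read_ear_trace(path: str | Path, frame_rate: float | None = None) -> EarTrace:
    """Read an EAR trace from CSV.

    Accepts ``time,ear`` columns (frame rate inferred from the spacing, which
    must be uniform to 0.1%) or a single ``ear`` column with ``frame_rate``
    declared by the caller.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path)
    cols = list(frame.columns)
    if "ear" not in cols:
        raise ValueError(f"{path}: expected an 'ear' column, got {cols}")
    values = frame["ear"].to_numpy(dtype=float)
    if "time" in cols:
        t = frame["time"].to_numpy(dtype=float)
        if len(t) >= 2:
            steps = np.diff(t)
            if np.any(steps <= 0):
                raise ValueError(f"{path}: timestamps must be strictly increasing")
            step = float(np.median(steps))
            if np.max(np.abs(steps - step)) > 1e-3 * step:
                raise ValueError(f"{path}: non-uniform frame spacing")
            frame_rate = 1.0 / step
        elif frame_rate is None:
            raise ValueError(f"{path}: single row needs an explicit frame_rate")
    elif frame_rate is None:
        raise ValueError(f"{path}: no time column; declare frame_rate")
    return EarTrace(frame_rate=float(frame_rate), values=values)


# ---------------------------------------------------------------------------
# episode tables
# ---------------------------------------------------------------------------


def write_episode_table(table: EpisodeTable, path: str | Path) -> None:
    """Write episodes as CSV, losslessly at millisecond resolution."""
    rows = []
    for ep in table.episodes:
        if table.origin is not None:
            start = (table.origin + dt.timedelta(seconds=ep.start)).strftime(_ISO_MS)[:-3]
            end = (table.origin + dt.timedelta(seconds=ep.end)).strftime(_ISO_MS)[:-3]
        else:
            start = f"{ep.start:.3f}"
            end = f"{ep.end:.3f}"
        rows.append({"index": ep.index, "label": ep.label, "start_time": start, "end_time": end})
    pd.DataFrame(rows, columns=["index", "label", "start_time", "end_time"]).to_csv(
        path, index=False
    )


def _parse_episode_time(text: str, origin: dt.datetime | None) -> tuple[float, dt.datetime | None]:
    try:
        return float(text), origin
    except ValueError:
        stamp = dt.datetime.fromisoformat(text)
        if origin is None:
            origin = stamp
        return (stamp - origin).total_seconds(), origin


def read_episode_table(path: str | Path, on_unordered: str = "sort") -> EpisodeTable:
    """Read an episode table written by :func:`write_episode_table`.

    Episodes out of file order are re-sorted by start time when
    ``on_unordered="sort"`` (the default) or rejected with
    ``on_unordered="error"``.  Overlapping episodes always raise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, dtype=str)
    origin: dt.datetime | None = None
    episodes: list[EpisodeRecord] = []
    for _, row in frame.iterrows():
        start, origin = _parse_episode_time(row["start_time"], origin)
        end, origin = _parse_episode_time(row["end_time"], origin)
        episodes.append(
            EpisodeRecord(index=int(row["index"]), label=row["label"], start=start, end=end)
        )
    starts = [e.start for e in episodes]
    if starts != sorted(starts):
        if on_unordered == "error":
            raise ValueError(f"{path}: episodes out of chronological order")
        episodes.sort(key=lambda e: e.start)
    return EpisodeTable(episodes=episodes, origin=origin)


# ---------------------------------------------------------------------------
# feature matrices / labels / sensitivity reports
# ---------------------------------------------------------------------------


def write_feature_matrix(features: pd.DataFrame, path: str | Path) -> None:
    features.to_csv(path, index=False)


def read_feature_matrix(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path)


def write_sensitivity_report(table: pd.DataFrame, path: str | Path) -> None:
    """Write the (feature, scope) sensitivity table; the per-subject vector is
    serialized as JSON in its own column."""
    out = table.copy()
    if "per_subject" in out.columns:
        out["per_subject"] = out["per_subject"].map(
            lambda v: json.dumps(list(np.round(np.asarray(v, dtype=float), 6)))
        )
    out.to_csv(path, index=False)


def read_sensitivity_report(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    if "per_subject" in frame.columns:
        frame["per_subject"] = frame["per_subject"].map(json.loads)
    return frame


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


def load_config(path: str | Path) -> dict:
    """Load a YAML configuration file.

    The schema is a flat mapping of section names to keyword arguments for
    the corresponding parameter dataclasses::

        blink:    {median_length: 17, ma_length: 5, offset: 0.04, min_blink_frames: 2}
        scoring:  {perclos_window: 60, perclos_threshold: 0.3, closdur_threshold: 2}
        preprocess: {fir_order: 25, hp_cutoff: 1, lp_cutoff: 30}
        features: {band_power_method: welch, rolloff: 0.9, weights: power}
        sim:      {duration: 3000, frame_rate: 30, eeg_rate: 200, ...}

    Unknown sections are preserved; unknown keys surface as ``TypeError`` when
    the section is applied to its dataclass.
    """
    with open(path) as fh:
        loaded = yaml.safe_load(fh) or {}
    if not isinstance(loaded, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    return loaded
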