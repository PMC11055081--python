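"""Seeded generator of coupled EAR + six-channel EEG sessions.

Clinical recordings of drowsy driving are rarely shareable, so this module
produces sessions with known ground truth that exercise every stage of the
pipeline:

* an **episode schedule** alternating wake and drowsy segments (random
  durations of 60-180 s wake / 20-90 s drowsy by default, or an explicit
  list), starting awake, over a 50-minute session;
* an **EAR trace** at 30 fps: an open-eye baseline with Gaussian noise,
  Poisson-timed 100-300 ms blinks during wake (12/min), and eye closures
  during drowsy segments — either repeated 2-6 s closures tuned to a target
  closure fraction (PERCLOS) of 0.4, or one continuous closure spanning the
  segment (a microsleep, the ``"single"`` mode used by the strong-effect
  preset).  Closures transition over ~2 frames;
* a **six-channel EEG** at 200 Hz: per channel the sum of four band-limited
  Gaussian components (delta/theta/alpha/beta) plus broadband noise.  Each
  component is white noise band-passed into its band and empirically
  rescaled — its in-band Welch power is measured and normalized — so the
  configured per-state band-power targets are met rather than trusted to
  filter gains.  During drowsy segments the per-band power moves from the
  wake target toward the drowsy target by the per-channel effect gain
  (largest on F4 by default, mirroring the frontal dominance of theta-alpha
  changes reported in drowsiness studies).

Every session is a deterministic function of the seed; independent
sub-streams drive the schedule, the EAR noise and each (channel, band)
component, so altering one block leaves the others' draws untouched.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
from scipy import signal

from .eeg_features import (
    BANDS,
    SpectrumEstimate,
    spectral_centroid,
    spectral_entropy,
    spectral_rolloff,
    spectral_spread,
)
from .io_formats import (
    DROWSY,
    EXPECTED_CHANNELS,
    WAKE,
    EarTrace,
    EegRecording,
    EpisodeRecord,
    EpisodeTable,
    write_ear_trace,
    write_edf,
    write_episode_table,
)

_DEFAULT_START = dt.datetime(2024, 1, 5, 8, 30, 0)


def _default_wake_power() -> dict[str, float]:
    # microvolt-squared band powers typical of an alert, eyes-open recording
    return {"delta": 20.0, "theta": 10.0, "alpha": 20.0, "beta": 5.0}


def _default_drowsy_power() -> dict[str, float]:
    # moderate drowsy shift: theta/delta up, alpha down, beta flat
    return {"delta": 30.0, "theta": 16.0, "alpha": 14.0, "beta": 5.0}


def _default_channel_gain() -> dict[str, float]:
    # frontal channels carry the largest drowsy effect, occipital next,
    # central least — F4 strongest by construction
    return {"F3": 0.45, "F4": 1.0, "C3": 0.12, "C4": 0.15, "O1": 0.2, "O2": 0.3}


@dataclass
class SimConfig:
    """Session-generator parameters; defaults emulate the study conditions
    (50-minute drive, 30 fps video, 200 Hz six-channel EEG)."""

    seed: int = 0
    duration: float = 3000.0
    frame_rate: float = 30.0
    eeg_rate: float = 200.0
    episode_schedule: list[tuple[str, float]] | None = None
    wake_duration: tuple[float, float] = (60.0, 180.0)
    drowsy_duration: tuple[float, float] = (20.0, 90.0)
    wake_blink_rate: float = 12.0  # blinks per minute
    wake_blink_duration: tuple[float, float] = (0.1, 0.3)  # seconds
    drowsy_closure_duration: tuple[float, float] = (2.0, 6.0)  # seconds
    drowsy_closure_fraction: float = 0.4  # target PERCLOS inside drowsy segments
    drowsy_closure_mode: str = "repeated"  # "repeated" | "single"
    open_ear: float = 0.32
    closed_ear: float = 0.05
    ear_noise_sd: float = 0.01
    band_power_wake: dict[str, float] = field(default_factory=_default_wake_power)
    band_power_drowsy: dict[str, float] = field(default_factory=_default_drowsy_power)
    channel_gain: dict[str, float] = field(default_factory=_default_channel_gain)
    eeg_noise_sd: float = 2.0  # broadband microvolts RMS
    start_time: dt.datetime = _DEFAULT_START

    def __post_init__(self) -> None:
        if self.frame_rate <= 0 or self.eeg_rate <= 0:
            raise ValueError("rates must be positive")
        if self.drowsy_closure_mode not in ("repeated", "single"):
            raise ValueError("drowsy_closure_mode must be 'repeated' or 'single'")
        if not (0 < self.drowsy_closure_fraction <= 1):
            raise ValueError("drowsy_closure_fraction must lie in (0, 1]")

    @classmethod
    def strong_effect(cls, seed: int = 0, **overrides) -> "SimConfig":
        """Pronounced drowsiness: theta and delta powers doubled, alpha
        halved, and drowsy segments spent in one continuous closure."""
        wake = _default_wake_power()
        drowsy = {
            "delta": 2 * wake["delta"],
            "theta": 2 * wake["theta"],
            "alpha": 0.5 * wake["alpha"],
            "beta": wake["beta"],
        }
        return cls(
            seed=seed,
            band_power_wake=wake,
            band_power_drowsy=drowsy,
            drowsy_closure_mode="single",
            **overrides,
        )

    @classmethod
    def null_effect(cls, seed: int = 0, **overrides) -> "SimConfig":
        """No EEG state dependence: drowsy band powers equal wake targets."""
        wake = _default_wake_power()
        return cls(
            seed=seed,
            band_power_wake=wake,
            band_power_drowsy=dict(wake),
            **overrides,
        )


@dataclass
class GroundTruth:
    """The generated session's truth: episodes and expected feature trends."""

    episodes: EpisodeTable
    feature_directions: dict[str, dict[str, int]]  # channel -> feature -> +-1/0
    channel_gain: dict[str, float]


class SimulatedSession(NamedTuple):
    ear: EarTrace
    eeg: EegRecording
    truth: GroundTruth


# ---------------------------------------------------------------------------
# schedule
# ---------------------------------------------------------------------------


def _draw_schedule(config: SimConfig, rng: np.random.Generator) -> list[tuple[str, float]]:
    if config.episode_schedule is not None:
        total = sum(d for _, d in config.episode_schedule)
        if total > config.duration + 1e-9:
            raise ValueError(
                f"episode schedule ({total:.1f} s) exceeds session duration "
                f"({config.duration:.1f} s)"
            )
        for label, dur in config.episode_schedule:
            if label not in (WAKE, DROWSY):
                raise ValueError(f"schedule label {label!r} must be wake/drowsy")
            if dur <= 0:
                raise ValueError("schedule durations must be positive")
        return list(config.episode_schedule)
    schedule: list[tuple[str, float]] = []
    elapsed = 0.0
    label = WAKE
    while elapsed < config.duration:
        lo, hi = config.wake_duration if label == WAKE else config.drowsy_duration
        dur = min(float(rng.uniform(lo, hi)), config.duration - elapsed)
        schedule.append((label, dur))
        elapsed += dur
        label = DROWSY if label == WAKE else WAKE
    return schedule


def _schedule_to_table(
    schedule: list[tuple[str, float]], origin: dt.datetime | None
) -> EpisodeTable:
    episodes = []
    t = 0.0
    for k, (label, dur) in enumerate(schedule):
        episodes.append(EpisodeRecord(index=k + 1, label=label, start=t, end=t + dur))
        t += dur
    return EpisodeTable(episodes=episodes, origin=origin)


# ---------------------------------------------------------------------------
# EAR synthesis
# ---------------------------------------------------------------------------


def _closure_intervals(
    schedule: list[tuple[str, float]], config: SimConfig, rng: np.random.Generator
) -> list[tuple[float, float]]:
    """Closed-eye intervals (seconds) across the whole session."""
    intervals: list[tuple[float, float]] = []
    t0 = 0.0
    for label, dur in schedule:
        if label == WAKE:
            t = t0 + float(rng.exponential(60.0 / config.wake_blink_rate))
            while t < t0 + dur:
                blink = float(rng.uniform(*config.wake_blink_duration))
                intervals.append((t, min(t + blink, t0 + dur)))
                t += blink + float(rng.exponential(60.0 / config.wake_blink_rate))
        elif config.drowsy_closure_mode == "single":
            margin = min(0.5, 0.05 * dur)
            intervals.append((t0 + margin, t0 + dur - margin))
        else:
            frac = config.drowsy_closure_fraction
            t = t0
            while t < t0 + dur:
                closure = float(rng.uniform(*config.drowsy_closure_duration))
                end = min(t + closure, t0 + dur)
                if end - t > 1e-3:
                    intervals.append((t, end))
                gap = closure * (1.0 - frac) / frac
                t = end + gap * float(rng.uniform(0.7, 1.3))
        t0 += dur
    return intervals


def _make_ear(
    schedule: list[tuple[str, float]], config: SimConfig, rng: np.random.Generator
) -> EarTrace:
    total = sum(d for _, d in schedule)
    n = int(round(total * config.frame_rate))
    level = np.full(n, config.open_ear)
    for start, end in _closure_intervals(schedule, config, rng):
        i0 = int(round(start * config.frame_rate))
        i1 = int(round(end * config.frame_rate))
        level[i0:i1] = config.closed_ear
    # ~2-frame lid transitions
    kernel = np.array([0.25, 0.5, 0.25])
    smooth = np.convolve(level, kernel, mode="same")
    smooth[0], smooth[-1] = level[0], level[-1]
    values = np.clip(smooth + rng.normal(0.0, config.ear_noise_sd, n), 0.0, None)
    return EarTrace(frame_rate=config.frame_rate, values=values, start_time=config.start_time)


# ---------------------------------------------------------------------------
# EEG synthesis
# ---------------------------------------------------------------------------


def _band_component(
    n: int, rate: float, band: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Band-limited noise with unit in-band Welch power (measure-and-rescale)."""
    lo, hi = band
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=rate, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    nperseg = min(n, int(8 * rate))
    freqs, psd = signal.welch(x, fs=rate, nperseg=nperseg, noverlap=nperseg // 2)
    mask = (freqs >= lo) & (freqs <= hi)
    power = float(np.trapezoid(psd[mask], freqs[mask]))
    if power <= 0:
        raise RuntimeError("degenerate band component")
    return x / np.sqrt(power)


def drowsy_band_power(config: SimConfig, channel: str, band: str) -> float:
    """Effective drowsy-state band-power target for one channel.

    The per-channel gain scales the wake-to-drowsy excursion:
    ``p_wake + gain * (p_drowsy - p_wake)``, floored at 5% of wake power.
    """
    wake = config.band_power_wake[band]
    drowsy = config.band_power_drowsy[band]
    gain = config.channel_gain.get(channel, 1.0)
    return max(wake + gain * (drowsy - wake), 0.05 * wake)


def _make_eeg(
    schedule: list[tuple[str, float]], config: SimConfig, seed_seq: np.random.SeedSequence
) -> EegRecording:
    total = sum(d for _, d in schedule)
    n = int(round(total * config.eeg_rate))
    channels = list(config.channel_gain) or list(EXPECTED_CHANNELS)

    # per-sample drowsy indicator
    drowsy_mask = np.zeros(n, dtype=bool)
    t = 0.0
    for label, dur in schedule:
        if label == DROWSY:
            i0 = int(round(t * config.eeg_rate))
            i1 = int(round((t + dur) * config.eeg_rate))
            drowsy_mask[i0:i1] = True
        t += dur

    streams = seed_seq.spawn(len(channels) * (len(BANDS) + 1))
    data = np.empty((len(channels), n))
    k = 0
    for ci, channel in enumerate(channels):
        rng = np.random.default_rng(streams[k])
        k += 1
        acc = config.eeg_noise_sd * rng.standard_normal(n)
        for band, edges in BANDS.items():
            rng = np.random.default_rng(streams[k])
            k += 1
            component = _band_component(n, config.eeg_rate, edges, rng)
            amp = np.where(
                drowsy_mask,
                np.sqrt(drowsy_band_power(config, channel, band)),
                np.sqrt(config.band_power_wake[band]),
            )
            acc += component * amp
        data[ci] = acc
    return EegRecording(channels, config.eeg_rate, data, config.start_time)


# ---------------------------------------------------------------------------
# expected feature directions
# ---------------------------------------------------------------------------


def _idealized_spectrum(powers: dict[str, float]) -> SpectrumEstimate:
    """Piecewise-flat PSD over 1-30 Hz realizing the configured band powers."""
    freqs = np.arange(1.0, 30.0 + 1e-9, 0.25)
    psd = np.zeros_like(freqs)
    for band, (lo, hi) in BANDS.items():
        mask = (freqs >= lo) & (freqs < hi)
        psd[mask] = powers[band] / (hi - lo)
    return SpectrumEstimate(freqs, psd)


def expected_feature_directions(config: SimConfig, channel: str) -> dict[str, int]:
    """Sign of each feature's wake-to-drowsy change implied by the targets."""
    wake = config.band_power_wake
    drowsy = {band: drowsy_band_power(config, channel, band) for band in BANDS}

    def sign(delta: float) -> int:
        return 0 if abs(delta) < 1e-12 else (1 if delta > 0 else -1)

    def ratio(p: dict[str, float], a: str, b: str) -> float:
        return p[a] / p[b]

    directions = {
        "theta_alpha": sign(ratio(drowsy, "theta", "alpha") - ratio(wake, "theta", "alpha")),
        "delta_alpha": sign(ratio(drowsy, "delta", "alpha") - ratio(wake, "delta", "alpha")),
        "delta_theta": sign(ratio(drowsy, "delta", "theta") - ratio(wake, "delta", "theta")),
        "psd_alpha": sign(drowsy["alpha"] - wake["alpha"]),
        "psd_theta": sign(drowsy["theta"] - wake["theta"]),
        "psd_delta": sign(drowsy["delta"] - wake["delta"]),
    }
    spec_w = _idealized_spectrum(wake)
    spec_d = _idealized_spectrum(drowsy)
    directions["spectral_entropy"] = sign(spectral_entropy(spec_d) - spectral_entropy(spec_w))
    directions["spectral_spread"] = sign(spectral_spread(spec_d) - spectral_spread(spec_w))
    directions["spectral_centroid"] = sign(
        spectral_centroid(spec_d) - spectral_centroid(spec_w)
    )
    directions["spectral_rolloff"] = sign(
        spectral_rolloff(spec_d) - spectral_rolloff(spec_w)
    )
    return directions


# ---------------------------------------------------------------------------
# top level
# ---------------------------------------------------------------------------


def simulate_session(config: SimConfig | None = None) -> SimulatedSession:
    """Generate one coupled EAR + EEG session; deterministic given the seed."""
    config = config or SimConfig()
    root = np.random.SeedSequence(config.seed)
    sched_seq, ear_seq, eeg_seq = root.spawn(3)
    schedule = _draw_schedule(config, np.random.default_rng(sched_seq))
    episodes = _schedule_to_table(schedule, config.start_time)
    ear = _make_ear(schedule, config, np.random.default_rng(ear_seq))
    eeg = _make_eeg(schedule, config, eeg_seq)
    truth = GroundTruth(
        episodes=episodes,
        feature_directions={
            ch: expected_feature_directions(config, ch) for ch in eeg.channel_labels
        },
        channel_gain=dict(config.channel_gain),
    )
    return SimulatedSession(ear=ear, eeg=eeg, truth=truth)


def make_fixture_suite(out_dir: str | Path, seed: int = 7) -> list[Path]:
    """Write the small canonical fixtures used by the tests and docs.

    Produces a one-blink EAR trace, a three-episode session (EAR + EDF EEG +
    episode table) and a three-subject, ten-episode-each cohort.  Running
    twice with the same seed yields identical bytes.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    # one-blink trace: 10 s of open baseline with a 5-frame blink at frame 150
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    values = 0.32 + rng.normal(0.0, 0.005, 300)
    values[150:155] = 0.05
    trace = EarTrace(frame_rate=30.0, values=np.clip(values, 0, None))
    path = out_dir / "ear_one_blink.csv"
    write_ear_trace(trace, path)
    written.append(path)

    # three-episode session: wake 30 s, drowsy 12 s, wake 30 s
    session_dir = out_dir / "session_three_episodes"
    session_dir.mkdir(exist_ok=True)
    config = SimConfig.strong_effect(
        seed=seed + 1,
        duration=72.0,
        episode_schedule=[(WAKE, 30.0), (DROWSY, 12.0), (WAKE, 30.0)],
    )
    session = simulate_session(config)
    write_ear_trace(session.ear, session_dir / "ear.csv")
    write_edf(session.eeg, session_dir / "eeg.edf")
    write_episode_table(session.truth.episodes, session_dir / "episodes.csv")
    written += sorted(session_dir.iterdir())

    # cohort: 3 subjects x 10 episodes (wake 20 s / drowsy 8 s alternating)
    schedule = [(WAKE, 20.0), (DROWSY, 8.0)] * 5
    for s in range(3):
        subject_dir = out_dir / "cohort" / f"subject{s + 1:02d}"
        subject_dir.mkdir(parents=True, exist_ok=True)
        config = SimConfig.strong_effect(
            seed=seed + 10 + s, duration=140.0, episode_schedule=schedule
        )
        session = simulate_session(config)
        write_ear_trace(session.ear, subject_dir / "ear.csv")
        write_edf(session.eeg, subject_dir / "eeg.edf")
        write_episode_table(session.truth.episodes, subject_dir / "episodes.csv")
        written += sorted(subject_dir.iterdir())
    return written
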