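"""drowsekit: video-oculography drowsiness scoring validated against EEG.

The package implements an offline pipeline for drowsiness studies in which a
driver's face is filmed (30 fps) while six EEG channels (F3, F4, C3, C4, O1,
O2; 200 Hz) are recorded:

1. :mod:`~drowsekit.ear_blink` — eye-aspect-ratio (EAR) computation from eye
   landmarks and blink/closure detection with an adaptive threshold that
   tracks the subject's baseline EAR.
2. :mod:`~drowsekit.episode_scoring` — PERCLOS and closure-duration tracks
   and segmentation of the session into alternating wake/drowsy episodes.
3. :mod:`~drowsekit.eeg_features` — FIR band-pass preprocessing, db2 wavelet
   decomposition, and ten spectral features per (episode, channel).
4. :mod:`~drowsekit.concordance` — per-episode agreement between the visual
   scoring and each EEG feature, plus a cross-subject Spearman association.
5. :mod:`~drowsekit.sensitivity` — per-channel / per-region / all-channel
   sensitivity percentages aggregated across subjects.
6. :mod:`~drowsekit.synthetic` — a seeded generator of coupled EAR + EEG
   sessions with ground-truth episode structure, used for testing and
   calibration because clinical recordings of this kind are rarely shareable.

File formats (EDF, CSV traces/tables, YAML configuration) live in
:mod:`~drowsekit.io_formats`.
"""

import logging

from . import (  # noqa: F401
    concordance,
    eeg_features,
    ear_blink,
    episode_scoring,
    io_formats,
    sensitivity,
    synthetic,
)
from .io_formats import EarTrace, EegRecording, EpisodeRecord, EpisodeTable

__version__ = "0.1.0"

__all__ = [
    "EarTrace",
    "EegRecording",
    "EpisodeRecord",
    "EpisodeTable",
    "configure_logging",
    "concordance",
    "eeg_features",
    "ear_blink",
    "episode_scoring",
    "io_formats",
    "sensitivity",
    "synthetic",
]

logging.getLogger("drowsekit").addHandler(logging.NullHandler())


def configure_logging(level: int | str = logging.INFO) -> None:
    """Attach a stderr handler with *level* to the package logger."""
    logger = logging.getLogger("drowsekit")
    handler = logging.StreamHandler()
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    )
    logger.addHandler(handler)
    logger.setLevel(level)
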