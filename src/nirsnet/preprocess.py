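"""Band-pass filtering, marker-based epoching, normalization and run
averaging of HbO2 recordings.

The analysis band is 0.01–0.3 Hz: the high-pass removes slow drifts, the
low-pass removes respiratory/cardiac oscillations, leaving the hemodynamic
band.  Epochs cover 13 s per trial (2 s pre-stimulus baseline + 11 s
post-stimulus and recovery).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .synthetic_data import CASES, Recording

__all__ = ["EpochSet", "bandpass", "segment", "normalize_and_average"]

logger = logging.getLogger(__name__)


@dataclass
class EpochSet:
    """Per-trial segmented epochs for one subject and case.

    ``epochs`` is trials × channels × samples; sample index ``pre_samples``
    is the marker onset.  ``averaged`` (channels × samples) is populated by
    :func:`normalize_and_average` and holds the run average of the normalized
    epochs.
    """

    subject_id: str
    group: str
    case: str
    channels: list[str]
    epochs: np.ndarray
    fs: float
    pre_samples: int
    averaged: np.ndarray | None = None

    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_samples(self) -> int:
        return self.epochs.shape[2]


def design_bandpass(low: float, high: float, fs: float, order: int = 4) -> np.ndarray:
    """Second-order sections of the zero-phase analysis band-pass.

    Butterworth of the given order; applied forward-backward, so the
    effective magnitude response is the squared design response.
    """
    if not (0 < low < high < fs / 2):
        raise ValueError(
            f"band edges must satisfy 0 < low < high < fs/2, got "
            f"low={low}, high={high}, fs={fs}"
        )
    return butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass(
    recording: Recording, low: float = 0.01, high: float = 0.3, order: int = 4
) -> Recording:
    """Zero-phase band-pass filtered copy; markers and metadata unchanged."""
    sos = design_bandpass(low, high, recording.fs, order)
    try:
        filtered = sosfiltfilt(sos, recording.data, axis=1)
    except ValueError as exc:
        raise ValueError(
            "recording is shorter than the filter warm-up length"
        ) from exc
    return replace(recording, data=filtered)


def segment(
    recording: Recording, case: str, pre_s: float = 2.0, post_s: float = 11.0
) -> EpochSet:
    """Cut one epoch per marker of ``case``.

    Epochs are aligned so that sample index ``pre_s * fs`` is the marker
    onset.  Markers too close to a recording boundary are dropped with a
    warning rather than raising.
    """
    if case not in CASES:
        raise ValueError(f"unknown case label {case!r}; expected one of {CASES}")
    onsets = [onset for onset, c in recording.markers if c == case]
    if not onsets:
        raise ValueError(
            f"recording {recording.subject_id!r} has no markers of case {case!r}"
        )
    pre = int(round(pre_s * recording.fs))
    post = int(round(post_s * recording.fs))
    n_samples = recording.n_samples
    epochs = []
    for onset in onsets:
        start, stop = onset - pre, onset + post
        if start < 0 or stop > n_samples:
            logger.warning(
                "dropping trial at sample %d of %s/%s: window [%d, %d) exceeds "
                "recording bounds",
                onset, recording.subject_id, case, start, stop,
            )
            continue
        epochs.append(recording.data[:, start:stop])
    stacked = (
        np.stack(epochs)
        if epochs
        else np.empty((0, len(recording.channels), pre + post))
    )
    return EpochSet(
        subject_id=recording.subject_id,
        group=recording.group,
        case=case,
        channels=list(recording.channels),
        epochs=stacked,
        fs=recording.fs,
        pre_samples=pre,
    )


def normalize_and_average(epoch_set: EpochSet, scale: bool = False) -> EpochSet:
    """Baseline-correct and normalize each epoch, then average across trials.

    Per epoch and channel the pre-stimulus mean is subtracted; with
    ``scale=True`` the epoch is additionally divided by its pre-stimulus
    standard deviation (skipped where that SD is 0, e.g. a constant
    baseline).  Scaling is off by default: a 2-s pre-stimulus window of a
    band-limited signal gives an SD estimate with so few effective degrees of
    freedom that dividing by it mostly injects per-trial noise and attenuates
    inter-channel correlations.  ``averaged`` becomes the trial mean of the
    normalized epochs.
    """
    if epoch_set.n_trials == 0:
        raise ValueError("cannot normalize an EpochSet with zero epochs")
    pre = epoch_set.pre_samples
    if pre < 1:
        raise ValueError("normalization requires a pre-stimulus window")
    baseline = epoch_set.epochs[:, :, :pre]
    mean = baseline.mean(axis=2, keepdims=True)
    centered = epoch_set.epochs - mean
    if scale:
        sd = baseline.std(axis=2, ddof=1, keepdims=True) if pre > 1 else np.zeros_like(mean)
        # scale-aware zero test: an SD at rounding-error level is "no variance"
        tiny = 1e-12 * np.maximum(1.0, np.abs(mean))
        centered = centered / np.where(sd > tiny, sd, 1.0)
    return replace(
        epoch_set, epochs=centered, averaged=centered.mean(axis=0)
    )
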