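"""Temporal filtering, decimation and stimulus-locked epoching.

All filtering is causal (forward-only): the pipeline has to run online, where
future samples do not exist, so zero-phase filtering is deliberately not used.
Conventions fixed package-wide: samples are 0-based, epochs are half-open
windows ``[onset, onset + window)`` at the *current* sampling rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import scipy.signal

from .paradigm import FlashEvent, FlashSchedule

__all__ = ["ContinuousRecording", "EpochSet", "bandpass", "decimate", "epoch"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContinuousRecording:
    """Multichannel continuous signal (channels x samples, µV) with markers."""

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    markers: FlashSchedule | None = None

    def __post_init__(self) -> None:
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel_labels length must match data rows")
        if self.markers is not None:
            onsets = self.markers.onset_samples()
            if len(onsets) and (onsets.min() < 0 or onsets.max() >= self.n_samples):
                raise ValueError("marker onset_samples outside recording")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class EpochSet:
    """Stimulus-locked windows with binary Target/No-Target labels.

    ``epochs`` is (n_epochs, n_channels, epoch_samples); ``labels`` is boolean
    (True = Target).  ``meta`` keeps (stim_id, char_index, repetition) per
    epoch so the decoder can reassemble score tables.
    """

    epochs: np.ndarray
    labels: np.ndarray
    meta: tuple[FlashEvent, ...]
    fs_epoch: float

    def __post_init__(self) -> None:
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be n_epochs x channels x samples")
        if len(self.labels) != len(self.epochs) or len(self.meta) != len(self.epochs):
            raise ValueError("labels/meta must align with epochs")

    def __len__(self) -> int:
        return len(self.epochs)


def bandpass(rec: ContinuousRecording, low: float = 1.0, high: float = 20.0,
             order: int = 4) -> ContinuousRecording:
    """Causal Butterworth bandpass, applied per channel.

    Defaults to the 1-20 Hz fourth-order filter used throughout the pipeline.
    """
    if not (0 < low < high < rec.fs / 2):
        raise ValueError(f"invalid band ({low}, {high}) Hz at fs={rec.fs}")
    sos = scipy.signal.butter(order, [low, high], btype="bandpass",
                              fs=rec.fs, output="sos")
    out = scipy.signal.sosfilt(sos, rec.data, axis=1)
    return replace(rec, data=out)


def decimate(rec: ContinuousRecording, factor: int = 4) -> ContinuousRecording:
    """Reduce the sampling rate by an integer factor (500 Hz -> 125 Hz).

    A causal anti-alias low-pass is applied before picking every ``factor``-th
    sample even though the 20 Hz bandpass already guarantees band limitation
    far below the new Nyquist.  Marker onsets are rescaled by floor division.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return rec
    data = scipy.signal.decimate(rec.data, factor, axis=1, ftype="iir",
                                 zero_phase=False)
    fs_new = rec.fs / factor
    markers = rec.markers
    if markers is not None:
        events = tuple(
            replace(e, onset_sample=e.onset_sample // factor) for e in markers.events
        )
        markers = replace(markers, events=events, fs=fs_new)
    return ContinuousRecording(data=data, fs=fs_new,
                               channel_labels=rec.channel_labels, markers=markers)


def epoch(rec: ContinuousRecording, window_s: float = 0.5) -> EpochSet:
    """Cut one fixed-length window per flash event.

    Window is ``[onset, onset + floor(window_s * fs))`` samples — 62 samples
    for 500 ms at 125 Hz.  Events whose window overruns the recording are
    rejected with a logged count.
    """
    if rec.markers is None:
        raise ValueError("recording has no markers to epoch around")
    n_win = int(np.floor(window_s * rec.fs))
    if n_win < 1:
        raise ValueError("window too short for the sampling rate")

    kept: list[FlashEvent] = []
    slabs: list[np.ndarray] = []
    rejected = 0
    for ev in rec.markers.events:
        stop = ev.onset_sample + n_win
        if stop > rec.n_samples:
            rejected += 1
            continue
        kept.append(ev)
        slabs.append(rec.data[:, ev.onset_sample:stop])
    if rejected:
        logger.info("epoch: rejected %d event(s) overrunning the recording end",
                    rejected)
    if not kept:
        raise ValueError("no complete epochs inside the recording")
    epochs = np.stack(slabs)
    labels = np.array([e.is_target for e in kept], dtype=bool)
    return EpochSet(epochs=epochs, labels=labels, meta=tuple(kept),
                    fs_epoch=rec.fs)
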