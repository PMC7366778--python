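"""Synthetic 64-channel speller sessions with a planted P300.

Emulates the statistical structure the detection pipeline assumes: a
stereotyped positive deflection ~300 ms after every attended (target) flash,
spatially distributed according to a fixed channel-weight pattern, embedded
in structured background noise (1/f "pink" activity, a 10 Hz alpha rhythm
with random phase per channel, and white sensor noise).  Overlapping evoked
responses from successive flashes (the ISI is shorter than the response) are
summed linearly, which is exactly the superposition model the xDAWN stage
estimates.

Nothing here claims physiological fidelity beyond that: there are no blinks,
no EMG, no volume-conduction physics.  See docs/methods.md for what passing
tests on this generator does and does not demonstrate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .paradigm import (
    FlashSchedule,
    SpellerGrid,
    TimingParams,
    generate_flash_schedule,
    session_duration,
)
from .preprocess import ContinuousRecording

__all__ = ["SynthConfig", "GroundTruth", "p300_waveform",
           "default_spatial_pattern", "synthesize_session"]


def default_spatial_pattern(n_channels: int = 64) -> np.ndarray:
    """Unit-norm channel weights concentrated on a contiguous block.

    A raised-cosine bump over the middle third of the channel list stands in
    for the centro-parietal topography of the P300; it gives the spatial
    filter a recoverable low-rank structure without claiming any fidelity to
    a real electrode layout.
    """
    w = np.zeros(n_channels)
    lo, hi = n_channels // 3, 2 * n_channels // 3
    width = max(hi - lo, 1)
    idx = np.arange(lo, hi)
    w[lo:hi] = 0.5 * (1 - np.cos(2 * np.pi * (idx - lo + 0.5) / width))
    return w / np.linalg.norm(w)


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters.  Amplitudes in µV, times in seconds.

    Defaults are the package's reference simulation conditions: a 5 µV
    response peaking 300 ms post-flash with 60 ms Gaussian width and 20 ms
    latency jitter, over 2 µV pink + 1 µV alpha + 0.5 µV white noise on 64
    channels at 500 Hz.
    """

    n_channels: int = 64
    fs: float = 500.0
    p300_amp: float = 5.0
    p300_latency: float = 0.30
    p300_width: float = 0.06
    latency_jitter_sd: float = 0.02
    spatial_pattern: np.ndarray | None = None
    pink_noise_sd: float = 2.0
    alpha_amp: float = 1.0
    alpha_freq: float = 10.0
    white_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 2 * self.alpha_freq:
            raise ValueError("fs must exceed twice the highest modeled frequency")
        for name in ("p300_amp", "pink_noise_sd", "alpha_amp", "white_noise_sd",
                     "latency_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.p300_width <= 0:
            raise ValueError("p300_width must be positive")
        if self.spatial_pattern is not None:
            p = np.asarray(self.spatial_pattern, dtype=float)
            if p.shape != (self.n_channels,):
                raise ValueError("spatial_pattern length must equal n_channels")
            if not np.isclose(np.linalg.norm(p), 1.0, atol=1e-8):
                raise ValueError("spatial_pattern must have unit Euclidean norm")

    def pattern(self) -> np.ndarray:
        if self.spatial_pattern is not None:
            return np.asarray(self.spatial_pattern, dtype=float)
        return default_spatial_pattern(self.n_channels)


@dataclass(frozen=True)
class GroundTruth:
    """What was actually planted: pattern, targets, realized latencies."""

    spatial_pattern: np.ndarray
    targets: tuple[str, ...]
    #: realized peak latency (s, post-onset) for each target event, in
    #: schedule order
    target_latencies: np.ndarray


def p300_waveform(
    t: "float | np.ndarray", latency: float, width: float, amp: float
) -> np.ndarray:
    """Gaussian bump model of the evoked deflection.

    Peaks at ``latency`` with value ``amp`` and decays to ~0 beyond three
    widths; its integral is ``amp * width * sqrt(2*pi)``.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    t = np.asarray(t, dtype=float)
    return amp * np.exp(-0.5 * ((t - latency) / width) ** 2)


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                fs: float, sd: float) -> np.ndarray:
    """1/f-amplitude noise via frequency-domain shaping with seeded phases."""
    if sd == 0:
        return np.zeros((n_channels, n_samples))
    n_freq = n_samples // 2 + 1
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    scale = np.zeros(n_freq)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])          # amplitude ∝ f^(-1/2) → power 1/f
    spec = (rng.standard_normal((n_channels, n_freq))
            + 1j * rng.standard_normal((n_channels, n_freq))) * scale
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    x *= sd / x.std(axis=1, keepdims=True)
    return x


def synthesize_session(
    grid: SpellerGrid,
    targets: "list[str] | str | tuple[str, ...]",
    timing: TimingParams,
    config: SynthConfig,
) -> tuple[ContinuousRecording, FlashSchedule, GroundTruth]:
    """Simulate one full speller session.

    Returns the continuous recording (channels x samples, µV), the exact
    flash schedule it was built from, and the planted ground truth.  Fully
    deterministic given ``config.seed``.
    """
    targets = tuple(targets)
    if not targets:
        raise ValueError("targets must be nonempty")
    rng = np.random.default_rng(config.seed)
    schedule = generate_flash_schedule(
        grid, targets, timing, seed=int(rng.integers(2**31)), fs=config.fs
    )

    tail_s = 1.0  # headroom after the last flash so its epoch fits
    n_samples = int(np.ceil((session_duration(timing, len(targets)) + tail_s)
                            * config.fs))
    data = _pink_noise(rng, config.n_channels, n_samples, config.fs,
                       config.pink_noise_sd)
    if config.alpha_amp > 0:
        t = np.arange(n_samples) / config.fs
        phases = rng.uniform(0, 2 * np.pi, size=config.n_channels)
        data += config.alpha_amp * np.sin(
            2 * np.pi * config.alpha_freq * t[None, :] + phases[:, None]
        )
    if config.white_noise_sd > 0:
        data += config.white_noise_sd * rng.standard_normal(data.shape)

    pattern = config.pattern()
    target_onsets = [e.onset_sample for e in schedule.events if e.is_target]
    latencies = config.p300_latency + config.latency_jitter_sd * rng.standard_normal(
        len(target_onsets)
    )
    # one shared single-channel template support, re-evaluated per event so
    # jittered peaks are exact, then broadcast across channels by the pattern
    support = int(round((config.p300_latency + 10 * config.p300_width) * config.fs))
    t_rel = np.arange(support) / config.fs
    for onset, lat in zip(target_onsets, latencies):
        stop = min(onset + support, n_samples)
        if stop <= onset:
            continue
        bump = p300_waveform(t_rel[: stop - onset], lat, config.p300_width,
                             config.p300_amp)
        data[:, onset:stop] += pattern[:, None] * bump[None, :]

    labels = [f"ch{c:02d}" for c in range(config.n_channels)]
    rec = ContinuousRecording(data=data, fs=config.fs, channel_labels=labels,
                              markers=schedule)
    truth = GroundTruth(spatial_pattern=pattern, targets=targets,
                        target_latencies=np.asarray(latencies))
    return rec, schedule, truth
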