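"""Row/column speller paradigm: grid layout, flash scheduling and session timing.

The oddball speller presents a 6x6 matrix of characters.  On each *repetition*
every row and every column flashes exactly once (12 stimuli); the two flashes
that contain the attended character are rare, attended events and elicit a
P300 response.  A character trial consists of ``n_reps`` repetitions; a
session is a sequence of character trials.

This module is purely combinatorial/arithmetic: it knows nothing about EEG.
It produces the ground-truth stimulus timeline (:class:`FlashSchedule`) that
both the synthetic-data generator and the decoding stages consume, and it
carries the closed-form session-duration and epoch-count models.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

__all__ = [
    "SpellerGrid",
    "TimingParams",
    "FlashEvent",
    "FlashSchedule",
    "TRAINING_TIMING",
    "ONLINE_TIMING",
    "STIM_IDS",
    "generate_flash_schedule",
    "session_duration",
    "count_epochs",
]

#: Canonical stimulus identifiers: six rows then six columns.
STIM_IDS: tuple[str, ...] = tuple(f"R{i}" for i in range(6)) + tuple(
    f"C{i}" for i in range(6)
)


@dataclass(frozen=True)
class SpellerGrid:
    """6x6 character matrix (26 letters + 10 digits by default).

    Parameters
    ----------
    characters
        Row-major string of 36 distinct symbols.
    """

    characters: str = string.ascii_uppercase + string.digits

    def __post_init__(self) -> None:
        if len(self.characters) != 36 or len(set(self.characters)) != 36:
            raise ValueError("grid requires exactly 36 distinct symbols")

    def row_of(self, symbol: str) -> int:
        """Row index (0-5) of ``symbol``."""
        return self.characters.index(symbol) // 6

    def col_of(self, symbol: str) -> int:
        """Column index (0-5) of ``symbol``."""
        return self.characters.index(symbol) % 6

    def char_at(self, row: int, col: int) -> str:
        """Symbol at (row, col)."""
        if not (0 <= row < 6 and 0 <= col < 6):
            raise ValueError(f"grid position out of range: ({row}, {col})")
        return self.characters[row * 6 + col]

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.characters


@dataclass(frozen=True)
class TimingParams:
    """Stimulus-presentation timing of a speller session.

    All durations are in seconds.  ``isi_s`` (interstimulus interval, onset to
    onset) is ``flash_s + gap_s``.  Delays between repetitions and between
    characters separate *consecutive* units, i.e. a session with ``n`` units
    contains ``n - 1`` delays.
    """

    flash_s: float
    gap_s: float
    inter_rep_s: float
    inter_char_s: float
    n_reps: int = 12
    n_stim_per_rep: int = 12

    def __post_init__(self) -> None:
        for name in ("flash_s", "gap_s", "inter_rep_s", "inter_char_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.n_stim_per_rep != 12:
            raise ValueError("a 6x6 grid implies 12 stimuli per repetition")

    @property
    def isi_s(self) -> float:
        return self.flash_s + self.gap_s

    def _isi_frac(self) -> Fraction:
        # exact rational ISI so long-session onsets never accumulate float drift
        return Fraction(str(self.flash_s)) + Fraction(str(self.gap_s))


#: Training protocol: 100 ms flash + 50 ms gap (ISI 150 ms), 0.5 s between
#: repetitions, 5 s between characters, 12 repetitions per character.
TRAINING_TIMING = TimingParams(flash_s=0.100, gap_s=0.050, inter_rep_s=0.5,
                               inter_char_s=5.0, n_reps=12)

#: Online protocol: 50 ms flash + 25 ms gap (ISI 75 ms), 0.25 s between
#: repetitions.  The delay between characters is not part of the per-decision
#: time; 5 s is kept as the stream layout default.
ONLINE_TIMING = TimingParams(flash_s=0.050, gap_s=0.025, inter_rep_s=0.25,
                             inter_char_s=5.0, n_reps=12)


@dataclass(frozen=True)
class FlashEvent:
    """One row/column flash.

    ``is_target`` is true iff the flashed row/column contains the character
    the user is attending to in this trial (2 of 12 events per repetition).
    """

    onset_s: float
    onset_sample: int
    stim_id: str
    is_target: bool
    char_index: int
    repetition: int


@dataclass(frozen=True)
class FlashSchedule:
    """Ordered stimulus timeline of a whole session."""

    events: tuple[FlashEvent, ...]
    timing: TimingParams
    targets: tuple[str, ...]
    fs: float

    def __post_init__(self) -> None:
        onsets = [e.onset_s for e in self.events]
        if onsets != sorted(onsets):
            raise ValueError("events must be sorted by onset")

    def __len__(self) -> int:
        return len(self.events)

    @property
    def n_targets(self) -> int:
        return sum(e.is_target for e in self.events)

    def onset_samples(self) -> np.ndarray:
        return np.array([e.onset_sample for e in self.events], dtype=np.intp)

    def target_onset_samples(self) -> np.ndarray:
        return np.array(
            [e.onset_sample for e in self.events if e.is_target], dtype=np.intp
        )


def generate_flash_schedule(
    grid: SpellerGrid,
    targets: "list[str] | str | tuple[str, ...]",
    timing: TimingParams,
    seed: int,
    fs: float = 500.0,
) -> FlashSchedule:
    """Generate the randomized flash sequence for a session.

    Within each repetition the 12 stimulus ids are presented in a fresh
    uniform random permutation; flash onsets within a repetition are ``isi_s``
    apart, repetitions are separated by ``inter_rep_s`` and characters by
    ``inter_char_s``.  Onsets are accumulated in exact rational seconds and
    rounded to the nearest sample of ``fs``.

    Parameters
    ----------
    targets
        The character attended to in each trial, in order.
    seed
        Fixes the permutation stream; identical seeds give identical schedules.
    """
    targets = tuple(targets)
    if not targets:
        raise ValueError("targets must be nonempty")
    for t in targets:
        if t not in grid:
            raise ValueError(f"target symbol {t!r} not in speller grid")

    rng = np.random.default_rng(seed)
    isi = timing._isi_frac()
    inter_rep = Fraction(str(timing.inter_rep_s))
    inter_char = Fraction(str(timing.inter_char_s))

    events: list[FlashEvent] = []
    t = Fraction(0)
    for ci, target in enumerate(targets):
        if ci > 0:
            t += inter_char
        tgt_stims = {f"R{grid.row_of(target)}", f"C{grid.col_of(target)}"}
        for rep in range(timing.n_reps):
            if rep > 0:
                t += inter_rep
            order = rng.permutation(len(STIM_IDS))
            for k in order:
                stim = STIM_IDS[k]
                events.append(
                    FlashEvent(
                        onset_s=float(t),
                        onset_sample=round(t * Fraction(str(fs))),
                        stim_id=stim,
                        is_target=stim in tgt_stims,
                        char_index=ci,
                        repetition=rep,
                    )
                )
                t += isi
    return FlashSchedule(events=tuple(events), timing=timing, targets=targets, fs=fs)


def session_duration(timing: TimingParams, n_chars: int) -> float:
    """Total stimulation time of a session, in seconds.

    Closed form::

        n_chars * (n_reps * 12 * isi + (n_reps - 1) * inter_rep)
        + (n_chars - 1) * inter_char

    equal to the last flash onset plus one ISI of the generated schedule.
    The training protocol with 15 characters gives 476.5 s.
    """
    if n_chars < 1:
        raise ValueError("n_chars must be >= 1")
    isi = timing._isi_frac()
    per_char = (
        timing.n_reps * timing.n_stim_per_rep * isi
        + (timing.n_reps - 1) * Fraction(str(timing.inter_rep_s))
    )
    total = n_chars * per_char + (n_chars - 1) * Fraction(str(timing.inter_char_s))
    return float(total)


def count_epochs(timing: TimingParams, n_chars: int) -> tuple[int, int, int]:
    """(total, target, nontarget) flash-locked epochs of a session.

    Each repetition contributes 12 epochs, of which exactly 2 (the target's
    row and column) are target epochs: a 15-character, 12-repetition session
    yields (2160, 360, 1800).
    """
    if n_chars < 1:
        raise ValueError("n_chars must be >= 1")
    total = n_chars * timing.n_reps * timing.n_stim_per_rep
    target = n_chars * timing.n_reps * 2
    return total, target, total - target
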