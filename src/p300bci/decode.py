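"""Turn per-flash classifier scores into speller-character decisions.

A character trial produces a 12-stimulus x n_reps table of real-valued P300
scores.  Scores are summed over repetitions per stimulus; the winning row and
winning column index the grid and yield the decoded character — the control
command at the boundary where an effector (robot, speller display, ...) would
attach.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .classify import predict_label, predict_score
from .paradigm import STIM_IDS, SpellerGrid, TimingParams
from .preprocess import ContinuousRecording, EpochSet, bandpass, decimate, epoch
from .metrics import ConfusionMatrix, confusion
from .xdawn import XdawnModel, apply_xdawn

__all__ = ["ScoreTable", "score_character", "build_score_tables",
           "decision_time", "run_offline", "run_online_sim", "OfflineResult",
           "OnlineDecision"]

logger = logging.getLogger(__name__)

_STIM_INDEX = {s: i for i, s in enumerate(STIM_IDS)}


@dataclass
class ScoreTable:
    """Scores for one character trial: (n_reps, 12) with NaN = missing."""

    scores: np.ndarray
    char_index: int

    @classmethod
    def empty(cls, n_reps: int, char_index: int) -> "ScoreTable":
        return cls(scores=np.full((n_reps, 12), np.nan), char_index=char_index)

    def set(self, repetition: int, stim_id: str, value: float) -> None:
        self.scores[repetition, _STIM_INDEX[stim_id]] = value

    def missing(self) -> list[tuple[int, str]]:
        r, c = np.nonzero(np.isnan(self.scores))
        return [(int(ri), STIM_IDS[ci]) for ri, ci in zip(r, c)]


def score_character(table: ScoreTable, grid: SpellerGrid) -> str:
    """Decode one character from a complete score table.

    Scores are summed over repetitions; row = argmax over R0-R5, column =
    argmax over C0-C5.  Ties resolve to the lowest index and are logged.
    """
    miss = table.missing()
    if miss:
        raise ValueError(f"incomplete score table, missing cells: {miss}")
    totals = table.scores.sum(axis=0)
    row_scores, col_scores = totals[:6], totals[6:]
    for name, s in (("row", row_scores), ("column", col_scores)):
        if (s == s.max()).sum() > 1:
            logger.info("score_character: %s tie in trial %d, lowest index wins",
                        name, table.char_index)
    return grid.char_at(int(np.argmax(row_scores)), int(np.argmax(col_scores)))


def build_score_tables(epochs: EpochSet, scores: np.ndarray) -> list[ScoreTable]:
    """Group per-epoch scores into one table per character trial."""
    if len(scores) != len(epochs):
        raise ValueError("one score per epoch required")
    n_reps = max(e.repetition for e in epochs.meta) + 1
    tables: dict[int, ScoreTable] = {}
    for ev, s in zip(epochs.meta, scores):
        tables.setdefault(ev.char_index, ScoreTable.empty(n_reps, ev.char_index))
        tables[ev.char_index].set(ev.repetition, ev.stim_id, float(s))
    return [tables[ci] for ci in sorted(tables)]


def decision_time(timing: TimingParams, n_reps: int | None = None) -> float:
    """Stimulation time T for one character decision, in seconds.

    T = n_reps * 12 * isi + (n_reps - 1) * inter_rep.  Online timing with 12
    repetitions gives 13.55 s; training timing gives 27.1 s.
    """
    n = timing.n_reps if n_reps is None else n_reps
    if n < 1:
        raise ValueError("n_reps must be >= 1")
    return float(n * timing.n_stim_per_rep * timing._isi_frac()
                 + (n - 1) * Fraction(str(timing.inter_rep_s)))


@dataclass(frozen=True)
class OfflineResult:
    epoch_accuracy: float
    char_accuracy: float
    confusion: ConfusionMatrix
    decoded: tuple[str, ...]
    targets: tuple[str, ...]


def _pipeline_epochs(rec: ContinuousRecording, decim: int = 4,
                     window_s: float = 0.5) -> EpochSet:
    return epoch(decimate(bandpass(rec), decim), window_s)


def run_offline(rec: ContinuousRecording, xdawn_model: XdawnModel,
                clf_model, grid: SpellerGrid) -> OfflineResult:
    """Deterministic end-to-end evaluation of a recorded session.

    Preprocess -> epoch -> spatial-filter features -> classifier scores ->
    epoch-level accuracy/confusion and character-level decoding accuracy
    against the schedule's target characters.
    """
    if rec.markers is None:
        raise ValueError("recording carries no flash schedule")
    eps = _pipeline_epochs(rec)
    feats = apply_xdawn(xdawn_model, eps)
    scores = predict_score(clf_model, feats)
    pred = predict_label(clf_model, feats)
    cm = confusion(eps.labels, pred)
    epoch_acc = float(np.mean(pred == eps.labels))
    decoded = tuple(score_character(t, grid) for t in build_score_tables(eps, scores))
    targets = rec.markers.targets
    if len(decoded) != len(targets):
        raise ValueError("decoded trial count does not match session targets")
    char_acc = float(np.mean([d == t for d, t in zip(decoded, targets)]))
    return OfflineResult(epoch_accuracy=epoch_acc, char_accuracy=char_acc,
                         confusion=cm, decoded=decoded, targets=targets)


@dataclass(frozen=True)
class OnlineDecision:
    char_index: int
    decoded: str
    stim_totals: np.ndarray   # aggregated score per stimulus id, R0..R5,C0..C5
    T: float                  # stimulation seconds consumed by this decision


def run_online_sim(rec: ContinuousRecording, xdawn_model: XdawnModel,
                   clf_model, grid: SpellerGrid,
                   n_reps: int | None = None) -> list[OnlineDecision]:
    """Simulate causal online decoding of a session.

    Every filter in the pipeline is causal (forward-only), so the filtered
    value at sample t never depends on later samples; emitting each decision
    from the epochs of its own trial is therefore exactly what a streaming
    implementation would produce.  One decision is emitted per character
    trial after ``n_reps`` repetitions (default: all repetitions present),
    with T the stimulation time of the trial.
    """
    if rec.markers is None:
        raise ValueError("recording carries no flash schedule")
    timing = rec.markers.timing
    n = timing.n_reps if n_reps is None else n_reps
    if not 1 <= n <= timing.n_reps:
        raise ValueError(f"n_reps must be in [1, {timing.n_reps}]")
    eps = _pipeline_epochs(rec)
    feats = apply_xdawn(xdawn_model, eps)
    scores = predict_score(clf_model, feats)
    T = decision_time(timing, n)

    decisions = []
    for table in build_score_tables(eps, scores):
        sub = ScoreTable(scores=table.scores[:n], char_index=table.char_index)
        decisions.append(OnlineDecision(
            char_index=table.char_index,
            decoded=score_character(sub, grid),
            stim_totals=sub.scores.sum(axis=0),
            T=T,
        ))
    return decisions
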