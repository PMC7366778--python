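"""Evaluation metrics: confusion-matrix statistics and the Shannon ITR.

Target flashes are the positive class.  The information transfer rate of a
selection system with accuracy P over N choices taking T seconds per
selection is

    ITR = 60/T * [ P log2 P + (1-P) log2((1-P)/(N-1)) + log2 N ]   bits/min,

with the convention 0·log2 0 = 0 so P ∈ {0, 1} is well defined.  Chance
performance (P = 1/N) carries exactly zero information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ConfusionMatrix", "ItrParams", "confusion", "sensitivity",
           "precision", "specificity", "f_measure", "itr", "aggregate_report"]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Two-class counts: target = positive."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.fp + self.tn

    def normalized(self) -> np.ndarray:
        """Row-normalized 2x2 matrix [[tp, fn], [fp, tn]] / row totals."""
        m = np.array([[self.tp, self.fn], [self.fp, self.tn]], dtype=float)
        sums = m.sum(axis=1, keepdims=True)
        if np.any(sums == 0):
            raise ValueError("cannot normalize: a true class is empty")
        return m / sums


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionMatrix:
    """Count TP/FN/FP/TN from boolean label arrays."""
    y_true = np.asarray(y_true, dtype=bool)
    y_pred = np.asarray(y_pred, dtype=bool)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    return ConfusionMatrix(
        tp=int(np.sum(y_true & y_pred)),
        fn=int(np.sum(y_true & ~y_pred)),
        fp=int(np.sum(~y_true & y_pred)),
        tn=int(np.sum(~y_true & ~y_pred)),
    )


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        raise ZeroDivisionError(f"{name} undefined: zero denominator")
    return num / den


def sensitivity(cm: ConfusionMatrix) -> float:
    """TP / (TP + FN): ability to detect target epochs."""
    return _ratio(cm.tp, cm.tp + cm.fn, "sensitivity")


def precision(cm: ConfusionMatrix) -> float:
    """TP / (TP + FP): fraction of predicted targets that are real."""
    return _ratio(cm.tp, cm.tp + cm.fp, "precision")


def specificity(cm: ConfusionMatrix) -> float:
    """TN / (TN + FP): ability to reject non-target epochs."""
    return _ratio(cm.tn, cm.tn + cm.fp, "specificity")


def f_measure(cm_or_pair: "ConfusionMatrix | tuple[float, float]") -> float:
    """Harmonic combination 2·P·S / (P + S) of precision P and sensitivity S.

    Accepts either a confusion matrix or a precomputed ``(precision,
    sensitivity)`` pair (e.g. published table rows).
    """
    if isinstance(cm_or_pair, ConfusionMatrix):
        p, s = precision(cm_or_pair), sensitivity(cm_or_pair)
    else:
        p, s = map(float, cm_or_pair)
    if p + s == 0:
        raise ZeroDivisionError("f_measure undefined: precision + sensitivity = 0")
    return 2 * p * s / (p + s)


@dataclass(frozen=True)
class ItrParams:
    """Inputs of the ITR formula: accuracy P, class count N, seconds T."""

    P: float
    N: int
    T: float

    def __post_init__(self) -> None:
        if not 0 <= self.P <= 1:
            raise ValueError("P must lie in [0, 1]")
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if self.T <= 0:
            raise ValueError("T must be positive")


def itr(params: "ItrParams | None" = None, *, P: float | None = None,
        N: int | None = None, T: float | None = None) -> float:
    """Shannon information transfer rate in bits/min.

    Call with an :class:`ItrParams` or keywords ``P``, ``N``, ``T``.
    P = 0.8083, N = 36, T = 13.55 s gives 15.42 bits/min.
    """
    if params is None:
        params = ItrParams(P=P, N=N, T=T)
    P_, N_, T_ = params.P, params.N, params.T

    def xlog2x(x: float) -> float:
        return 0.0 if x == 0 else x * np.log2(x)

    bits = (xlog2x(P_) + (0.0 if P_ == 1 else (1 - P_) * np.log2((1 - P_) / (N_ - 1)))
            + np.log2(N_))
    return float(60.0 * bits / T_)


def aggregate_report(table: pd.DataFrame, decimals: int | None = None
                     ) -> pd.DataFrame:
    """Column means and sample (n−1) standard deviations of a metric table.

    Rows are participants/sessions, columns are metrics.  Returns a two-row
    frame indexed ``mean`` / ``std``; ``decimals`` optionally rounds for
    display (4 for fractions, 2 for percentages).
    """
    table = pd.DataFrame(table)
    if len(table) == 0:
        raise ValueError("empty metric table")
    if len(table) < 2:
        out = pd.DataFrame([table.mean(), table.iloc[0] * 0.0],
                           index=["mean", "std"])
    else:
        out = pd.DataFrame([table.mean(), table.std(ddof=1)],
                           index=["mean", "std"])
    return out.round(decimals) if decimals is not None else out
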