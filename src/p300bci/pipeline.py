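"""Convenience glue: train the full detector stack on one session."""

from __future__ import annotations

from functools import partial

import numpy as np

from .classify import (TrainReport, cross_validate, fit_lda, fit_mlp, fit_svm)
from .preprocess import ContinuousRecording, bandpass, decimate, epoch
from .xdawn import XdawnModel, apply_xdawn, fit_xdawn

__all__ = ["preprocess_session", "fit_session"]

FITTERS = {
    "lda": lambda seed: lambda X, y: fit_lda(X, y),
    "svm": lambda seed: lambda X, y: fit_svm(X, y, C=1.0),
    "mlp": lambda seed: lambda X, y: fit_mlp(X, y, seed=seed),
}


def preprocess_session(rec: ContinuousRecording, decim: int = 4,
                       window_s: float = 0.5):
    """Bandpass -> decimate -> epoch; returns (filtered recording, epochs)."""
    filt = decimate(bandpass(rec), decim)
    return filt, epoch(filt, window_s)


def fit_session(rec: ContinuousRecording, clf: str = "lda", seed: int = 0,
                n_components: int = 3, cv_folds: int | None = 5,
                ) -> tuple[XdawnModel, object, "TrainReport | None"]:
    """Train xDAWN + a classifier on a marked training session.

    Returns the spatial-filter model, the fitted detector and (optionally)
    its stratified cross-validation report on the training epochs.
    """
    if clf not in FITTERS:
        raise ValueError(f"clf must be one of {sorted(FITTERS)}")
    filt, eps = preprocess_session(rec)
    epoch_len = eps.epochs.shape[2]
    target_onsets = [e.onset_sample for e in filt.markers.events if e.is_target]
    xd = fit_xdawn(filt.data.T, target_onsets, epoch_len, k=n_components)
    X = apply_xdawn(xd, eps)
    y = eps.labels
    fit_fn = FITTERS[clf](seed)
    model = fit_fn(X, y)
    report = None
    if cv_folds:
        report = cross_validate(X, y, fit_fn, k=cv_folds, seed=seed)
    return xd, model, report
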