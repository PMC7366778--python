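"""xDAWN spatial filtering: evoked-response estimation and SSNR maximization.

The preprocessed recording ``X`` (samples x channels) is modeled as a linear
superposition of a target evoked response ``A1`` replicated at every target
onset by a 0/1 Toeplitz design ``D1``, plus everything else:

    X = D1 A1 + D2 A2 + N

``A1`` is recovered by least squares.  A spatial filter ``u`` is then scored
by its signal-to-signal-plus-noise ratio — the generalized Rayleigh quotient

    SSNR(u) = (uᵀ Σ1 u) / (uᵀ Σx u),

where ``Σ1`` is the covariance of the reconstructed evoked signal ``D1 A1``
and ``Σx`` the covariance of the raw signal.  Maximizers are the leading
eigenvectors of the generalized symmetric eigenproblem ``Σ1 u = λ Σx u``;
the top three components are kept, compressing 64 channels to 3 enhanced
virtual channels.

Because the design matrix handles overlap explicitly, responses from flashes
closer together than the epoch length are separated correctly — the regime
the speller's 150/75 ms ISI actually operates in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse

from .preprocess import EpochSet

__all__ = ["ToeplitzDesign", "XdawnModel", "build_toeplitz", "estimate_erp",
           "fit_xdawn", "apply_xdawn", "ssnr"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ToeplitzDesign:
    """Sparse 0/1 design replicating a time-locked waveform at event onsets.

    Column ``k`` has a 1 in every row that lies ``k`` samples after an event
    onset; ``D @ A`` therefore superimposes the waveform ``A`` at each event.
    """

    matrix: scipy.sparse.csr_matrix
    onsets: np.ndarray
    epoch_len: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape


@dataclass(frozen=True)
class XdawnModel:
    """Fitted spatial-filter model.

    Attributes
    ----------
    A1_hat
        Estimated evoked response, epoch_len x channels.
    U
        Spatial filters, channels x k, SSNR-descending columns.
    ssnr_values
        Generalized eigenvalues (the SSNR of each filter), descending.
    """

    A1_hat: np.ndarray
    U: np.ndarray
    ssnr_values: np.ndarray
    epoch_len: int

    @property
    def n_components(self) -> int:
        return self.U.shape[1]


def build_toeplitz(onsets: "np.ndarray | list[int]", n_samples: int,
                   epoch_len: int) -> ToeplitzDesign:
    """Build the event design matrix for the given onset samples.

    Rows that would fall beyond ``n_samples`` (an epoch overrunning the
    recording) are truncated and logged.
    """
    onsets = np.asarray(onsets, dtype=np.intp)
    if len(onsets) and (onsets.min() < 0 or onsets.max() >= n_samples):
        raise ValueError("event onsets outside the recording")
    rows, cols = [], []
    truncated = 0
    for onset in onsets:
        stop = min(onset + epoch_len, n_samples)
        if stop - onset < epoch_len:
            truncated += 1
        rows.extend(range(onset, stop))
        cols.extend(range(stop - onset))
    if truncated:
        logger.info("build_toeplitz: truncated %d epoch(s) at recording end",
                    truncated)
    data = np.ones(len(rows))
    mat = scipy.sparse.csr_matrix(
        (data, (rows, cols)), shape=(n_samples, epoch_len)
    )
    return ToeplitzDesign(matrix=mat, onsets=onsets, epoch_len=epoch_len)


def estimate_erp(X: np.ndarray, design: ToeplitzDesign) -> np.ndarray:
    """Least-squares evoked response: argmin_A ||X - D A||².

    Solved via the normal equations (DᵀD is epoch_len x epoch_len and well
    conditioned whenever every lag is covered by enough events).
    """
    D = design.matrix
    gram = (D.T @ D).toarray()
    diag = np.diag(gram)
    if np.any(diag == 0):
        bad = np.flatnonzero(diag == 0)
        raise np.linalg.LinAlgError(
            f"rank-deficient design: no events cover lags {bad.tolist()}"
        )
    rhs = D.T @ X
    try:
        return scipy.linalg.solve(gram, rhs, assume_a="pos")
    except scipy.linalg.LinAlgError as err:  # pragma: no cover - rare
        raise np.linalg.LinAlgError(f"singular design gram matrix: {err}") from err


def ssnr(u: np.ndarray, sigma1: np.ndarray, sigma_x: np.ndarray) -> float:
    """Rayleigh quotient uᵀΣ1u / uᵀΣxu for a single filter."""
    u = np.asarray(u, dtype=float)
    return float(u @ sigma1 @ u) / float(u @ sigma_x @ u)


def _covariances(X: np.ndarray, design: ToeplitzDesign,
                 A1: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = X.shape[0]
    evoked = design.matrix @ A1
    sigma1 = evoked.T @ evoked / n
    sigma_x = X.T @ X / n
    return sigma1, sigma_x


def fit_xdawn(X: np.ndarray, target_onsets: "np.ndarray | list[int]",
              epoch_len: int, k: int = 3) -> XdawnModel:
    """Estimate the evoked model and the top-k SSNR-maximizing filters.

    Parameters
    ----------
    X
        Preprocessed continuous signal, samples x channels.
    target_onsets
        Target flash onsets in samples of ``X``'s rate.
    k
        Number of spatial filters kept (3 in the reference pipeline).
    """
    X = np.asarray(X, dtype=float)
    n_channels = X.shape[1]
    if not 1 <= k <= n_channels:
        raise ValueError("k must be in [1, n_channels]")
    design = build_toeplitz(target_onsets, X.shape[0], epoch_len)
    A1 = estimate_erp(X, design)
    sigma1, sigma_x = _covariances(X, design, A1)

    # guard: total covariance must be PD for the generalized eigenproblem
    try:
        scipy.linalg.cholesky(sigma_x)
    except scipy.linalg.LinAlgError:
        eps = 1e-10 * np.trace(sigma_x) / n_channels
        logger.warning("fit_xdawn: signal covariance not PD, ridge eps=%.3e", eps)
        sigma_x = sigma_x + eps * np.eye(n_channels)

    eigvals, eigvecs = scipy.linalg.eigh(sigma1, sigma_x)
    order = np.argsort(eigvals)[::-1][:k]
    U = eigvecs[:, order]
    vals = eigvals[order]
    # determinism: orient each filter so its largest-magnitude entry is positive
    for j in range(U.shape[1]):
        i = np.argmax(np.abs(U[:, j]))
        if U[i, j] < 0:
            U[:, j] = -U[:, j]
    return XdawnModel(A1_hat=A1, U=U, ssnr_values=vals, epoch_len=epoch_len)


def apply_xdawn(model: XdawnModel, epochs: EpochSet) -> np.ndarray:
    """Project epochs through the spatial filters and flatten.

    Returns (n_epochs, k * epoch_samples): 186 features for 3 components of
    62 samples.
    """
    data = epochs.epochs
    if data.shape[1] != model.U.shape[0]:
        raise ValueError(
            f"epoch channel count {data.shape[1]} does not match "
            f"model channels {model.U.shape[0]}"
        )
    # (n, ch, t) -> (n, k, t)
    virt = np.einsum("ck,nct->nkt", model.U, data)
    return virt.reshape(len(data), -1)
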