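"""Binary P300 epoch detectors: Fisher LDA, kernel SVM and a small MLP.

All three are implemented from first principles (no external ML library):

* **LDA** maximizes the Fisher criterion J(v) = vᵀS_b v / vᵀS_w v, the ratio
  of between-class to within-class scatter along the projection v; the
  maximizer is the leading generalized eigenvector of (S_b, S_w).
* **SVM** solves the soft-margin dual with an inhomogeneous cubic polynomial
  kernel K(x, y) = (x·y + 1)³ using a max-violating-pair SMO loop
  (two-variable analytic updates until the KKT gap closes).
* **MLP** is a two-hidden-layer tanh network with a logistic output, trained
  by full-batch gradient descent on the cross-entropy loss with exact
  backpropagated gradients.

Scores are real-valued; ``predict_label`` thresholds at 0 (LDA/SVM signed
distance) or 0.5 (MLP posterior).  Positive label = Target (P300 present).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.special

__all__ = [
    "LDAModel", "SVMModel", "MLPModel", "TrainReport",
    "fit_lda", "fit_svm", "fit_mlp",
    "predict_score", "predict_label", "cross_validate",
    "fisher_criterion", "poly3_kernel",
]

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# LDA
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LDAModel:
    V_EEG: np.ndarray          # discriminant direction
    bias: float                # midpoint of projected class means
    class_means: np.ndarray    # (2, d): [nontarget, target]
    S_b: np.ndarray
    S_w: np.ndarray
    J: float                   # Fisher criterion at V_EEG


def _scatters(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    m0 = X[~y].mean(axis=0)
    m1 = X[y].mean(axis=0)
    d = m1 - m0
    S_b = np.outer(d, d)
    X0 = X[~y] - m0
    X1 = X[y] - m1
    S_w = X0.T @ X0 + X1.T @ X1
    return np.stack([m0, m1]), S_b, S_w


def fisher_criterion(v: np.ndarray, S_b: np.ndarray, S_w: np.ndarray) -> float:
    """J(v) = vᵀS_b v / vᵀS_w v."""
    v = np.asarray(v, dtype=float)
    return float(v @ S_b @ v) / float(v @ S_w @ v)


def fit_lda(X: np.ndarray, y: np.ndarray, shrinkage: float = 1e-6) -> LDAModel:
    """Fisher discriminant with a small shrinkage ridge on S_w.

    ``shrinkage`` scales trace(S_w)/d, guarding against ill-conditioning when
    the feature dimension approaches the epoch count.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    means, S_b, S_w = _scatters(X, y)
    d = X.shape[1]
    S_w_reg = S_w + shrinkage * np.trace(S_w) / d * np.eye(d)
    eigvals, eigvecs = scipy.linalg.eigh(S_b, S_w_reg)
    v = eigvecs[:, -1]
    if v @ (means[1] - means[0]) < 0:   # orient: target projects positive
        v = -v
    bias = float(v @ (means[0] + means[1]) / 2)
    return LDAModel(V_EEG=v, bias=bias, class_means=means, S_b=S_b, S_w=S_w_reg,
                    J=fisher_criterion(v, S_b, S_w_reg))


# --------------------------------------------------------------------------
# SVM
# --------------------------------------------------------------------------

def poly3_kernel(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Inhomogeneous cubic kernel (A Bᵀ + 1)³."""
    return (np.asarray(A, float) @ np.asarray(B, float).T + 1.0) ** 3


@dataclass(frozen=True)
class SVMModel:
    support_vectors: np.ndarray
    support_labels: np.ndarray    # in {-1, +1}
    alphas: np.ndarray            # dual coefficients of the support vectors
    b: float
    C: float
    class_weight: dict | None
    kkt_gap: float


def fit_svm(X: np.ndarray, y: np.ndarray, C: float = 1.0,
            class_weight: "str | None" = "balanced",
            tol: float = 1e-4, max_iter: int = 200_000) -> SVMModel:
    """Soft-margin dual SVM with the cubic polynomial kernel.

    Solves  min ½αᵀQα − Σα  s.t. 0 ≤ α_i ≤ C_i, Σα_iL_i = 0  (Q = LLᵀ∘K) by
    repeatedly updating the maximal violating pair; stops when the KKT gap
    m(α) − M(α) falls below ``tol``.

    ``class_weight='balanced'`` scales each class's box constraint inversely
    to its frequency, compensating the 1:5 Target/No-Target imbalance of the
    speller paradigm.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    uniq = set(np.unique(y).tolist())
    if uniq <= {False, True} or uniq <= {0, 1}:
        L = np.where(y.astype(bool), 1.0, -1.0)
    elif uniq <= {-1, 1}:
        L = y.astype(float)
    else:
        raise ValueError(f"labels must be boolean, {{0,1}} or {{-1,1}}, got {uniq}")
    if len(np.unique(L)) < 2:
        raise ValueError("both classes must be present")
    n = len(X)
    if class_weight == "balanced":
        n_pos, n_neg = int((L > 0).sum()), int((L < 0).sum())
        Ci = np.where(L > 0, C * n / (2 * n_pos), C * n / (2 * n_neg))
        cw = {"+1": C * n / (2 * n_pos), "-1": C * n / (2 * n_neg)}
    else:
        Ci = np.full(n, C)
        cw = None

    K = poly3_kernel(X, X)
    Q = (L[:, None] * L[None, :]) * K
    alpha = np.zeros(n)
    grad = -np.ones(n)          # Qα − 1 at α = 0

    gap = np.inf
    for it in range(max_iter):
        # working-set selection: maximal violating pair (Keerthi/LIBSVM WSS1)
        up = ((L > 0) & (alpha < Ci - 1e-12)) | ((L < 0) & (alpha > 1e-12))
        low = ((L < 0) & (alpha < Ci - 1e-12)) | ((L > 0) & (alpha > 1e-12))
        if not up.any() or not low.any():
            gap = 0.0
            break
        neg_Lg = -L * grad
        i = np.flatnonzero(up)[np.argmax(neg_Lg[up])]
        j = np.flatnonzero(low)[np.argmin(neg_Lg[low])]
        gap = neg_Lg[i] - neg_Lg[j]
        if gap < tol:
            break
        quad = max(K[i, i] + K[j, j] - 2 * K[i, j], 1e-12)
        t = gap / quad
        # feasibility clipping: α_i moves by +L_i t, α_j by −L_j t
        if L[i] > 0:
            t = min(t, Ci[i] - alpha[i])
        else:
            t = min(t, alpha[i])
        if L[j] > 0:
            t = min(t, alpha[j])
        else:
            t = min(t, Ci[j] - alpha[j])
        if t <= 0:
            break
        alpha[i] += L[i] * t
        alpha[j] -= L[j] * t
        grad += Q[:, i] * (L[i] * t) - Q[:, j] * (L[j] * t)
    else:
        raise RuntimeError(
            f"SMO did not converge in {max_iter} iterations "
            f"(KKT gap {gap:.3e}, n={n}, C={C})"
        )
    if gap >= tol and gap != np.inf:
        # loop exited via break on t<=0 with gap unresolved
        raise RuntimeError(f"SMO stalled with KKT gap {gap:.3e} (n={n}, C={C})")

    # bias from the free/violating band midpoint
    neg_Lg = -L * grad
    up = ((L > 0) & (alpha < Ci - 1e-12)) | ((L < 0) & (alpha > 1e-12))
    low = ((L < 0) & (alpha < Ci - 1e-12)) | ((L > 0) & (alpha > 1e-12))
    hi = neg_Lg[up].max() if up.any() else 0.0
    lo = neg_Lg[low].min() if low.any() else 0.0
    b = (hi + lo) / 2

    sv = alpha > 1e-10
    return SVMModel(support_vectors=X[sv], support_labels=L[sv],
                    alphas=alpha[sv], b=float(b), C=C, class_weight=cw,
                    kkt_gap=float(max(gap, 0.0)))


# --------------------------------------------------------------------------
# MLP
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MLPModel:
    weights: tuple[np.ndarray, ...]
    biases: tuple[np.ndarray, ...]
    x_mean: np.ndarray
    x_sd: np.ndarray
    loss_trace: np.ndarray


def _mlp_init(n_in: int, hidden: tuple[int, int], rng: np.random.Generator):
    sizes = [n_in, *hidden, 1]
    Ws = [rng.standard_normal((sizes[i], sizes[i + 1])) / np.sqrt(sizes[i])
          for i in range(len(sizes) - 1)]
    bs = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]
    return Ws, bs


def _mlp_forward(Ws, bs, X):
    acts = [X]
    h = X
    for W, b in zip(Ws[:-1], bs[:-1]):
        h = np.tanh(h @ W + b)
        acts.append(h)
    z = h @ Ws[-1] + bs[-1]
    p = scipy.special.expit(z)
    return acts, p.ravel()


def mlp_loss_and_grad(Ws, bs, X, y):
    """Mean cross-entropy and its exact gradients (backpropagation)."""
    n = len(X)
    acts, p = _mlp_forward(Ws, bs, X)
    eps = 1e-12
    loss = -np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
    delta = ((p - y) / n)[:, None]                   # dL/dz at the output
    gWs, gbs = [], []
    for layer in range(len(Ws) - 1, -1, -1):
        gWs.append(acts[layer].T @ delta)
        gbs.append(delta.sum(axis=0))
        if layer > 0:
            delta = (delta @ Ws[layer].T) * (1 - acts[layer] ** 2)
    return loss, gWs[::-1], gbs[::-1]


def fit_mlp(X: np.ndarray, y: np.ndarray, hidden: tuple[int, int] = (32, 16),
            lr: float = 0.5, n_iter: int = 500, seed: int = 0) -> MLPModel:
    """Two-hidden-layer tanh network trained by full-batch gradient descent.

    Inputs are standardized internally (stored in the model) so the default
    learning rate behaves across feature scales.  Raises if the loss diverges.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if not np.all(np.isfinite(X)):
        raise ValueError("inputs must be finite")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    rng = np.random.default_rng(seed)
    Ws, bs = _mlp_init(X.shape[1], hidden, rng)
    trace = np.empty(n_iter)
    for it in range(n_iter):
        loss, gWs, gbs = mlp_loss_and_grad(Ws, bs, Xs, y)
        # tanh saturation keeps the loss finite even when weights explode,
        # so a runaway loss (well above its starting point) also counts
        if not np.isfinite(loss) or (it > 0 and loss > 10 * max(trace[0], 1.0)):
            raise RuntimeError(
                f"MLP training diverged at iteration {it} (loss {loss:.3g}); "
                f"reduce lr={lr}"
            )
        trace[it] = loss
        Ws = [W - lr * g for W, g in zip(Ws, gWs)]
        bs = [b - lr * g for b, g in zip(bs, gbs)]
    return MLPModel(weights=tuple(Ws), biases=tuple(bs), x_mean=mu, x_sd=sd,
                    loss_trace=trace)


# --------------------------------------------------------------------------
# prediction and cross-validation
# --------------------------------------------------------------------------

def predict_score(model, X: np.ndarray) -> np.ndarray:
    """Real-valued P300 score per epoch (higher = more target-like)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (n_epochs, n_features)")
    if isinstance(model, LDAModel):
        if X.shape[1] != len(model.V_EEG):
            raise ValueError("feature dimension does not match training")
        return X @ model.V_EEG - model.bias
    if isinstance(model, SVMModel):
        if X.shape[1] != model.support_vectors.shape[1]:
            raise ValueError("feature dimension does not match training")
        K = poly3_kernel(X, model.support_vectors)
        return K @ (model.alphas * model.support_labels) + model.b
    if isinstance(model, MLPModel):
        if X.shape[1] != len(model.x_mean):
            raise ValueError("feature dimension does not match training")
        Xs = (X - model.x_mean) / model.x_sd
        _, p = _mlp_forward(list(model.weights), list(model.biases), Xs)
        return p
    raise TypeError(f"unknown model type {type(model).__name__}")


def predict_label(model, X: np.ndarray) -> np.ndarray:
    """Boolean Target prediction: score > 0 (LDA/SVM) or posterior > 0.5 (MLP)."""
    s = predict_score(model, X)
    thr = 0.5 if isinstance(model, MLPModel) else 0.0
    return s > thr


@dataclass(frozen=True)
class TrainReport:
    """Per-fold held-out accuracies with mean ± sample (n−1) std."""

    fold_accuracies: np.ndarray

    @property
    def mean(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def std(self) -> float:
        return float(np.std(self.fold_accuracies, ddof=1))

    def __str__(self) -> str:
        return f"{100 * self.mean:.2f} ± {100 * self.std:.2f} %"


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Seeded stratified partition: fold id per sample, each class spread
    round-robin over folds after shuffling."""
    folds = np.empty(len(y), dtype=int)
    for cls in (False, True):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        folds[idx] = np.arange(len(idx)) % k
    return folds


def cross_validate(X: np.ndarray, y: np.ndarray, fit_fn, k: int = 5,
                   seed: int = 0, max_redraws: int = 10) -> TrainReport:
    """k-fold stratified cross-validation of a detector.

    ``fit_fn(X_train, y_train) -> model`` is any of the fitters above
    (partially applied with its hyperparameters).  Folds covering a single
    class are redrawn with a logged warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=bool)
    if len(X) < k:
        raise ValueError("need at least k samples")
    rng = np.random.default_rng(seed)
    for attempt in range(max_redraws):
        folds = _stratified_folds(y, k, rng)
        ok = all(len(np.unique(y[folds == f])) == 2 for f in range(k))
        if ok:
            break
        logger.warning("cross_validate: single-class fold, redrawing partition")
    else:
        raise ValueError("could not draw a partition with both classes per fold")

    accs = np.empty(k)
    for f in range(k):
        test = folds == f
        model = fit_fn(X[~test], y[~test])
        accs[f] = np.mean(predict_label(model, X[test]) == y[test])
    return TrainReport(fold_accuracies=accs)
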