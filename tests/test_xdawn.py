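"""xDAWN: Toeplitz design, ERP least squares, SSNR eigenproblem, projection."""

import numpy as np
import pytest
import scipy.linalg

from p300bci.preprocess import EpochSet
from p300bci.paradigm import FlashEvent
from p300bci.xdawn import (XdawnModel, apply_xdawn, build_toeplitz,
                           estimate_erp, fit_xdawn, ssnr)


def _toy_signal(rng, n_samples=400, n_channels=4, n_events=12, epoch_len=20,
                noise=0.1):
    """Known ERP replicated at random non-colliding onsets plus white noise."""
    a1 = np.sin(np.linspace(0, np.pi, epoch_len))          # temporal
    w1 = np.array([0.8, 0.5, -0.2, 0.1])[:n_channels]      # spatial
    w1 = w1 / np.linalg.norm(w1)
    onsets = rng.choice(np.arange(0, n_samples - epoch_len, epoch_len),
                        size=n_events, replace=False)
    A1 = np.outer(a1, w1)
    D = build_toeplitz(onsets, n_samples, epoch_len)
    X = D.matrix @ A1 + noise * rng.standard_normal((n_samples, n_channels))
    return X, onsets, A1, w1


class TestBuildToeplitz:
    def test_single_event_diagonal(self):
        D = build_toeplitz([0], n_samples=5, epoch_len=3).matrix.toarray()
        assert D[0, 0] == D[1, 1] == D[2, 2] == 1
        assert D.sum() == 3

    def test_disjoint_events_column_sums(self):
        D = build_toeplitz([0, 10], n_samples=20, epoch_len=3).matrix
        np.testing.assert_array_equal(np.asarray(D.sum(axis=0)).ravel(),
                                      [2, 2, 2])

    def test_overlapping_events_superpose(self):
        # direct-construction oracle: D @ a equals the summed shifted copies
        a = np.arange(1.0, 5.0)
        D = build_toeplitz([0, 2], n_samples=8, epoch_len=4).matrix
        expect = np.zeros(8)
        expect[0:4] += a
        expect[2:6] += a
        np.testing.assert_allclose(D @ a, expect)
        assert (np.asarray(D.sum(axis=1)).ravel() > 1).any()

    def test_out_of_range_onset_rejected(self):
        with pytest.raises(ValueError):
            build_toeplitz([100], n_samples=50, epoch_len=3)


class TestEstimateErp:
    def test_exact_recovery_noise_free(self):
        rng = np.random.default_rng(0)
        X, onsets, A1, _ = _toy_signal(rng, noise=0.0)
        D = build_toeplitz(onsets, X.shape[0], A1.shape[0])
        np.testing.assert_allclose(estimate_erp(X, D), A1, atol=1e-10)

    def test_error_decreases_with_event_count(self):
        # Monte-Carlo oracle: more events -> better least-squares estimate
        errs = []
        for n_events, n_samples in ((6, 400), (18, 800)):
            rng = np.random.default_rng(1)
            X, onsets, A1, _ = _toy_signal(rng, n_samples=n_samples,
                                           n_events=n_events, noise=0.5)
            D = build_toeplitz(onsets, X.shape[0], A1.shape[0])
            errs.append(np.linalg.norm(estimate_erp(X, D) - A1))
        assert errs[1] < errs[0]

    def test_zero_signal_estimate_near_zero(self):
        rng = np.random.default_rng(2)
        n, el = 2000, 20
        onsets = np.arange(0, n - el, 2 * el)
        D = build_toeplitz(onsets, n, el)
        X = 0.3 * rng.standard_normal((n, 3))
        A = estimate_erp(X, D)
        assert np.abs(A).max() < 5 * 0.3 / np.sqrt(len(onsets))

    def test_rank_deficiency_names_lags(self):
        D = build_toeplitz([8], n_samples=10, epoch_len=5)  # lags 2.. truncated
        with pytest.raises(np.linalg.LinAlgError, match="lags"):
            estimate_erp(np.zeros((10, 2)), D)


class TestFitXdawn:
    def test_matches_dense_eigendecomposition_oracle(self):
        """Tiny instance: the fitted filters must agree with a brute-force
        dense solve of inv(Σx) Σ1 to 1e-8."""
        rng = np.random.default_rng(3)
        X, onsets, A1, _ = _toy_signal(rng, n_samples=200, n_events=8,
                                       epoch_len=10, noise=0.3)
        model = fit_xdawn(X, onsets, epoch_len=10, k=4)

        D = build_toeplitz(onsets, X.shape[0], 10)
        A_hat = estimate_erp(X, D)
        evoked = D.matrix @ A_hat
        s1 = evoked.T @ evoked / len(X)
        sx = X.T @ X / len(X)
        vals = np.sort(np.linalg.eigvals(np.linalg.inv(sx) @ s1).real)[::-1]
        np.testing.assert_allclose(model.ssnr_values, vals, atol=1e-8)
        # eigen residual: Σ1 u = λ Σx u
        for j in range(4):
            u, lam = model.U[:, j], model.ssnr_values[j]
            assert np.linalg.norm(s1 @ u - lam * sx @ u) < 1e-8

    def test_top_filter_beats_random_filters(self):
        rng = np.random.default_rng(4)
        X, onsets, A1, _ = _toy_signal(rng, noise=0.3)
        model = fit_xdawn(X, onsets, epoch_len=A1.shape[0], k=3)
        D = build_toeplitz(onsets, X.shape[0], A1.shape[0])
        evoked = D.matrix @ estimate_erp(X, D)
        s1 = evoked.T @ evoked / len(X)
        sx = X.T @ X / len(X)
        best = ssnr(model.U[:, 0], s1, sx)
        for _ in range(1000):
            v = rng.standard_normal(X.shape[1])
            assert best >= ssnr(v / np.linalg.norm(v), s1, sx) - 1e-12

    def test_stationarity_under_small_perturbations(self):
        rng = np.random.default_rng(5)
        X, onsets, A1, _ = _toy_signal(rng, noise=0.3)
        model = fit_xdawn(X, onsets, epoch_len=A1.shape[0], k=1)
        D = build_toeplitz(onsets, X.shape[0], A1.shape[0])
        evoked = D.matrix @ estimate_erp(X, D)
        s1 = evoked.T @ evoked / len(X)
        sx = X.T @ X / len(X)
        q0 = ssnr(model.U[:, 0], s1, sx)
        for _ in range(50):
            d = rng.standard_normal(X.shape[1]) * 1e-4
            assert ssnr(model.U[:, 0] + d, s1, sx) <= q0 * (1 + 1e-6)

    def test_ssnr_invariant_to_orthonormal_channel_rotation(self):
        rng = np.random.default_rng(6)
        X, onsets, A1, _ = _toy_signal(rng, noise=0.3)
        R = scipy.linalg.qr(rng.standard_normal((4, 4)))[0]
        m1 = fit_xdawn(X, onsets, epoch_len=A1.shape[0], k=3)
        m2 = fit_xdawn(X @ R, onsets, epoch_len=A1.shape[0], k=3)
        np.testing.assert_allclose(m1.ssnr_values, m2.ssnr_values, atol=1e-10)

    def test_recovers_planted_spatial_pattern(self, train_session):
        """Default-condition session: the leading filter's forward model
        (Σx u) matches the planted pattern with cosine >= 0.95."""
        from p300bci.pipeline import preprocess_session
        from p300bci.xdawn import fit_xdawn as fx
        rec, _, truth = train_session
        filt, eps = preprocess_session(rec)
        onsets = [e.onset_sample for e in filt.markers.events if e.is_target]
        model = fx(filt.data.T, onsets, eps.epochs.shape[2], k=3)
        sx = filt.data @ filt.data.T / filt.n_samples
        fwd = sx @ model.U[:, 0]
        cos = abs(fwd @ truth.spatial_pattern) / np.linalg.norm(fwd)
        assert cos >= 0.95


class TestApplyXdawn:
    def _epochs(self, rng, n=5, ch=4, t=10):
        events = tuple(
            FlashEvent(onset_s=i * 1.0, onset_sample=i, stim_id="R0",
                       is_target=False, char_index=0, repetition=i)
            for i in range(n)
        )
        return EpochSet(epochs=rng.standard_normal((n, ch, t)),
                        labels=np.zeros(n, bool), meta=events, fs_epoch=125.0)

    def test_identity_filters_select_channels(self):
        rng = np.random.default_rng(7)
        eps = self._epochs(rng)
        U = np.eye(4)[:, :2]
        model = XdawnModel(A1_hat=np.zeros((10, 4)), U=U,
                           ssnr_values=np.array([1.0, 0.5]), epoch_len=10)
        feats = apply_xdawn(model, eps)
        np.testing.assert_allclose(feats, eps.epochs[:, :2, :].reshape(5, -1))

    def test_linearity_in_epoch_scale(self):
        rng = np.random.default_rng(8)
        eps = self._epochs(rng)
        U = rng.standard_normal((4, 3))
        model = XdawnModel(A1_hat=np.zeros((10, 4)), U=U,
                           ssnr_values=np.ones(3), epoch_len=10)
        f1 = apply_xdawn(model, eps)
        scaled = EpochSet(epochs=3.0 * eps.epochs, labels=eps.labels,
                          meta=eps.meta, fs_epoch=eps.fs_epoch)
        np.testing.assert_allclose(apply_xdawn(model, scaled), 3.0 * f1)

    def test_feature_dimension_and_shape_mismatch(self, train_session):
        from p300bci.pipeline import fit_session  # noqa: F401
        rng = np.random.default_rng(9)
        eps = self._epochs(rng, ch=6)
        model = XdawnModel(A1_hat=np.zeros((10, 4)), U=np.eye(4)[:, :3],
                           ssnr_values=np.ones(3), epoch_len=10)
        with pytest.raises(ValueError, match="channel count"):
            apply_xdawn(model, eps)

    def test_planted_signal_energy_concentrates_in_component_0(self, train_session,
                                                               trained_lda):
        from p300bci.pipeline import preprocess_session
        rec, _, _ = train_session
        xd = trained_lda[0]
        _, eps = preprocess_session(rec)
        avg = eps.epochs[eps.labels].mean(axis=0, keepdims=True)
        avg_set = EpochSet(epochs=avg, labels=np.array([True]),
                           meta=(eps.meta[0],), fs_epoch=eps.fs_epoch)
        feats = apply_xdawn(xd, avg_set).reshape(3, -1)
        norms = np.linalg.norm(feats, axis=1)
        assert norms[0] > norms[1] and norms[0] > norms[2]
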