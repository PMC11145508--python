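import numpy as np
import pytest

from semgclean import (
    IcaConfig,
    NegentropyFastICA,
    Whitener,
    amari_index,
    center,
    extract_components,
    fastica_fixed_point_update,
    generate_ecg,
    generate_semg,
    gradient_refine,
    pca_whiten,
    reconstruct_channels,
)
from semgclean.ica import E_G_GAUSS, _G, _negentropy_surrogate

from conftest import best_match_abs_corr


def _two_source_whitened(n=20000, seed=0):
    """Whitened mixture of a uniform and a Laplacian source."""
    rng = np.random.default_rng(seed)
    S = np.vstack([rng.uniform(-1, 1, n), rng.laplace(size=n)])
    A = np.array([[1.0, 0.6], [0.4, 1.0]])
    Xc, _ = center(A @ S)
    Z, wm = pca_whiten(Xc)
    return Z, wm, S, A


class TestCenter:
    def test_arithmetic_example(self):
        Xc, mu = center(np.array([[1.0, 2.0, 3.0]]))
        np.testing.assert_array_equal(Xc, [[-1.0, 0.0, 1.0]])
        np.testing.assert_array_equal(mu, [2.0])

    def test_idempotent_on_zero_mean(self, rng):
        X = rng.standard_normal((3, 100))
        X -= X.mean(axis=1, keepdims=True)
        Xc, mu = center(X)
        np.testing.assert_allclose(Xc, X, atol=1e-12)
        assert np.all(np.abs(mu) < 1e-12)

    def test_round_trip(self, rng):
        for seed in range(20):
            X = np.random.default_rng(seed).standard_normal((4, 50)) * 7 + 3
            Xc, mu = center(X)
            np.testing.assert_allclose(Xc + mu[:, None], X, rtol=0, atol=1e-13)
            assert np.all(np.abs(Xc.mean(axis=1)) <= 1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            center(np.empty((2, 0)))


class TestWhitening:
    def _cov(self, Z):
        return Z @ Z.T / Z.shape[1]

    def test_identity_covariance_on_seeded_fixtures(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            A = rng.standard_normal((4, 4))
            X = A @ rng.standard_normal((4, 3000))
            Xc, _ = center(X)
            Z, _ = pca_whiten(Xc)
            err = np.max(np.abs(self._cov(Z) - np.eye(Z.shape[0])))
            assert err <= 1e-8

    def test_diagonal_covariance_closed_form(self, rng):
        # rows with sample variances 2 and 0.5: whitening rescales by
        # 1/sqrt(2) and sqrt(2) up to permutation/sign
        n = 4000
        X = np.vstack([rng.standard_normal(n), rng.standard_normal(n)])
        X -= X.mean(axis=1, keepdims=True)
        X[1] -= (X[1] @ X[0]) / (X[0] @ X[0]) * X[0]  # exactly uncorrelated rows
        X -= X.mean(axis=1, keepdims=True)
        X[0] *= np.sqrt(2.0) / X[0].std()
        X[1] *= np.sqrt(0.5) / X[1].std()
        Z, model = pca_whiten(X)
        np.testing.assert_allclose(sorted(model.eigvals), [0.5, 2.0], atol=1e-9)
        P = np.abs(model.whiten)
        np.testing.assert_allclose(
            sorted(P.ravel())[-2:], sorted([1 / np.sqrt(2), np.sqrt(2)]), atol=1e-9
        )
        np.testing.assert_allclose(self._cov(Z), np.eye(2), atol=1e-8)

    def test_already_white_input(self, rng):
        X = rng.standard_normal((3, 200000))
        Xc, _ = center(X)
        Z, model = pca_whiten(Xc)
        np.testing.assert_allclose(self._cov(Z), np.eye(3), atol=1e-8)
        # whitening map of near-identity covariance is near-orthonormal
        WtW = model.whiten @ model.whiten.T
        assert np.max(np.abs(WtW - np.eye(3))) < 0.05

    def test_rank_one_input_keeps_one_dimension(self, rng):
        base = rng.standard_normal(1000)
        X = np.vstack([base, 2 * base])
        X -= X.mean(axis=1, keepdims=True)
        _, model = pca_whiten(X, var_floor=1e-6)
        assert model.kept_dims == 1

    def test_dewhiten_inverts_whiten_on_kept_subspace(self, rng):
        X = rng.standard_normal((3, 5000))
        Xc, _ = center(X)
        _, m = pca_whiten(Xc)
        np.testing.assert_allclose(m.whiten @ m.dewhiten, np.eye(3), atol=1e-8)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            pca_whiten(np.zeros((2, 100)))

    def test_whitener_transformer_round_trip(self, rng):
        X = rng.standard_normal((500, 3)) @ rng.standard_normal((3, 3)) + 5
        w = Whitener().fit(X)
        Z = w.transform(X)
        np.testing.assert_allclose(Z.T @ Z / len(Z), np.eye(3), atol=1e-8)
        np.testing.assert_allclose(w.inverse_transform(Z), X, atol=1e-8)


class TestFixedPointUpdate:
    def test_output_is_unit_norm(self, rng):
        Z, *_ = _two_source_whitened(2000, 1)
        for _ in range(10):
            w = rng.standard_normal(2)
            w /= np.linalg.norm(w)
            assert np.linalg.norm(
                fastica_fixed_point_update(w, Z)
            ) == pytest.approx(1.0, abs=1e-12)

    def test_converged_direction_is_a_fixed_point(self):
        Z, *_ = _two_source_whitened(20000, 2)
        w = np.array([1.0, 0.0])
        for _ in range(200):
            w_new = fastica_fixed_point_update(w, Z)
            if abs(abs(w_new @ w)) >= 1 - 1e-12:
                break
            w = w_new
        once_more = fastica_fixed_point_update(w_new, Z)
        assert abs(abs(once_more @ w_new)) >= 1 - 1e-6

    def test_many_starts_converge_to_source_directions(self):
        Z, wm, S, A = _two_source_whitened(20000, 3)
        rng = np.random.default_rng(99)
        for _ in range(50):
            w = rng.standard_normal(2)
            w /= np.linalg.norm(w)
            for _i in range(200):
                w_new = fastica_fixed_point_update(w, Z)
                if abs(abs(w_new @ w)) >= 1 - 1e-9:
                    break
                w = w_new
            y = w_new @ Z
            corr = max(
                abs(np.corrcoef(y, S[0])[0, 1]), abs(np.corrcoef(y, S[1])[0, 1])
            )
            assert corr >= 0.95


class TestGradientRefine:
    def test_zero_steps_is_noop(self, rng):
        Z, *_ = _two_source_whitened(2000, 4)
        w = rng.standard_normal(2)
        w /= np.linalg.norm(w)
        np.testing.assert_array_equal(gradient_refine(w, Z, steps=0), w)

    def test_surrogate_never_decreases_across_steps(self):
        Z, *_ = _two_source_whitened(20000, 5)
        rng = np.random.default_rng(7)
        for _ in range(10):
            w = rng.standard_normal(2)
            w /= np.linalg.norm(w)
            j_prev = _negentropy_surrogate(w, Z)
            for _s in range(5):
                w = gradient_refine(w, Z, steps=1)
                j = _negentropy_surrogate(w, Z)
                assert j >= j_prev - 1e-15
                j_prev = j

    def test_refined_starts_speed_up_fixed_point(self):
        # paired comparison: mean iterations with refinement <= without
        iters = {0: [], 5: []}
        for seed in range(50):
            Z, *_ = _two_source_whitened(5000, seed + 100)
            for steps in iters:
                cfg = IcaConfig(grad_refine_steps=steps, seed=seed)
                um = extract_components(Z, cfg)
                iters[steps].append(sum(um.n_iter))
        assert np.mean(iters[5]) <= np.mean(iters[0])

    def test_gaussian_baseline_by_quadrature(self):
        # E[log cosh v] for v ~ N(0,1): cross-check against dense sampling
        v = np.random.default_rng(0).standard_normal(2_000_000)
        assert E_G_GAUSS == pytest.approx(float(np.mean(_G(v))), abs=2e-3)


class TestExtractComponents:
    def test_single_source_recovered_up_to_sign(self):
        rng = np.random.default_rng(6)
        s = rng.laplace(size=20000)
        Xc, _ = center(np.vstack([s]))
        Z, wm = pca_whiten(Xc)
        um = extract_components(Z, IcaConfig(n_components=1, seed=0))
        assert abs(np.corrcoef(um.sources[0], s)[0, 1]) >= 0.999

    def test_three_source_separation_with_ground_truth(self):
        n, fs = 20000, 2000.0
        ecg = generate_ecg(n / fs, fs, 72.0, rr_jitter=0.02, seed=11).samples
        semg = generate_semg(n / fs, fs, passband=(20, 150), seed=111).samples
        uni = np.random.default_rng(211).uniform(-1, 1, n)
        S = np.vstack([ecg, semg, uni])
        A = np.array([[1.0, 0.5, 0.3], [0.4, 1.0, 0.6], [0.3, 0.7, 1.0]])
        Xc, _ = center(A @ S)
        Z, wm = pca_whiten(Xc)
        um = extract_components(Z, IcaConfig(seed=11), whitening=wm)
        best, _ = best_match_abs_corr(um.sources, S)
        assert np.all(best >= 0.95)
        assert amari_index(um.W @ (wm.whiten @ A)) <= 0.1

    def test_unmixing_rows_orthonormal(self):
        Z, *_ = _two_source_whitened(10000, 8)
        um = extract_components(Z, IcaConfig(seed=3))
        np.testing.assert_allclose(um.W @ um.W.T, np.eye(2), atol=1e-6)

    def test_deterministic_under_seed(self):
        Z, *_ = _two_source_whitened(5000, 9)
        a = extract_components(Z, IcaConfig(seed=42))
        b = extract_components(Z, IcaConfig(seed=42))
        np.testing.assert_array_equal(a.W, b.W)

    def test_sources_equal_w_times_z(self):
        Z, *_ = _two_source_whitened(5000, 10)
        um = extract_components(Z, IcaConfig(seed=1))
        np.testing.assert_array_equal(um.sources, um.W @ Z)

    def test_channel_permutation_equivariance(self):
        n = 10000
        rng = np.random.default_rng(13)
        S = np.vstack([rng.uniform(-1, 1, n), rng.laplace(size=n),
                       rng.uniform(-2, 2, n) ** 3])
        A = np.array([[1.0, 0.5, 0.3], [0.4, 1.0, 0.6], [0.3, 0.7, 1.0]])
        X = A @ S

        def scores(X):
            Xc, _ = center(X)
            Z, _ = pca_whiten(Xc)
            um = extract_components(Z, IcaConfig(seed=5))
            best, _ = best_match_abs_corr(um.sources, S)
            return np.sort(best)

        perm = [2, 0, 1]
        s1, s2 = scores(X), scores(X[perm])
        np.testing.assert_allclose(s1, s2, atol=5e-3)

    def test_cross_check_against_reference_fastica(self):
        # independent implementation agreement on recovered sources
        from sklearn.decomposition import FastICA

        n = 20000
        rng = np.random.default_rng(21)
        S = np.vstack([rng.uniform(-1, 1, n), rng.laplace(size=n)])
        A = np.array([[1.0, 0.6], [0.4, 1.0]])
        X = A @ S
        Xc, _ = center(X)
        Z, wm = pca_whiten(Xc)
        um = extract_components(Z, IcaConfig(seed=2), whitening=wm)
        ref = FastICA(
            n_components=2, fun="logcosh", whiten="unit-variance", random_state=0
        ).fit_transform(X.T).T
        _, cross = best_match_abs_corr(um.sources, ref)
        # each reference component matched by exactly one of ours
        assert np.all(np.sort(cross.max(axis=0)) >= 0.999)


class TestReconstruction:
    def _fitted(self, seed=0):
        n = 8000
        rng = np.random.default_rng(seed)
        S = np.vstack([rng.uniform(-1, 1, n), rng.laplace(size=n),
                       rng.standard_normal(n)])
        A = np.array([[1.0, 0.5, 0.3], [0.4, 1.0, 0.6], [0.3, 0.7, 1.0]])
        X = A @ S + 2.0
        Xc, mu = center(X)
        Z, wm = pca_whiten(Xc, mean=mu)
        um = extract_components(Z, IcaConfig(seed=seed), whitening=wm)
        return X, S, A, wm, um

    def test_keep_all_round_trip(self):
        X, _, _, wm, um = self._fitted()
        Xh = reconstruct_channels(um, np.ones(3, bool), wm)
        assert np.linalg.norm(Xh - X) / np.linalg.norm(X) <= 1e-6

    def test_keep_none_returns_mean(self):
        X, _, _, wm, um = self._fitted()
        Xh = reconstruct_channels(um, np.zeros(3, bool), wm)
        np.testing.assert_allclose(Xh, np.tile(wm.mean[:, None], (1, X.shape[1])))

    def test_dropping_matched_ecg_component_improves_channel(self):
        n, fs = 10000, 1000.0
        ecg = generate_ecg(n / fs, fs, 72.0, seed=31).samples * 2
        semg = generate_semg(n / fs, fs, seed=32).samples
        noise = np.random.default_rng(33).standard_normal(n) * 0.3
        S = np.vstack([semg, ecg, noise])
        A = np.array([[1.0, 0.9, 0.3], [0.4, 1.0, 0.6], [0.3, 0.7, 1.0]])
        X = A @ S
        Xc, mu = center(X)
        Z, wm = pca_whiten(Xc, mean=mu)
        um = extract_components(Z, IcaConfig(seed=34), whitening=wm)
        corr_ecg = [abs(np.corrcoef(s, ecg)[0, 1]) for s in um.sources]
        keep = np.ones(3, bool)
        keep[int(np.argmax(corr_ecg))] = False
        Xh = reconstruct_channels(um, keep, wm)
        ref = A[0, 0] * semg + A[0, 2] * noise  # channel 1 without ECG
        c_clean = np.corrcoef(Xh[0], ref)[0, 1]
        c_dirty = np.corrcoef(X[0], ref)[0, 1]
        assert c_clean >= c_dirty

    def test_mask_length_mismatch_rejected(self):
        _, _, _, wm, um = self._fitted()
        with pytest.raises(ValueError, match="keep_mask"):
            reconstruct_channels(um, np.ones(2, bool), wm)


class TestEstimatorApi:
    def test_fit_transform_inverse_round_trip(self):
        n = 8000
        rng = np.random.default_rng(17)
        S = np.vstack([rng.uniform(-1, 1, n), rng.laplace(size=n)])
        A = np.array([[1.0, 0.6], [0.4, 1.0]])
        X = (A @ S).T + 3.0
        ica = NegentropyFastICA(random_state=0).fit(X)
        Y = ica.transform(X)
        np.testing.assert_allclose(ica.inverse_transform(Y), X, atol=1e-8)
        assert Y.shape == (n, 2)
        assert all(ica.converged_)

    def test_mixing_unmixing_consistency(self):
        n = 8000
        rng = np.random.default_rng(18)
        S = np.vstack([rng.uniform(-1, 1, n), rng.laplace(size=n)])
        A = np.array([[1.0, 0.6], [0.4, 1.0]])
        X = (A @ S).T
        ica = NegentropyFastICA(random_state=1).fit(X)
        # components_ @ mixing_ is identity on the kept subspace
        np.testing.assert_allclose(
            ica.components_ @ ica.mixing_, np.eye(2), atol=1e-8
        )
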