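"""Bag-of-keypoints chain: dense SIFT, sampling, codebook, histograms, PCA."""

import numpy as np
import pytest
from scipy.stats import chisquare

from oracles import nearest_center_bruteforce
from raybok.features import (
    DESCRIPTOR_DIM,
    BagOfKeypointsExtractor,
    DescriptorSet,
    apply_pca,
    build_codebook,
    dense_sift,
    fit_pca,
    quantize,
    sample_descriptors,
    spatial_histogram,
)


class TestDenseSift:
    def test_uniform_image_all_low_contrast(self):
        ds = dense_sift(np.full((64, 64), 0.5))
        assert ds.low_contrast.all()
        assert np.all(ds.descriptors == 0)

    @pytest.mark.parametrize("shape,step,bins", [((64, 64), 4, (4,)), ((97, 53), 4, (4, 6)), ((80, 80), 8, (4, 6, 8, 10))])
    def test_frame_count_matches_grid_formula(self, rng, shape, step, bins):
        ds = dense_sift(rng.random(shape), step=step, bin_sizes=bins)
        H, W = shape
        expected = sum(
            ((H - 4 * b) // step + 1) * ((W - 4 * b) // step + 1)
            for b in bins
            if H >= 4 * b and W >= 4 * b
        )
        assert len(ds) == expected

    def test_descriptor_shape_and_nonnegativity(self, rng):
        ds = dense_sift(rng.random((48, 48)))
        assert ds.descriptors.shape[1] == DESCRIPTOR_DIM == 128
        assert np.all(ds.descriptors >= 0)
        assert np.all(np.isfinite(ds.descriptors))

    def test_too_small_image_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            ds = dense_sift(np.random.default_rng(0).random((8, 8)))
        assert len(ds) == 0

    def test_layered_input_collapsed_to_luminance(self, rng):
        g = rng.random((48, 48))
        layered = np.stack([g, g, g], axis=-1)
        a, b = dense_sift(g), dense_sift(layered)
        assert np.array_equal(a.descriptors, b.descriptors)


class TestSampleDescriptors:
    def _sets(self, rng, counts):
        out = []
        for n in counts:
            d = rng.random((n, DESCRIPTOR_DIM)).astype(np.float32)
            out.append(DescriptorSet(np.zeros((n, 3)), d, np.zeros(n, dtype=bool)))
        return out

    def test_saturation_returns_all(self, rng):
        sets = self._sets(rng, [10, 5])
        assert len(sample_descriptors(sets, 1000, seed=0)) == 15

    def test_deterministic_under_seed(self, rng):
        sets = self._sets(rng, [200])
        a = sample_descriptors(sets, 50, seed=9)
        b = sample_descriptors(sets, 50, seed=9)
        assert np.array_equal(a, b)

    def test_all_low_contrast_is_error(self, rng):
        d = np.zeros((5, DESCRIPTOR_DIM), dtype=np.float32)
        s = DescriptorSet(np.zeros((5, 3)), d, np.ones(5, dtype=bool))
        with pytest.raises(ValueError):
            sample_descriptors([s], 3, seed=0)

    def test_pool_proportional_to_image_counts(self, rng):
        """Sampling is uniform over the pooled descriptors, so per-image
        representation tracks per-image descriptor counts."""
        counts = [4000, 8000, 12000]
        sets = self._sets(rng, counts)
        # tag descriptors by source via first coordinate
        for i, s in enumerate(sets):
            s.descriptors[:, 0] = i
        pool = sample_descriptors(sets, 10000, seed=1)
        observed = np.bincount(pool[:, 0].astype(int), minlength=3)
        expected = np.array(counts) / sum(counts) * len(pool)
        assert chisquare(observed, expected).pvalue > 1e-4


class TestCodebook:
    def test_pool_of_exactly_k_points(self, rng):
        pool = rng.random((8, DESCRIPTOR_DIM))
        book = build_codebook(pool, 8, seed=0)
        assert book.objective_history[-1] == pytest.approx(0.0, abs=1e-12)
        assert {tuple(np.round(c, 9)) for c in book.centers} == {
            tuple(np.round(p, 9)) for p in pool
        }

    def test_objective_non_increasing_exact(self, rng):
        pool = rng.random((400, 16))
        book = build_codebook(pool, 10, seed=3, assign="exact")
        h = book.objective_history
        assert all(a >= b - 1e-9 for a, b in zip(h, h[1:]))

    def test_two_blob_center_recovery(self, rng):
        mu = np.zeros((2, 16))
        mu[1, 0] = 1.0
        pts = np.concatenate(
            [rng.normal(mu[i], 0.01, size=(250, 16)) for i in range(2)]
        )
        book = build_codebook(pts, 2, seed=4)
        d = np.array([[np.linalg.norm(c - m) for m in mu] for c in book.centers])
        assert d.min(axis=1).max() < 0.01

    def test_pool_smaller_than_k_rejected(self, rng):
        with pytest.raises(ValueError):
            build_codebook(rng.random((5, 16)), 10, seed=0)

    def test_ann_with_zero_eps_matches_exact(self, rng):
        pool = rng.random((300, 16))
        a = build_codebook(pool, 8, seed=7, assign="exact")
        b = build_codebook(pool, 8, seed=7, assign="kdtree", approx_eps=0.0)
        assert np.allclose(a.centers, b.centers)


class TestQuantize:
    def test_descriptor_equal_to_center(self, rng):
        pool = rng.random((60, DESCRIPTOR_DIM))
        book = build_codebook(pool, 20, seed=0)
        words = quantize(book.centers[7:8], book, mode="exact")
        assert words[0] == 7

    def test_exact_matches_bruteforce(self, rng):
        centers = rng.random((50, DESCRIPTOR_DIM))
        X = rng.random((500, DESCRIPTOR_DIM))
        from raybok.features import Codebook

        book = Codebook(centers=centers, train_seed=0)
        mine = quantize(X, book, mode="exact")
        ref = nearest_center_bruteforce(X, centers)
        assert np.array_equal(mine, ref)

    def test_kdtree_matches_exact(self, rng):
        from raybok.features import Codebook

        centers = rng.random((30, DESCRIPTOR_DIM))
        X = rng.random((400, DESCRIPTOR_DIM))
        book = Codebook(centers=centers, train_seed=0)
        assert np.array_equal(
            quantize(X, book, mode="exact"), quantize(X, book, mode="kdtree")
        )

    def test_empty_descriptor_set(self, rng):
        from raybok.features import Codebook

        book = Codebook(centers=rng.random((5, DESCRIPTOR_DIM)), train_seed=0)
        assert len(quantize(np.empty((0, DESCRIPTOR_DIM)), book)) == 0

    def test_dimension_mismatch_rejected(self, rng):
        from raybok.features import Codebook

        book = Codebook(centers=rng.random((5, DESCRIPTOR_DIM)), train_seed=0)
        with pytest.raises(ValueError):
            quantize(rng.random((3, 64)), book)


class TestSpatialHistogram:
    def test_length_is_grid_times_k(self, rng):
        h = spatial_histogram(
            rng.random((10, 3)) * 50, rng.integers(0, 1000, 10), (100, 100), k=1000
        )
        assert len(h) == 4000

    def test_conserves_descriptor_count(self, rng):
        n = 500
        frames = rng.random((n, 3)) * 99
        words = rng.integers(0, 20, n)
        h = spatial_histogram(frames, words, (100, 100), k=20)
        assert h.sum() == n

    def test_top_left_locality(self, rng):
        n, k = 40, 10
        frames = rng.random((n, 3)) * 20  # x, y < 20 < 50 = half size
        words = rng.integers(0, k, n)
        h = spatial_histogram(frames, words, (100, 100), k=k)
        assert h[:k].sum() == n and h[k:].sum() == 0

    def test_permutation_invariant(self, rng):
        n, k = 200, 15
        frames = rng.random((n, 3)) * 80
        words = rng.integers(0, k, n)
        perm = rng.permutation(n)
        a = spatial_histogram(frames, words, (80, 80), k=k)
        b = spatial_histogram(frames[perm], words[perm], (80, 80), k=k)
        assert np.array_equal(a, b)

    def test_word_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            spatial_histogram(np.zeros((1, 3)), np.array([7]), (10, 10), k=5)


class TestPca:
    def test_mean_projects_to_zero(self, rng):
        X = rng.random((50, 20))
        m = fit_pca(X, out_dim=5)
        assert np.allclose(apply_pca(m, X.mean(axis=0)), 0.0, atol=1e-10)

    def test_reconstruction_error_equals_discarded_eigenvalues(self, rng):
        """Eigendecomposition oracle: mean reconstruction error equals the
        sum of the eigenvalues of the dropped components."""
        X = rng.random((200, 50))
        out_dim = 10
        m = fit_pca(X, out_dim=out_dim)
        scores = apply_pca(m, X)
        recon = scores @ m.components + X.mean(axis=0)
        mse = np.sum((X - recon) ** 2) / (len(X) - 1)
        evals = np.linalg.eigvalsh(np.cov(X.T))[::-1]
        assert mse == pytest.approx(evals[out_dim:].sum(), abs=1e-8)

    def test_score_variance_matches_explained_variance(self, rng):
        X = rng.random((120, 30))
        m = fit_pca(X, out_dim=8)
        v = apply_pca(m, X).var(axis=0, ddof=1)
        assert np.allclose(v, m.explained_variances, atol=1e-6)
        assert np.all(np.diff(m.explained_variances) <= 1e-12)

    def test_components_orthonormal_and_scores_uncorrelated(self, rng):
        X = rng.random((150, 40))
        m = fit_pca(X, out_dim=12)
        G = m.components @ m.components.T
        assert np.allclose(G, np.eye(12), atol=1e-8)
        S = apply_pca(m, X)
        C = np.cov(S.T)
        off = C - np.diag(np.diag(C))
        assert np.abs(off).max() < 1e-6 * np.trace(C)

    def test_component_projection_is_unit_basis_vector(self, rng):
        X = rng.random((60, 25))
        m = fit_pca(X, out_dim=6)
        e2 = apply_pca(m, m.mean + m.components[2])
        assert np.allclose(e2, np.eye(6)[2], atol=1e-8)

    def test_sign_convention_deterministic(self, rng):
        X = rng.random((80, 15))
        m = fit_pca(X, out_dim=4)
        for row in m.components:
            assert row[np.argmax(np.abs(row))] > 0

    def test_too_few_rows_rejected_with_suggestion(self, rng):
        with pytest.raises(ValueError, match="reduce out_dim"):
            fit_pca(rng.random((10, 20)), out_dim=15)

    def test_apply_dimension_mismatch(self, rng):
        m = fit_pca(rng.random((30, 10)), out_dim=3)
        with pytest.raises(ValueError):
            apply_pca(m, rng.random((5, 11)))


class TestExtractor:
    def test_fit_transform_matches_transform_on_train(self, rng):
        imgs = [rng.random((72, 72)) for _ in range(12)]
        ex = BagOfKeypointsExtractor(k=10, pca_dim=5, per_image_cap=200, random_state=0)
        Xtr = ex.fit_transform(imgs)
        assert Xtr.shape == (12, 5)
        assert np.allclose(Xtr, ex.transform(imgs), atol=1e-9)

    def test_checksum_records_fit_inputs(self, rng):
        from raybok.features import _image_checksum

        imgs = [rng.random((64, 64)) for _ in range(8)]
        ex = BagOfKeypointsExtractor(k=5, pca_dim=3, per_image_cap=100, random_state=1)
        ex.fit(imgs)
        assert ex.fit_checksum_ == _image_checksum(imgs)

    def test_sklearn_param_interface(self):
        ex = BagOfKeypointsExtractor(k=7)
        assert ex.get_params()["k"] == 7
        ex.set_params(k=9)
        assert ex.k == 9
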