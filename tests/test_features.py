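"""Dictionary learning: distances, whitening, streaming fits, projection."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.linear_model import LogisticRegression

from spectrodict.evaluate import auc
from spectrodict.exceptions import (DimensionMismatchError, TooShortError,
                                    ZeroNormError)
from spectrodict.features import (FeatureDictionary, FeatureSequence,
                                  OnlineSphericalKMeans, PatchConfig,
                                  WhiteningTransform, cosine_distance,
                                  fit_dictionary, fit_two_layer, fit_whitening,
                                  load_dictionary, maxpool_downsample,
                                  normalise_patches, project,
                                  project_two_layer, random_projection,
                                  reservoir_sample_pass, save_dictionary,
                                  stack_frames)
from spectrodict.summarise import summarise_mean_std
from spectrodict.synth import planted_dictionary_data


def batch_spherical_kmeans(init, X, max_iter=300):
    """Batch (Lloyd-style) spherical k-means oracle run to convergence."""
    Xn = X / np.linalg.norm(X, axis=1, keepdims=True)
    C = init.copy()
    for _ in range(max_iter):
        assign = (Xn @ C.T).argmax(axis=1)
        new = C.copy()
        for j in range(len(C)):
            members = Xn[assign == j]
            if len(members):
                v = members.sum(axis=0)
                n = np.linalg.norm(v)
                if n > 0:
                    new[j] = v / n
        if np.allclose(new, C, atol=1e-12):
            break
        C = new
    return C, float(np.mean(1.0 - (Xn @ C.T).max(axis=1)))


class TestCosineDistance:
    def test_identical_directions(self):
        assert cosine_distance([2.0, 1.0], [4.0, 2.0]) == pytest.approx(0.0)

    def test_orthogonal(self):
        assert cosine_distance([1.0, 0.0], [0.0, 5.0]) == pytest.approx(1.0)

    def test_closed_form(self):
        assert cosine_distance([1.0, 1.0], [1.0, 0.0]) == pytest.approx(1 - 1 / np.sqrt(2))

    def test_zero_norm_raises(self):
        with pytest.raises(ZeroNormError):
            cosine_distance([0.0, 0.0], [1.0, 0.0])

    @given(st.integers(0, 2**31 - 1))
    def test_range(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.standard_normal((2, 6))
        d = cosine_distance(a, b)
        assert -1e-12 <= d <= 2 + 1e-12


class TestStackFrames:
    def test_row_length_four_times_forty(self):
        X = np.random.default_rng(0).standard_normal((10, 40))
        assert stack_frames(X, 4).shape == (7, 160)

    def test_delta_one_is_identity(self):
        X = np.random.default_rng(1).standard_normal((5, 3))
        np.testing.assert_array_equal(stack_frames(X, 1), X)

    def test_content_matches_naive_concatenation(self):
        X = np.arange(12.0).reshape(6, 2)
        P = stack_frames(X, 3)
        for t in range(4):
            np.testing.assert_array_equal(P[t], np.concatenate([X[t], X[t + 1], X[t + 2]]))

    def test_too_few_frames_raises(self):
        with pytest.raises(TooShortError):
            stack_frames(np.ones((2, 4)), 3)


class TestWhitening:
    def test_whitened_covariance_is_identity(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((2000, 8)) @ rng.standard_normal((8, 8)) + rng.normal(size=8)
        wt = fit_whitening(X)
        W = wt.apply(X)
        np.testing.assert_allclose(W.mean(axis=0), 0.0, atol=1e-10)
        cov = np.cov(W, rowvar=False, ddof=0)  # brute-force recompute
        # epsilon floor biases each eigenvalue by ~eps/lambda
        np.testing.assert_allclose(cov, np.eye(8), atol=1e-4)

    def test_constant_column_is_floored_not_blown_up(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((200, 4))
        X[:, 2] = 1.5
        W = fit_whitening(X, epsilon=1e-8).apply(X)
        assert np.all(np.isfinite(W))

    def test_identity_transform(self):
        wt = WhiteningTransform.identity(3)
        X = np.random.default_rng(9).standard_normal((5, 3))
        np.testing.assert_array_equal(wt.apply(X), X)


class TestReservoir:
    def test_small_stream_returned_whole(self):
        rows = [np.array([float(i)]) for i in range(100)]
        out = reservoir_sample_pass(iter(rows), capacity=1000, seed=0)
        assert sorted(out.ravel()) == list(map(float, range(100)))

    def test_determinism(self):
        rows = [np.array([float(i)]) for i in range(500)]
        a = reservoir_sample_pass(iter(rows), capacity=50, seed=3)
        b = reservoir_sample_pass(iter(rows), capacity=50, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_inclusion_is_uniform(self):
        """Monte-Carlo check of reservoir uniformity: per-item inclusion
        frequency stays within binomial sampling error."""
        n, cap, reps = 2000, 200, 200
        counts = np.zeros(n)
        for seed in range(reps):
            out = reservoir_sample_pass(
                (np.array([float(i)]) for i in range(n)), cap, seed=seed)
            counts[out.ravel().astype(int)] += 1
        p = cap / n
        sigma = np.sqrt(p * (1 - p) / reps)
        freqs = counts / reps
        assert abs(freqs.mean() - p) < 3 * sigma / np.sqrt(n) * 10
        assert np.max(np.abs(freqs - p)) < 5 * sigma

    def test_empty_stream_raises(self):
        with pytest.raises(TooShortError):
            reservoir_sample_pass(iter([]), capacity=10, seed=0)


class TestOnlineTrainer:
    def test_state_size_independent_of_stream_length(self):
        rng = np.random.default_rng(0)
        tr = OnlineSphericalKMeans(rng.standard_normal((4, 6)))
        shapes = (tr.centroids.shape, tr.counts.shape)
        for _ in range(500):
            tr.partial_fit(rng.standard_normal(6))
        assert (tr.centroids.shape, tr.counts.shape) == shapes

    def test_zero_patch_skipped(self):
        tr = OnlineSphericalKMeans(np.eye(3))
        assert tr.partial_fit(np.zeros(3)) == -1
        assert tr.n_skipped == 1

    def test_equidistant_tie_goes_to_lowest_index(self):
        tr = OnlineSphericalKMeans(np.array([[1.0, 0.0], [0.0, 1.0]]))
        assert tr.partial_fit(np.array([1.0, 1.0])) == 0


class TestFitDictionary:
    def test_planted_three_directions_recovered(self):
        """Three well-separated planted directions are each matched by a
        centroid of a (slightly overcomplete) fitted dictionary, and the
        online objective agrees with the batch oracle run to convergence
        from the fitted centroids."""
        X, D, _ = planted_dictionary_data(3, 12, 300, snr_db=30.0, seed=4)
        d = fit_dictionary([X], PatchConfig(delta=1, normalise=False), k=6,
                           seed=4, whiten=False)
        sims = np.abs(d.bases @ D.T)
        assert np.all(sims.max(axis=0) >= 0.98)
        Xn = X / np.linalg.norm(X, axis=1, keepdims=True)
        _, batch_obj = batch_spherical_kmeans(d.bases.copy(), X)
        online_obj = float(np.mean(1 - (Xn @ d.bases.T).max(axis=1)))
        assert online_obj <= batch_obj * 1.10 + 1e-9

    def test_all_centroids_unit_norm(self, clip_mels):
        d = fit_dictionary(list(clip_mels.values()), PatchConfig(delta=2), k=30, seed=0)
        np.testing.assert_allclose(np.linalg.norm(d.bases, axis=1), 1.0, atol=1e-6)

    def test_determinism_bit_identical(self, clip_mels):
        mels = list(clip_mels.values())
        a = fit_dictionary(mels, PatchConfig(delta=2), k=20, seed=5)
        b = fit_dictionary(mels, PatchConfig(delta=2), k=20, seed=5)
        np.testing.assert_array_equal(a.bases, b.bases)
        np.testing.assert_array_equal(a.update_counts, b.update_counts)

    def test_fewer_patches_than_k_raises(self):
        X = np.random.default_rng(0).standard_normal((10, 4))
        with pytest.raises(TooShortError):
            fit_dictionary([X], PatchConfig(delta=1), k=50, seed=0)

    def test_roundtrip_serialisation(self, clip_mels, tmp_path):
        d = fit_dictionary(list(clip_mels.values()), PatchConfig(delta=3), k=15, seed=2)
        path = tmp_path / "dict.npz"
        save_dictionary(path, d)
        d2 = load_dictionary(path)
        np.testing.assert_array_equal(d.bases, d2.bases)
        np.testing.assert_array_equal(d.whitening.matrix, d2.whitening.matrix)
        assert d2.patch.delta == 3 and d2.seed == 2


def _identity_dictionary(m, bases=None, normalise=False):
    if bases is None:
        bases = np.eye(m)
    return FeatureDictionary(bases=bases, whitening=WhiteningTransform.identity(m),
                             patch=PatchConfig(delta=1, normalise=normalise))


class TestProject:
    def test_identity_basis_reproduces_spectrogram(self):
        X = np.abs(np.random.default_rng(3).standard_normal((6, 5)))
        seq = project(X, _identity_dictionary(5))
        np.testing.assert_allclose(seq.values, X)

    def test_scalar_multiple_of_basis(self):
        b = np.zeros(4)
        b[1] = 1.0
        d = _identity_dictionary(4, bases=b[None, :])
        seq = project((3.0 * b)[None, :], d)
        assert seq.values[0, 0] == pytest.approx(3.0)

    def test_matches_naive_double_loop(self):
        """Projection equals the brute-force sum over frame offsets and
        bands for stacked patches."""
        rng = np.random.default_rng(12)
        M, delta, k, n = 6, 3, 4, 10
        X = rng.standard_normal((n, M))
        bases = rng.standard_normal((k, M * delta))
        bases /= np.linalg.norm(bases, axis=1, keepdims=True)
        d = FeatureDictionary(bases=bases, whitening=WhiteningTransform.identity(M * delta),
                              patch=PatchConfig(delta=delta, normalise=False))
        seq = project(X, d)
        for t in range(n - delta + 1):
            for j in range(k):
                expected = sum(bases[j, dd * M + i] * X[t + dd, i]
                               for dd in range(delta) for i in range(M))
                assert seq.values[t, j] == pytest.approx(expected)

    def test_linearity_without_patch_normalisation(self):
        rng = np.random.default_rng(13)
        d = _identity_dictionary(5, bases=rng.standard_normal((7, 5)))
        x, y = rng.standard_normal((2, 4, 5))
        np.testing.assert_allclose(project(2.5 * x, d).values, 2.5 * project(x, d).values)
        np.testing.assert_allclose(project(x + y, d).values,
                                   project(x, d).values + project(y, d).values)

    def test_dimension_mismatch_raises(self):
        d = _identity_dictionary(5)
        with pytest.raises(DimensionMismatchError):
            project(np.ones((4, 7)), d)


class TestMaxpool:
    def test_sixteen_frames_factor_eight(self):
        X = np.random.default_rng(4).standard_normal((16, 3))
        out = maxpool_downsample(FeatureSequence(X, 0.02), 8)
        assert out.values.shape == (2, 3)
        np.testing.assert_array_equal(out.values[0], X[:8].max(axis=0))
        np.testing.assert_array_equal(out.values[1], X[8:].max(axis=0))

    def test_factor_one_identity(self):
        X = np.random.default_rng(5).standard_normal((9, 2))
        np.testing.assert_array_equal(maxpool_downsample(FeatureSequence(X, 0.02), 1).values, X)

    def test_partial_trailing_block(self):
        X = np.random.default_rng(6).standard_normal((17, 2))
        out = maxpool_downsample(FeatureSequence(X, 0.02), 8)
        assert out.values.shape == (3, 2)
        np.testing.assert_array_equal(out.values[2], X[16])


class TestTwoLayer:
    def test_layer2_basis_length(self, clip_mels):
        d1, d2 = fit_two_layer(list(clip_mels.values()),
                               PatchConfig(delta=4, layer2=True), k=10, seed=0)
        assert d2.patch_dim == 10 * 4
        np.testing.assert_allclose(np.linalg.norm(d1.bases, axis=1), 1.0, atol=1e-6)
        np.testing.assert_allclose(np.linalg.norm(d2.bases, axis=1), 1.0, atol=1e-6)

    def test_orderings_separated_better_by_layer2(self):
        """Two syllable orderings (A then B vs B then A) with identical
        frame-wise and local-patch statistics: a linear probe on layer-2
        summaries separates them better than on layer-1 summaries."""
        rng = np.random.default_rng(42)

        def make_seq(order):
            X = 0.05 * np.abs(rng.standard_normal((64, 40)))
            bands = {"A": slice(5, 13), "B": slice(25, 33)}
            j1, j2 = rng.integers(-4, 5, 2)
            slots = [slice(8 + j1, 24 + j1), slice(40 + j2, 56 + j2)]
            for slot, syl in zip(slots, order):
                X[slot, bands[syl]] += 1.0 + 0.1 * rng.standard_normal((16, 8))
            return X

        seqs = [make_seq("AB") for _ in range(40)] + [make_seq("BA") for _ in range(40)]
        y = np.array([0] * 40 + [1] * 40)
        d1, d2 = fit_two_layer(seqs, PatchConfig(delta=4, layer2=True, pool_factor=8),
                               k=40, seed=0)
        f1 = np.vstack([summarise_mean_std(project(s, d1)).values for s in seqs])
        f2 = np.vstack([summarise_mean_std(project_two_layer(s, d1, d2)).values
                        for s in seqs])

        def probe_auc(feats):
            idx = np.random.default_rng(0).permutation(len(y))
            tr, te = idx[:40], idx[40:]
            clf = LogisticRegression(max_iter=2000).fit(feats[tr], y[tr])
            return auc(clf.decision_function(feats[te]), y[te])

        a1, a2 = probe_auc(f1), probe_auc(f2)
        assert a2 > a1 + 0.1
        assert a2 > 0.65


class TestRandomProjection:
    def test_output_dimension(self):
        X = np.random.default_rng(1).standard_normal((8, 52))
        assert random_projection(X, 200, seed=0).shape == (8, 200)

    def test_same_seed_same_matrix(self):
        X = np.random.default_rng(2).standard_normal((5, 30))
        np.testing.assert_array_equal(random_projection(X, 10, seed=7),
                                      random_projection(X, 10, seed=7))

    def test_distances_approximately_preserved(self):
        """Johnson-Lindenstrauss sanity: pairwise distance matrices before
        and after projection correlate strongly."""
        from scipy.spatial.distance import pdist
        rng = np.random.default_rng(3)
        # heterogeneous norms so pairwise distances actually vary
        X = rng.standard_normal((40, 1000)) * rng.lognormal(0, 1, size=(40, 1))
        P = random_projection(X, 200, seed=1)
        r = np.corrcoef(pdist(X), pdist(P))[0, 1]
        assert r > 0.8


def test_normalise_patches_zero_mean_unit_norm():
    rng = np.random.default_rng(0)
    P = normalise_patches(rng.standard_normal((20, 8)))
    np.testing.assert_allclose(P.mean(axis=1), 0.0, atol=1e-12)
    np.testing.assert_allclose(np.linalg.norm(P, axis=1), 1.0, atol=1e-12)
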