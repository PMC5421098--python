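"""Two-level codebook fitting and encoding."""

import itertools

import numpy as np
import pytest

from histocode.codebook import (
    CodebookPairL2,
    CodeGrid,
    UnusableImageError,
    encode_image,
    encode_l1,
    fit_l1,
    fit_l2_pair,
    l2_descriptor,
    sample_l2_descriptors,
    sample_patch_descriptors,
    window_validity,
)
from histocode.extract import ImageFeatures


def make_feats(descriptors: np.ndarray, valid: np.ndarray | None = None, image_id: str = "img") -> ImageFeatures:
    if valid is None:
        valid = np.ones(descriptors.shape[:2], dtype=bool)
    return ImageFeatures(image_id=image_id, descriptors=descriptors, valid=valid)


def brute_force_kmeans_objective(points: np.ndarray, k: int) -> float:
    """Exhaustive minimum of the within-cluster sum of squares over every
    assignment of points to at most k clusters."""
    best = np.inf
    n = len(points)
    for assign in itertools.product(range(k), repeat=n):
        a = np.array(assign)
        sse = 0.0
        for c in range(k):
            members = points[a == c]
            if len(members):
                sse += ((members - members.mean(axis=0)) ** 2).sum()
        best = min(best, sse)
    return best


class TestSampling:
    def test_capped_at_n(self, rng):
        feats = make_feats(rng.uniform(size=(80, 80, 4)))
        assert sample_patch_descriptors(feats, n=1000, rng=rng).shape == (1000, 4)

    def test_returns_all_when_fewer_valid(self, rng):
        valid = np.zeros((30, 30), dtype=bool)
        valid[:20, :30] = True  # 600 valid patches
        feats = make_feats(rng.uniform(size=(30, 30, 4)), valid)
        assert sample_patch_descriptors(feats, n=1000, rng=rng).shape == (600, 4)

    def test_deterministic_given_seed(self, rng):
        feats = make_feats(rng.uniform(size=(50, 50, 4)))
        a = sample_patch_descriptors(feats, n=100, rng=7)
        b = sample_patch_descriptors(feats, n=100, rng=7)
        assert np.array_equal(a, b)

    def test_no_valid_patch_warns_and_skips(self, rng):
        feats = make_feats(rng.uniform(size=(4, 4, 4)), np.zeros((4, 4), dtype=bool))
        with pytest.warns(UserWarning):
            out = sample_patch_descriptors(feats, rng=rng)
        assert out.shape == (0, 4)


class TestFitL1:
    def test_k_points_k_clusters_recovers_points(self, rng):
        pts = rng.uniform(size=(5, 6))
        cb = fit_l1(pts, k1=5, rng_seed=0)
        z = cb.standardize(pts)
        # every point must coincide with some centroid
        d = np.linalg.norm(z[:, None, :] - cb.centroids[None], axis=2)
        assert np.allclose(d.min(axis=1), 0.0, atol=1e-8)

    def test_two_blob_recovery(self, rng):
        a = rng.normal(0.0, 0.05, size=(200, 8))
        b = rng.normal(1.0, 0.05, size=(200, 8))
        cb = fit_l1(np.vstack([a, b]), k1=2, rng_seed=0)
        za = cb.standardize(a.mean(axis=0)[None])
        d = np.linalg.norm(cb.centroids - za, axis=1)
        assert d.min() < 3 * 0.05 * np.sqrt(8)

    def test_matches_exhaustive_partition_minimum(self, rng):
        # small enough to enumerate every assignment
        for n, k in ((8, 2), (9, 3)):
            pts = rng.uniform(size=(n, 2))
            cb = fit_l1(pts, k1=k, rng_seed=0, restarts=10)
            z = cb.standardize(pts)
            d = ((z[:, None, :] - cb.centroids[None]) ** 2).sum(axis=2)
            assign = d.argmin(axis=1)
            sse = sum(
                ((z[assign == c] - z[assign == c].mean(axis=0)) ** 2).sum()
                for c in range(k)
                if (assign == c).any()
            )
            assert np.isclose(sse, brute_force_kmeans_objective(z, k), rtol=1e-7, atol=1e-9)

    def test_too_few_distinct_points_rejected(self):
        pts = np.tile(np.arange(6.0)[:, None], (1, 3))[np.array([0, 0, 1, 1, 2, 2])]
        with pytest.raises(ValueError):
            fit_l1(pts, k1=4, rng_seed=0)

    def test_objective_beats_random_assignment(self, rng):
        pts = rng.uniform(size=(60, 5))
        cb = fit_l1(pts, k1=4, rng_seed=0)
        z = cb.standardize(pts)
        d = ((z[:, None, :] - cb.centroids[None]) ** 2).sum(axis=2)
        fitted = d.min(axis=1).sum()
        a = rng.integers(0, 4, size=60)
        random_sse = sum(((z[a == c] - z[a == c].mean(axis=0)) ** 2).sum() for c in range(4) if (a == c).any())
        assert fitted <= random_sse


class TestEncodeL1:
    def test_centroid_descriptor_gets_its_code(self, rng):
        pts = rng.uniform(size=(50, 4))
        cb = fit_l1(pts, k1=8, rng_seed=0)
        raw = cb.centroids[6] * cb.sd + cb.mean  # undo standardization
        feats = make_feats(raw.reshape(1, 1, 4))
        assert encode_l1(feats, cb).codes[0, 0] == 7

    def test_tie_goes_to_lowest_index(self):
        from histocode.codebook import CodebookL1

        cb = CodebookL1(
            centroids=np.array([[2.0, 0.0], [-1.0, 0.0], [1.0, 0.0]]),
            mean=np.zeros(2),
            sd=np.ones(2),
            k1=3,
        )
        feats = make_feats(np.zeros((1, 1, 2)))  # equidistant to centroids 2 and 3
        assert encode_l1(feats, cb).codes[0, 0] == 2

    def test_codes_in_range_with_sentinel(self, rng):
        pts = rng.uniform(size=(100, 4))
        cb = fit_l1(pts, k1=8, rng_seed=0)
        valid = rng.random((10, 10)) < 0.7
        feats = make_feats(rng.uniform(size=(10, 10, 4)), valid)
        codes = encode_l1(feats, cb).codes
        assert set(np.unique(codes[valid])) <= set(range(1, 9))
        assert np.all(codes[~valid] == 0)

    def test_dimension_mismatch_rejected(self, rng):
        cb = fit_l1(rng.uniform(size=(20, 4)), k1=3, rng_seed=0)
        with pytest.raises(ValueError):
            encode_l1(make_feats(rng.uniform(size=(2, 2, 5))), cb)


class TestL2:
    def test_uniform_window_is_indicator(self):
        grid = CodeGrid(codes=np.full((15, 15), 5, dtype=np.int32), k1=8)
        freq = l2_descriptor(grid, 0, 0)
        expected = np.zeros(8)
        expected[4] = 1.0
        assert np.allclose(freq, expected)

    def test_majority_invalid_window_is_invalid(self, rng):
        codes = rng.integers(1, 9, size=(15, 15)).astype(np.int32)
        flat = codes.ravel()
        flat[rng.choice(225, size=113, replace=False)] = 0  # 113/225 > 0.5
        grid = CodeGrid(codes=flat.reshape(15, 15), k1=8)
        assert l2_descriptor(grid, 0, 0) is None

    def test_just_under_half_invalid_still_valid_and_normalized(self, rng):
        codes = rng.integers(1, 9, size=(15, 15)).astype(np.int32)
        flat = codes.ravel()
        flat[rng.choice(225, size=112, replace=False)] = 0
        grid = CodeGrid(codes=flat.reshape(15, 15), k1=8)
        freq = l2_descriptor(grid, 0, 0)
        assert freq is not None and np.isclose(freq.sum(), 1.0)

    def test_out_of_bounds_window_rejected(self):
        grid = CodeGrid(codes=np.ones((20, 20), dtype=np.int32), k1=4)
        with pytest.raises(ValueError):
            l2_descriptor(grid, 6, 0)

    def test_window_validity_matches_descriptor(self, rng):
        codes = rng.integers(0, 5, size=(25, 31)).astype(np.int32)
        grid = CodeGrid(codes=codes, k1=4)
        ok = window_validity(grid)
        for r in range(ok.shape[0]):
            for c in range(ok.shape[1]):
                assert ok[r, c] == (l2_descriptor(grid, r, c) is not None)

    def test_sampling_capped_and_deterministic(self, rng):
        grid = CodeGrid(codes=rng.integers(1, 5, size=(40, 40)).astype(np.int32), k1=4)
        s1 = sample_l2_descriptors(grid, n=50, rng=3)
        s2 = sample_l2_descriptors(grid, n=50, rng=3)
        assert s1.shape == (50, 4)
        assert np.array_equal(s1, s2)


class TestL2PairAndHistogram:
    def test_identical_class_inputs_give_identical_blocks(self, rng):
        d = rng.dirichlet(np.ones(6), size=60)
        pair = fit_l2_pair(d, d.copy(), k2=4, rng_seed=9)
        assert np.allclose(pair.positive, pair.negative)
        assert pair.stacked.shape == (8, 6)

    def test_class_specific_codebooks_separate_motifs(self, rng):
        # class-exclusive frequency profiles: held-out vectors must fall in
        # their own class's block
        pos = rng.dirichlet([10, 10, 1, 1, 1, 1], size=120)
        neg = rng.dirichlet([1, 1, 1, 1, 10, 10], size=120)
        pair = fit_l2_pair(pos[:80], neg[:80], k2=4, rng_seed=0)
        stacked = pair.stacked

        def block(v):
            d = ((stacked - v) ** 2).sum(axis=1)
            return 0 if d.argmin() < 4 else 1

        pos_ok = np.mean([block(v) == 0 for v in pos[80:]])
        neg_ok = np.mean([block(v) == 1 for v in neg[80:]])
        assert pos_ok >= 0.9 and neg_ok >= 0.9

    def test_histogram_length_and_normalization(self, rng):
        codes = rng.integers(1, 5, size=(30, 30)).astype(np.int32)
        grid = CodeGrid(codes=codes, k1=4)
        pair = fit_l2_pair(rng.dirichlet(np.ones(4), 30), rng.dirichlet(np.ones(4), 30), k2=4, rng_seed=0)
        hist = encode_image(grid, pair)
        assert hist.shape == (8,)
        assert np.isclose(hist.sum(), 1.0)

    def test_single_window_indicator(self, rng):
        pair = fit_l2_pair(rng.dirichlet(np.ones(4), 30), rng.dirichlet(np.ones(4), 30), k2=4, rng_seed=0)
        # build a window whose frequency vector equals positive centroid 0
        target = pair.positive[0]
        counts = np.round(target * 225).astype(int)
        counts[0] += 225 - counts.sum()
        codes = np.repeat(np.arange(1, 5), counts)[:225].reshape(15, 15).astype(np.int32)
        hist = encode_image(CodeGrid(codes=codes, k1=4), pair)
        assert np.isclose(hist.sum(), 1.0)
        assert hist.max() == 1.0  # single window -> indicator histogram

    def test_window_order_invariance(self, rng):
        codes = rng.integers(1, 5, size=(30, 30)).astype(np.int32)
        grid = CodeGrid(codes=codes, k1=4)
        pair = fit_l2_pair(rng.dirichlet(np.ones(4), 30), rng.dirichlet(np.ones(4), 30), k2=4, rng_seed=0)
        h1 = encode_image(grid, pair)
        # swap the four 15x15 tiles
        swapped = np.block(
            [[codes[15:, 15:], codes[15:, :15]], [codes[:15, 15:], codes[:15, :15]]]
        )
        h2 = encode_image(CodeGrid(codes=swapped, k1=4), pair)
        assert np.allclose(h1, h2)

    def test_no_valid_window_raises(self, rng):
        grid = CodeGrid(codes=np.zeros((15, 15), dtype=np.int32), k1=4)
        pair = fit_l2_pair(rng.dirichlet(np.ones(4), 30), rng.dirichlet(np.ones(4), 30), k2=4, rng_seed=0)
        with pytest.raises(UnusableImageError):
            encode_image(grid, pair)


class TestCohortInvariants:
    def test_no_cluster_dominated_by_single_image(self):
        # shared motif mixture (zero divergence): every texture kind occurs
        # across many images, so no codeword may be owned by one image
        from histocode.pipeline import _image_rng
        from histocode.synthetic import CohortSpec, cohort_features, generate_cohort

        spec = CohortSpec(n_images=16, image_px=(1024, 1024), background_margin_px=32, divergence=0.0, seed=3)
        feats = cohort_features(generate_cohort(spec))
        samples, owners = [], []
        for f in feats:
            s = sample_patch_descriptors(f, 1000, _image_rng(3, f.image_id, 1))
            samples.append(s)
            owners.append(np.full(len(s), f.image_id))
        pooled = np.vstack(samples)
        owners = np.concatenate(owners)
        cb = fit_l1(pooled, k1=8, rng_seed=0)
        z = cb.standardize(pooled)
        assign = ((z[:, None, :] - cb.centroids[None]) ** 2).sum(axis=2).argmin(axis=1)
        for c in range(8):
            members = owners[assign == c]
            if len(members) == 0:
                continue
            _, counts = np.unique(members, return_counts=True)
            assert counts.max() / len(members) < 0.5
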