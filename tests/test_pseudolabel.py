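"""KNN density, confidence sampling, elbow estimate and K-means++
pseudolabels."""
import numpy as np
import pytest

from pseudosorter.pseudolabel import (PseudoLabelSet, assign_pseudolabels,
                                      density_k, estimate_k_elbow,
                                      knn_density, sample_densest,
                                      sample_weighted)

from conftest import gaussian_blobs


def brute_force_knn_density(pts, K):
    """All-pairs oracle for the KNN density."""
    pts = np.atleast_2d(pts)
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    d.sort(axis=1)
    return 1.0 / np.maximum(d[:, :K].mean(axis=1), 1e-12)


class TestKnnDensity:
    def test_collinear_unit_spacing(self):
        pts = np.array([[0.0], [1.0], [2.0]])
        np.testing.assert_allclose(knn_density(pts, 1), [1.0, 1.0, 1.0])

    def test_hand_computed_asymmetric(self):
        pts = np.array([[0.0], [1.0], [3.0]])
        np.testing.assert_allclose(knn_density(pts, 1), [1.0, 1.0, 0.5])

    def test_coincident_points_guarded(self):
        pts = np.array([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]])
        d = knn_density(pts, 1)
        assert np.isfinite(d).all()
        assert d[0] == pytest.approx(1e12)

    def test_matches_brute_force_oracle(self, rng):
        pts = rng.normal(size=(300, 10))
        K = density_k(300)  # = 2
        np.testing.assert_allclose(knn_density(pts, K),
                                   brute_force_knn_density(pts, K),
                                   atol=1e-10)

    def test_errors(self):
        with pytest.raises(ValueError):
            knn_density(np.zeros((3, 2)), 3)
        with pytest.raises(ValueError):
            knn_density(np.zeros((3, 2)), 0)


class TestSampleDensest:
    def test_examples(self):
        assert list(sample_densest(np.array([3.0, 1.0, 2.0]), 1 / 3)) == [0]
        assert list(sample_densest(np.array([3.0, 1.0, 2.0]), 1.0)) == [0, 1, 2]

    def test_tie_at_cut_resolved_by_index(self):
        # densities tie; the lower index wins
        assert list(sample_densest(np.array([1.0, 1.0, 1.0]), 1 / 3)) == [0]

    def test_exact_top_fraction_set(self, rng):
        d = rng.normal(size=200)
        got = sample_densest(d, 0.25)
        expect = np.sort(np.argsort(-d, kind="stable")[:50])
        np.testing.assert_array_equal(got, expect)


class TestSampleWeighted:
    def test_size_uniqueness_bounds(self, rng):
        d = rng.exponential(size=1000)
        idx = sample_weighted(d, 0.1, seed=0)
        assert idx.size == 100
        assert np.unique(idx).size == 100
        assert idx.min() >= 0 and idx.max() < 1000

    def test_fraction_one_returns_everything(self, rng):
        d = rng.exponential(size=57)
        np.testing.assert_array_equal(sample_weighted(d, 1.0, seed=3),
                                      np.arange(57))

    def test_seeded_determinism(self, rng):
        d = rng.exponential(size=500)
        np.testing.assert_array_equal(sample_weighted(d, 0.2, seed=5),
                                      sample_weighted(d, 0.2, seed=5))

    def test_biased_toward_density_on_bimodal_fixture(self):
        # bimodal density: half the points dense, half sparse
        d = np.concatenate([np.full(500, 10.0), np.full(500, 0.1)])
        wins = 0
        reps = 200
        for s in range(reps):
            idx = sample_weighted(d, 0.1, seed=s)
            if d[idx].mean() > d.mean():
                wins += 1
        assert wins / reps >= 0.99

    def test_every_point_reachable(self):
        # the sparsest point appears in some seeded draws
        d = np.linspace(1.0, 0.0, 50)
        seen = set()
        for s in range(300):
            seen.update(sample_weighted(d, 0.2, seed=s).tolist())
        assert seen == set(range(50))

    def test_densest_vs_weighted_ordering(self, rng):
        d = rng.exponential(size=1000)
        densest = d[sample_densest(d, 0.2)].mean()
        weighted = np.mean([d[sample_weighted(d, 0.2, seed=s)].mean()
                            for s in range(20)])
        assert densest >= weighted >= d.mean()


class TestElbow:
    @pytest.mark.parametrize("k_true", [3, 5])
    def test_blob_recovery(self, k_true):
        hits = 0
        for s in range(20):
            pts, _ = gaussian_blobs(k_true, 3000 // k_true, sep=20.0, seed=s)
            if estimate_k_elbow(pts, (2, 20), seed=s) == k_true:
                hits += 1
        assert hits >= 18

    def test_result_clamped_to_range(self, rng):
        pts = rng.normal(size=(100, 5))  # structureless
        k = estimate_k_elbow(pts, (2, 20), seed=0)
        assert 2 <= k <= 20

    def test_subset_too_small_raises(self, rng):
        with pytest.raises(ValueError):
            estimate_k_elbow(rng.normal(size=(15, 3)), (2, 20), seed=0)


class TestAssignPseudolabels:
    def test_separated_blobs_partition_exactly(self):
        pts, labels = gaussian_blobs(2, 200, sep=20.0, seed=1)
        pls = assign_pseudolabels(pts, np.arange(400), 2, seed=0)
        # partition matches blob membership up to label naming
        agree = max((pls.labels == labels).mean(),
                    (pls.labels == 1 - labels).mean())
        assert agree == 1.0

    def test_k_equals_n_sampled(self, rng):
        pts = rng.normal(size=(40, 3))
        idx = np.arange(6)
        pls = assign_pseudolabels(pts, idx, 6, seed=0)
        assert sorted(pls.labels.tolist()) == [0, 1, 2, 3, 4, 5]

    def test_seeded_determinism(self, rng):
        pts = rng.normal(size=(100, 4))
        idx = np.arange(50)
        a = assign_pseudolabels(pts, idx, 4, seed=9)
        b = assign_pseudolabels(pts, idx, 4, seed=9)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_too_few_points_raises(self, rng):
        with pytest.raises(ValueError):
            assign_pseudolabels(rng.normal(size=(10, 2)), np.arange(3), 5)

    def test_pseudolabelset_invariants(self):
        with pytest.raises(ValueError):
            PseudoLabelSet(indices=np.array([1, 1]), labels=np.array([0, 1]),
                           k=2, fraction=0.1)
        with pytest.raises(ValueError):
            PseudoLabelSet(indices=np.array([1, 2]), labels=np.array([0, 5]),
                           k=2, fraction=0.1)
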