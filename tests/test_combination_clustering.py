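"""Ensemble clustering: subset enumeration, weak learners, co-association."""

import numpy as np
import pytest
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from dreamcatcher.combination_clustering import (CoAssocMatrix, EnsembleConfig,
                                                 SubClustering, accumulate,
                                                 extract_two_clusters,
                                                 mean_silhouette,
                                                 run_combination_clustering,
                                                 sample_combinations, subcluster,
                                                 two_means)


class TestSampleCombinations:
    def test_reference_configuration_enumerates_82475(self):
        subsets = sample_combinations(2475, EnsembleConfig())
        assert len(subsets) == 82_475

    def test_small_arithmetic(self):
        cfg = EnsembleConfig(subset_sizes=(2,), combinations=3)
        assert len(sample_combinations(5, cfg)) == 5 + 3

    def test_deterministic_under_seed(self):
        cfg = EnsembleConfig(subset_sizes=(2, 3), combinations=5, seed=42)
        a = sample_combinations(10, cfg)
        b = sample_combinations(10, cfg)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_too_few_features_rejected(self):
        with pytest.raises(ValueError):
            sample_combinations(5, EnsembleConfig(subset_sizes=(9,)))


class TestTwoMeans:
    def test_matches_sklearn_on_separated_blobs(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(-5, 1, (20, 3)), rng.normal(5, 1, (20, 3))])
        ours = two_means(X, restarts=5, rng=np.random.default_rng(1))
        ref = KMeans(n_clusters=2, n_init=5, random_state=1).fit_predict(X)
        agree = np.mean(ours == ref)
        assert agree in (0.0, 1.0)  # identical up to label swap

    def test_silhouette_matches_sklearn(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((30, 4))
        labels = (rng.random(30) > 0.4).astype(int)
        assert mean_silhouette(X, labels) == pytest.approx(
            silhouette_score(X, labels), abs=1e-10)


class TestSubcluster:
    def test_separated_blobs_score_high(self):
        rng = np.random.default_rng(3)
        X = np.concatenate([rng.normal(-10, 0.5, 25), rng.normal(10, 0.5, 25)])
        sc = subcluster(X[:, None], EnsembleConfig(), np.random.default_rng(4))
        assert sc.weight > 0.9
        assert np.unique(sc.labels[:25]).size == 1
        assert sc.labels[0] != sc.labels[-1]

    def test_identical_points_zero_weight(self):
        sc = subcluster(np.ones((10, 2)), EnsembleConfig(), np.random.default_rng(5))
        assert sc.weight == 0.0
        assert np.unique(sc.labels).size == 1

    def test_scale_invariance_of_1d_split(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal(40)
        a = subcluster(X[:, None], EnsembleConfig(), np.random.default_rng(7))
        b = subcluster(5.0 * X[:, None], EnsembleConfig(), np.random.default_rng(7))
        assert np.array_equal(a.labels, b.labels) or \
            np.array_equal(a.labels, 1 - b.labels)


class TestAccumulate:
    def test_single_subclustering_gives_binary_blocks(self):
        labels = np.repeat([0, 1], 3)
        m = accumulate([SubClustering(np.array([0]), labels, 0.7)])
        expect = (labels[:, None] == labels[None, :]).astype(float)
        np.fill_diagonal(expect, 1.0)
        np.testing.assert_allclose(m.values, expect)

    def test_duplicate_subclusterings_normalize_out(self):
        labels = np.repeat([0, 1], 3)
        one = accumulate([SubClustering(np.array([0]), labels, 0.5)])
        two = accumulate([SubClustering(np.array([0]), labels, 0.5),
                          SubClustering(np.array([0]), labels, 2.0)])
        np.testing.assert_allclose(one.values, two.values)

    def test_orthogonal_splits_hand_tally(self):
        a = np.array([0, 0, 1, 1])
        b = np.array([0, 1, 0, 1])
        m = accumulate([SubClustering(np.array([0]), a, 1.0),
                        SubClustering(np.array([1]), b, 1.0)])
        off = m.values[~np.eye(4, dtype=bool)]
        assert set(np.round(off, 12)) <= {0.0, 0.5}

    def test_zero_weight_rejected(self):
        with pytest.raises(ValueError):
            accumulate([SubClustering(np.array([0]), np.zeros(4, dtype=int), 0.0)])

    def test_invariants_on_random_ensembles(self):
        rng = np.random.default_rng(8)
        scs = [SubClustering(np.array([0]), rng.integers(0, 2, 20), rng.random())
               for _ in range(15)]
        m = accumulate(scs)
        assert np.allclose(m.values, m.values.T)
        assert m.values.min() >= 0 and m.values.max() <= 1
        assert np.allclose(np.diag(m.values), 1.0)


def block_matrix(sizes, between=0.0, pairs_between=None):
    n = sum(sizes)
    vals = np.full((n, n), between)
    starts = np.cumsum([0] + list(sizes))
    for i, s in enumerate(sizes):
        vals[starts[i]:starts[i + 1], starts[i]:starts[i + 1]] = 1.0
    if pairs_between:
        for (i, j), v in pairs_between.items():
            vals[starts[i]:starts[i + 1], starts[j]:starts[j + 1]] = v
            vals[starts[j]:starts[j + 1], starts[i]:starts[i + 1]] = v
    np.fill_diagonal(vals, 1.0)
    return CoAssocMatrix(vals)


class TestExtractTwoClusters:
    def test_perfect_balanced_blocks(self):
        res = extract_two_clusters(block_matrix([27, 27]))
        assert sorted([res.size(1), res.size(2)]) == [27, 27]
        assert np.unique(res.labels[:27]).size == 1

    def test_unbalanced_28_26_shape_representable(self):
        res = extract_two_clusters(block_matrix([28, 26]))
        assert sorted([res.size(1), res.size(2)]) == [26, 28]

    def test_three_block_dendrogram_picks_nearest_half(self):
        # blocks 20/20/14; A-B similar (0.6), C distant: the k=3 cut owns a
        # 20-case cluster (|20-27|=7) beating the k=2 cut's 40 vs 14
        m = block_matrix([20, 20, 14], between=0.0, pairs_between={(0, 1): 0.6})
        res = extract_two_clusters(m)
        assert sorted([res.size(1), res.size(2)]) == [20, 34]
        assert np.unique(res.labels[:20]).size == 1

    def test_flat_matrix_rejected(self):
        vals = np.full((6, 6), 0.4)
        np.fill_diagonal(vals, 1.0)
        with pytest.raises(ValueError, match="separable"):
            extract_two_clusters(CoAssocMatrix(vals))


class TestRunCombinationClustering:
    def test_recovers_dominant_structure(self):
        rng = np.random.default_rng(9)
        truth = np.repeat([0, 1], 27)
        X = np.column_stack([truth * 4.0 + rng.normal(0, 1, 54) for _ in range(5)])
        cfg = EnsembleConfig(subset_sizes=(2, 3), combinations=30, seed=10)
        res, coassoc = run_combination_clustering(X, cfg)
        agree = max(np.mean((res.labels == 1) == (truth == 0)),
                    np.mean((res.labels == 1) == (truth == 1)))
        assert agree >= 0.95
        assert coassoc.values.shape == (54, 54)

    def test_oracle_equivalence_single_informative_feature(self):
        rng = np.random.default_rng(11)
        x = np.concatenate([rng.normal(-3, 0.5, 25), rng.normal(3, 0.5, 25)])
        cfg = EnsembleConfig(subset_sizes=(1,), combinations=1, seed=12)
        res, _ = run_combination_clustering(x[:, None], cfg)
        direct = KMeans(n_clusters=2, n_init=10, random_state=0).fit_predict(x[:, None])
        agree = np.mean((res.labels == 1) == (direct == 0))
        assert agree in (0.0, 1.0)

    def test_case_permutation_equivariance(self):
        rng = np.random.default_rng(13)
        truth = np.repeat([0, 1], 15)
        X = np.column_stack([truth * 6.0 + rng.normal(0, 0.5, 30) for _ in range(4)])
        cfg = EnsembleConfig(subset_sizes=(2,), combinations=10, seed=14)
        res, _ = run_combination_clustering(X, cfg)
        perm = np.random.default_rng(15).permutation(30)
        res_p, _ = run_combination_clustering(X[perm], cfg)
        a, b = res.labels[perm], res_p.labels
        assert np.array_equal(a, b) or np.array_equal(a, 3 - b)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(16)
        X = rng.standard_normal((20, 6))
        cfg = EnsembleConfig(subset_sizes=(2, 3), combinations=10, seed=17)
        r1, c1 = run_combination_clustering(X, cfg)
        r2, c2 = run_combination_clustering(X, cfg)
        assert np.array_equal(r1.labels, r2.labels)
        np.testing.assert_array_equal(c1.values, c2.values)
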