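"""Difference vectors, mean orientation, hyperplane splits, MC weights."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dreamcatcher.combination_clustering import EnsembleConfig
from dreamcatcher.features import FeatureMatrix, studentize
from dreamcatcher.paired_geometry import (DifferenceVectorSet,
                                          expected_random_goodness,
                                          hyperplane_subcluster,
                                          mc_normalize_goodness,
                                          mean_orientation,
                                          mean_orientation_exhaustive,
                                          pair_differences, pairwise_ensemble,
                                          step3_similarity,
                                          step4_condition_differences)


def random_pairing(n_pairs=27, n_features=50, seed=0):
    rng = np.random.default_rng(seed)
    ids = [f"ID{i:02d}" for i in range(1, 2 * n_pairs + 1)]
    df = pd.DataFrame(rng.standard_normal((2 * n_pairs, n_features)), index=ids)
    pairs = pd.DataFrame({"case_id": ids,
                          "pair": [f"P{i // 2 + 1:02d}" for i in range(2 * n_pairs)]})
    return df, pairs


class TestPairDifferences:
    def test_27_unit_canonical_vectors_in_50d(self):
        df, pairs = random_pairing()
        st_ = studentize(FeatureMatrix(df))
        dvs = pair_differences(st_, pairs)
        assert dvs.vectors.shape == (27, 50)
        np.testing.assert_allclose(np.linalg.norm(dvs.vectors, axis=1), 1.0)
        # canonical polarity: first non-zero coordinate non-negative
        for row in dvs.vectors:
            nz = row[np.abs(row) > 1e-12]
            assert nz[0] >= 0

    def test_member_order_does_not_matter(self):
        df, pairs = random_pairing(n_pairs=3, n_features=4, seed=1)
        flipped = pairs.iloc[::-1].reset_index(drop=True)
        a = pair_differences(df, pairs)
        b = pair_differences(df, flipped)
        np.testing.assert_allclose(a.vectors, b.vectors, atol=1e-12)

    def test_identical_members_excluded_with_warning(self):
        df, pairs = random_pairing(n_pairs=3, n_features=4, seed=2)
        df.iloc[1] = df.iloc[0]
        with pytest.warns(UserWarning, match="identical members"):
            dvs = pair_differences(df, pairs)
        assert len(dvs) == 2


class TestMeanOrientation:
    def test_identical_vectors_goodness_one(self):
        u = np.tile([0.6, 0.8], (5, 1))
        out = mean_orientation(u)
        assert out.goodness == pytest.approx(1.0, abs=1e-12)
        assert abs(abs(out.vector @ [0.6, 0.8]) - 1.0) < 1e-12

    def test_one_dimensional_goodness_is_one(self):
        u = np.array([[1.0], [-2.0], [0.5]])
        assert mean_orientation(u).goodness == pytest.approx(1.0)

    def test_ascent_is_monotone(self):
        rng = np.random.default_rng(3)
        u = rng.standard_normal((10, 4))
        _, hist = mean_orientation(u, return_history=True)
        assert all(b >= a - 1e-12 for a, b in zip(hist, hist[1:]))

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        d = int(rng.integers(2, 5))
        u = rng.standard_normal((n, d))
        ours = mean_orientation(u, seed=seed).goodness
        oracle = mean_orientation_exhaustive(u).goodness
        assert ours == pytest.approx(oracle, abs=1e-9)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            mean_orientation(np.empty((0, 3)))


class TestHyperplane:
    def make_dvs(self, raw, ids=None):
        raw = np.asarray(raw, dtype=float)
        m = raw.shape[0]
        ids = ids or [(f"a{i}", f"b{i}") for i in range(m)]
        units = raw / np.linalg.norm(raw, axis=1, keepdims=True)
        return DifferenceVectorSet(units, raw, ids, [f"P{i}" for i in range(m)])

    def test_pair_members_always_opposite(self):
        rng = np.random.default_rng(4)
        dvs = self.make_dvs(rng.standard_normal((8, 5)))
        v = mean_orientation(dvs).vector
        sc = hyperplane_subcluster(dvs, v)
        idx = {e: i for i, e in enumerate(sorted(x for ab in dvs.members for x in ab))}
        for a, b in dvs.members:
            assert sc.labels[idx[a]] != sc.labels[idx[b]]

    def test_two_pairs_hand_geometry(self):
        # v ~ (1, 0): first members of both pairs project to opposite sides
        raw = np.array([[2.0, 0.1], [-2.0, 0.3]])
        dvs = self.make_dvs(raw, ids=[("a1", "a2"), ("b1", "b2")])
        sc = hyperplane_subcluster(dvs, np.array([1.0, 0.0]))
        idx = {e: i for i, e in enumerate(sorted(["a1", "a2", "b1", "b2"]))}
        assert sc.labels[idx["a1"]] == 1 and sc.labels[idx["a2"]] == 0
        assert sc.labels[idx["b1"]] == 0 and sc.labels[idx["b2"]] == 1

    def test_parallel_vectors_reproduce_consistent_split(self):
        raw = np.tile([1.0, 1.0], (4, 1)) + 0.01 * np.random.default_rng(5).standard_normal((4, 2))
        dvs = self.make_dvs(raw)
        v = mean_orientation(dvs).vector
        sc = hyperplane_subcluster(dvs, v)
        firsts = [sc.labels[i] for i, e in
                  enumerate(sorted(x for ab in dvs.members for x in ab)) if e.startswith("a")]
        assert len(set(firsts)) == 1  # all first members on the same side

    def test_non_unit_orientation_rejected(self):
        dvs = self.make_dvs(np.array([[1.0, 0.0]]))
        with pytest.raises(ValueError):
            hyperplane_subcluster(dvs, np.array([2.0, 0.0]))


class TestMcNormalization:
    def test_dim_one_is_identity(self):
        assert mc_normalize_goodness(0.7, 10, 1) == pytest.approx(0.7)

    def test_single_vector_expected_one(self):
        assert expected_random_goodness(1, 50) == 1.0

    def test_dim50_n27_bounds_and_determinism(self):
        e1 = expected_random_goodness(27, 50, reps=1000, seed=1)
        e2 = expected_random_goodness(27, 50, reps=1000, seed=1)
        assert e1 == e2
        assert 1 / np.sqrt(50) < e1 < 1.0


class TestStepEnsembles:
    def test_aligned_pairs_drive_block_structure(self):
        # all pair differences parallel to a common axis: the hyperplane
        # ensemble must split the two sides consistently
        rng = np.random.default_rng(6)
        n_pairs = 8
        base = rng.standard_normal((n_pairs, 6))
        rows, ids = [], []
        for p in range(n_pairs):
            rows.append(base[p] + 2.0 * np.eye(6)[0])
            rows.append(base[p] - 2.0 * np.eye(6)[0])
            ids += [f"a{p}", f"b{p}"]
        df = pd.DataFrame(np.vstack(rows), index=ids)
        pairs = pd.DataFrame({"case_id": ids,
                              "pair": [f"P{p}" for p in range(n_pairs) for _ in range(2)]})
        cfg = EnsembleConfig(subset_sizes=(2, 3), combinations=15, seed=7)
        coassoc = pairwise_ensemble(df.to_numpy(), ids, pairs, cfg)
        idx = {cid: i for i, cid in enumerate(ids)}
        a_rows = [idx[f"a{p}"] for p in range(n_pairs)]
        b_rows = [idx[f"b{p}"] for p in range(n_pairs)]
        within_a = coassoc.values[np.ix_(a_rows, a_rows)][~np.eye(n_pairs, dtype=bool)]
        cross = coassoc.values[np.ix_(a_rows, b_rows)][~np.eye(n_pairs, dtype=bool)]
        assert within_a.mean() > 0.8
        assert cross.mean() < 0.2
        # pair members never co-associate
        for p in range(n_pairs):
            assert coassoc.values[idx[f"a{p}"], idx[f"b{p}"]] == 0.0

    def test_step3_single_participant_degeneracy(self):
        df, pairs = random_pairing(n_pairs=3, n_features=6, seed=8)
        participants = pairs.assign(participant="S1")
        cfg = EnsembleConfig(subset_sizes=(2,), combinations=8, seed=9)
        a = pairwise_ensemble(df.to_numpy(), list(df.index), pairs, cfg)
        b = pairwise_ensemble(df.to_numpy(), list(df.index), pairs, cfg,
                              participants=participants)
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_step3_matrix_satisfies_invariants(self):
        df, pairs = random_pairing(n_pairs=6, n_features=8, seed=10)
        participants = pairs.assign(
            participant=[f"S{i // 4 + 1}" for i in range(12)])
        cfg = EnsembleConfig(subset_sizes=(2,), combinations=8, seed=11)
        m = step3_similarity(df, pairs, participants, cfg)
        assert np.allclose(m.values, m.values.T)
        assert np.allclose(np.diag(m.values), 1.0)
        assert m.values.min() >= 0 and m.values.max() <= 1


class TestStep4:
    def make_groups(self, n_parts=9, n_features=50, seed=12):
        rng = np.random.default_rng(seed)
        rows, recs = [], []
        for p in range(n_parts):
            for g in range(2):
                for c in range(3):
                    rows.append(rng.standard_normal(n_features))
                    recs.append({"case_id": f"c{p}_{g}_{c}",
                                 "participant": f"S{p + 1}",
                                 "participant_condition": f"G{2 * p + g + 1:02d}"})
        df = pd.DataFrame(np.vstack(rows), index=[r["case_id"] for r in recs])
        return df, pd.DataFrame(recs)

    def test_nine_unit_vectors(self):
        df, groups = self.make_groups()
        dvs = step4_condition_differences(df, groups)
        assert dvs.vectors.shape == (9, 50)
        np.testing.assert_allclose(np.linalg.norm(dvs.vectors, axis=1), 1.0)

    def test_group_swap_invariance(self):
        df, groups = self.make_groups(n_parts=2, n_features=5, seed=13)
        swapped = groups.copy()
        m = swapped["participant"] == "S1"
        swapped.loc[m, "participant_condition"] = \
            swapped.loc[m, "participant_condition"].map({"G01": "G02", "G02": "G01"})
        a = step4_condition_differences(df, groups)
        b = step4_condition_differences(df, swapped)
        np.testing.assert_allclose(np.abs(a.vectors), np.abs(b.vectors), atol=1e-12)

    def test_zero_group_difference_excluded(self):
        df, groups = self.make_groups(n_parts=2, n_features=5, seed=14)
        g2 = groups.loc[groups["participant"] == "S2"]
        ids_a = g2.loc[g2["participant_condition"] == "G03", "case_id"].tolist()
        ids_b = g2.loc[g2["participant_condition"] == "G04", "case_id"].tolist()
        df.loc[ids_b] = df.loc[ids_a].to_numpy()
        with pytest.warns(UserWarning, match="zero group difference"):
            dvs = step4_condition_differences(df, groups)
        assert len(dvs) == 1

    def test_wrong_group_size_rejected(self):
        df, groups = self.make_groups(n_parts=2, n_features=5, seed=15)
        with pytest.raises(ValueError, match="3"):
            step4_condition_differences(df.iloc[1:], groups.iloc[1:])
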