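"""Consensus clustering: matrix invariants, k selection, assignment, labeling."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from oxphos.consensus import (
    HIGH_OXPHOS,
    LOW_OXPHOS,
    assign_clusters,
    consensus_matrix,
    label_oxphos,
    pac_score,
    select_k,
    ward_order,
)
from oxphos.prep import ProteinMatrix


def blobs(sizes, sep, dim=5, seed=0):
    rng = np.random.default_rng(seed)
    parts, labels = [], []
    for i, n in enumerate(sizes):
        center = np.zeros(dim)
        center[i % dim] = i * sep
        parts.append(rng.normal(center, 1.0, size=(n, dim)))
        labels += [i] * n
    return np.vstack(parts), np.array(labels)


class TestConsensusMatrix:
    def test_invariants_on_degenerate_input(self):
        x = np.zeros((6, 3))  # identical points
        cons, counts = consensus_matrix(x, k=2, iterations=30, rng=np.random.default_rng(0))
        assert np.allclose(cons, cons.T)
        assert np.allclose(np.diag(cons), 1.0)
        assert ((cons >= 0) & (cons <= 1)).all()
        assert counts.max() <= 30

    def test_full_resampling_separated_data_is_binary(self):
        x, _ = blobs([10, 10], sep=50, seed=1)
        cons, _ = consensus_matrix(
            x, k=2, iterations=20, resample_fraction=1.0, rng=np.random.default_rng(1)
        )
        assert set(np.round(np.unique(cons), 12)) <= {0.0, 1.0}

    def test_two_blobs_within_vs_between(self):
        x, labels = blobs([15, 15], sep=10, seed=2)
        cons, _ = consensus_matrix(x, k=2, iterations=200, rng=np.random.default_rng(2))
        same = labels[:, None] == labels[None, :]
        off = ~np.eye(len(labels), dtype=bool)
        assert cons[same & off].min() >= 0.99
        assert cons[~same].max() <= 0.01

    def test_k_must_fit_subsample(self):
        x = np.random.default_rng(0).normal(size=(5, 2))
        with pytest.raises(ValueError, match="subsample"):
            consensus_matrix(x, k=4, iterations=5, resample_fraction=0.8)


class TestAssignClusters:
    def test_block_diagonal_exact_recovery(self):
        cons = np.zeros((8, 8))
        cons[:5, :5] = 1.0
        cons[5:, 5:] = 1.0
        labels = assign_clusters(cons, 2)
        assert len(set(labels[:5])) == 1
        assert len(set(labels[5:])) == 1
        assert labels[0] != labels[6]
        assert (labels[:5] == 0).all()  # larger block gets label 0

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        cons = np.zeros((10, 10))
        cons[:6, :6] = 1.0
        cons[6:, 6:] = 1.0
        perm = rng.permutation(10)
        base = assign_clusters(cons, 2)
        permuted = assign_clusters(cons[np.ix_(perm, perm)], 2)
        assert (permuted == base[perm]).all()

    def test_noisy_two_block_recovery(self):
        rng = np.random.default_rng(4)
        truth = np.array([0] * 12 + [1] * 8)
        cons = (truth[:, None] == truth[None, :]).astype(float)
        flip = rng.random((20, 20)) < 0.05
        flip = np.triu(flip, 1)
        cons = np.clip(cons + (flip + flip.T) * rng.choice([-1.0, 1.0]), 0, 1)
        np.fill_diagonal(cons, 1.0)
        labels = assign_clusters(cons, 2)
        assert adjusted_rand_score(truth, labels) >= 0.9

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(ValueError):
            assign_clusters(np.eye(3), 4)


class TestSelectK:
    @staticmethod
    def run_selection(sizes, sep, seed, k_range=range(2, 6)):
        x, labels = blobs(sizes, sep=sep, seed=seed)
        rng = np.random.default_rng(seed)
        by_k = {
            k: consensus_matrix(x, k, iterations=100, rng=rng)[0] for k in k_range
        }
        return select_k(by_k), labels, by_k

    def test_two_separated_groups_select_two(self):
        (chosen, area, delta, pac, low_conf), _, _ = self.run_selection([20, 25], 10, seed=5)
        assert chosen == 2
        assert not low_conf
        assert pac[2] <= 0.01

    def test_three_separated_groups_select_three(self):
        (chosen, *_), _, _ = self.run_selection([15, 15, 15], 12, seed=6)
        assert chosen == 3

    def test_structureless_data_flagged_low_confidence(self):
        x = np.random.default_rng(7).normal(size=(40, 5))
        rng = np.random.default_rng(7)
        by_k = {k: consensus_matrix(x, k, iterations=60, rng=rng)[0] for k in range(2, 5)}
        *_, pac, low_conf = select_k(by_k)
        assert low_conf
        assert min(pac.values()) > 0.2

    def test_degenerate_matrices_return_smallest_k(self):
        ones = np.ones((6, 6))
        with pytest.warns(UserWarning, match="degenerate"):
            chosen, *_ = select_k({2: ones.copy(), 3: ones.copy()})
        assert chosen == 2

    def test_delta_area_diagnostics_monotone_area(self):
        (chosen, area, delta, *_), _, _ = self.run_selection([20, 20], 10, seed=8)
        ks = sorted(area)
        assert all(area[a] <= area[b] + 1e-9 for a, b in zip(ks, ks[1:]))
        assert delta[ks[0]] == pytest.approx(area[ks[0]])


class TestPac:
    def test_binary_matrix_has_zero_pac(self):
        cons = np.zeros((6, 6))
        cons[:3, :3] = 1.0
        cons[3:, 3:] = 1.0
        assert pac_score(cons) == 0.0

    def test_half_consensus_is_fully_ambiguous(self):
        cons = np.full((6, 6), 0.5)
        np.fill_diagonal(cons, 1.0)
        assert pac_score(cons) == 1.0


class TestLabelOxphos:
    def test_higher_mean_cluster_is_high(self):
        labels = np.array([0, 0, 1, 1])
        scores = pd.Series([-0.5, -0.5, 0.5, 0.5], index=list("abcd"))
        out = label_oxphos(labels, scores)
        assert out.labels.tolist() == [LOW_OXPHOS, LOW_OXPHOS, HIGH_OXPHOS, HIGH_OXPHOS]
        assert out.cluster_scores == {0: -0.5, 1: 0.5}

    def test_tie_labels_smaller_cluster_high_with_warning(self):
        labels = np.array([0, 0, 0, 1, 1])
        scores = pd.Series([1.0] * 5, index=list("abcde"))
        with pytest.warns(UserWarning, match="equal cluster means"):
            out = label_oxphos(labels, scores)
        assert (out.labels[labels == 1] == HIGH_OXPHOS).all()

    def test_requires_two_clusters(self):
        with pytest.raises(ValueError):
            label_oxphos(np.array([0, 1, 2]), pd.Series([1.0, 2.0, 3.0]))


def naive_ward(x):
    """Lance-Williams Ward linkage, O(n^3), for cross-checking merge heights."""
    n = x.shape[0]
    active = {i: (x[i : i + 1].mean(axis=0), 1) for i in range(n)}
    d = {
        (i, j): np.sum((x[i] - x[j]) ** 2) ** 0.5
        for i in range(n)
        for j in range(i + 1, n)
    }
    heights = []
    sizes = {i: 1 for i in range(n)}
    dist = {k: v for k, v in d.items()}
    clusters = list(range(n))
    next_id = n
    while len(clusters) > 1:
        (i, j), h = min(dist.items(), key=lambda kv: kv[1])
        heights.append(h)
        merged = next_id
        next_id += 1
        sizes[merged] = sizes[i] + sizes[j]
        new_dist = {}
        for k in clusters:
            if k in (i, j):
                continue
            dik = dist[tuple(sorted((i, k)))]
            djk = dist[tuple(sorted((j, k)))]
            dij = dist[tuple(sorted((i, j)))]
            si, sj, sk = sizes[i], sizes[j], sizes[k]
            s = si + sj + sk
            val = np.sqrt(
                ((si + sk) * dik**2 + (sj + sk) * djk**2 - sk * dij**2) / s
            )
            new_dist[tuple(sorted((merged, k)))] = val
        clusters = [k for k in clusters if k not in (i, j)] + [merged]
        dist = {
            k: v
            for k, v in dist.items()
            if i not in k and j not in k
        }
        dist.update(new_dist)
    return sorted(heights)


class TestWardOrder:
    @staticmethod
    def matrix_from(x):
        values = pd.DataFrame(x, index=[f"s{i}" for i in range(len(x))])
        values.columns = [f"P{j}" for j in range(x.shape[1])]
        return ProteinMatrix(values, pd.Series(["r"] * len(x), index=values.index))

    def test_identical_samples_merge_first_at_zero(self):
        x = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0]])
        tree, order = ward_order(self.matrix_from(x))
        assert tree[0, 2] == 0.0
        assert set(tree[0, :2].astype(int)) == {0, 1}

    def test_collinear_points_first_merge(self):
        x = np.array([[0.0], [1.0], [10.0]])
        tree, _ = ward_order(self.matrix_from(x))
        assert set(tree[0, :2].astype(int)) == {0, 1}

    def test_merge_heights_match_naive_ward(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(8, 5))
        tree, order = ward_order(self.matrix_from(x))
        assert sorted(tree[:, 2]) == pytest.approx(naive_ward(x), rel=1e-9)
        assert sorted(order) == list(range(8))

    def test_missing_values_imputed(self):
        x = np.array([[0.0, 1.0], [np.nan, 1.0], [5.0, 6.0]])
        tree, order = ward_order(self.matrix_from(x))
        assert len(order) == 3
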