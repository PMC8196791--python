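"""K-means categorization, internal validity indices and group profiles."""

import itertools

import numpy as np
import pytest
from scipy.spatial.distance import cdist
from sklearn.metrics import adjusted_rand_score

from cgmcoda.clustering import (
    LETTERS_6H,
    LETTERS_24H,
    calinski_harabasz,
    dunn,
    expected_minutes,
    fold_change,
    group_log_ratio_profile,
    kmeans_coords,
    select_k,
    silhouette,
)
from cgmcoda.coordinates import clr_transform, compositional_center


def planted_coords(rng, centers, n_per, scale=1.0):
    X = np.vstack([rng.normal(c, scale, size=(n_per, len(c))) for c in centers])
    labels = np.repeat(np.arange(len(centers)), n_per)
    return X, labels


class TestKMeans:
    def test_k1_center_is_mean(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 4))
        model = kmeans_coords(X, 1, seed=0)
        assert set(model.labels) == {0}
        np.testing.assert_allclose(model.centers[0], X.mean(axis=0), rtol=1e-10)

    def test_planted_clusters_recovered_perfectly(self):
        rng = np.random.default_rng(1)
        X, truth = planted_coords(rng, [np.zeros(4), np.full(4, 10.0)], 40)
        model = kmeans_coords(X, 2, seed=3)
        assert adjusted_rand_score(truth, model.labels) == 1.0

    def test_same_seed_reproducible(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 4))
        a = kmeans_coords(X, 3, seed=11)
        b = kmeans_coords(X, 3, seed=11)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert a.inertia == b.inertia

    def test_more_restarts_never_worse(self):
        rng = np.random.default_rng(3)
        X, _ = planted_coords(rng, [np.zeros(4), np.full(4, 6.0), -np.full(4, 6.0)], 20)
        few = kmeans_coords(X, 3, n_init=1, seed=5)
        many = kmeans_coords(X, 3, n_init=25, seed=5)
        assert many.inertia <= few.inertia + 1e-9

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            kmeans_coords(np.zeros((3, 4)), 5)


def brute_force_indices(X, labels):
    """O(n^2) reference for CH, Dunn and silhouette on tiny fixtures."""
    n = len(X)
    clusters = {g: np.flatnonzero(labels == g) for g in np.unique(labels)}
    k = len(clusters)
    grand = X.mean(axis=0)
    wss = sum(((X[idx] - X[idx].mean(axis=0)) ** 2).sum() for idx in clusters.values())
    bss = sum(len(idx) * ((X[idx].mean(axis=0) - grand) ** 2).sum()
              for idx in clusters.values())
    ch = (bss / (k - 1)) / (wss / (n - k))

    d = cdist(X, X)
    inter = min(d[i, j] for gi, gj in itertools.combinations(clusters.values(), 2)
                for i in gi for j in gj)
    diam = max((d[i, j] for idx in clusters.values()
                for i in idx for j in idx), default=0.0)
    dn = inter / diam

    sil = []
    for i in range(n):
        own = clusters[labels[i]]
        if len(own) == 1:
            sil.append(0.0)
            continue
        a = d[i, [j for j in own if j != i]].mean()
        b = min(d[i, idx].mean() for g, idx in clusters.items() if g != labels[i])
        sil.append((b - a) / max(a, b))
    return ch, dn, float(np.mean(sil))


class TestValidityIndices:
    def test_dunn_on_hand_fixture(self):
        X = np.array([[0.0], [0.1], [10.0], [10.1]])
        labels = np.array([0, 0, 1, 1])
        assert dunn(X, labels) == pytest.approx(9.9 / 0.1, rel=1e-12)

    def test_silhouette_on_hand_fixture(self):
        X = np.array([[0.0], [0.1], [10.0], [10.1]])
        labels = np.array([0, 0, 1, 1])
        # inner point: a=0.1, b=(9.9+10)/2; outer point: a=0.1, b=(10+10.1)/2
        expected = (1 - 0.1 / 9.95 + 1 - 0.1 / 10.05) / 2
        assert silhouette(X, labels) == pytest.approx(expected, rel=1e-10)

    def test_single_cluster_rejected(self):
        X = np.array([[0.0], [0.1], [10.0], [10.1]])
        for index in (calinski_harabasz, dunn, silhouette):
            with pytest.raises(ValueError):
                index(X, np.zeros(4, dtype=int))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_all_indices_match_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(18, 3))
        labels = rng.integers(0, 3, size=18)
        while len(np.unique(labels)) < 3:
            labels = rng.integers(0, 3, size=18)
        ch, dn, sil = brute_force_indices(X, labels)
        assert calinski_harabasz(X, labels) == pytest.approx(ch, abs=1e-10, rel=1e-10)
        assert dunn(X, labels) == pytest.approx(dn, abs=1e-10, rel=1e-10)
        assert silhouette(X, labels) == pytest.approx(sil, abs=1e-10, rel=1e-10)

    def test_select_k_optimal_at_true_k(self):
        rng = np.random.default_rng(9)
        centers = [np.zeros(4), np.full(4, 8.0), np.array([8.0, -8, 0, 0])]
        X, _ = planted_coords(rng, centers, 30, scale=0.5)
        table = select_k(X, [2, 3, 4, 5], seed=0)
        assert table.shape[0] == 4
        for col in ("calinski_harabasz", "dunn", "silhouette"):
            assert table.loc[table[col].idxmax(), "k"] == 3
        past = table[table.k > 3].dunn.to_numpy()
        assert np.all(past < table.loc[table.k == 3, "dunn"].item())

    def test_select_k_single_row(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(20, 4))
        table = select_k(X, [2], seed=0)
        assert list(table.k) == [2]


class TestGroupProfile:
    def test_single_group_log_ratios_zero(self):
        rng = np.random.default_rng(11)
        X = rng.dirichlet(np.ones(5), size=8) * 1440
        prof = group_log_ratio_profile(X, np.zeros(8, dtype=int), C=1440.0)
        np.testing.assert_allclose(prof.log_ratios.to_numpy(), 0.0, atol=1e-12)

    def test_exp_consistency_identity(self):
        rng = np.random.default_rng(12)
        X = rng.dirichlet(np.ones(5), size=20) * 1440
        labels = rng.integers(0, 3, size=20)
        prof = group_log_ratio_profile(X, labels, C=1440.0)
        overall = np.asarray(prof.overall_center)
        for g in prof.groups:
            recon = overall * np.exp(prof.log_ratios.loc[g].to_numpy())
            np.testing.assert_allclose(recon, prof.centers.loc[g].to_numpy(),
                                       rtol=1e-9)

    def test_overall_clr_is_mean_of_row_clrs(self):
        rng = np.random.default_rng(13)
        X = rng.dirichlet(np.ones(5), size=15) * 1440
        center = compositional_center(X, 1440.0)
        np.testing.assert_allclose(
            clr_transform(np.asarray(center)), clr_transform(X).mean(axis=0),
            atol=1e-10,
        )

    def test_fold_change_interpretation(self):
        # a log-ratio of 4.12 on a 0.6-min overall part reads as ~61-fold
        # (the log-ratio itself is printed rounded, hence the unit band),
        # i.e. roughly 37 minutes in that range for the group
        assert float(fold_change(4.12)) == pytest.approx(61, abs=1)
        assert round(float(expected_minutes(0.6, 4.12))) == 37

    def test_label_length_mismatch_rejected(self):
        X = np.ones((4, 5))
        with pytest.raises(ValueError):
            group_log_ratio_profile(X, np.array([0, 0, 1]))


class TestLetterAssignment:
    def test_letters_sorted_by_first_balance(self):
        centers = np.array([[-5.0, 0, 0, 0], [2.0, 0, 0, 0], [-1.0, 0, 0, 0]])
        model = kmeans_coords(
            np.repeat(centers, 5, axis=0) , 3, seed=0
        )
        m = model.letter_map(LETTERS_24H)
        ordered = [m[int(np.argmin(np.abs(model.centers[:, 0] - v)))]
                   for v in (2.0, -1.0, -5.0)]
        assert ordered == ["V", "W", "X"]

    def test_too_few_letters_rejected(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(30, 4)) + np.repeat(np.arange(5)[:, None] * 10, 6, axis=0)
        model = kmeans_coords(X, 5, seed=0)
        with pytest.raises(ValueError):
            model.letter_map(LETTERS_6H)
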