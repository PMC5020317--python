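"""Normalisation, clustering, silhouette and k-selection behaviour."""

import itertools

import numpy as np
import pandas as pd
import pytest

from citrec.engagement import METRIC_COLUMNS
from citrec.profiling import (
    EngagementProfiler,
    average_silhouette_width,
    kmeans_profiles,
    metric_correlations,
    normalize_metrics,
    select_k,
    ward_tree,
)


def _metrics_frame(X):
    return pd.DataFrame(np.asarray(X, float), columns=METRIC_COLUMNS)


class TestNormalize:
    def test_minmax_scaling(self):
        df = _metrics_frame(np.tile([[2.0], [4.0], [6.0]], (1, 4)))
        out = normalize_metrics(df)
        assert np.allclose(out[:, 0], [0, 0.5, 1])

    def test_constant_column_maps_to_zero_with_warning(self):
        X = np.tile([[2.0], [4.0], [6.0]], (1, 4))
        X[:, 2] = 5.0
        with pytest.warns(UserWarning, match="constant metric"):
            out = normalize_metrics(_metrics_frame(X))
        assert (out[:, 2] == 0).all()

    def test_unit_range_column_unchanged(self):
        X = np.tile(np.array([[0.0], [0.25], [1.0]]), (1, 4))
        assert np.allclose(normalize_metrics(_metrics_frame(X)), X)

    def test_single_volunteer_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            normalize_metrics(_metrics_frame([[1, 1, 1, 1]]))


def _best_two_partition_wss(X):
    """Exhaustive search over all 2-partitions (oracle for small n)."""
    n = len(X)
    best, best_labels = np.inf, None
    for assign in itertools.product([0, 1], repeat=n - 1):
        labels = np.array((0,) + assign)
        if len(set(labels)) < 2:
            continue
        wss = sum(
            ((X[labels == g] - X[labels == g].mean(axis=0)) ** 2).sum()
            for g in (0, 1)
        )
        if wss < best:
            best, best_labels = wss, labels
    return best, best_labels


class TestWard:
    def test_two_separated_clouds_split_first(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 0.05, (4, 2)), rng.normal(3, 0.05, (4, 2))])
        from scipy.cluster.hierarchy import fcluster

        Z, wss = ward_tree(X, k_max=4)
        labels = fcluster(Z, t=2, criterion="maxclust")
        planted = np.array([1] * 4 + [2] * 4)
        assert (labels == planted).all() or (labels == 3 - planted).all()
        # the cut at k=2 achieves the exhaustive-search optimum
        best, _ = _best_two_partition_wss(X)
        got = wss[2]
        assert got == pytest.approx(best)

    def test_wss_at_one_is_total_sum_of_squares(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 3))
        _, wss = ward_tree(X, k_max=3)
        assert wss[1] == pytest.approx(((X - X.mean(axis=0)) ** 2).sum())

    def test_two_points(self):
        _, wss = ward_tree(np.array([[0.0, 0.0], [1.0, 1.0]]), k_max=2)
        assert wss[2] == pytest.approx(0.0)

    def test_wss_non_increasing_in_k(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 4))
        _, wss = ward_tree(X, k_max=8)
        vals = [wss[k] for k in sorted(wss)]
        assert all(a >= b - 1e-9 for a, b in zip(vals, vals[1:]))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            ward_tree(np.array([[np.nan, 0.0], [1.0, 1.0]]))


class TestKMeans:
    def test_one_dimensional_pairs(self):
        X = np.array([[0.0], [0.01], [0.99], [1.0]])
        labels, centers = kmeans_profiles(X, 2, seed=0)
        assert labels[0] == labels[1] and labels[2] == labels[3]
        assert labels[0] != labels[2]
        # exhaustive check: this is the optimal 2-partition
        best, best_labels = _best_two_partition_wss(X)
        assert (labels == best_labels).all() or (labels == 1 - best_labels).all()

    def test_k_equals_n_gives_zero_wss(self):
        X = np.arange(8, dtype=float).reshape(4, 2)
        labels, centers = kmeans_profiles(X, 4, seed=0)
        assert len(set(labels)) == 4
        assert np.allclose(sorted(centers.tolist()), sorted(X.tolist()))

    def test_duplicated_dataset_same_centroids(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(0, 0.1, (10, 2)), rng.normal(5, 0.1, (10, 2))])
        _, c1 = kmeans_profiles(X, 2, seed=0)
        _, c2 = kmeans_profiles(np.vstack([X, X]), 2, seed=0)
        assert np.allclose(sorted(c1.tolist()), sorted(c2.tolist()), atol=1e-8)

    def test_k_too_large_raises(self):
        with pytest.raises(ValueError):
            kmeans_profiles(np.zeros((3, 2)), 4)


def _silhouette_by_hand(X, labels):
    n = len(X)
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    scores = []
    for i in range(n):
        same = (labels == labels[i]) & (np.arange(n) != i)
        if not same.any():
            scores.append(0.0)
            continue
        a = D[i, same].mean()
        b = min(
            D[i, labels == other].mean()
            for other in set(labels)
            if other != labels[i]
        )
        scores.append((b - a) / max(a, b))
    return float(np.mean(scores))


class TestSilhouette:
    def test_matches_hand_formula(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 3))
        labels = rng.integers(0, 3, size=30)
        while len(set(labels)) < 3:
            labels = rng.integers(0, 3, size=30)
        assert average_silhouette_width(X, labels) == pytest.approx(
            _silhouette_by_hand(X, labels)
        )

    def test_two_far_tight_pairs(self):
        X = np.array([[0.0], [1.0], [1000.0], [1001.0]])
        labels = np.array([0, 0, 1, 1])
        assert average_silhouette_width(X, labels) >= 0.99

    def test_random_labels_on_blob_near_zero(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(200, 4))
        labels = rng.integers(0, 2, size=200)
        assert abs(average_silhouette_width(X, labels)) < 0.1

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            average_silhouette_width(np.zeros((4, 2)), np.zeros(4, dtype=int))


class TestSelectK:
    def _cluster_curves(self, X, k_range=range(2, 9)):
        _, wss = ward_tree(X, k_max=max(k_range) + 1)
        asw = {}
        for k in k_range:
            labels, _ = kmeans_profiles(X, k, seed=0)
            asw[k] = average_silhouette_width(X, labels)
        return wss, asw

    def test_three_separated_archetypes_select_three(self):
        rng = np.random.default_rng(7)
        X = np.vstack(
            [rng.normal(c, 0.03, (60, 4)) for c in (0.1, 0.5, 0.9)]
        )
        wss, asw = self._cluster_curves(X)
        assert select_k(wss, asw) == 3
        assert select_k(wss, asw, policy="argmax") == 3

    def test_single_blob_rejected_at_default_threshold(self):
        rng = np.random.default_rng(8)
        X = rng.normal(0.5, 0.1, (150, 4))
        wss, asw = self._cluster_curves(X)
        assert select_k(wss, asw) is None

    def test_threshold_minus_one_argmax_always_returns(self):
        rng = np.random.default_rng(9)
        X = rng.normal(0.5, 0.1, (80, 4))
        wss, asw = self._cluster_curves(X)
        k = select_k(wss, asw, threshold=-1, policy="argmax")
        assert k == max(asw, key=asw.get)


def _spearman_no_ties_oracle(x, y):
    """rho = 1 - 6 sum d^2 / (n (n^2 - 1)), valid without ties."""
    rx = np.argsort(np.argsort(x))
    ry = np.argsort(np.argsort(y))
    d = rx - ry
    n = len(x)
    return 1 - 6 * (d**2).sum() / (n * (n**2 - 1))


class TestCorrelations:
    def test_monotone_pairs(self):
        df = _metrics_frame(
            np.column_stack(
                [np.arange(5), np.arange(5) ** 2, 5 - np.arange(5), np.ones(5)]
            )
        )
        rho, p = metric_correlations(df)
        assert rho.iloc[0, 1] == pytest.approx(1.0)
        assert rho.iloc[0, 2] == pytest.approx(-1.0)
        assert np.isnan(rho.iloc[0, 3])  # constant column

    def test_matches_bruteforce_rank_formula(self):
        rng = np.random.default_rng(10)
        x = rng.permutation(20).astype(float)
        y = rng.normal(size=20)
        df = _metrics_frame(
            np.column_stack([x, y, rng.normal(size=20), rng.normal(size=20)])
        )
        rho, _ = metric_correlations(df)
        assert rho.iloc[0, 1] == pytest.approx(_spearman_no_ties_oracle(x, y))


class TestProfilerPipeline:
    def _cohort(self, seed=0, n=120):
        rng = np.random.default_rng(seed)
        centers = {
            "lo": [5, 0.9, 0.02, 0.8],
            "mid": [50, 0.5, 0.1, 1.0],
            "hi": [900, 0.2, 0.5, 3.0],
        }
        rows, planted = [], []
        for name, c in centers.items():
            for _ in range(n // 3):
                rows.append(
                    [
                        max(1, rng.normal(c[0], c[0] * 0.05)),
                        np.clip(rng.normal(c[1], 0.01), 0.01, 1),
                        np.clip(rng.normal(c[2], 0.005), 0.001, 1),
                        max(0.01, rng.normal(c[3], 0.05)),
                    ]
                )
                planted.append(name)
        df = _metrics_frame(rows)
        df["single_day_flag"] = False
        return df, planted

    def test_three_profiles_named_by_ascending_observations(self):
        df, planted = self._cohort()
        res = EngagementProfiler(df).fit(seed=0)
        assert res.k == 3
        assert res.profile_names == ["dabbler", "steady", "enthusiast"]
        raw = res.centroids_raw["n_observations"]
        assert raw["dabbler"] < raw["steady"] < raw["enthusiast"]

    def test_deterministic_given_seed(self):
        df, _ = self._cohort()
        r1 = EngagementProfiler(df).fit(seed=11)
        r2 = EngagementProfiler(df).fit(seed=11)
        assert (r1.assignments == r2.assignments).all()
        assert r1.asw == r2.asw
        assert r1.diagnostics() == r2.diagnostics()

    def test_planted_partition_beats_random_relabelings(self):
        df, planted = self._cohort()
        X = normalize_metrics(df)
        codes = pd.Categorical(planted).codes
        planted_asw = average_silhouette_width(X, codes)
        rng = np.random.default_rng(12)
        for _ in range(100):
            perm = rng.permutation(codes)
            assert planted_asw >= average_silhouette_width(X, perm)

    def test_summary_percentages_sum_to_100(self):
        df, _ = self._cohort()
        res = EngagementProfiler(df).fit(seed=0)
        s = res.summary()
        assert abs(s["percent_volunteers"].sum() - 100) <= 2  # rounding slack
        assert s["n_volunteers"].sum() == len(df)

    def test_forced_k_one_cluster_rejected(self):
        df, _ = self._cohort()
        with pytest.raises(ValueError):
            EngagementProfiler(df, k_range=range(1, 2))
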