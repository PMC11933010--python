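"""Subsampling stability tests: JSC, co-association, matching checks."""
import numpy as np
import pandas as pd
import pytest

from colliclust import featcluster as fc
from colliclust import stability as st


def blobs(K=3, n_per=30, sep=8.0, seed=0, d=3):
    rng = np.random.default_rng(seed)
    means = rng.normal(0, sep, (K, d))
    X = np.vstack([rng.normal(m, 1.0, (n_per, d)) for m in means])
    return X, np.repeat(np.arange(K), n_per)


def brute_force_jsc(full_labels, subsets):
    """Independent oracle: exhaustive set arithmetic with python sets."""
    out = {}
    for c in np.unique(full_labels):
        vals = []
        for sub in subsets:
            members_full = {i for i in sub.indices if full_labels[i] == c}
            if not members_full:
                continue
            best = 0.0
            for cs in np.unique(sub.labels):
                members_sub = {i for i, lab in zip(sub.indices, sub.labels)
                               if lab == cs}
                inter = len(members_full & members_sub)
                union = len(members_full | members_sub)
                best = max(best, inter / union)
            vals.append(best)
        out[int(c)] = np.mean(vals) if vals else np.nan
    return out


def brute_force_cam(subsets, n):
    """Independent oracle: per-pair counting loops."""
    cam = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(n):
            co, tot = 0, 0
            for sub in subsets:
                pos = {idx: lab for idx, lab in zip(sub.indices, sub.labels)}
                if i in pos and j in pos:
                    tot += 1
                    co += pos[i] == pos[j]
            if tot:
                cam[i, j] = co / tot
    return cam


class TestSubsample:
    def test_full_fraction_reproduces_full_fit(self):
        X, _ = blobs(seed=1)
        full = fc.fit_gmm(X, 3, n_init=3, seed=18)
        subs = st.subsample_clusterings(X, 3, fraction=1.0, n_subsets=1,
                                        seed=1, n_init=3)
        # identical data at the same K: same partition up to label names
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(full.labels, subs[0].labels) == 1.0

    def test_subset_sizes(self):
        X, _ = blobs(seed=2)
        subs = st.subsample_clusterings(X, 3, fraction=0.9, n_subsets=5,
                                        seed=0)
        m = int(np.floor(0.9 * len(X)))
        assert all(len(s.indices) == m for s in subs)

    def test_disjoint_blobs_match_planted_partition(self):
        X, labels = blobs(sep=12.0, seed=3)
        subs = st.subsample_clusterings(X, 3, n_subsets=5, seed=0)
        from sklearn.metrics import adjusted_rand_score

        for sub in subs:
            assert adjusted_rand_score(labels[sub.indices], sub.labels) == 1.0

    def test_subset_smaller_than_k_rejected(self):
        X, _ = blobs(n_per=2, seed=4)
        with pytest.raises(ValueError):
            st.subsample_clusterings(X, 5, fraction=0.5, n_subsets=1)


class TestJaccard:
    def test_identical_partitions_unity(self):
        labels = np.repeat([0, 1, 2], 10)
        subs = [st.SubsetClustering(np.arange(30), labels.copy())]
        jsc = st.jaccard_stability(labels, subs)
        np.testing.assert_allclose(jsc.jsc_mean, 1.0)

    def test_even_split_gives_half(self):
        labels = np.zeros(100, dtype=int)
        split = np.repeat([0, 1], 50)
        subs = [st.SubsetClustering(np.arange(100), split)]
        jsc = st.jaccard_stability(labels, subs)
        assert jsc.jsc_mean[0] == pytest.approx(0.5)

    def test_matches_brute_force_on_random_partitions(self):
        rng = np.random.default_rng(5)
        n = 20
        full = rng.integers(0, 3, n)
        subs = []
        for j in range(6):
            idx = np.sort(rng.choice(n, 15, replace=False))
            subs.append(st.SubsetClustering(idx, rng.integers(0, 3, 15)))
        ours = st.jaccard_stability(full, subs)
        oracle = brute_force_jsc(full, subs)
        for row in ours.itertuples():
            assert row.jsc_mean == pytest.approx(oracle[row.cluster],
                                                 abs=1e-12)

    def test_monotone_under_label_noise(self):
        X, labels = blobs(sep=12.0, seed=6)
        rng = np.random.default_rng(0)
        means = []
        for noise in (0.0, 0.2, 0.5):
            subs = []
            for j in range(5):
                idx = np.sort(rng.choice(len(X), 81, replace=False))
                lab = labels[idx].copy()
                flip = rng.random(len(lab)) < noise
                lab[flip] = rng.integers(0, 3, flip.sum())
                subs.append(st.SubsetClustering(idx, lab))
            means.append(st.jaccard_stability(labels, subs).jsc_mean.mean())
        assert means[0] > means[1] > means[2]

    def test_stability_gate_on_separated_session(self):
        X, labels = blobs(K=4, n_per=40, sep=10.0, seed=7)
        full = fc.fit_gmm(X, 4, n_init=3, seed=0)
        subs = st.subsample_clusterings(X, 4, n_subsets=20, seed=1)
        jsc = st.jaccard_stability(full.labels, subs)
        assert jsc.jsc_mean.min() >= 0.5
        assert jsc.stable.all()


class TestCoassociation:
    def test_always_together_is_one(self):
        labels = np.zeros(4, dtype=int)
        subs = [st.SubsetClustering(np.arange(4), labels)] * 3
        cam, counts, _ = st.coassociation(subs, 4)
        np.testing.assert_allclose(cam, 1.0)

    def test_partial_cooccurrence_count(self):
        # pair (0, 1) co-sampled 4 times, co-clustered once
        subs = []
        for j in range(4):
            lab = np.array([0, 0 if j == 0 else 1])
            subs.append(st.SubsetClustering(np.array([0, 1]), lab))
        cam, counts, _ = st.coassociation(subs, 2)
        assert counts[0, 1] == 4
        assert cam[0, 1] == pytest.approx(0.25)

    def test_never_cosampled_flagged(self):
        subs = [st.SubsetClustering(np.array([0]), np.array([0])),
                st.SubsetClustering(np.array([1]), np.array([0]))]
        cam, counts, _ = st.coassociation(subs, 2)
        assert np.isnan(cam[0, 1]) and counts[0, 1] == 0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(8)
        n = 12
        subs = []
        for j in range(5):
            idx = np.sort(rng.choice(n, 9, replace=False))
            subs.append(st.SubsetClustering(idx, rng.integers(0, 3, 9)))
        cam, _, _ = st.coassociation(subs, n)
        oracle = brute_force_cam(subs, n)
        np.testing.assert_allclose(cam, oracle, equal_nan=True)

    def test_symmetric_in_unit_range(self):
        rng = np.random.default_rng(9)
        subs = []
        for j in range(8):
            idx = np.sort(rng.choice(30, 24, replace=False))
            subs.append(st.SubsetClustering(idx, rng.integers(0, 4, 24)))
        cam, _, _ = st.coassociation(subs, 30)
        valid = np.isfinite(cam)
        assert np.all(cam[valid] >= 0.0) and np.all(cam[valid] <= 1.0)
        np.testing.assert_allclose(cam, cam.T, equal_nan=True)

    def test_between_rate_identity_on_disjoint_blobs(self):
        X, labels = blobs(sep=12.0, seed=10)
        subs = st.subsample_clusterings(X, 3, n_subsets=10, seed=2)
        _, _, rate = st.coassociation(subs, len(X), labels)
        assert np.nanmin(np.diag(rate)) > 0.95
        off = rate[~np.eye(3, dtype=bool)]
        assert np.nanmax(off) < 0.05


class TestMatchingAndDistances:
    def test_matching_permutation_invariant(self):
        rng = np.random.default_rng(11)
        full = rng.integers(0, 3, 40)
        idx = np.arange(40)
        labels = rng.integers(0, 3, 40)
        m1 = st.match_clusters(full, st.SubsetClustering(idx, labels))
        relabel = np.array([2, 0, 1])
        m2 = st.match_clusters(full, st.SubsetClustering(idx, relabel[labels]))
        for c in m1:
            assert relabel[m1[c]] == m2[c]

    def test_identical_subsets_zero_distance_unit_correlation(self):
        X, labels = blobs(sep=10.0, seed=12)
        D = np.hstack([X, X])  # stand-in temporal profiles
        full = fc.fit_gmm(X, 3, n_init=3, seed=5)
        subs = [st.SubsetClustering(np.arange(len(X)), full.labels.copy(),
                                    means=full.mu.copy())]
        dist, corr = st.distance_and_correlation_checks(full, subs, D=D)
        np.testing.assert_allclose(dist.matched_distance_mean, 0.0, atol=1e-9)
        np.testing.assert_allclose(corr.median_correlation, 1.0, atol=1e-9)

    def test_matched_distance_below_nearest_other(self):
        X, labels = blobs(K=4, n_per=40, sep=10.0, seed=13)
        full = fc.fit_gmm(X, 4, n_init=3, seed=0)
        subs = st.subsample_clusterings(X, 4, n_subsets=10, seed=3)
        dist, _ = st.distance_and_correlation_checks(full, subs)
        assert (dist.matched_distance_mean
                < dist.nearest_other_cluster).all()
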