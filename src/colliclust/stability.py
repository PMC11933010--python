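"""Cluster-stability analysis by repeated 90% subsampling.

For a clustering fixed at the full-data component count K, draws
``n_subsets`` random subsamples, refits the mixture on each, and reports:

* per-cluster Jaccard similarity (JSC): for each original cluster, the
  subset-average of the maximum intersection-over-union with any subset
  cluster (computed on the subset's neuron set); clusters below 0.5 count
  as unstable;
* the co-association matrix CAM(i, j): the fraction of subsets containing
  both neurons in which they share a label, and its cluster-wise average
  (the between-cluster rate);
* per-cluster Euclidean distances between the original cluster means and
  their maximum-overlap matches on the subsets, compared with the nearest
  other original cluster, plus the median correlation of matched mean
  temporal profiles.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .featcluster import GmmClustering, fit_gmm


@dataclass
class SubsetClustering:
    indices: np.ndarray  # neuron indices drawn into the subset
    labels: np.ndarray  # cluster label per drawn neuron
    means: np.ndarray | None = None  # component means in feature space


@dataclass
class StabilityReport:
    jsc_per_cluster: pd.DataFrame  # cluster, jsc_mean, jsc_sd, n_subsets, stable
    cam: np.ndarray
    cam_counts: np.ndarray  # co-sampling counts (0 -> entry undefined)
    between_cluster_rate: np.ndarray
    distance_table: pd.DataFrame = field(default=None)
    correlation_hist: pd.DataFrame = field(default=None)


def subsample_clusterings(X: np.ndarray, K: int, fraction: float = 0.9,
                          n_subsets: int = 100, seed: int = 0,
                          n_init: int = 3) -> list[SubsetClustering]:
    """Refit the mixture at fixed K on ``n_subsets`` random draws of
    ``fraction`` of the neurons (without replacement); deterministic under
    ``seed``."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    n = X.shape[0]
    m = int(np.floor(fraction * n))
    if m < K:
        raise ValueError("subset smaller than the number of components")
    rng = np.random.default_rng(seed)
    out = []
    for j in range(n_subsets):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        fit = fit_gmm(X[idx], K, n_init=n_init, seed=seed + 17 * j + 1)
        out.append(SubsetClustering(indices=idx, labels=fit.labels,
                                    means=fit.mu))
    return out


def jaccard_stability(full_labels: np.ndarray,
                      subsets: list[SubsetClustering]) -> pd.DataFrame:
    """Per-original-cluster JSC averaged over subsets.

    Empty original clusters are flagged with NaN.
    """
    full_labels = np.asarray(full_labels)
    clusters = np.unique(full_labels)
    per_cluster: dict[int, list[float]] = {int(c): [] for c in clusters}
    for sub in subsets:
        ref = full_labels[sub.indices]
        for c in clusters:
            a = ref == c
            if not a.any():
                continue
            best = 0.0
            for cs in np.unique(sub.labels):
                b = sub.labels == cs
                inter = np.count_nonzero(a & b)
                union = np.count_nonzero(a | b)
                if union and inter / union > best:
                    best = inter / union
            per_cluster[int(c)].append(best)
    rows = []
    for c in clusters:
        vals = per_cluster[int(c)]
        if np.count_nonzero(full_labels == c) == 0 or not vals:
            rows.append({"cluster": int(c), "jsc_mean": np.nan,
                         "jsc_sd": np.nan, "n_subsets": 0, "stable": False})
            continue
        rows.append({
            "cluster": int(c), "jsc_mean": float(np.mean(vals)),
            "jsc_sd": float(np.std(vals)), "n_subsets": len(vals),
            "stable": bool(np.mean(vals) >= 0.5),
        })
    return pd.DataFrame(rows)


def coassociation(subsets: list[SubsetClustering], n_neurons: int,
                  full_labels: np.ndarray | None = None
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Co-association matrix and (optionally) its cluster-wise average.

    Returns ``(cam, counts, between_cluster_rate)``; CAM entries for pairs
    never co-sampled are NaN and excluded from the averages.
    """
    if not subsets:
        raise ValueError("need at least one subset")
    together = np.zeros((n_neurons, n_neurons))
    counts = np.zeros((n_neurons, n_neurons))
    for sub in subsets:
        idx = sub.indices
        counts[np.ix_(idx, idx)] += 1.0
        for lab in np.unique(sub.labels):
            members = idx[sub.labels == lab]
            together[np.ix_(members, members)] += 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        cam = np.where(counts > 0, together / np.maximum(counts, 1), np.nan)
    rate = None
    if full_labels is not None:
        full_labels = np.asarray(full_labels)
        clusters = np.unique(full_labels)
        K = len(clusters)
        rate = np.full((K, K), np.nan)
        for a, ca in enumerate(clusters):
            ia = np.flatnonzero(full_labels == ca)
            for b, cb in enumerate(clusters):
                ib = np.flatnonzero(full_labels == cb)
                blockc = counts[np.ix_(ia, ib)]
                blockv = cam[np.ix_(ia, ib)]
                if a == b:
                    off = ~np.eye(len(ia), dtype=bool)
                    blockc, blockv = blockc[off], blockv[off]
                valid = blockc > 0
                if valid.any():
                    rate[a, b] = float(np.nanmean(blockv[valid.ravel()]
                                                  if blockv.ndim == 1
                                                  else blockv[valid]))
    return cam, counts, rate


def match_clusters(full_labels: np.ndarray,
                   sub: SubsetClustering) -> dict[int, int]:
    """Greedy maximum-|intersection| matching of original clusters to
    subset clusters (ties to the lower cluster index)."""
    ref = np.asarray(full_labels)[sub.indices]
    pairs = []
    for c in np.unique(ref):
        for cs in np.unique(sub.labels):
            inter = np.count_nonzero((ref == c) & (sub.labels == cs))
            pairs.append((inter, -int(c), -int(cs)))
    pairs.sort(reverse=True)
    used_full: set[int] = set()
    used_sub: set[int] = set()
    matching: dict[int, int] = {}
    for inter, nc, ncs in pairs:
        c, cs = -nc, -ncs
        if inter == 0 or c in used_full or cs in used_sub:
            continue
        matching[c] = cs
        used_full.add(c)
        used_sub.add(cs)
    return matching


def distance_and_correlation_checks(
        full: GmmClustering, subsets: list[SubsetClustering],
        D: np.ndarray | None = None,
        full_labels: np.ndarray | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Feature-space distances and temporal-profile correlations between
    original clusters and their matched subset clusters.

    Per original cluster: the mean Euclidean distance to the matched
    subset-cluster means, the smallest distance to any *other* original
    cluster mean, and (when the response matrix ``D`` is given) the median
    Pearson correlation between matched mean temporal profiles.
    """
    labels = full.labels if full_labels is None else np.asarray(full_labels)
    clusters = np.unique(labels)
    dists: dict[int, list[float]] = {int(c): [] for c in clusters}
    corrs: dict[int, list[float]] = {int(c): [] for c in clusters}
    for sub in subsets:
        matching = match_clusters(labels, sub)
        for c, cs in matching.items():
            if sub.means is not None:
                dists[c].append(float(np.linalg.norm(
                    full.mu[list(clusters).index(c)] - sub.means[cs])))
            if D is not None:
                prof_full = D[labels == c].mean(axis=0)
                members = sub.indices[sub.labels == cs]
                if len(members) == 0:
                    continue
                prof_sub = D[members].mean(axis=0)
                if prof_full.std() == 0 or prof_sub.std() == 0:
                    continue
                corrs[c].append(float(np.corrcoef(prof_full, prof_sub)[0, 1]))
    rows_d, rows_c = [], []
    mus = full.mu
    for i, c in enumerate(clusters):
        others = np.delete(np.arange(len(clusters)), i)
        nearest_other = float(np.min(np.linalg.norm(
            mus[others] - mus[i], axis=1))) if len(others) else np.nan
        rows_d.append({
            "cluster": int(c),
            "matched_distance_mean": float(np.mean(dists[int(c)]))
            if dists[int(c)] else np.nan,
            "matched_distance_sd": float(np.std(dists[int(c)]))
            if dists[int(c)] else np.nan,
            "nearest_other_cluster": nearest_other,
            "n_matched": len(dists[int(c)]),
        })
        rows_c.append({
            "cluster": int(c),
            "median_correlation": float(np.median(corrs[int(c)]))
            if corrs[int(c)] else np.nan,
            "n_matched": len(corrs[int(c)]),
        })
    return pd.DataFrame(rows_d), pd.DataFrame(rows_c)


def stability_report(X: np.ndarray, full: GmmClustering,
                     D: np.ndarray | None = None, fraction: float = 0.9,
                     n_subsets: int = 100, seed: int = 0,
                     n_init: int = 3) -> StabilityReport:
    subsets = subsample_clusterings(X, full.K, fraction=fraction,
                                    n_subsets=n_subsets, seed=seed,
                                    n_init=n_init)
    jsc = jaccard_stability(full.labels, subsets)
    cam, counts, rate = coassociation(subsets, X.shape[0], full.labels)
    dist, corr = distance_and_correlation_checks(full, subsets, D=D)
    return StabilityReport(jsc_per_cluster=jsc, cam=cam, cam_counts=counts,
                           between_cluster_rate=rate, distance_table=dist,
                           correlation_hist=corr)
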