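"""Movie-response feature matrix (PCA) and BIC-selected Gaussian-mixture
clustering, plus the Ward dendrogram over cluster means.

The neuron x time matrix D concatenates each neuron's trial-averaged
responses to the four movies (fixed order), min-max scaled to [0, 1] per
neuron.  PCA factorizes D ~ X F (X: neuron x feature weights, F: feature
x time basis); the number of features is the smallest count explaining the
target variance fraction (default 70%), and the standardized weights are
clustered with a Gaussian mixture whose component count K is chosen by the
Bayesian information criterion, BIC = -2 ln L + k ln n.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import linkage
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

from .config import ClusterConfig


@dataclass
class FeatureDecomposition:
    D: np.ndarray  # (n_neuron, n_time) normalized responses
    F: np.ndarray  # (n_feature, n_time) feature basis (principal axes)
    X: np.ndarray  # (n_neuron, n_feature) standardized weights
    scores: np.ndarray  # unstandardized PCA scores (for reconstruction)
    mean: np.ndarray  # column mean of D removed by PCA
    variance_explained: float
    explained_ratio: np.ndarray  # per-component variance fractions

    @property
    def n_features(self) -> int:
        return self.F.shape[0]

    def reconstruct(self) -> np.ndarray:
        return self.scores @ self.F + self.mean


@dataclass
class GmmClustering:
    K: int
    phi: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    labels: np.ndarray
    responsibilities: np.ndarray
    bic: float
    model: GaussianMixture = field(repr=False, default=None)
    bic_curve: dict[int, float] = field(default_factory=dict)


def normalize_movie_responses(trial_means: dict[str, np.ndarray],
                              order: list[str] | None = None) -> np.ndarray:
    """Concatenate per-movie trial-mean traces (fixed order) and min-max
    scale each neuron's concatenation to [0, 1].

    Constant rows (max = min) map to zeros with a warning.
    """
    if order is None:
        order = list(trial_means)
    D = np.concatenate([np.asarray(trial_means[name], dtype=float)
                        for name in order], axis=1)
    lo = D.min(axis=1, keepdims=True)
    hi = D.max(axis=1, keepdims=True)
    rng = hi - lo
    flat = rng[:, 0] == 0
    if np.any(flat):
        warnings.warn(f"{int(flat.sum())} constant trace(s) map to zeros")
    rng[flat] = 1.0
    D = (D - lo) / rng
    D[flat] = 0.0
    return D


def extract_features(D: np.ndarray, target_variance: float = 0.70,
                     n_features: int | None = None) -> FeatureDecomposition:
    """PCA features of the normalized response matrix.

    Picks the smallest component count whose cumulative explained variance
    reaches ``target_variance`` unless ``n_features`` is fixed; weights are
    standardized columnwise (mean 0, SD 1).
    """
    D = np.asarray(D, dtype=float)
    max_rank = min(D.shape) - 1 if min(D.shape) > 1 else 1
    pca = PCA(n_components=max_rank, svd_solver="full")
    scores_full = pca.fit_transform(D)
    ratio = pca.explained_variance_ratio_
    if n_features is None:
        csum = np.cumsum(ratio)
        n_features = int(np.searchsorted(csum, target_variance - 1e-12) + 1)
    n_features = int(min(n_features, max_rank))
    scores = scores_full[:, :n_features]
    sd = scores.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    X = (scores - scores.mean(axis=0)) / sd
    return FeatureDecomposition(
        D=D, F=pca.components_[:n_features], X=X, scores=scores,
        mean=pca.mean_, variance_explained=float(ratio[:n_features].sum()),
        explained_ratio=ratio,
    )


def _n_parameters(K: int, d: int, covariance: str) -> int:
    """Free-parameter count of a K-component mixture in d dimensions."""
    mean_p = K * d
    weight_p = K - 1
    if covariance == "full":
        cov_p = K * d * (d + 1) // 2
    elif covariance == "diag":
        cov_p = K * d
    elif covariance == "spherical":
        cov_p = K
    elif covariance == "tied":
        cov_p = d * (d + 1) // 2
    else:
        raise ValueError(f"unknown covariance structure {covariance!r}")
    return mean_p + weight_p + cov_p


def bic(model: GaussianMixture, X: np.ndarray) -> float:
    """BIC = -2 ln L + k ln n with k from the covariance structure."""
    n = X.shape[0]
    log_l = float(model.score_samples(X).sum())
    k = _n_parameters(model.n_components, X.shape[1], model.covariance_type)
    return -2.0 * log_l + k * np.log(n)


def fit_gmm(X: np.ndarray, K: int, n_init: int = 50, seed: int = 0,
            covariance: str = "full", reg_covar: float = 1e-6,
            max_iter: int = 200,
            init_params: str = "k-means++") -> GmmClustering:
    """Best-of-``n_init`` EM fit, deterministic under ``seed``.

    Restarts are seeded with k-means++ draws by default: purely random
    initial states almost never place one component per well-separated
    mode at exactly the right K, which biases the BIC curve toward larger
    K through under-fitting (set ``init_params='random_from_data'`` for
    plain random restarts).  Vanishing covariances are regularized by
    ``reg_covar`` on the diagonal.  Hard labels are the posterior argmax
    (ties resolved to the lowest component index by argmax convention).
    """
    X = np.asarray(X, dtype=float)
    model = GaussianMixture(
        n_components=K, covariance_type=covariance, n_init=n_init,
        init_params=init_params if K > 1 else "kmeans",
        reg_covar=reg_covar, max_iter=max_iter, random_state=seed,
    ).fit(X)
    resp = model.predict_proba(X)
    return GmmClustering(
        K=K, phi=model.weights_, mu=model.means_, sigma=model.covariances_,
        labels=np.argmax(resp, axis=1), responsibilities=resp,
        bic=bic(model, X), model=model,
    )


def scan_components(X: np.ndarray, k_min: int = 2, k_max: int = 30,
                    n_init: int = 50, seed: int = 0,
                    covariance: str = "full",
                    config: ClusterConfig | None = None) -> GmmClustering:
    """Fit mixtures for K = k_min..k_max and return the BIC-argmin model
    with the full BIC curve attached."""
    if config is not None:
        k_min, k_max = config.kmin, config.kmax
        n_init, seed = config.n_init, config.seed
        covariance = config.covariance
    if k_max >= X.shape[0]:
        raise ValueError("k_max must be below the number of neurons")
    curve: dict[int, float] = {}
    best: GmmClustering | None = None
    for K in range(k_min, k_max + 1):
        fit = fit_gmm(X, K, n_init=n_init, seed=seed, covariance=covariance)
        curve[K] = fit.bic
        if best is None or fit.bic < best.bic:
            best = fit
    best.bic_curve = curve
    return best


def dendrogram(cluster_means: np.ndarray) -> np.ndarray:
    """Ward-linkage tree over cluster means (Euclidean distances).

    Returns the scipy linkage matrix; leaf count equals the number of
    clusters.
    """
    cluster_means = np.asarray(cluster_means, dtype=float)
    if cluster_means.shape[0] < 2:
        raise ValueError("need at least 2 clusters for a dendrogram")
    return linkage(cluster_means, method="ward", metric="euclidean")
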