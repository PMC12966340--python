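"""K-means clustering with two cluster-count selection criteria.

``multi_kmeans`` sweeps K over [k_min, n/2] and keeps the clustering whose
cluster sizes are closest to uniform, scored by the upper-tail p-value of
a chi-squared test against the exact uniform expectation n/K (df = K-1);
configurations with empty or sparsely populated clusters are excluded.
``xmeans_sweep`` runs the same sweep but selects the K minimising a
spherical-Gaussian BIC, which assumes vectors are normally distributed
around their centroids and therefore tends to prefer finer partitions
than the uniformity criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans

from .config import StudyConfig

__all__ = ["Clustering", "ClusteringResult", "kmeans", "unif_score",
           "multi_kmeans", "bic", "xmeans_sweep"]

_VAR_FLOOR = 1e-12


@dataclass
class Clustering:
    K: int
    assignments: np.ndarray          # shape (n,), values in [0, K)
    centroids: np.ndarray            # shape (K, d)
    sse: float                       # within-cluster sum of squared distances

    def sizes(self) -> np.ndarray:
        return np.bincount(self.assignments, minlength=self.K)


@dataclass
class ClusteringResult:
    best: Clustering
    K_star: int
    selection_scores: dict[int, float]            # K -> UNIF p-value or BIC
    excluded_Ks: list[tuple[int, str]] = field(default_factory=list)
    log: list[str] = field(default_factory=list)


def kmeans(X: np.ndarray, K: int, seed: int, restarts: int = 10,
           max_iter: int = 300) -> Clustering:
    """Best-of-``restarts`` K-means (Lloyd) with centroids drawn from the data.

    Deterministic given the seed. Raises if K exceeds the number of points.
    """
    n = X.shape[0]
    if not 2 <= K <= n:
        raise ValueError(f"K={K} outside [2, n={n}]")
    km = KMeans(n_clusters=K, init="random", n_init=restarts,
                max_iter=max_iter, random_state=seed).fit(X)
    labels = km.labels_.astype(int)
    # recompute centroids as exact member means (invariant of the container)
    centroids = np.vstack([
        X[labels == k].mean(axis=0) if np.any(labels == k) else km.cluster_centers_[k]
        for k in range(K)
    ])
    sse = float(((X - centroids[labels]) ** 2).sum())
    return Clustering(K=K, assignments=labels, centroids=centroids, sse=sse)


def unif_score(c: Clustering) -> float:
    """Uniformity of the cluster-size distribution as a chi-squared p-value.

    X^2 = sum_i (O_i - n/K)^2 / (n/K) over the observed sizes O_i; returns
    the upper-tail probability at K-1 degrees of freedom. Higher means
    closer to the theoretical uniform allocation (exactly 1 when all sizes
    equal n/K).
    """
    if c.K < 2:
        raise ValueError("uniformity score requires K >= 2")
    sizes = c.sizes().astype(float)
    expected = sizes.sum() / c.K
    x2 = float(((sizes - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(x2, df=c.K - 1))


def bic(c: Clustering, X: np.ndarray) -> float:
    """Spherical-Gaussian BIC of a clustering (identical shared variance).

    The classification log-likelihood uses sigma^2 = SSE / (d (n - K)) and
    mixture weights n_k/n; the parameter count is K*d centroids + K weights
    + 1 variance. Lower is better. A zero SSE is floored to keep the
    likelihood finite.
    """
    n, d = X.shape
    if n <= c.K:
        raise ValueError("BIC requires n > K")
    var = c.sse / (d * (n - c.K))
    if var <= _VAR_FLOOR:
        var = _VAR_FLOOR
    sizes = c.sizes().astype(float)
    nz = sizes[sizes > 0]
    loglik = (float((nz * np.log(nz / n)).sum())
              - 0.5 * n * d * np.log(2.0 * np.pi * var)
              - c.sse / (2.0 * var))
    n_params = c.K * d + c.K + 1
    return float(-2.0 * loglik + n_params * np.log(n))


def _sweep(X: np.ndarray, cfg: StudyConfig) -> dict[int, Clustering]:
    n = X.shape[0]
    k_lo, k_hi = cfg.k_min, cfg.k_max(n)
    if n < 2 * k_lo:
        raise ValueError(f"need at least {2 * cfg.k_min} points for the K sweep")
    out = {}
    for K in range(k_lo, k_hi + 1):
        out[K] = kmeans(X, K, seed=cfg.seed, restarts=cfg.restarts,
                        max_iter=cfg.max_iter)
    return out


def multi_kmeans(X: np.ndarray, cfg: StudyConfig) -> ClusteringResult:
    """Select K* by maximal cluster-size uniformity (ties to the smallest K).

    A configuration is excluded when any cluster is empty or sparsely
    populated — smaller than half the uniform share n/K (never below 2).
    The K-relative threshold is what keeps the criterion from
    over-segmenting: isolating a few outliers into mini-clusters would
    otherwise make the remaining sizes look deceptively uniform, and the
    selector would drift to large K instead of favouring the larger,
    homogeneous clusters it is meant to prefer. If every K is excluded
    the K with the fewest undersized clusters wins, with a prominent log
    entry.
    """
    n = X.shape[0]
    sweep = _sweep(X, cfg)
    scores: dict[int, float] = {}
    excluded: list[tuple[int, str]] = []
    log: list[str] = []
    for K, c in sweep.items():
        sizes = c.sizes()
        min_size = max(2, int(np.ceil(cfg.min_cluster_frac * n / K)))
        if (sizes == 0).any():
            excluded.append((K, "empty"))
            continue
        if (sizes < min_size).any():
            excluded.append((K, f"sparse(<{min_size})"))
            continue
        scores[K] = unif_score(c)
    if scores:
        best_p = max(scores.values())
        k_star = min(K for K, p in scores.items() if p == best_p)
    else:
        undersized = {
            K: int((c.sizes() < max(2, int(np.ceil(cfg.min_cluster_frac * n / K)))).sum())
            for K, c in sweep.items()
        }
        k_star = min(K for K, u in undersized.items() if u == min(undersized.values()))
        log.append("WARNING: all K excluded by the uniformity rules; "
                   f"fell back to K={k_star} (fewest undersized clusters)")
        scores[k_star] = unif_score(sweep[k_star])
    return ClusteringResult(best=sweep[k_star], K_star=k_star,
                            selection_scores=scores, excluded_Ks=excluded, log=log)


def xmeans_sweep(X: np.ndarray, cfg: StudyConfig) -> ClusteringResult:
    """Select K* by minimal BIC over the same K range (ties to the smallest K)."""
    sweep = _sweep(X, cfg)
    scores = {K: bic(c, X) for K, c in sweep.items()}
    best = min(scores.values())
    k_star = min(K for K, b in scores.items() if b == best)
    return ClusteringResult(best=sweep[k_star], K_star=k_star,
                            selection_scores=scores, excluded_Ks=[])
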