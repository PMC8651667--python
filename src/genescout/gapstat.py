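"""Gap-statistic selection of the cluster number and profile clustering.

The gap statistic compares log within-cluster dispersion on the data with its
expectation under a reference null (uniform over each feature's observed
range): Gap(k) = E*[log W_k] - log W_k, with the simulation-error term
s_k = sd_k * sqrt(1 + 1/B). K-means is the default clusterer inside the gap
evaluation; the final gene assignment defaults to hierarchical clustering with
Euclidean distance and complete linkage — the two are independently
configurable because both are sensible and serve different roles.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)


@dataclass
class GapConfig:
    kmax: int = 100
    B: int = 50  # number of reference datasets
    clusterer: str = "kmeans"  # kmeans | hierarchical (inside the gap evaluation)
    restarts: int = 10  # k-means restarts (k-means++ seeding, best of)
    rule: str = "tibshirani_1se"  # tibshirani_1se | global_max
    seed: int = 0

    def __post_init__(self):
        if self.kmax < 1:
            raise ValueError("kmax must be >= 1")
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if self.clusterer not in ("kmeans", "hierarchical"):
            raise ValueError(f"unknown clusterer {self.clusterer!r}")


@dataclass
class GapCurve:
    k: np.ndarray
    log_w: np.ndarray
    log_w_ref_mean: np.ndarray
    gap: np.ndarray
    s_k: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "k": self.k, "log_w": self.log_w,
            "log_w_ref_mean": self.log_w_ref_mean,
            "gap": self.gap, "s_k": self.s_k,
        })


@dataclass
class ClusterAssignment:
    labels: pd.Series  # gene_id -> 1..K
    K: int
    method: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        lab = np.asarray(self.labels, dtype=int)
        present = np.unique(lab)
        if not np.array_equal(present, np.arange(1, self.K + 1)):
            raise ValueError(f"labels must be contiguous 1..{self.K}, got {present}")

    def members(self, k: int) -> list[str]:
        return list(self.labels.index[self.labels == k])

    def clusters(self) -> dict[int, list[str]]:
        return {k: self.members(k) for k in range(1, self.K + 1)}


def within_dispersion(X: np.ndarray, labels: np.ndarray) -> float:
    """W = sum over clusters of squared distances to the cluster centroid
    (algebraically equal to sum_r D_r / (2 n_r) with D_r the sum of pairwise
    squared Euclidean distances)."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if labels.shape[0] != X.shape[0]:
        raise ValueError("labels must cover every item")
    W = 0.0
    for lab in np.unique(labels):
        pts = X[labels == lab]
        centroid = pts.mean(axis=0)
        W += float(((pts - centroid) ** 2).sum())
    return W


def kmeans_cluster(X: np.ndarray, k: int, restarts: int = 10, seed: int = 0) -> np.ndarray:
    """Best-of-restarts Lloyd with k-means++ seeding; 0-based labels."""
    X = np.asarray(X, dtype=float)
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds the number of items {X.shape[0]}")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # duplicate-point convergence chatter
        return km.fit_predict(X)


def hierarchical_cluster(X: np.ndarray, k: int) -> np.ndarray:
    """Complete-linkage agglomeration on Euclidean distances, cut to k
    clusters; 0-based contiguous labels."""
    X = np.asarray(X, dtype=float)
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds the number of items {X.shape[0]}")
    if k == X.shape[0]:
        return np.arange(X.shape[0])
    Z = linkage(X, method="complete", metric="euclidean")
    raw = fcluster(Z, t=k, criterion="maxclust")
    _, labels = np.unique(raw, return_inverse=True)
    return labels


def _cluster(X, k, config: GapConfig, seed: int) -> np.ndarray:
    if config.clusterer == "kmeans":
        return kmeans_cluster(X, k, restarts=config.restarts, seed=seed)
    return hierarchical_cluster(X, k)


def gap_statistic(X: np.ndarray, config: GapConfig) -> GapCurve:
    """Gap curve for k = 1..kmax, deterministic under ``config.seed``.

    Reference datasets are drawn uniformly per feature over that feature's
    observed [min, max]. kmax is clipped to n_items - 1 (log W is undefined at
    k = n) with a warning.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 items for the gap statistic")
    kmax = config.kmax
    if kmax >= n:
        logger.warning("kmax=%d clipped to n_items-1=%d", kmax, n - 1)
        kmax = n - 1

    ss = np.random.SeedSequence(config.seed)
    rng = np.random.Generator(np.random.PCG64(ss))
    # fixed-order draws: B reference datasets, then one k-means seed per fit
    lo, hi = X.min(axis=0), X.max(axis=0)
    refs = [rng.uniform(lo, hi, size=X.shape) for _ in range(config.B)]
    fit_seeds = rng.integers(0, 2**31 - 1, size=(kmax, config.B + 1))

    ks = np.arange(1, kmax + 1)
    log_w = np.empty(kmax)
    log_w_ref = np.empty((config.B, kmax))
    for i, k in enumerate(ks):
        log_w[i] = np.log(max(within_dispersion(X, _cluster(X, k, config, int(fit_seeds[i, 0]))),
                              1e-300))
        for b in range(config.B):
            Wb = within_dispersion(refs[b], _cluster(refs[b], k, config,
                                                     int(fit_seeds[i, b + 1])))
            log_w_ref[b, i] = np.log(max(Wb, 1e-300))

    ref_mean = log_w_ref.mean(axis=0)
    sd_k = log_w_ref.std(axis=0, ddof=0)
    s_k = sd_k * np.sqrt(1.0 + 1.0 / config.B)
    return GapCurve(k=ks, log_w=log_w, log_w_ref_mean=ref_mean,
                    gap=ref_mean - log_w, s_k=s_k)


def select_k(curve: GapCurve, rule: str = "tibshirani_1se") -> int:
    """Pick K from a gap curve.

    tibshirani_1se: smallest k with Gap(k) >= Gap(k+1) - s_{k+1};
    global_max: argmax Gap(k). Ties go to the smallest k; a maximum sitting at
    kmax is returned with a warning to raise kmax.
    """
    gap, s = curve.gap, curve.s_k
    kmax = int(curve.k[-1])
    if rule == "tibshirani_1se":
        for i in range(len(gap) - 1):
            if gap[i] >= gap[i + 1] - s[i + 1]:
                return int(curve.k[i])
        logger.warning("1-SE rule never satisfied up to kmax=%d; consider raising kmax", kmax)
        return kmax
    if rule == "global_max":
        best = int(curve.k[int(np.argmax(gap))])
        if best == kmax:
            logger.warning("gap maximum at kmax=%d; consider raising kmax", kmax)
        return best
    raise ValueError(f"unknown selection rule {rule!r}")


def assign_clusters(X: np.ndarray, K: int, gene_ids, method: str = "hierarchical",
                    restarts: int = 10, seed: int = 0) -> ClusterAssignment:
    """Final gene -> cluster labels (1..K) with the chosen method (default
    hierarchical complete/Euclidean, as used for the published assignments)."""
    if method == "hierarchical":
        raw = hierarchical_cluster(X, K)
        metadata = {"linkage": "complete", "metric": "euclidean"}
    elif method == "kmeans":
        raw = kmeans_cluster(X, K, restarts=restarts, seed=seed)
        metadata = {"restarts": restarts, "seed": seed}
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    _, contig = np.unique(raw, return_inverse=True)
    K_eff = int(contig.max()) + 1
    if K_eff != K:
        logger.warning("requested K=%d but only %d distinct clusters produced", K, K_eff)
    return ClusterAssignment(labels=pd.Series(contig + 1, index=list(gene_ids)),
                             K=K_eff, method=method, metadata=metadata)
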