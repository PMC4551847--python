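"""Clustering of modelled trajectories and set-based enrichment.

Fitted curves (or their derivatives) are clustered with five standard
algorithm families — hierarchical (complete linkage), k-means,
partitioning around medoids (PAM), a one-dimensional self-organizing map
(SOM) and Gaussian-mixture model-based clustering — over a range of
cluster counts.  The Dunn index (smallest inter-cluster distance over
largest intra-cluster distance; larger means better separated) selects
both the algorithm and the number of clusters.  Biological relevance of
each cluster is scored against user-supplied annotation sets with a
one-sided hypergeometric test.

PAM and the SOM are implemented here directly (small, deterministic,
seeded); distance-based algorithms accept a Euclidean or correlation
metric, centroid-based ones operate in the Euclidean curve space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import hypergeom
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

from .de import adjust_bh

ALGORITHMS = ("hierarchical", "kmeans", "pam", "som", "model_based")


@dataclass
class ClusterEvaluation:
    """One clustering solution plus its Dunn index."""

    algorithm: str
    k: int
    assignments: pd.Series          # molecule -> cluster label (1..k)
    dunn: float
    metric: str


def dunn_index(distances: np.ndarray, assignments) -> float:
    """Ratio of the smallest inter- to the largest intra-cluster distance.

    ``distances`` is a symmetric non-negative matrix with zero diagonal.
    An all-singleton clustering (max intra-cluster distance 0) returns
    +inf by convention; a single cluster is an error.
    """
    D = np.asarray(distances, dtype=float)
    labels = np.asarray(assignments)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("Dunn index needs >=2 non-empty clusters")
    masks = [labels == c for c in uniq]
    max_intra = 0.0
    for m in masks:
        if m.sum() > 1:
            max_intra = max(max_intra, D[np.ix_(m, m)].max())
    min_inter = np.inf
    for i in range(len(masks)):
        for j in range(i + 1, len(masks)):
            min_inter = min(min_inter, D[np.ix_(masks[i], masks[j])].min())
    if max_intra == 0.0:
        return np.inf
    return float(min_inter / max_intra)


def _distance_matrix(curves: np.ndarray, metric: str) -> np.ndarray:
    if metric == "euclidean":
        return squareform(pdist(curves, metric="euclidean"))
    if metric == "correlation":
        return squareform(pdist(curves, metric="correlation"))
    raise ValueError(f"unknown metric {metric!r}")


def _pam(D: np.ndarray, k: int, max_iter: int = 100) -> np.ndarray:
    """Partitioning around medoids on a precomputed distance matrix.

    Greedy BUILD initialization followed by SWAP steps until no swap
    lowers the total within-cluster distance; deterministic.
    """
    n = D.shape[0]
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        nearest = D[:, medoids].min(axis=1)
        gains = np.array([np.maximum(nearest - D[:, c], 0.0).sum()
                          if c not in medoids else -np.inf
                          for c in range(n)])
        medoids.append(int(np.argmax(gains)))
    medoids = np.array(sorted(medoids))
    cost = D[:, medoids].min(axis=1).sum()
    for _ in range(max_iter):
        improved = False
        for mi in range(k):
            others = np.delete(medoids, mi)
            for c in range(n):
                if c in medoids:
                    continue
                trial = np.sort(np.append(others, c))
                tc = D[:, trial].min(axis=1).sum()
                if tc < cost - 1e-12:
                    medoids, cost, improved = trial, tc, True
        if not improved:
            break
    return np.argmin(D[:, medoids], axis=1) + 1


def _som_1d(X: np.ndarray, k: int, rng: np.random.Generator,
            epochs: int = 100, restarts: int = 10) -> np.ndarray:
    """One-dimensional self-organizing map with k nodes (= clusters).

    Sequential training with linearly decaying learning rate and
    neighbourhood radius; best of ``restarts`` by within-cluster sum of
    squared distances to the winning node.
    """
    n = X.shape[0]
    best_labels, best_cost = None, np.inf
    for _ in range(restarts):
        nodes = X[rng.choice(n, size=k, replace=n < k)].astype(float).copy()
        for epoch in range(epochs):
            frac = epoch / max(epochs - 1, 1)
            lr = 0.5 * (1.0 - frac) + 0.01 * frac
            radius = max((k / 2.0) * (1.0 - frac), 0.5)
            for i in rng.permutation(n):
                d = ((nodes - X[i]) ** 2).sum(axis=1)
                win = int(np.argmin(d))
                h = np.exp(-0.5 * ((np.arange(k) - win) / radius) ** 2)
                nodes += lr * h[:, None] * (X[i] - nodes)
        d2 = ((X[:, None, :] - nodes[None, :, :]) ** 2).sum(axis=2)
        labels = np.argmin(d2, axis=1)
        cost = d2[np.arange(n), labels].sum()
        if cost < best_cost:
            best_cost, best_labels = cost, labels
    return best_labels + 1


def cluster_profiles(curves: pd.DataFrame, algorithm: str, k: int,
                     metric: str = "euclidean", seed: int = 0,
                     standardize: bool = False) -> pd.Series:
    """Cluster molecule curves into k groups with the chosen algorithm.

    ``curves`` is a molecules x grid frame with no missing values.
    Deterministic given ``seed``; centroid methods run 10 restarts.
    """
    X = curves.to_numpy(float)
    if not np.isfinite(X).all():
        raise ValueError("curves must not contain missing values")
    n = X.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} molecules")
    if standardize:
        sd = X.std(axis=0)
        X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    rng = np.random.default_rng(seed)
    if algorithm == "hierarchical":
        Z = linkage(X, method="complete", metric=metric)
        labels = fcluster(Z, t=k, criterion="maxclust")
    elif algorithm == "kmeans":
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels = km.fit_predict(X) + 1
    elif algorithm == "pam":
        labels = _pam(_distance_matrix(X, metric), k)
    elif algorithm == "som":
        labels = _som_1d(X, k, rng)
    elif algorithm == "model_based":
        gm = GaussianMixture(n_components=k, covariance_type="diag",
                             n_init=5, random_state=seed, reg_covar=1e-6)
        labels = gm.fit_predict(X) + 1
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    return pd.Series(labels, index=curves.index, name="cluster")


def select_clustering(curves: pd.DataFrame, algorithms=ALGORITHMS,
                      k_range=range(2, 10), metric: str = "euclidean",
                      seed: int = 0, allow_singleton: bool = False,
                      ) -> tuple[ClusterEvaluation, pd.DataFrame]:
    """Evaluate every (algorithm, k) by Dunn index and return the best.

    Ties prefer the smaller k, then the algorithm order as listed.
    Solutions with an infinite Dunn index (all-singleton clusters) are
    excluded from the argmax unless ``allow_singleton``.
    """
    D = _distance_matrix(curves.to_numpy(float), metric)
    grid_rows, evals = [], []
    for algorithm in algorithms:
        for k in k_range:
            try:
                assign = cluster_profiles(curves, algorithm, k,
                                          metric=metric, seed=seed)
                dunn = dunn_index(D, assign.to_numpy())
            except (ValueError, np.linalg.LinAlgError) as err:
                grid_rows.append((algorithm, k, np.nan, str(err)))
                continue
            grid_rows.append((algorithm, k, dunn, ""))
            evals.append(ClusterEvaluation(algorithm, k, assign, dunn,
                                           metric))
    grid = pd.DataFrame(grid_rows,
                        columns=["algorithm", "k", "dunn", "error"])
    usable = [e for e in evals
              if allow_singleton or np.isfinite(e.dunn)]
    if not usable:
        raise ValueError("no clustering evaluation succeeded")
    alg_rank = {a: i for i, a in enumerate(algorithms)}
    best = max(usable,
               key=lambda e: (e.dunn, -e.k, -alg_rank[e.algorithm]))
    return best, grid


def enrich(assignments: pd.Series, annotation: dict[str, set],
           universe: set) -> pd.DataFrame:
    """Hypergeometric over-representation of annotation sets per cluster.

    For each (cluster, term): with universe size N, ``K`` annotated
    molecules, cluster size n and overlap x, p = P(X >= x) for
    X ~ Hypergeom(N, K, n).  The log odds ratio comes from the 2x2 table
    with 0.5 added to empty cells.  Terms annotating at most one molecule
    of the universe are dropped; BH adjustment is applied across terms
    within each cluster.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    rows = []
    N = len(universe)
    for cluster, members in assignments.groupby(assignments):
        cl = set(members.index) & universe
        n = len(cl)
        for term, annotated in annotation.items():
            ann = set(annotated) & universe
            K = len(ann)
            x = len(cl & ann)
            if K <= 1:
                continue
            p = float(hypergeom.sf(x - 1, N, K, n))
            a, b = x, K - x
            c, d = n - x, N - K - (n - x)
            table = np.array([a, b, c, d], dtype=float)
            table[table == 0] += 0.5
            log_or = float(np.log(table[0] * table[3]
                                  / (table[1] * table[2])))
            rows.append((cluster, term, x, n, K, N, p, log_or))
    out = pd.DataFrame(rows, columns=["cluster", "term", "overlap",
                                      "cluster_size", "annotated",
                                      "universe", "p", "log_odds"])
    if len(out):
        out["adj_p"] = np.nan
        for cluster, idx in out.groupby("cluster").groups.items():
            out.loc[idx, "adj_p"] = adjust_bh(out.loc[idx, "p"])
    else:
        out["adj_p"] = pd.Series(dtype=float)
    return out
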