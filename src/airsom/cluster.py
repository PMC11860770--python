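"""Ward clustering of the SOM codebook into "air types".

Ward linkage (Ward.D2 convention: heights on the Euclidean distance scale)
is delegated to scipy; cluster-count selection uses the Davies-Bouldin
index implemented here from its definition.  Cluster ids are assigned by
decreasing cluster size (ties by smallest member index) so that reports are
reproducible across runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import kruskal, mannwhitneyu

from .som import Codebook

__all__ = [
    "LinkageTree",
    "ClusterSolution",
    "ClusterTests",
    "ward_linkage",
    "cut_clusters",
    "davies_bouldin",
    "select_k",
    "cluster_tests",
]


def _as_matrix(M) -> np.ndarray:
    if isinstance(M, Codebook):
        M = M.M
    M = np.asarray(M, dtype=float)
    if np.isnan(M).any():
        raise ValueError("matrix contains NaN")
    return M


@dataclass(eq=False)
class LinkageTree:
    """Agglomeration history in scipy linkage format (n_leaves - 1 merges)."""

    Z: np.ndarray
    n_leaves: int

    @property
    def heights(self) -> np.ndarray:
        return self.Z[:, 2]


@dataclass(eq=False)
class ClusterSolution:
    k: int
    labels: np.ndarray  # per-node cluster id in 1..k
    centroids: np.ndarray  # (k, n_variables) member means
    db_table: pd.DataFrame  # columns: k, db
    tree: LinkageTree


@dataclass(eq=False)
class ClusterTests:
    kw: pd.DataFrame  # variable, statistic, p
    pairwise: pd.DataFrame  # variable, cluster_a, cluster_b, p_raw, p_adj


def ward_linkage(codebook) -> LinkageTree:
    """Ward's minimum-variance agglomeration on Euclidean distances."""
    M = _as_matrix(codebook)
    if M.shape[0] < 2:
        raise ValueError("need at least 2 rows to build a linkage")
    Z = linkage(M, method="ward")
    return LinkageTree(Z=Z, n_leaves=M.shape[0])


def _relabel_by_size(raw: np.ndarray) -> np.ndarray:
    """Map arbitrary labels to 1..k by decreasing size, ties by first index."""
    ids, first = np.unique(raw, return_index=True)
    sizes = {c: int(np.sum(raw == c)) for c in ids}
    firsts = dict(zip(ids, first))
    order = sorted(ids, key=lambda c: (-sizes[c], firsts[c]))
    mapping = {old: new + 1 for new, old in enumerate(order)}
    return np.array([mapping[c] for c in raw], dtype=int)


def cut_clusters(tree: LinkageTree, k: int) -> np.ndarray:
    """Cut the tree into ``k`` groups; labels in 1..k ordered by size."""
    if not 1 <= k <= tree.n_leaves:
        raise ValueError(f"k must be in [1, {tree.n_leaves}], got {k}")
    if k == tree.n_leaves:
        raw = np.arange(tree.n_leaves)
    else:
        raw = fcluster(tree.Z, t=k, criterion="maxclust")
    return _relabel_by_size(raw)


def davies_bouldin(M: np.ndarray, labels: np.ndarray) -> float:
    """Davies-Bouldin index: mean over clusters of the worst
    ``(S_i + S_j) / d(centroid_i, centroid_j)`` ratio, where ``S_i`` is the
    mean Euclidean distance of members to their centroid.  Identical
    centroids yield ``inf``."""
    M = _as_matrix(M)
    labels = np.asarray(labels)
    ids = np.unique(labels)
    if len(ids) < 2:
        raise ValueError("need at least 2 clusters")
    cents = np.stack([M[labels == c].mean(axis=0) for c in ids])
    scatters = np.array(
        [np.linalg.norm(M[labels == c] - cents[i], axis=1).mean() for i, c in enumerate(ids)]
    )
    k = len(ids)
    worst = np.zeros(k)
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            sep = np.linalg.norm(cents[i] - cents[j])
            ratio = np.inf if sep == 0 else (scatters[i] + scatters[j]) / sep
            worst[i] = max(worst[i], ratio)
    return float(worst.mean())


def select_k(codebook, kmin: int = 2, kmax: int = 10) -> ClusterSolution:
    """Cut and score every k in [kmin, kmax]; keep the Davies-Bouldin
    minimiser (ties to the smallest k)."""
    M = _as_matrix(codebook)
    n = M.shape[0]
    if not 2 <= kmin <= kmax <= n:
        raise ValueError(f"need 2 <= kmin <= kmax <= {n}")
    tree = ward_linkage(M)
    ks = list(range(kmin, kmax + 1))
    scores, all_labels = [], []
    for k in ks:
        labels = cut_clusters(tree, k)
        all_labels.append(labels)
        scores.append(davies_bouldin(M, labels))
    best = int(np.argmin(scores))
    labels = all_labels[best]
    k = int(labels.max())  # equals ks[best] unless the cut degenerated
    centroids = np.stack([M[labels == c].mean(axis=0) for c in range(1, k + 1)])
    db_table = pd.DataFrame({"k": ks, "db": scores})
    return ClusterSolution(k=k, labels=labels, centroids=centroids, db_table=db_table, tree=tree)


def cluster_tests(M: np.ndarray, labels: np.ndarray, variable_names=None) -> ClusterTests:
    """Nonparametric cluster-difference tests per variable.

    Kruskal-Wallis (tie-corrected, chi-square approximation) across all
    clusters, then all-pairs two-sided Wilcoxon rank-sum tests with
    Bonferroni correction (``p_adj = min(1, p * k(k-1)/2)``).  Pairs
    involving a cluster with fewer than 2 members are reported as NaN.
    """
    M = _as_matrix(M)
    labels = np.asarray(labels)
    ids = sorted(np.unique(labels).tolist())
    if len(ids) < 2:
        raise ValueError("need at least 2 clusters")
    names = list(variable_names) if variable_names is not None else [
        f"var{j}" for j in range(M.shape[1])
    ]
    m_comp = len(ids) * (len(ids) - 1) // 2
    kw_rows, pw_rows = [], []
    for j, name in enumerate(names):
        groups = [M[labels == c, j] for c in ids]
        usable = [g for g in groups if len(g) >= 2]
        if len(usable) >= 2:
            try:
                stat, p = kruskal(*usable)
            except ValueError:  # all values identical
                stat, p = 0.0, 1.0
        else:
            stat, p = np.nan, np.nan
        kw_rows.append({"variable": name, "statistic": stat, "p": p})
        for (ia, ca), (ib, cb) in combinations(enumerate(ids), 2):
            ga, gb = groups[ia], groups[ib]
            if len(ga) < 2 or len(gb) < 2:
                p_raw = np.nan
            else:
                p_raw = float(
                    mannwhitneyu(ga, gb, alternative="two-sided", method="auto").pvalue
                )
            pw_rows.append(
                {
                    "variable": name,
                    "cluster_a": ca,
                    "cluster_b": cb,
                    "p_raw": p_raw,
                    "p_adj": min(1.0, p_raw * m_comp) if np.isfinite(p_raw) else np.nan,
                }
            )
    return ClusterTests(kw=pd.DataFrame(kw_rows), pairwise=pd.DataFrame(pw_rows))
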