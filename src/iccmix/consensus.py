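"""Consensus clustering over the post-burn-in label chain.

Different ICC iterations impute different partitions (and hence select
different variables). The chain is aggregated into one partition via the
co-assignment dissimilarity

    d_ij = (T - t0) - #{ t > t0 : tau_i^(t) == tau_j^(t) },

i.e. the number of retained iterations in which samples i and j landed in
different clusters. Average-linkage hierarchical clustering of D, cut at K,
yields the consensus partition; a final SIS-MCP fit per consensus cluster
gives the reported model. d_ij depends only on co-assignment, so the
consensus is invariant to label switching across iterations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import dendrogram, fcluster, linkage, to_tree
from scipy.spatial.distance import squareform

from .icc import MIN_CLUSTER_SIZE, ICCTrace, MixtureModel, update_component
from .screening import SparseFit

__all__ = [
    "DissimilarityMatrix",
    "ConsensusResult",
    "dissimilarity",
    "consensus_cluster",
    "clusterwise_select",
    "fit_mixture",
    "dendrogram_newick",
]


@dataclass
class DissimilarityMatrix:
    """Symmetric n x n matrix of co-assignment disagreement counts.

    Entries are raw counts in [0, n_iterations]; ``normalized()`` returns
    the [0, 1] fraction (used for plotting only).
    """

    matrix: np.ndarray
    n_iterations: int     # size of the window the counts were taken over
    t0: int
    T: int

    def __post_init__(self) -> None:
        D = np.asarray(self.matrix)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        if not np.array_equal(D, D.T):
            raise ValueError("dissimilarity matrix must be symmetric")
        if np.any(np.diag(D) != 0):
            raise ValueError("self-dissimilarity must be zero")
        if D.min() < 0 or D.max() > self.n_iterations:
            raise ValueError("entries must lie in [0, n_iterations]")
        self.matrix = D

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def normalized(self) -> np.ndarray:
        return self.matrix / max(self.n_iterations, 1)


def dissimilarity(trace: ICCTrace) -> DissimilarityMatrix:
    """Co-assignment dissimilarity over the post-burn-in window of a trace."""
    labels = trace.memberships[trace.post_burn_in]
    n_iter, n = labels.shape
    if n_iter == 0:
        raise ValueError("post-burn-in window is empty")
    # co-assignment counts as a sum of per-component indicator Grams
    co = np.zeros((n, n))
    for k in range(trace.K):
        ind = (labels == k).astype(np.float64)
        co += ind.T @ ind
    D = n_iter - co
    np.fill_diagonal(D, 0.0)
    D = np.clip(D, 0.0, n_iter)
    D = (D + D.T) / 2.0
    return DissimilarityMatrix(matrix=D, n_iterations=n_iter, t0=trace.t0, T=trace.T)


def consensus_cluster(D: DissimilarityMatrix, K: int) -> np.ndarray:
    """Average-linkage agglomeration of D cut at K clusters.

    Returns 0-based labels; deterministic given D (ties resolved by the
    linkage algorithm's fixed scan order). K = 1 puts everything in one
    cluster; K > n is an error.
    """
    n = D.n
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n:
        raise ValueError(f"cannot form K={K} clusters from n={n} samples")
    if K == 1:
        return np.zeros(n, dtype=np.intp)
    Z = linkage(squareform(D.matrix, checks=False), method="average")
    labels = fcluster(Z, t=K, criterion="maxclust") - 1
    return labels.astype(np.intp)


@dataclass
class ConsensusResult:
    """Final consensus partition with per-cluster sparse fits.

    ``model`` is the reported mixture estimator: pi from consensus cluster
    sizes, beta from the per-cluster SIS-MCP fits, sigma from the
    degrees-of-freedom-corrected residual variance on each cluster.
    """

    labels: np.ndarray             # (n,) 0-based cluster labels
    fits: list[SparseFit]
    sizes: np.ndarray              # (K,) cluster sample counts
    model: MixtureModel


def clusterwise_select(
    X: np.ndarray,
    y: np.ndarray,
    labels: np.ndarray,
    min_cluster_size: int = MIN_CLUSTER_SIZE,
    **fit_kw,
) -> ConsensusResult:
    """Independent SIS-MCP variable selection on each consensus cluster.

    Clusters below ``min_cluster_size`` get an intercept-only fit with an
    empty selected-variable list. A single all-encompassing cluster reduces
    to a plain SIS-MCP fit of the whole sample.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    labels = np.asarray(labels, dtype=np.intp)
    n = len(y)
    ks = np.unique(labels)
    K = len(ks)
    # relabel to contiguous 0..K-1 preserving order
    remap = {int(k): i for i, k in enumerate(ks)}
    labels = np.asarray([remap[int(l)] for l in labels], dtype=np.intp)

    pis = np.zeros(K)
    fits: list[SparseFit] = []
    sigmas = np.zeros(K)
    sizes = np.zeros(K, dtype=int)
    for k in range(K):
        idx = np.flatnonzero(labels == k)
        sizes[k] = len(idx)
        pis[k], fit, sigmas[k] = update_component(
            X, y, idx, n_total=n, min_cluster_size=min_cluster_size, **fit_kw
        )
        fits.append(fit)
    model = MixtureModel(pi=pis, betas=fits, sigmas=sigmas)
    return ConsensusResult(labels=labels, fits=fits, sizes=sizes, model=model)


def fit_mixture(
    X: np.ndarray,
    y: np.ndarray,
    K: int,
    T: int = 500,
    t0: int = 100,
    seed: int | None = None,
    **kw,
):
    """End-to-end pipeline: ICC chain -> consensus partition -> clusterwise
    selection. Returns ``(ConsensusResult, ICCTrace)``."""
    from .icc import run_icc

    trace = run_icc(X, y, K=K, T=T, t0=t0, seed=seed, **kw)
    if K == 1:
        labels = np.zeros(len(y), dtype=np.intp)
    else:
        D = dissimilarity(trace)
        labels = consensus_cluster(D, K)
    result = clusterwise_select(X, y, labels, **{
        k: v for k, v in kw.items() if k == "min_cluster_size"
    })
    return result, trace


def dendrogram_newick(D: DissimilarityMatrix, leaf_names=None) -> str:
    """Newick text of the average-linkage dendrogram of D."""
    Z = linkage(squareform(D.matrix, checks=False), method="average")
    tree = to_tree(Z)
    if leaf_names is None:
        leaf_names = [str(i) for i in range(D.n)]

    def rec(node, parent_dist):
        length = parent_dist - node.dist
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});"


def plot_dendrogram(D: DissimilarityMatrix, ax=None, **kw):
    """Matplotlib dendrogram of the consensus tree (plotting helper)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    Z = linkage(squareform(D.matrix, checks=False), method="average")
    dendrogram(Z, ax=ax, no_labels=D.n > 40, **kw)
    ax.set_ylabel("average co-assignment dissimilarity")
    return ax
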