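"""Stage-profile clustering of differentially expressed miRNAs.

Hard groups come from deterministic agglomerative clustering of per-feature
standardised expression profiles (Euclidean distance, complete linkage by
default), with the tree cut into k groups (default 5, the number of distinct
stage profiles the analysis expects). Soft fuzzy c-means memberships are
provided for profile visualisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist


@dataclass
class ClusterAssignment:
    labels: pd.Series                 # feature_id -> cluster label in 1..k
    cluster_profiles: pd.DataFrame    # cluster label x columns, mean profile
    memberships: pd.DataFrame | None = None   # feature x cluster fuzzy weights
    tree_newick: str | None = None

    @property
    def k(self) -> int:
        return int(self.labels.max())


def standardize_profiles(profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-feature standardisation to mean 0, sd 1; constant rows are an error."""
    mu = profiles.mean(axis=1)
    sd = profiles.std(axis=1, ddof=0)
    flat = sd[sd == 0].index.tolist()
    if flat:
        raise ValueError(f"constant profile cannot be standardised: {flat[:5]}")
    return profiles.sub(mu, axis=0).div(sd, axis=0)


def _to_newick(Z: np.ndarray, leaf_names: list[str]) -> str:
    tree = hierarchy.to_tree(Z)

    def rec(node) -> str:
        if node.is_leaf():
            return leaf_names[node.id]
        return f"({rec(node.left)},{rec(node.right)}):{node.dist:.6g}"

    return rec(tree) + ";"


def hierarchical_clusters(profiles: pd.DataFrame, k: int,
                          linkage: str = "complete",
                          distance: str = "euclidean") -> ClusterAssignment:
    """Agglomerative clustering of feature profiles, cut into k groups.

    Features are processed in sorted id order so the result does not depend on
    input row order. Cluster labels are renumbered 1..k by order of first
    appearance along the sorted feature list.
    """
    n = profiles.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, {n}]")
    ordered = profiles.sort_index(kind="mergesort")
    X = ordered.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("profiles contain non-finite values")
    Z = hierarchy.linkage(pdist(X, metric=distance), method=linkage)
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    # renumber by first appearance for determinism
    remap: dict[int, int] = {}
    labels = np.empty_like(raw)
    for i, lab in enumerate(raw):
        if lab not in remap:
            remap[lab] = len(remap) + 1
        labels[i] = remap[lab]
    label_s = pd.Series(labels, index=ordered.index, name="cluster")
    prof = ordered.groupby(label_s).mean()
    prof.index.name = "cluster"
    return ClusterAssignment(label_s, prof,
                             tree_newick=_to_newick(Z, list(ordered.index)))


def fuzzy_profiles(profiles: pd.DataFrame, k: int, m: float = 2.0,
                   rng_seed: int = 0, tol: float = 1e-6,
                   max_iter: int = 200) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fuzzy c-means soft memberships for profile plots.

    ``profiles`` must already be standardised per feature (constant rows are
    rejected). Returns (memberships: feature x cluster, centroids: cluster x
    column). The objective sum_ij u_ij^m d_ij^2 is non-increasing across
    iterations; iteration stops when the maximum centroid shift falls below
    ``tol`` or after ``max_iter`` rounds.
    """
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    sd = profiles.std(axis=1, ddof=0)
    flat = sd[sd == 0].index.tolist()
    if flat:
        raise ValueError(f"constant profile reached fuzzy clustering: {flat[:5]}")
    X = profiles.sort_index(kind="mergesort").to_numpy(dtype=float)
    index = profiles.sort_index(kind="mergesort").index
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, {n}]")
    rng = np.random.default_rng(rng_seed)
    U = rng.dirichlet(np.ones(k), size=n)                 # n x k
    centroids = np.zeros((k, X.shape[1]))
    for _ in range(max_iter):
        W = U ** m
        centroids_new = (W.T @ X) / W.sum(axis=0)[:, None]
        d2 = np.maximum(
            ((X[:, None, :] - centroids_new[None, :, :]) ** 2).sum(axis=2), 0.0)
        zero = d2 < 1e-12
        with np.errstate(divide="ignore"):
            inv = d2 ** (-1.0 / (m - 1.0))        # d^{-2/(m-1)} with d2 = d^2
        U_new = np.where(
            zero.any(axis=1, keepdims=True),
            zero / np.maximum(zero.sum(axis=1, keepdims=True), 1),
            inv / inv.sum(axis=1, keepdims=True),
        )
        shift = np.abs(centroids_new - centroids).max() if centroids.any() else np.inf
        centroids = centroids_new
        U = U_new
        if shift < tol:
            break
    memberships = pd.DataFrame(U, index=index,
                               columns=[i + 1 for i in range(k)])
    cent = pd.DataFrame(centroids, index=[i + 1 for i in range(k)],
                        columns=profiles.columns)
    return memberships, cent


def fcm_objective(X: np.ndarray, U: np.ndarray, centroids: np.ndarray,
                  m: float) -> float:
    """The fuzzy c-means objective; exposed for monotonicity checks."""
    d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    return float(((U ** m) * d2).sum())
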