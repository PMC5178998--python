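"""Agglomerative Ward linkage applied directly to supplied dissimilarities.

This is the historical "ward.D" behavior of the R clustering stack: the
Lance-Williams update

    d(i∪j, k) = [ (n_i+n_k) d(i,k) + (n_j+n_k) d(j,k) - n_k d(i,j) ]
                / (n_i + n_j + n_k)

is applied to the dissimilarities as given, without squaring, which is what
makes it usable on a Pearson distance (1 - r) that is not Euclidean.  SciPy's
``linkage(..., 'ward')`` squares internally (the "ward.D2" convention), so
the update is implemented here.

Among equal-cost merges the pair with the smallest lexicographic (i, j) of
current cluster row positions is merged, making the dendrogram deterministic.
"""

from __future__ import annotations

import numpy as np

__all__ = ["ward_linkage", "cut_merges"]


def ward_linkage(dist: np.ndarray) -> np.ndarray:
    """Cluster items given a square symmetric dissimilarity matrix.

    Returns a SciPy-style linkage matrix Z with rows
    (cluster_a, cluster_b, merge_cost, new_size); original items are
    0..n-1, the cluster formed at step t gets id n+t.
    """
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least two items")
    work = d.copy()
    np.fill_diagonal(work, np.inf)
    sizes = np.ones(n)
    cluster_id = np.arange(n)
    active = np.ones(n, dtype=bool)
    Z = np.empty((n - 1, 4))
    masked = work.copy()
    for step in range(n - 1):
        # row-major argmin => first occurrence is the lexicographically
        # smallest (i, j) among ties
        flat = np.argmin(masked)
        i, j = divmod(flat, n)
        if i > j:
            i, j = j, i
        cost = work[i, j]
        ni, nj = sizes[i], sizes[j]
        Z[step] = (cluster_id[i], cluster_id[j], cost, ni + nj)
        # Lance-Williams ward.D update into row/col i
        k = active.copy()
        k[i] = k[j] = False
        nk = sizes[k]
        dik = work[i, k]
        djk = work[j, k]
        new = ((ni + nk) * dik + (nj + nk) * djk - nk * cost) / (ni + nj + nk)
        work[i, k] = new
        work[k, i] = new
        masked[i, k] = new
        masked[k, i] = new
        active[j] = False
        sizes[i] = ni + nj
        cluster_id[i] = n + step
        masked[j, :] = np.inf
        masked[:, j] = np.inf
        masked[i, i] = np.inf
    return Z


def cut_merges(Z: np.ndarray, n: int, k: int) -> np.ndarray:
    """Labels 0..k-1 after applying the first n-k merges of ``Z``.

    Cutting by merge order (rather than by height) is robust to the
    inversions ward.D can produce on non-Euclidean input.  Labels are
    assigned in order of each cluster's smallest item index, so the
    labeling is deterministic.
    """
    if k < 1 or k > n:
        raise ValueError(f"k={k} outside [1, {n}]")
    parent = np.arange(n + max(0, n - k))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step in range(n - k):
        a, b, _, _ = Z[step]
        new = n + step
        parent[find(int(a))] = new
        parent[find(int(b))] = new
    roots = [find(i) for i in range(n)]
    labels = np.empty(n, dtype=int)
    seen: dict[int, int] = {}
    for i, r in enumerate(roots):
        if r not in seen:
            seen[r] = len(seen)
        labels[i] = seen[r]
    return labels
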