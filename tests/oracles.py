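"""Independent reference implementations used to cross-check the package.

These deliberately avoid the code paths they validate: the clustering
oracle merges clusters by exhaustive pairwise search instead of calling
scipy's hierarchy machinery, and the smoothing oracle builds and applies
the separable Gaussian kernel by hand.
"""

import numpy as np
from scipy.spatial.distance import pdist, squareform


def single_linkage_labels(X: np.ndarray, k: int) -> np.ndarray:
    """Exhaustive single-linkage agglomeration: start from singletons and
    repeatedly merge the two clusters whose closest member pair is nearest,
    until ``k`` clusters remain. O(n^3); fine for n <= 200."""
    n = len(X)
    if k >= n:
        return np.arange(n)
    D = squareform(pdist(X))
    np.fill_diagonal(D, np.inf)
    members: list[list[int]] = [[i] for i in range(n)]
    dist = D.copy()  # current cluster-to-cluster minimum distances
    while len(members) > k:
        m = len(members)
        a, b = divmod(int(np.argmin(dist)), m)
        if a > b:
            a, b = b, a
        newrow = np.minimum(dist[a], dist[b])
        dist[a, :] = newrow
        dist[:, a] = newrow
        dist[a, a] = np.inf
        keep = [i for i in range(m) if i != b]
        dist = dist[np.ix_(keep, keep)]
        members[a].extend(members[b])
        del members[b]
    labels = np.empty(n, dtype=int)
    for lab, mem in enumerate(members):
        labels[mem] = lab
    return labels


def canonical_partition(labels) -> tuple:
    """Relabel a partition by order of first appearance so two labelings of
    the same partition compare equal."""
    seen: dict = {}
    return tuple(seen.setdefault(int(l), len(seen)) for l in labels)


def minmax_weighted(features: np.ndarray, weights) -> np.ndarray:
    """The same scaling contract the clustering applies, computed
    independently: min-max to [0,1] per column, then weighted."""
    lo = features.min(axis=0)
    span = features.max(axis=0) - lo
    span[span == 0] = 1.0
    return (features - lo) / span * np.asarray(weights, dtype=float)


def gaussian_smooth_dense(mat: np.ndarray, sigmas: tuple, truncate: float = 4.0) -> np.ndarray:
    """Direct separable Gaussian convolution with edge replication,
    matching the kernel construction convention (radius = int(t*sigma+0.5),
    unit-sum kernel)."""
    out = np.asarray(mat, dtype=float).copy()
    for axis, sigma in enumerate(sigmas):
        if sigma <= 0:
            continue
        radius = int(truncate * sigma + 0.5)
        x = np.arange(-radius, radius + 1)
        kernel = np.exp(-0.5 * (x / sigma) ** 2)
        kernel /= kernel.sum()
        moved = np.moveaxis(out, axis, -1)
        padded = np.pad(moved, [(0, 0)] * (moved.ndim - 1) + [(radius, radius)], mode="edge")
        conv = np.empty_like(moved)
        for idx in np.ndindex(moved.shape[:-1]):
            conv[idx] = np.convolve(padded[idx], kernel, mode="valid")
        out = np.moveaxis(conv, -1, axis)
    return out
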