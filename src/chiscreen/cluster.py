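"""Two-way hierarchical clustering of weighted interaction profiles.

Similarity is the uncentered Pearson correlation (the cosine of the angle
between weight vectors, with no mean subtraction), converted to a distance
d = 1 - s, and clustered agglomeratively with average linkage (UPGMA): the
distance between two clusters is the unweighted arithmetic mean of all
cross-pair leaf distances.  Rows (alleles) and columns (genes) are
clustered independently on the same weighted matrix.

All-zero profiles have an undefined cosine and are dropped (with a warning)
before clustering — in the screen these are the genes that never
interacted with any point allele.

Ties in the minimum inter-cluster distance are broken by the smallest
(row index, column index) in the current cluster ordering, which makes the
merge sequence deterministic across platforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .matrix import WeightedMatrix


class UndefinedSimilarityError(ValueError):
    """Cosine similarity is undefined for an all-zero profile."""


def uncentered_pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Cosine similarity: sum(x*y) / (||x|| * ||y||), no mean-centering."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 1:
        raise ValueError(f"need equal-length 1-d vectors, got {x.shape} and {y.shape}")
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise UndefinedSimilarityError("similarity undefined for an all-zero vector")
    return float(np.clip(np.dot(x, y) / (nx * ny), -1.0, 1.0))


def similarity_to_distance(s: float) -> float:
    """d = 1 - s, mapping similarity in [-1, 1] onto distance in [0, 2]."""
    if not -1.0 - 1e-12 <= s <= 1.0 + 1e-12:
        raise ValueError(f"similarity {s} outside [-1, 1]")
    return float(1.0 - np.clip(s, -1.0, 1.0))


def similarity_matrix(profiles: np.ndarray) -> np.ndarray:
    """Pairwise uncentered Pearson similarity between the rows of `profiles`.

    Raises :class:`UndefinedSimilarityError` if any row is all-zero.
    """
    profiles = np.asarray(profiles, dtype=float)
    norms = np.linalg.norm(profiles, axis=1)
    if np.any(norms == 0):
        bad = np.nonzero(norms == 0)[0].tolist()
        raise UndefinedSimilarityError(f"all-zero profiles at rows {bad}")
    unit = profiles / norms[:, None]
    s = unit @ unit.T
    np.clip(s, -1.0, 1.0, out=s)
    np.fill_diagonal(s, 1.0)
    return s


@dataclass(frozen=True)
class Dendrogram:
    """An agglomerative merge tree.

    Leaves are numbered 0..n-1 in the order of `ids`; the node created by
    merge ``t`` (0-based) has index ``n + t``.  `merges` records, first to
    last, ``(node_a, node_b, join_similarity)`` with join_similarity =
    1 - merge distance.
    """

    ids: tuple[str, ...]
    merges: tuple[tuple[int, int, float], ...]

    def __post_init__(self) -> None:
        n = len(self.ids)
        if len(self.merges) != max(n - 1, 0):
            raise ValueError(f"{n} leaves require {n - 1} merges, got {len(self.merges)}")
        consumed: set[int] = set()
        for t, (a, b, s) in enumerate(self.merges):
            for node in (a, b):
                if node in consumed or not 0 <= node < n + t:
                    raise ValueError(f"merge {t}: node {node} invalid or reused")
                consumed.add(node)
            if not np.isfinite(s):
                raise ValueError(f"merge {t}: non-finite join similarity")

    @property
    def n_leaves(self) -> int:
        return len(self.ids)

    @property
    def merge_heights(self) -> tuple[float, ...]:
        return tuple(1.0 - s for _, _, s in self.merges)

    def leaf_order(self) -> tuple[str, ...]:
        """Ids in dendrogram display order (left child subtree first)."""
        n = self.n_leaves
        if n == 1:
            return self.ids
        children = {n + t: (a, b) for t, (a, b, _) in enumerate(self.merges)}
        order: list[str] = []
        stack = [n + len(self.merges) - 1]
        while stack:
            node = stack.pop()
            if node < n:
                order.append(self.ids[node])
            else:
                a, b = children[node]
                stack.append(b)  # popped after a: left-to-right order
                stack.append(a)
        return tuple(order)


def average_linkage(dist: np.ndarray, ids: Sequence[str]) -> Dendrogram:
    """UPGMA clustering of a symmetric distance matrix.

    Uses the Lance-Williams average update; the pair merged at each step is
    the minimum-distance pair, ties broken by smallest (row, column) index
    over the currently active cluster slots.
    """
    d = np.array(dist, dtype=float)
    n = d.shape[0]
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError(f"distance matrix must be square, got {d.shape}")
    if n != len(ids):
        raise ValueError("ids length does not match matrix size")
    if n < 2:
        raise ValueError("need at least 2 items to cluster")
    if np.isnan(d).any():
        raise ValueError("NaN distances")
    if not np.isfinite(d).all():
        raise ValueError("non-finite distances")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix not symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-8):
        raise ValueError("distance matrix diagonal not zero")

    work = d.copy()
    np.fill_diagonal(work, np.inf)
    active = np.ones(n, dtype=bool)
    sizes = np.ones(n, dtype=int)
    node = np.arange(n)
    merges: list[tuple[int, int, float]] = []
    for t in range(n - 1):
        # row-major argmin lands on the smallest (row, col) among ties
        flat = int(np.argmin(work))
        i, j = divmod(flat, n)
        if i > j:  # symmetric partner appears first row-major, keep i < j
            i, j = j, i
        height = work[i, j]
        merges.append((int(node[i]), int(node[j]), float(1.0 - height)))
        # Lance-Williams average-linkage update into slot i
        others = active.copy()
        others[i] = others[j] = False
        new_row = (sizes[i] * work[i, others] + sizes[j] * work[j, others]) / (
            sizes[i] + sizes[j]
        )
        work[i, others] = new_row
        work[others, i] = new_row
        work[j, :] = np.inf
        work[:, j] = np.inf
        active[j] = False
        sizes[i] += sizes[j]
        node[i] = n + t
    return Dendrogram(ids=tuple(ids), merges=tuple(merges))


def drop_empty_profiles(m: WeightedMatrix) -> WeightedMatrix:
    """Remove all-zero rows and columns, warning about what was dropped."""
    w = m.weights
    zero_rows = w.index[(w == 0).all(axis=1)].tolist()
    zero_cols = w.columns[(w == 0).all(axis=0)].tolist()
    if zero_rows:
        warnings.warn(f"dropping {len(zero_rows)} all-zero allele profiles: {zero_rows}")
    if zero_cols:
        warnings.warn(f"dropping {len(zero_cols)} all-zero gene profiles: {zero_cols}")
    if zero_rows or zero_cols:
        w = w.drop(index=zero_rows, columns=zero_cols)
    return WeightedMatrix(weights=w)


def two_way_cluster(m: WeightedMatrix) -> tuple[Dendrogram, Dendrogram]:
    """Cluster alleles (rows) and genes (columns) independently.

    Returns (allele dendrogram, gene dendrogram) built on 1 - uncentered
    Pearson distances of the respective profile vectors.
    """
    filtered = drop_empty_profiles(m)
    w = filtered.weights
    if w.shape[0] < 2 or w.shape[1] < 2:
        raise ValueError(
            f"need at least 2 nonzero rows and columns, got {w.shape[0]}x{w.shape[1]}"
        )
    dend_rows = average_linkage(_profile_distances(w.to_numpy()), w.index)
    dend_cols = average_linkage(_profile_distances(w.to_numpy().T), w.columns)
    return dend_rows, dend_cols


def _profile_distances(profiles: np.ndarray) -> np.ndarray:
    d = 1.0 - similarity_matrix(profiles)
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2.0


def cut_clusters(dend: Dendrogram, k: int) -> dict[str, int]:
    """Partition leaves into k clusters by undoing the last k-1 merges.

    Labels are 1..k, assigned in order of first appearance along the
    dendrogram leaf order.
    """
    n = dend.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside 1..{n}")
    parent = list(range(n + len(dend.merges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for t, (a, b, _) in enumerate(dend.merges[: n - k]):
        new = n + t
        parent[find(a)] = new
        parent[find(b)] = new

    index_of = {leaf: i for i, leaf in enumerate(dend.ids)}
    labels: dict[str, int] = {}
    roots: dict[int, int] = {}
    for leaf in dend.leaf_order():
        root = find(index_of[leaf])
        if root not in roots:
            roots[root] = len(roots) + 1
        labels[leaf] = roots[root]
    return labels


def cluster_sets(assignment: Mapping[str, int]) -> dict[int, frozenset[str]]:
    """Invert an id -> label assignment into label -> member set."""
    out: dict[int, set[str]] = {}
    for leaf, label in assignment.items():
        out.setdefault(label, set()).add(leaf)
    return {k: frozenset(v) for k, v in out.items()}
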