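"""Ward agglomerative clustering and silhouette-guided group selection.

The dissimilarity matrix produced by optimal matching is not Euclidean, so
Ward's method is executed directly through the Lance–Williams recurrence on
*squared* dissimilarities (the classical behavior of agglomerative-nesting
implementations); merge heights are reported on the original scale.  The
starting number of behavioral groups is chosen from average silhouette
widths (ASW, in [-1, 1]): the most parsimonious k whose ASW meets the 0.5
benchmark, or failing that the k with the highest ASW.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distance import DissimilarityMatrix


def _as_matrix(d) -> np.ndarray:
    if isinstance(d, DissimilarityMatrix):
        return d.values
    m = np.asarray(d, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("dissimilarity must be a square matrix")
    if not np.allclose(m, m.T):
        raise ValueError("dissimilarity matrix must be symmetric")
    if (m < -1e-12).any():
        raise ValueError("dissimilarity matrix must be non-negative")
    return m


@dataclass
class MergeTree:
    """Agglomeration history: (n - 1) merges over n leaves.

    ``merges`` follows the linkage-matrix convention: row t holds
    ``[id_a, id_b, height, size]`` where ids < n are leaves and id n + t is
    the cluster created at step t.  Ward is monotone, so heights are
    non-decreasing.
    """

    n_leaves: int
    merges: np.ndarray

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


def ward_tree(d) -> MergeTree:
    """Ward agglomeration of a precomputed dissimilarity matrix.

    Deterministic given the matrix: merge-candidate ties are broken by the
    lowest (row-major) index pair.
    """
    m = _as_matrix(d)
    n = m.shape[0]
    if n < 2:
        raise ValueError("need at least two items")
    W = m.astype(float) ** 2  # squared-dissimilarity working matrix
    np.fill_diagonal(W, np.inf)
    active = np.ones(n, dtype=bool)
    size = np.ones(n)
    cid = np.arange(n)
    merges = np.empty((n - 1, 4))
    for step in range(n - 1):
        Wm = np.where(active[:, None] & active[None, :], W, np.inf)
        i, j = np.unravel_index(np.argmin(Wm), Wm.shape)  # lowest-index tie-break
        if i > j:
            i, j = j, i
        h = float(np.sqrt(W[i, j]))
        si, sj = size[i], size[j]
        merges[step] = (cid[i], cid[j], h, si + sj)
        for v in np.nonzero(active)[0]:
            if v == i or v == j:
                continue
            sv = size[v]
            W[i, v] = W[v, i] = (
                (si + sv) * W[i, v] + (sj + sv) * W[j, v] - sv * W[i, j]
            ) / (si + sj + sv)
        active[j] = False
        size[i] = si + sj
        cid[i] = n + step
    return MergeTree(n, merges)


def cut_tree(tree: MergeTree, k: int) -> np.ndarray:
    """Labels (0..k-1) of the k-group partition; cuts refine as k grows."""
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    parent = np.arange(2 * n - 1)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for t in range(n - k):
        a, b, _, _ = tree.merges[t]
        new = n + t
        parent[find(int(a))] = new
        parent[find(int(b))] = new
    roots: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for leaf in range(n):
        r = find(leaf)
        labels[leaf] = roots.setdefault(r, len(roots))
    return labels


def average_silhouette(d, labels) -> float:
    """Mean silhouette width s(i) = (b(i) - a(i)) / max(a(i), b(i)).

    Singleton clusters contribute s(i) = 0, as does the degenerate 0/0
    case of coincident points.
    """
    m = _as_matrix(d)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(labels) != m.shape[0]:
        raise ValueError("labels do not match matrix size")
    if len(groups) < 2:
        raise ValueError("silhouette undefined for a single group")
    s = np.zeros(len(labels))
    for i in range(len(labels)):
        own = labels == labels[i]
        n_own = own.sum()
        if n_own == 1:
            continue  # singleton convention
        a = m[i, own].sum() / (n_own - 1)
        b = min(m[i, labels == g].mean() for g in groups if g != labels[i])
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(s.mean())


@dataclass
class GroupSelection:
    """ASW profile over k and the selected starting group number."""

    asw_by_k: dict[int, float]
    chosen_k: int
    rule_applied: str  # "parsimonious_above_benchmark" or "max_asw"
    benchmark: float = 0.5

    def to_dict(self) -> dict:
        return {
            "asw_by_k": {str(k): v for k, v in self.asw_by_k.items()},
            "chosen_k": self.chosen_k,
            "rule_applied": self.rule_applied,
            "benchmark": self.benchmark,
        }


def select_from_asw(
    asw_by_k: dict[int, float], benchmark: float = 0.5
) -> tuple[int, str]:
    """Apply the selection rule to a precomputed ASW map."""
    if not asw_by_k:
        raise ValueError("empty ASW map")
    above = sorted(k for k, v in asw_by_k.items() if v >= benchmark)
    if above:
        return above[0], "parsimonious_above_benchmark"
    best = max(asw_by_k.values())
    k = min(k for k, v in asw_by_k.items() if v == best)  # ties -> smaller k
    return k, "max_asw"


def select_group_number(d, kmax: int = 10, benchmark: float = 0.5) -> GroupSelection:
    """ASW-based choice of the starting number of behavioral groups.

    Evaluates k = 2..min(kmax, n-1) on the Ward tree; picks the smallest k
    with ASW >= ``benchmark``, else the k maximizing ASW (ties -> smaller).
    """
    m = _as_matrix(d)
    n = m.shape[0]
    if n < 3:
        raise ValueError("need at least three items to select a group number")
    tree = ward_tree(m)
    asw_by_k = {
        k: average_silhouette(m, cut_tree(tree, k))
        for k in range(2, min(kmax, n - 1) + 1)
    }
    chosen, rule = select_from_asw(asw_by_k, benchmark)
    return GroupSelection(asw_by_k, chosen, rule, benchmark)
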