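"""UPGMA morphogroup discovery.

Candidate specimen groups are cut from a UPGMA dendrogram built on
Euclidean distances between complete measurement rows.  Agglomeration
uses size-weighted average linkage; a merge at distance d places the new
node at height d/2, so leaves sit at height 0 and the tree is ultrametric.
Tie-breaking is the lowest-index pair first, which makes the whole
procedure deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.spatial.distance import pdist, squareform

from .containers import MeasurementMatrix

__all__ = [
    "pairwise_distances",
    "upgma",
    "cut_to_k",
    "Dendrogram",
    "MorphogroupPartition",
]


def pairwise_distances(m: MeasurementMatrix, standardize: bool = False) -> np.ndarray:
    """Symmetric Euclidean distance grid between specimen rows.

    With ``standardize`` the columns are z-scored first.  Missing cells
    are an error — impute first.
    """
    if m.mask.any():
        raise ValueError("matrix has missing cells; run imputation first")
    X = m.values.astype(float)
    if standardize:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    return squareform(pdist(X, metric="euclidean"))


@dataclass
class Dendrogram:
    """Result of UPGMA agglomeration.

    ``merges`` lists, in agglomeration order, tuples
    ``(left_id, right_id, height, size)`` where ids < n are leaves and ids
    >= n are earlier merge nodes; ``height`` is half the merge distance.
    """

    labels: list
    merges: list = field(default_factory=list)
    tie_log: list = field(default_factory=list)

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def heights(self) -> np.ndarray:
        return np.array([h for _, _, h, _ in self.merges])

    def leaf_sets(self) -> dict[int, frozenset]:
        """Map every node id to the set of leaf labels beneath it."""
        n = self.n_leaves
        out = {i: frozenset([self.labels[i]]) for i in range(n)}
        for k, (a, b, _, _) in enumerate(self.merges):
            out[n + k] = out[a] | out[b]
        return out

    def to_tree(self) -> dendropy.Tree:
        """Export as a dendropy ultrametric tree (edge lengths from heights)."""
        taxa = dendropy.TaxonNamespace([str(l) for l in self.labels])
        nodes = {}
        height = {}
        for i, label in enumerate(self.labels):
            nd = dendropy.Node(taxon=taxa.get_taxon(str(label)))
            nodes[i] = nd
            height[i] = 0.0
        n = self.n_leaves
        for k, (a, b, h, _) in enumerate(self.merges):
            nd = dendropy.Node()
            for child in (a, b):
                nodes[child].edge.length = h - height[child]
                nd.add_child(nodes[child])
            nodes[n + k] = nd
            height[n + k] = h
        tree = dendropy.Tree(taxon_namespace=taxa)
        tree.seed_node = nodes[n + len(self.merges) - 1]
        tree.is_rooted = True
        return tree


def upgma(d: np.ndarray, labels) -> Dendrogram:
    """Size-weighted average-linkage agglomeration of a distance grid."""
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance grid must be square")
    if np.isnan(d).any():
        raise ValueError("NaN in distance grid")
    if not np.allclose(d, d.T, atol=1e-9):
        raise ValueError("distance grid not symmetric")
    if (d < 0).any():
        raise ValueError("negative distances")
    labels = list(labels)
    n = d.shape[0]
    if len(labels) != n:
        raise ValueError("label count does not match grid")
    if n < 1:
        raise ValueError("empty grid")

    dend = Dendrogram(labels)
    work = d.astype(float).copy()
    np.fill_diagonal(work, np.inf)
    active = {i: (i, 1) for i in range(n)}  # slot -> (node id, cluster size)
    next_id = n
    for step in range(n - 1):
        # row-major argmin = lowest-index pair first on exact ties
        flat = int(np.argmin(work))
        si, sj = divmod(flat, work.shape[1])
        if si > sj:
            si, sj = sj, si
        dist = work[si, sj]
        iu = np.triu_indices_from(work, 1)
        n_tied = int((work[iu] == dist).sum())
        if n_tied > 1:
            dend.tie_log.append((step, (si, sj), n_tied))
        id_i, size_i = active[si]
        id_j, size_j = active[sj]
        new_size = size_i + size_j
        dend.merges.append((id_i, id_j, dist / 2.0, new_size))
        # size-weighted average linkage update, stored in slot si
        for sk in list(active):
            if sk in (si, sj):
                continue
            work[si, sk] = work[sk, si] = (
                size_i * work[si, sk] + size_j * work[sj, sk]) / new_size
        work[sj, :] = np.inf
        work[:, sj] = np.inf
        active[si] = (next_id, new_size)
        del active[sj]
        next_id += 1
    return dend


@dataclass
class MorphogroupPartition:
    """Assignment of specimens to k groups cut from a dendrogram."""

    k: int
    assignment: dict  # specimen id -> group index (0..k-1)
    source: str = ""
    dfa_accuracy: float | None = None
    validation_mode: str | None = None  # "split" | "jackknife"

    def __post_init__(self):
        groups = set(self.assignment.values())
        if len(groups) != self.k:
            raise ValueError("assignment does not realise k groups")

    @property
    def specimen_ids(self) -> list:
        return list(self.assignment)

    def groups(self) -> list[list]:
        out = [[] for _ in range(self.k)]
        for s, g in self.assignment.items():
            out[g].append(s)
        return out

    def labels_for(self, ids) -> np.ndarray:
        return np.array([self.assignment[i] for i in ids])

    def group_sizes(self) -> list[int]:
        return [len(g) for g in self.groups()]


def cut_to_k(dend: Dendrogram, k: int) -> MorphogroupPartition:
    """Cut the dendrogram into the k subtrees below the k-1 highest merges.

    UPGMA merge heights are non-decreasing, so the k-1 highest merge nodes
    are the last k-1 merges; exact height ties are resolved by earliest
    merge order (recorded in the dendrogram's tie log at agglomeration
    time), keeping the cut deterministic.
    """
    n = dend.n_leaves
    if not (2 <= k <= n):
        raise ValueError(f"k must be in [2, {n}]")
    keep = dend.merges[: len(dend.merges) - (k - 1)]
    parent = list(range(n + len(keep)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for idx, (a, b, _, _) in enumerate(keep):
        node = n + idx
        for child in (a, b):
            parent[find(child)] = find(node)

    roots = {}
    assignment = {}
    for i in range(n):
        r = find(i)
        if r not in roots:
            roots[r] = len(roots)
        assignment[dend.labels[i]] = roots[r]
    return MorphogroupPartition(k=k, assignment=assignment, source=f"upgma-cut-k{k}")
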