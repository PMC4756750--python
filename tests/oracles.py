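"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (dynamic programming over explicit
state labelings, full topology enumeration, pairwise double loops) and
shares no code path with the implementations it checks.
"""

import itertools

import numpy as np

from morphodelim.containers import CharacterMatrix
from morphodelim.parsimony import (_all_edges, _copy_adj, _insert_leaf,
                                   _postorder, _three_leaf_tree)


def random_character_matrix(rng, n_taxa, n_char, n_states=3, miss=0.1):
    cells = rng.integers(0, n_states, size=(n_taxa, n_char)).astype(np.int8)
    mask = rng.random((n_taxa, n_char)) < miss
    cells[mask] = -1
    for i in range(n_taxa):
        if (cells[i] < 0).all():
            cells[i, 0] = 0
    return CharacterMatrix([f"t{i}" for i in range(n_taxa)], cells)


def all_topologies(n):
    """Every unrooted binary topology on leaves 0..n-1 (adjacency maps)."""
    trees = [_three_leaf_tree(0, 1, 2, n)]
    for leaf in range(3, n):
        new = []
        for adj in trees:
            for e in _all_edges(adj):
                a = _copy_adj(adj)
                _insert_leaf(a, leaf, e, n + (leaf - 2))
                new.append(a)
        trees = new
    return trees


def sankoff_length(adj, cm):
    """Minimum-mutation count by explicit DP over internal state labelings."""
    n = cm.n_taxa
    INF = 10 ** 6
    total = 0
    root = min(adj)
    for c in range(cm.n_characters):
        order, parent = _postorder(adj, root)
        cost = {}
        for v in order:
            kids = [w for w in adj[v] if w != parent[v]]
            if v < n:
                s = cm.cells[v, c]
                base = [0 if (s < 0 or s == st) else INF for st in range(5)]
            else:
                base = [0] * 5
            for w in kids:
                base = [base[st] + min(cost[w][s2] + (0 if s2 == st else 1)
                                       for s2 in range(5))
                        for st in range(5)]
            cost[v] = base
        total += min(cost[root])
    return total


def brute_force_min_length(cm, topologies=None):
    """(best length, set of optimal topology keys) by full enumeration."""
    from morphodelim.parsimony import _leaf_sets, _split_key, _tree_length
    n = cm.n_taxa
    topologies = topologies or all_topologies(n)
    ls = _leaf_sets(cm)
    lengths = [_tree_length(t, ls) for t in topologies]
    best = min(lengths)
    keys = {_split_key(t, n) for t, L in zip(topologies, lengths) if L == best}
    return best, keys


def naive_upgma(d):
    """Step-by-step size-weighted average-linkage agglomeration.

    Returns merge records (left, right, height, size) using the same id
    convention as the implementation but computed with per-pair python
    loops over explicit cluster member lists.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    clusters = {i: [i] for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            # average of the original pairwise distances between members
            dist = np.mean([d[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or dist < best[0] - 1e-12:
                best = (dist, a, b)
        dist, a, b = best
        members = clusters.pop(a) + clusters.pop(b)
        clusters[next_id] = members
        merges.append((a, b, dist / 2.0, len(members)))
        next_id += 1
    return merges


def pairwise_euclidean_loops(X):
    n = X.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = np.sqrt(np.sum((X[i] - X[j]) ** 2))
    return out
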