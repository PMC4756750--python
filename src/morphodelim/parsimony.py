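"""Unordered-character maximum parsimony.

Tree length is Fitch length: the minimum number of unordered state
changes, summed over characters.  The module provides

* :func:`fitch_length` — score any (possibly polytomous) tree,
* :func:`exact_search` — branch-and-bound over stepwise addition,
  guaranteed to return *all* minimum-length trees (<= 14 taxa),
* :func:`heuristic_search` — random-addition-sequence starts plus TBR
  branch swapping with an equal-length tree buffer and a final closure
  pass over the buffer, for matrices too large to enumerate,
* :func:`consensus` — strict or majority-rule consensus with clade
  frequencies,
* :func:`char_step_bounds` / :func:`ensemble_ci_ri` — the Kluge–Farris
  ensemble consistency and retention indices,
* :func:`bremer_supports` and :func:`jackknife_supports` — decay and
  character-jackknife clade support.

Internally trees are unrooted binary adjacency maps over integer node ids
(leaves ``0..n-1``); character states are uint8 bitmasks so one numpy
vector op scores all characters of a node at once.  TBR candidates are
scored exactly and cheaply with the junction rule: the length of joining
two subtrees A and B at edges eA, eB equals
``L(A) + L(B) + #{characters whose edge state sets are disjoint}``,
where the edge state set is the Fitch preliminary set of the subtree
rooted at a virtual node on that edge.  Every accepted tree is re-scored
from scratch; the invariant is asserted.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .containers import MAX_STATE, CharacterMatrix

__all__ = [
    "TreeSet",
    "fitch_length",
    "char_step_bounds",
    "ensemble_ci_ri",
    "exact_search",
    "heuristic_search",
    "consensus",
    "clade_frequencies",
    "bremer_supports",
    "jackknife_supports",
    "support_table",
    "mpt_count",
]

_ALL = np.uint8((1 << (MAX_STATE + 1)) - 1)  # "any state" mask for ?/-

EXACT_TAXON_LIMIT = 14


# ---------------------------------------------------------------------------
# encoding and basic Fitch machinery
# ---------------------------------------------------------------------------

def _leaf_sets(cm: CharacterMatrix) -> np.ndarray:
    """n_taxa x n_char uint8 bitmasks; missing/inapplicable = any state."""
    cells = cm.cells
    sets = np.where(cells >= 0, np.left_shift(1, np.maximum(cells, 0)), _ALL)
    return sets.astype(np.uint8)


def _combine(a: np.ndarray, b: np.ndarray):
    """Fitch combine of two state-set vectors: (result, union_count)."""
    inter = a & b
    empty = inter == 0
    res = np.where(empty, a | b, inter)
    return res, int(empty.sum())


def _hartigan(children_sets):
    """Exact minimum-mutation combine of >2 child state sets (Hartigan).

    Keeps the states carried by the largest number of children; the cost
    is children minus that maximum.  Reduces to Fitch for two children.
    """
    C = np.stack(children_sets)  # k x m
    counts = np.stack([((C >> s) & 1).sum(axis=0)
                       for s in range(MAX_STATE + 1)])
    K = counts.max(axis=0)
    V = np.zeros(C.shape[1], dtype=np.uint8)
    for s in range(MAX_STATE + 1):
        V |= ((counts[s] == K).astype(np.uint8) << s)
    return V, int((C.shape[0] - K).sum())


def _postorder(adj, root):
    """Iterative postorder of the tree rooted at ``root``.

    Returns (order, parent) where order lists nodes children-first.
    """
    parent = {root: None}
    stack = [root]
    order = []
    while stack:
        v = stack.pop()
        order.append(v)
        for w in adj[v]:
            if w != parent[v]:
                parent[w] = v
                stack.append(w)
    order.reverse()
    return order, parent


def _down_sets(adj, leaf_sets, root):
    """Fitch down-pass sets for the tree rooted at ``root`` (may be a leaf).

    Returns (length, down, order, parent); ``down[v]`` is the preliminary
    set of the subtree at v, *including* v's own state set when v is a
    leaf (this matters when the root itself is a leaf).
    """
    n = leaf_sets.shape[0]
    order, parent = _postorder(adj, root)
    down = {}
    length = 0
    for v in order:
        items = [leaf_sets[v]] if v < n else []
        items += [down[w] for w in adj[v] if w != parent[v]]
        if len(items) == 1:
            down[v] = items[0]
        elif len(items) == 2:
            down[v], cost = _combine(items[0], items[1])
            length += cost
        else:  # polytomy: Hartigan's exact generalisation
            down[v], cost = _hartigan(items)
            length += cost
    return length, down, order, parent


def _tree_length(adj, leaf_sets):
    """Unrooted Fitch length (rooting-invariant)."""
    length, _, _, _ = _down_sets(adj, leaf_sets, min(adj))
    return length


def _edge_sets(adj, leaf_sets, root):
    """Per-edge virtual-root Fitch sets of the component containing root.

    Returns (L, edges, R) where edges[i] = (parent, child) and R[i] is the
    preliminary set of the whole component rooted on that edge.  Each
    undirected edge appears once.  If ``root`` is internal with degree 2
    (a junction about to be suppressed), its two incident edges represent
    one merged edge; only the first is listed.
    """
    n = leaf_sets.shape[0]
    L, down, order, parent = _down_sets(adj, leaf_sets, root)
    # up[v]: preliminary set of (component minus subtree v), rooted at parent
    up = {}
    for v in order[::-1]:  # preorder
        kids = [w for w in adj[v] if w != parent[v]]
        for w in kids:
            others = [down[x] for x in kids if x != w]
            if v < n:
                others.append(leaf_sets[v])
            if parent[v] is not None:
                others.append(up[v])
            acc = others[0]
            for o in others[1:]:
                acc, _ = _combine(acc, o)
            up[w] = acc
    edges, sets = [], []
    skip = None
    if root >= n and len(adj[root]) == 2:
        skip = (root, adj[root][1])  # merged edge: keep only one side
    for v in order:
        if parent[v] is None or skip == (parent[v], v):
            continue
        r, _ = _combine(down[v], up[v])
        edges.append((parent[v], v))
        sets.append(r)
    return L, edges, np.array(sets, dtype=np.uint8)


# ---------------------------------------------------------------------------
# adjacency-tree utilities
# ---------------------------------------------------------------------------

def _copy_adj(adj):
    return {v: list(ws) for v, ws in adj.items()}


def _three_leaf_tree(a, b, c, hub):
    return {a: [hub], b: [hub], c: [hub], hub: [a, b, c]}


def _insert_leaf(adj, leaf, edge, new_internal):
    """Attach ``leaf`` by subdividing ``edge`` with ``new_internal``."""
    u, v = edge
    adj[u] = [new_internal if w == v else w for w in adj[u]]
    adj[v] = [new_internal if w == u else w for w in adj[v]]
    adj[new_internal] = [u, v, leaf]
    adj[leaf] = [new_internal]


def _remove_leaf(adj, leaf):
    """Inverse of _insert_leaf; returns the freed internal node id."""
    hub = adj[leaf][0]
    u, v = [w for w in adj[hub] if w != leaf]
    adj[u] = [v if w == hub else w for w in adj[u]]
    adj[v] = [u if w == hub else w for w in adj[v]]
    del adj[hub], adj[leaf]
    return hub


def _split_key(adj, n_leaves):
    """Canonical topology key: the set of non-trivial splits, each written
    as the frozenset of leaves on the side not containing leaf 0."""
    order, parent = _postorder(adj, 0)
    below = {}
    splits = set()
    for v in order:
        kids = [w for w in adj[v] if w != parent[v]]
        if not kids:
            below[v] = frozenset([v]) if v < n_leaves else frozenset()
            continue
        s = frozenset().union(*[below[w] for w in kids])
        if v < n_leaves:
            s = s | {v}
        below[v] = s
        if parent[v] is not None and 2 <= len(s) <= n_leaves - 2:
            splits.add(s)
    return frozenset(splits)


def _clades(adj, n_leaves):
    """Non-trivial clades relative to rooting at leaf 0 (= unrooted splits)."""
    return set(_split_key(adj, n_leaves))


# ---------------------------------------------------------------------------
# public scoring operations
# ---------------------------------------------------------------------------

def _adj_from_dendropy(tree: dendropy.Tree, taxon_names):
    index = {name: i for i, name in enumerate(taxon_names)}
    tree = tree.clone(depth=1)
    tree.deroot()  # score on the unrooted shape
    adj = {}
    next_id = itertools.count(len(taxon_names))
    node_id = {}

    def get_id(nd):
        if nd in node_id:
            return node_id[nd]
        if nd.is_leaf():
            label = nd.taxon.label if nd.taxon else None
            if label not in index:
                raise ValueError(f"leaf {label!r} not in the character matrix")
            node_id[nd] = index[label]
        else:
            node_id[nd] = next(next_id)
        return node_id[nd]

    for nd in tree.preorder_node_iter():
        i = get_id(nd)
        adj.setdefault(i, [])
        for ch in nd.child_nodes():
            j = get_id(ch)
            adj[i].append(j)
            adj.setdefault(j, []).append(i)
    leaves = [i for i, ws in adj.items() if len(ws) == 1]
    if sorted(i for i in adj if i < len(taxon_names)) != list(range(len(taxon_names))):
        raise ValueError("tree leaves do not match the matrix taxa")
    if len(leaves) != len(taxon_names):
        raise ValueError("tree leaves do not match the matrix taxa")
    return adj


def fitch_length(tree, cm: CharacterMatrix) -> int:
    """Fitch parsimony length of a tree for an unordered character matrix.

    ``tree`` may be a dendropy Tree (leaf labels matching ``cm`` taxa) or
    an internal adjacency map.  Polytomies are scored exactly via
    Hartigan's multi-child generalisation of the state-set pass.  Missing
    and inapplicable cells carry the full state set.
    """
    if isinstance(tree, dendropy.Tree):
        adj = _adj_from_dendropy(tree, cm.taxon_names)
    else:
        adj = tree
    return _tree_length(adj, _leaf_sets(cm))


def char_step_bounds(cm: CharacterMatrix):
    """Per-character (m_i, g_i).

    m_i = observed states - 1 is the minimum conceivable steps; for an
    unordered character g_i = scored taxa - count of the most frequent
    state is the maximum (star tree / no-structure) steps.
    """
    m = np.zeros(cm.n_characters, dtype=int)
    g = np.zeros(cm.n_characters, dtype=int)
    for c in range(cm.n_characters):
        col = cm.cells[:, c]
        scored = col[col >= 0]
        if scored.size == 0:
            continue
        _, counts = np.unique(scored, return_counts=True)
        m[c] = len(counts) - 1
        g[c] = scored.size - counts.max()
    return m, g


def ensemble_ci_ri(cm: CharacterMatrix, length: int):
    """Ensemble CI = sum(m)/L and RI = (sum(g) - L) / (sum(g) - sum(m)).

    RI is undefined (returned as nan) when sum(g) == sum(m).
    """
    m, g = char_step_bounds(cm)
    sm, sg = int(m.sum()), int(g.sum())
    if length < sm:
        raise ValueError(f"length {length} below the minimum conceivable {sm}")
    ci = sm / length if length > 0 else float("nan")
    ri = (sg - length) / (sg - sm) if sg > sm else float("nan")
    return float(ci), float(ri)


# ---------------------------------------------------------------------------
# TreeSet
# ---------------------------------------------------------------------------

@dataclass
class TreeSet:
    """A set of unrooted binary trees over one taxon set with lengths."""

    taxon_names: list
    trees: list                      # adjacency maps
    best_length: int
    per_tree_length: list = field(default_factory=list)

    def __post_init__(self):
        if self.per_tree_length and min(self.per_tree_length) < self.best_length:
            raise ValueError("per-tree length below best_length")

    def __len__(self):
        return len(self.trees)

    def to_dendropy(self, i: int = 0, outgroup=None,
                    taxon_namespace=None) -> dendropy.Tree:
        """Export tree i, rooted on the outgroup edge when given."""
        return _adj_to_dendropy(self.trees[i], self.taxon_names, outgroup,
                                taxon_namespace=taxon_namespace)

    def newick(self, i: int = 0, outgroup=None) -> str:
        return self.to_dendropy(i, outgroup).as_string(
            schema="newick", suppress_rooting=True).strip()


def _adj_to_dendropy(adj, taxon_names, outgroup=None, annotations=None,
                     taxon_namespace=None):
    n = len(taxon_names)
    taxa = taxon_namespace or dendropy.TaxonNamespace(list(taxon_names))
    # choose root edge: the split separating the outgroup if present,
    # else the pendant edge of the first outgroup taxon, else leaf 0's edge
    root_edge = (0, adj[0][0])
    if outgroup:
        og = frozenset(taxon_names.index(t) if isinstance(t, str) else t
                       for t in outgroup)
        order, parent = _postorder(adj, 0)
        below = {}
        cand = None
        for v in order:
            kids = [w for w in adj[v] if w != parent[v]]
            s = frozenset([v]) if v < n else frozenset()
            for w in kids:
                s |= below[w]
            below[v] = s
            if parent[v] is not None and (s == og or s == frozenset(range(n)) - og):
                cand = (parent[v], v)
        if cand is None:
            first = min(og)
            cand = (adj[first][0], first)
        root_edge = cand

    u, v = root_edge
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node

    def build(node_id, par_id, dnode):
        if node_id < n:
            dnode.taxon = taxa.get_taxon(str(taxon_names[node_id]))
        if annotations and node_id in annotations:
            dnode.label = str(annotations[node_id])
        for w in adj[node_id]:
            if w == par_id:
                continue
            ch = dendropy.Node()
            dnode.add_child(ch)
            build(w, node_id, ch)

    left = dendropy.Node()
    right = dendropy.Node()
    root.add_child(left)
    root.add_child(right)
    build(u, v, left)
    build(v, u, right)
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# stepwise addition and exact (branch-and-bound) search
# ---------------------------------------------------------------------------

def _addition_tree(leaf_sets, order, rng=None):
    """Stepwise-addition tree over ``order``; greedy min-cost insertion.

    Ties between equally good insertion edges are broken uniformly at
    random when ``rng`` is given, else by first occurrence.  Returns
    (adjacency, length).
    """
    n = leaf_sets.shape[0]
    order = list(order)
    hub = n
    adj = _three_leaf_tree(order[0], order[1], order[2], hub)
    next_internal = n + 1
    length = _tree_length(adj, leaf_sets)
    for leaf in order[3:]:
        L, edges, R = _edge_sets(adj, leaf_sets, order[0])
        inter = R & leaf_sets[leaf][None, :]
        costs = (inter == 0).sum(axis=1)
        best = costs.min()
        if rng is None:
            pick = int(costs.argmin())
        else:
            pick = int(rng.choice(np.where(costs == best)[0]))
        _insert_leaf(adj, leaf, edges[pick], next_internal)
        next_internal += 1
        length = L + int(best)
    return adj, length


def exact_search(cm: CharacterMatrix, outgroup=None) -> TreeSet:
    """Branch and bound over stepwise addition: all minimum-length trees.

    Enforced for at most 14 taxa; beyond that use heuristic_search.  The
    returned trees are unrooted; export with ``to_dendropy(outgroup=...)``
    places the root on the outgroup edge.
    """
    n = cm.n_taxa
    if n > EXACT_TAXON_LIMIT:
        raise ValueError(
            f"exact search is limited to {EXACT_TAXON_LIMIT} taxa "
            f"(got {n}); use heuristic_search")
    if n < 3:
        raise ValueError("need at least 3 taxa")
    leaf_sets = _leaf_sets(cm)
    if n == 3:
        adj = _three_leaf_tree(0, 1, 2, 3)
        L = _tree_length(adj, leaf_sets)
        return TreeSet(list(cm.taxon_names), [adj], L, [L])

    # initial upper bound from a greedy addition
    _, bound = _addition_tree(leaf_sets, range(n))
    best_trees = []
    best_len = bound

    hub = n
    adj = _three_leaf_tree(0, 1, 2, hub)

    def recurse(adj, next_leaf, next_internal, length):
        nonlocal best_len, best_trees
        if next_leaf == n:
            if length < best_len:
                best_len = length
                best_trees = [_copy_adj(adj)]
            elif length == best_len:
                best_trees.append(_copy_adj(adj))
            return
        L, edges, R = _edge_sets(adj, leaf_sets, 0)
        inter = R & leaf_sets[next_leaf][None, :]
        costs = (inter == 0).sum(axis=1)
        for ei in np.argsort(costs, kind="stable"):
            new_len = L + int(costs[ei])
            if new_len > best_len:
                break  # sorted: the rest are no better
            _insert_leaf(adj, next_leaf, edges[ei], next_internal)
            recurse(adj, next_leaf + 1, next_internal + 1, new_len)
            _remove_leaf(adj, next_leaf)

    recurse(adj, 3, n + 1, _tree_length(adj, leaf_sets))
    # deduplicate (different addition paths can yield one topology)
    seen, uniq = set(), []
    for t in best_trees:
        k = _split_key(t, n)
        if k not in seen:
            seen.add(k)
            uniq.append(t)
    return TreeSet(list(cm.taxon_names), uniq, best_len,
                   [best_len] * len(uniq))


# ---------------------------------------------------------------------------
# TBR branch swapping and heuristic search
# ---------------------------------------------------------------------------

def _all_edges(adj):
    return [(u, v) for u in adj for v in adj[u] if u < v]


def _tbr_best_moves(adj, leaf_sets, n_leaves):
    """Scan the full TBR neighbourhood with exact junction scoring.

    Returns (best_candidate_length, moves) where moves lists
    (cut_edge, reconnect_edge_A, reconnect_edge_B) achieving that length.
    """
    best = None
    moves = []
    for cut in _all_edges(adj):
        a, b = cut
        # detach: temporarily remove the edge
        adj[a].remove(b)
        adj[b].remove(a)
        try:
            sides = []
            for endpoint in (a, b):
                if not adj[endpoint]:  # isolated leaf component
                    sides.append((0, [("leaf", endpoint)],
                                  leaf_sets[endpoint][None, :]))
                else:
                    L, edges, R = _edge_sets(adj, leaf_sets, endpoint)
                    if endpoint >= n_leaves and len(adj[endpoint]) == 2:
                        # the junction will be suppressed: translate its
                        # incident edge to the merged edge it stands for
                        c1, c2 = adj[endpoint]
                        edges = [("merged", c1, c2) if e == (endpoint, c1)
                                 else e for e in edges]
                    sides.append((L, edges, R))
            (LA, eA, RA), (LB, eB, RB) = sides
            inter = RA[:, None, :] & RB[None, :, :]
            cost = (inter == 0).sum(axis=2) + (LA + LB)
            m = int(cost.min())
            if best is None or m < best:
                best = m
                moves = []
            if m == best:
                for i, j in zip(*np.where(cost == m)):
                    moves.append((cut, eA[int(i)], eB[int(j)]))
        finally:
            adj[a].append(b)
            adj[b].append(a)
    return best, moves


def _apply_tbr(adj, move):
    """Apply one TBR move, returning a new adjacency map."""
    (a, b), ea, eb = move
    adj = _copy_adj(adj)
    adj[a].remove(b)
    adj[b].remove(a)
    freed = []
    for endpoint in (a, b):
        if len(adj[endpoint]) == 2:  # suppress the degree-2 junction
            u, v = adj[endpoint]
            adj[u] = [v if w == endpoint else w for w in adj[u]]
            adj[v] = [u if w == endpoint else w for w in adj[v]]
            del adj[endpoint]
            freed.append(endpoint)
    it = iter(freed)

    def attach_point(edge):
        if edge[0] == "leaf":
            return edge[1]
        u, v = (edge[1], edge[2]) if edge[0] == "merged" else edge
        x = next(it)  # reuse a suppressed junction id
        adj[u] = [x if w == v else w for w in adj[u]]
        adj[v] = [x if w == u else w for w in adj[v]]
        adj[x] = [u, v]
        return x

    pa = attach_point(ea)
    pb = attach_point(eb)
    adj[pa].append(pb)
    adj[pb].append(pa)
    return adj


def _hill_climb(adj, length, leaf_sets, n_leaves, rng):
    """Strict-improvement TBR until a local optimum; exact rescoring."""
    while True:
        cand, moves = _tbr_best_moves(adj, leaf_sets, n_leaves)
        if cand is None or cand >= length:
            return adj, length
        move = moves[int(rng.integers(len(moves)))]
        adj = _apply_tbr(adj, move)
        new_len = _tree_length(adj, leaf_sets)
        assert new_len == cand, "junction-rule score mismatch"
        length = new_len


def heuristic_search(cm: CharacterMatrix, replicates: int = 100,
                     seed: int = 0, hold: int = 1000,
                     closure: bool = True) -> TreeSet:
    """Random-addition-sequence + TBR search.

    Per replicate a random-order stepwise-addition tree is TBR-swapped to
    a local optimum; a global buffer keeps up to ``hold`` distinct trees
    at the best length found.  With ``closure`` the buffer is expanded by
    swapping through equal-length TBR neighbours of every held tree, which
    approximates the full set of most parsimonious trees.  Deterministic
    per seed.
    """
    n = cm.n_taxa
    if n < 4:
        raise ValueError("need at least 4 taxa")
    leaf_sets = _leaf_sets(cm)
    rng = np.random.default_rng(seed)

    best_len = None
    buffer = {}
    for _ in range(replicates):
        order = rng.permutation(n)
        adj, length = _addition_tree(leaf_sets, order, rng)
        adj, length = _hill_climb(adj, length, leaf_sets, n, rng)
        if best_len is None or length < best_len:
            best_len = length
            buffer = {}
        if length == best_len and len(buffer) < hold:
            buffer.setdefault(_split_key(adj, n), adj)

    if closure:
        queue = list(buffer.values())
        while queue and len(buffer) < hold:
            adj = queue.pop()
            cand, moves = _tbr_best_moves(adj, leaf_sets, n)
            if cand is None or cand > best_len:
                continue
            if cand < best_len:
                # a held tree had an improving neighbour after all: follow it
                new = _apply_tbr(adj, moves[0])
                new, cand = _hill_climb(new, cand, leaf_sets, n, rng)
                best_len = cand
                buffer = {_split_key(new, n): new}
                queue = [new]
                continue
            for move in moves:
                new = _apply_tbr(adj, move)
                key = _split_key(new, n)
                if key not in buffer:
                    assert _tree_length(new, leaf_sets) == cand
                    buffer[key] = new
                    queue.append(new)
                    if len(buffer) >= hold:
                        break

    trees = list(buffer.values())
    return TreeSet(list(cm.taxon_names), trees, best_len,
                   [best_len] * len(trees))


def mpt_count(ts: TreeSet, cm: CharacterMatrix = None,
              collapse: bool = False) -> int:
    """Number of distinct most-parsimonious trees in a TreeSet.

    ``collapse=False`` counts distinct fully binary topologies.  With
    ``collapse=True`` (needs the matrix) edges whose contraction leaves
    the length unchanged are collapsed first, and the resulting
    (possibly polytomous) topologies are counted — reported MPT counts
    are sensitive to this convention.
    """
    n = len(ts.taxon_names)
    if not collapse:
        return len({_split_key(t, n) for t in ts.trees})
    if cm is None:
        raise ValueError("collapse counting needs the character matrix")
    leaf_sets = _leaf_sets(cm)
    keys = set()
    for adj in ts.trees:
        base = _tree_length(adj, leaf_sets)
        splits = set()
        order, parent = _postorder(adj, 0)
        below = {}
        for v in order:
            kids = [w for w in adj[v] if w != parent[v]]
            s = frozenset([v]) if v < n else frozenset()
            for w in kids:
                s |= below[w]
            below[v] = s
            if parent[v] is None or not (2 <= len(s) <= n - 2):
                continue
            contracted = _contract_edge(adj, (parent[v], v))
            if _tree_length(contracted, leaf_sets) > base:
                splits.add(s)  # the split has unambiguous support
        keys.add(frozenset(splits))
    return len(keys)


def _contract_edge(adj, edge):
    u, v = edge
    adj = _copy_adj(adj)
    adj[u].remove(v)
    adj[v].remove(u)
    for w in adj[v]:
        adj[w] = [u if x == v else x for x in adj[w]]
        adj[u].append(w)
    del adj[v]
    return adj


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def clade_frequencies(ts: TreeSet) -> dict:
    """Frequency in [0, 1] of every non-trivial clade across the tree set.

    Clades are keyed canonically: the frozenset of taxon indices on the
    side not containing taxon 0 (i.e. unrooted splits).
    """
    n = len(ts.taxon_names)
    counts = {}
    for adj in ts.trees:
        for s in _clades(adj, n):
            counts[s] = counts.get(s, 0) + 1
    return {s: c / len(ts.trees) for s, c in counts.items()}


def consensus(ts: TreeSet, cutoff: float = 0.5,
              outgroup=None) -> dendropy.Tree:
    """Majority-rule (freq > cutoff) or strict (cutoff=1.0) consensus.

    Node labels carry the clade frequency as a percentage.  Retained
    clades are mutually compatible for any cutoff >= 0.5 (asserted).
    """
    if len(ts.trees) == 0:
        raise ValueError("empty tree set")
    n = len(ts.taxon_names)
    freqs = clade_frequencies(ts)
    if cutoff >= 1.0:
        keep = {s: f for s, f in freqs.items() if f >= 1.0}
    else:
        keep = {s: f for s, f in freqs.items() if f > cutoff}
    for a, b in itertools.combinations(keep, 2):
        assert not (a & b) or (a <= b) or (b <= a), \
            "incompatible clades retained in consensus"

    taxa = dendropy.TaxonNamespace([str(t) for t in ts.taxon_names])
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    node_of = {frozenset(range(n)): root}
    for s in sorted(keep, key=len, reverse=True):
        parent_set = min((t for t in node_of if s < t), key=len)
        nd = dendropy.Node()
        nd.label = str(int(round(100 * keep[s])))
        node_of[parent_set].add_child(nd)
        node_of[s] = nd
    for i, name in enumerate(ts.taxon_names):
        leafsets = [t for t in node_of if i in t]
        parent_set = min(leafsets, key=len)
        nd = dendropy.Node(taxon=taxa.get_taxon(str(name)))
        node_of[parent_set].add_child(nd)
    tree.is_rooted = True
    if outgroup:
        og = {t.label if hasattr(t, "label") else str(t) for t in outgroup}
        mrca = tree.mrca(taxa=[taxa.get_taxon(t) for t in og])
        if mrca is not tree.seed_node:
            tree.reroot_at_edge(mrca.edge, update_bipartitions=False)
    return tree


# ---------------------------------------------------------------------------
# support metrics
# ---------------------------------------------------------------------------

def bremer_supports(cm: CharacterMatrix, best: TreeSet,
                    max_suboptimal: int = 10, seed: int = 0,
                    replicates: int = 20, clades=None) -> dict:
    """Bremer decay per consensus clade.

    decay(clade) = best length of a tree lacking the clade minus the
    optimal length.  A window search retains every tree visited within
    ``max_suboptimal`` extra steps; a clade never lost there is probed by
    a constrained re-search (penalising trees that contain it), and if it
    still never disappears the decay is reported as None, printed ">10".
    """
    n = len(best.taxon_names)
    leaf_sets = _leaf_sets(cm)
    rng = np.random.default_rng(seed)
    if clades is None:
        clades = sorted(clade_frequencies(best).keys(), key=sorted)
    base = best.best_length

    # window sweep: RAS + TBR accepting anything within the window,
    # recording the best length seen for each tree lacking each clade
    best_without = {s: np.inf for s in clades}

    def note(adj, length):
        present = _clades(adj, n)
        for s in clades:
            if s not in present and length < best_without[s]:
                best_without[s] = length

    for adj, length in zip(best.trees, best.per_tree_length):
        note(adj, length)
    for _ in range(replicates):
        order = rng.permutation(n)
        adj, length = _addition_tree(leaf_sets, order, rng)
        note(adj, length)
        # drift within the window, recording every visited tree
        for _ in range(30):
            cand, moves = _tbr_best_moves(adj, leaf_sets, n)
            if cand is None:
                break
            move = moves[int(rng.integers(len(moves)))]
            adj = _apply_tbr(adj, move)
            length = _tree_length(adj, leaf_sets)
            note(adj, length)
            if length > base + max_suboptimal:
                break

    out = {}
    for s in clades:
        if np.isfinite(best_without[s]):
            out[s] = int(best_without[s] - base)
        else:
            out[s] = _constrained_decay(cm, leaf_sets, s, base, n, rng,
                                        max_suboptimal)
    return out


def _constrained_decay(cm, leaf_sets, clade, base, n, rng, window,
                       tries: int = 10, steps: int = 60):
    """Best length of a tree lacking ``clade`` via penalised hill-climb."""
    penalty = 10 * (base + window + 1)

    def score(adj):
        L = _tree_length(adj, leaf_sets)
        return L + (penalty if clade in _clades(adj, n) else 0), L

    best = np.inf
    for _ in range(tries):
        order = rng.permutation(n)
        adj, _ = _addition_tree(leaf_sets, order, rng)
        cur, L = score(adj)
        for _ in range(steps):
            cand, moves = _tbr_best_moves(adj, leaf_sets, n)
            if cand is None:
                break
            improved = False
            for move in (moves[i] for i in rng.permutation(len(moves))):
                trial = _apply_tbr(adj, move)
                s, L2 = score(trial)
                if s < cur:
                    adj, cur, L = trial, s, L2
                    improved = True
                    break
            if not improved:
                break
        if cur < penalty and L < best:
            best = L
    if not np.isfinite(best) or best - base > window:
        return None  # printed as ">{window}"
    return int(best - base)


def jackknife_supports(cm: CharacterMatrix, replicates: int = 1000,
                       p_delete: float = 0.3679, seed: int = 0,
                       search_replicates: int = 2, hold: int = 50) -> dict:
    """Character-jackknife clade support (percent of replicates).

    Each replicate deletes every character independently with probability
    ``p_delete`` (default e^-1, the conventional removal probability), runs
    a reduced-effort search, takes the majority-rule consensus of its best
    trees, and scores which clades that consensus contains.
    """
    n = cm.n_taxa
    rng = np.random.default_rng(seed)
    counts = {}
    redraws = 0
    for _ in range(replicates):
        while True:
            keep = np.where(rng.random(cm.n_characters) >= p_delete)[0]
            if keep.size:
                break
            redraws += 1
        sub = cm.subset_characters(keep)
        ts = heuristic_search(sub, replicates=search_replicates,
                              seed=int(rng.integers(2 ** 31)), hold=hold,
                              closure=False)
        freqs = clade_frequencies(ts)
        for s, f in freqs.items():
            if f > 0.5:
                counts[s] = counts.get(s, 0) + 1
    return {s: 100.0 * c / replicates for s, c in counts.items()}


def support_table(ts: TreeSet, bremer: dict = None,
                  jackknife: dict = None) -> pd.DataFrame:
    """Assemble a per-clade support table (frequencies in %, Bremer decay,
    jackknife %).  Clades are keyed by the sorted taxon names of the side
    not containing the first taxon."""
    freqs = clade_frequencies(ts)
    rows = []
    for s, f in sorted(freqs.items(), key=lambda kv: (-kv[1], sorted(kv[0]))):
        names = tuple(sorted(ts.taxon_names[i] for i in s))
        br = None if bremer is None else bremer.get(s)
        rows.append({
            "clade": names,
            "majority_frequency": 100.0 * f,
            "bremer": ">10" if (bremer is not None and br is None) else br,
            "jackknife": None if jackknife is None else jackknife.get(s, 0.0),
        })
    return pd.DataFrame(rows)
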