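"""Parsimony and distance tree inference, support measures, tree utilities.

Parsimony uses Fitch counting with two gap treatments: ``FIFTH_STATE``
(a gap is a character state of its own, so shared gaps can group taxa) and
``MISSING`` (gaps and ``N`` are fully ambiguous).  Character states are
bit masks (A=1, C=2, G=4, T=8, gap=16), so set intersection/union are
bitwise operations vectorised over alignment columns.

Tree search is a deterministic, seeded simplification of a parsimony
ratchet: random-addition Wagner starts, steepest NNI+SPR hill climbing, and
a reweighting ratchet.  All equally best distinct topologies encountered are
returned (capped at 1,000).
"""

from __future__ import annotations

import itertools
import math
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import dendropy
import numpy as np

from .core import ConcatenatedAlignment, GapMode

__all__ = [
    "fitch_score",
    "search_mp",
    "nj_tree",
    "distance_matrix",
    "jc69_distance",
    "tn93_distance",
    "concordance_counts",
    "unique_topologies",
    "robinson_foulds",
    "bipartition_set",
    "indel_step_decomposition",
    "count_rooted_topologies",
    "round_half_up",
]

GAP = 16
_FULL = 15  # {A,C,G,T}

# code (from core.encode) -> state bit mask, per gap mode
_MASKS = {
    GapMode.FIFTH_STATE: np.array([1, 2, 4, 8, _FULL, GAP], dtype=np.uint8),
    GapMode.MISSING: np.array([1, 2, 4, 8, _FULL, _FULL], dtype=np.uint8),
}

MAX_TREES = 1000


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal-style half-up rounding (3.25 -> 3.3 at 1 digit)."""
    factor = 10.0 ** ndigits
    return math.floor(x * factor + 0.5) / factor


# ----------------------------------------------------------- tree plumbing


def _leaf_labels(tree: dendropy.Tree) -> List[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def _tree_to_adjacency(
    tree: dendropy.Tree, taxa: Sequence[str]
) -> Dict[int, List[int]]:
    """Convert a dendropy tree to an adjacency map over integer node ids.

    Leaves get ids 0..n-1 in ``taxa`` order; internal nodes follow.  Degree-2
    nodes (e.g. a rooted tree's root) are suppressed, so the result is the
    unrooted topology.
    """
    index = {t: i for i, t in enumerate(taxa)}
    adj: Dict[int, List[int]] = {}
    next_id = len(taxa)
    node_id: Dict[dendropy.Node, int] = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            if node.taxon is None or node.taxon.label not in index:
                raise ValueError("tree leaf not present in taxa")
            node_id[node] = index[node.taxon.label]
        else:
            node_id[node] = next_id
            next_id += 1
        adj.setdefault(node_id[node], [])
        if node.parent_node is not None:
            a, b = node_id[node.parent_node], node_id[node]
            adj[a].append(b)
            adj[b].append(a)
    # suppress degree-2 nodes (typically the root of a rooted input)
    for v in [v for v, nb in adj.items() if len(nb) == 2]:
        a, b = adj[v]
        adj[a] = [x if x != v else b for x in adj[a]]
        adj[b] = [x if x != v else a for x in adj[b]]
        del adj[v]
    return adj


def _adjacency_to_tree(
    adj: Dict[int, List[int]], taxa: Sequence[str],
    namespace: Optional[dendropy.TaxonNamespace] = None,
) -> dendropy.Tree:
    ns = namespace or dendropy.TaxonNamespace(list(taxa))
    tree = dendropy.Tree(taxon_namespace=ns)
    n = len(taxa)
    if len(adj) == 1:  # single leaf
        tree.seed_node.taxon = ns.get_taxon(taxa[0])
        return tree
    # root at an internal node adjacent to leaf 0 (or leaf 0's neighbor)
    start = adj[0][0]
    nodes: Dict[int, dendropy.Node] = {}

    def build(v: int, parent: Optional[int]) -> dendropy.Node:
        node = dendropy.Node()
        nodes[v] = node
        if v < n:
            node.taxon = ns.get_taxon(taxa[v])
        for w in adj[v]:
            if w != parent:
                node.add_child(build(w, v))
        return node

    tree.seed_node = build(start, None)
    tree.is_rooted = False
    return tree


def _postorder_arrays(
    adj: Dict[int, List[int]], n_leaves: int
) -> List[Tuple[int, int, int]]:
    """Left-deep binarised postorder (node, left, right) triples.

    The unrooted tree is rooted at the first internal node; multifurcations
    are nested left-deep with virtual node ids >= max(adj)+1.
    """
    root = next(v for v in adj if v >= n_leaves) if len(adj) > 2 else None
    if root is None:
        # 2-leaf tree: single virtual root
        return [(2, 0, 1)]
    triples: List[Tuple[int, int, int]] = []
    next_virtual = max(adj) + 1

    def visit(v: int, parent: Optional[int]) -> int:
        nonlocal next_virtual
        children = [w for w in adj[v] if w != parent]
        if not children:
            return v
        ids = [visit(w, v) for w in children]
        acc = ids[0]
        for other in ids[1:-1]:
            triples.append((next_virtual, acc, other))
            acc = next_virtual
            next_virtual += 1
        triples.append((v, acc, ids[-1]))
        return v

    visit(root, None)
    return triples


# ---------------------------------------------------------- Fitch scoring


def _state_matrix(aln: ConcatenatedAlignment, mode: GapMode) -> np.ndarray:
    """(n_taxa, n_columns) uint8 bit-mask matrix in aln.taxa order."""
    return _MASKS[mode][aln.matrix()]


def _compress(states: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Unique site patterns and their multiplicities."""
    patterns, counts = np.unique(states, axis=1, return_counts=True)
    return patterns, counts


def _fitch_counts(
    triples: List[Tuple[int, int, int]],
    leaf_states: np.ndarray,
    weights: np.ndarray,
) -> float:
    """Weighted Fitch length over patterns.

    ``leaf_states`` is (n_leaves, P); internal node states are computed on
    the fly following the postorder triples.
    """
    n_leaves, P = leaf_states.shape
    max_id = max(t[0] for t in triples) + 1
    states = np.zeros((max_id, P), dtype=np.uint8)
    states[:n_leaves] = leaf_states
    total = 0.0
    for node, left, right in triples:
        inter = states[left] & states[right]
        empty = inter == 0
        states[node] = np.where(empty, states[left] | states[right], inter)
        if empty.any():
            total += float(weights[empty].sum())
    return total


def fitch_score(
    tree: dendropy.Tree, aln: ConcatenatedAlignment, mode: GapMode
) -> int:
    """Fitch parsimony length of ``tree`` on ``aln`` under a gap mode."""
    if set(_leaf_labels(tree)) != set(aln.taxa):
        raise ValueError("tree leaves do not match alignment taxa")
    if aln.n_columns == 0:
        return 0
    adj = _tree_to_adjacency(tree, aln.taxa)
    triples = _postorder_arrays(adj, aln.n_taxa)
    patterns, counts = _compress(_state_matrix(aln, mode))
    return int(round(_fitch_counts(triples, patterns, counts.astype(np.float64))))


# ----------------------------------------------------------- bipartitions


def bipartition_set(tree: dendropy.Tree) -> Set[FrozenSet[str]]:
    """Non-trivial bipartitions of the unrooted topology.

    Each bipartition is canonicalised as the side *not* containing the
    lexicographically smallest leaf label.
    """
    labels = sorted(_leaf_labels(tree))
    ref = labels[0]
    full = set(labels)
    out: Set[FrozenSet[str]] = set()
    tree2 = tree  # operate on clades of the given rooting; sides are the same
    for node in tree2.preorder_internal_node_iter():
        clade = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if len(clade) < 2 or len(clade) > len(full) - 2:
            continue
        side = clade if ref not in clade else frozenset(full - clade)
        if 2 <= len(side) <= len(full) - 2:
            out.add(side)
    return out


def robinson_foulds(a: dendropy.Tree, b: dendropy.Tree) -> int:
    """Unrooted Robinson-Foulds distance (bipartition symmetric difference)."""
    la, lb = set(_leaf_labels(a)), set(_leaf_labels(b))
    if la != lb:
        raise ValueError("trees have different leaf sets")
    return len(bipartition_set(a) ^ bipartition_set(b))


def unique_topologies(trees: Sequence[dendropy.Tree]) -> int:
    """Number of distinct unrooted topologies (RF distance 0 classes)."""
    seen = set()
    for t in trees:
        seen.add(frozenset(bipartition_set(t)))
    return len(seen)


def _prune_to(tree: dendropy.Tree, keep: Set[str]) -> dendropy.Tree:
    clone = tree.clone(depth=1)
    taxa = [tx for tx in clone.taxon_namespace if tx.label in keep]
    clone.retain_taxa(taxa)
    return clone


def concordance_counts(
    reference: dendropy.Tree, trees: Sequence[dendropy.Tree]
) -> dendropy.Tree:
    """Annotate each internal edge of ``reference`` with the number of input
    trees that contain the same bipartition.

    Trees with missing leaves are pruned to the common leaf set first; the
    reference bipartitions are restricted to that set for comparison.  The
    returned tree is a clone whose internal nodes carry a
    ``concordance_count`` annotation (also mirrored into the node label).
    """
    if not trees:
        raise ValueError("empty tree list")
    common = set(_leaf_labels(reference))
    for t in trees:
        common &= set(_leaf_labels(t))
    if len(common) < 4:
        raise ValueError("fewer than 4 shared leaves")
    tree_biparts = []
    for t in trees:
        pruned = _prune_to(t, common) if set(_leaf_labels(t)) != common else t
        tree_biparts.append(bipartition_set(pruned))

    ref = reference.clone(depth=1)
    labels_sorted = sorted(common)
    ref_label = labels_sorted[0]
    for node in ref.preorder_internal_node_iter():
        clade = {lf.taxon.label for lf in node.leaf_iter()} & common
        side = clade if ref_label not in clade else common - clade
        if not (2 <= len(side) <= len(common) - 2):
            continue
        key = frozenset(side)
        count = sum(1 for bp in tree_biparts if key in bp)
        node.annotations.add_new("concordance_count", count)
        node.label = str(count)
    return ref


# -------------------------------------------------------------- distances


def _pair_site_stats(row_a: np.ndarray, row_b: np.ndarray) -> Tuple[int, int, int, int, np.ndarray]:
    """Compared sites, mismatches, transition counts, base counts for a pair.

    Rows are uint8 code vectors (core.encode).  Sites where either row is a
    gap or N are excluded from comparison.
    """
    ok = (row_a < 4) & (row_b < 4)
    a, b = row_a[ok], row_b[ok]
    n = int(ok.sum())
    diff = a != b
    # transitions: A<->G (codes 0,2), C<->T (codes 1,3)
    p1 = int(np.sum(diff & (((a == 0) & (b == 2)) | ((a == 2) & (b == 0)))))
    p2 = int(np.sum(diff & (((a == 1) & (b == 3)) | ((a == 3) & (b == 1)))))
    freqs = np.bincount(np.concatenate([a, b]), minlength=4).astype(float)
    return n, int(diff.sum()), p1, p2, freqs


class SaturationError(ValueError):
    """Raised when a pairwise distance is undefined (saturated) for a pair."""


def jc69_distance(p: float) -> float:
    """Jukes-Cantor distance from a mismatch proportion."""
    if p >= 0.75:
        raise SaturationError(f"JC69 undefined for p={p:.4f} >= 0.75")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def tn93_distance(
    p1: float, p2: float, q: float, freqs: np.ndarray
) -> float:
    """Tamura-Nei (1993) distance from transition/transversion proportions.

    ``p1``: A<->G proportion, ``p2``: C<->T proportion, ``q``: transversion
    proportion, ``freqs``: base frequencies (A,C,G,T).  HKY distances are the
    equal-transition-class special case and are served by this formula.
    """
    ga, gc, gg, gt = (float(x) for x in freqs / freqs.sum())
    gr, gy = ga + gg, gc + gt
    if min(ga, gc, gg, gt) <= 0:
        # degenerate composition: fall back to JC on total difference
        return jc69_distance(p1 + p2 + q)
    k1 = 2.0 * ga * gg / gr
    k2 = 2.0 * gc * gt / gy
    w1 = 1.0 - p1 / k1 - q / (2.0 * gr)
    w2 = 1.0 - p2 / k2 - q / (2.0 * gy)
    w3 = 1.0 - q / (2.0 * gr * gy)
    if w1 <= 0 or w2 <= 0 or w3 <= 0:
        raise SaturationError("TN93 undefined (log argument <= 0)")
    k3 = 2.0 * (gr * gy - ga * gg * gy / gr - gc * gt * gr / gy)
    return -k1 * math.log(w1) - k2 * math.log(w2) - k3 * math.log(w3)


def distance_matrix(
    aln: ConcatenatedAlignment, model: str = "JC69"
) -> np.ndarray:
    """Model-corrected pairwise distance matrix over aln.taxa order."""
    model = model.upper()
    if model not in {"JC69", "TN93", "HKY"}:
        raise ValueError(f"unknown distance model {model!r}")
    mat = aln.matrix()
    n = aln.n_taxa
    d = np.zeros((n, n), dtype=float)
    for i, j in itertools.combinations(range(n), 2):
        nc, nd, p1, p2, freqs = _pair_site_stats(mat[i], mat[j])
        if nc == 0:
            raise ValueError(
                f"no comparable sites between {aln.taxa[i]} and {aln.taxa[j]}"
            )
        try:
            if model == "JC69":
                dij = jc69_distance(nd / nc)
            else:
                q = (nd - p1 - p2) / nc
                dij = tn93_distance(p1 / nc, p2 / nc, q, freqs)
        except SaturationError as exc:
            raise SaturationError(
                f"saturated pair {aln.taxa[i]} / {aln.taxa[j]}: {exc}"
            ) from exc
        d[i, j] = d[j, i] = dij
    return d


def nj_tree(aln: ConcatenatedAlignment, model: str = "JC69") -> dendropy.Tree:
    """Neighbor joining on the model-corrected distance matrix.

    Standard Saitou-Nei agglomeration; the returned tree is unrooted with
    branch lengths.  Ties in the Q matrix are broken by smallest index pair,
    so the result is deterministic.
    """
    if aln.n_taxa < 3:
        raise ValueError("NJ needs at least 3 taxa")
    d = distance_matrix(aln, model)
    return nj_from_distance_matrix(d, aln.taxa)


def nj_from_distance_matrix(
    d: np.ndarray, taxa: Sequence[str]
) -> dendropy.Tree:
    n = len(taxa)
    ns = dendropy.TaxonNamespace(list(taxa))
    nodes: List[dendropy.Node] = []
    for t in taxa:
        node = dendropy.Node()
        node.taxon = ns.get_taxon(t)
        nodes.append(node)
    active = list(range(n))
    D = d.astype(float).copy()

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # deterministic argmin: first occurrence in row-major order
        ai, aj = np.unravel_index(int(np.argmin(q)), q.shape)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        parent = dendropy.Node()
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        # distances to the new node
        new_row = 0.5 * (D[i, active] + D[j, active] - dij)
        k = D.shape[0]
        D = np.pad(D, ((0, 1), (0, 1)))
        D[k, active] = new_row
        D[active, k] = new_row
        D[k, k] = 0.0
        nodes.append(parent)
        active = [x for x in active if x not in (i, j)] + [k]

    tree = dendropy.Tree(taxon_namespace=ns)
    root = tree.seed_node
    if len(active) == 3:
        i, j, k = active
        li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
        lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
        lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        for idx, ln in zip((i, j, k), (li, lj, lk)):
            nodes[idx].edge.length = ln
            root.add_child(nodes[idx])
    else:  # exactly 2 remaining (n == 3 never reaches here; n == 2 unused)
        i, j = active
        nodes[i].edge.length = nodes[j].edge.length = D[i, j] / 2.0
        root.add_child(nodes[i])
        root.add_child(nodes[j])
    tree.is_rooted = False
    return tree


# ------------------------------------------------------------- tree search


def _edges_of(adj: Dict[int, List[int]]) -> List[Tuple[int, int]]:
    return sorted(
        {(min(a, b), max(a, b)) for a, nbs in adj.items() for b in nbs}
    )


def _copy_adj(adj: Dict[int, List[int]]) -> Dict[int, List[int]]:
    return {k: list(v) for k, v in adj.items()}


def _insert_leaf(
    adj: Dict[int, List[int]], leaf: int, edge: Tuple[int, int], new_node: int
) -> Dict[int, List[int]]:
    """Attach ``leaf`` by subdividing ``edge`` with ``new_node``."""
    a, b = edge
    out = _copy_adj(adj)
    out[a] = [x if x != b else new_node for x in out[a]]
    out[b] = [x if x != a else new_node for x in out[b]]
    out[new_node] = [a, b, leaf]
    out[leaf] = [new_node]
    return out


def _adj_key(adj: Dict[int, List[int]], n_leaves: int) -> FrozenSet[FrozenSet[int]]:
    """Canonical topology key: the set of non-trivial leaf bipartitions."""
    leaves = set(range(n_leaves)) & set(adj)
    out = set()
    seen = set()

    def side(v: int, parent: int) -> FrozenSet[int]:
        stack = [(v, parent)]
        acc = set()
        while stack:
            x, p = stack.pop()
            if x in leaves:
                acc.add(x)
            for w in adj[x]:
                if w != p:
                    stack.append((w, x))
        return frozenset(acc)

    for a, b in _edges_of(adj):
        s = side(b, a)
        if 2 <= len(s) <= len(leaves) - 2:
            canon = s if 0 not in s else frozenset(leaves - s)
            out.add(canon)
    return frozenset(out)


def _spr_neighbors(
    adj: Dict[int, List[int]], n_leaves: int
) -> Iterable[Dict[int, List[int]]]:
    """All SPR rearrangements (includes every NNI) of an unrooted tree.

    Enumeration order is deterministic (sorted edges), which fixes the
    tie-breaking of the search.
    """
    edges = _edges_of(adj)
    for a, b in edges:
        for prune_root, anchor in ((b, a), (a, b)):
            # prune the subtree containing prune_root (cut edge anchor-prune_root)
            if len(adj[anchor]) != 3:
                continue  # anchor must be internal so it can be suppressed
            rest_nb = [x for x in adj[anchor] if x != prune_root]
            pruned = _copy_adj(adj)
            pruned[anchor] = []
            # collect pruned-side nodes
            side_nodes = set()
            stack = [(prune_root, anchor)]
            while stack:
                x, p = stack.pop()
                side_nodes.add(x)
                for w in pruned[x]:
                    if w != p and w != anchor:
                        stack.append((w, x))
            pruned[prune_root] = [x for x in adj[prune_root] if x != anchor]
            # suppress anchor in the remaining tree
            u, v = rest_nb
            pruned[u] = [x if x != anchor else v for x in adj[u]]
            pruned[v] = [x if x != anchor else u for x in adj[v]]
            del pruned[anchor]
            # regraft on every edge of the remaining tree
            remaining_edges = [
                (x, y)
                for x, y in _edges_of(pruned)
                if x not in side_nodes and y not in side_nodes
            ]
            for x, y in remaining_edges:
                if {x, y} == {u, v}:
                    continue  # recreates the original tree
                out = _copy_adj(pruned)
                out[x] = [z if z != y else anchor for z in out[x]]
                out[y] = [z if z != x else anchor for z in out[y]]
                out[anchor] = [x, y, prune_root]
                out[prune_root] = pruned[prune_root] + [anchor]
                yield out


class _PatternData:
    """Alignment patterns split into search-relevant and constant parts.

    Parsimony-uninformative columns have the same length on every topology
    ((#states - 1)), so only informative patterns need to be rescored during
    search; the constant remainder is added back at the end.
    """

    def __init__(self, aln: ConcatenatedAlignment, mode: GapMode):
        self.taxa = list(aln.taxa)
        states = _state_matrix(aln, mode)
        patterns, counts = _compress(states)
        n_tax, P = patterns.shape
        # per-pattern counts of each concrete state (ambiguity cells ignored)
        per_state = np.stack(
            [(patterns == b).sum(axis=0) for b in (1, 2, 4, 8, 16)]
        )
        distinct = (per_state >= 1).sum(axis=0)
        informative = (per_state >= 2).sum(axis=0) >= 2
        const_steps = np.where(informative, 0, np.maximum(distinct - 1, 0))
        self.patterns = patterns[:, informative]
        self.weights = counts[informative].astype(np.float64)
        self.const = int(np.sum(const_steps * counts))
        self.n_leaves = n_tax

    def score(self, adj: Dict[int, List[int]], weights=None) -> float:
        w = self.weights if weights is None else weights
        if self.patterns.shape[1] == 0:
            return float(self.const)
        triples = _postorder_arrays(adj, self.n_leaves)
        return self.const + _fitch_counts(triples, self.patterns, w)

    def score_partial(self, adj: Dict[int, List[int]]) -> float:
        """Score a tree over a subset of leaves (used by Wagner addition)."""
        if self.patterns.shape[1] == 0:
            return 0.0
        triples = _postorder_arrays(adj, self.n_leaves)
        return _fitch_counts(triples, self.patterns, self.weights)


def _wagner_start(
    data: _PatternData, order: np.ndarray
) -> Dict[int, List[int]]:
    """Random-addition Wagner tree (greedy sequential insertion)."""
    n = data.n_leaves
    a, b, c = (int(x) for x in order[:3])
    hub = n  # first internal node id
    adj: Dict[int, List[int]] = {a: [hub], b: [hub], c: [hub], hub: [a, b, c]}
    next_internal = n + 1
    for leaf in order[3:]:
        leaf = int(leaf)
        best = None
        for edge in _edges_of(adj):
            cand = _insert_leaf(adj, leaf, edge, next_internal)
            s = data.score_partial(cand)
            if best is None or s < best[0]:
                best = (s, cand)
        adj = best[1]
        next_internal += 1
    return adj


def _hill_climb(
    adj: Dict[int, List[int]],
    data: _PatternData,
    weights: Optional[np.ndarray],
    pool: Dict[FrozenSet, Tuple[float, Dict[int, List[int]]]],
    record_pool: bool,
) -> Tuple[float, Dict[int, List[int]]]:
    """Steepest-descent NNI+SPR hill climbing.

    When ``record_pool`` is set, every evaluated tree scoring equal to the
    best true-weights score seen so far is added to the tie pool.
    """
    cur_score = data.score(adj, weights)
    while True:
        best_score, best_adj = cur_score, None
        for cand in _spr_neighbors(adj, data.n_leaves):
            s = data.score(cand, weights)
            if record_pool:
                true_s = s if weights is None else data.score(cand)
                _offer(pool, cand, true_s, data.n_leaves)
            if s < best_score:
                best_score, best_adj = s, cand
        if best_adj is None:
            return cur_score, adj
        cur_score, adj = best_score, best_adj
        if record_pool:
            _offer(pool, adj, data.score(adj), data.n_leaves)


def _offer(
    pool: Dict[FrozenSet, Tuple[float, Dict[int, List[int]]]],
    adj: Dict[int, List[int]],
    score: float,
    n_leaves: int,
) -> None:
    if pool:
        best = min(s for s, _ in pool.values())
        if score > best:
            return
        if score < best:
            pool.clear()
    if len(pool) >= MAX_TREES:
        return
    pool[_adj_key(adj, n_leaves)] = (score, _copy_adj(adj))


def search_mp(
    aln: ConcatenatedAlignment,
    mode: GapMode = GapMode.FIFTH_STATE,
    n_starts: int = 4,
    ratchet_iters: int = 3,
    seed: int = 0,
) -> List[dendropy.Tree]:
    """Heuristic most-parsimonious tree search.

    Random-addition Wagner starts, steepest NNI+SPR hill climbing, and a
    simple parsimony ratchet (double the weight of a random 25% of patterns,
    re-search, restore, re-search).  Returns every distinct topology found at
    the best score (capped at 1,000), sorted by Newick string for
    determinism.
    """
    if aln.n_taxa < 4:
        raise ValueError("tree search needs at least 4 taxa")
    rng = np.random.default_rng(seed)
    data = _PatternData(aln, mode)
    pool: Dict[FrozenSet, Tuple[float, Dict[int, List[int]]]] = {}

    for _ in range(max(1, n_starts)):
        order = rng.permutation(aln.n_taxa)
        adj = _wagner_start(data, order)
        _offer(pool, adj, data.score(adj), data.n_leaves)
        score, adj = _hill_climb(adj, data, None, pool, record_pool=True)
        _offer(pool, adj, score, data.n_leaves)
        for _ in range(ratchet_iters):
            P = data.patterns.shape[1]
            if P == 0:
                break
            w = data.weights.copy()
            idx = rng.choice(P, size=max(1, P // 4), replace=False)
            w[idx] *= 2.0
            _, adj = _hill_climb(adj, data, w, pool, record_pool=False)
            score, adj = _hill_climb(adj, data, None, pool, record_pool=True)
            _offer(pool, adj, score, data.n_leaves)

    best = min(s for s, _ in pool.values())
    winners = [a for s, a in pool.values() if s == best]
    trees = [_adjacency_to_tree(a, aln.taxa) for a in winners]
    trees.sort(key=lambda t: t.as_string(schema="newick"))
    return trees[:MAX_TREES]


# ----------------------------------------------- indel step decomposition


def indel_step_decomposition(
    tree: dendropy.Tree, aln: ConcatenatedAlignment
) -> Dict[str, float]:
    """Partition fifth-state parsimony steps into indel vs substitution steps
    and internal vs terminal indel steps.

    Runs Fitch bottom-up then a top-down assignment per column (a node keeps
    its parent's state when available, otherwise takes the smallest of its
    state set in A<C<G<T<'-' order).  A step is an edge whose endpoints
    receive different states; it is an indel step when either endpoint is the
    gap state; it is internal when the child endpoint is an internal node.
    """
    if set(_leaf_labels(tree)) != set(aln.taxa):
        raise ValueError("tree leaves do not match alignment taxa")
    adj = _tree_to_adjacency(tree, aln.taxa)
    triples = _postorder_arrays(adj, aln.n_taxa)
    patterns, counts = _compress(_state_matrix(aln, GapMode.FIFTH_STATE))
    n_leaves, P = aln.n_taxa, patterns.shape[1]
    if P == 0:
        patterns = np.zeros((n_leaves, 0), dtype=np.uint8)
        counts = np.zeros(0, dtype=np.int64)

    max_id = max(t[0] for t in triples) + 1
    sets = np.zeros((max_id, P), dtype=np.uint8)
    sets[:n_leaves] = patterns
    for node, left, right in triples:
        inter = sets[left] & sets[right]
        sets[node] = np.where(inter == 0, sets[left] | sets[right], inter)

    # top-down refinement
    state = np.zeros((max_id, P), dtype=np.uint8)
    root = triples[-1][0]
    lowest = lambda m: m & (-m.astype(np.int16)).astype(np.uint8)  # noqa: E731
    state[root] = lowest(sets[root])
    internal_ids = {t[0] for t in triples}
    totals = {"total": 0, "indel_internal": 0, "indel_terminal": 0, "indel": 0}
    for node, left, right in reversed(triples):
        for child in (left, right):
            keep = (sets[child] & state[node]) != 0
            state[child] = np.where(keep, state[node], lowest(sets[child]))
            step = state[child] != state[node]
            is_indel = step & ((state[child] == GAP) | (state[node] == GAP))
            totals["total"] += int(counts[step].sum())
            n_indel = int(counts[is_indel].sum())
            totals["indel"] += n_indel
            if child in internal_ids:
                totals["indel_internal"] += n_indel
            else:
                totals["indel_terminal"] += n_indel

    total_steps = totals["total"]
    total_indel = totals["indel"]
    internal = totals["indel_internal"]
    return {
        "internal_indel_steps": internal,
        "terminal_indel_steps": totals["indel_terminal"],
        "total_indel_steps": total_indel,
        "total_steps": total_steps,
        "pct_internal_of_indel": round_half_up(
            100.0 * internal / total_indel, 1
        )
        if total_indel
        else 0.0,
        "pct_internal_of_total": round_half_up(
            100.0 * internal / total_steps, 1
        )
        if total_steps
        else 0.0,
    }


def indel_share_of_tree_length(internal_indel_steps: int, total_steps: int) -> float:
    """Internal-indel steps as a percentage of tree length (1 decimal)."""
    if total_steps <= 0:
        raise ValueError("total_steps must be positive")
    return round_half_up(100.0 * internal_indel_steps / total_steps, 1)


# --------------------------------------------------------------- counting


def count_rooted_topologies(n_taxa: int) -> int:
    """Exact number of rooted bifurcating leaf-labeled topologies, (2n-3)!!."""
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    out = 1
    for k in range(3, 2 * n_taxa - 2, 2):
        out *= k
    return out
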