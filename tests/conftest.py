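"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately re-derive quantities by brute force
(exhaustive enumeration, naive dynamic programming) so they stay
independent of the library code paths they check.
"""

from __future__ import annotations

import itertools
from typing import Dict, List, Sequence, Set, Tuple

import dendropy
import numpy as np
import pytest

from lcbphylo.core import ConcatenatedAlignment, GapMode


def aln_from(rows: Dict[str, str]) -> ConcatenatedAlignment:
    return ConcatenatedAlignment(taxa=list(rows), rows=dict(rows))


@pytest.fixture
def small_alignment() -> ConcatenatedAlignment:
    return aln_from(
        {
            "a": "ACGTACGTAC",
            "b": "ACGTACGTAC",
            "c": "ACGAACGTAC",
            "d": "ACGAACTTAC",
        }
    )


# ------------------------------------------------------- tree enumeration


def enumerate_unrooted_topologies(labels: Sequence[str]) -> List[dendropy.Tree]:
    """All distinct unrooted binary topologies by sequential edge insertion."""
    labels = list(labels)
    assert len(labels) >= 3
    ns = dendropy.TaxonNamespace(labels)

    def build(newick: str) -> dendropy.Tree:
        return dendropy.Tree.get(
            data=newick + ";", schema="newick", taxon_namespace=ns
        )

    # represent trees as nested tuples, inserting each new label on each edge;
    # every node except the (degree-3) root subtends exactly one edge
    base = (labels[0], labels[1], labels[2])

    def edges(tree) -> int:
        def cnt(node) -> int:
            if isinstance(node, str):
                return 1
            return 1 + sum(cnt(c) for c in node)

        return sum(cnt(c) for c in tree)

    def insert(tree, label, which: int):
        """Insert label on edge number ``which`` (preorder edge count)."""

        def rec(node, n):
            # ``node`` is a non-root subtree: its own edge is a position
            if n == 0:
                return (node, label), -1
            n -= 1
            if isinstance(node, str):
                return node, n
            out = []
            for c in node:
                if n >= 0:
                    c, n = rec(c, n)
                out.append(c)
            return tuple(out), n

        res = []
        n = which
        for c in tree:
            if n >= 0:
                c, n = rec(c, n)
            res.append(c)
        assert n == -1
        return tuple(res)

    trees = [base]
    for label in labels[3:]:
        nxt = []
        for t in trees:
            for e in range(edges(t)):
                nxt.append(insert(t, label, e))
        trees = nxt

    def to_newick(node) -> str:
        if isinstance(node, str):
            return node
        return "(" + ",".join(to_newick(c) for c in node) + ")"

    return [build(to_newick(t)) for t in trees]


# ------------------------------------------------------ brute-force Fitch

_STATE_SETS = {
    GapMode.FIFTH_STATE: {
        "A": {"A"},
        "C": {"C"},
        "G": {"G"},
        "T": {"T"},
        "N": {"A", "C", "G", "T"},
        "-": {"-"},
    },
    GapMode.MISSING: {
        "A": {"A"},
        "C": {"C"},
        "G": {"G"},
        "T": {"T"},
        "N": {"A", "C", "G", "T"},
        "-": {"A", "C", "G", "T"},
    },
}

_ALL_STATES = ("A", "C", "G", "T", "-")


def brute_force_parsimony(
    tree: dendropy.Tree, aln: ConcatenatedAlignment, mode: GapMode
) -> int:
    """Minimum total edge changes over all internal-state assignments."""
    leaves = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    assert set(leaves) == set(aln.taxa)
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    state_sets = _STATE_SETS[mode]
    total = 0
    for col in range(aln.n_columns):
        best = None
        leaf_opts = {t: state_sets[aln.rows[t][col]] for t in aln.taxa}
        for assign in itertools.product(_ALL_STATES, repeat=len(internals)):
            node_state = {id(n): s for n, s in zip(internals, assign)}
            cost = 0
            for node in tree.preorder_node_iter():
                if node.parent_node is None:
                    continue
                ps = node_state[id(node.parent_node)]
                if node.is_leaf():
                    opts = leaf_opts[node.taxon.label]
                    cost += 0 if ps in opts else 1
                else:
                    cost += 0 if node_state[id(node)] == ps else 1
            if best is None or cost < best:
                best = cost
        total += best
    return total


def brute_force_bipartitions(tree: dendropy.Tree) -> Set[frozenset]:
    """Non-trivial splits via leaf-set enumeration per edge (independent)."""
    all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    ref = min(all_leaves)
    out = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        clade = frozenset(lf.taxon.label for lf in node.leaf_iter())
        side = clade if ref not in clade else all_leaves - clade
        if 2 <= len(side) <= len(all_leaves) - 2:
            out.add(frozenset(side))
    return out


def random_tree(labels: Sequence[str], rng: np.random.Generator) -> dendropy.Tree:
    """Random unrooted binary topology by random sequential insertion."""
    labels = list(labels)
    ns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree.get(
        data=f"({labels[0]},{labels[1]},{labels[2]});",
        schema="newick",
        taxon_namespace=ns,
    )
    for label in labels[3:]:
        edges = [e for e in tree.preorder_edge_iter() if e.head_node.parent_node]
        edge = edges[int(rng.integers(len(edges)))]
        old_head = edge.head_node
        parent = edge.tail_node
        new_internal = dendropy.Node()
        parent.remove_child(old_head)
        parent.add_child(new_internal)
        new_internal.add_child(old_head)
        leaf = dendropy.Node()
        leaf.taxon = ns.get_taxon(label)
        new_internal.add_child(leaf)
    return tree


def random_alignment(
    labels: Sequence[str],
    n_cols: int,
    rng: np.random.Generator,
    alphabet: str = "ACGT-N",
) -> ConcatenatedAlignment:
    rows = {
        t: "".join(alphabet[i] for i in rng.integers(0, len(alphabet), n_cols))
        for t in labels
    }
    return aln_from(rows)
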