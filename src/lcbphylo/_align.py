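"""Progressive multiple alignment: UPGMA guide tree + profile Needleman-Wunsch.

Scores: match +2, mismatch -1, affine gaps (open -4 for the first gap
character, extend -1 for each further one).  ``N`` matches nothing and is
scored as a mismatch against everything including itself.  Profile columns
are scored as the average pairwise residue score; pairs involving an
existing gap contribute 0.  Dynamic-programming ties prefer the diagonal,
then the vertical (gap in the second profile), then the horizontal move, so
the output is deterministic.

The DP is banded: only cells within a diagonal band wide enough to absorb
the length difference plus ``band`` positions are considered.  Blocks fed to
this aligner are collinear by construction, so the optimal path stays near
the diagonal; a band at least as long as both sequences makes the DP exact.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

import numpy as np
from numba import njit
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .core import decode, encode

__all__ = [
    "progressive_align_sequences",
    "build_guide_tree",
    "MATCH",
    "MISMATCH",
    "GAP_OPEN",
    "GAP_EXTEND",
]

MATCH = 2.0
MISMATCH = -1.0
GAP_OPEN = -4.0
GAP_EXTEND = -1.0

# residue pair score matrix over codes A,C,G,T,N,- (gap rows/cols are 0)
_PAIR = np.full((6, 6), MISMATCH, dtype=np.float32)
for _i in range(4):
    _PAIR[_i, _i] = MATCH
_PAIR[4, :] = MISMATCH
_PAIR[:, 4] = MISMATCH
_PAIR[5, :] = 0.0
_PAIR[:, 5] = 0.0

_NEG = np.float32(-1e30)


@njit(cache=True, fastmath=True)
def _banded_profile_nw(
    sa: np.ndarray,  # (LA, 6) float32: PAIR . column-counts of profile A
    cb: np.ndarray,  # (LB, 6) float32: column counts of profile B
    gfa: np.ndarray,  # (LA,) float32: non-gap fraction per column of A
    gfb: np.ndarray,  # (LB,) float32: non-gap fraction per column of B
    inv_norm: np.float32,
    dmin: int,
    dmax: int,
    gap_open: np.float32,
    gap_extend: np.float32,
):  # pragma: no cover - exercised via the python wrapper
    la = sa.shape[0]
    lb = cb.shape[0]
    width = dmax - dmin + 1
    m = np.full((la + 1, width), _NEG, dtype=np.float32)
    x = np.full((la + 1, width), _NEG, dtype=np.float32)
    y = np.full((la + 1, width), _NEG, dtype=np.float32)
    # pointers: 0 from M, 1 from X, 2 from Y, 255 none
    pm = np.full((la + 1, width), 255, dtype=np.uint8)
    px = np.full((la + 1, width), 255, dtype=np.uint8)
    py = np.full((la + 1, width), 255, dtype=np.uint8)

    k0 = -dmin  # band column of j == i
    if 0 <= k0 < width:
        m[0, k0] = 0.0

    for i in range(0, la + 1):
        jlo = max(0, i + dmin)
        jhi = min(lb, i + dmax)
        for j in range(jlo, jhi + 1):
            k = j - i - dmin
            if i > 0 and j > 0:
                # diagonal: column scores
                s = np.float32(0.0)
                for c in range(6):
                    s += sa[i - 1, c] * cb[j - 1, c]
                s *= inv_norm
                best = m[i - 1, k]
                ptr = 0
                if x[i - 1, k] > best:
                    best = x[i - 1, k]
                    ptr = 1
                if y[i - 1, k] > best:
                    best = y[i - 1, k]
                    ptr = 2
                if best > _NEG / 2:
                    m[i, k] = best + s
                    pm[i, k] = ptr
            if i > 0 and k + 1 < width:
                # vertical: consume a column of A against a new gap in B;
                # penalties scale with the non-gap fraction of the consumed
                # column, so gapping an already-gappy column is nearly free
                w = gfa[i - 1]
                v_m = m[i - 1, k + 1] + gap_open * w
                v_x = x[i - 1, k + 1] + gap_extend * w
                v_y = y[i - 1, k + 1] + gap_open * w
                best = v_m
                ptr = 0
                if v_x > best:
                    best = v_x
                    ptr = 1
                if v_y > best:
                    best = v_y
                    ptr = 2
                if best > _NEG / 2:
                    x[i, k] = best
                    px[i, k] = ptr
            if j > 0 and k - 1 >= 0:
                # horizontal: consume a column of B against a new gap in A
                w = gfb[j - 1]
                h_m = m[i, k - 1] + gap_open * w
                h_x = x[i, k - 1] + gap_open * w
                h_y = y[i, k - 1] + gap_extend * w
                best = h_m
                ptr = 0
                if h_x > best:
                    best = h_x
                    ptr = 1
                if h_y > best:
                    best = h_y
                    ptr = 2
                if best > _NEG / 2:
                    y[i, k] = best
                    py[i, k] = ptr

    kend = lb - la - dmin
    best = m[la, kend]
    state = 0
    if x[la, kend] > best:
        best = x[la, kend]
        state = 1
    if y[la, kend] > best:
        best = y[la, kend]
        state = 2

    # traceback: moves recorded newest-first (0 diag, 1 vertical, 2 horizontal)
    moves = np.empty(la + lb, dtype=np.uint8)
    nmoves = 0
    i = la
    j = lb
    while i > 0 or j > 0:
        k = j - i - dmin
        if state == 0:
            prev = pm[i, k]
            moves[nmoves] = 0
            i -= 1
            j -= 1
        elif state == 1:
            prev = px[i, k]
            moves[nmoves] = 1
            i -= 1
        else:
            prev = py[i, k]
            moves[nmoves] = 2
            j -= 1
        nmoves += 1
        state = prev
    return best, moves[:nmoves]


def _profile_counts(profile: np.ndarray) -> np.ndarray:
    """(L, 6) float32 per-column residue counts of a (rows, L) code matrix."""
    L = profile.shape[1]
    counts = np.zeros((L, 6), dtype=np.float32)
    for c in range(6):
        counts[:, c] = (profile == c).sum(axis=0)
    return counts


def _align_profiles(
    pa: np.ndarray, pb: np.ndarray, band: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Merge two profiles; returns gap masks mapping old to new columns."""
    la, lb = pa.shape[1], pb.shape[1]
    ca = _profile_counts(pa)
    cb = _profile_counts(pb)
    sa = ca @ _PAIR  # (LA, 6)
    gfa = (1.0 - ca[:, 5] / pa.shape[0]).astype(np.float32)
    gfb = (1.0 - cb[:, 5] / pb.shape[0]).astype(np.float32)
    inv_norm = np.float32(1.0 / (pa.shape[0] * pb.shape[0]))
    dmin = min(0, lb - la) - band
    dmax = max(0, lb - la) + band
    _, moves = _banded_profile_nw(
        sa.astype(np.float32),
        cb,
        gfa,
        gfb,
        inv_norm,
        dmin,
        dmax,
        np.float32(GAP_OPEN),
        np.float32(GAP_EXTEND),
    )
    moves = moves[::-1]  # oldest-first
    n_cols = len(moves)
    new_a = np.full((pa.shape[0], n_cols), 5, dtype=np.uint8)
    new_b = np.full((pb.shape[0], n_cols), 5, dtype=np.uint8)
    ia = ib = 0
    for col, mv in enumerate(moves):
        if mv == 0:
            new_a[:, col] = pa[:, ia]
            new_b[:, col] = pb[:, ib]
            ia += 1
            ib += 1
        elif mv == 1:
            new_a[:, col] = pa[:, ia]
            ia += 1
        else:
            new_b[:, col] = pb[:, ib]
            ib += 1
    return new_a, new_b


def _unstack_insertions(
    matrix: np.ndarray, identity_threshold: float = 0.5
) -> np.ndarray:
    """Separate stacked independent insertions into their own columns.

    Progressive alignment tends to pile insertions from unrelated rows into
    the same columns because sharing gap columns is cheaper than opening new
    ones.  Under gap-as-fifth-state scoring such stacked columns manufacture
    shared-gap characters grouping the inserting rows.  This pass scans
    minority-base gap runs (maximal column intervals whose non-gap row set
    is constant and covers at most half the rows), clusters the inserted
    sequences by pairwise identity (single linkage), and, when a run mixes
    dissimilar — hence independently inserted — sequences, rewrites it with
    one column block per cluster.  Residue order within every row is
    preserved, so ungapping is unaffected.
    """
    n, width = matrix.shape
    if n < 3 or width == 0:
        return matrix
    gap = matrix == 5
    nongap_count = (~gap).sum(axis=0)
    minority = (nongap_count >= 2) & (nongap_count <= n // 2)

    # encode each column's non-gap row set to find constant runs
    keys = np.zeros(width, dtype=np.int64)
    for r in range(n):
        keys |= (~gap[r]).astype(np.int64) << r

    pieces = []
    col = 0
    changed = False
    while col < width:
        if not minority[col]:
            nxt = col + 1
            while nxt < width and not minority[nxt]:
                nxt += 1
            pieces.append(matrix[:, col:nxt])
            col = nxt
            continue
        run_end = col + 1
        while run_end < width and minority[run_end] and keys[run_end] == keys[col]:
            run_end += 1
        run = matrix[:, col:run_end]
        rows_in = np.flatnonzero(~gap[:, col])
        clusters = _identity_clusters(run, rows_in, identity_threshold)
        if len(clusters) <= 1:
            pieces.append(run)
        else:
            changed = True
            for cluster in clusters:
                block = np.full_like(run, 5)
                block[cluster] = run[cluster]
                pieces.append(block)
        col = run_end
    if not changed:
        return matrix
    return np.concatenate(pieces, axis=1)


def _identity_clusters(run: np.ndarray, rows_in: np.ndarray, thr: float):
    """Single-linkage clusters of rows by residue identity over a gap run."""
    m = len(rows_in)
    parent = list(range(m))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(m):
        for j in range(i + 1, m):
            a, b = run[rows_in[i]], run[rows_in[j]]
            ident = float((a == b).mean())
            if ident >= thr:
                pi, pj = find(i), find(j)
                if pi != pj:
                    parent[pj] = pi
    groups = {}
    for i in range(m):
        groups.setdefault(find(i), []).append(int(rows_in[i]))
    return [groups[k] for k in sorted(groups, key=lambda k: groups[k][0])]


def _kmer_sets(seq: str, k: int = 8) -> set:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _guide_merge_order(seqs: Sequence[str], k: int = 8) -> List[Tuple[int, int]]:
    """UPGMA merge order from 1 - shared-k-mer-fraction distances.

    Returns a list of (i, j) cluster-index pairs in scipy linkage convention
    (new clusters numbered n, n+1, ...).
    """
    n = len(seqs)
    if n == 2:
        return [(0, 1)]
    sets = [_kmer_sets(s, k) for s in seqs]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            denom = min(len(sets[i]), len(sets[j]))
            shared = len(sets[i] & sets[j]) / denom if denom else 0.0
            d[i, j] = d[j, i] = 1.0 - shared
    z = linkage(squareform(d, checks=False), method="average")
    return [(int(a), int(b)) for a, b, _, _ in z]


def build_guide_tree(seqs: Dict[str, str], k: int = 14):
    """UPGMA guide tree over named sequences as a nested-tuple structure.

    Distances are 1 − shared-k-mer fraction.  Built once from whole genomes
    and reused for every block, this fixes a single consistent merge order,
    estimated from far more signal than any individual block provides.  The
    default k is larger than the within-block guide's (8) because k-mer
    space must not saturate at genome scale.
    """
    names = list(seqs)
    if len(names) == 1:
        return names[0]
    if len(names) == 2:
        return (names[0], names[1])
    order = _guide_merge_order([seqs[n].upper() for n in names], k)
    nodes: Dict[int, object] = {i: n for i, n in enumerate(names)}
    next_id = len(names)
    for a, b in order:
        nodes[next_id] = (nodes.pop(a), nodes.pop(b))
        next_id += 1
    (root,) = nodes.values()
    return root


def _prune_guide(guide, keep: set):
    """Restrict a nested-tuple guide tree to ``keep``; None when empty."""
    if isinstance(guide, str):
        return guide if guide in keep else None
    left = _prune_guide(guide[0], keep)
    right = _prune_guide(guide[1], keep)
    if left is None:
        return right
    if right is None:
        return left
    return (left, right)


def progressive_align_sequences(
    seqs: Dict[str, str], band: int = 128, guide_k: int = 8, guide=None
) -> Dict[str, str]:
    """Progressively align named sequences; returns equal-length gapped rows.

    Ungapping any output row recovers the input sequence exactly.  With a
    single input the sequence is returned unchanged.  ``guide`` (optional)
    is a nested-tuple guide tree from :func:`build_guide_tree`; without it
    a UPGMA guide tree is built from these sequences alone.
    """
    names = list(seqs)
    for name in names:
        if not seqs[name]:
            raise ValueError(f"empty sequence for {name}")
    if len(names) == 1:
        return {names[0]: seqs[names[0]].upper()}

    if guide is not None:
        pruned = _prune_guide(guide, set(names))
        missing = set(names) - _guide_leaves(pruned)
        if missing:
            raise ValueError(f"guide tree lacks sequences: {sorted(missing)[:3]}")

        def rec(node) -> Tuple[List[str], np.ndarray]:
            if isinstance(node, str):
                return [node], encode(seqs[node].upper())[None, :]
            names_a, pa = rec(node[0])
            names_b, pb = rec(node[1])
            new_a, new_b = _align_profiles(pa, pb, band)
            return names_a + names_b, np.vstack([new_a, new_b])

        final_names, matrix = rec(pruned)
    else:
        profiles: Dict[int, Tuple[List[str], np.ndarray]] = {
            i: ([name], encode(seqs[name].upper())[None, :])
            for i, name in enumerate(names)
        }
        next_id = len(names)
        for a, b in _guide_merge_order([seqs[n].upper() for n in names], guide_k):
            names_a, pa = profiles.pop(a)
            names_b, pb = profiles.pop(b)
            new_a, new_b = _align_profiles(pa, pb, band)
            profiles[next_id] = (names_a + names_b, np.vstack([new_a, new_b]))
            next_id += 1
        (final_names, matrix), = profiles.values()
    matrix = _unstack_insertions(matrix)
    return {name: decode(matrix[i]) for i, name in enumerate(final_names)}


def _guide_leaves(guide) -> set:
    if guide is None:
        return set()
    if isinstance(guide, str):
        return {guide}
    return _guide_leaves(guide[0]) | _guide_leaves(guide[1])
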