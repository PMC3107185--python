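"""Locally collinear block detection by unique-k-mer anchoring and chaining.

The detector approximates the anchor-and-extend strategy of whole-genome
aligners: exact k-mers occurring exactly once per genome (in canonical
strand form) seed anchors; anchors sharing a taxon set and orientation
pattern are chained while they stay collinear in every shared genome with
inter-anchor gaps at most ``max_gap``.  Chains claim genome intervals
greedily — larger taxon sets first, then more anchored bp — and
lower-priority chains are re-walked around the claimed intervals, so a
subset chain nested inside an all-taxa block dissolves instead of
double-claiming sequence.  Chain extents become LCB segments, extended
outward by at most ``max_gap/2`` and split at the midpoint between
neighbouring chains, so no genome position belongs to two LCBs: between any
two genomes the segment mapping is a partial bijection.

Anchor bookkeeping is fully vectorised (integer-packed k-mers, occurrence
matrices per taxon-set signature); the public :class:`Anchor` objects are a
thin view used by the step-by-step API.
"""

from __future__ import annotations

from collections import deque
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import LCB, Anchor, Genome, Segment, check_pairwise_bijection, encode
from .phylo import round_half_up

__all__ = [
    "find_anchors",
    "chain_anchors",
    "partition_lcbs",
    "coverage_stats",
    "detect_lcbs",
]

DEFAULT_K = 15
DEFAULT_MAX_GAP = 5_000
DEFAULT_MIN_CHAIN_BP = 60
CUT_STRIDE = 4_000  # spacing of internal anchors kept as aligner cut points
# Chain extents are extended outward by at most this many bp (never more
# than max_gap/2, and never past the midpoint to a neighbouring chain).
# Unanchored extension is kept to roughly anchor scale: longer extensions
# mostly pull in sequence from beyond rearrangement breakpoints, asserting
# homology the anchors never supported.
DEFAULT_BOUNDARY_EXT = 50


# ------------------------------------------------------------------ anchors


def _unique_kmers(
    seq_codes: np.ndarray, k: int
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Canonical k-mers occurring exactly once in a genome.

    Returns (packed k-mer integers, positions, strands); strand is +1 when
    the canonical form is the forward k-mer.  Windows containing N are
    skipped.
    """
    L = len(seq_codes)
    if L < k:
        empty = np.zeros(0, dtype=np.int64)
        return empty, empty, empty
    c = seq_codes.astype(np.int64)
    n_win = L - k + 1
    fwd = np.zeros(n_win, dtype=np.int64)
    rc = np.zeros(n_win, dtype=np.int64)
    for j in range(k):
        fwd = (fwd << 2) | np.where(c[j : j + n_win] < 4, c[j : j + n_win], 0)
        comp = (3 - c[k - 1 - j : k - 1 - j + n_win]) % 4
        rc = (rc << 2) | comp
    bad = np.cumsum(np.concatenate([[0], (seq_codes >= 4).astype(np.int64)]))
    valid = (bad[k:] - bad[:-k]) == 0
    canonical = np.minimum(fwd, rc)
    strand = np.where(fwd <= rc, 1, -1).astype(np.int64)
    pos = np.flatnonzero(valid)
    vals = canonical[pos]
    uniq, first, counts = np.unique(vals, return_index=True, return_counts=True)
    once = counts == 1
    sel = first[once]
    return uniq[once], pos[sel], strand[pos[sel]]


class _OccClass:
    """All anchors sharing one taxon set: (n_anchors, n_taxa) matrices."""

    __slots__ = ("taxa", "pos", "strand")

    def __init__(self, taxa: Tuple[str, ...], pos: np.ndarray, strand: np.ndarray):
        self.taxa = taxa  # in input-genome order
        self.pos = pos
        self.strand = strand

    @property
    def n(self) -> int:
        return self.pos.shape[0]


def _group_occurrences(
    genomes: Sequence[Genome], k: int
) -> List[_OccClass]:
    """Group unique shared k-mers into per-signature occurrence matrices."""
    if len(genomes) < 2:
        raise ValueError("need at least 2 genomes")
    if k < 8:
        raise ValueError("kmer_length must be >= 8")
    if k > 31:
        raise ValueError("kmer_length must be <= 31 (64-bit packing)")
    if len(genomes) > 62:
        raise ValueError("at most 62 genomes (signature bit packing)")

    kms, gis, pps, sss = [], [], [], []
    for gi, g in enumerate(genomes):
        km, pos, st = _unique_kmers(encode(g.sequence), k)
        kms.append(km)
        gis.append(np.full(km.size, gi, dtype=np.int64))
        pps.append(pos)
        sss.append(st)
    km = np.concatenate(kms)
    gg = np.concatenate(gis)
    pp = np.concatenate(pps)
    ss = np.concatenate(sss)
    order = np.argsort(km, kind="stable")  # stable keeps genome order in groups
    km, gg, pp, ss = km[order], gg[order], pp[order], ss[order]
    if km.size == 0:
        return []
    new = np.flatnonzero(np.diff(km)) + 1
    starts = np.concatenate([[0], new])
    sizes = np.diff(np.concatenate([starts, [km.size]]))
    sig = np.bitwise_or.reduceat(np.int64(1) << gg, starts)
    gid = np.repeat(np.arange(starts.size), sizes)

    keep_group = sizes >= 2
    row_keep = keep_group[gid]
    gg, pp, ss = gg[row_keep], pp[row_keep], ss[row_keep]
    row_sig = sig[gid[row_keep]]
    row_gid = gid[row_keep]

    order2 = np.argsort(row_sig, kind="stable")
    gg, pp, ss, row_sig, row_gid = (
        gg[order2],
        pp[order2],
        ss[order2],
        row_sig[order2],
        row_gid[order2],
    )
    classes: List[_OccClass] = []
    bounds = np.concatenate(
        [[0], np.flatnonzero(np.diff(row_sig)) + 1, [row_sig.size]]
    )
    taxa_names = [g.taxon_id for g in genomes]
    for b0, b1 in zip(bounds, bounds[1:]):
        s = int(bin(int(row_sig[b0])).count("1"))
        n_rows = (b1 - b0) // s
        taxa = tuple(
            taxa_names[i] for i in range(len(genomes)) if (int(row_sig[b0]) >> i) & 1
        )
        pos = pp[b0:b1].reshape(n_rows, s)
        strand = ss[b0:b1].reshape(n_rows, s)
        classes.append(_OccClass(taxa, pos, strand))
    return classes


def find_anchors(
    genomes: Sequence[Genome], kmer_length: int = DEFAULT_K
) -> List[Anchor]:
    """All k-mers unique within each genome and present in at least two.

    Anchors are ordered by the first listed genome that contains them, then
    by position there, so the output is deterministic.
    """
    classes = _group_occurrences(genomes, kmer_length)
    order_index = {g.taxon_id: i for i, g in enumerate(genomes)}
    anchors: List[Anchor] = []
    for cls in classes:
        for r in range(cls.n):
            occurrences = tuple(
                (t, int(cls.pos[r, j]), "+" if cls.strand[r, j] > 0 else "-")
                for j, t in enumerate(cls.taxa)
            )
            anchors.append(Anchor(kmer_length=kmer_length, occurrences=occurrences))

    def sort_key(a: Anchor):
        return min((order_index[t], p) for t, p, _ in a.occurrences)

    anchors.sort(key=sort_key)
    return anchors


# ----------------------------------------------------------------- chaining


class _IntervalIndex:
    """Per-taxon sorted non-overlapping claimed intervals with batch queries."""

    def __init__(self) -> None:
        self._items: Dict[str, List[Tuple[int, int]]] = {}
        self._cache: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}

    def add(self, taxon: str, start: int, end: int) -> None:
        self._items.setdefault(taxon, []).append((start, end))
        self._cache.pop(taxon, None)

    def _arrays(self, taxon: str) -> Optional[Tuple[np.ndarray, np.ndarray]]:
        items = self._items.get(taxon)
        if not items:
            return None
        cached = self._cache.get(taxon)
        if cached is None or cached[0].size != len(items):
            items.sort()
            starts = np.array([s for s, _ in items], dtype=np.int64)
            ends = np.array([e for _, e in items], dtype=np.int64)
            cached = (starts, ends)
            self._cache[taxon] = cached
        return cached

    def overlaps(self, taxon: str, qs: np.ndarray, qe: np.ndarray) -> np.ndarray:
        """Boolean vector: does [qs, qe) overlap any claimed interval?"""
        arrays = self._arrays(taxon)
        if arrays is None:
            return np.zeros(np.shape(qs), dtype=bool)
        starts, ends = arrays
        i = np.searchsorted(starts, qs, side="right") - 1
        hit_prev = (i >= 0) & (ends[np.where(i < 0, 0, i)] > qs)
        j = i + 1
        hit_next = (j < starts.size) & (
            starts[np.where(j >= starts.size, starts.size - 1, j)] < qe
        )
        return hit_prev | hit_next


GAP_SLACK_BP = 500
GAP_SLACK_FRAC = 0.25


def _join_mask(
    pos: np.ndarray,
    strand: np.ndarray,
    k: int,
    max_gap: int,
    taxa: Tuple[str, ...],
    barrier: Optional[_IntervalIndex],
) -> np.ndarray:
    """joined[i]: may row i+1 continue row i's chain?"""
    if pos.shape[0] < 2:
        return np.zeros(0, dtype=bool)
    same = (strand[1:] == strand[:-1]).all(axis=1)
    m = (pos[1:] - pos[:-1]) * strand[:-1]  # signed advance per taxon
    ok = (m > 0) & (m <= max_gap + k)
    joined = same & ok.all(axis=1)
    # collinearity consistency: the advance between two anchors must be
    # similar in every genome — a genome carrying kilobases of extra
    # material between the same two anchors has had an insertion or a
    # rearrangement there, and bridging it would glue non-homologous
    # sequence into the block
    spread = m.max(axis=1) - m.min(axis=1)
    allowance = GAP_SLACK_BP + GAP_SLACK_FRAC * np.maximum(m.min(axis=1), 0)
    joined &= spread <= allowance
    if barrier is not None and joined.any():
        lo = np.minimum(pos[1:], pos[:-1])
        hi = np.maximum(pos[1:], pos[:-1])
        for j, t in enumerate(taxa):
            gap_exists = hi[:, j] > lo[:, j] + k
            cross = barrier.overlaps(t, lo[:, j] + k, hi[:, j])
            joined &= ~(gap_exists & cross)
    return joined


def _split_runs(pos: np.ndarray, strand: np.ndarray, joined: np.ndarray):
    breaks = np.flatnonzero(~joined) + 1
    starts = np.concatenate([[0], breaks])
    ends = np.concatenate([breaks, [pos.shape[0]]])
    return [(pos[s:e], strand[s:e]) for s, e in zip(starts, ends)]


def _anchored_bp(ref_pos: np.ndarray, k: int) -> int:
    d = np.diff(np.sort(ref_pos))
    return int(k + np.minimum(d, k).sum())


def _chain_core(
    classes: Sequence[_OccClass],
    k: int,
    max_gap: int,
    min_chain_bp: int,
    genome_lengths: Optional[Dict[str, int]],
    boundary_ext: int = DEFAULT_BOUNDARY_EXT,
) -> List[LCB]:
    candidates: List[Tuple[Tuple[str, ...], np.ndarray, np.ndarray, int]] = []
    for cls in sorted(classes, key=lambda c: c.taxa):
        pos, strand = cls.pos, cls.strand
        flip = strand[:, 0] < 0
        strand = strand.copy()
        strand[flip] *= -1
        order = np.argsort(pos[:, 0], kind="stable")
        pos, strand = pos[order], strand[order]
        joined = _join_mask(pos, strand, k, max_gap, cls.taxa, None)
        for rp, rs in _split_runs(pos, strand, joined):
            bp = _anchored_bp(rp[:, 0], k)
            if bp >= min_chain_bp:  # runs only shrink during claiming
                candidates.append((cls.taxa, rp, rs, bp))

    # greedy priority: larger taxon sets first, then more anchored bp
    candidates.sort(key=lambda c: (-len(c[0]), -c[3], c[0], int(c[1][0, 0])))

    claimed = _IntervalIndex()
    chains: List[Dict[str, Tuple[int, int, int]]] = []
    for taxa, run_pos, run_strand, _bp in candidates:
        pending = deque([(run_pos, run_strand)])
        while pending:
            pos, strand = pending.popleft()
            drop = np.zeros(pos.shape[0], dtype=bool)
            for j, t in enumerate(taxa):
                drop |= claimed.overlaps(t, pos[:, j], pos[:, j] + k)
            keep = ~drop
            if not keep.any():
                continue
            fp, fs = pos[keep], strand[keep]
            joined = _join_mask(fp, fs, k, max_gap, taxa, claimed)
            pieces = _split_runs(fp, fs, joined)
            if drop.any() or len(pieces) > 1:
                pending.extend(pieces)
                continue
            pp, ps = pieces[0]
            if _anchored_bp(pp[:, 0], k) < min_chain_bp:
                continue
            chain: Dict[str, Tuple[int, int, int]] = {}
            for j, t in enumerate(taxa):
                lo = int(pp[:, j].min())
                hi = int(pp[:, j].max()) + k
                chain[t] = (lo, hi, int(ps[0, j]))
                claimed.add(t, lo, hi)
            # periodic internal anchors let the aligner cut long blocks at
            # exactly homologous positions
            cut_rows: List[Dict[str, int]] = []
            last_ref = int(pp[0, 0])
            for r in range(1, pp.shape[0]):
                if int(pp[r, 0]) - last_ref >= CUT_STRIDE:
                    cut_rows.append({t: int(pp[r, j]) for j, t in enumerate(taxa)})
                    last_ref = int(pp[r, 0])
            chains.append((chain, cut_rows))

    # deterministic ids: order chains by their smallest (taxon, start)
    order = sorted(
        range(len(chains)),
        key=lambda i: min((t, se[0]) for t, se in chains[i][0].items()),
    )
    segs: List[Dict[str, List[int]]] = [
        {t: [s, e, st] for t, (s, e, st) in chains[i][0].items()} for i in order
    ]
    all_cuts = [chains[i][1] for i in order]
    _extend_boundaries(segs, min(boundary_ext, max_gap // 2), genome_lengths)

    lcbs: List[LCB] = []
    for seg, cut_rows in zip(segs, all_cuts):
        segments = {
            t: Segment(start=s, end=e, strand="+" if st > 0 else "-")
            for t, (s, e, st) in seg.items()
            if e > s
        }
        if len(segments) < 2:
            continue
        cut_offsets = _cut_offsets(segments, cut_rows, k)
        lcbs.append(
            LCB(lcb_id=len(lcbs), segments=segments, cut_offsets=cut_offsets)
        )
    check_pairwise_bijection(lcbs)
    return lcbs


def _cut_offsets(
    segments: Dict[str, Segment],
    cut_rows: List[Dict[str, int]],
    k: int,
) -> Optional[Dict[str, List[int]]]:
    """Anchor genome positions -> block-orientation offsets, validated."""
    if not cut_rows:
        return None
    out: Dict[str, List[int]] = {t: [] for t in segments}
    prev: Dict[str, int] = {t: 0 for t in segments}
    for row in cut_rows:
        offs = {}
        ok = True
        for t, seg in segments.items():
            pos = row.get(t)
            if pos is None:
                ok = False
                break
            o = pos - seg.start if seg.strand == "+" else seg.end - (pos + k)
            if not (prev[t] < o < seg.length):
                ok = False
                break
            offs[t] = o
        if ok:
            for t, o in offs.items():
                out[t].append(o)
                prev[t] = o
    if not any(out.values()):
        return None
    return out


def _extend_boundaries(
    segs: List[Dict[str, List[int]]],
    ext: int,
    genome_lengths: Optional[Dict[str, int]],
) -> None:
    """Extend chain extents outward by at most ``ext`` bp per side,
    splitting the sequence between neighbouring chains at the midpoint."""
    per_taxon: Dict[str, List[Tuple[int, int]]] = {}
    for ci, seg in enumerate(segs):
        for t in seg:
            per_taxon.setdefault(t, []).append((seg[t][0], ci))
    for t, items in per_taxon.items():
        items.sort()
        order = [ci for _, ci in items]
        orig = [(segs[ci][t][0], segs[ci][t][1]) for ci in order]
        L = genome_lengths.get(t) if genome_lengths else None
        for i, ci in enumerate(order):
            left_bound = orig[i - 1][1] if i > 0 else 0
            gap = orig[i][0] - left_bound
            left_ext = min(ext, gap // 2) if i > 0 else min(ext, gap)
            if i + 1 < len(order):
                rgap = orig[i + 1][0] - orig[i][1]
                right_ext = min(ext, rgap - rgap // 2)
            elif L is not None:
                right_ext = min(ext, L - orig[i][1])
            else:
                right_ext = 0
            segs[ci][t][0] = orig[i][0] - left_ext
            segs[ci][t][1] = orig[i][1] + right_ext


def _anchors_to_classes(anchors: Sequence[Anchor]) -> List[_OccClass]:
    by_sig: Dict[Tuple[str, ...], List[Anchor]] = {}
    for a in anchors:
        key = tuple(sorted(a.taxa))
        by_sig.setdefault(key, []).append(a)
    classes = []
    for taxa, group in sorted(by_sig.items()):
        pos = np.zeros((len(group), len(taxa)), dtype=np.int64)
        strand = np.zeros((len(group), len(taxa)), dtype=np.int64)
        for r, a in enumerate(group):
            for j, t in enumerate(taxa):
                p, s = a.occurrence(t)
                pos[r, j] = p
                strand[r, j] = 1 if s == "+" else -1
        classes.append(_OccClass(taxa, pos, strand))
    return classes


def chain_anchors(
    anchors: Sequence[Anchor],
    max_gap: int = DEFAULT_MAX_GAP,
    min_chain_bp: int = DEFAULT_MIN_CHAIN_BP,
    genome_lengths: Optional[Dict[str, int]] = None,
    boundary_ext: int = DEFAULT_BOUNDARY_EXT,
) -> List[LCB]:
    """Merge collinear anchors into LCBs (see module docstring).

    Consecutive anchors join one chain iff they share taxon set and
    orientation and, in every shared genome, appear in the same order and
    orientation at most ``max_gap`` apart; chains with fewer than
    ``min_chain_bp`` anchored bp are discarded; no genome position is
    assigned to two LCBs.
    """
    if not anchors:
        return []
    k = anchors[0].kmer_length
    classes = _anchors_to_classes(anchors)
    return _chain_core(classes, k, max_gap, min_chain_bp, genome_lengths, boundary_ext)


def detect_lcbs(
    genomes: Sequence[Genome],
    kmer_length: int = DEFAULT_K,
    max_gap: int = DEFAULT_MAX_GAP,
    min_chain_bp: int = DEFAULT_MIN_CHAIN_BP,
    boundary_ext: int = DEFAULT_BOUNDARY_EXT,
) -> List[LCB]:
    """Anchor finding + chaining in one call (fast array path)."""
    classes = _group_occurrences(genomes, kmer_length)
    lengths = {g.taxon_id: len(g) for g in genomes}
    return _chain_core(
        classes, kmer_length, max_gap, min_chain_bp, lengths, boundary_ext
    )


# -------------------------------------------------------------- partitioning


def partition_lcbs(
    lcbs: Sequence[LCB],
    all_taxa: FrozenSet[str],
    min_subset_bp: int = 100,
) -> Tuple[List[LCB], List[LCB]]:
    """Split LCBs into all-taxa blocks and subset blocks.

    Subset blocks cover at least 2 but not all taxa and have mean segment
    length above ``min_subset_bp``; blocks failing both criteria are
    dropped.
    """
    all_taxa = frozenset(all_taxa)
    full: List[LCB] = []
    subset: List[LCB] = []
    for lcb in lcbs:
        if lcb.taxa == all_taxa:
            full.append(lcb)
        elif lcb.n_taxa >= 2 and lcb.mean_segment_length > min_subset_bp:
            subset.append(lcb)
    return full, subset


# ------------------------------------------------------------ coverage stats


def coverage_stats(
    lcbs: Sequence[LCB], genomes: Sequence[Genome]
) -> pd.DataFrame:
    """Per-taxon coverage table: bp covered, % of genome, genes overlapped.

    Percentages use half-up rounding to one decimal.  The gene count is the
    number of annotated features whose span overlaps any LCB segment by at
    least 1 bp (absent annotation gives a missing value).
    """
    by_taxon = {g.taxon_id: g for g in genomes}
    cov: Dict[str, int] = {g.taxon_id: 0 for g in genomes}
    seg_lists: Dict[str, List[Tuple[int, int]]] = {g.taxon_id: [] for g in genomes}
    for lcb in lcbs:
        for t, seg in lcb.segments.items():
            if t not in by_taxon:
                raise ValueError(f"LCB taxon {t!r} absent from genomes")
            cov[t] += seg.length
            seg_lists[t].append((seg.start, seg.end))
    rows = []
    for g in genomes:
        t = g.taxon_id
        n_genes: Optional[int] = None
        if g.features:
            segs = sorted(seg_lists[t])
            n_genes = 0
            for f in g.features:
                if any(f.start < e and s < f.end for s, e in segs):
                    n_genes += 1
        rows.append(
            {
                "taxon": t,
                "genome_length": len(g),
                "bp_covered": cov[t],
                "pct_of_genome": round_half_up(100.0 * cov[t] / len(g), 1),
                "n_genes": n_genes,
            }
        )
    return pd.DataFrame(rows)
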