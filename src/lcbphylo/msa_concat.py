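"""Align LCB rows, concatenate blocks, extract loci, subsample columns."""

from __future__ import annotations

import itertools
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ._align import progressive_align_sequences
from .core import (
    LCB,
    ConcatenatedAlignment,
    GapMode,
    Genome,
    decode,
    encode,
)
from .phylo import round_half_up

__all__ = [
    "progressive_align",
    "align_all",
    "concatenate",
    "subsample_columns",
    "extract_locus_alignment",
    "alignment_summary",
    "MissingLocusError",
]


def progressive_align(
    lcb: LCB, genomes: Sequence[Genome], band: int = 128, guide=None
) -> LCB:
    """Fill ``lcb.rows`` with a progressive multiple alignment of its segments.

    Segment sequences are taken in block orientation (reverse-complemented
    for '-' segments) so that ungapping a row and undoing the orientation
    recovers the genome slice.  When the detector supplied internal anchor
    ``cut_offsets``, the block is aligned window-by-window between those
    exactly homologous positions (same scores and guide-tree procedure per
    window), which bounds how far the dynamic-programming band must reach.
    ``guide`` is an optional genome-scale guide tree (see
    :func:`lcbphylo._align.build_guide_tree`); fixing one merge order for
    every block and window avoids thousands of independently (and
    arbitrarily) resolved per-window guide trees.
    """
    if lcb.n_taxa < 2:
        raise ValueError(f"LCB {lcb.lcb_id} has fewer than 2 segments")
    by_id = {g.taxon_id: g for g in genomes}
    seqs: Dict[str, str] = {}
    for taxon, seg in lcb.segments.items():
        seqs[taxon] = by_id[taxon].slice(seg.start, seg.end, seg.strand)

    cuts = lcb.cut_offsets
    if not cuts:
        lcb.rows = progressive_align_sequences(seqs, band=band, guide=guide)
        return lcb

    taxa = list(seqs)
    n_cuts = len(cuts[taxa[0]])
    bounds = {
        t: [0] + list(cuts[t]) + [len(seqs[t])] for t in taxa
    }
    parts: Dict[str, List[str]] = {t: [] for t in taxa}
    for w in range(n_cuts + 1):
        window = {t: seqs[t][bounds[t][w] : bounds[t][w + 1]] for t in taxa}
        if any(not s for s in window.values()):
            # degenerate window (cut at a boundary): fall back to plain rows
            width = max(len(s) for s in window.values())
            aligned = {t: s + "-" * (width - len(s)) for t, s in window.items()}
        else:
            aligned = progressive_align_sequences(window, band=band, guide=guide)
        for t in taxa:
            parts[t].append(aligned[t])
    lcb.rows = {t: "".join(parts[t]) for t in taxa}
    return lcb


def align_all(
    lcbs: Sequence[LCB],
    genomes: Sequence[Genome],
    band: int = 128,
    genome_guide: bool = False,
) -> List[LCB]:
    """Align every block, optionally under one genome-scale guide tree.

    The default keeps independent per-window guide trees (with rotating
    tie-breaks): a single genome-wide guide is cheaper and more consistent
    but stamps any mis-resolved short branch into every ambiguous indel.
    """
    guide = None
    if genome_guide and len(genomes) > 2:
        from ._align import build_guide_tree

        guide = build_guide_tree({g.taxon_id: g.sequence for g in genomes})
    return [progressive_align(lcb, genomes, band=band, guide=guide) for lcb in lcbs]


def concatenate(
    lcbs: Sequence[LCB], taxa: Optional[Sequence[str]] = None
) -> ConcatenatedAlignment:
    """Concatenate aligned LCBs into a partitioned super-alignment.

    Blocks are laid out in ``lcb_id`` order; taxa missing from a block are
    padded with gaps across its partition.
    """
    blocks = sorted(lcbs, key=lambda b: b.lcb_id)
    if taxa is None:
        taxa = sorted({t for b in blocks for t in b.taxa})
    taxa = list(taxa)
    parts: List[Tuple[str, int, int]] = []
    chunks: Dict[str, List[str]] = {t: [] for t in taxa}
    col = 0
    for b in blocks:
        if b.rows is None:
            raise ValueError(f"LCB {b.lcb_id} is not aligned")
        if len(b.rows) != len(b.segments):
            raise ValueError(f"LCB {b.lcb_id}: rows/segments mismatch")
        width = b.alignment_length
        for t in taxa:
            chunks[t].append(b.rows.get(t, "-" * width))
        parts.append((f"lcb{b.lcb_id}", col, col + width))
        col += width
    rows = {t: "".join(chunks[t]) for t in taxa}
    return ConcatenatedAlignment(taxa=taxa, rows=rows, partitions=parts)


def subsample_columns(
    aln: ConcatenatedAlignment,
    n_columns: int,
    seed: int,
    with_replacement: bool = False,
) -> ConcatenatedAlignment:
    """Uniform random column subset (jackknife) or resample (bootstrap).

    The partition table of the result is replaced by ``source_columns``, the
    index each sampled column had in the input.  Sampling is seeded and
    deterministic.
    """
    total = aln.n_columns
    if not with_replacement and n_columns > total:
        raise ValueError(
            f"cannot draw {n_columns} of {total} columns without replacement"
        )
    rng = np.random.default_rng(seed)
    if n_columns == 0:
        return ConcatenatedAlignment(
            taxa=list(aln.taxa),
            rows={t: "" for t in aln.taxa},
            source_columns=np.zeros(0, dtype=np.int64),
        )
    idx = rng.choice(total, size=n_columns, replace=with_replacement)
    return aln.select_columns(idx)


class MissingLocusError(KeyError):
    """A requested locus is absent from one or more genomes."""

    def __init__(self, locus: str, taxa: Sequence[str]):
        self.locus = locus
        self.taxa = list(taxa)
        super().__init__(f"locus {locus!r} missing from: {', '.join(self.taxa)}")


def extract_locus_alignment(
    genomes: Sequence[Genome], locus_names: Sequence[str], band: int = 128
) -> ConcatenatedAlignment:
    """Per-locus progressive alignments concatenated in the given order.

    The first feature bearing each requested name is used per genome;
    '-'-strand loci are reverse-complemented before alignment.
    """
    taxa = [g.taxon_id for g in genomes]
    blocks: List[LCB] = []
    for i, locus in enumerate(locus_names):
        seqs: Dict[str, str] = {}
        missing: List[str] = []
        for g in genomes:
            feat = g.feature_by_name(locus)
            if feat is None:
                missing.append(g.taxon_id)
            else:
                seqs[g.taxon_id] = g.slice(feat.start, feat.end, feat.strand)
        if missing:
            raise MissingLocusError(locus, missing)
        rows = progressive_align_sequences(seqs, band=band)
        width = len(next(iter(rows.values())))
        blocks.append((locus, rows, width))

    parts: List[Tuple[str, int, int]] = []
    chunks: Dict[str, List[str]] = {t: [] for t in taxa}
    col = 0
    for locus, rows, width in blocks:
        for t in taxa:
            chunks[t].append(rows[t])
        parts.append((locus, col, col + width))
        col += width
    return ConcatenatedAlignment(
        taxa=list(taxa), rows={t: "".join(chunks[t]) for t in taxa}, partitions=parts
    )


def alignment_summary(
    aln: ConcatenatedAlignment, gap_mode: GapMode = GapMode.FIFTH_STATE
) -> Dict[str, float]:
    """Column count, mean pairwise identity, parsimony-informative columns.

    Identity is averaged over row pairs; sites where either row has a gap
    (or N) are excluded from that pair's comparison.  A column is parsimony
    informative iff at least two character states are each borne by at least
    two taxa; the gap counts as a state only under ``FIFTH_STATE``.
    """
    mat = aln.matrix()
    n, L = mat.shape
    idents = []
    for i, j in itertools.combinations(range(n), 2):
        ok = (mat[i] < 4) & (mat[j] < 4)
        m = int(ok.sum())
        if m:
            idents.append(float((mat[i][ok] == mat[j][ok]).sum()) / m)
    mean_identity = float(np.mean(idents)) if idents else 1.0

    states = [0, 1, 2, 3] + ([5] if gap_mode is GapMode.FIFTH_STATE else [])
    per_state = np.stack([(mat == s).sum(axis=0) for s in states])
    informative = (per_state >= 2).sum(axis=0) >= 2
    n_inf = int(informative.sum())
    return {
        "n_columns": L,
        "mean_pairwise_identity_pct": round_half_up(100.0 * mean_identity, 1),
        "parsimony_informative": n_inf,
        "parsimony_informative_pct": round_half_up(100.0 * n_inf / L, 2)
        if L
        else 0.0,
    }
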