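"""Project gene annotations onto LCB alignments; gene/non-coding accounting.

Feature intervals are mapped through each taxon's gapped alignment row to
alignment columns (strand-aware), so a gene's extent can be compared across
taxa in column space; residual non-gap columns are labelled non-coding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import LCB, Feature, Genome
from .phylo import round_half_up

__all__ = [
    "ProjectedTrack",
    "project_annotations",
    "genes_per_lcb",
    "noncoding_fraction",
    "write_tracks_tsv",
]


@dataclass(frozen=True)
class TrackInterval:
    """One labelled run of alignment columns (0-based half-open)."""

    col_start: int
    col_end: int
    name: str
    strand: str
    kind: str  # 'gene' | 'rRNA' | 'noncoding'


@dataclass
class ProjectedTrack:
    lcb_id: int
    taxon_id: str
    intervals: List[TrackInterval]


def _column_positions(row: str, seg_start: int, seg_end: int, strand: str):
    """Non-gap column indices and their forward-strand genome positions."""
    arr = np.frombuffer(row.encode("ascii"), dtype=np.uint8)
    cols = np.flatnonzero(arr != ord("-"))
    n = cols.size
    if strand == "+":
        pos = seg_start + np.arange(n)
    else:
        pos = seg_end - 1 - np.arange(n)
    return cols, pos


def project_annotations(
    lcb: LCB, genomes: Sequence[Genome]
) -> List[ProjectedTrack]:
    """One labelled track per taxon of an aligned LCB.

    Overlapping features are resolved by the first-listed feature; columns
    whose genome position lies in no feature are labelled ``noncoding``.
    """
    if lcb.rows is None:
        raise ValueError(f"LCB {lcb.lcb_id} is not aligned")
    by_id = {g.taxon_id: g for g in genomes}
    tracks: List[ProjectedTrack] = []
    for taxon in sorted(lcb.segments):
        genome = by_id[taxon]
        seg = lcb.segments[taxon]
        for f in genome.features:
            if f.end > len(genome):
                raise ValueError(
                    f"feature {f.name} outside genome {taxon}"
                )
        cols, pos = _column_positions(lcb.rows[taxon], seg.start, seg.end, seg.strand)
        # per-position feature index within the segment (first-listed wins)
        owner = np.full(seg.length, -1, dtype=np.int64)
        for fi, f in enumerate(genome.features):
            lo, hi = max(f.start, seg.start), min(f.end, seg.end)
            if lo < hi:
                sl = owner[lo - seg.start : hi - seg.start]
                sl[sl == -1] = fi
        labels = owner[pos - seg.start]

        intervals: List[TrackInterval] = []
        run_start = 0
        for i in range(1, len(cols) + 1):
            if i < len(cols) and labels[i] == labels[run_start]:
                continue
            fi = int(labels[run_start])
            if fi >= 0:
                f = genome.features[fi]
                iv = TrackInterval(
                    col_start=int(cols[run_start]),
                    col_end=int(cols[i - 1]) + 1,
                    name=f.name,
                    strand=f.strand,
                    kind=f.type,
                )
            else:
                iv = TrackInterval(
                    col_start=int(cols[run_start]),
                    col_end=int(cols[i - 1]) + 1,
                    name=".",
                    strand=".",
                    kind="noncoding",
                )
            intervals.append(iv)
            run_start = i
        tracks.append(ProjectedTrack(lcb_id=lcb.lcb_id, taxon_id=taxon, intervals=intervals))
    return tracks


def _segment_feature_overlap(
    features: Sequence[Feature], start: int, end: int
) -> int:
    """bp of [start,end) covered by at least one feature."""
    ivs = sorted(
        (max(f.start, start), min(f.end, end))
        for f in features
        if f.start < end and f.end > start
    )
    covered = 0
    cur_s = cur_e = None
    for s, e in ivs:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        covered += cur_e - cur_s
    return covered


def genes_per_lcb(
    lcbs: Sequence[LCB], genomes: Sequence[Genome], taxon: str
) -> Dict[str, object]:
    """Per-LCB gene counts for one taxon plus min/max/mean (2 decimals).

    A gene counts for an LCB iff its span overlaps the taxon's segment by at
    least 1 bp; a gene split over an LCB boundary still counts as one whole
    gene.
    """
    genome = next(g for g in genomes if g.taxon_id == taxon)
    counts: Dict[int, int] = {}
    for lcb in lcbs:
        seg = lcb.segments.get(taxon)
        if seg is None:
            continue
        counts[lcb.lcb_id] = sum(
            1 for f in genome.features if f.start < seg.end and f.end > seg.start
        )
    values = list(counts.values())
    return {
        "per_lcb": counts,
        "min": min(values) if values else 0,
        "max": max(values) if values else 0,
        "mean": round_half_up(float(np.mean(values)), 2) if values else 0.0,
    }


def noncoding_fraction(
    lcbs: Sequence[LCB], genomes: Sequence[Genome], taxon: str
) -> Dict[str, float]:
    """Non-coding bp inside the taxon's LCB segments, as count and percent.

    Counts unaligned (genome) base pairs inside segments that no annotated
    feature covers; partial feature overlap contributes only the overlapping
    base pairs.
    """
    genome = next(g for g in genomes if g.taxon_id == taxon)
    total = 0
    coding = 0
    for lcb in lcbs:
        seg = lcb.segments.get(taxon)
        if seg is None:
            continue
        total += seg.length
        coding += _segment_feature_overlap(genome.features, seg.start, seg.end)
    noncoding = total - coding
    return {
        "noncoding_bp": noncoding,
        "total_bp": total,
        "pct_noncoding": round_half_up(100.0 * noncoding / total, 1) if total else 0.0,
    }


def write_tracks_tsv(tracks: Sequence[ProjectedTrack], path: str) -> None:
    rows = []
    for tr in tracks:
        for iv in tr.intervals:
            rows.append(
                {
                    "lcb": tr.lcb_id,
                    "taxon": tr.taxon_id,
                    "col_start": iv.col_start + 1,
                    "col_end": iv.col_end,
                    "kind": iv.kind,
                    "name": iv.name,
                    "strand": iv.strand,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
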