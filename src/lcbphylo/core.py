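"""Core data containers shared across the pipeline.

Coordinate conventions
----------------------
Internally every coordinate is 0-based, half-open (``[start, end)``) on the
forward strand.  All external formats (FASTA headers, GFF3, XMFA, TSV
reports) use the 1-based inclusive convention; the conversion happens in
:mod:`lcbphylo.io` and nowhere else.  A segment on the ``-`` strand still
stores forward-strand coordinates; only its *row text* (after alignment) is
reverse-complemented.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Feature",
    "Genome",
    "Anchor",
    "Segment",
    "LCB",
    "ConcatenatedAlignment",
    "GapMode",
    "revcomp",
    "encode",
    "decode",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# numeric base codes used throughout the numeric kernels
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4, "-": 5}
_ALPHABET = np.frombuffer(b"ACGTN-", dtype=np.uint8)

_ENC_LUT = np.full(256, 4, dtype=np.uint8)  # unknown letters -> N
for _b, _c in _CODE.items():
    _ENC_LUT[ord(_b)] = _c
    _ENC_LUT[ord(_b.lower())] = _c


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to uint8 codes (A,C,G,T,N,- -> 0..5)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENC_LUT[raw]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`."""
    return _ALPHABET[codes].tobytes().decode("ascii")


@dataclass(frozen=True)
class Feature:
    """One annotated feature, 0-based half-open internal coordinates."""

    name: str
    start: int
    end: int
    strand: str  # '+' or '-'
    type: str = "gene"  # 'gene' | 'rRNA'

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad feature interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Genome:
    """One taxon's DNA sequence plus optional annotation.

    ``features`` may be empty; when present they must lie inside the
    sequence.  ``circular`` is carried as metadata only — coordinates are
    always linear with the origin fixed at 0.
    """

    taxon_id: str
    sequence: str
    circular: bool = False
    features: List[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        for f in self.features:
            if f.end > len(self.sequence):
                raise ValueError(
                    f"feature {f.name} [{f.start},{f.end}) outside genome "
                    f"{self.taxon_id} of length {len(self.sequence)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def slice(self, start: int, end: int, strand: str = "+") -> str:
        """Forward-strand slice, reverse-complemented when strand is '-'."""
        s = self.sequence[start:end]
        return revcomp(s) if strand == "-" else s

    def feature_by_name(self, name: str) -> Optional[Feature]:
        for f in self.features:
            if f.name == name:
                return f
        return None


@dataclass(frozen=True)
class Anchor:
    """A unique exact k-mer match across two or more genomes.

    ``occurrences`` maps taxon_id -> (position, strand) where *position* is
    the 0-based forward-strand start of the k-mer and strand says whether the
    canonical k-mer appears forward ('+') or reverse-complemented ('-') at
    that site.  A taxon is listed only if the k-mer occurs exactly once in
    its genome.
    """

    kmer_length: int
    occurrences: Tuple[Tuple[str, int, str], ...]  # (taxon, pos, strand)

    @property
    def taxa(self) -> frozenset:
        return frozenset(t for t, _, _ in self.occurrences)

    def occurrence(self, taxon: str) -> Tuple[int, str]:
        for t, p, s in self.occurrences:
            if t == taxon:
                return p, s
        raise KeyError(taxon)


@dataclass(frozen=True)
class Segment:
    """One taxon's extent of an LCB (forward-strand, 0-based half-open)."""

    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad segment [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class LCB:
    """A locally collinear block: at most one segment per taxon.

    After alignment, ``rows`` holds equal-length gapped sequences in block
    orientation: ungapping a row and (for '-' segments) reverse-complementing
    reproduces the forward-strand genome slice.

    ``cut_offsets`` (optional, detector-provided) are block-orientation
    offsets of internal anchor k-mers, one equally-long ascending list per
    taxon, marking exactly homologous positions the aligner may cut at.
    """

    lcb_id: int
    segments: Dict[str, Segment]
    rows: Optional[Dict[str, str]] = None
    cut_offsets: Optional[Dict[str, List[int]]] = None

    @property
    def taxa(self) -> frozenset:
        return frozenset(self.segments)

    @property
    def n_taxa(self) -> int:
        return len(self.segments)

    @property
    def mean_segment_length(self) -> float:
        return float(np.mean([s.length for s in self.segments.values()]))

    @property
    def alignment_length(self) -> int:
        if not self.rows:
            raise ValueError(f"LCB {self.lcb_id} is not aligned")
        return len(next(iter(self.rows.values())))

    def validate_rows(self, genomes: Dict[str, "Genome"]) -> None:
        """Check the row/segment round-trip invariant; raise on violation."""
        if self.rows is None:
            return
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) != 1:
            raise ValueError(f"LCB {self.lcb_id}: unequal row lengths")
        for taxon, seg in self.segments.items():
            ungapped = self.rows[taxon].replace("-", "")
            expect = genomes[taxon].slice(seg.start, seg.end, seg.strand)
            if ungapped != expect:
                raise ValueError(
                    f"LCB {self.lcb_id}: row of {taxon} does not reproduce "
                    "its genome slice"
                )


class GapMode(enum.Enum):
    """How alignment gaps are treated by parsimony scoring.

    FIFTH_STATE: '-' is a character state of its own ('N' stays fully
    ambiguous over A,C,G,T).  MISSING: both '-' and 'N' are fully ambiguous.
    """

    FIFTH_STATE = "fifth"
    MISSING = "missing"


@dataclass
class ConcatenatedAlignment:
    """Taxa x columns character matrix with a partition table.

    ``partitions`` maps each source block/locus to a contiguous 0-based
    half-open column range.  Column-subsampled alignments instead carry
    ``source_columns``, the index of each column in the parent alignment.
    """

    taxa: List[str]
    rows: Dict[str, str]
    partitions: List[Tuple[str, int, int]] = field(default_factory=list)
    source_columns: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        lengths = {len(self.rows[t]) for t in self.taxa}
        if len(lengths) > 1:
            raise ValueError("rows of unequal length")
        if set(self.taxa) != set(self.rows):
            raise ValueError("taxa and rows disagree")

    @property
    def n_columns(self) -> int:
        if not self.taxa:
            return 0
        return len(self.rows[self.taxa[0]])

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def matrix(self) -> np.ndarray:
        """(n_taxa, n_columns) uint8 code matrix in ``taxa`` order."""
        if not self.taxa:
            return np.zeros((0, 0), dtype=np.uint8)
        return np.vstack([encode(self.rows[t]) for t in self.taxa])

    def select_columns(self, idx: Sequence[int]) -> "ConcatenatedAlignment":
        idx = np.asarray(idx, dtype=np.int64)
        mat = self.matrix()[:, idx]
        rows = {t: decode(mat[i]) for i, t in enumerate(self.taxa)}
        return ConcatenatedAlignment(
            taxa=list(self.taxa), rows=rows, partitions=[], source_columns=idx
        )


def check_pairwise_bijection(lcbs: Iterable[LCB]) -> None:
    """Verify the one-to-one homology contract.

    Within each genome, segments of distinct LCBs must not overlap; because
    each LCB holds at most one segment per taxon, this makes the induced
    pairwise interval mapping a partial bijection.  Raises ``ValueError`` on
    violation.
    """
    per_taxon: Dict[str, List[Tuple[int, int, int]]] = {}
    for lcb in lcbs:
        for taxon, seg in lcb.segments.items():
            per_taxon.setdefault(taxon, []).append((seg.start, seg.end, lcb.lcb_id))
    for taxon, ivs in per_taxon.items():
        ivs.sort()
        for (s1, e1, i1), (s2, e2, i2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError(
                    f"LCBs {i1} and {i2} overlap in {taxon}: "
                    f"[{s1},{e1}) vs [{s2},{e2})"
                )
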