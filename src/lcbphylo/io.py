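"""Readers and writers for the pipeline's on-disk formats.

FASTA goes through Biopython.  GFF3 here is the minimal gene/rRNA feature
table the pipeline itself emits (columns fixed, attribute ``Name=``); XMFA is
the multi-block gapped-FASTA genome-alignment format, one gapped FASTA
section per block with blocks terminated by ``=`` lines.  All on-disk
coordinates are 1-based inclusive; negative-strand coordinates are given on
the forward strand with the row text reverse-complemented.
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import LCB, ConcatenatedAlignment, Feature, Genome, Segment

__all__ = [
    "read_fasta_genome",
    "read_genome_dir",
    "write_fasta_genome",
    "read_gff3",
    "write_gff3",
    "read_xmfa",
    "write_xmfa",
    "write_phylip",
    "write_alignment_fasta",
    "write_partitions",
    "read_newick",
    "write_newick",
]


# ---------------------------------------------------------------- FASTA/GFF3


def write_fasta_genome(genome: Genome, path: str) -> None:
    rec = SeqRecord(Seq(genome.sequence), id=genome.taxon_id, description="")
    SeqIO.write([rec], path, "fasta")


def read_fasta_genome(path: str, taxon_id: Optional[str] = None) -> Genome:
    """Read a single-record FASTA as one genome.

    The taxon id defaults to the record id.  A sibling ``<stem>.gff3`` file,
    if present, is read as the genome's feature table.
    """
    rec = next(SeqIO.parse(path, "fasta"))
    genome = Genome(
        taxon_id=taxon_id or rec.id, sequence=str(rec.seq).upper()
    )
    gff = os.path.splitext(path)[0] + ".gff3"
    if os.path.exists(gff):
        genome.features = read_gff3(gff)
    return genome


def read_genome_dir(path: str) -> List[Genome]:
    """Read every ``*.fasta``/``*.fa`` in a directory (sorted by name)."""
    genomes = []
    for name in sorted(os.listdir(path)):
        if name.endswith((".fasta", ".fa", ".fna")):
            genomes.append(read_fasta_genome(os.path.join(path, name)))
    if not genomes:
        raise FileNotFoundError(f"no FASTA files in {path}")
    return genomes


def write_gff3(features: Sequence[Feature], seqid: str, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(
                f"{seqid}\tlcbphylo\t{f.type}\t{f.start + 1}\t{f.end}\t.\t"
                f"{f.strand}\t.\tName={f.name}\n"
            )


def read_gff3(path: str) -> List[Feature]:
    feats: List[Feature] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            name = "unknown"
            for item in cols[8].split(";"):
                if item.startswith("Name="):
                    name = item[5:]
            feats.append(
                Feature(
                    name=name,
                    start=int(cols[3]) - 1,
                    end=int(cols[4]),
                    strand=cols[6],
                    type=cols[2],
                )
            )
    return feats


# --------------------------------------------------------------------- XMFA


def write_xmfa(lcbs: Iterable[LCB], path: str) -> None:
    """Write aligned LCBs as XMFA (one gapped FASTA section per block)."""
    with open(path, "w") as fh:
        fh.write("#FormatVersion lcbphylo 1\n")
        for lcb in lcbs:
            if lcb.rows is None:
                raise ValueError(f"LCB {lcb.lcb_id} is not aligned")
            for taxon in sorted(lcb.segments):
                seg = lcb.segments[taxon]
                fh.write(
                    f">{taxon}:{seg.start + 1}-{seg.end} {seg.strand} "
                    f"lcb{lcb.lcb_id}\n"
                )
                row = lcb.rows[taxon]
                for i in range(0, len(row), 80):
                    fh.write(row[i : i + 80] + "\n")
            fh.write("=\n")


def read_xmfa(path: str) -> List[LCB]:
    lcbs: List[LCB] = []
    segments: Dict[str, Segment] = {}
    rows: Dict[str, str] = {}
    cur: Optional[Tuple[str, Segment]] = None
    buf: List[str] = []

    def flush_record() -> None:
        nonlocal cur
        if cur is not None:
            taxon, seg = cur
            segments[taxon] = seg
            rows[taxon] = "".join(buf)
        cur = None
        buf.clear()

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.startswith("="):
                flush_record()
                if segments:
                    lcbs.append(
                        LCB(lcb_id=len(lcbs), segments=dict(segments), rows=dict(rows))
                    )
                segments.clear()
                rows.clear()
            elif line.startswith(">"):
                flush_record()
                head = line[1:].split()
                taxon, rng = head[0].rsplit(":", 1)
                strand = head[1] if len(head) > 1 else "+"
                start, end = rng.split("-")
                cur = (taxon, Segment(int(start) - 1, int(end), strand))
            else:
                buf.append(line)
        flush_record()
        if segments:  # trailing block without '='
            lcbs.append(LCB(lcb_id=len(lcbs), segments=dict(segments), rows=dict(rows)))
    return lcbs


# --------------------------------------------------- alignments & partitions


def write_phylip(aln: ConcatenatedAlignment, path: str) -> None:
    """Relaxed PHYLIP: full names, one sequence per line."""
    with open(path, "w") as fh:
        fh.write(f"{aln.n_taxa} {aln.n_columns}\n")
        for taxon in aln.taxa:
            fh.write(f"{taxon}  {aln.rows[taxon]}\n")


def write_alignment_fasta(aln: ConcatenatedAlignment, path: str) -> None:
    recs = [
        SeqRecord(Seq(aln.rows[t]), id=t, description="") for t in aln.taxa
    ]
    SeqIO.write(recs, path, "fasta")


def read_alignment_fasta(path: str) -> ConcatenatedAlignment:
    taxa: List[str] = []
    rows: Dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        taxa.append(rec.id)
        rows[rec.id] = str(rec.seq).upper()
    return ConcatenatedAlignment(taxa=taxa, rows=rows)


def write_partitions(aln: ConcatenatedAlignment, path: str) -> None:
    """RAxML-style partition text (1-based inclusive column ranges)."""
    with open(path, "w") as fh:
        for name, first, last in aln.partitions:
            fh.write(f"DNA, {name} = {first + 1}-{last}\n")


# ------------------------------------------------------------------- Newick


def read_newick(path: str) -> dendropy.Tree:
    return dendropy.Tree.get(path=path, schema="newick", preserve_underscores=True)


def write_newick(tree: dendropy.Tree, path: str) -> None:
    tree.write(path=path, schema="newick", suppress_rooting=True, unquoted_underscores=True)
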