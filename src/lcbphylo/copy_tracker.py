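"""Multi-copy gene family tracking: the 16S-rRNA-style investigation.

Copies of a family are extracted from annotated genomes, placed into LCBs
(positional homology), aligned into an all-copies matrix, and — given a
tree built from all copies — each species' copies are classified as
monophyletic, paraphyletic (one foreign clade nested inside) or
polyphyletic.  A high fraction of monophyletic multi-copy species is the
signature of concerted evolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Set, Tuple

import dendropy

from ._align import progressive_align_sequences
from .core import LCB, ConcatenatedAlignment, Genome
from .phylo import round_half_up

__all__ = [
    "GeneCopy",
    "CopyGrid",
    "extract_copies",
    "assign_copies_to_lcbs",
    "test_positional_orthology",
    "find_identical_copies",
    "align_copies",
    "classify_species_copy_topology",
    "concerted_index",
]

MONOPHYLETIC = "MONOPHYLETIC"
PARAPHYLETIC = "PARAPHYLETIC"
POLYPHYLETIC = "POLYPHYLETIC"


@dataclass
class GeneCopy:
    """One copy of a multi-copy family in one genome."""

    taxon_id: str
    copy_index: int
    start: int
    end: int
    strand: str
    sequence: str
    lcb_id: Optional[int] = None

    @property
    def label(self) -> str:
        return f"{self.taxon_id}|copy{self.copy_index}"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CopyGrid:
    """LCB x taxon grid of family copy placements (the Fig-2-style grid)."""

    lcb_ids: List[int]
    taxa: List[str]
    cells: Dict[Tuple[int, str], List[int]] = field(default_factory=dict)
    unassigned: List[GeneCopy] = field(default_factory=list)

    def row_taxa(self, lcb_id: int) -> Set[str]:
        return {t for (l, t) in self.cells if l == lcb_id}

    @property
    def n_rows(self) -> int:
        return len(self.lcb_ids)


def extract_copies(genomes: Sequence[Genome], family: str) -> List[GeneCopy]:
    """All copies of ``family`` (features matching by type or name prefix),
    strand-corrected, ordered by taxon then coordinate."""
    copies: List[GeneCopy] = []
    for g in sorted(genomes, key=lambda g: g.taxon_id):
        feats = [
            f for f in g.features if f.type == family or f.name.startswith(family)
        ]
        feats.sort(key=lambda f: f.start)
        for i, f in enumerate(feats):
            copies.append(
                GeneCopy(
                    taxon_id=g.taxon_id,
                    copy_index=i + 1,
                    start=f.start,
                    end=f.end,
                    strand=f.strand,
                    sequence=g.slice(f.start, f.end, f.strand),
                )
            )
    if not copies:
        raise KeyError(f"family {family!r} not found in any genome")
    return copies


def assign_copies_to_lcbs(
    copies: Sequence[GeneCopy], lcbs: Sequence[LCB]
) -> CopyGrid:
    """Assign each copy to the LCB overlapping at least half of its length.

    LCB segments never overlap within a genome, so at most one LCB can reach
    the 50% threshold (asserted).  Unassigned copies are recorded with
    ``lcb_id`` None.
    """
    taxa = sorted({c.taxon_id for c in copies})
    grid = CopyGrid(lcb_ids=[], taxa=taxa)
    for copy in copies:
        hits = []
        for lcb in lcbs:
            seg = lcb.segments.get(copy.taxon_id)
            if seg is None:
                continue
            overlap = min(copy.end, seg.end) - max(copy.start, seg.start)
            if overlap * 2 >= copy.length and overlap > 0:
                hits.append(lcb.lcb_id)
        assert len(hits) <= 1, "copy majority-overlaps two LCBs (non-overlap broken)"
        if hits:
            copy.lcb_id = hits[0]
            grid.cells.setdefault((hits[0], copy.taxon_id), []).append(copy.copy_index)
        else:
            copy.lcb_id = None
            grid.unassigned.append(copy)
    grid.lcb_ids = sorted({l for (l, _) in grid.cells})
    return grid


def test_positional_orthology(
    grid: CopyGrid, all_taxa: FrozenSet[str]
) -> Dict[str, object]:
    """Is any single LCB's copy row filled for every taxon?

    Returns the verdict plus, per grid row, the covered taxon set — the
    evidence for (or against) a positionally orthologous copy.
    """
    all_taxa = frozenset(all_taxa)
    rows = {l: frozenset(grid.row_taxa(l)) for l in grid.lcb_ids}
    verdict = any(all_taxa <= covered for covered in rows.values())
    return {"positional_orthology": verdict, "rows": rows}


def find_identical_copies(copies: Sequence[GeneCopy]) -> List[Dict[str, object]]:
    """Equivalence classes of byte-identical copy sequences.

    Each class is flagged ``within_taxon`` (all members from one genome),
    ``between_taxa`` (all members from different genomes) or ``mixed``.
    """
    groups: Dict[str, List[GeneCopy]] = {}
    for c in copies:
        groups.setdefault(c.sequence, []).append(c)
    out = []
    for seq, members in sorted(groups.items(), key=lambda kv: kv[1][0].label):
        taxa = [c.taxon_id for c in members]
        if len(set(taxa)) == 1:
            flag = "within_taxon"
        elif len(set(taxa)) == len(taxa):
            flag = "between_taxa"
        else:
            flag = "mixed"
        out.append(
            {"members": [c.label for c in members], "flag": flag, "size": len(members)}
        )
    return out


def align_copies(copies: Sequence[GeneCopy], band: int = 128) -> ConcatenatedAlignment:
    """Multiple alignment of all copy sequences (leaf labels taxon|copyN)."""
    seqs = {c.label: c.sequence for c in copies}
    rows = progressive_align_sequences(seqs, band=band)
    return ConcatenatedAlignment(taxa=list(seqs), rows=rows)


def _clade_leafsets(tree: dendropy.Tree) -> List[FrozenSet[str]]:
    out = []
    for node in tree.preorder_node_iter():
        out.append(frozenset(lf.taxon.label for lf in node.leaf_iter()))
    return out


def classify_species_copy_topology(
    tree: dendropy.Tree,
    copy_labels: Mapping[str, str],
    outgroup_taxa: Optional[Sequence[str]] = None,
) -> Dict[str, str]:
    """Classify each taxon's copies as mono-, para- or polyphyletic.

    ``copy_labels`` maps tree leaf labels to taxa.  When ``outgroup_taxa``
    is given the tree is first rooted above the MRCA of the outgroup's
    copies, which fixes the direction in which grades are read.  A taxon is
    PARAPHYLETIC only when its copies' MRCA contains exactly one nested
    foreign clade; deeper grades are reported POLYPHYLETIC.  Single-copy
    taxa are trivially MONOPHYLETIC.
    """
    tree = tree.clone(depth=1)
    tree.is_rooted = True
    leaf_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    unknown = set(copy_labels) - leaf_labels
    if unknown:
        raise KeyError(f"copy labels not in tree: {sorted(unknown)[:3]}")

    if outgroup_taxa:
        og = [l for l, t in copy_labels.items() if t in set(outgroup_taxa)]
        if og:
            og_taxa = [tx for tx in tree.taxon_namespace if tx.label in set(og)]
            mrca = tree.mrca(taxa=og_taxa)
            if mrca is not tree.seed_node:
                tree.reroot_at_edge(mrca.edge, update_bipartitions=False)

    by_taxon: Dict[str, List[str]] = {}
    for leaf, taxon in copy_labels.items():
        by_taxon.setdefault(taxon, []).append(leaf)

    # monophyly is rooting-independent: the taxon's copies must form one
    # side of a bipartition of the unrooted topology
    from .phylo import bipartition_set

    biparts = bipartition_set(tree)
    all_leaves = frozenset(leaf_labels)
    ref = min(all_leaves)

    clades = set(_clade_leafsets(tree))
    out: Dict[str, str] = {}
    for taxon, leaves in sorted(by_taxon.items()):
        if not leaves:
            raise KeyError(f"taxon {taxon} has no copies")
        if len(leaves) == 1:
            out[taxon] = MONOPHYLETIC
            continue
        own = frozenset(leaves)
        canon = own if ref not in own else frozenset(all_leaves - own)
        if canon in biparts or len(own) >= len(all_leaves) - 1:
            out[taxon] = MONOPHYLETIC
            continue
        # grade structure is read on the (outgroup-)rooted tree
        taxa_objs = [tx for tx in tree.taxon_namespace if tx.label in own]
        mrca = tree.mrca(taxa=taxa_objs)
        mrca_leaves = frozenset(lf.taxon.label for lf in mrca.leaf_iter())
        extra = mrca_leaves - own
        if not extra:
            out[taxon] = MONOPHYLETIC
        elif extra in clades:
            out[taxon] = PARAPHYLETIC
        else:
            out[taxon] = POLYPHYLETIC
    return out


def concerted_index(
    classes: Mapping[str, str],
    multi_copy_taxa: Optional[Set[str]] = None,
) -> float:
    """Fraction of (multi-copy) taxa classified MONOPHYLETIC, to 3 decimals."""
    taxa = list(classes)
    if multi_copy_taxa is not None:
        taxa = [t for t in taxa if t in multi_copy_taxa]
    if not taxa:
        raise ValueError("no taxa to score")
    frac = sum(1 for t in taxa if classes[t] == MONOPHYLETIC) / len(taxa)
    return round_half_up(frac, 3)
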