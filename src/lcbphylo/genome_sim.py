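"""Genome evolution simulator with known tree, homology, and gene history.

A root genome (genes, intergenic spacers, and a multi-copy rRNA family) is
evolved down a Yule tree.  Along every branch the simulator applies, in
order: Jukes-Cantor substitutions (rRNA sites at a reduced rate),
within-genome gene conversion of the rRNA family (concerted evolution),
indels with geometric lengths, inversions (reverse-complement in place) and
translocations (excise and reinsert).  Every site carries its root-genome
coordinate, orientation and feature id throughout, so each leaf genome comes
with an exact site-level homology map back to the root — the ground truth
against which LCB detection is scored.

Branch lengths are rescaled so the root-to-tip depth is 1.0; all per-branch
rates are therefore on the root-to-tip scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import dendropy
import numpy as np

from .core import Feature, Genome, decode, revcomp

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "TruthInterval",
    "sample_yule_tree",
    "evolve_genomes",
    "apply_gene_conversion",
    "write_dataset",
]

_SEVEN_LOCI = ("gyrB", "rpoA", "recA", "topA", "mreB", "gapA", "atpA")


@dataclass
class SimulationConfig:
    """Parameters of one simulated dataset.

    Rates are per unit branch length on the root-to-tip scale (the tree is
    rescaled to depth 1.0): ``subs_per_site`` is the expected number of
    substitutions per site on a root-to-tip path; ``indel_rate`` is events
    per site; inversion/translocation/conversion/hgt rates are events per
    genome (per rRNA copy for conversion).
    """

    n_taxa: int = 22
    genome_length: int = 5_000_000
    tree_seed: int = 1
    mutation_seed: int = 2
    birth_rate: float = 1.0
    subs_per_site: float = 0.2
    indel_rate: float = 0.01
    indel_length_geom_p: float = 0.3
    inversion_rate: float = 5.0
    translocation_rate: float = 3.0
    rearrangement_length_range: Tuple[int, int] = (1_000, 50_000)
    n_rrna_copies: Union[int, Tuple[int, int]] = (8, 11)
    rrna_length: int = 1_500
    rrna_rate_scale: float = 0.1
    rrna_paralog_divergence: float = 0.02
    conversion_rate: float = 1.0
    gene_density: float = 0.85
    mean_gene_length: int = 900
    hgt_rate: float = 0.0

    def __post_init__(self) -> None:
        rates = (
            self.subs_per_site,
            self.indel_rate,
            self.inversion_rate,
            self.translocation_rate,
            self.conversion_rate,
            self.hgt_rate,
            self.birth_rate,
        )
        if any(r < 0 for r in rates):
            raise ValueError("all rates must be >= 0")
        if not (0.0 < self.indel_length_geom_p <= 1.0):
            raise ValueError("indel_length_geom_p must be in (0, 1]")
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        if self.genome_length < 10 * self.mean_gene_length:
            raise ValueError("genome_length must be >= 10 x mean gene length")
        if not (0.0 < self.gene_density <= 1.0):
            raise ValueError("gene_density must be in (0, 1]")
        lo, hi = self._rrna_range()
        if lo < 1:
            raise ValueError("n_rrna_copies must be >= 1")
        if hi < lo:
            raise ValueError("bad n_rrna_copies range")

    def _rrna_range(self) -> Tuple[int, int]:
        if isinstance(self.n_rrna_copies, int):
            return self.n_rrna_copies, self.n_rrna_copies
        lo, hi = self.n_rrna_copies
        return int(lo), int(hi)


@dataclass(frozen=True)
class TruthInterval:
    """A maximal leaf-genome run mapping to one ancestral (root) interval.

    ``root_start == -1`` flags de-novo (inserted) material.  Coordinates are
    0-based half-open; ``orient`` is '+' when leaf and root run in the same
    direction.
    """

    leaf_start: int
    leaf_end: int
    root_start: int
    root_end: int
    orient: str


@dataclass
class SimulatedDataset:
    genomes: List[Genome]
    true_tree: dendropy.Tree
    truth_maps: Dict[str, List[TruthInterval]]
    copy_registry: List[Dict[str, object]]
    config: SimulationConfig
    # per-site root coordinate (-1 de novo) and orientation, per taxon;
    # the interval truth_maps above are derived from these arrays
    ancestries: Dict[str, np.ndarray] = field(default_factory=dict)
    strands: Dict[str, np.ndarray] = field(default_factory=dict)
    root_features: List[Feature] = field(default_factory=list)


# ------------------------------------------------------------------- trees


def sample_yule_tree(n_taxa: int, birth_rate: float, seed: int) -> dendropy.Tree:
    """Pure-birth (Yule) tree with ``n_taxa`` leaves; ultrametric, with the
    root at the first split.  Identical seeds give identical Newick output.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be > 0")
    rng = np.random.default_rng(seed)
    ns = dendropy.TaxonNamespace([f"t{i + 1}" for i in range(n_taxa)])
    tree = dendropy.Tree(taxon_namespace=ns)
    root = tree.seed_node
    root.birth_time = 0.0
    active: List[dendropy.Node] = []
    for _ in range(2):
        child = dendropy.Node()
        child.birth_time = 0.0
        root.add_child(child)
        active.append(child)
    now = 0.0
    while len(active) < n_taxa:
        now += float(rng.exponential(1.0 / (birth_rate * len(active))))
        idx = int(rng.integers(len(active)))
        parent = active.pop(idx)
        parent.split_time = now
        for _ in range(2):
            child = dendropy.Node()
            child.birth_time = now
            parent.add_child(child)
            active.append(child)
    # one more waiting time sets the total depth
    now += float(rng.exponential(1.0 / (birth_rate * len(active))))
    leaf_no = 0
    for node in tree.preorder_node_iter():
        if node is root:
            node.edge.length = None
            continue
        end = getattr(node, "split_time", now)
        node.edge.length = end - node.birth_time
        if node.is_leaf():
            leaf_no += 1
            node.taxon = ns.get_taxon(f"t{leaf_no}")
    tree.is_rooted = True
    return tree


def _scaled_to_unit_depth(tree: dendropy.Tree) -> dendropy.Tree:
    clone = tree.clone(depth=1)
    depth = max(
        lf.distance_from_root() for lf in clone.leaf_node_iter()
    )
    if depth <= 0:
        raise ValueError("tree has zero depth")
    for edge in clone.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length / depth
    return clone


# ----------------------------------------------------------- lineage state


class _Lineage:
    """Mutable per-lineage genome state during simulation."""

    __slots__ = ("seq", "anc", "strand", "feat")

    def __init__(self, seq, anc, strand, feat):
        self.seq = seq  # uint8 codes 0..3
        self.anc = anc  # int64 root coordinate, -1 de novo
        self.strand = strand  # int8 +-1 orientation relative to root
        self.feat = feat  # int32 feature id, -1 intergenic

    def copy(self) -> "_Lineage":
        return _Lineage(
            self.seq.copy(), self.anc.copy(), self.strand.copy(), self.feat.copy()
        )

    def __len__(self) -> int:
        return len(self.seq)


def _build_root(
    cfg: SimulationConfig, rng: np.random.Generator
) -> Tuple[_Lineage, List[Feature], int]:
    """Random root genome with gene/rRNA layout.

    Returns the root lineage, the root feature table (feature id == index)
    and the rRNA copy count.  rRNA copies occupy feature ids 0..n_copies-1.
    """
    L = cfg.genome_length
    seq = rng.integers(0, 4, size=L, dtype=np.uint8)
    feat = np.full(L, -1, dtype=np.int32)
    lo, hi = cfg._rrna_range()
    n_copies = int(rng.integers(lo, hi + 1))

    template = rng.integers(0, 4, size=cfg.rrna_length, dtype=np.uint8)

    # expected spacer keeps the requested gene density
    mean_spacer = cfg.mean_gene_length * (1.0 - cfg.gene_density) / cfg.gene_density
    approx_slots = max(n_copies + 1, int(L * cfg.gene_density / cfg.mean_gene_length))
    rrna_slots = set(
        int(x) for x in rng.choice(approx_slots, size=n_copies, replace=False)
    )

    features: List[Feature] = []
    # rRNA features first so their ids are 0..n_copies-1
    rrna_records: List[Tuple[int, int, str]] = []
    gene_records: List[Tuple[int, int, str]] = []
    pos = 0
    slot = 0
    copy_no = 0
    while pos < L - cfg.mean_gene_length and slot < 10 * approx_slots:
        spacer = int(rng.exponential(mean_spacer)) if mean_spacer > 0 else 0
        pos += spacer
        if slot in rrna_slots and copy_no < n_copies:
            length = cfg.rrna_length
            if pos + length > L:
                break
            rrna_records.append((pos, pos + length, "+" if rng.random() < 0.5 else "-"))
            copy_no += 1
        else:
            length = max(150, int(rng.normal(cfg.mean_gene_length, cfg.mean_gene_length / 4)))
            if pos + length > L:
                break
            gene_records.append((pos, pos + length, "+" if rng.random() < 0.5 else "-"))
        pos += length
        slot += 1
    # force-place any rRNA copies that did not get a slot (tiny genomes)
    while copy_no < n_copies and gene_records:
        s, e, st = gene_records.pop(int(rng.integers(len(gene_records))))
        rrna_records.append((s, min(e, s + cfg.rrna_length), st))
        copy_no += 1
    if copy_no < n_copies:
        raise ValueError("genome too short to place the rRNA family")

    rrna_records.sort()
    for i, (s, e, st) in enumerate(rrna_records):
        features.append(Feature(name=f"rrn_{i + 1}", start=s, end=e, strand=st, type="rRNA"))
        sub = template[: e - s]
        seq[s:e] = sub if st == "+" else (3 - sub)[::-1]
        feat[s:e] = i
    gene_records.sort()
    for i, (s, e, st) in enumerate(gene_records):
        name = _SEVEN_LOCI[i] if i < len(_SEVEN_LOCI) else f"gene_{i + 1:04d}"
        features.append(
            Feature(name=name, start=s, end=e, strand=st, type="gene")
        )
        feat[s:e] = n_copies + i

    # root-era paralog divergence of the rRNA copies
    if cfg.rrna_paralog_divergence > 0:
        for i, (s, e, st) in enumerate(rrna_records):
            _jc_mutate(seq, s, e, cfg.rrna_paralog_divergence / 2.0, rng)

    lineage = _Lineage(
        seq=seq,
        anc=np.arange(L, dtype=np.int64),
        strand=np.ones(L, dtype=np.int8),
        feat=feat,
    )
    return lineage, features, n_copies


def _jc_mutate(seq: np.ndarray, start: int, end: int, d: float, rng) -> None:
    """Apply JC substitutions at expected ``d`` substitutions/site in place."""
    if d <= 0 or end <= start:
        return
    p = 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))
    hit = np.flatnonzero(rng.random(end - start) < p) + start
    if hit.size:
        seq[hit] = (seq[hit] + rng.integers(1, 4, size=hit.size)) % 4


# ------------------------------------------------------------ branch events


def _apply_substitutions(lin: _Lineage, d_bg: float, d_rrna: float, n_copies: int, rng) -> None:
    if d_bg <= 0 and d_rrna <= 0:
        return
    is_rrna = (lin.feat >= 0) & (lin.feat < n_copies)
    p_bg = 0.75 * (1.0 - np.exp(-4.0 * d_bg / 3.0))
    p_rr = 0.75 * (1.0 - np.exp(-4.0 * d_rrna / 3.0))
    p = np.where(is_rrna, p_rr, p_bg)
    hit = np.flatnonzero(rng.random(len(lin)) < p)
    if hit.size:
        lin.seq[hit] = (lin.seq[hit] + rng.integers(1, 4, size=hit.size)) % 4


def _copy_span(lin: _Lineage, fid: int) -> Optional[Tuple[int, int, int]]:
    """(start, end, orientation) of a feature id's longest contiguous run.

    Rearrangements can fragment a copy or drop foreign material inside it;
    bridging fragments with min..max would make conversion splice unrelated
    sequence between copies, so only the largest intact piece is used.
    """
    pos = np.flatnonzero(lin.feat == fid)
    if pos.size < 2:
        return None
    breaks = np.flatnonzero(np.diff(pos) > 1) + 1
    starts = np.concatenate([[0], breaks])
    ends = np.concatenate([breaks, [pos.size]])
    li = int(np.argmax(ends - starts))
    s, e = int(pos[starts[li]]), int(pos[ends[li] - 1]) + 1
    if e - s < 2:
        return None
    orient = 1 if int(lin.strand[s:e].sum()) >= 0 else -1
    return s, e, orient


def _reading_sign(
    lin: _Lineage,
    start: int,
    end: int,
    orient: int,
    root_features: Sequence[Feature],
    root_feat0: np.ndarray,
    fallback_fid: int,
) -> int:
    """Reading orientation of a span: site orientation times the strand of
    the root feature its material actually descends from (conversion may
    have replaced a copy's content with another paralog's)."""
    anc = lin.anc[start:end]
    ok = anc[anc >= 0]
    root_fid = -1
    if ok.size:
        cands = root_feat0[ok[: min(ok.size, 50)]]
        cands = cands[cands >= 0]
        if cands.size:
            root_fid = int(cands[0])
    if root_fid < 0:
        root_fid = fallback_fid
    return orient * (1 if root_features[root_fid].strand == "+" else -1)


def _splice(lin: _Lineage, start: int, end: int, seq, anc, strand, feat) -> None:
    lin.seq = np.concatenate([lin.seq[:start], seq, lin.seq[end:]])
    lin.anc = np.concatenate([lin.anc[:start], anc, lin.anc[end:]])
    lin.strand = np.concatenate([lin.strand[:start], strand, lin.strand[end:]])
    lin.feat = np.concatenate([lin.feat[:start], feat, lin.feat[end:]])


def _apply_conversion(
    lin: _Lineage,
    n_copies: int,
    n_events: int,
    rng,
    registry,
    lineage_label: str,
    root_features: Sequence[Feature],
    root_feat0: "np.ndarray",
) -> None:
    """Gene conversion: overwrite one rRNA copy with another, in place.

    Copies on opposite strands are homogenised in reading orientation: the
    donor's material is reverse-complemented so the recipient keeps its own
    strand.  A copy's effective strand combines its root feature strand with
    any inversions its site carries (the ancestry orientation sign).
    """
    for ev in range(n_events):
        fids = [f for f in range(n_copies) if _copy_span(lin, f) is not None]
        if len(fids) < 2:
            return
        recipient, donor = rng.choice(len(fids), size=2, replace=False)
        rf, df = fids[int(recipient)], fids[int(donor)]
        r0, r1, r_or = _copy_span(lin, rf)
        d0, d1, d_or = _copy_span(lin, df)
        r_eff = _reading_sign(lin, r0, r1, r_or, root_features, root_feat0, rf)
        d_eff = _reading_sign(lin, d0, d1, d_or, root_features, root_feat0, df)
        seq = lin.seq[d0:d1].copy()
        anc = lin.anc[d0:d1].copy()
        strand = lin.strand[d0:d1].copy()
        if r_eff != d_eff:  # keep the recipient's reading orientation
            seq = (3 - seq)[::-1]
            anc = anc[::-1]
            strand = (-strand)[::-1]
        feat = np.full(d1 - d0, rf, dtype=np.int32)
        _splice(lin, r0, r1, seq, anc, strand, feat)
        registry.append(
            {
                "lineage": lineage_label,
                "event": ev,
                "recipient": f"rrn_{rf + 1}",
                "donor": f"rrn_{df + 1}",
            }
        )


def _apply_indels(lin: _Lineage, n_events: int, geom_p: float, rng) -> None:
    """Batched indels; event positions refer to pre-event coordinates."""
    if n_events <= 0 or len(lin) == 0:
        return
    L = len(lin)
    pos = np.sort(rng.integers(0, L, size=n_events))
    lengths = rng.geometric(geom_p, size=n_events)
    is_del = rng.random(n_events) < 0.5

    seqs, ancs, strands, feats = [], [], [], []
    cursor = 0
    for p, ln, deln in zip(pos, lengths, is_del):
        p = int(max(p, cursor))
        if p >= L:
            break
        if deln:
            end = min(p + int(ln), L)
            seqs.append(lin.seq[cursor:p])
            ancs.append(lin.anc[cursor:p])
            strands.append(lin.strand[cursor:p])
            feats.append(lin.feat[cursor:p])
            cursor = end
        else:
            ins = int(ln)
            seqs.append(lin.seq[cursor:p])
            ancs.append(lin.anc[cursor:p])
            strands.append(lin.strand[cursor:p])
            feats.append(lin.feat[cursor:p])
            new_seq = rng.integers(0, 4, size=ins, dtype=np.uint8)
            fid = -1
            if 0 < p < L and lin.feat[p - 1] == lin.feat[p]:
                fid = int(lin.feat[p])
            seqs.append(new_seq)
            ancs.append(np.full(ins, -1, dtype=np.int64))
            strands.append(np.ones(ins, dtype=np.int8))
            feats.append(np.full(ins, fid, dtype=np.int32))
            cursor = p
    seqs.append(lin.seq[cursor:])
    ancs.append(lin.anc[cursor:])
    strands.append(lin.strand[cursor:])
    feats.append(lin.feat[cursor:])
    lin.seq = np.concatenate(seqs)
    lin.anc = np.concatenate(ancs)
    lin.strand = np.concatenate(strands)
    lin.feat = np.concatenate(feats)


def _draw_segment(L: int, length_range: Tuple[int, int], rng) -> Optional[Tuple[int, int]]:
    lo, hi = length_range
    ln = int(rng.integers(lo, hi + 1))
    ln = min(ln, max(1, L - 1))
    if L - ln <= 0:
        return None
    s = int(rng.integers(0, L - ln + 1))
    return s, s + ln


def _apply_inversions(lin: _Lineage, n_events: int, length_range, rng) -> None:
    for _ in range(n_events):
        seg = _draw_segment(len(lin), length_range, rng)
        if seg is None:
            continue
        s, e = seg
        lin.seq[s:e] = (3 - lin.seq[s:e])[::-1]
        lin.anc[s:e] = lin.anc[s:e][::-1]
        lin.strand[s:e] = (-lin.strand[s:e])[::-1]
        lin.feat[s:e] = lin.feat[s:e][::-1]


def _apply_translocations(lin: _Lineage, n_events: int, length_range, rng) -> None:
    for _ in range(n_events):
        seg = _draw_segment(len(lin), length_range, rng)
        if seg is None:
            continue
        s, e = seg
        piece = (
            lin.seq[s:e].copy(),
            lin.anc[s:e].copy(),
            lin.strand[s:e].copy(),
            lin.feat[s:e].copy(),
        )
        _splice(
            lin,
            s,
            e,
            np.zeros(0, dtype=np.uint8),
            np.zeros(0, dtype=np.int64),
            np.zeros(0, dtype=np.int8),
            np.zeros(0, dtype=np.int32),
        )
        target = int(rng.integers(0, len(lin) + 1))
        _splice(lin, target, target, *piece)


def _evolve_branch(
    lin: _Lineage,
    t: float,
    cfg: SimulationConfig,
    n_copies: int,
    rng,
    registry,
    label: str,
    root_features: Sequence[Feature],
    root_feat0: "np.ndarray",
) -> None:
    _apply_substitutions(
        lin,
        cfg.subs_per_site * t,
        cfg.subs_per_site * cfg.rrna_rate_scale * t,
        n_copies,
        rng,
    )
    if cfg.conversion_rate > 0:
        k = int(rng.poisson(cfg.conversion_rate * n_copies * t))
        _apply_conversion(
            lin, n_copies, k, rng, registry, label, root_features, root_feat0
        )
    if cfg.indel_rate > 0:
        k = int(rng.poisson(cfg.indel_rate * len(lin) * t))
        _apply_indels(lin, k, cfg.indel_length_geom_p, rng)
    if cfg.inversion_rate > 0:
        k = int(rng.poisson(cfg.inversion_rate * t))
        _apply_inversions(lin, k, cfg.rearrangement_length_range, rng)
    if cfg.translocation_rate > 0:
        k = int(rng.poisson(cfg.translocation_rate * t))
        _apply_translocations(lin, k, cfg.rearrangement_length_range, rng)
    if cfg.hgt_rate > 0:
        # modelled as acquisition of foreign (de novo) material
        k = int(rng.poisson(cfg.hgt_rate * t))
        for _ in range(k):
            seg = _draw_segment(len(lin), cfg.rearrangement_length_range, rng)
            if seg is None:
                continue
            s, e = seg
            ins = int(rng.integers(0, len(lin) + 1))
            n = e - s
            _splice(
                lin,
                ins,
                ins,
                rng.integers(0, 4, size=n, dtype=np.uint8),
                np.full(n, -1, dtype=np.int64),
                np.ones(n, dtype=np.int8),
                np.full(n, -1, dtype=np.int32),
            )


# -------------------------------------------------------------- leaf export


def _leaf_features(
    lin: _Lineage,
    root_features: Sequence[Feature],
    root_feat0: np.ndarray,
    min_len: int = 10,
) -> List[Feature]:
    """Reconstruct the leaf feature table from per-site feature ids.

    A feature rearranged into several pieces keeps only its longest run.
    The reported strand is the material's reading orientation: the strand
    of the root feature it descends from (conversion may have swapped
    paralog content) combined with the site orientation.
    """
    feat = lin.feat
    if len(feat) == 0:
        return []
    breaks = np.flatnonzero(np.diff(feat)) + 1
    starts = np.concatenate([[0], breaks])
    ends = np.concatenate([breaks, [len(feat)]])
    best: Dict[int, Tuple[int, int]] = {}
    for s, e in zip(starts, ends):
        fid = int(feat[s])
        if fid < 0 or e - s < min_len:
            continue
        if fid not in best or (e - s) > (best[fid][1] - best[fid][0]):
            best[fid] = (int(s), int(e))
    out: List[Feature] = []
    for fid in sorted(best, key=lambda f: best[f][0]):
        s, e = best[fid]
        root_feat = root_features[fid]
        orient = 1 if int(lin.strand[s:e].sum()) >= 0 else -1
        sign = _reading_sign(lin, s, e, orient, root_features, root_feat0, fid)
        out.append(
            Feature(
                name=root_feat.name,
                start=s,
                end=e,
                strand="+" if sign > 0 else "-",
                type=root_feat.type,
            )
        )
    return out


def _truth_intervals(lin: _Lineage) -> List[TruthInterval]:
    anc, strand = lin.anc, lin.strand
    L = len(anc)
    if L == 0:
        return []
    cont = np.zeros(L - 1, dtype=bool)
    both_anc = (anc[:-1] >= 0) & (anc[1:] >= 0)
    same_strand = strand[:-1] == strand[1:]
    step_ok = anc[1:] == anc[:-1] + strand[:-1]
    cont |= both_anc & same_strand & step_ok
    cont |= (anc[:-1] < 0) & (anc[1:] < 0)
    breaks = np.flatnonzero(~cont) + 1
    starts = np.concatenate([[0], breaks])
    ends = np.concatenate([breaks, [L]])
    out: List[TruthInterval] = []
    for s, e in zip(starts, ends):
        if anc[s] < 0:
            out.append(TruthInterval(int(s), int(e), -1, -1, "+"))
        elif strand[s] > 0:
            out.append(
                TruthInterval(int(s), int(e), int(anc[s]), int(anc[e - 1]) + 1, "+")
            )
        else:
            out.append(
                TruthInterval(int(s), int(e), int(anc[e - 1]), int(anc[s]) + 1, "-")
            )
    return out


def evolve_genomes(config: SimulationConfig) -> SimulatedDataset:
    """Simulate one dataset under ``config``; fully seeded and deterministic."""
    tree = sample_yule_tree(config.n_taxa, config.birth_rate, config.tree_seed)
    scaled = _scaled_to_unit_depth(tree)
    rng = np.random.default_rng(config.mutation_seed)
    root_lineage, root_features, n_copies = _build_root(config, rng)
    root_feat0 = root_lineage.feat.copy()  # root-coordinate feature lookup
    registry: List[Dict[str, object]] = []

    genomes: List[Genome] = []
    truth_maps: Dict[str, List[TruthInterval]] = {}
    ancestries: Dict[str, np.ndarray] = {}
    strands: Dict[str, np.ndarray] = {}

    internal_counter = [0]

    def descend(node: dendropy.Node, state: _Lineage) -> None:
        children = node.child_nodes()
        for i, child in enumerate(children):
            # reuse the parent's arrays for the last child, copy otherwise
            lin = state.copy() if i < len(children) - 1 else state
            if child.is_leaf():
                label = child.taxon.label
            else:
                internal_counter[0] += 1
                label = f"internal_{internal_counter[0]}"
            _evolve_branch(
                lin,
                child.edge.length,
                config,
                n_copies,
                rng,
                registry,
                label,
                root_features,
                root_feat0,
            )
            if child.is_leaf():
                taxon = child.taxon.label
                genomes.append(
                    Genome(
                        taxon_id=taxon,
                        sequence=decode(lin.seq),
                        circular=True,
                        features=_leaf_features(lin, root_features, root_feat0),
                    )
                )
                truth_maps[taxon] = _truth_intervals(lin)
                ancestries[taxon] = lin.anc
                strands[taxon] = lin.strand
            else:
                descend(child, lin)

    descend(scaled.seed_node, root_lineage)
    genomes.sort(key=lambda g: g.taxon_id)
    return SimulatedDataset(
        genomes=genomes,
        true_tree=tree,
        truth_maps=truth_maps,
        copy_registry=registry,
        config=config,
        ancestries=ancestries,
        strands=strands,
        root_features=list(root_features),
    )


# ----------------------------------------------------- string-level op


def apply_gene_conversion(
    genome: Genome, family: str, n_events: int, seed: int
) -> Genome:
    """Within-genome gene conversion on an annotated genome.

    Each event overwrites one randomly chosen copy of ``family`` (features
    whose type or name-prefix matches) with the sequence of another copy
    from the same genome, keeping the recipient's strand.  Returns a new
    genome; copy count is unchanged.
    """
    idx = [
        i
        for i, f in enumerate(genome.features)
        if f.type == family or f.name.startswith(family)
    ]
    if len(idx) < 2:
        raise ValueError(f"family {family!r} has fewer than 2 copies")
    rng = np.random.default_rng(seed)
    seq = genome.sequence
    features = list(genome.features)
    for _ in range(n_events):
        r, d = rng.choice(len(idx), size=2, replace=False)
        i_rec, i_don = idx[int(r)], idx[int(d)]
        rec, don = features[i_rec], features[i_don]
        donor_seq = seq[don.start : don.end]
        if don.strand != rec.strand:
            donor_seq = revcomp(donor_seq)
        delta = len(donor_seq) - rec.length
        seq = seq[: rec.start] + donor_seq + seq[rec.end :]
        for i, f in enumerate(features):
            if i == i_rec:
                features[i] = Feature(
                    f.name, f.start, f.start + len(donor_seq), f.strand, f.type
                )
            elif f.start >= rec.end and delta != 0:
                features[i] = Feature(
                    f.name, f.start + delta, f.end + delta, f.strand, f.type
                )
    return Genome(
        taxon_id=genome.taxon_id,
        sequence=seq,
        circular=genome.circular,
        features=features,
    )


# ------------------------------------------------------------------ output


def write_dataset(dataset: SimulatedDataset, outdir: str) -> None:
    """Write FASTA + GFF3 per genome, the true tree, and truth TSVs."""
    import os

    from . import io as lio

    os.makedirs(outdir, exist_ok=True)
    for g in dataset.genomes:
        lio.write_fasta_genome(g, os.path.join(outdir, f"{g.taxon_id}.fasta"))
        lio.write_gff3(g.features, g.taxon_id, os.path.join(outdir, f"{g.taxon_id}.gff3"))
    lio.write_newick(dataset.true_tree, os.path.join(outdir, "true_tree.nwk"))
    with open(os.path.join(outdir, "truth_map.tsv"), "w") as fh:
        fh.write("taxon\tleaf_start\tleaf_end\troot_start\troot_end\torient\n")
        for taxon in sorted(dataset.truth_maps):
            for iv in dataset.truth_maps[taxon]:
                fh.write(
                    f"{taxon}\t{iv.leaf_start + 1}\t{iv.leaf_end}\t"
                    f"{iv.root_start + 1 if iv.root_start >= 0 else 0}\t"
                    f"{iv.root_end if iv.root_end >= 0 else 0}\t{iv.orient}\n"
                )
    with open(os.path.join(outdir, "copy_registry.tsv"), "w") as fh:
        fh.write("lineage\tevent\trecipient\tdonor\n")
        for row in dataset.copy_registry:
            fh.write(f"{row['lineage']}\t{row['event']}\t{row['recipient']}\t{row['donor']}\n")
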