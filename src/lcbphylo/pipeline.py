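"""End-to-end orchestration: simulate/load -> LCBs -> trees -> reports.

One ``RunConfig`` drives every stage; a single global seed deterministically
derives per-stage seeds, so identical configs reproduce byte-identical
outputs.  When the input is simulated, the run is scored against ground
truth: Robinson-Foulds distance of the inferred genome tree to the true
tree and site-level precision/recall of the LCB homology statements.
"""

from __future__ import annotations

import json
import logging
import os
import zlib
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import dendropy
import numpy as np

from . import io as lio
from .annotation_projection import project_annotations, write_tracks_tsv
from .copy_tracker import (
    align_copies,
    assign_copies_to_lcbs,
    classify_species_copy_topology,
    concerted_index,
    extract_copies,
    find_identical_copies,
    test_positional_orthology,
)
from .core import ConcatenatedAlignment, GapMode, Genome, LCB
from .genome_sim import SimulatedDataset, SimulationConfig, evolve_genomes, write_dataset
from .lcb_detection import (
    DEFAULT_K,
    DEFAULT_MAX_GAP,
    DEFAULT_MIN_CHAIN_BP,
    chain_anchors,
    coverage_stats,
    detect_lcbs,
    find_anchors,
    partition_lcbs,
)
from .msa_concat import align_all, alignment_summary, concatenate, subsample_columns
from .phylo import (
    concordance_counts,
    fitch_score,
    indel_step_decomposition,
    nj_tree,
    robinson_foulds,
    search_mp,
    unique_topologies,
)

logger = logging.getLogger("lcbphylo")

__all__ = ["RunConfig", "run_pipeline", "compare_to_truth", "lcb_precision_recall"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run (exactly one input mode)."""

    out_dir: str
    seed: int = 0
    sim: Optional[SimulationConfig] = None
    genomes_dir: Optional[str] = None
    # detector
    kmer_length: int = DEFAULT_K
    max_gap: int = DEFAULT_MAX_GAP
    min_chain_bp: int = DEFAULT_MIN_CHAIN_BP
    min_subset_bp: int = 100
    # aligner
    band: int = 128
    # tree search
    mp_starts: int = 2
    ratchet_iters: int = 2
    nj_model: str = "JC69"
    # support
    subsample_sizes: Tuple[int, ...] = (20_000,)
    # copy tracking
    copy_family: str = "rRNA"
    copy_tree_max_mp_leaves: int = 32

    def __post_init__(self) -> None:
        if (self.sim is None) == (self.genomes_dir is None):
            raise ValueError("exactly one of sim / genomes_dir must be set")


def _stage_seed(seed: int, stage: str) -> int:
    return (seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


def run_pipeline(config: RunConfig) -> Dict[str, object]:
    """Run every stage and return (and write) the summary report."""
    os.makedirs(config.out_dir, exist_ok=True)
    with open(os.path.join(config.out_dir, "run_config.json"), "w") as fh:
        json.dump(asdict(config), fh, indent=2, default=str)
    report: Dict[str, object] = {}

    # ----- input stage
    dataset: Optional[SimulatedDataset] = None
    if config.sim is not None:
        logger.info("simulating dataset (%d taxa)", config.sim.n_taxa)
        dataset = evolve_genomes(config.sim)
        genomes = dataset.genomes
        truth_dir = os.path.join(config.out_dir, "truth")
        write_dataset(dataset, truth_dir)
    else:
        logger.info("loading genomes from %s", config.genomes_dir)
        genomes = lio.read_genome_dir(config.genomes_dir)
    taxa = sorted(g.taxon_id for g in genomes)
    report["n_taxa"] = len(taxa)

    # ----- LCB detection
    logger.info("detecting LCBs")
    lcbs = detect_lcbs(genomes, config.kmer_length, config.max_gap, config.min_chain_bp)
    full, subset = partition_lcbs(lcbs, frozenset(taxa), config.min_subset_bp)
    report["n_lcbs_all_taxa"] = len(full)
    report["n_lcbs_subset"] = len(subset)
    cov = coverage_stats(full, genomes)
    cov.to_csv(os.path.join(config.out_dir, "coverage_all_taxa.tsv"), sep="\t", index=False)
    cov_sub = coverage_stats(full + subset, genomes)
    cov_sub.to_csv(os.path.join(config.out_dir, "coverage_with_subset.tsv"), sep="\t", index=False)

    if not full:
        raise RuntimeError("stage lcb_detection: no all-taxa LCBs found")

    # ----- alignment + concatenation
    logger.info("aligning %d all-taxa LCBs", len(full))
    full = align_all(full, genomes, band=config.band)
    lio.write_xmfa(full, os.path.join(config.out_dir, "lcbs_all_taxa.xmfa"))
    aln = concatenate(full, taxa)
    lio.write_phylip(aln, os.path.join(config.out_dir, "concatenated.phy"))
    lio.write_partitions(aln, os.path.join(config.out_dir, "partitions.txt"))
    report["concatenated_columns"] = aln.n_columns
    report["alignment_summary"] = alignment_summary(aln, GapMode.FIFTH_STATE)

    # ----- genome trees
    logger.info("tree inference")
    mp_fifth = search_mp(
        aln,
        GapMode.FIFTH_STATE,
        n_starts=config.mp_starts,
        ratchet_iters=config.ratchet_iters,
        seed=_stage_seed(config.seed, "mp_fifth"),
    )
    genome_tree = mp_fifth[0]
    report["mp_trees_fifth"] = len(mp_fifth)
    report["score_fifth"] = fitch_score(genome_tree, aln, GapMode.FIFTH_STATE)
    lio.write_newick(genome_tree, os.path.join(config.out_dir, "genome_tree_fifth.nwk"))

    mp_missing = search_mp(
        aln,
        GapMode.MISSING,
        n_starts=config.mp_starts,
        ratchet_iters=config.ratchet_iters,
        seed=_stage_seed(config.seed, "mp_missing"),
    )
    report["score_missing"] = fitch_score(mp_missing[0], aln, GapMode.MISSING)
    lio.write_newick(mp_missing[0], os.path.join(config.out_dir, "genome_tree_missing.nwk"))

    nj = nj_tree(aln, config.nj_model)
    lio.write_newick(nj, os.path.join(config.out_dir, "nj_tree.nwk"))
    report["nj_matches_mp"] = robinson_foulds(nj, genome_tree) == 0

    # ----- per-LCB trees and concordance
    logger.info("per-LCB trees")
    lcb_trees: List[dendropy.Tree] = []
    for block in full:
        block_aln = concatenate([block], taxa)
        trees = search_mp(
            block_aln,
            GapMode.FIFTH_STATE,
            n_starts=1,
            ratchet_iters=0,
            seed=_stage_seed(config.seed, f"lcb_tree_{block.lcb_id}"),
        )
        lcb_trees.append(trees[0])
    report["n_lcb_trees"] = len(lcb_trees)
    report["lcb_unique_topologies"] = unique_topologies(lcb_trees)
    report["lcb_trees_matching_genome_tree"] = sum(
        1 for t in lcb_trees if robinson_foulds(t, genome_tree) == 0
    )
    annotated = concordance_counts(genome_tree, lcb_trees)
    lio.write_newick(annotated, os.path.join(config.out_dir, "genome_tree_concordance.nwk"))

    # ----- jackknife subsets
    jack: Dict[str, object] = {}
    for size in config.subsample_sizes:
        n = min(size, aln.n_columns)
        sub = subsample_columns(
            aln, n, seed=_stage_seed(config.seed, f"jack_{size}"), with_replacement=False
        )
        sub_tree = search_mp(
            sub,
            GapMode.FIFTH_STATE,
            n_starts=1,
            ratchet_iters=1,
            seed=_stage_seed(config.seed, f"jack_tree_{size}"),
        )[0]
        jack[str(size)] = {
            "columns": n,
            "matches_genome_tree": robinson_foulds(sub_tree, genome_tree) == 0,
        }
    report["jackknife"] = jack

    # ----- indel decomposition
    report["indel_decomposition"] = indel_step_decomposition(genome_tree, aln)

    # ----- annotation projection (first aligned block as the showcase track)
    if any(g.features for g in genomes):
        tracks = project_annotations(full[0], genomes)
        write_tracks_tsv(tracks, os.path.join(config.out_dir, "tracks_lcb0.tsv"))

    # ----- copy tracking
    copy_report: Dict[str, object] = {}
    try:
        copies = extract_copies(genomes, config.copy_family)
    except KeyError:
        copies = []
    if copies and sum(1 for c in copies) >= 4:
        grid = assign_copies_to_lcbs(copies, lcbs)
        copy_report["n_copies"] = len(copies)
        copy_report["n_grid_rows"] = grid.n_rows
        orth = test_positional_orthology(grid, frozenset(taxa))
        copy_report["positional_orthology"] = orth["positional_orthology"]
        copy_report["identical_groups"] = [
            g for g in find_identical_copies(copies) if g["size"] > 1
        ]
        copy_aln = align_copies(copies, band=config.band)
        if len(copies) <= config.copy_tree_max_mp_leaves:
            copy_tree = search_mp(
                copy_aln,
                GapMode.FIFTH_STATE,
                n_starts=1,
                ratchet_iters=1,
                seed=_stage_seed(config.seed, "copy_tree"),
            )[0]
            copy_report["copy_tree_method"] = "mp_fifth"
        else:
            copy_tree = nj_tree(copy_aln, "JC69")
            copy_report["copy_tree_method"] = "nj_jc69"
        lio.write_newick(copy_tree, os.path.join(config.out_dir, "copy_tree.nwk"))
        labels = {c.label: c.taxon_id for c in copies}
        classes = classify_species_copy_topology(copy_tree, labels)
        multi = {t for t in taxa if sum(1 for c in copies if c.taxon_id == t) > 1}
        copy_report["classes"] = classes
        if multi:
            copy_report["concerted_index"] = concerted_index(classes, multi)
    report["copy_tracking"] = copy_report

    # ----- truth comparison
    if dataset is not None:
        report["truth"] = compare_to_truth_objects(dataset, full, genome_tree)

    with open(os.path.join(config.out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report


# ------------------------------------------------------------ truth scoring


def lcb_precision_recall(
    lcbs: Sequence[LCB],
    ancestries: Dict[str, np.ndarray],
) -> Tuple[float, float]:
    """Site-level precision/recall of LCB homology statements.

    An aligned column of an LCB asserts homology between the genome
    positions it pairs; the assertion is true when both sites descend from
    the same root coordinate.  Recall counts, per genome pair, the root
    coordinates present in both genomes that some LCB column recovers.
    Micro-averaged over all genome pairs.
    """
    taxa = sorted(ancestries)
    n_true_pairs = 0
    n_asserted = 0
    n_correct = 0
    recovered: Dict[Tuple[str, str], set] = {}
    for i, ti in enumerate(taxa):
        for tj in taxa[i + 1 :]:
            a_i = ancestries[ti]
            a_j = ancestries[tj]
            shared = np.intersect1d(a_i[a_i >= 0], a_j[a_j >= 0])
            n_true_pairs += shared.size
            recovered[(ti, tj)] = set()
    for lcb in lcbs:
        if lcb.rows is None:
            continue
        cols_pos: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
        width = lcb.alignment_length
        for t, seg in lcb.segments.items():
            if t not in ancestries:
                continue
            row = np.frombuffer(lcb.rows[t].encode(), dtype=np.uint8)
            nz = np.flatnonzero(row != ord("-"))
            if seg.strand == "+":
                pos = seg.start + np.arange(nz.size)
            else:
                pos = seg.end - 1 - np.arange(nz.size)
            colmap = np.full(width, -1, dtype=np.int64)
            colmap[nz] = pos
            cols_pos[t] = colmap
        ts = sorted(cols_pos)
        for x, ti in enumerate(ts):
            for tj in ts[x + 1 :]:
                ci, cj = cols_pos[ti], cols_pos[tj]
                both = (ci >= 0) & (cj >= 0)
                pi, pj = ci[both], cj[both]
                ri = ancestries[ti][pi]
                rj = ancestries[tj][pj]
                good = (ri >= 0) & (ri == rj)
                n_asserted += pi.size
                n_correct += int(good.sum())
                recovered[(ti, tj)].update(ri[good].tolist())
    n_recovered = sum(len(s) for s in recovered.values())
    precision = n_correct / n_asserted if n_asserted else 0.0
    recall = n_recovered / n_true_pairs if n_true_pairs else 0.0
    return precision, recall


def compare_to_truth_objects(
    dataset: SimulatedDataset,
    aligned_lcbs: Sequence[LCB],
    genome_tree: dendropy.Tree,
) -> Dict[str, float]:
    rf = robinson_foulds(genome_tree, dataset.true_tree)
    precision, recall = lcb_precision_recall(aligned_lcbs, dataset.ancestries)
    return {
        "rf_to_true_tree": rf,
        "lcb_precision": precision,
        "lcb_recall": recall,
    }


def compare_to_truth(report_dir: str, truth_dir: str) -> Dict[str, float]:
    """Score retained pipeline outputs against a written truth directory."""
    tree_path = os.path.join(report_dir, "genome_tree_fifth.nwk")
    xmfa_path = os.path.join(report_dir, "lcbs_all_taxa.xmfa")
    true_tree_path = os.path.join(truth_dir, "true_tree.nwk")
    map_path = os.path.join(truth_dir, "truth_map.tsv")
    for p in (tree_path, xmfa_path, true_tree_path, map_path):
        if not os.path.exists(p):
            raise FileNotFoundError(p)
    genome_tree = lio.read_newick(tree_path)
    true_tree = lio.read_newick(true_tree_path)
    lcbs = lio.read_xmfa(xmfa_path)

    # rebuild per-site ancestry arrays from the interval truth map
    spans: Dict[str, List[Tuple[int, int, int, int, str]]] = {}
    with open(map_path) as fh:
        header = fh.readline()
        for line in fh:
            taxon, ls, le, rs, re_, orient = line.rstrip("\n").split("\t")
            spans.setdefault(taxon, []).append(
                (int(ls) - 1, int(le), int(rs) - 1, int(re_), orient)
            )
    ancestries: Dict[str, np.ndarray] = {}
    for taxon, ivs in spans.items():
        L = max(le for _, le, _, _, _ in ivs)
        anc = np.full(L, -1, dtype=np.int64)
        for ls, le, rs, re_, orient in ivs:
            if rs < 0:
                continue
            if orient == "+":
                anc[ls:le] = np.arange(rs, re_)
            else:
                anc[ls:le] = np.arange(re_ - 1, rs - 1, -1)
        ancestries[taxon] = anc

    precision, recall = lcb_precision_recall(lcbs, ancestries)
    return {
        "rf_to_true_tree": robinson_foulds(genome_tree, true_tree),
        "lcb_precision": precision,
        "lcb_recall": recall,
    }
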