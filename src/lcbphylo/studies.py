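"""Canonical simulation study designs used for method validation.

Each function returns the configuration of one seeded replicate of a named
study; the studies themselves (problem sizes, rates, what is measured) are
described in the package documentation.  Keeping them here, rather than in
the test suite, makes every validation run reproducible from the library
alone.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np

from .core import GapMode
from .genome_sim import SimulationConfig, evolve_genomes
from .lcb_detection import detect_lcbs
from .msa_concat import align_all, concatenate, subsample_columns
from .lcb_detection import partition_lcbs
from .phylo import robinson_foulds, search_mp

__all__ = [
    "parameter_recovery_config",
    "concerted_evolution_config",
    "detector_contract_config",
    "run_parameter_recovery_replicate",
    "run_concerted_replicate",
]


def parameter_recovery_config(seed: int) -> SimulationConfig:
    """One replicate of the genome-tree parameter-recovery study.

    Twelve taxa, ~300 kb genomes, rearrangement dense enough that the
    genome fragments into on the order of 10^2 collinear blocks — the same
    block-count scale as a real many-genome analysis, so that each block
    alone carries weak signal while the concatenation carries strong
    signal.  Root-to-tip divergence sits at 0.05 substitutions/site — high
    enough that even short internal branches leave a substitution
    footprint, low enough that exact-k-mer anchoring still finds 15-mers
    conserved across every taxon (deep trees provide none at much higher
    divergence).  The rRNA
    family is scaled to 2 copies so the repeat family keeps roughly its
    real-genome share of sequence (~1%) at this reduced genome size.
    """
    return SimulationConfig(
        n_taxa=12,
        genome_length=300_000,
        tree_seed=seed,
        mutation_seed=seed + 1000,
        subs_per_site=0.05,
        indel_rate=0.004,
        indel_length_geom_p=0.3,
        inversion_rate=2.5,
        translocation_rate=1.5,
        rearrangement_length_range=(500, 4_000),
        n_rrna_copies=2,
        rrna_length=1_500,
        # conversion off here: a converted multi-copy family's non-treelike
        # signal is ~10x over-weighted at this reduced genome size and is
        # the subject of the dedicated concerted-evolution study instead
        conversion_rate=0.0,
        gene_density=0.8,
        mean_gene_length=900,
    )


def concerted_evolution_config(
    seed: int, conversion_rate: float, paralog_divergence: Optional[float] = None
) -> SimulationConfig:
    """One replicate of the concerted-evolution contrast.

    Six taxa with a 3-copy rRNA family.  Each arm starts from the
    stationary state of its own regime: under gene conversion the root
    copies are identical (concerted evolution has always operated); with
    conversion off the root copies carry 20% pairwise paralog divergence.
    The conversion arm must homogenise much faster than speciation —
    within-family polymorphism surviving a short internode sorts
    independently into the daughter species exactly like allelic
    incomplete lineage sorting, scattering copies across species — so the
    "high" regime is 100 events/copy/unit branch, well above the inverse
    of the shortest Yule internodes.  The rRNA clock runs at half the
    background rate here (species-level 16S divergence at this compressed
    tree depth), so every species has diagnostic copy variants.
    """
    if paralog_divergence is None:
        paralog_divergence = 0.0 if conversion_rate > 0 else 0.2
    return SimulationConfig(
        n_taxa=6,
        genome_length=50_000,
        tree_seed=seed,
        mutation_seed=seed + 5000,
        subs_per_site=0.08,
        indel_rate=0.001,
        inversion_rate=0.3,
        translocation_rate=0.3,
        rearrangement_length_range=(500, 4_000),
        n_rrna_copies=3,
        rrna_length=1_500,
        rrna_rate_scale=0.5,
        rrna_paralog_divergence=paralog_divergence,
        conversion_rate=conversion_rate,
        gene_density=0.7,
        mean_gene_length=700,
    )


def detector_contract_config(seed: int) -> SimulationConfig:
    """One replicate of the detector precision/recall study.

    Eight taxa, 100 kb, low rearrangement rates (about one event per branch
    in total), where block homology statements can be scored base-by-base
    against the simulator's ancestry map.
    """
    return SimulationConfig(
        n_taxa=8,
        genome_length=100_000,
        tree_seed=seed,
        mutation_seed=seed + 9000,
        subs_per_site=0.03,
        indel_rate=0.002,
        inversion_rate=0.5,
        translocation_rate=0.5,
        rearrangement_length_range=(500, 10_000),
        n_rrna_copies=2,
        rrna_length=1_200,
        conversion_rate=1.0,
        gene_density=0.8,
        mean_gene_length=900,
    )


def run_parameter_recovery_replicate(seed: int, band: int = 64) -> Dict[str, object]:
    """Simulate, detect, align, and infer for one parameter-recovery seed.

    Returns the Robinson-Foulds distance of the concatenated-alignment
    parsimony tree to the true tree, per-LCB tree agreement, and whether a
    20,000-column jackknife recovers the genome topology (the topology
    counts as recovered when it is among the returned equally most
    parsimonious trees).
    """
    cfg = parameter_recovery_config(seed)
    ds = evolve_genomes(cfg)
    lcbs = detect_lcbs(ds.genomes)
    taxa = sorted(g.taxon_id for g in ds.genomes)
    full, _subset = partition_lcbs(lcbs, frozenset(taxa))
    full = align_all(full, ds.genomes, band=band)
    aln = concatenate(full, taxa)
    mp_trees = search_mp(aln, GapMode.FIFTH_STATE, n_starts=2, ratchet_iters=2, seed=seed)
    mp = mp_trees[0]
    rf_truth = min(robinson_foulds(t, ds.true_tree) for t in mp_trees)

    # all equally-most-parsimonious trees of every block, compared per tree
    n_block_trees = 0
    n_differing = 0
    for block in full:
        block_aln = concatenate([block], taxa)
        bts = search_mp(block_aln, GapMode.FIFTH_STATE, n_starts=1, ratchet_iters=0, seed=seed)
        n_block_trees += len(bts)
        n_differing += sum(1 for t in bts if robinson_foulds(t, mp) != 0)

    sub = subsample_columns(aln, min(20_000, aln.n_columns), seed=seed + 7)
    sub_trees = search_mp(sub, GapMode.FIFTH_STATE, n_starts=2, ratchet_iters=1, seed=seed)
    jackknife_ok = any(robinson_foulds(t, mp) == 0 for t in sub_trees)

    return {
        "rf_to_truth": rf_truth,
        "n_lcbs": len(full),
        "n_block_trees": n_block_trees,
        "n_block_trees_differing": n_differing,
        "jackknife_recovers": jackknife_ok,
        "columns": aln.n_columns,
        "dataset": ds,
        "aligned_lcbs": full,
    }


def run_concerted_replicate(seed: int, conversion_rate: float) -> float:
    """Concerted-evolution index of one replicate's all-copies MP tree."""
    from .copy_tracker import (
        align_copies,
        classify_species_copy_topology,
        concerted_index,
        extract_copies,
    )

    cfg = concerted_evolution_config(seed, conversion_rate)
    ds = evolve_genomes(cfg)
    copies = extract_copies(ds.genomes, "rRNA")
    aln = align_copies(copies)
    tree = search_mp(aln, GapMode.FIFTH_STATE, n_starts=1, ratchet_iters=1, seed=seed)[0]
    classes = classify_species_copy_topology(
        tree, {c.label: c.taxon_id for c in copies}
    )
    taxa = {g.taxon_id for g in ds.genomes}
    multi = {t for t in taxa if sum(1 for c in copies if c.taxon_id == t) > 1}
    return concerted_index(classes, multi)
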