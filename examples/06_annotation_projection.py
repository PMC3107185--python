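"""Project gene annotations onto an LCB alignment.

Maps each genome's features through its gapped alignment row into column
space, so gene boundaries can be compared across taxa, and tallies how
much of each genome's blocks is non-coding.
"""

from lcbphylo import (
    SimulationConfig,
    align_all,
    detect_lcbs,
    evolve_genomes,
    genes_per_lcb,
    noncoding_fraction,
    partition_lcbs,
    project_annotations,
)

dataset = evolve_genomes(
    SimulationConfig(
        n_taxa=6, genome_length=60_000, tree_seed=7, mutation_seed=8,
        subs_per_site=0.05, indel_rate=0.002, inversion_rate=1.0,
        translocation_rate=0.5, rearrangement_length_range=(500, 5_000),
        n_rrna_copies=(3, 4), rrna_length=800, conversion_rate=1.0,
        gene_density=0.75,
    )
)
taxa = frozenset(g.taxon_id for g in dataset.genomes)
full, _ = partition_lcbs(detect_lcbs(dataset.genomes), taxa)
full = align_all(full, dataset.genomes)

block = full[0]
tracks = project_annotations(block, dataset.genomes)
print(f"LCB {block.lcb_id}: {block.alignment_length:,} aligned columns")
for track in tracks[:2]:
    genes = [iv for iv in track.intervals if iv.kind != "noncoding"]
    print(f"  {track.taxon_id}: {len(genes)} features projected, first: "
          + ", ".join(f"{iv.name}[{iv.col_start}-{iv.col_end})" for iv in genes[:3]))

taxon = sorted(taxa)[0]
stats = genes_per_lcb(full, dataset.genomes, taxon)
frac = noncoding_fraction(full, dataset.genomes, taxon)
print(f"{taxon}: genes per LCB min {stats['min']} max {stats['max']} "
      f"mean {stats['mean']}")
print(f"{taxon}: {frac['noncoding_bp']:,} of {frac['total_bp']:,} bp in blocks "
      f"are non-coding ({frac['pct_noncoding']}%)")
# Matching feature names at matching columns across taxa is the projected
# (annotation-based) hypothesis of homology, to compare with the
# alignment-based one.
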