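"""Simulate a small bacterial genome dataset with known evolutionary truth.

Builds six ~60 kb genomes down a Yule tree with substitutions, indels,
inversions, translocations and a concertedly evolving multi-copy rRNA
family, then prints what the simulator knows to be true about the data.
"""

from lcbphylo import SimulationConfig, evolve_genomes

config = SimulationConfig(
    n_taxa=6,
    genome_length=60_000,
    tree_seed=7,
    mutation_seed=8,
    subs_per_site=0.05,     # expected substitutions/site, root to tip
    indel_rate=0.002,       # indel events per site per unit branch
    inversion_rate=1.0,     # genome-scale events per unit branch
    translocation_rate=0.5,
    rearrangement_length_range=(500, 5_000),
    n_rrna_copies=(3, 4),
    rrna_length=800,
    conversion_rate=1.0,    # gene-conversion events per copy per unit branch
    gene_density=0.75,
)
dataset = evolve_genomes(config)

print("true tree:", dataset.true_tree.as_string(schema="newick").strip())
for genome in dataset.genomes:
    n_rrna = sum(1 for f in genome.features if f.type == "rRNA")
    n_gene = sum(1 for f in genome.features if f.type == "gene")
    de_novo = sum(
        iv.leaf_end - iv.leaf_start
        for iv in dataset.truth_maps[genome.taxon_id]
        if iv.root_start < 0
    )
    print(
        f"{genome.taxon_id}: {len(genome):,} bp, {n_gene} genes, "
        f"{n_rrna} rRNA copies, {de_novo} bp inserted de novo"
    )
print(f"gene-conversion events recorded: {len(dataset.copy_registry)}")

# Each genome knows, per position, which root-genome coordinate it descends
# from; that truth map is what LCB detection is later scored against.
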