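"""Genome evolution simulator: determinism, limits, closed-form checks."""

import math

import numpy as np
import pytest

from lcbphylo.genome_sim import (
    SimulationConfig,
    apply_gene_conversion,
    evolve_genomes,
    sample_yule_tree,
)


def small_config(**kw):
    defaults = dict(
        n_taxa=4,
        genome_length=20_000,
        tree_seed=1,
        mutation_seed=2,
        subs_per_site=0.05,
        indel_rate=0.001,
        inversion_rate=0.5,
        translocation_rate=0.5,
        rearrangement_length_range=(200, 2000),
        n_rrna_copies=3,
        rrna_length=600,
        conversion_rate=0.5,
        gene_density=0.7,
        mean_gene_length=600,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestYuleTree:
    def test_two_taxa_forced_topology(self):
        tree = sample_yule_tree(2, 1.0, seed=5)
        assert len(tree.leaf_nodes()) == 2
        assert sum(1 for n in tree.preorder_node_iter() if not n.is_leaf()) == 1

    def test_22_taxa_has_21_internal_nodes(self):
        tree = sample_yule_tree(22, 1.0, seed=5)
        assert len(tree.leaf_nodes()) == 22
        assert sum(1 for n in tree.preorder_node_iter() if not n.is_leaf()) == 21

    def test_same_seed_same_newick(self):
        a = sample_yule_tree(8, 1.0, seed=3).as_string(schema="newick")
        b = sample_yule_tree(8, 1.0, seed=3).as_string(schema="newick")
        assert a == b

    def test_branch_lengths_positive_and_ultrametric(self):
        tree = sample_yule_tree(10, 2.0, seed=7)
        for e in tree.preorder_edge_iter():
            if e.head_node.parent_node is not None:
                assert e.length > 0
        depths = {round(lf.distance_from_root(), 9) for lf in tree.leaf_node_iter()}
        assert len(depths) == 1

    def test_invalid_argument(self):
        with pytest.raises(ValueError):
            sample_yule_tree(1, 1.0, seed=0)


class TestEvolveGenomes:
    def test_no_evolution_limit_gives_identical_genomes(self):
        cfg = small_config(
            subs_per_site=0.0,
            indel_rate=0.0,
            inversion_rate=0.0,
            translocation_rate=0.0,
            conversion_rate=0.0,
            rrna_paralog_divergence=0.0,
        )
        ds = evolve_genomes(cfg)
        seqs = {g.sequence for g in ds.genomes}
        assert len(seqs) == 1
        assert len(ds.genomes) == 4

    def test_determinism_byte_identical(self):
        cfg = small_config()
        d1 = evolve_genomes(cfg)
        d2 = evolve_genomes(cfg)
        for g1, g2 in zip(d1.genomes, d2.genomes):
            assert g1.sequence == g2.sequence
            assert g1.features == g2.features
        assert d1.true_tree.as_string(schema="newick") == d2.true_tree.as_string(
            schema="newick"
        )

    def test_observed_divergence_matches_jc_expectation(self):
        """Two taxa, substitutions only: the proportion of differing
        background sites must sit within 3 standard errors of the JC
        saturation curve 3/4 (1 - exp(-4 d / 3)) at the realized path
        length d (here 2 x 0.1, tips at depth 1 after scaling)."""
        cfg = small_config(
            n_taxa=2,
            genome_length=50_000,
            subs_per_site=0.1,
            indel_rate=0.0,
            inversion_rate=0.0,
            translocation_rate=0.0,
            conversion_rate=0.0,
            rrna_paralog_divergence=0.0,
        )
        ds = evolve_genomes(cfg)
        a, b = ds.genomes
        # restrict to background (non-rRNA) sites via the feature table
        rrna = [(f.start, f.end) for f in a.features if f.type == "rRNA"]
        mask = np.ones(len(a.sequence), dtype=bool)
        for s, e in rrna:
            mask[s:e] = False
        sa = np.frombuffer(a.sequence.encode(), dtype=np.uint8)[mask]
        sb = np.frombuffer(b.sequence.encode(), dtype=np.uint8)[mask]
        p_obs = float((sa != sb).mean())
        d = 0.2  # both root-to-tip paths scaled to depth 1.0
        p_exp = 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))
        se = math.sqrt(p_exp * (1 - p_exp) / mask.sum())
        assert abs(p_obs - p_exp) < 3 * se

    def test_rrna_copy_counts_in_configured_range(self):
        cfg = small_config(n_taxa=6, n_rrna_copies=(8, 11), genome_length=60_000)
        ds = evolve_genomes(cfg)
        for g in ds.genomes:
            n = sum(1 for f in g.features if f.type == "rRNA")
            assert 8 <= n <= 11

    def test_truth_map_partitions_each_genome(self):
        """Every genome position maps to exactly one ancestral interval or
        de-novo flag; interval lengths sum to the genome length."""
        ds = evolve_genomes(small_config(indel_rate=0.005))
        for g in ds.genomes:
            ivs = ds.truth_maps[g.taxon_id]
            assert ivs[0].leaf_start == 0
            assert ivs[-1].leaf_end == len(g)
            total = 0
            prev_end = 0
            for iv in ivs:
                assert iv.leaf_start == prev_end
                prev_end = iv.leaf_end
                total += iv.leaf_end - iv.leaf_start
                if iv.root_start >= 0:
                    assert iv.root_end - iv.root_start == iv.leaf_end - iv.leaf_start
            assert total == len(g)

    def test_rearrangements_recorded_with_orientation(self):
        cfg = small_config(inversion_rate=3.0, translocation_rate=2.0)
        ds = evolve_genomes(cfg)
        orients = {
            iv.orient for ivs in ds.truth_maps.values() for iv in ivs if iv.root_start >= 0
        }
        assert orients == {"+", "-"}


class TestGeneConversion:
    def _genome(self):
        cfg = small_config(
            n_taxa=2,
            conversion_rate=0.0,
            indel_rate=0.0,
            inversion_rate=0.0,
            translocation_rate=0.0,
            rrna_paralog_divergence=0.1,
            n_rrna_copies=5,
        )
        return evolve_genomes(cfg).genomes[0]

    def test_zero_events_is_identity(self):
        g = self._genome()
        out = apply_gene_conversion(g, "rRNA", n_events=0, seed=1)
        assert out.sequence == g.sequence
        assert out.features == g.features

    def test_two_copies_many_events_become_identical(self):
        g = self._genome()
        out = apply_gene_conversion(g, "rRNA", n_events=40, seed=1)
        copies = [f for f in out.features if f.type == "rRNA"]
        # with many events conversion is absorbing: all copies coalesce
        all_seqs = {out.slice(f.start, f.end, f.strand) for f in copies}
        assert len(all_seqs) == 1

    def test_conversion_increases_within_genome_identity(self):
        g = self._genome()

        def mean_identity(genome):
            copies = [
                genome.slice(f.start, f.end, f.strand)
                for f in genome.features
                if f.type == "rRNA"
            ]
            vals = []
            for i in range(len(copies)):
                for j in range(i + 1, len(copies)):
                    a, b = copies[i], copies[j]
                    n = min(len(a), len(b))
                    vals.append(sum(x == y for x, y in zip(a[:n], b[:n])) / n)
            return sum(vals) / len(vals)

        before = mean_identity(g)
        after = mean_identity(apply_gene_conversion(g, "rRNA", n_events=10, seed=2))
        assert after > before

    def test_single_copy_family_rejected(self):
        g = self._genome()
        g.features = [f for f in g.features if f.type != "rRNA"][:1]
        with pytest.raises(ValueError):
            apply_gene_conversion(g, "gene_", n_events=1, seed=0)
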