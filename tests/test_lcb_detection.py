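"""LCB detection: anchors, chaining, partitioning, coverage accounting."""

import numpy as np
import pytest

from lcbphylo.core import LCB, Feature, Genome, Segment, check_pairwise_bijection, revcomp
from lcbphylo.lcb_detection import (
    chain_anchors,
    coverage_stats,
    detect_lcbs,
    find_anchors,
    partition_lcbs,
)


def random_seq(n, seed):
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[c] for c in rng.integers(0, 4, n))


def brute_force_unique_kmers(seq: str, k: int) -> dict:
    """Independent canonical k-mer dictionary (python strings)."""
    counts = {}
    where = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        canon = min(kmer, revcomp(kmer))
        counts[canon] = counts.get(canon, 0) + 1
        where.setdefault(canon, (i, "+" if kmer <= revcomp(kmer) else "-"))
    return {km: where[km] for km, c in counts.items() if c == 1}


class TestFindAnchors:
    def test_identical_genomes_share_every_unique_kmer_forward(self):
        seq = random_seq(1000, 1)
        g1, g2 = Genome("a", seq), Genome("b", seq)
        anchors = find_anchors([g1, g2], 15)
        assert anchors
        for a in anchors:
            (t1, p1, s1), (t2, p2, s2) = sorted(a.occurrences)
            assert p1 == p2 and s1 == s2

    def test_reverse_complement_genome_flips_strand(self):
        seq = random_seq(800, 2)
        g1, g2 = Genome("a", seq), Genome("b", revcomp(seq))
        anchors = find_anchors([g1, g2], 15)
        assert anchors
        for a in anchors:
            occ = dict((t, (p, s)) for t, p, s in a.occurrences)
            assert occ["a"][1] != occ["b"][1]

    def test_matches_brute_force_on_planted_segment(self):
        """Two random genomes sharing one planted 100 bp segment: anchors
        equal the intersection of per-genome unique canonical k-mers."""
        planted = random_seq(100, 3)
        ga = random_seq(5000, 4) + planted + random_seq(5000, 5)
        gb = random_seq(5000, 6) + planted + random_seq(5000, 7)
        anchors = find_anchors([Genome("a", ga), Genome("b", gb)], 15)
        ua = brute_force_unique_kmers(ga, 15)
        ub = brute_force_unique_kmers(gb, 15)
        shared = set(ua) & set(ub)
        assert len(anchors) == len(shared)
        covered = {p for a in anchors for t, p, s in a.occurrences if t == "a"}
        planted_hits = [p for p in covered if 5000 <= p < 5100 - 14]
        assert len(planted_hits) > 50  # the planted segment is anchored

    def test_fewer_than_two_genomes_rejected(self):
        with pytest.raises(ValueError):
            find_anchors([Genome("a", random_seq(100, 0))], 15)

    def test_small_k_rejected(self):
        gs = [Genome("a", random_seq(100, 0)), Genome("b", random_seq(100, 1))]
        with pytest.raises(ValueError):
            find_anchors(gs, 7)


class TestChaining:
    def test_collinear_genomes_give_single_lcb(self):
        seq = random_seq(4000, 10)
        genomes = [Genome("a", seq), Genome("b", seq)]
        anchors = find_anchors(genomes, 15)
        lcbs = chain_anchors(anchors, genome_lengths={"a": 4000, "b": 4000})
        assert len(lcbs) == 1
        assert lcbs[0].taxa == {"a", "b"}

    def test_inversion_splits_into_two_lcbs_with_minus_strand(self):
        """Genome b inverts the middle third: two blocks, one on '-' in b."""
        left, mid, right = random_seq(3000, 11), random_seq(3000, 12), random_seq(3000, 13)
        ga = Genome("a", left + mid + right)
        gb = Genome("b", left + revcomp(mid) + right)
        lcbs = detect_lcbs([ga, gb], max_gap=500)
        strands = sorted(
            (lcb.segments["a"].strand, lcb.segments["b"].strand) for lcb in lcbs
        )
        # left+right stay collinear forward; mid maps forward in a, reverse in b
        assert ("+", "-") in strands
        assert ("+", "+") in strands
        check_pairwise_bijection(lcbs)

    def test_gap_longer_than_max_gap_splits_chain(self):
        shared1, shared2 = random_seq(500, 14), random_seq(500, 15)
        spacer_a = random_seq(3000, 16)
        spacer_b = random_seq(3000, 17)
        ga = Genome("a", shared1 + spacer_a + shared2)
        gb = Genome("b", shared1 + spacer_b + shared2)
        lcbs_split = detect_lcbs([ga, gb], max_gap=1000)
        two_taxa = [l for l in lcbs_split if l.n_taxa == 2]
        assert len(two_taxa) >= 2

    def test_segments_never_overlap_within_a_genome(self):
        rng = np.random.default_rng(20)
        base = random_seq(20_000, 21)
        genomes = [Genome("a", base)]
        # shuffle blocks of b relative to a
        blocks = [base[i : i + 4000] for i in range(0, 20_000, 4000)]
        rng.shuffle(blocks)
        genomes.append(Genome("b", "".join(blocks)))
        lcbs = detect_lcbs(genomes)
        check_pairwise_bijection(lcbs)  # raises on violation


class TestPartition:
    def _lcb(self, lcb_id, taxa, length=500):
        return LCB(
            lcb_id,
            {t: Segment(lcb_id * 10_000, lcb_id * 10_000 + length, "+") for t in taxa},
        )

    def test_mixed_taxon_counts_enumeration(self):
        """Taxon counts {22, 22, 3, 2, 1} over 22 taxa -> (2 full, 2 subset)."""
        all_taxa = frozenset(f"t{i}" for i in range(22))
        lcbs = [
            self._lcb(0, all_taxa),
            self._lcb(1, all_taxa),
            self._lcb(2, list(all_taxa)[:3]),
            self._lcb(3, list(all_taxa)[:2]),
            self._lcb(4, list(all_taxa)[:1]),  # single-taxon: dropped
        ]
        full, subset = partition_lcbs(lcbs, all_taxa, min_subset_bp=100)
        assert (len(full), len(subset)) == (2, 2)

    def test_all_full_means_empty_subset(self):
        all_taxa = frozenset(["a", "b", "c"])
        lcbs = [self._lcb(i, all_taxa) for i in range(4)]
        full, subset = partition_lcbs(lcbs, all_taxa)
        assert len(full) == 4 and subset == []

    def test_short_subset_blocks_dropped(self):
        all_taxa = frozenset(["a", "b", "c"])
        short = self._lcb(0, ["a", "b"], length=80)  # <= 100 bp
        full, subset = partition_lcbs([short], all_taxa, min_subset_bp=100)
        assert full == [] and subset == []


class TestCoverageStats:
    def test_printed_table_arithmetic(self):
        """bp covered 1,312,077 of 4,306,142 prints as 30.5%."""
        genome = Genome("amazonensis", "A" * 4_306_142)
        lcb = LCB(0, {"amazonensis": Segment(0, 1_312_077, "+"),
                      "other": Segment(0, 1_312_077, "+")})
        other = Genome("other", "A" * 2_000_000)
        df = coverage_stats([lcb], [genome, other])
        row = df[df.taxon == "amazonensis"].iloc[0]
        assert row.bp_covered == 1_312_077
        assert row.pct_of_genome == 30.5

    def test_no_lcbs_gives_zero_coverage(self):
        df = coverage_stats([], [Genome("a", "ACGT" * 100)])
        assert df.iloc[0].bp_covered == 0
        assert df.iloc[0].pct_of_genome == 0.0

    def test_full_coverage_is_100(self):
        g = Genome("a", "ACGT" * 250)
        lcb = LCB(0, {"a": Segment(0, 1000, "+"), "b": Segment(0, 1000, "+")})
        df = coverage_stats([lcb], [g, Genome("b", "ACGT" * 250)])
        assert df[df.taxon == "a"].iloc[0].pct_of_genome == 100.0

    def test_gene_overlap_counting(self):
        g = Genome(
            "a",
            "A" * 1000,
            features=[
                Feature("x", 0, 100, "+", "gene"),
                Feature("y", 450, 520, "+", "gene"),  # straddles segment start
                Feature("z", 800, 900, "+", "gene"),  # outside
            ],
        )
        lcb = LCB(0, {"a": Segment(500, 700, "+"), "b": Segment(0, 200, "+")})
        df = coverage_stats([lcb], [g, Genome("b", "A" * 1000)])
        assert df[df.taxon == "a"].iloc[0].n_genes == 1

    def test_unknown_taxon_in_lcbs_rejected(self):
        lcb = LCB(0, {"a": Segment(0, 10, "+"), "zz": Segment(0, 10, "+")})
        with pytest.raises(ValueError):
            coverage_stats([lcb], [Genome("a", "A" * 100)])
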