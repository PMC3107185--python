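"""Concatenation, column subsampling, locus extraction, summaries."""

import numpy as np
import pytest

from lcbphylo.core import LCB, Feature, GapMode, Genome, Segment
from lcbphylo.msa_concat import (
    MissingLocusError,
    alignment_summary,
    concatenate,
    extract_locus_alignment,
    progressive_align,
    subsample_columns,
)
from lcbphylo.phylo import fitch_score, search_mp

from conftest import aln_from


def make_lcb(lcb_id, rows, starts=None, strands=None):
    width0 = {t: len(r.replace("-", "")) for t, r in rows.items()}
    segments = {}
    for t, r in rows.items():
        s = (starts or {}).get(t, 0)
        segments[t] = Segment(s, s + width0[t], (strands or {}).get(t, "+"))
    return LCB(lcb_id=lcb_id, segments=segments, rows=rows)


class TestConcatenate:
    def test_single_block_is_identity(self):
        lcb = make_lcb(0, {"a": "ACGT", "b": "AC-T"})
        aln = concatenate([lcb], ["a", "b"])
        assert aln.rows == {"a": "ACGT", "b": "AC-T"}
        assert aln.partitions == [("lcb0", 0, 4)]

    def test_blocks_laid_out_in_id_order_with_partitions(self):
        b1 = make_lcb(7, {"a": "ACGTACGTACGT", "b": "ACGTACGTACGT"})
        b0 = make_lcb(2, {"a": "TTTT", "b": "TTTT"})
        aln = concatenate([b1, b0], ["a", "b"])
        assert aln.n_columns == 16
        assert aln.partitions == [("lcb2", 0, 4), ("lcb7", 4, 16)]

    def test_missing_taxon_padded_with_gaps(self):
        b0 = make_lcb(0, {"a": "ACGT", "b": "ACGT", "c": "ACGT"})
        b1 = make_lcb(1, {"a": "GGGG", "b": "GGGG"})
        aln = concatenate([b0, b1], ["a", "b", "c"])
        assert aln.rows["c"] == "ACGT----"

    def test_unaligned_block_rejected(self):
        lcb = LCB(0, {"a": Segment(0, 4, "+"), "b": Segment(0, 4, "+")})
        with pytest.raises(ValueError):
            concatenate([lcb], ["a", "b"])


class TestSubsampleColumns:
    @pytest.fixture
    def aln(self):
        rng = np.random.default_rng(0)
        return aln_from(
            {
                t: "".join("ACGT-"[c] for c in rng.integers(0, 5, 500))
                for t in ("a", "b", "c", "d", "e")
            }
        )

    def test_same_seed_same_columns(self, aln):
        s1 = subsample_columns(aln, 100, seed=3)
        s2 = subsample_columns(aln, 100, seed=3)
        assert np.array_equal(s1.source_columns, s2.source_columns)
        assert s1.rows == s2.rows

    def test_all_columns_without_replacement_preserves_score(self, aln):
        """A full-size jackknife permutes columns, so any tree's parsimony
        length is unchanged."""
        sub = subsample_columns(aln, aln.n_columns, seed=1)
        tree = search_mp(aln, GapMode.FIFTH_STATE, n_starts=1, seed=0)[0]
        assert fitch_score(tree, sub, GapMode.FIFTH_STATE) == fitch_score(
            tree, aln, GapMode.FIFTH_STATE
        )

    def test_zero_columns_gives_empty_alignment(self, aln):
        sub = subsample_columns(aln, 0, seed=1)
        assert sub.n_columns == 0

    def test_oversampling_without_replacement_rejected(self, aln):
        with pytest.raises(ValueError):
            subsample_columns(aln, aln.n_columns + 1, seed=1)

    def test_bootstrap_can_oversample(self, aln):
        sub = subsample_columns(aln, aln.n_columns + 50, seed=1, with_replacement=True)
        assert sub.n_columns == aln.n_columns + 50


class TestLocusExtraction:
    def _genomes(self):
        # two genomes sharing loci gyrB (+) and recA (-)
        g1 = Genome(
            "t1",
            "AAAA" + "ACGTACGTGG" + "CCCC" + "TTGGCCAATT" + "AAAA",
            features=[
                Feature("gyrB", 4, 14, "+", "gene"),
                Feature("recA", 18, 28, "-", "gene"),
            ],
        )
        g2 = Genome(
            "t2",
            "GG" + "ACGTACGTGG" + "AA" + "TTGGCCAATT" + "GG",
            features=[
                Feature("gyrB", 2, 12, "+", "gene"),
                Feature("recA", 14, 24, "-", "gene"),
            ],
        )
        return [g1, g2]

    def test_two_loci_two_partitions(self):
        aln = extract_locus_alignment(self._genomes(), ["gyrB", "recA"])
        assert len(aln.partitions) == 2
        assert aln.n_taxa == 2
        assert [p[0] for p in aln.partitions] == ["gyrB", "recA"]

    def test_minus_strand_locus_reverse_complemented(self):
        aln = extract_locus_alignment(self._genomes(), ["recA"])
        # revcomp of TTGGCCAATT
        assert aln.rows["t1"] == "AATTGGCCAA"

    def test_missing_locus_lists_taxa(self):
        genomes = self._genomes()
        genomes[1].features = [genomes[1].features[0]]
        with pytest.raises(MissingLocusError, match="t2"):
            extract_locus_alignment(genomes, ["gyrB", "recA"])


class TestAlignmentSummary:
    def test_identical_gap_free_rows(self):
        aln = aln_from({"a": "ACGT", "b": "ACGT", "c": "ACGT"})
        rec = alignment_summary(aln)
        assert rec["mean_pairwise_identity_pct"] == 100.0
        assert rec["parsimony_informative"] == 0

    def test_single_informative_column(self):
        aln = aln_from({"a": "A", "b": "A", "c": "T", "d": "T"})
        assert alignment_summary(aln)["parsimony_informative"] == 1

    def test_gap_column_informative_only_under_fifth_state(self):
        aln = aln_from({"a": "A", "b": "-", "c": "A", "d": "-"})
        assert alignment_summary(aln, GapMode.FIFTH_STATE)["parsimony_informative"] == 1
        assert alignment_summary(aln, GapMode.MISSING)["parsimony_informative"] == 0

    def test_identity_excludes_gap_pairs(self):
        aln = aln_from({"a": "AC-T", "b": "ACGT"})
        # compared sites: A,C,T -> identity 100%
        assert alignment_summary(aln)["mean_pairwise_identity_pct"] == 100.0


class TestProgressiveAlignLCB:
    def test_rows_reproduce_segments_including_minus_strand(self):
        #              0123456789
        g1 = Genome("t1", "AACCGGTTAA")
        # t2 carries the reverse complement of t1's [2, 8)
        g2 = Genome("t2", "TTAACCGGTT")
        lcb = LCB(
            0,
            {
                "t1": Segment(2, 8, "+"),
                "t2": Segment(2, 8, "-"),
            },
        )
        progressive_align(lcb, [g1, g2])
        assert lcb.rows["t1"].replace("-", "") == "CCGGTT"
        assert lcb.rows["t2"].replace("-", "") == "CCGGTT"  # revcomp of AACCGG
        lcb.validate_rows({"t1": g1, "t2": g2})
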