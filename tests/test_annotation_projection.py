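"""Annotation projection onto LCB alignments and composition accounting."""

import pytest

from lcbphylo.annotation_projection import (
    genes_per_lcb,
    noncoding_fraction,
    project_annotations,
)
from lcbphylo.core import LCB, Feature, Genome, Segment


def build_lcb(lcb_id, segments, rows):
    return LCB(lcb_id=lcb_id, segments=segments, rows=rows)


class TestProjectAnnotations:
    def test_feature_spanning_gap_free_segment_is_one_interval(self):
        g = Genome("a", "ACGTACGTAC", features=[Feature("x", 0, 10, "+", "gene")])
        lcb = build_lcb(
            0,
            {"a": Segment(0, 10, "+"), "b": Segment(0, 10, "+")},
            {"a": "ACGTACGTAC", "b": "ACGTACGTAC"},
        )
        tracks = project_annotations(lcb, [g, Genome("b", "ACGTACGTAC")])
        tr = next(t for t in tracks if t.taxon_id == "a")
        assert len(tr.intervals) == 1
        iv = tr.intervals[0]
        assert (iv.col_start, iv.col_end, iv.kind, iv.name) == (0, 10, "gene", "x")

    def test_insertion_in_other_taxon_shifts_columns_preserving_width(self):
        """A 5 bp insertion in b pushes a's feature across gap columns, but
        the number of non-gap columns it covers is unchanged."""
        g_a = Genome("a", "AAACCCGGG", features=[Feature("x", 3, 9, "+", "gene")])
        g_b = Genome("b", "AAATTTTTCCCGGG")
        lcb = build_lcb(
            0,
            {"a": Segment(0, 9, "+"), "b": Segment(0, 14, "+")},
            {"a": "AAA-----CCCGGG", "b": "AAATTTTTCCCGGG"},
        )
        tracks = project_annotations(lcb, [g_a, g_b])
        tr = next(t for t in tracks if t.taxon_id == "a")
        gene = next(iv for iv in tr.intervals if iv.kind == "gene")
        assert gene.col_start == 8  # pushed past the 5 inserted columns
        assert gene.col_end == 14
        # ungapped width preserved: count of non-gap columns inside
        row = lcb.rows["a"]
        nongap = sum(1 for c in row[gene.col_start : gene.col_end] if c != "-")
        assert nongap == 6

    def test_minus_strand_segment_reports_strand(self):
        from lcbphylo.core import revcomp

        fwd = "AACCGGTTAA"
        g_a = Genome("a", fwd, features=[Feature("x", 2, 8, "+", "gene")])
        g_b = Genome("b", revcomp(fwd))
        lcb = build_lcb(
            0,
            {"a": Segment(0, 10, "+"), "b": Segment(0, 10, "-")},
            {"a": fwd, "b": fwd},
        )
        tracks = project_annotations(lcb, [g_a, g_b])
        tr_a = next(t for t in tracks if t.taxon_id == "a")
        gene = next(iv for iv in tr_a.intervals if iv.kind == "gene")
        assert gene.strand == "+"
        tr_b = next(t for t in tracks if t.taxon_id == "b")
        assert all(iv.kind == "noncoding" for iv in tr_b.intervals)

    def test_column_conservation_gene_plus_noncoding_covers_nongap(self):
        g = Genome(
            "a",
            "AAACCCGGGTTT",
            features=[Feature("x", 3, 6, "+", "gene"), Feature("y", 9, 12, "-", "rRNA")],
        )
        row = "AAA--CCCGGGTT--T"
        assert row.replace("-", "") == "AAACCCGGGTTT"
        lcb = build_lcb(
            0,
            {"a": Segment(0, 12, "+"), "b": Segment(0, 16, "+")},
            {"a": row, "b": "AAAAACCCGGGTTAAT"},
        )
        tracks = project_annotations(lcb, [g, Genome("b", "AAAAACCCGGGTTAAT")])
        tr = next(t for t in tracks if t.taxon_id == "a")
        covered = 0
        for iv in tr.intervals:
            covered += sum(
                1 for c in lcb.rows["a"][iv.col_start : iv.col_end] if c != "-"
            )
        assert covered == 12

    def test_projection_round_trip_recovers_genome_coordinates(self):
        g = Genome("a", "ACGTACGTAC", features=[Feature("x", 2, 7, "+", "gene")])
        row = "AC--GTACGTAC"
        lcb = build_lcb(
            0,
            {"a": Segment(0, 10, "+"), "b": Segment(0, 12, "+")},
            {"a": row, "b": "ACAAGTACGTAC"},
        )
        tracks = project_annotations(lcb, [g, Genome("b", "ACAAGTACGTAC")])
        tr = next(t for t in tracks if t.taxon_id == "a")
        gene = next(iv for iv in tr.intervals if iv.kind == "gene")
        # map interval columns back to genome positions through the row
        positions = []
        pos = 0
        for col, c in enumerate(row):
            if c != "-":
                if gene.col_start <= col < gene.col_end:
                    positions.append(pos)
                pos += 1
        assert (min(positions), max(positions) + 1) == (2, 7)


class TestGenesPerLcb:
    def _setup(self):
        feats = [
            Feature("g1", 0, 100, "+", "gene"),
            Feature("g2", 150, 260, "+", "gene"),
            Feature("g3", 300, 400, "-", "gene"),
            Feature("g4", 500, 620, "+", "gene"),
        ]
        g = Genome("a", "A" * 1000, features=feats)
        lcbs = [
            LCB(0, {"a": Segment(0, 200, "+"), "b": Segment(0, 200, "+")}),
            LCB(1, {"a": Segment(250, 450, "+"), "b": Segment(200, 400, "+")}),
            LCB(2, {"a": Segment(700, 900, "+"), "b": Segment(400, 600, "+")}),
        ]
        return lcbs, [g, Genome("b", "A" * 1000)]

    def test_counts_match_interval_overlap_oracle(self):
        lcbs, genomes = self._setup()
        rec = genes_per_lcb(lcbs, genomes, "a")
        # oracle: brute-force overlap scan
        feats = genomes[0].features
        expected = {}
        for lcb in lcbs:
            seg = lcb.segments["a"]
            expected[lcb.lcb_id] = sum(
                1 for f in feats if f.start < seg.end and f.end > seg.start
            )
        assert rec["per_lcb"] == expected
        assert rec["min"] == 0 and rec["max"] == 2
        assert rec["mean"] == round((2 + 2 + 0) / 3, 2)

    def test_no_features_gives_zeros(self):
        lcbs, genomes = self._setup()
        genomes[0].features = []
        rec = genes_per_lcb(lcbs, genomes, "a")
        assert rec["min"] == rec["max"] == 0 and rec["mean"] == 0.0

    def test_simple_stats(self):
        # counts (0, 5, 10) -> min 0, max 10, mean 5.00
        feats = [Feature(f"g{i}", 200 + i * 30, 220 + i * 30, "+", "gene") for i in range(5)]
        feats += [Feature(f"h{i}", 400 + i * 30, 420 + i * 30, "+", "gene") for i in range(10)]
        g = Genome("a", "A" * 1000, features=feats)
        lcbs = [
            LCB(0, {"a": Segment(0, 150, "+"), "b": Segment(0, 150, "+")}),
            LCB(1, {"a": Segment(190, 380, "+"), "b": Segment(150, 340, "+")}),
            LCB(2, {"a": Segment(390, 800, "+"), "b": Segment(340, 750, "+")}),
        ]
        rec = genes_per_lcb(lcbs, [g, Genome("b", "A" * 1000)], "a")
        assert sorted(rec["per_lcb"].values()) == [0, 5, 10]
        assert rec["mean"] == 5.0


class TestNoncodingFraction:
    def test_printed_arithmetic(self):
        """218,403 non-coding of 1,478,293 unaligned bp prints as 14.8%."""
        total = 1_478_293
        coding = total - 218_403
        g = Genome(
            "mr7",
            "A" * 2_000_000,
            features=[Feature("big", 0, coding, "+", "gene")],
        )
        lcb = LCB(0, {"mr7": Segment(0, total, "+"), "b": Segment(0, total, "+")})
        rec = noncoding_fraction([lcb], [g, Genome("b", "A" * 2_000_000)], "mr7")
        assert rec["noncoding_bp"] == 218_403
        assert rec["total_bp"] == total
        assert rec["pct_noncoding"] == 14.8

    def test_fully_coding_segments(self):
        g = Genome("a", "A" * 100, features=[Feature("x", 0, 100, "+", "gene")])
        lcb = LCB(0, {"a": Segment(0, 100, "+"), "b": Segment(0, 100, "+")})
        rec = noncoding_fraction([lcb], [g, Genome("b", "A" * 100)], "a")
        assert rec["pct_noncoding"] == 0.0

    def test_known_intergenic_fraction_recovered(self):
        """A genome built with exactly 30% intergenic DNA inside the block."""
        feats = []
        pos = 0
        while pos + 70 <= 1000:
            feats.append(Feature(f"g{pos}", pos, pos + 70, "+", "gene"))
            pos += 100  # 70 coding + 30 intergenic
        g = Genome("a", "A" * 1000, features=feats)
        lcb = LCB(0, {"a": Segment(0, 1000, "+"), "b": Segment(0, 1000, "+")})
        rec = noncoding_fraction([lcb], [g, Genome("b", "A" * 1000)], "a")
        assert rec["pct_noncoding"] == 30.0
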