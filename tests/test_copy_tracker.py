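"""Multi-copy family tracking: extraction, grids, topology classes."""

import dendropy
import itertools
import pytest

from lcbphylo.copy_tracker import (
    GeneCopy,
    MONOPHYLETIC,
    PARAPHYLETIC,
    POLYPHYLETIC,
    assign_copies_to_lcbs,
    classify_species_copy_topology,
    concerted_index,
    extract_copies,
    find_identical_copies,
    test_positional_orthology as positional_orthology,
)
from lcbphylo.core import LCB, Feature, Genome, Segment, revcomp


def t(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick")


class TestExtractCopies:
    def _genome(self, taxon, n_copies, seq="ACGTACGTAA"):
        feats = [
            Feature(f"rrn_{i+1}", i * 20, i * 20 + len(seq), "+" if i % 2 == 0 else "-", "rRNA")
            for i in range(n_copies)
        ]
        body = "".join(
            (seq if i % 2 == 0 else revcomp(seq)) + "T" * 10 for i in range(n_copies)
        )
        return Genome(taxon, body, features=feats)

    def test_deterministic_order_and_counts(self):
        genomes = [self._genome("b", 3), self._genome("a", 2)]
        copies = extract_copies(genomes, "rRNA")
        assert [c.taxon_id for c in copies] == ["a", "a", "b", "b", "b"]
        assert [c.copy_index for c in copies] == [1, 2, 1, 2, 3]

    def test_minus_strand_copy_is_reverse_complement_of_slice(self):
        g = self._genome("a", 2)
        copies = extract_copies([g], "rRNA")
        minus = next(c for c in copies if c.strand == "-")
        assert minus.sequence == revcomp(g.sequence[minus.start : minus.end])
        # strand-corrected sequences of all copies are identical
        assert len({c.sequence for c in copies}) == 1

    def test_absent_family_raises(self):
        with pytest.raises(KeyError):
            extract_copies([Genome("a", "ACGT" * 10)], "rRNA")

    def test_single_copy_family_one_record_per_genome(self):
        genomes = [self._genome("a", 1), self._genome("b", 1)]
        copies = extract_copies(genomes, "rRNA")
        assert len(copies) == 2


class TestAssignCopies:
    def _copy(self, taxon, start, end):
        return GeneCopy(taxon, 1, start, end, "+", "A" * (end - start))

    def test_copy_inside_segment_assigned(self):
        lcb = LCB(3, {"a": Segment(100, 400, "+"), "b": Segment(0, 300, "+")})
        copy = self._copy("a", 150, 250)
        grid = assign_copies_to_lcbs([copy], [lcb])
        assert copy.lcb_id == 3
        assert grid.cells[(3, "a")] == [1]

    def test_copy_outside_all_segments_unassigned(self):
        lcb = LCB(3, {"a": Segment(100, 400, "+"), "b": Segment(0, 300, "+")})
        copy = self._copy("a", 600, 700)
        grid = assign_copies_to_lcbs([copy], [lcb])
        assert copy.lcb_id is None
        assert grid.unassigned == [copy]

    def test_minority_overlap_not_assigned(self):
        lcb = LCB(0, {"a": Segment(100, 400, "+"), "b": Segment(0, 300, "+")})
        copy = self._copy("a", 350, 500)  # 50 of 150 bp inside
        grid = assign_copies_to_lcbs([copy], [lcb])
        assert copy.lcb_id is None

    def test_grid_rows_match_occupied_lcbs(self):
        """A constructed 13-block grid has 13 rows (one per occupied LCB)."""
        lcbs = [
            LCB(i, {"a": Segment(i * 1000, i * 1000 + 500, "+"),
                    "b": Segment(i * 1000, i * 1000 + 500, "+")})
            for i in range(15)
        ]
        copies = [self._copy("a", i * 1000 + 10, i * 1000 + 110) for i in range(13)]
        grid = assign_copies_to_lcbs(copies, lcbs)
        assert grid.n_rows == 13

    def test_every_copy_in_grid_or_unassigned(self):
        lcbs = [
            LCB(0, {"a": Segment(0, 500, "+"), "b": Segment(0, 500, "+")}),
        ]
        copies = [self._copy("a", 10, 110), self._copy("a", 900, 1000)]
        grid = assign_copies_to_lcbs(copies, lcbs)
        placed = sum(len(v) for v in grid.cells.values())
        assert placed + len(grid.unassigned) == 2


class TestPositionalOrthology:
    def test_full_row_means_orthology_candidate(self):
        lcb = LCB(0, {"a": Segment(0, 500, "+"), "b": Segment(0, 500, "+")})
        copies = [
            GeneCopy("a", 1, 10, 110, "+", "A" * 100),
            GeneCopy("b", 1, 10, 110, "+", "A" * 100),
        ]
        grid = assign_copies_to_lcbs(copies, [lcb])
        verdict = positional_orthology(grid, frozenset({"a", "b"}))
        assert verdict["positional_orthology"] is True

    def test_no_row_covering_all_taxa(self):
        lcbs = [
            LCB(0, {"a": Segment(0, 500, "+"), "b": Segment(0, 500, "+")}),
            LCB(1, {"a": Segment(600, 1100, "+"), "c": Segment(0, 500, "+")}),
        ]
        copies = [
            GeneCopy("a", 1, 10, 110, "+", "A" * 100),
            GeneCopy("b", 1, 10, 110, "+", "A" * 100),
            GeneCopy("c", 1, 10, 110, "+", "A" * 100),
        ]
        grid = assign_copies_to_lcbs(copies, lcbs)
        verdict = positional_orthology(grid, frozenset({"a", "b", "c"}))
        assert verdict["positional_orthology"] is False
        # and restricting to an ingroup subset that still lacks a full row
        verdict_sub = positional_orthology(grid, frozenset({"b", "c"}))
        assert verdict_sub["positional_orthology"] is False


class TestIdenticalCopies:
    def test_all_distinct_gives_singletons(self):
        copies = [
            GeneCopy("a", 1, 0, 4, "+", "ACGT"),
            GeneCopy("b", 1, 0, 4, "+", "AGGT"),
        ]
        groups = find_identical_copies(copies)
        assert all(g["size"] == 1 for g in groups)

    def test_within_taxon_class(self):
        copies = [
            GeneCopy("a", 1, 0, 4, "+", "ACGT"),
            GeneCopy("a", 2, 10, 14, "+", "ACGT"),
            GeneCopy("b", 1, 0, 4, "+", "AGGT"),
        ]
        groups = find_identical_copies(copies)
        big = next(g for g in groups if g["size"] == 2)
        assert big["flag"] == "within_taxon"

    def test_between_taxa_class(self):
        copies = [
            GeneCopy("a", 1, 0, 4, "+", "ACGT"),
            GeneCopy("b", 1, 0, 4, "+", "ACGT"),
        ]
        groups = find_identical_copies(copies)
        assert groups[0]["flag"] == "between_taxa"


def brute_force_classification(tree, copy_labels):
    """Clade-enumeration oracle for mono/para/polyphyly (independent)."""
    clades = set()
    for node in tree.preorder_node_iter():
        clades.add(frozenset(lf.taxon.label for lf in node.leaf_iter()))
    out = {}
    by_taxon = {}
    for leaf, taxon in copy_labels.items():
        by_taxon.setdefault(taxon, set()).add(leaf)
    for taxon, own in by_taxon.items():
        own = frozenset(own)
        if len(own) == 1 or own in clades:
            out[taxon] = MONOPHYLETIC
            continue
        # smallest enclosing clade = the MRCA's leaf set; paraphyletic iff
        # what it adds beyond the taxon's own copies is itself one clade
        smallest = min((c for c in clades if own <= c), key=len)
        extra = frozenset(smallest - own)
        out[taxon] = PARAPHYLETIC if extra in clades else POLYPHYLETIC
    return out


class TestClassification:
    def test_monophyletic_clade(self):
        tree = t("((x1,(x2,x3)),((y1,y2),z1));")
        labels = {"x1": "x", "x2": "x", "x3": "x", "y1": "y", "y2": "y", "z1": "z"}
        classes = classify_species_copy_topology(tree, labels)
        assert classes["x"] == MONOPHYLETIC
        assert classes["y"] == MONOPHYLETIC
        assert classes["z"] == MONOPHYLETIC  # single copy: trivially so

    def test_paraphyletic_grade_with_one_nested_clade(self):
        """The halifaxensis/pealeana pattern: x's copies form a grade with
        y's clade nested inside."""
        tree = t("((x1,(x2,((y1,y2),x3))),(z1,z2));")
        labels = {
            "x1": "x", "x2": "x", "x3": "x",
            "y1": "y", "y2": "y", "z1": "z", "z2": "z",
        }
        classes = classify_species_copy_topology(tree, labels)
        assert classes["x"] == PARAPHYLETIC
        assert classes["y"] == MONOPHYLETIC

    def test_polyphyletic_scattered_copies(self):
        tree = t("((x1,(y1,y2)),((x2,z1),(w1,w2)));")
        labels = {
            "x1": "x", "x2": "x", "y1": "y", "y2": "y",
            "z1": "z", "w1": "w", "w2": "w",
        }
        classes = classify_species_copy_topology(tree, labels)
        assert classes["x"] == POLYPHYLETIC

    def test_matches_brute_force_oracle_on_fixture_suite(self):
        import numpy as np

        from conftest import random_tree

        rng = np.random.default_rng(13)
        for _ in range(25):
            n = int(rng.integers(6, 12))
            leaves = [f"c{i}" for i in range(n)]
            tree = random_tree(leaves, rng)
            labels = {leaf: f"sp{int(rng.integers(3))}" for leaf in leaves}
            mine = classify_species_copy_topology(tree, labels)
            oracle = brute_force_classification(tree, labels)
            assert mine == oracle


class TestConcertedIndex:
    def test_all_monophyletic(self):
        classes = {f"t{i}": MONOPHYLETIC for i in range(5)}
        assert concerted_index(classes) == 1.0

    def test_half_monophyletic(self):
        classes = {f"t{i}": MONOPHYLETIC if i < 6 else POLYPHYLETIC for i in range(12)}
        assert concerted_index(classes) == 0.5

    def test_multi_copy_filter(self):
        classes = {"a": MONOPHYLETIC, "b": POLYPHYLETIC, "c": MONOPHYLETIC}
        # c is single-copy: excluded from the index
        assert concerted_index(classes, multi_copy_taxa={"a", "b"}) == 0.5
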