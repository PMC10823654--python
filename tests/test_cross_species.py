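"""MAF traversal, allele lookup, sharing classification and aggregation."""

import io

import pytest

from paleovar.cross_species import (
    MISSING,
    NOT_SHARED,
    SHARED,
    AlignmentBlock,
    MafIndex,
    MafRow,
    build_sharing_matrix,
    classify_sharing,
    domain_overlap_table,
    lookup_species_allele,
    read_maf,
)
from paleovar.stats_report import kruskal_wallis
from paleovar.synthetic_data import REFERENCE_SPECIES
from paleovar.variant_catalog import VariantRecord


def rec(pos, ref, alt, cls="PV", gene="G1"):
    return VariantRecord(
        gene=gene, chrom="ref1", pos=pos, ref=ref, alt=alt,
        hgvs_c=f"c.{pos}", clin_class=cls,
    )


MINIMAL_MAF = """##maf version=1
a score=100.0
s Human.chr1 0 10 + 100 ACGTACGTAC
s mouse.chr1 0 10 + 200 ACGTACGTAC

"""


class TestReadMaf:
    def test_minimal_two_species_block(self):
        (block,) = read_maf(io.StringIO(MINIMAL_MAF))
        assert block.score == 100.0
        assert len(block.rows) == 2
        assert block.rows[1].species == "mouse"

    def test_negative_strand_forward_interval(self):
        """srcSize − start − size recovers the forward interval: a '-' row
        with start 5, size 12, srcSize 100 spans forward [83, 95)."""
        maf = (
            "##maf version=1\n"
            "a score=1\n"
            "s Human.chr1 10 12 + 100 ACGTACGTACGT\n"
            "s fish.chr2   5 12 - 100 ACGTACGTACGT\n\n"
        )
        (block,) = read_maf(io.StringIO(maf))
        fish = block.rows[1]
        assert fish.forward_start == 100 - 5 - 12 == 83
        assert fish.forward_end == 95

    def test_empty_file_after_header(self):
        assert list(read_maf(io.StringIO("##maf version=1\n\n"))) == []

    def test_row_length_mismatch_names_block_ordinal(self):
        maf = (
            "##maf version=1\n"
            "a score=1\n"
            "s Human.chr1 0 4 + 10 ACGT\n"
            "s mouse.chr1 0 4 + 10 ACGT\n\n"
            "a score=1\n"
            "s Human.chr1 4 4 + 10 ACGT\n"
            "s mouse.chr1 4 3 + 10 ACG\n\n"
        )
        with pytest.raises(ValueError, match="block 1"):
            list(read_maf(io.StringIO(maf)))

    def test_e_i_q_lines_tolerated(self):
        maf = (
            "##maf version=1\n"
            "a score=1\n"
            "s Human.chr1 0 4 + 10 ACGT\n"
            "s mouse.chr1 0 4 + 10 ACGT\n"
            "i mouse.chr1 N 0 C 0\n"
            "q mouse.chr1 9999\n"
            "e rat.chr1 0 4 + 10 I\n\n"
        )
        (block,) = read_maf(io.StringIO(maf))
        assert len(block.rows) == 2


def block_of(score, *rows):
    return AlignmentBlock(score=score, rows=list(rows))


def hrow(start, text, src_size=1000):
    size = len(text) - text.count("-")
    return MafRow(REFERENCE_SPECIES, f"{REFERENCE_SPECIES}.ref1", start, size, "+", src_size, text)


def srow(species, text, start=0, strand="+", src_size=1000):
    size = len(text) - text.count("-")
    return MafRow(species, f"{species}.chr1", start, size, strand, src_size, text)


class TestLookupAndClassify:
    def test_identity_alignment_returns_ref(self):
        index = MafIndex([block_of(1, hrow(0, "ACGTACGT"), srow("sp", "ACGTACGT"))], REFERENCE_SPECIES)
        obs = lookup_species_allele(rec(3, "G", "A"), index, "sp")
        assert obs.bases == "G"
        assert classify_sharing(rec(3, "G", "A"), obs) == NOT_SHARED

    def test_alt_base_is_shared(self):
        index = MafIndex([block_of(1, hrow(0, "ACGTACGT"), srow("sp", "ACATACGT"))], REFERENCE_SPECIES)
        variant = rec(3, "G", "A")
        obs = lookup_species_allele(variant, index, "sp")
        assert classify_sharing(variant, obs) == SHARED

    def test_gap_at_variant_column_is_missing(self):
        index = MafIndex([block_of(1, hrow(0, "ACGTACGT"), srow("sp", "AC-TACGT"))], REFERENCE_SPECIES)
        variant = rec(3, "G", "A")
        obs = lookup_species_allele(variant, index, "sp")
        assert obs.missing and obs.reason == "gap"
        assert classify_sharing(variant, obs) == MISSING

    def test_species_absent_and_uncovered_are_missing(self):
        index = MafIndex([block_of(1, hrow(0, "ACGT"), srow("sp", "ACGT"))], REFERENCE_SPECIES)
        assert lookup_species_allele(rec(2, "C", "T"), index, "other").reason == "species_absent"
        assert lookup_species_allele(rec(99, "C", "T"), index, "sp").reason == "uncovered"

    def test_soft_masked_base_flagged_but_compared(self):
        index = MafIndex([block_of(1, hrow(0, "ACGTACGT"), srow("sp", "ACaTACGT"))], REFERENCE_SPECIES)
        variant = rec(3, "G", "A")
        obs = lookup_species_allele(variant, index, "sp")
        assert obs.masked
        assert classify_sharing(variant, obs) == SHARED

    def test_highest_scoring_overlapping_block_wins(self):
        """Crafted 3-block fixture; manual column walk says the high-score
        block's base (T) is reported, not the low-score ones (C/G)."""
        blocks = [
            block_of(10, hrow(0, "ACGTACGT"), srow("sp", "ACCTACGT")),
            block_of(99, hrow(2, "GTACGT"), srow("sp", "GTT-GT", start=50)),
            block_of(5, hrow(0, "ACGTACGT"), srow("sp", "ACGGACGT")),
        ]
        index = MafIndex(blocks, REFERENCE_SPECIES)
        variant = rec(5, "A", "T")  # 0-based 4 -> column 2 of block 2
        obs = lookup_species_allele(variant, index, "sp")
        assert obs.block_score == 99
        assert obs.bases == "T"

    def test_deletion_shared_by_post_deletion_haplotype(self):
        """Species carrying the 2-bp deletion shows anchor + gaps over the
        footprint; its ungapped span equals the post-deletion haplotype."""
        variant = rec(2, "CGT", "C")  # delete GT after anchor C at pos 2
        index = MafIndex(
            [block_of(1, hrow(0, "ACGTAC"), srow("del_sp", "AC--AC"), srow("ref_sp", "ACGTAC"))],
            REFERENCE_SPECIES,
        )
        obs_del = lookup_species_allele(variant, index, "del_sp")
        obs_ref = lookup_species_allele(variant, index, "ref_sp")
        assert classify_sharing(variant, obs_del) == SHARED
        assert classify_sharing(variant, obs_ref) == NOT_SHARED

    def test_insertion_shared_via_reference_gap_columns(self):
        variant = rec(2, "C", "CTT")
        index = MafIndex(
            [block_of(1, hrow(0, "AC--GT"), srow("ins_sp", "ACTTGT"), srow("ref_sp", "AC--GT"))],
            REFERENCE_SPECIES,
        )
        assert classify_sharing(variant, lookup_species_allele(variant, index, "ins_sp")) == SHARED
        assert classify_sharing(variant, lookup_species_allele(variant, index, "ref_sp")) == NOT_SHARED

    def test_strand_invariance_of_observation(self):
        """Re-labelling a species row as '-' strand (same aligned text,
        converted coordinates) leaves the observation unchanged."""
        plus = block_of(1, hrow(0, "ACGTACGT"), srow("sp", "ACATACGT", start=100, strand="+", src_size=1000))
        minus = block_of(1, hrow(0, "ACGTACGT"), srow("sp", "ACATACGT", start=1000 - 100 - 8, strand="-", src_size=1000))
        variant = rec(3, "G", "A")
        obs_p = lookup_species_allele(variant, MafIndex([plus], REFERENCE_SPECIES), "sp")
        obs_m = lookup_species_allele(variant, MafIndex([minus], REFERENCE_SPECIES), "sp")
        assert obs_p.bases == obs_m.bases


class TestSharingMatrix:
    def test_planted_truth_recovered_exactly(self, sim):
        matrix = build_sharing_matrix(
            sim.records, sim.blocks, list(sim.clade_map), REFERENCE_SPECIES
        )
        for vid, states in sim.truth.sharing_grid.items():
            for species, state in states.items():
                assert matrix.grid.loc[vid, species] == state

    def test_row_sums_partition_species(self, sim):
        matrix = build_sharing_matrix(
            sim.records, sim.blocks, list(sim.clade_map), REFERENCE_SPECIES
        )
        counts = matrix.per_variant_counts()
        n = len(sim.clade_map) - 1  # non-reference species
        assert ((counts[SHARED] + counts[NOT_SHARED] + counts[MISSING]) == n).all()

    def test_no_pv_records_means_zero_pv_counts(self, sim):
        non_pv = [r for r in sim.records if r.clin_class != "PV"]
        matrix = build_sharing_matrix(
            non_pv, sim.blocks, list(sim.clade_map), REFERENCE_SPECIES
        )
        assert (matrix.per_species_counts()["shared_PV"] == 0).all()

    def test_removing_species_rows_only_creates_missing(self, sim):
        """Monotone missingness: dropping one species' rows can only move
        its cells to missing, never flip shared <-> not_shared."""
        victim = next(s for s in sim.clade_map if s != REFERENCE_SPECIES)
        full = build_sharing_matrix(
            sim.records, sim.blocks, list(sim.clade_map), REFERENCE_SPECIES
        )
        stripped_blocks = [
            AlignmentBlock(b.score, [r for r in b.rows if r.species != victim])
            for b in sim.blocks
        ]
        stripped = build_sharing_matrix(
            sim.records, stripped_blocks, list(sim.clade_map), REFERENCE_SPECIES
        )
        assert (stripped.grid[victim] == MISSING).all()
        others = [c for c in full.grid.columns if c != victim]
        assert stripped.grid[others].equals(full.grid[others])


class TestAggregation:
    def test_partition_and_tree_order(self, sim):
        from paleovar.phylogeny import parse_newick

        tree = parse_newick(sim.newick, reference=REFERENCE_SPECIES)
        matrix = build_sharing_matrix(
            sim.records, sim.blocks, list(sim.clade_map), REFERENCE_SPECIES
        )
        per_species, clade_groups, order = (
            __import__("paleovar.cross_species", fromlist=["aggregate_by_clade"])
            .aggregate_by_clade(matrix, sim.clade_map, tree)
        )
        assert sum(len(v) for v in clade_groups.values()) == len(per_species)
        assert list(per_species.index) == order
        assert order[0].startswith("Primate")  # reference clade first

    def test_planted_distal_gradient_recovered(self, sim):
        """Sharing was planted to rise with clade distance: the farthest
        clade's median shared-PV count exceeds the nearest clade's, and the
        per-species counts trend upward with patristic distance."""
        import numpy as np

        from paleovar.cross_species import aggregate_by_clade
        from paleovar.phylogeny import parse_newick

        tree = parse_newick(sim.newick, reference=REFERENCE_SPECIES)
        matrix = build_sharing_matrix(
            sim.records, sim.blocks, list(sim.clade_map), REFERENCE_SPECIES
        )
        per_species, clade_groups, _ = aggregate_by_clade(
            matrix, sim.clade_map, tree
        )
        clades = [c for c, _ in sim.config.clade_spec]
        near = np.median(clade_groups[clades[0]])
        far = np.median(clade_groups[clades[-1]])
        assert far > near
        corr = np.corrcoef(
            per_species["distance_to_reference"], per_species["shared_PV"]
        )[0, 1]
        assert corr > 0

    def test_single_clade_refused_downstream(self, sim):
        groups = {"only_clade": [1, 2, 3]}
        with pytest.raises(ValueError):
            kruskal_wallis(groups)


class TestDomainOverlap:
    def test_no_domains_single_outside_stratum(self):
        records = [rec(p, "C", "T") for p in (5, 10, 15)]
        tab = domain_overlap_table({records[0].variant_id}, records, [])
        assert list(tab.index) == ["outside"]
        assert tab.loc["outside"].sum() == 3

    def test_half_open_boundary_convention(self):
        records = [rec(11, "C", "T"), rec(21, "C", "T")]
        # 0-based half-open [10, 20): position 11 (0-based 10) inside,
        # position 21 (0-based 20) outside
        tab = domain_overlap_table(set(), records, [(10, 20, "dom")])
        assert tab.loc["dom", "not_shared"] == 1
        assert tab.loc["outside", "not_shared"] == 1

    def test_crafted_ten_variant_fixture(self):
        """Manual interval intersection: 4 of 10 variants in-domain."""
        records = [rec(p, "C", "T") for p in range(1, 11)]
        shared = {records[i].variant_id for i in (0, 4, 8)}
        tab = domain_overlap_table(shared, records, [(2, 6, "dom")])  # pos 3..6
        assert tab.loc["dom"].sum() == 4
        assert tab.loc["outside"].sum() == 6
        assert tab.loc["dom", "shared"] == 1  # pos 5
        assert tab.loc["outside", "shared"] == 2

    def test_overlapping_domains_merged(self):
        records = [rec(5, "C", "T")]
        tab = domain_overlap_table(set(), records, [(0, 6, "a"), (4, 9, "b")])
        assert "a+b" in tab.index
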