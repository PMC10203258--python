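"""Interval algebra and file-format round trips, checked against per-base
oracles and (for strand-aware merging) against bedtools."""

import gzip
import shutil
import subprocess

import pytest
from hypothesis import given, settings, strategies as st

from exrbp import (
    BindingSiteSet,
    GenomicInterval,
    merge_cross_cell_line,
    partition_union,
    read_coverage,
    read_sites,
    region_set_inventory,
    write_coverage,
    write_sites,
)
from exrbp.genomic_io import ParseError, merge_intervals

from conftest import brute_force_membership


class TestGenomicInterval:
    def test_rejects_degenerate(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 5, 5)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 5)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 5)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 0, 5, "x")


class TestReadCoverage:
    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.bedgraph"
        p.write_text("")
        assert read_coverage(p).intervals == []

    def test_three_line_fixture(self, tmp_path):
        p = tmp_path / "t.bedgraph"
        p.write_text("chr1\t0\t5\t2\nchr1\t5\t8\t4\nchr2\t0\t3\t1\n")
        track = read_coverage(p)
        assert [(iv.chrom, iv.start, iv.end, d) for iv, d in track.intervals] == [
            ("chr1", 0, 5, 2), ("chr1", 5, 8, 4), ("chr2", 0, 3, 1),
        ]

    def test_overlap_rejected(self, tmp_path):
        p = tmp_path / "o.bedgraph"
        p.write_text("chr1\t0\t5\t2\nchr1\t3\t8\t4\n")
        with pytest.raises(ValueError, match="overlap"):
            read_coverage(p)

    def test_malformed_line_names_lineno(self, tmp_path):
        p = tmp_path / "bad.bedgraph"
        p.write_text("chr1\t0\t5\t2\nchr1\tnope\t8\t4\n")
        with pytest.raises(ParseError, match=":2"):
            read_coverage(p)

    def test_track_header_skipped_and_gzip(self, tmp_path):
        body = "track type=bedGraph\nchr1\t0\t5\t2\n"
        gz = tmp_path / "t.bedgraph.gz"
        with gzip.open(gz, "wt") as fh:
            fh.write(body)
        track = read_coverage(gz)
        assert len(track.intervals) == 1

    def test_round_trip(self, small_study, tmp_path):
        track = small_study["tracks"][0]
        p = tmp_path / "rt.bedgraph"
        write_coverage(track, p)
        again = read_coverage(p, sample_id=track.sample_id)
        assert again.intervals == track.intervals


class TestReadSites:
    def test_narrowpeak_line(self, tmp_path):
        p = tmp_path / "s.narrowPeak"
        p.write_text("chr1\t10\t50\tpeak1\t0\t+\t1.5\t2.5\t-1\t20\n")
        ss = read_sites(p, rbp="X", cell_line="lineA")
        assert ss.sites == [GenomicInterval("chr1", 10, 50, "+")]

    def test_empty_file(self, tmp_path):
        p = tmp_path / "e.bed"
        p.write_text("")
        assert len(read_sites(p, "X", "lineA")) == 0

    def test_missing_strand_column(self, tmp_path):
        p = tmp_path / "m.bed"
        p.write_text("chr1\t10\t50\n")
        with pytest.raises(ParseError, match="6 columns"):
            read_sites(p, "X", "lineA")

    def test_unknown_strand_symbol(self, tmp_path):
        p = tmp_path / "u.bed"
        p.write_text("chr1\t10\t50\tpeak\t0\t?\n")
        with pytest.raises(ParseError, match="strand"):
            read_sites(p, "X", "lineA")

    def test_mixed_strand_fixture_order_normalized(self, tmp_path):
        lines = [
            f"chr{c}\t{s}\t{s+10}\tp\t0\t{st}"
            for c, s, st in [
                (2, 50, "+"), (1, 30, "-"), (1, 10, "+"), (1, 90, "-"), (2, 5, "-"),
                (1, 50, "+"), (2, 20, "+"), (1, 70, "-"), (2, 80, "+"), (1, 110, "+"),
            ]
        ]
        p = tmp_path / "mix.bed"
        p.write_text("\n".join(lines) + "\n")
        ss = read_sites(p, "X", "lineA")
        assert len(ss) == 10
        keys = [(s.chrom, s.start) for s in ss.sites]
        assert keys == sorted(keys)


class TestMerge:
    def test_same_strand_overlap_coalesces(self):
        a = BindingSiteSet("X", "lineA", [GenomicInterval("chr1", 0, 10, "+")])
        b = BindingSiteSet("X", "lineB", [GenomicInterval("chr1", 5, 15, "+")])
        merged = merge_cross_cell_line(a, b)
        assert merged.sites == [GenomicInterval("chr1", 0, 15, "+")]
        assert merged.cell_line == "merged"

    def test_opposite_strands_kept_separate(self):
        a = BindingSiteSet("X", "lineA", [GenomicInterval("chr1", 0, 10, "+")])
        b = BindingSiteSet("X", "lineB", [GenomicInterval("chr1", 5, 15, "-")])
        merged = merge_cross_cell_line(a, b)
        assert len(merged) == 2

    def test_book_ended_coalesce(self):
        a = BindingSiteSet("X", "lineA", [GenomicInterval("chr1", 0, 10, "+")])
        b = BindingSiteSet("X", "lineB", [GenomicInterval("chr1", 10, 20, "+")])
        assert merge_cross_cell_line(a, b).sites == [GenomicInterval("chr1", 0, 20, "+")]

    def test_idempotent_and_commutative(self, small_study):
        a, b = small_study["sites"][0], small_study["sites"][1]
        b = BindingSiteSet(a.rbp, "lineB", list(b.sites))
        ab = merge_cross_cell_line(a, b)
        ba = merge_cross_cell_line(b, a)
        assert ab.sites == ba.sites
        again = merge_cross_cell_line(ab, BindingSiteSet(a.rbp, "lineA", list(ab.sites)))
        assert again.sites == ab.sites
        total = sum(len(s) for s in ab.sites)
        assert total <= sum(len(s) for s in a.sites) + sum(len(s) for s in b.sites)

    def test_mismatched_rbp_rejected(self):
        a = BindingSiteSet("X", "lineA", [GenomicInterval("chr1", 0, 10, "+")])
        b = BindingSiteSet("Y", "lineB", [GenomicInterval("chr1", 5, 15, "+")])
        with pytest.raises(ValueError, match="different RBPs"):
            merge_cross_cell_line(a, b)

    @pytest.mark.skipif(shutil.which("bedtools") is None, reason="bedtools not on PATH")
    def test_against_bedtools_merge(self, small_study, tmp_path):
        """Independent oracle: bedtools merge -s on the concatenated site sets."""
        a, b0 = small_study["sites"][2], small_study["sites"][3]
        b = BindingSiteSet(a.rbp, "lineB", list(b0.sites))
        merged = merge_cross_cell_line(a, b)
        cat = tmp_path / "cat.bed"
        both = BindingSiteSet(a.rbp, "both", list(a.sites) + list(b.sites))
        write_sites(both, cat)
        out = subprocess.run(
            ["bedtools", "merge", "-s", "-c", "6", "-o", "distinct", "-i", str(cat)],
            capture_output=True, text=True, check=True,
        ).stdout
        expect = set()
        for line in out.strip().splitlines():
            chrom, s, e, strand = line.split("\t")
            expect.add((chrom, int(s), int(e), strand))
        got = {(s.chrom, s.start, s.end, s.strand) for s in merged.sites}
        assert got == expect


class TestPartitionUnion:
    def test_printed_two_site_example(self, toy_sites):
        atoms = partition_union(toy_sites)
        assert [(a.interval.start, a.interval.end, a.members) for a in atoms] == [
            (0, 4, ("A",)), (4, 10, ("A", "B")), (10, 15, ("B",)),
        ]

    def test_single_set_identity(self, small_study):
        ss = small_study["sites"][0]
        atoms = partition_union([ss])
        merged = merge_intervals(ss.sites, stranded=False)
        got = [(a.interval.chrom, a.interval.start, a.interval.end) for a in atoms]
        assert got == [(m.chrom, m.start, m.end) for m in merged]
        assert all(a.members == (ss.rbp,) for a in atoms)

    def test_three_nested_intervals(self):
        sets = [
            BindingSiteSet("R1", "merged", [GenomicInterval("chr1", 0, 30, "+")]),
            BindingSiteSet("R2", "merged", [GenomicInterval("chr1", 10, 20, "+")]),
            BindingSiteSet("R3", "merged", [GenomicInterval("chr1", 12, 18, "+")]),
        ]
        atoms = partition_union(sets)
        assert [a.members for a in atoms] == [
            ("R1",), ("R1", "R2"), ("R1", "R2", "R3"), ("R1", "R2"), ("R1",),
        ]

    @settings(max_examples=40, deadline=None)
    @given(st.data())
    def test_per_base_oracle(self, data):
        """Atoms are disjoint, sorted, and agree base-for-base with brute force."""
        n_rbps = data.draw(st.integers(2, 4))
        sets = []
        for r in range(n_rbps):
            n_sites = data.draw(st.integers(1, 5))
            sites = []
            for _ in range(n_sites):
                start = data.draw(st.integers(0, 180))
                length = data.draw(st.integers(1, 40))
                sites.append(GenomicInterval("chrT", start, start + length, "+"))
            sets.append(BindingSiteSet(f"R{r}", "merged", merge_intervals(sites)))
        atoms = partition_union(sets)
        # disjoint + sorted
        for x, y in zip(atoms[:-1], atoms[1:]):
            assert x.interval.end <= y.interval.start or x.interval.chrom != y.interval.chrom
        # base-for-base membership agreement
        truth = brute_force_membership(sets, "chrT", 0, 260)
        got = [set() for _ in range(260)]
        for a in atoms:
            for pos in range(a.interval.start, a.interval.end):
                got[pos] = set(a.members)
        assert got == truth


class TestRegionSetInventory:
    def test_published_accounting(self):
        """103 + 120 per-cell-line sets with 73 shared RBPs -> 296 files."""
        line_a = [f"A{i}" for i in range(30)] + [f"S{i}" for i in range(73)]
        line_b = [f"B{i}" for i in range(47)] + [f"S{i}" for i in range(73)]
        inv = region_set_inventory(line_a, line_b)
        assert len(line_a) == 103 and len(line_b) == 120
        assert len(inv) == 296
        assert sum(1 for _, cl in inv if cl == "merged") == 73
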