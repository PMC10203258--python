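"""Interval containers and readers/writers for the formats the pipeline consumes.

All coordinates are 0-based half-open, the native convention of bedGraph and
BED.  Prose coordinates of the form ``chr1:1-10`` (1-based inclusive) convert
to half-open ``[0, 10)``.

Three container types cover the inputs: :class:`CoverageTrack` (one sample's
per-base read depth, from a bedGraph), :class:`BindingSiteSet` (one RBP's
stranded eCLIP peak intervals, from BED6/narrowPeak), and
:class:`AnnotationSet` (gene/biotype records; a region may carry several
biotypes).  :func:`merge_cross_cell_line` and :func:`partition_union`
implement the strand-aware peak merging and the atomic-region partition used
to build sample-centric intersection matrices.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

log = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")

__all__ = [
    "GenomicInterval",
    "CoverageTrack",
    "BindingSiteSet",
    "AnnotationRecord",
    "AnnotationSet",
    "Atom",
    "read_coverage",
    "write_coverage",
    "read_sites",
    "write_sites",
    "read_annotation",
    "merge_cross_cell_line",
    "merge_intervals",
    "partition_union",
    "write_atoms",
    "region_set_inventory",
]


class ParseError(ValueError):
    """A malformed line in an input file; the message names the line number."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``.

    ``strand`` is ``"+"``, ``"-"`` or ``"."`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self}")
        if self.end <= self.start:
            raise ValueError(f"empty or inverted interval: {self}")
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class CoverageTrack:
    """One sample's per-base read depth as sorted, non-overlapping intervals."""

    sample_id: str
    intervals: list[tuple[GenomicInterval, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals.sort(key=lambda iv: (iv[0].chrom, iv[0].start))
        prev: GenomicInterval | None = None
        for iv, depth in self.intervals:
            if depth < 0:
                raise ValueError(f"negative depth {depth} at {iv}")
            if prev is not None and prev.chrom == iv.chrom and iv.start < prev.end:
                raise ValueError(
                    f"overlapping coverage intervals {prev} and {iv} "
                    f"in sample {self.sample_id}"
                )
            prev = iv

    @property
    def chroms(self) -> list[str]:
        return sorted({iv.chrom for iv, _ in self.intervals})

    def total_bases(self) -> int:
        return sum(len(iv) for iv, _ in self.intervals)


@dataclass
class BindingSiteSet:
    """One RBP's stranded binding-site intervals for one cell line (or merged)."""

    rbp: str
    cell_line: str
    sites: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        for s in self.sites:
            if s.strand not in ("+", "-"):
                raise ValueError(f"binding site must be stranded: {s}")
        self.sites.sort(key=lambda s: (s.chrom, s.start, s.end, s.strand))

    def __len__(self) -> int:
        return len(self.sites)


@dataclass(frozen=True)
class AnnotationRecord:
    interval: GenomicInterval
    gene_id: str
    biotype: str
    gene_name: str = ""


@dataclass
class AnnotationSet:
    """Gene annotation; one region may carry several records/biotypes."""

    records: list[AnnotationRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def biotypes(self) -> list[str]:
        return sorted({r.biotype for r in self.records})


@dataclass(frozen=True)
class Atom:
    """A maximal interval over which the covering RBP set is constant."""

    interval: GenomicInterval
    members: tuple[str, ...]


def _open_text(path):
    """Open plain or gzip text transparently."""
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _is_header(line: str) -> bool:
    s = line.strip()
    return (
        not s
        or s.startswith("#")
        or s.startswith("track")
        or s.startswith("browser")
    )


def read_coverage(path, sample_id: str | None = None) -> CoverageTrack:
    """Read a 4-column bedGraph into a :class:`CoverageTrack`.

    Track/browser/comment header lines are skipped.  Raises
    :class:`ParseError` naming the offending line, and ``ValueError`` if two
    intervals overlap.
    """
    if sample_id is None:
        name = str(path).rsplit("/", 1)[-1]
        for suffix in (".gz", ".bedgraph", ".bedGraph", ".bg"):
            if name.endswith(suffix):
                name = name[: -len(suffix)]
        sample_id = name
    intervals: list[tuple[GenomicInterval, int]] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if _is_header(line):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
            chrom, start, end, value = fields[:4]
            try:
                iv = GenomicInterval(chrom, int(start), int(end))
                depth = int(float(value))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if depth < 0:
                raise ParseError(f"{path}:{lineno}: negative depth {depth}")
            intervals.append((iv, depth))
    return CoverageTrack(sample_id=sample_id, intervals=intervals)


def write_coverage(track: CoverageTrack, path) -> None:
    """Write a track as a sorted 4-column bedGraph."""
    with open(path, "wt") as fh:
        for iv, depth in track.intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{depth}\n")


def read_sites(path, rbp: str, cell_line: str) -> BindingSiteSet:
    """Read a BED6/narrowPeak file into a stranded, sorted BindingSiteSet.

    Columns beyond the first six (narrowPeak statistics) are ignored.
    """
    sites: list[GenomicInterval] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if _is_header(line):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ParseError(
                    f"{path}:{lineno}: BED6/narrowPeak needs >= 6 columns "
                    f"(strand in column 6), got {len(fields)}"
                )
            chrom, start, end = fields[0], fields[1], fields[2]
            strand = fields[5]
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: unknown strand symbol {strand!r}")
            try:
                sites.append(GenomicInterval(chrom, int(start), int(end), strand))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return BindingSiteSet(rbp=rbp, cell_line=cell_line, sites=sites)


def write_sites(siteset: BindingSiteSet, path) -> None:
    """Write a BindingSiteSet as BED6 (name = RBP, score = 0)."""
    with open(path, "wt") as fh:
        for s in siteset.sites:
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{siteset.rbp}\t0\t{s.strand}\n")


def read_annotation(path) -> AnnotationSet:
    """Read a BED-like annotation: chrom start end gene_id biotype [gene_name] [strand]."""
    records: list[AnnotationRecord] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if _is_header(line):
                continue
            fields = line.split()
            if len(fields) < 5:
                raise ParseError(
                    f"{path}:{lineno}: annotation needs >= 5 columns "
                    "(chrom start end gene_id biotype)"
                )
            chrom, start, end, gene_id, biotype = fields[:5]
            gene_name = fields[5] if len(fields) > 5 else ""
            strand = fields[6] if len(fields) > 6 and fields[6] in STRANDS else "."
            try:
                iv = GenomicInterval(chrom, int(start), int(end), strand)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            records.append(AnnotationRecord(iv, gene_id, biotype, gene_name))
    return AnnotationSet(records=records)


def write_annotation(ann: AnnotationSet, path) -> None:
    with open(path, "wt") as fh:
        for r in ann.records:
            fh.write(
                f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}\t"
                f"{r.gene_id}\t{r.biotype}\t{r.gene_name}\t{r.interval.strand}\n"
            )


def merge_intervals(
    intervals: Iterable[GenomicInterval], stranded: bool = True
) -> list[GenomicInterval]:
    """Coalesce overlapping or book-ended intervals.

    When ``stranded``, intervals merge only within a strand (bedtools
    ``merge -s`` semantics); otherwise strand is ignored and the result is
    unstranded.
    """
    def key(iv: GenomicInterval):
        return (iv.chrom, iv.strand if stranded else ".")

    by_group: dict[tuple[str, str], list[GenomicInterval]] = {}
    for iv in intervals:
        by_group.setdefault(key(iv), []).append(iv)

    out: list[GenomicInterval] = []
    for (chrom, strand), ivs in by_group.items():
        ivs.sort(key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:  # book-ended intervals coalesce
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_start, cur_end, strand))
                cur_start, cur_end = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_start, cur_end, strand))
    out.sort(key=lambda iv: (iv.chrom, iv.start, iv.end, iv.strand))
    return out


def merge_cross_cell_line(a: BindingSiteSet, b: BindingSiteSet) -> BindingSiteSet:
    """Strand-aware union of one RBP's two cell-line site sets.

    Same-strand overlapping or book-ended peaks coalesce; opposite-strand
    overlaps stay separate.  The result carries ``cell_line="merged"``.
    """
    if a.rbp != b.rbp:
        raise ValueError(f"cannot merge different RBPs: {a.rbp!r} vs {b.rbp!r}")
    merged = merge_intervals(list(a.sites) + list(b.sites), stranded=True)
    return BindingSiteSet(rbp=a.rbp, cell_line="merged", sites=merged)


def partition_union(sets: Sequence[BindingSiteSet]) -> list[Atom]:
    """Partition the union of all sites into atomic regions.

    An atom is a maximal interval over which the set of covering RBPs is
    constant (strand is ignored for membership, matching non-strand-specific
    sample-centric intersection).  Atoms are disjoint, sorted, and cover
    exactly the union of the inputs.  Two overlapping sites ``chr1:[0,10)``
    and ``chr1:[4,15)`` of RBPs A and B yield three atoms ``[0,4) {A}``,
    ``[4,10) {A,B}``, ``[10,15) {B}``.
    """
    if not sets:
        raise ValueError("partition_union needs at least one site set")
    events: dict[str, list[tuple[int, int, str]]] = {}
    for ss in sets:
        for s in ss.sites:
            events.setdefault(s.chrom, []).append((s.start, s.end, ss.rbp))

    atoms: list[Atom] = []
    for chrom in sorted(events):
        sites = events[chrom]
        bounds = sorted({p for s, e, _ in sites for p in (s, e)})
        # membership per elementary slice between consecutive boundaries
        prev_members: tuple[str, ...] | None = None
        run_start: int | None = None
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            members = tuple(sorted({r for s, e, r in sites if s <= lo and hi <= e}))
            if not members:
                if prev_members is not None:
                    atoms.append(
                        Atom(GenomicInterval(chrom, run_start, lo), prev_members)
                    )
                    prev_members, run_start = None, None
                continue
            if members != prev_members:
                if prev_members is not None:
                    atoms.append(
                        Atom(GenomicInterval(chrom, run_start, lo), prev_members)
                    )
                prev_members, run_start = members, lo
        if prev_members is not None:
            atoms.append(
                Atom(GenomicInterval(chrom, run_start, bounds[-1]), prev_members)
            )
    return atoms


def write_atoms(atoms: Sequence[Atom], path) -> None:
    """Write atoms as BED6; the name column holds member RBPs, semicolon-separated."""
    with open(path, "wt") as fh:
        for a in atoms:
            iv = a.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{';'.join(a.members)}\t0\t{iv.strand}\n"
            )


def region_set_inventory(
    rbps_line_a: Iterable[str], rbps_line_b: Iterable[str]
) -> list[tuple[str, str]]:
    """Enumerate the distinct (rbp, cell_line) region-set files the pipeline keeps.

    One set per RBP per cell line, plus one strand-aware merged set for every
    RBP profiled in both cell lines.  103 + 120 per-cell-line sets sharing 73
    RBPs therefore yield 296 files.
    """
    a, b = set(rbps_line_a), set(rbps_line_b)
    inventory = [(r, "lineA") for r in sorted(a)]
    inventory += [(r, "lineB") for r in sorted(b)]
    inventory += [(r, "merged") for r in sorted(a & b)]
    return inventory


def warn_if_disjoint_chroms(track: CoverageTrack, sites: BindingSiteSet) -> None:
    """Log a warning when track and sites share no chromosome names.

    Chromosome naming is taken verbatim; a naming mismatch yields zero
    overlap, which is legal but usually an input error.
    """
    track_chroms = set(track.chroms)
    site_chroms = {s.chrom for s in sites.sites}
    if track_chroms and site_chroms and not (track_chroms & site_chroms):
        warnings.warn(
            f"track {track.sample_id!r} and sites for {sites.rbp!r} share no "
            "chromosome names; counts will be zero",
            stacklevel=2,
        )
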