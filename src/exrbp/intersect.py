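"""Coverage × binding-site intersection: count matrices and strand accounting.

The read-count proxy for a region is an aggregate of per-base depth inside
it.  exRNA fragments and eCLIP peaks are shorter than a sequencing read, so
stacked identical fragments produce a depth equal to the number of reads;
the maximum per-base depth within a site is therefore used as the unique
read count by default (``operator="max"``; ``sum`` and ``mean`` are
available).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .genomic_io import (
    AnnotationSet,
    Atom,
    BindingSiteSet,
    CoverageTrack,
    GenomicInterval,
    partition_union,
    warn_if_disjoint_chroms,
)

Operator = Literal["max", "sum", "mean"]

__all__ = [
    "LocusCountMatrix",
    "SampleRBPMatrix",
    "count_site_reads",
    "build_rbp_matrix",
    "build_sample_matrix",
    "off_strand_percent",
    "annotate_loci",
]


@dataclass
class LocusCountMatrix:
    """Loci × samples read counts for one RBP (or for atomic regions)."""

    rbp: str
    loci: list[GenomicInterval]
    samples: list[str]
    counts: np.ndarray  # shape (n_loci, n_samples), non-negative ints

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.loci), len(self.samples)):
            raise ValueError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.loci)} loci x {len(self.samples)} samples"
            )
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("duplicate loci")

    def drop_zero_rows(self) -> "LocusCountMatrix":
        keep = self.counts.sum(axis=1) > 0
        return LocusCountMatrix(
            rbp=self.rbp,
            loci=[l for l, k in zip(self.loci, keep) if k],
            samples=list(self.samples),
            counts=self.counts[keep],
        )

    def subset_loci(self, indices: Sequence[int]) -> "LocusCountMatrix":
        idx = list(indices)
        return LocusCountMatrix(
            rbp=self.rbp,
            loci=[self.loci[i] for i in idx],
            samples=list(self.samples),
            counts=self.counts[idx],
        )


@dataclass
class SampleRBPMatrix:
    """Atomic regions × RBPs counts for one sample.

    An atom's count is zero for every RBP that is not a member of it.
    """

    sample_id: str
    atoms: list[Atom]
    rbp_columns: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.atoms), len(self.rbp_columns)):
            raise ValueError("atom matrix shape mismatch")
        col = {r: j for j, r in enumerate(self.rbp_columns)}
        for i, atom in enumerate(self.atoms):
            nonmember = [j for r, j in col.items() if r not in atom.members]
            if nonmember and self.counts[i, nonmember].any():
                raise ValueError(f"nonzero count for non-member RBP at atom {atom}")


class _DepthIndex:
    """Per-chromosome sorted depth arrays for fast interval queries."""

    def __init__(self, track: CoverageTrack):
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        buf: dict[str, list[tuple[int, int, int]]] = {}
        for iv, depth in track.intervals:
            buf.setdefault(iv.chrom, []).append((iv.start, iv.end, depth))
        for chrom, rows in buf.items():
            starts = np.array([r[0] for r in rows])
            ends = np.array([r[1] for r in rows])
            depths = np.array([r[2] for r in rows])
            self.by_chrom[chrom] = (starts, ends, depths)

    def aggregate(self, iv: GenomicInterval, operator: Operator) -> float:
        got = self.by_chrom.get(iv.chrom)
        if got is None:
            return 0
        starts, ends, depths = got
        lo = np.searchsorted(ends, iv.start, side="right")
        hi = np.searchsorted(starts, iv.end, side="left")
        if lo >= hi:
            return 0
        s = np.maximum(starts[lo:hi], iv.start)
        e = np.minimum(ends[lo:hi], iv.end)
        d = depths[lo:hi]
        if operator == "max":
            return int(d.max()) if d.size else 0
        covered = np.maximum(e - s, 0)
        total = int((covered * d).sum())
        if operator == "sum":
            return total
        return total / len(iv)  # mean over all bases of the site


def count_site_reads(
    track: CoverageTrack,
    sites: BindingSiteSet,
    operator: Operator = "max",
    warn_on_disjoint: bool = True,
) -> np.ndarray:
    """Per-site read-count proxy from one sample's coverage.

    Returns one value per site, in site order; zero where the track has no
    overlap.  Strand-specific counting is done by supplying a strand-split
    track and restricting ``sites`` to that strand (see
    :func:`off_strand_percent`).
    """
    if warn_on_disjoint:
        warn_if_disjoint_chroms(track, sites)
    index = _DepthIndex(track)
    out = np.array([index.aggregate(s, operator) for s in sites.sites])
    if operator in ("max", "sum"):
        out = out.astype(np.int64)
    return out


def build_rbp_matrix(
    tracks: Sequence[CoverageTrack],
    sites: BindingSiteSet,
    operator: Operator = "max",
    drop_zero_rows: bool = False,
) -> LocusCountMatrix:
    """Assemble the RBP-centric loci × samples count matrix.

    Column *s* is :func:`count_site_reads` of track *s*; loci keep site
    order.  ``drop_zero_rows`` removes loci with no reads in any sample
    (done by default downstream at cohort preparation).
    """
    if not tracks:
        raise ValueError("need at least one coverage track")
    ids = [t.sample_id for t in tracks]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate sample_id in tracks: {ids}")
    cols = [count_site_reads(t, sites, operator) for t in tracks]
    m = LocusCountMatrix(
        rbp=sites.rbp,
        loci=list(sites.sites),
        samples=ids,
        counts=np.column_stack(cols) if cols else np.zeros((len(sites.sites), 0)),
    )
    return m.drop_zero_rows() if drop_zero_rows else m


def build_sample_matrix(
    track: CoverageTrack,
    sets: Sequence[BindingSiteSet],
    operator: Operator = "max",
) -> SampleRBPMatrix:
    """Assemble the sample-centric atoms × RBPs matrix for one sample.

    Rows are the atomic partition of the union of all site sets; the entry
    for (atom, RBP) is the read-count proxy within the atom when the RBP is
    a member, else zero.
    """
    if not sets:
        raise ValueError("need at least one binding-site set")
    atoms = partition_union(sets)
    rbps = sorted({ss.rbp for ss in sets})
    index = _DepthIndex(track)
    counts = np.zeros((len(atoms), len(rbps)), dtype=np.int64)
    col = {r: j for j, r in enumerate(rbps)}
    for i, atom in enumerate(atoms):
        v = index.aggregate(atom.interval, operator)
        for r in atom.members:
            counts[i, col[r]] = v
    return SampleRBPMatrix(
        sample_id=track.sample_id, atoms=atoms, rbp_columns=rbps, counts=counts
    )


def off_strand_percent(
    track_plus: CoverageTrack,
    track_minus: CoverageTrack,
    sites: BindingSiteSet,
    operator: Operator = "max",
) -> float:
    """Percent of intersected signal attributable to the opposite strand.

    ``track_plus``/``track_minus`` are the strand-split coverage of one
    sample.  For every site, the stranded total uses only the track matching
    the site's strand while the unstranded total uses the combined coverage;
    the result is ``100 * (unstranded - stranded) / unstranded`` summed over
    sites.  Returns NaN (with a warning) when the unstranded total is zero.
    """
    plus_sites = BindingSiteSet(
        sites.rbp, sites.cell_line, [s for s in sites.sites if s.strand == "+"]
    )
    minus_sites = BindingSiteSet(
        sites.rbp, sites.cell_line, [s for s in sites.sites if s.strand == "-"]
    )
    stranded = int(
        count_site_reads(track_plus, plus_sites, operator, warn_on_disjoint=False).sum()
        + count_site_reads(track_minus, minus_sites, operator, warn_on_disjoint=False).sum()
    )

    # combined per-base coverage of the two strand tracks
    combined = _combine_tracks(track_plus, track_minus)
    unstranded = int(
        count_site_reads(combined, sites, operator, warn_on_disjoint=False).sum()
    )
    if unstranded == 0:
        warnings.warn("unstranded total is zero; off-strand percent undefined")
        return math.nan
    return 100.0 * (unstranded - stranded) / unstranded


def _combine_tracks(a: CoverageTrack, b: CoverageTrack) -> CoverageTrack:
    """Base-wise sum of two depth tracks."""
    events: dict[str, list[tuple[int, int, int]]] = {}
    for track in (a, b):
        for iv, depth in track.intervals:
            events.setdefault(iv.chrom, []).append((iv.start, iv.end, depth))
    intervals: list[tuple[GenomicInterval, int]] = []
    for chrom, rows in events.items():
        bounds = sorted({p for s, e, _ in rows for p in (s, e)})
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            depth = sum(d for s, e, d in rows if s <= lo and hi <= e)
            if depth > 0:
                intervals.append((GenomicInterval(chrom, lo, hi), depth))
    return CoverageTrack(sample_id=f"{a.sample_id}+{b.sample_id}", intervals=intervals)


def annotate_loci(
    sites: BindingSiteSet, ann: AnnotationSet
) -> tuple[list[list[str]], dict[str, int]]:
    """Biotypes of every annotation record overlapping each locus.

    Returns (per-locus biotype lists, per-biotype locus counts).  A locus
    overlapping records of several biotypes counts toward each of them; a
    locus overlapping nothing is labelled ``"unannotated"``.  Overlap is
    non-strand-specific, matching the annotation intersection of the
    pipeline.
    """
    per_locus: list[list[str]] = []
    counts: dict[str, int] = {}
    for locus in sites.sites:
        biotypes = sorted(
            {
                r.biotype
                for r in ann.records
                if r.interval.chrom == locus.chrom
                and r.interval.start < locus.end
                and locus.start < r.interval.end
            }
        )
        if not biotypes:
            biotypes = ["unannotated"]
        per_locus.append(biotypes)
        for b in biotypes:
            counts[b] = counts.get(b, 0) + 1
    return per_locus, counts
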