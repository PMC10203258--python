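"""Synthetic cohorts with planted ground truth for every pipeline stage.

The generator emulates the statistical structure the footprinting analysis
assumes: large sample-to-sample variation in the relative abundance of
exRNA carriers.  Counts of loci belonging to a planted (carried) RBP share
a per-sample latent carrier-abundance factor on the log scale; background
loci are independent with the same marginal scale, so coverage-matched null
sampling stays non-degenerate.  A fixed two-chromosome mini-genome (under
1 Mb) keeps per-base oracle checks tractable.

Count model for a planted RBP c, locus l, sample s:

    count = round(b_l * f(c, s) * eps),   f ~ LogNormal(0, latent_factor_sd^2),
                                          eps ~ LogNormal(0, noise_sd^2)

so the expected pairwise log-scale correlation between two loci of the same
carrier is latent_factor_sd^2 / (latent_factor_sd^2 + noise_sd^2).
Background loci use a single LogNormal(0, latent_factor_sd^2 + noise_sd^2)
factor, which matches the planted marginal mean exactly.

EV sample sets (four samples, as in an RBC-EV experiment) are generated
separately: a *consistent* RBP has one locus-abundance profile shared by
all samples up to near-equal library scales with Poisson counting noise;
an *inconsistent* RBP draws an independent abundance factor per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .carriers import CT_LABELS, RESULTS_MAPPING
from .genomic_io import (
    AnnotationRecord,
    AnnotationSet,
    BindingSiteSet,
    CoverageTrack,
    GenomicInterval,
)
from .intersect import LocusCountMatrix

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_sites",
    "simulate_cohort",
    "simulate_ct_profiles",
    "simulate_fraction_profiles",
    "simulate_ev_samples",
]

DEFAULT_BIOTYPES = ("miRNA", "tRNA", "snoRNA", "piRNA", "Y_RNA")

# rng stream offsets so each stage is independently deterministic per seed
_STREAM_SITES = 1
_STREAM_COHORT = 2
_STREAM_CT = 3
_STREAM_FRACTION = 4
_STREAM_EV = 5


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohorts.

    Defaults describe a plasma-scale cohort: 100 samples, 20 RBPs with 100
    binding loci each, 5 planted exRBPs whose loci share a latent carrier
    factor giving an expected pairwise log-scale correlation of
    0.8^2 / (0.8^2 + 0.6^2) = 0.64.
    """

    seed: int
    n_samples: int = 100
    n_rbps: int = 20
    loci_per_rbp: int = 100
    n_planted_exrbps: int = 5
    latent_factor_sd: float = 0.8
    noise_sd: float = 0.6
    baseline_count_mean: float = 20.0
    baseline_log_sd: float = 0.5
    overlap_fraction: float = 0.1
    biotype_labels: tuple[str, ...] = DEFAULT_BIOTYPES
    n_cts: int = 6
    # EV-study conditions (4 RBC-EV-like samples)
    n_ev_samples: int = 4
    n_ev_consistent: int = 10
    ev_mean_count: float = 30.0
    ev_locus_log_sd: float = 1.0
    ev_library_sd: float = 0.05
    ev_indep_sd: float = 0.8

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("n_samples", "n_rbps", "loci_per_rbp", "n_cts", "n_ev_samples"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0 <= self.overlap_fraction < 1):
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.latent_factor_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.n_planted_exrbps > self.n_rbps:
            raise ValueError("more planted exRBPs than RBPs")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])

    @property
    def rbp_names(self) -> list[str]:
        return [f"RBP{i + 1:03d}" for i in range(self.n_rbps)]

    @property
    def sample_names(self) -> list[str]:
        return [f"S{i + 1:03d}" for i in range(self.n_samples)]

    @property
    def expected_log_correlation(self) -> float:
        v = self.latent_factor_sd**2
        return v / (v + self.noise_sd**2) if v + self.noise_sd**2 > 0 else 0.0

    def to_flat(self) -> dict[str, str]:
        d = asdict(self)
        d["biotype_labels"] = ",".join(self.biotype_labels)
        return {k: str(v) for k, v in d.items()}


@dataclass
class GroundTruth:
    """Planted truth, sufficient to score every downstream stage."""

    planted_exrbps: list[str] = field(default_factory=list)
    locus_carrier: dict[GenomicInterval, str | None] = field(default_factory=dict)
    latent_factors: pd.DataFrame | None = None  # planted RBPs x samples
    ct_assignments: dict[str, tuple[str, ...]] = field(default_factory=dict)
    fraction_consistent: dict[str, bool] = field(default_factory=dict)
    ev_consistent_rbps: list[str] = field(default_factory=list)


def simulate_sites(
    config: SimulationConfig,
) -> tuple[list[BindingSiteSet], AnnotationSet]:
    """Lay out non-overlapping binding loci on a 2-chromosome mini-genome.

    A controlled fraction of each RBP's loci is shared verbatim with a
    partner RBP (consecutive pairs), exercising unique-locus removal.  Each
    locus receives one overlapping gene annotation record whose biotype is
    the RBP's preferred biotype with probability 0.7, uniform otherwise.
    Byte-identical output for a fixed seed.
    """
    rng = config.rng(_STREAM_SITES)
    n_shared = int(round(config.overlap_fraction * config.loci_per_rbp))
    if n_shared > 0 and config.n_rbps < 2:
        raise ValueError("overlap_fraction > 0 requires >= 2 RBPs")

    names = config.rbp_names
    # consecutive pairs share loci: (0,1), (2,3), ...
    partner = {}
    for i in range(0, config.n_rbps - 1, 2):
        partner[i] = i + 1

    n_private = config.loci_per_rbp - n_shared
    n_total = config.n_rbps * n_private + (config.n_rbps // 2) * n_shared
    # honour the overlap budget for unpaired trailing RBP
    if config.n_rbps % 2 == 1:
        n_total += n_shared  # its "shared" loci fall back to private

    # sequential layout with random gaps, split over two chromosomes
    lengths = rng.integers(20, 61, size=n_total)
    gaps = rng.integers(50, 201, size=n_total)
    strands = rng.choice(["+", "-"], size=n_total)
    half = (n_total + 1) // 2
    intervals: list[GenomicInterval] = []
    for chrom, idx in (("chrS1", range(half)), ("chrS2", range(half, n_total))):
        pos = 100
        for i in idx:
            start = pos + int(gaps[i])
            end = start + int(lengths[i])
            intervals.append(GenomicInterval(chrom, start, end, str(strands[i])))
            pos = end
    it = iter(intervals)

    site_lists: dict[str, list[GenomicInterval]] = {n: [] for n in names}
    for i, name in enumerate(names):
        priv = n_private if (i in partner or (i - 1) in partner) else config.loci_per_rbp
        for _ in range(priv):
            site_lists[name].append(next(it))
    for i, j in partner.items():
        for _ in range(n_shared):
            shared = next(it)
            site_lists[names[i]].append(shared)
            site_lists[names[j]].append(shared)

    sets = [
        BindingSiteSet(rbp=n, cell_line="merged", sites=site_lists[n]) for n in names
    ]

    preferred = {
        n: config.biotype_labels[i % len(config.biotype_labels)]
        for i, n in enumerate(names)
    }
    records: list[AnnotationRecord] = []
    gene_no = 0
    seen: set[GenomicInterval] = set()
    for ss in sets:
        for locus in ss.sites:
            if locus in seen:
                continue
            seen.add(locus)
            gene_no += 1
            if rng.random() < 0.7:
                biotype = preferred[ss.rbp]
            else:
                biotype = str(rng.choice(config.biotype_labels))
            pad = int(rng.integers(0, 10))
            iv = GenomicInterval(
                locus.chrom, max(0, locus.start - pad), locus.end + pad, locus.strand
            )
            records.append(
                AnnotationRecord(iv, f"G{gene_no:05d}", biotype, f"gene{gene_no}")
            )
    return sets, AnnotationSet(records=records)


def simulate_cohort(
    config: SimulationConfig,
    sites: Sequence[BindingSiteSet],
    tracks: bool = False,
) -> tuple[dict[str, LocusCountMatrix], GroundTruth, list[CoverageTrack]]:
    """Draw the loci x samples counts with planted carrier covariation.

    Private loci of the first ``n_planted_exrbps`` RBPs share that RBP's
    per-sample latent factor; loci shared between RBPs and all loci of
    non-planted RBPs are independent background with matching marginal
    scale.  With ``tracks=True`` also emits one bedGraph-ready
    CoverageTrack per sample in which each locus carries a constant depth
    equal to its count (fragments shorter than a read, stacked).
    """
    rng = config.rng(_STREAM_COHORT)
    names = config.rbp_names
    planted = names[: config.n_planted_exrbps]
    samples = config.sample_names

    # unique locus universe with owner lists
    owners: dict[GenomicInterval, list[str]] = {}
    for ss in sites:
        for locus in ss.sites:
            owners.setdefault(locus, []).append(ss.rbp)
    loci = sorted(owners, key=lambda l: (l.chrom, l.start, l.end))

    factors = pd.DataFrame(
        np.exp(rng.normal(0.0, config.latent_factor_sd, (len(planted), len(samples)))),
        index=planted,
        columns=samples,
    )
    total_sd = float(np.hypot(config.latent_factor_sd, config.noise_sd))

    counts: dict[GenomicInterval, np.ndarray] = {}
    carrier: dict[GenomicInterval, str | None] = {}
    for locus in loci:
        own = owners[locus]
        b = config.baseline_count_mean * float(
            np.exp(rng.normal(0.0, config.baseline_log_sd))
        )
        if len(own) == 1 and own[0] in planted:
            c = own[0]
            eps = np.exp(rng.normal(0.0, config.noise_sd, len(samples)))
            row = np.round(b * factors.loc[c].to_numpy() * eps)
            carrier[locus] = c
        else:
            eta = np.exp(rng.normal(0.0, total_sd, len(samples)))
            row = np.round(b * eta)
            carrier[locus] = None
        counts[locus] = row.astype(np.int64)

    matrices = {
        ss.rbp: LocusCountMatrix(
            rbp=ss.rbp,
            loci=list(ss.sites),
            samples=list(samples),
            counts=np.vstack([counts[l] for l in ss.sites]),
        )
        for ss in sites
    }
    truth = GroundTruth(
        planted_exrbps=list(planted),
        locus_carrier=carrier,
        latent_factors=factors,
    )

    track_list: list[CoverageTrack] = []
    if tracks:
        for j, sample in enumerate(samples):
            ivs = [
                (GenomicInterval(l.chrom, l.start, l.end), int(counts[l][j]))
                for l in loci
                if counts[l][j] > 0
            ]
            track_list.append(CoverageTrack(sample_id=sample, intervals=ivs))
    return matrices, truth, track_list


def simulate_ct_profiles(
    config: SimulationConfig,
    sites: Sequence[BindingSiteSet],
    truth: GroundTruth,
    contrast: float = 5.0,
    profile_noise_sd: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Per-RBP loci x CT average per-base coverage with planted CT assignments.

    Every RBP is assigned 1-3 cargo types (recorded in ``truth``); assigned
    CTs get ``(1 + contrast)`` times the baseline per-base coverage, others
    baseline leakage, both with mild multiplicative noise.  ``contrast=0``
    makes all enrichment scores 1.
    """
    rng = config.rng(_STREAM_CT)
    labels = list(CT_LABELS[: config.n_cts])
    out: dict[str, pd.DataFrame] = {}
    for ss in sites:
        if ss.rbp not in truth.ct_assignments:
            k = int(rng.integers(1, 4))
            assigned = tuple(sorted(str(c) for c in rng.choice(labels, size=k, replace=False)))
            truth.ct_assignments[ss.rbp] = assigned
        assigned = truth.ct_assignments[ss.rbp]
        base = np.exp(rng.normal(0.0, 0.3, len(ss.sites)))  # per-base coverage units
        data = {}
        for ct in labels:
            gain = 1.0 + contrast if ct in assigned else 1.0
            eps = (
                np.exp(rng.normal(0.0, profile_noise_sd, len(ss.sites)))
                if profile_noise_sd > 0
                else 1.0
            )
            data[ct] = base * gain * eps
        out[ss.rbp] = pd.DataFrame(
            data, index=[f"{l.chrom}:{l.start}-{l.end}" for l in ss.sites]
        )
    return out


def simulate_fraction_profiles(
    config: SimulationConfig,
    sites: Sequence[BindingSiteSet],
    truth: GroundTruth,
    mapping: dict[str, str] = RESULTS_MAPPING,
    consistent_fraction: float = 0.7,
    contrast: float = 5.0,
    profile_noise_sd: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Density-gradient fraction-class profiles concordant (or not) with the CTs.

    A ``consistent_fraction`` of RBPs get fraction-class enrichment in the
    classes their assigned CTs map to; the rest are planted discordant
    (enriched in classes their CTs do *not* map to).  ``truth`` records the
    planted consistency flags.
    """
    if not truth.ct_assignments:
        raise ValueError("run simulate_ct_profiles first (truth lacks CT assignments)")
    rng = config.rng(_STREAM_FRACTION)
    classes = sorted(set(mapping.values()))
    out: dict[str, pd.DataFrame] = {}
    for ss in sites:
        cts = truth.ct_assignments[ss.rbp]
        mapped = sorted({mapping["CT3" if ct.startswith("CT3") else ct] for ct in cts})
        consistent = bool(rng.random() < consistent_fraction)
        # exactly one enriched class: with k of 4 classes enriched the score
        # tops out at 4(1+c)/(k(1+c)+4-k), which for k >= 3 stays below 1.4
        if consistent:
            enriched_classes = [str(rng.choice(mapped))]
        else:
            complement = [c for c in classes if c not in mapped]
            if not complement:  # cannot plant discordance; fall back to consistent
                enriched_classes, consistent = [str(rng.choice(mapped))], True
            else:
                enriched_classes = [str(rng.choice(complement))]
        truth.fraction_consistent[ss.rbp] = consistent
        base = np.exp(rng.normal(0.0, 0.3, len(ss.sites)))
        data = {}
        for cls in classes:
            gain = 1.0 + contrast if cls in enriched_classes else 1.0
            eps = (
                np.exp(rng.normal(0.0, profile_noise_sd, len(ss.sites)))
                if profile_noise_sd > 0
                else 1.0
            )
            data[cls] = base * gain * eps
        out[ss.rbp] = pd.DataFrame(
            data, index=[f"{l.chrom}:{l.start}-{l.end}" for l in ss.sites]
        )
    return out


def simulate_ev_samples(
    config: SimulationConfig,
    sites: Sequence[BindingSiteSet],
    truth: GroundTruth,
    noise: bool = True,
) -> dict[str, LocusCountMatrix]:
    """Four-sample EV count matrices per RBP with planted consistency.

    Consistent RBPs (the first ``n_ev_consistent``) share one locus
    abundance profile across samples, scaled by near-equal library factors,
    with Poisson counting noise; inconsistent RBPs draw an independent
    log-normal abundance factor per sample and locus.  ``noise=False``
    disables both the library scatter and the Poisson draw, making
    consistent matrices exactly proportional (CV = 0).
    """
    rng = config.rng(_STREAM_EV)
    names = [ss.rbp for ss in sites]
    consistent = set(names[: config.n_ev_consistent])
    truth.ev_consistent_rbps = sorted(consistent)
    samples = [f"EV{i + 1}" for i in range(config.n_ev_samples)]
    out: dict[str, LocusCountMatrix] = {}
    for ss in sites:
        L = len(ss.sites)
        b = np.exp(
            rng.normal(np.log(config.ev_mean_count), config.ev_locus_log_sd, L)
        )
        if ss.rbp in consistent:
            if noise:
                s = np.exp(rng.normal(0.0, config.ev_library_sd, config.n_ev_samples))
                lam = b[:, None] * s[None, :]
                counts = rng.poisson(lam)
            else:
                counts = np.tile(np.round(b)[:, None], (1, config.n_ev_samples))
        else:
            eta = np.exp(
                rng.normal(0.0, config.ev_indep_sd, (L, config.n_ev_samples))
            )
            lam = b[:, None] * eta
            counts = rng.poisson(lam) if noise else np.round(lam)
        out[ss.rbp] = LocusCountMatrix(
            rbp=ss.rbp,
            loci=list(ss.sites),
            samples=samples,
            counts=counts.astype(np.int64),
        )
    return out
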