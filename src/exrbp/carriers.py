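"""Cargo-type (CT) enrichment of RBP-bound exRNA and fraction concordance.

Deconvolution of exRNA profiles yields six carrier cargo types (CT1
low-density vesicles, CT2 lipoproteins, CT3A/B/C ribonucleoprotein-like,
CT4 high-density vesicles).  For each RBP, the per-CT mean of per-base
locus coverage is divided by the unweighted grand mean over CTs, giving an
enrichment score whose row mean is exactly 1; scores at or above 1.4 mark
the RBP as enriched in that CT.  Density-gradient fraction classes provide
an independent assignment, and an RBP is "consistent" when the two agree
under the CT-to-fraction mapping.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_io import AnnotationSet, GenomicInterval

log = logging.getLogger(__name__)

CT_LABELS = ("CT1", "CT2", "CT3A", "CT3B", "CT3C", "CT4")

#: Results-text mapping of C-DGUC fraction classes to cargo types.
RESULTS_MAPPING = {
    "CT4": "fractions_1_3",
    "CT1": "fractions_4_7",
    "CT2": "fractions_9_12",
    "CT3": "unfractionated",
}
#: The Methods text states the opposite CT1/CT2 pairing; both are provided.
METHODS_MAPPING = {
    "CT4": "fractions_1_3",
    "CT2": "fractions_4_7",
    "CT1": "fractions_9_12",
    "CT3": "unfractionated",
}

DEFAULT_ENRICHMENT_THRESHOLD = 1.4

__all__ = [
    "CT_LABELS",
    "RESULTS_MAPPING",
    "METHODS_MAPPING",
    "DEFAULT_ENRICHMENT_THRESHOLD",
    "CargoTypeProfile",
    "ct_enrichment",
    "enrichment_table",
    "enrichment_percentile",
    "enriched_cts",
    "fraction_consistency",
    "biotype_ct_fraction",
]


@dataclass
class CargoTypeProfile:
    """Average per-base coverage of a set of loci in one cargo type.

    ``coverage[locus]`` is estimated reads divided by locus length, averaged
    over the CT's deconvolved profiles.
    """

    ct_label: str
    coverage: dict[GenomicInterval, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for locus, cov in self.coverage.items():
            if cov < 0:
                raise ValueError(f"negative coverage at {locus}")


def ct_enrichment(
    profiles: Sequence[CargoTypeProfile] | pd.DataFrame,
    rbp_loci: Sequence[GenomicInterval] | None = None,
) -> pd.Series | None:
    """Per-CT enrichment score for one RBP's loci.

    score(CT) = mean over loci of per-base coverage in that CT, divided by
    the unweighted mean over CTs of those per-CT means (the grand mean).
    The scores therefore average exactly 1 across CTs.  Returns ``None``
    (with a warning) when the grand mean is zero.

    ``profiles`` may be CargoTypeProfile objects or a loci x CTs DataFrame
    of per-base coverage.
    """
    if isinstance(profiles, pd.DataFrame):
        per_ct_mean = profiles.mean(axis=0)
    else:
        if len(profiles) < 2:
            raise ValueError("need at least 2 cargo types")
        if rbp_loci is None:
            raise ValueError("rbp_loci required with CargoTypeProfile inputs")
        if not rbp_loci:
            raise ValueError("need at least 1 locus")
        per_ct_mean = pd.Series(
            {
                p.ct_label: float(
                    np.mean([p.coverage.get(l, 0.0) for l in rbp_loci])
                )
                for p in profiles
            }
        )
    if len(per_ct_mean) < 2:
        raise ValueError("need at least 2 cargo types")
    grand = per_ct_mean.mean()
    if grand == 0:
        warnings.warn("zero grand-mean coverage; row dropped")
        return None
    return per_ct_mean / grand


def enrichment_table(
    per_rbp_profiles: Mapping[str, pd.DataFrame],
) -> pd.DataFrame:
    """RBPs x CTs enrichment scores; zero-coverage rows are dropped with a warning."""
    rows = {}
    for rbp, prof in per_rbp_profiles.items():
        score = ct_enrichment(prof)
        if score is not None:
            rows[rbp] = score
    return pd.DataFrame(rows).T.sort_index()


def enrichment_percentile(table: pd.DataFrame, q: float = 75.0) -> float:
    """Percentile of all enrichment scores (the published 75th was 1.34)."""
    return float(np.percentile(table.values.ravel(), q))


def enriched_cts(
    table: pd.DataFrame,
    threshold: float = DEFAULT_ENRICHMENT_THRESHOLD,
) -> tuple[dict[str, frozenset[str]], pd.Series]:
    """Threshold the enrichment table into per-RBP CT sets.

    A cell is enriched when score >= threshold (non-strict).  Returns each
    RBP's enriched-CT set and an upset-style count of RBPs per distinct set.
    """
    sets = {
        rbp: frozenset(table.columns[table.loc[rbp] >= threshold])
        for rbp in table.index
    }
    freq = (
        pd.Series([";".join(sorted(s)) for s in sets.values()])
        .value_counts()
        .sort_index()
    )
    return sets, freq


def fraction_consistency(
    ct_sets: Mapping[str, frozenset[str]],
    fraction_sets: Mapping[str, frozenset[str]],
    mapping: Mapping[str, str] = RESULTS_MAPPING,
) -> list[str]:
    """RBPs whose deconvolved CT assignment agrees with the fraction assignment.

    An RBP is consistent when at least one of its enriched CTs maps (via
    ``mapping``; CT3A/B/C collapse onto CT3) to one of its enriched fraction
    classes.  Raises when the mapping misses a CT present in the data.
    """
    def fraction_of(ct: str) -> str:
        key = "CT3" if ct.startswith("CT3") else ct
        if key not in mapping:
            raise ValueError(f"mapping has no entry for cargo type {ct}")
        return mapping[key]

    consistent = []
    for rbp in sorted(set(ct_sets) & set(fraction_sets)):
        mapped = {fraction_of(ct) for ct in ct_sets[rbp]}
        if mapped & set(fraction_sets[rbp]):
            consistent.append(rbp)
    return consistent


def _unique_bases(intervals: Sequence[GenomicInterval]) -> int:
    """Total bases covered by the union of intervals (strand-blind)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    total = 0
    for spans in by_chrom.values():
        spans.sort()
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
        total += cur_e - cur_s
    return total


def biotype_ct_fraction(
    studies: Mapping[str, tuple[np.ndarray, pd.DataFrame]],
    loci: Sequence[GenomicInterval],
    ann: AnnotationSet,
    expressed_cutoff: float = 5,
    ct_cutoff: float = 2,
    alpha: float = 0.05,
):
    """Fraction of each biotype's gene bases bound by RBPs, per CT, with tests.

    ``studies`` maps study id to ``(raw_counts, ct_estimates)`` where
    ``raw_counts`` is loci x samples raw reads (the ``expressed_cutoff``
    requires >= 5 reads in at least one sample) and ``ct_estimates`` is a
    loci x CT DataFrame of deconvolved counts (a locus is expressed in a CT
    when its estimate is >= ``ct_cutoff``).

    For each (study, CT, biotype): fraction = unique bases of genes whose
    transcripts pass both cutoffs and overlap an RBP-bound locus, divided by
    unique bases of all genes of that biotype.  Per biotype, a
    Kruskal-Wallis omnibus test across CTs uses studies as replicates;
    where omnibus p < alpha, pairwise rank-sum tests follow with Holm
    adjustment.

    Returns ``(fractions, omnibus, pairwise)`` DataFrames.
    """
    from statsmodels.stats.multitest import multipletests

    loci = list(loci)
    biotypes = ann.biotypes()
    # gene universe per biotype and gene interval lists
    genes_by_biotype: dict[str, dict[str, list[GenomicInterval]]] = {}
    for r in ann.records:
        genes_by_biotype.setdefault(r.biotype, {}).setdefault(r.gene_id, []).append(
            r.interval
        )

    # which genes overlap which loci (non-strand-specific)
    def gene_overlaps_locus(gene_ivs: list[GenomicInterval], locus: GenomicInterval):
        return any(
            g.chrom == locus.chrom and g.start < locus.end and locus.start < g.end
            for g in gene_ivs
        )

    frac_rows = []
    for study, (raw_counts, ct_est) in studies.items():
        raw_counts = np.asarray(raw_counts)
        expressed = (raw_counts >= expressed_cutoff).any(axis=1)
        for ct in ct_est.columns:
            in_ct = expressed & (ct_est[ct].to_numpy() >= ct_cutoff)
            active = [l for l, keep in zip(loci, in_ct) if keep]
            for biotype in biotypes:
                genes = genes_by_biotype.get(biotype, {})
                if not genes:
                    continue
                bound_ivs = [
                    iv
                    for gene_ivs in genes.values()
                    if any(gene_overlaps_locus(gene_ivs, l) for l in active)
                    for iv in gene_ivs
                ]
                denom = _unique_bases(
                    [iv for gene_ivs in genes.values() for iv in gene_ivs]
                )
                num = _unique_bases(bound_ivs) if bound_ivs else 0
                frac_rows.append(
                    {
                        "study": study,
                        "ct": ct,
                        "biotype": biotype,
                        "fraction": num / denom if denom else 0.0,
                    }
                )
    fractions = pd.DataFrame(frac_rows)

    omni_rows, pair_rows = [], []
    for biotype, grp in fractions.groupby("biotype"):
        groups = [g["fraction"].to_numpy() for _, g in grp.groupby("ct")]
        cts = sorted(grp["ct"].unique())
        if len(groups) < 2 or np.ptp(np.concatenate(groups)) == 0:
            # identical values across all CTs: no association detectable
            omni_rows.append({"biotype": biotype, "kw_p": 1.0, "significant": False})
            continue
        try:
            kw = stats.kruskal(*groups)
            kw_p = float(kw.pvalue)
        except ValueError:  # all numbers identical
            kw_p = 1.0
        sig = kw_p < alpha
        omni_rows.append({"biotype": biotype, "kw_p": kw_p, "significant": sig})
        if sig:
            pairs, pvals = [], []
            for i in range(len(cts)):
                for j in range(i + 1, len(cts)):
                    a = grp.loc[grp["ct"] == cts[i], "fraction"].to_numpy()
                    b = grp.loc[grp["ct"] == cts[j], "fraction"].to_numpy()
                    stat = stats.ranksums(a, b)
                    pairs.append((cts[i], cts[j]))
                    pvals.append(float(stat.pvalue))
            adj = multipletests(pvals, method="holm")[1]
            for (a, b), p_raw, p_adj in zip(pairs, pvals, adj):
                pair_rows.append(
                    {
                        "biotype": biotype,
                        "ct_a": a,
                        "ct_b": b,
                        "raw_p": p_raw,
                        "holm_p": float(p_adj),
                    }
                )
    omnibus = pd.DataFrame(omni_rows, columns=["biotype", "kw_p", "significant"])
    pairwise = pd.DataFrame(
        pair_rows, columns=["biotype", "ct_a", "ct_b", "raw_p", "holm_p"]
    )
    return fractions, omnibus, pairwise
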