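"""Correlation footprinting: the two-stage Kolmogorov-Smirnov exRBP test.

The premise is that sample-to-sample variation in the relative abundance of
exRNA carriers makes the loci bound by one carried RBP covary across
samples.  For each locus of an RBP, the distribution of its Pearson
correlations with the RBP's other loci is compared (two-sample KS) with the
correlations of a coverage-matched locus drawn from a different RBP.  The
per-locus KS p-values are then aggregated per RBP: they are compared, with
a one-sided two-sample KS, against mirror p-values computed on the matched
null loci themselves, and the RBP is called when its p-values are
stochastically smaller (Bonferroni-adjusted across the RBPs tested in the
run).

All KS p-values use the asymptotic approximation; correlations are Pearson
on raw counts.  Loci with zero variance across samples carry no correlation
signal and are excluded from both the true and the null pools.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .genomic_io import AnnotationSet, BindingSiteSet, GenomicInterval
from .intersect import LocusCountMatrix, annotate_loci

log = logging.getLogger(__name__)

#: the published screening grid: (min_samples, min_coverage)
DEFAULT_FILTER_GRID = ((30, 5), (20, 5), (10, 5), (30, 2), (20, 2), (10, 2))

__all__ = [
    "FilterSpec",
    "NullMatch",
    "LocusFootprint",
    "RBPFootprint",
    "DEFAULT_FILTER_GRID",
    "prepare_cohort",
    "locus_coverage",
    "select_matched_null",
    "locus_footprint_pvalue",
    "rbp_footprint_test",
    "footprint_screen",
    "biotype_footprint",
]


@dataclass(frozen=True)
class FilterSpec:
    """Locus filter: keep loci with >= min_coverage reads in >= min_samples samples."""

    min_samples: int
    min_coverage: int

    def __post_init__(self) -> None:
        if self.min_samples < 1 or self.min_coverage < 1:
            raise ValueError("filter thresholds must be >= 1")

    def __str__(self) -> str:
        return f"{self.min_samples}:{self.min_coverage}"

    def mask(self, counts: np.ndarray) -> np.ndarray:
        """Boolean row mask of loci passing the filter."""
        return (counts >= self.min_coverage).sum(axis=1) >= self.min_samples


@dataclass(frozen=True)
class NullMatch:
    """A coverage-matched negative-control locus from a different RBP."""

    locus: GenomicInterval
    matched_null: GenomicInterval
    target_coverage: int
    matched_coverage: int
    pool_index: int
    exhausted: bool  # |delta| > 1: the preferred +-1 fallback was not enough

    @property
    def delta(self) -> int:
        return self.matched_coverage - self.target_coverage


@dataclass(frozen=True)
class LocusFootprint:
    locus: GenomicInterval
    ks_statistic: float
    p_value: float
    n_correlations: int


@dataclass
class RBPFootprint:
    """Aggregated footprint decision for one RBP in one cohort/filter run."""

    rbp: str
    fluid_or_cohort: str
    filter: FilterSpec | None
    n_loci: int
    ks_statistic: float
    raw_p: float
    bonferroni_p: float
    direction_ok: bool
    called: bool
    locus_footprints: list[LocusFootprint] = field(default_factory=list)
    null_pvalues: list[float] = field(default_factory=list)


def prepare_cohort(
    matrices: dict[str, LocusCountMatrix], unique_only: bool = True
) -> dict[str, LocusCountMatrix]:
    """Filter per-RBP matrices before footprinting.

    When ``unique_only``, loci overlapping any other RBP's loci are removed
    from every matrix (regions bound by multiple RBPs are not RBP-specific).
    Rows with no reads in any sample are always dropped.
    """
    if not matrices:
        raise ValueError("empty cohort")
    sample_sets = {tuple(m.samples) for m in matrices.values()}
    if len(sample_sets) != 1:
        raise ValueError("all matrices must share the same sample set")

    out: dict[str, LocusCountMatrix] = {}
    for rbp, m in matrices.items():
        if unique_only:
            others = [
                l for other, om in matrices.items() if other != rbp for l in om.loci
            ]
            by_chrom: dict[str, list[GenomicInterval]] = {}
            for l in others:
                by_chrom.setdefault(l.chrom, []).append(l)
            keep = [
                i
                for i, locus in enumerate(m.loci)
                if not any(
                    o.start < locus.end and locus.start < o.end
                    for o in by_chrom.get(locus.chrom, ())
                )
            ]
            m = m.subset_loci(keep)
        out[rbp] = m.drop_zero_rows()
    return out


def locus_coverage(matrix: LocusCountMatrix, locus_index: int) -> int:
    """Total read count of one locus summed across samples (null-matching scalar)."""
    return int(matrix.counts[locus_index].sum())


def select_matched_null(
    target_coverage: int,
    pool_coverages: np.ndarray,
    rng: np.random.Generator,
) -> tuple[int, bool]:
    """Pick a pool index with coverage matching the target.

    Exact match first; otherwise coverage ``target+1`` (or ``target-1`` when
    no pool locus has greater coverage at all); the fallback chain extends
    +-2, +-3, ...  Returns ``(index, exhausted)`` where ``exhausted`` flags
    |delta| > 1.  Ties break uniformly at random under ``rng``.
    """
    pool_coverages = np.asarray(pool_coverages)
    if pool_coverages.size == 0:
        raise ValueError("empty null pool")
    exact = np.flatnonzero(pool_coverages == target_coverage)
    if exact.size:
        return int(rng.choice(exact)), False
    has_greater = bool((pool_coverages > target_coverage).any())
    delta = 1
    while True:
        if has_greater:
            up = np.flatnonzero(pool_coverages == target_coverage + delta)
            if up.size:
                if delta > 1:
                    log.info("null match exhausted: delta=+%d", delta)
                return int(rng.choice(up)), delta > 1
        down = np.flatnonzero(pool_coverages == target_coverage - delta)
        if down.size:
            if delta > 1:
                log.info("null match exhausted: delta=-%d", delta)
            return int(rng.choice(down)), delta > 1
        delta += 1


def _ks_asymp(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    res = stats.ks_2samp(x, y, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


def _pearson_rows(counts: np.ndarray) -> np.ndarray:
    """Row-by-row Pearson correlation matrix of a counts block."""
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.corrcoef(counts.astype(float))


def locus_footprint_pvalue(
    matrix: LocusCountMatrix,
    locus_index: int,
    null_counts: np.ndarray,
) -> LocusFootprint:
    """Two-sample KS comparing within-RBP and against-null correlation distributions.

    Distribution 1: Pearson r between the test locus and every *other* locus
    of the RBP.  Distribution 2: Pearson r between the coverage-matched null
    locus and *all* loci of the RBP.  Raises ``ValueError`` for
    zero-variance loci or when fewer than 3 usable correlations exist; the
    caller skips such loci with a logged reason.
    """
    counts = matrix.counts.astype(float)
    x = counts[locus_index]
    if np.ptp(x) == 0:
        raise ValueError(f"zero-variance locus {matrix.loci[locus_index]}")
    null_counts = np.asarray(null_counts, dtype=float)
    if np.ptp(null_counts) == 0:
        raise ValueError("zero-variance null locus")
    others = np.delete(np.arange(len(matrix.loci)), locus_index)
    usable = [i for i in others if np.ptp(counts[i]) > 0]
    if len(usable) < 3:
        raise ValueError("fewer than 3 usable correlations")
    block = counts[usable]
    r_true = _corr_one_vs_block(x, block)
    r_null = _corr_one_vs_block(null_counts, np.vstack([block, x[None, :]]))
    d, p = _ks_asymp(r_true, r_null)
    return LocusFootprint(
        locus=matrix.loci[locus_index],
        ks_statistic=d,
        p_value=p,
        n_correlations=len(r_true),
    )


def _corr_one_vs_block(x: np.ndarray, block: np.ndarray) -> np.ndarray:
    xc = x - x.mean()
    bc = block - block.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc**2).sum() * (bc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (bc @ xc) / denom


def rbp_footprint_test(
    matrix: LocusCountMatrix,
    pool_counts: np.ndarray,
    pool_loci: Sequence[GenomicInterval] | None = None,
    rng: np.random.Generator | None = None,
    min_loci: int = 10,
    alpha: float = 0.05,
    label: str = "cohort",
    filter_spec: FilterSpec | None = None,
) -> RBPFootprint:
    """Aggregate per-locus footprint evidence into one RBP-level decision.

    For every usable locus a coverage-matched null locus is drawn from
    ``pool_counts`` (loci of other RBPs; rows x samples).  Per-locus KS
    p-values ``p_i`` are computed as in :func:`locus_footprint_pvalue`;
    mirror p-values ``q_i`` apply the identical construction with the roles
    swapped (each null locus against the other matched nulls, the true locus
    as its outsider).  The RBP-level raw p is a one-sided two-sample KS
    testing whether {p_i} is stochastically smaller than {q_i};
    ``direction_ok`` additionally requires median(p) < median(q).
    ``bonferroni_p`` is initialised to ``raw_p``; a screening caller rescales
    it by the number of RBPs in the run.
    """
    if rng is None:
        rng = np.random.default_rng()
    counts = matrix.counts.astype(float)
    pool_counts = np.asarray(pool_counts, dtype=float)
    if pool_counts.size == 0:
        raise ValueError(f"{matrix.rbp}: empty null pool")

    usable = [i for i in range(len(matrix.loci)) if np.ptp(counts[i]) > 0]
    skipped = len(matrix.loci) - len(usable)
    if skipped:
        log.info("%s: %d zero-variance loci skipped", matrix.rbp, skipped)
    if len(usable) < min_loci:
        raise ValueError(
            f"{matrix.rbp}: only {len(usable)} usable loci (< min_loci={min_loci})"
        )

    pool_usable = np.flatnonzero(np.ptp(pool_counts, axis=1) > 0)
    if pool_usable.size == 0:
        raise ValueError(f"{matrix.rbp}: null pool has no variable loci")
    pool_counts = pool_counts[pool_usable]
    pool_cov = pool_counts.sum(axis=1).astype(np.int64)

    true = counts[usable]
    L = len(usable)
    null_rows = np.empty(L, dtype=np.int64)
    for j, i in enumerate(usable):
        target = int(counts[i].sum())
        idx, _ = select_matched_null(target, pool_cov, rng)
        null_rows[j] = idx
    nulls = pool_counts[null_rows]

    C = _pearson_rows(np.vstack([true, nulls]))
    T, N, TN = C[:L, :L], C[L:, L:], C[:L, L:]

    p_true = np.empty(L)
    p_null = np.empty(L)
    d_true = np.empty(L)
    for j in range(L):
        r_in = np.delete(T[j], j)       # locus j vs other true loci
        r_out = TN[:, j]                # its matched null vs all true loci
        d_true[j], p_true[j] = _ks_asymp(r_in, r_out)
        r_in_n = np.delete(N[j], j)     # matched null j vs other matched nulls
        r_out_n = TN[j, :]              # true locus j vs all matched nulls
        _, p_null[j] = _ks_asymp(r_in_n, r_out_n)

    res = stats.ks_2samp(p_true, p_null, alternative="greater", method="asymp")
    raw_p = float(res.pvalue)
    direction_ok = bool(np.median(p_true) < np.median(p_null))
    footprints = [
        LocusFootprint(matrix.loci[i], float(d_true[j]), float(p_true[j]), L - 1)
        for j, i in enumerate(usable)
    ]
    return RBPFootprint(
        rbp=matrix.rbp,
        fluid_or_cohort=label,
        filter=filter_spec,
        n_loci=L,
        ks_statistic=float(res.statistic),
        raw_p=raw_p,
        bonferroni_p=raw_p,
        direction_ok=direction_ok,
        called=bool(raw_p < alpha and direction_ok),
        locus_footprints=footprints,
        null_pvalues=list(map(float, p_null)),
    )


def footprint_screen(
    cohort: dict[str, LocusCountMatrix],
    alpha: float = 0.05,
    filters: Sequence[tuple[int, int]] = DEFAULT_FILTER_GRID,
    seed: int | np.random.Generator = 0,
    min_loci: int = 10,
    label: str = "cohort",
):
    """Run the footprint test for every RBP under each filter of the grid.

    Within one (cohort, filter) run the Bonferroni family is the set of RBPs
    actually tested in that run.  An RBP is *called* when it is significant
    (adjusted p < alpha with the correct direction) in at least one filter
    set; the summary reports each RBP's best (smallest adjusted p) filter.

    Returns ``(table, summary)`` pandas DataFrames: one row per (RBP,
    filter) tested, and one row per RBP.
    """
    import pandas as pd

    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    specs = [f if isinstance(f, FilterSpec) else FilterSpec(*f) for f in filters]
    rows = []
    for spec in specs:
        filtered: dict[str, LocusCountMatrix] = {}
        for rbp in sorted(cohort):
            m = cohort[rbp]
            keep = np.flatnonzero(spec.mask(m.counts))
            if keep.size >= min_loci:
                filtered[rbp] = m.subset_loci(keep)
        results: list[RBPFootprint] = []
        for rbp in sorted(filtered):
            pool = np.vstack(
                [filtered[o].counts for o in sorted(filtered) if o != rbp]
            ) if len(filtered) > 1 else np.empty((0, 0))
            try:
                res = rbp_footprint_test(
                    filtered[rbp],
                    pool,
                    rng=rng,
                    min_loci=min_loci,
                    alpha=alpha,
                    label=label,
                    filter_spec=spec,
                )
            except ValueError as exc:
                log.info("filter %s: %s", spec, exc)
                continue
            results.append(res)
        n_tested = len(results)
        for res in results:
            res.bonferroni_p = min(1.0, res.raw_p * n_tested)
            res.called = bool(res.bonferroni_p < alpha and res.direction_ok)
            rows.append(
                {
                    "rbp": res.rbp,
                    "cohort": label,
                    "filter": str(res.filter),
                    "n_loci": res.n_loci,
                    "D": res.ks_statistic,
                    "raw_p": res.raw_p,
                    "bonferroni_p": res.bonferroni_p,
                    "direction_ok": res.direction_ok,
                    "called": res.called,
                }
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "rbp", "cohort", "filter", "n_loci", "D",
            "raw_p", "bonferroni_p", "direction_ok", "called",
        ],
    )
    if table.empty:
        log.warning("no RBP testable under any filter")
        summary = pd.DataFrame(
            columns=["rbp", "cohort", "called", "best_filter", "best_bonferroni_p"]
        )
        return table, summary
    best = table.loc[table.groupby("rbp")["bonferroni_p"].idxmin()]
    summary = pd.DataFrame(
        {
            "rbp": best["rbp"].values,
            "cohort": label,
            "called": table.groupby("rbp")["called"].any().reindex(best["rbp"]).values,
            "best_filter": best["filter"].values,
            "best_bonferroni_p": best["bonferroni_p"].values,
        }
    ).sort_values("rbp").reset_index(drop=True)
    return table, summary


def biotype_footprint(
    cohort: dict[str, LocusCountMatrix],
    sites: dict[str, BindingSiteSet],
    ann: AnnotationSet,
    biotypes: Sequence[str] | None = None,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
    min_loci: int = 10,
    label: str = "cohort",
):
    """Footprint test restricted to loci of one biotype at a time.

    For each (RBP, biotype) with at least ``min_loci`` loci overlapping the
    biotype's annotation, the standard per-RBP procedure runs on the subset;
    Bonferroni spans the (RBP, biotype) pairs tested per biotype.  Pairs
    with too few loci are skipped.  Returns a pandas DataFrame.
    """
    import pandas as pd

    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if biotypes is None:
        biotypes = ann.biotypes()
    rows = []
    for biotype in biotypes:
        subset: dict[str, LocusCountMatrix] = {}
        for rbp in sorted(cohort):
            m = cohort[rbp]
            locus_biotypes, _ = annotate_loci(
                BindingSiteSet(rbp, "any", [
                    GenomicInterval(l.chrom, l.start, l.end, l.strand if l.strand != "." else "+")
                    for l in m.loci
                ]),
                ann,
            )
            keep = [i for i, bts in enumerate(locus_biotypes) if biotype in bts]
            if len(keep) >= min_loci:
                subset[rbp] = m.subset_loci(keep)
            else:
                log.info("%s/%s: %d loci (< %d), skipped", rbp, biotype, len(keep), min_loci)
        results = []
        for rbp in sorted(subset):
            pool = np.vstack(
                [subset[o].counts for o in sorted(subset) if o != rbp]
            ) if len(subset) > 1 else np.empty((0, 0))
            try:
                res = rbp_footprint_test(
                    subset[rbp], pool, rng=rng, min_loci=min_loci,
                    alpha=alpha, label=label,
                )
            except ValueError as exc:
                log.info("%s/%s: %s", rbp, biotype, exc)
                continue
            results.append(res)
        for res in results:
            res.bonferroni_p = min(1.0, res.raw_p * len(results))
            res.called = bool(res.bonferroni_p < alpha and res.direction_ok)
            rows.append(
                {
                    "rbp": res.rbp,
                    "biotype": biotype,
                    "n_loci": res.n_loci,
                    "D": res.ks_statistic,
                    "raw_p": res.raw_p,
                    "bonferroni_p": res.bonferroni_p,
                    "called": res.called,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["rbp", "biotype", "n_loci", "D", "raw_p", "bonferroni_p", "called"],
    )
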