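"""Small-cohort EV analysis: pooled-CV statistic with a permutation null.

With only four EV samples, pairwise correlation footprinting is
underpowered, so consistency of an RBP's locus profile across samples is
tested instead.  For every locus and every unordered sample pair the
absolute count difference is formed; the statistic is the coefficient of
variation CV = (sd / mean) x 100 over the pooled differences.  A
proportionally consistent RBP (same locus profile in every sample, up to
library scale and counting noise) yields differences that scale with the
square root of locus abundance and hence a *low* CV relative to the null.

The null distribution permutes each sample column independently across
loci, destroying the cross-sample alignment of locus profiles while
preserving every sample's marginal counts.  (Permuting within a locus row
would leave the pooled multiset of pairwise differences — and therefore the
CV — unchanged, so it cannot serve as a null.)  The p-value is lower-tail
with the +1 permutation floor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .intersect import LocusCountMatrix

__all__ = [
    "CVResult",
    "filter_ev_rbps",
    "cv_statistic",
    "permutation_pvalue",
    "random_locus_sets",
    "cohort_fdr",
]

MIN_EV_LOCI = 15


@dataclass(frozen=True)
class CVResult:
    rbp: str
    cv_observed: float
    p_value: float
    n_perm: int
    significant: bool
    randomized: bool = False

    def __post_init__(self) -> None:
        floor = 1.0 / (self.n_perm + 1)
        if not (floor - 1e-12 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [{floor}, 1]")


def _eligible_rows(counts: np.ndarray, min_samples_nonzero: int = 2) -> np.ndarray:
    return (counts > 0).sum(axis=1) >= min_samples_nonzero


def filter_ev_rbps(
    matrices: Mapping[str, LocusCountMatrix],
    min_loci: int = MIN_EV_LOCI,
    min_samples_nonzero: int = 2,
) -> dict[str, LocusCountMatrix]:
    """Keep loci with reads in >= 2 samples, then RBPs with >= 15 such loci."""
    sample_sets = {tuple(m.samples) for m in matrices.values()}
    if len(sample_sets) > 1:
        raise ValueError("EV matrices must share the sample set")
    out = {}
    for rbp, m in matrices.items():
        keep = np.flatnonzero(_eligible_rows(m.counts, min_samples_nonzero))
        if keep.size >= min_loci:
            out[rbp] = m.subset_loci(keep)
    return out


def _pair_differences(counts: np.ndarray) -> np.ndarray:
    """|x(l,s) - x(l,t)| pooled over loci and unordered sample pairs."""
    s, t = np.triu_indices(counts.shape[1], k=1)
    return np.abs(counts[:, s] - counts[:, t]).ravel().astype(float)


def cv_statistic(counts: np.ndarray) -> float:
    """Pooled coefficient of variation of pairwise sample differences, in percent.

    Four samples give 6 unordered pairs, so L loci pool 6L differences.
    Defined as 0 (with a warning) when every difference is zero — perfectly
    identical samples.
    """
    counts = np.asarray(counts)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("need >= 2 loci and >= 2 samples")
    d = _pair_differences(counts)
    mu = d.mean()
    if mu == 0:
        warnings.warn("all pairwise differences are zero; CV defined as 0")
        return 0.0
    return float(d.std(ddof=1) / mu * 100.0)


def permutation_pvalue(
    matrix: LocusCountMatrix | np.ndarray,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    alpha: float = 0.05,
    rbp: str | None = None,
    randomized: bool = False,
) -> CVResult:
    """Lower-tail permutation p-value for cross-sample consistency.

    p = (1 + #{CV_null <= CV_obs}) / (n_perm + 1); significant iff p < alpha.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if isinstance(matrix, LocusCountMatrix):
        counts = matrix.counts
        rbp = rbp or matrix.rbp
    else:
        counts = np.asarray(matrix)
        rbp = rbp or "?"
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    obs = cv_statistic(counts)
    L, S = counts.shape
    hits = 0
    for _ in range(n_perm):
        perm = np.empty_like(counts)
        for j in range(S):
            perm[:, j] = counts[rng.permutation(L), j]
        if cv_statistic_quiet(perm) <= obs:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return CVResult(
        rbp=rbp,
        cv_observed=obs,
        p_value=p,
        n_perm=n_perm,
        significant=bool(p < alpha),
        randomized=randomized,
    )


def cv_statistic_quiet(counts: np.ndarray) -> float:
    d = _pair_differences(counts)
    mu = d.mean()
    return 0.0 if mu == 0 else float(d.std(ddof=1) / mu * 100.0)


def random_locus_sets(
    matrices: Mapping[str, LocusCountMatrix],
    seed: int | np.random.Generator = 0,
) -> dict[str, np.ndarray]:
    """Size-matched random control sets: for each RBP, an equally sized set of
    loci drawn uniformly (without replacement) from all other RBPs' eligible loci."""
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    out = {}
    names = sorted(matrices)
    for rbp in names:
        pool = np.vstack([matrices[o].counts for o in names if o != rbp])
        size = matrices[rbp].counts.shape[0]
        idx = rng.choice(pool.shape[0], size=min(size, pool.shape[0]), replace=False)
        out[rbp] = pool[idx]
    return out


def cohort_fdr(
    true_results: Sequence[CVResult],
    random_results: Sequence[CVResult],
    alpha: float = 0.05,
) -> dict:
    """Randomized-set FDR estimate plus a KS comparison of p-value distributions.

    fdr_percent = 100 * (#significant randomized sets) / (#significant true
    sets); e.g. 15 significant random sets against 50 significant true sets
    estimate a 30% FDR.  ``ks_p`` is a two-sample KS test between the true
    and randomized p-value distributions.  fdr is NaN when no true set is
    significant.
    """
    n_sig_true = sum(r.significant for r in true_results)
    n_sig_random = sum(r.significant for r in random_results)
    if n_sig_true == 0:
        warnings.warn("no significant true sets; FDR undefined")
        fdr = float("nan")
    else:
        fdr = 100.0 * n_sig_random / n_sig_true
    p_true = [r.p_value for r in true_results]
    p_rand = [r.p_value for r in random_results]
    if p_true and p_rand:
        ks_p = float(stats.ks_2samp(p_true, p_rand, method="asymp").pvalue)
    else:
        ks_p = float("nan")
    return {
        "n_sig_true": n_sig_true,
        "n_sig_random": n_sig_random,
        "fdr_percent": fdr,
        "ks_p": ks_p,
    }
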