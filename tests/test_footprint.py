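"""Correlation-footprint procedure: filters, null matching, KS stages."""

import numpy as np
import pytest

from exrbp import (
    FilterSpec,
    GenomicInterval,
    LocusCountMatrix,
    biotype_footprint,
    footprint_screen,
    locus_footprint_pvalue,
    prepare_cohort,
    rbp_footprint_test,
    select_matched_null,
    simulate_cohort,
    simulate_sites,
)
from exrbp.footprint import locus_coverage


def matrix(counts, rbp="X", chrom="chr1"):
    counts = np.asarray(counts)
    loci = [
        GenomicInterval(chrom, 100 * i, 100 * i + 30, "+")
        for i in range(counts.shape[0])
    ]
    samples = [f"s{j}" for j in range(counts.shape[1])]
    return LocusCountMatrix(rbp=rbp, loci=loci, samples=samples, counts=counts)


class TestPrepareCohort:
    def test_shared_locus_removed_from_both(self, small_study):
        cohort = prepare_cohort(small_study["matrices"], unique_only=True)
        all_loci = [
            (rbp, (l.chrom, l.start, l.end))
            for rbp, m in cohort.items()
            for l in m.loci
        ]
        coords = [c for _, c in all_loci]
        assert len(coords) == len(set(coords))

    def test_pass_through_keeps_shared(self, small_study):
        keep = prepare_cohort(small_study["matrices"], unique_only=False)
        drop = prepare_cohort(small_study["matrices"], unique_only=True)
        for rbp in keep:
            assert len(keep[rbp].loci) >= len(drop[rbp].loci)

    def test_counted_removal(self):
        shared = GenomicInterval("chr1", 0, 30, "+")
        a = matrix(np.ones((10, 4), dtype=int), rbp="A")
        a.loci[0] = shared
        b = matrix(np.ones((5, 4), dtype=int), rbp="B", chrom="chr2")
        b.loci[0] = shared
        out = prepare_cohort({"A": a, "B": b}, unique_only=True)
        assert len(out["A"].loci) == 9
        assert len(out["B"].loci) == 4

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            prepare_cohort({})


class TestLocusCoverage:
    @pytest.mark.parametrize(
        "row,expect", [((0, 0, 0), 0), ((5, 2, 3), 10), ((7, 1, 0), 8)]
    )
    def test_sum_across_samples(self, row, expect):
        m = matrix(np.array([row, (1, 1, 1)]))
        assert locus_coverage(m, 0) == expect


class TestSelectMatchedNull:
    def test_exact_match_preferred(self):
        rng = np.random.default_rng(0)
        pool = np.array([10, 11])
        idx, exhausted = select_matched_null(10, pool, rng)
        assert pool[idx] == 10 and not exhausted

    def test_one_higher_when_no_exact(self):
        rng = np.random.default_rng(0)
        pool = np.array([9, 11])
        idx, exhausted = select_matched_null(10, pool, rng)
        assert pool[idx] == 11 and not exhausted

    def test_one_lower_when_nothing_greater(self):
        rng = np.random.default_rng(0)
        pool = np.array([9])
        idx, exhausted = select_matched_null(10, pool, rng)
        assert pool[idx] == 9 and not exhausted

    def test_exhausted_flag_beyond_one(self):
        rng = np.random.default_rng(0)
        pool = np.array([15])
        idx, exhausted = select_matched_null(10, pool, rng)
        assert pool[idx] == 15 and exhausted

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            select_matched_null(10, np.array([]), np.random.default_rng(0))


class TestLocusFootprint:
    def test_identical_null_gives_no_signal(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(1, 50, size=(10, 40))
        m = matrix(counts)
        fp = locus_footprint_pvalue(m, 0, counts[0])
        # null identical to the locus itself: distributions nearly coincide
        assert fp.p_value > 0.9

    def test_planted_latent_factor_detected(self):
        # 50 loci sharing a latent factor at expected log-correlation ~0.6
        rng = np.random.default_rng(1)
        n, L = 100, 50
        f = np.exp(rng.normal(0, 0.8, n))
        eps = np.exp(rng.normal(0, 0.65, (L, n)))
        counts = np.round(20 * f[None, :] * eps)
        null = np.round(20 * np.exp(rng.normal(0, 1.03, n)))
        fp = locus_footprint_pvalue(matrix(counts), 0, null)
        assert fp.p_value < 0.01

    def test_constant_locus_skipped(self):
        counts = np.vstack([np.full(20, 5), np.random.default_rng(0).integers(1, 9, (6, 20))])
        with pytest.raises(ValueError, match="zero-variance"):
            locus_footprint_pvalue(matrix(counts), 0, counts[1])

    def test_too_few_usable_correlations(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(1, 9, (3, 20))
        with pytest.raises(ValueError, match="fewer than 3"):
            locus_footprint_pvalue(matrix(counts), 0, counts[1])


class TestRBPFootprintTest:
    def test_too_few_loci_names_rbp(self):
        rng = np.random.default_rng(0)
        m = matrix(rng.integers(1, 9, (2, 12)), rbp="SPARSE")
        with pytest.raises(ValueError, match="SPARSE"):
            rbp_footprint_test(m, rng.integers(1, 9, (40, 12)), rng=rng, min_loci=10)

    def test_planted_rbp_called(self, small_study):
        cohort = prepare_cohort(small_study["matrices"], unique_only=True)
        truth = small_study["truth"]
        planted = truth.planted_exrbps[0]
        pool = np.vstack(
            [cohort[r].counts for r in sorted(cohort) if r != planted]
        )
        res = rbp_footprint_test(
            cohort[planted], pool, rng=np.random.default_rng(5), min_loci=10
        )
        assert res.raw_p < 0.05 and res.direction_ok

    def test_deterministic_under_seed(self, small_study):
        cohort = prepare_cohort(small_study["matrices"], unique_only=True)
        rbp = sorted(cohort)[0]
        pool = np.vstack([cohort[r].counts for r in sorted(cohort) if r != rbp])
        a = rbp_footprint_test(cohort[rbp], pool, rng=np.random.default_rng(9))
        b = rbp_footprint_test(cohort[rbp], pool, rng=np.random.default_rng(9))
        assert a.raw_p == b.raw_p and a.ks_statistic == b.ks_statistic


class TestFootprintScreen:
    def test_filter_boundary(self):
        spec = FilterSpec(min_samples=10, min_coverage=5)
        counts = np.zeros((1, 30), dtype=int)
        counts[0, :10] = 5
        assert spec.mask(counts).tolist() == [True]
        assert FilterSpec(20, 5).mask(counts).tolist() == [False]

    def test_recovery_and_specificity(self, small_study):
        cohort = prepare_cohort(small_study["matrices"], unique_only=True)
        table, summary = footprint_screen(cohort, seed=11, min_loci=8)
        called = set(summary.loc[summary["called"], "rbp"])
        planted = set(small_study["truth"].planted_exrbps)
        assert len(called & planted) >= 2  # 3 planted in the small cohort
        assert len(called - planted) <= 1

    def test_bonferroni_at_least_raw(self, small_study):
        cohort = prepare_cohort(small_study["matrices"], unique_only=True)
        table, _ = footprint_screen(cohort, seed=11, min_loci=8,
                                    filters=[(10, 2)])
        assert (table["bonferroni_p"] >= table["raw_p"] - 1e-15).all()
        assert (table["bonferroni_p"] <= 1.0).all()
        assert table["raw_p"].between(0, 1).all()

    def test_identical_seed_identical_table(self, small_study):
        cohort = prepare_cohort(small_study["matrices"], unique_only=True)
        t1, s1 = footprint_screen(cohort, seed=3, min_loci=8, filters=[(10, 2), (20, 2)])
        t2, s2 = footprint_screen(cohort, seed=3, min_loci=8, filters=[(10, 2), (20, 2)])
        assert t1.equals(t2) and s1.equals(s2)

    def test_unique_restriction_never_adds_loci(self, small_study):
        all_loci = prepare_cohort(small_study["matrices"], unique_only=False)
        unique = prepare_cohort(small_study["matrices"], unique_only=True)
        for rbp in all_loci:
            assert len(unique[rbp].loci) <= len(all_loci[rbp].loci)


class TestBiotypeFootprint:
    def test_planted_biotype_detected(self, small_study):
        """The planted RBP's preferred biotype drives a biotype-restricted call."""
        cohort = prepare_cohort(small_study["matrices"], unique_only=True)
        ann = small_study["ann"]
        out = biotype_footprint(cohort, {}, ann, seed=2, min_loci=8)
        assert not out.empty
        planted = set(small_study["truth"].planted_exrbps)
        called = out.loc[out["called"]]
        assert set(called["rbp"]) & planted
        # every called (rbp, biotype) pair is a planted RBP
        assert set(called["rbp"]) <= planted

    def test_absent_biotype_skipped(self, small_study):
        cohort = prepare_cohort(small_study["matrices"], unique_only=True)
        out = biotype_footprint(
            cohort, {}, small_study["ann"], biotypes=["no_such_biotype"], seed=2
        )
        assert out.empty
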