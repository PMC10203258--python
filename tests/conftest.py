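import numpy as np
import pytest

from exrbp import (
    BindingSiteSet,
    CoverageTrack,
    GenomicInterval,
    SimulationConfig,
    simulate_cohort,
    simulate_sites,
)


@pytest.fixture(scope="session")
def small_config():
    """A compact cohort: 8 RBPs x 25 loci, 60 samples, 3 planted."""
    return SimulationConfig(
        seed=7,
        n_samples=60,
        n_rbps=8,
        loci_per_rbp=25,
        n_planted_exrbps=3,
        overlap_fraction=0.12,
        n_ev_consistent=4,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    sites, ann = simulate_sites(small_config)
    matrices, truth, tracks = simulate_cohort(small_config, sites, tracks=True)
    return {
        "config": small_config,
        "sites": sites,
        "ann": ann,
        "matrices": matrices,
        "truth": truth,
        "tracks": tracks,
    }


def brute_force_depth(track: CoverageTrack, chrom: str, lo: int, hi: int) -> np.ndarray:
    """Per-base depth array over [lo, hi) computed by literal base iteration."""
    out = np.zeros(hi - lo, dtype=int)
    for iv, depth in track.intervals:
        if iv.chrom != chrom:
            continue
        for pos in range(max(iv.start, lo), min(iv.end, hi)):
            out[pos - lo] = depth
    return out


def brute_force_membership(sets, chrom: str, lo: int, hi: int):
    """Per-base covering-RBP sets over [lo, hi) by literal base iteration."""
    out = [set() for _ in range(hi - lo)]
    for ss in sets:
        for s in ss.sites:
            if s.chrom != chrom:
                continue
            for pos in range(max(s.start, lo), min(s.end, hi)):
                out[pos - lo].add(ss.rbp)
    return out


@pytest.fixture
def toy_sites():
    """The printed two-site worked example: A binds 1-10, B binds 5-15 (1-based)."""
    a = BindingSiteSet("A", "merged", [GenomicInterval("chr1", 0, 10, "+")])
    b = BindingSiteSet("B", "merged", [GenomicInterval("chr1", 4, 15, "+")])
    return [a, b]
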