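# Methods

## Problem and model

Extracellular RNA (exRNA) in a biofluid sample is a mixture of fragments
bound to carriers — vesicles of different densities, lipoprotein particles,
and ribonucleoprotein (RNP) complexes built around RNA-binding proteins
(RBPs). The relative abundance of each carrier varies strongly from sample
to sample for biological and technical reasons. Under that premise, the
read coverage of genomic loci bound by one carried RBP (binding sites known
from eCLIP) should **covary across samples**, because all of them rise and
fall with the carrier's abundance. The package turns that premise into a
testable statistic (the *correlation footprint*) and surrounds it with the
interval plumbing, enrichment scoring and small-cohort permutation test
needed for a complete analysis.

## Coordinates and interval algebra

All intervals are 0-based half-open, the native bedGraph/BED convention;
prose coordinates like `chr1:1-10` (1-based inclusive) convert to
`[0, 10)`. Same-strand overlapping **or book-ended** peaks coalesce during
cross-cell-line merging (conventional merge semantics; whether book-ended
eCLIP peaks should coalesce is not externally constrained, so the
conventional choice was made). Opposite strands never merge. Zero- or
negative-length intervals are rejected at parse time. Chromosome names are
taken verbatim; a naming mismatch between a track and a site set yields
zero counts plus a warning rather than an error, because it is legal input
even though it is usually a mistake.

The *atomic partition* of several site sets is the list of maximal
intervals over which the set of covering RBPs is constant. Membership is
strand-blind, matching the non-strand-specific sample-centric intersection;
strand-level accounting is available separately through the off-strand
percentage, which compares strand-matched and combined-coverage
intersection totals of strand-split tracks.

## Read-count proxy

exRNA fragments and eCLIP peaks are shorter than a sequencing read, so
stacked identical fragments produce a per-base depth equal to the number of
reads covering the region. The count of a region is therefore the
**maximum per-base depth** inside it (`operator="max"`, the default);
`sum` and `mean` are provided for sensitivity analyses. Counts are used
raw downstream — no normalisation or log transform — and rows with no reads
in any sample are dropped when a cohort is prepared for statistics.

## Correlation footprinting

Input: one loci × samples count matrix per RBP, all sharing the sample
set. Preparation removes loci overlapping any other RBP's loci
(`unique_only`, the default), because multi-RBP regions are not
RBP-specific; it never increases the number of loci tested.

Per locus *i* of RBP *R* with usable (non-constant) counts:

1. A **coverage-matched null locus** n_i is drawn from the loci of all
   other RBPs. The matching scalar is the total count summed across
   samples. Exact matches are preferred; otherwise coverage +1 (or −1 when
   no pool locus has greater coverage at all), extending ±2, ±3, … with an
   "exhausted" flag once |Δ| > 1. Ties break uniformly at random under the
   run seed.
2. p_i is the two-sample Kolmogorov–Smirnov p-value comparing
   {r(i, j) : j ≠ i, j ∈ R} against {r(n_i, j) : j ∈ R}, Pearson
   correlations on raw counts.
3. The mirror p-value q_i applies the identical construction with roles
   swapped: {r(n_i, n_j) : j ≠ i} against {r(i, n_j) : j}.

The RBP-level raw p is a **one-sided** two-sample KS test of whether
{p_i} is stochastically smaller than {q_i}, plus an explicit direction
check median(p) < median(q). One-sided aggregation with the median check
was chosen over a two-sided test with post-hoc filtering because the
alternative of interest is strictly one-directional (true loci more
correlated than background). The role-swapped mirror makes {p_i} and
{q_i} exchangeable under the global null, which is what calibrates the
final test.

All KS p-values use the asymptotic approximation. This matters twice:
(a) it is orders of magnitude faster at screening scale, and (b) the exact
small-sample KS distribution is markedly conservative at these sample
sizes, while the asymptotic one-sided test is very slightly liberal; in
combination with the positive pairing correlation between p_i and q_i
(they share the (locus, matched-null) pair) the measured null rejection
rate at α = 0.05 sits at ≈ 0.049 — verified by the calibration test over
200 all-noise cohorts.

Screening runs the test under six locus filters — loci kept when at least
{30, 20, 10} samples have a count of at least {5, 2} — and Bonferroni
multiplies each raw p by the number of RBPs actually tested in that
(cohort, filter) run. The family choice (RBPs per run, not filters or
cohorts) reflects that each filter set is reported as a separate screen;
an RBP is called when significant in at least one filter, and the smallest
adjusted p identifies its best filter. A biotype-restricted variant
subsets each RBP's loci to those overlapping a biotype's annotation
records (a locus may carry several biotypes) and adjusts within the pairs
tested per biotype.

Zero-variance loci are excluded from both the true and null pools; RBPs
with fewer than `min_loci` (default 10) usable loci are skipped with a
named error.

## Cargo-type enrichment

For each RBP, per-locus estimated reads in each cargo type are divided by
locus length and averaged over the CT's deconvolved profiles, giving a
per-CT mean per-base coverage m_c. The enrichment score is
s_c = m_c / mean(m), with the **unweighted** mean over CTs as the
denominator — that equal-weight choice is exactly what makes every row
average 1, which the tests assert to 1e-9. Rows with zero grand-mean
coverage are dropped with a warning rather than propagating NaN.
Deconvolution itself is consumed as input (the synthetic module emits
ground-truth CT profiles directly); re-deriving carrier proportions is out
of scope.

A cell is *enriched* at score ≥ 1.4 (non-strict; the published 75th
percentile of scores, 1.34, motivates the cutoff, and an
`enrichment_percentile` utility recomputes it). Raising the threshold can
only shrink the enriched set (monotonicity, property-tested).

Fraction concordance maps each CT to a density-gradient fraction class.
Two mappings ship because the source material is internally contradictory
about the CT1/CT2 pairing: the default `RESULTS_MAPPING`
(CT4↔fractions 1–3, CT1↔4–7, CT2↔9–12, CT3↔unfractionated) and the
alternative `METHODS_MAPPING` with CT1/CT2 swapped. Neither is asserted as
the true intent; the flag `--mapping {results|methods}` exposes both.

`biotype_ct_fraction` computes, per study, CT and biotype, the unique
gene bases whose transcripts pass both expression cutoffs (≥ 5 raw reads
in some sample; ≥ 2 estimated reads within the CT) and overlap an RBP
binding site, divided by the unique bases of all the biotype's genes.
Studies are the replicates for a Kruskal–Wallis omnibus test per biotype,
followed (when p < 0.05) by pairwise rank-sum tests with Holm adjustment.

## EV permutation test

Four EV samples are too few for correlation footprinting, so consistency
is tested instead. The statistic pools |x(ℓ,s) − x(ℓ,t)| over all loci ℓ
and unordered sample pairs (s,t) (4 samples → 6 pairs) and reports
CV = (sd/mean)·100 with sample sd (ddof = 1); absolute values are used
because signed differences pool to mean ≈ 0 and make σ/μ unstable. When
every difference is zero the CV is defined as 0 (perfect consistency) with
a warning.

The null permutes **each sample column independently across loci**, which
destroys the cross-sample alignment of locus profiles while preserving
each sample's marginal counts. Permuting within a locus row is *not* a
valid null here: the pooled multiset of a row's pairwise differences is
invariant to any permutation of that row, so the statistic would never
move. The p-value is lower tail with the permutation floor,
p = (1 + #{CV_null ≤ CV_obs}) / (n_perm + 1), n_perm = 1000 by default;
"significant" means p < 0.05 (a p-threshold — the CV itself lives on a
percent scale where 0.05 would be meaningless).

Randomized control sets (for each eligible RBP, an equally sized locus set
drawn uniformly without replacement from the other RBPs' eligible loci)
re-run the identical analysis; the ratio of significant random to
significant true sets estimates the FDR, and a two-sample KS test compares
the two p-value distributions. The KS comparison is applied to the
p-value distributions (rather than the CV distributions) — the more direct
reading of comparing "true" vs "randomized" outcomes; the alternative is a
one-line change.

Eligibility: loci with reads in at least 2 of the samples, RBPs with at
least 15 such loci.

## Synthetic data

The generator produces every input the pipeline consumes, on a fixed
mini-genome (two chromosomes, < 1 Mb, loci of 20–60 bp with 50–200 bp
gaps) small enough for per-base brute-force oracles.

* **Sites**: `loci_per_rbp` stranded loci per RBP; a fraction
  `overlap_fraction` of each RBP's loci is shared verbatim with a partner
  RBP (consecutive pairs), exercising unique-locus removal and the atomic
  partition. Each locus gets one gene annotation record; the biotype is the
  RBP's preferred biotype with probability 0.7.
* **Cohort counts**: for planted RBP c, sample s, locus ℓ:
  count = round(b_ℓ · f(c,s) · ε) with f ~ LogNormal(0, latent_factor_sd²)
  shared across the RBP's private loci and ε ~ LogNormal(0, noise_sd²)
  independent. Defaults latent_factor_sd = 0.8, noise_sd = 0.6 give an
  expected pairwise log-scale correlation of 0.64 (closed form
  σ_f²/(σ_f²+σ_ε²), Monte-Carlo-verified in the tests). Background loci
  use one LogNormal(0, σ_f²+σ_ε²) factor, which matches the planted
  marginal mean *exactly* (both scale by exp((σ_f²+σ_ε²)/2)), keeping
  coverage-matched null sampling non-degenerate. Baselines
  b_ℓ = 20·LogNormal(0, 0.5) give occasional zero counts, exercising the
  all-zero-row and zero-variance paths. Optional per-sample tracks place
  each locus's count as a constant depth, so the depth-as-count proxy holds
  by construction and bedGraph round-trips reproduce the matrices.
* **CT / fraction profiles**: every RBP is assigned 1–3 CTs; assigned CTs
  get (1+contrast)× the per-locus baseline coverage (contrast 5 by
  default), others baseline leakage, with 5% multiplicative noise. At
  contrast 5 the planted assignments are recovered exactly at threshold
  1.4. Fraction profiles enrich exactly **one** class per RBP — with k of
  4 classes enriched the score tops out at 4(1+c)/(k(1+c)+4−k), which for
  k ≥ 3 can never reach 1.4, so multi-class enrichment would make planted
  consistency undetectable by construction.
* **EV sample sets**: consistent RBPs draw one abundance profile
  b_ℓ ~ LogNormal(log 30, 1.0) and near-equal library scales
  (LogNormal(0, 0.05)), with **Poisson** counting noise; inconsistent RBPs
  draw an independent LogNormal(0, 0.8) abundance factor per sample and
  locus. Poisson noise is the load-bearing choice: it makes a consistent
  RBP's pairwise differences scale with √abundance, which is what gives
  the observed pooled CV a lower value than the locus-shuffled null.
  Multiplicative noise, however small, makes differences proportional to
  abundance and pushes the observed CV *above* the null in every regime —
  the statistic is then blind to proportional consistency. About 100
  eligible loci per RBP and a log-scale abundance sd of 1.0 give the test
  ≥ 0.8 per-RBP sensitivity at these conditions (pre-build simulation;
  heavier-tailed abundance distributions destabilise the sample CV and
  *reduce* power).

Seeding: every stage derives its generator from `(seed, stage-offset)`,
so each stage is independently deterministic and byte-identical per seed.

## Numerical and design notes

* Pearson correlations are computed on raw counts; no transformation is
  applied anywhere in the statistic path.
* Whether the per-locus comparison should feed correlation *coefficients*
  or correlation-test p-values into the KS stage is ambiguous in
  principle; coefficients were chosen (the KS test only needs the two
  samples to be comparable, and coefficients avoid an extra layer of
  n-dependent transformation).
* The calibration and recovery tests run at reduced scale (200 replicate
  cohorts of 20 RBPs × 30 loci × 60 samples; default cohorts of 20 RBPs ×
  100 loci × 100 samples), the package's standing choice for routine test
  runs.
* `bedtools merge -s` serves as an independent oracle for the strand-aware
  merge in the test suite; the per-base brute-force oracles are pure
  Python reimplementations kept deliberately naive.

## Limitations

* The synthetic cohorts model carrier covariation as a single log-normal
  latent factor per RBP; real biofluid data has correlated batch and
  biofluid effects, compositional constraints, and alignment artefacts
  that the generator does not emulate. Passing recovery tests show the
  statistics behave as designed under the assumed model, not that the
  model captures every property of real exRNA profiles.
* Upstream read alignment, deconvolution of carrier proportions, and any
  genome-build lifting are out of scope; their outputs are consumed as
  inputs.
* The footprint test inherits the KS test's discreteness at small locus
  counts; below ~15 usable loci per RBP, p-values are coarse and the
  direction check does most of the work.
* With only four samples, the EV permutation null has at most (4!)⁴
  distinguishable column permutations per locus set; n_perm = 1000 samples
  that space rather than enumerating it.
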