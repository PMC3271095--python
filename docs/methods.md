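# Methods

This note documents the models and procedures implemented in `mirsnpkit`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic generators do and do not emulate.

## Target-site model

A miRNA recognition element (MRE) is modelled as a stretch of the UTR that
is the exact Watson–Crick reverse complement of a 5′ prefix of the mature
miRNA.  The site's 3′-most UTR base pairs the first matched miRNA
nucleotide, so UTR coordinates map to miRNA positions by
`utr_end − utr_position + 1`.  At each anchor only the maximal consecutive
match is reported; distinct anchors are reported independently even when
their sites overlap.

Choices and rationale:

- **Prefix anchoring.** Matching starts at miRNA nucleotide 1 by default
  (`prefix_start=1`), with `prefix_start=2` available to anchor at the
  first seed base.  Published consensus tables list matched miRNA 5′-end
  sequences of length 7–10, which is consistent with prefix matching from
  the terminus, while the canonical seed used for impact classification is
  nucleotides 2–8.  Both conventions are therefore exposed.
- **Strict pairing.** G:U wobble is not allowed.  This makes the planted
  fixtures certifiable (a site is present iff the generator wrote it) at
  the cost of missing wobble-tolerant sites real miRNAs can use.
- **Minimum match** defaults to 7 nt (`min_match=7`), the usual seed-match
  threshold; values below 6 are rejected because chance matches dominate.
- **T/U handling.** Sequences are normalized internally to the RNA
  alphabet; DNA input is accepted everywhere.  `revcomp` returns DNA only
  for unambiguously-DNA input (contains T, no U) and RNA otherwise.
- **Coordinates** are 1-based inclusive ascending throughout the library;
  the descending START/END report convention (START pairs miRNA nt 1) is
  provided as derived columns and parsed by the published-table reader,
  which trusts START + match length because printed END values contain
  typos.

## Poisson enrichment p-value

The chance occurrence of a k-nt pairing in a UTR of length L is modelled as
Poisson with

    λ = (L − k + 1) · ∏ over site positions of background probability,

and the p-value is P(X ≥ m_obs), where m_obs is the number of observed
sites for the miRNA–UTR pair; m_obs = 0 returns 1 by convention, and k > L
degenerates to p = 1 with a warning.  The background is uniform (0.25 per
base) by default; the empirical UTR composition can be selected, in which
case the matched site's own bases enter the product.  λ shrinks with k, so
the single-site p-value strictly decreases for longer matches — longer
matches are rarer and hence more significant.  Published p-values from
prediction servers are *not* reproduction targets: their background
composition and counting rules are not disclosed, so this model reproduces
the filtering semantics (p < 0.05), not the printed digits.

## SNP impact classification

Both allele versions of the UTR are re-scanned and sites are compared per
anchor (shared `utr_end`):

- ref site covering the SNP, no surviving alt site at that anchor →
  **abolished**;
- sites at the anchor on both alleles (the alt match is truncated at the
  mismatch but still reaches `min_match`) → **weakened**;
- alt-only site covering the SNP → **created**;
- SNP inside no site on either allele → **outside_site**.

A site whose truncated remnant falls below `min_match` counts as a hard
loss (abolished) even when the SNP pairs a non-seed position: the
motivating reporter experiments show a binary loss of repression, and a
sub-threshold remnant is no longer a predicted site under this model.  The
summary classification over multiple affected sites is the worst case in
the order abolished > created > weakened > outside_site.  Swapping ref and
alt maps abolished ↔ created and fixes weakened, which the property tests
assert.

## Barnard's unconditional exact test

For carriers x1/n1 vs x2/n2 (two independent binomials) the ordering
statistic is the pooled-variance Wald statistic

    W = (p̂1 − p̂2) / sqrt( p̂ (1 − p̂) (1/n1 + 1/n2) ),  p̂ = (x1+x2)/(n1+n2).

Outcome tables with pooled p̂ ∈ {0, 1} have zero pooled variance; W is
defined as 0 there, so they enter the two-sided region only when W_obs = 0
(then p = 1).  The two-sided region is {|W(y1,y2)| ≥ |W_obs|}; its
probability under a common success probability π,

    tail(π) = Σ over the region of Binom(y1; n1, π) · Binom(y2; n2, π),

is maximized over π.  Implementation details:

- the region's probability is collapsed onto total-success counts
  s = y1 + y2 (the coefficients A_s are sums of binomial-coefficient
  products), and tail(π) = Σ A_s π^s (1−π)^(N−s) is evaluated in log
  space — O(N) per π instead of O(n1·n2);
- π runs over a grid of step `grid_step` (default 1e-4, must be ≤ 1e-3)
  on (ε, 1−ε), ε = 1e-8, followed by bounded golden-section refinement in
  the best grid cell; the maximizing π* and the grid step are recorded in
  the result for reproducibility;
- |W| ties are included with a 1e-12 tolerance.  This matters: the mirror
  image of the observed table has exactly |W_obs| up to floating-point
  noise, and a strict comparison (as in scipy's implementation) can drop
  it, shrinking the two-sided p-value of small tables by several percent.
  The one-sided option (`alternative="less"/"greater"`) agrees with
  scipy's `barnard_exact` to ~1e-6, which the tests use as an independent
  cross-check; the two-sided path is verified against a brute-force
  oracle (direct pmf sums over a 10⁵-point grid, separate code path)
  exhaustively for all tables with n1, n2 ≤ 6.

The dominant model collapses genotypes to carriers (CT + TT) vs CC.  The
carrier odds ratio is oriented case (group 2) versus reference (group 1);
zero cells are rejected by default, naming the offending cell, with the
Haldane–Anscombe +0.5 correction available by flag.  Hardy–Weinberg
equilibrium is tested by Pearson's χ² with 1 df against expected counts
n·[(1−q)², 2q(1−q), q²] at the observed minor-allele frequency q;
monomorphic cohorts return χ² = 0, p = 1 with a warning.  No
multiple-testing correction is applied anywhere; every comparison is
reported unadjusted.

## In-silico RFLP assay

The amplicon is the forward primer, the intervening template, and the
reverse complement of the reverse primer; primer bases override the
template inside their footprints, which is how a deliberate primer
mismatch enters the product.  Primers must match their footprints exactly
except at the declared engineered offset (counted from the 3′ end;
"penultimate" = 2), and each footprint must be unique on the template —
no thermodynamic annealing model is attempted.  Recognition sites are
IUPAC patterns searched on both strands (bottom-strand hits are occurrences
of the reverse-complemented pattern, reported in top-strand coordinates;
palindromic patterns are counted once per duplex position).  Fragments are
defined by top-strand cut positions — pattern end + `cut_offset_top` for
top-strand hits, mirrored for bottom-strand hits — with cuts falling
outside the molecule dropped; fragment lengths always sum to the amplicon
length.  BsrI ships as ACTGG(1/−1).  The enzyme table is user-extensible
because cut geometries vary and only the pattern is load-bearing for
allele discrimination, which is decided by comparing fragment-length
multisets between the two allele digests.

The packaged fixture embeds the two published genotyping primers in a
synthetic template (the real genomic context is not bundled): the template
carries the wild-type T at the engineered penultimate position, the SNP
base sits immediately downstream of the forward footprint, and the random
flanks are certified free of further BsrI sites, so the T-allele amplicon
is cut exactly once and the C-allele amplicon not at all.  Real fragment
sizes are not asserted anywhere — only the qualitative cut/no-cut
contrast, since the true amplicon length is not derivable from the
printed material.

## Synthetic generators

All generators are deterministic given (spec, seed); independent PRNG
streams are derived per call tag from `SeedSequence([seed, crc32(tag)])`,
so adding a generator never perturbs existing fixtures.

- **Genotypes** are multinomial draws from HWE proportions
  [(1−q)², 2q(1−q), q²].  Sampling 10⁵ genotypes at q = 0.18 and testing
  HWE rejects at the nominal 5% rate (calibration test, 2,000 replicates).
- **Case-control cohorts**: severity is Bernoulli with carrier odds
  `or_carrier` times the baseline (non-carrier) odds.  Defaults are the
  study conditions: n1 = 45 mild, n2 = 33 severe, allele frequency 0.1225
  (carrier rate ≈ 0.23, the full-cohort carrier fraction), carrier OR 3.7,
  baseline severity rate 0.42 (the severe fraction of the 78-patient
  cohort).  The default conditioned mode draws individuals until both
  cohorts reach their requested sizes (the case-control design);
  unconditioned mode returns realized sizes.  At 5,000 per arm the median
  estimated carrier OR over 500 replicates falls in [3.5, 3.9].
- **UTR fixtures** plant exact reverse-complement sites on an i.i.d.
  uniform background and certify by rejection sampling — with a naive
  brute-force scanner kept independent of the production scanner — that
  no accidental site of length ≥ `min_match` exists for any involved
  miRNA, and that a planted SNP realises its requested truth label on
  both allele sequences.  Certified absence is what makes 100%
  truth-recovery a meaningful test.
- **Reporter draws** are Gaussian per group with sd = SEM·√n; defaults are
  the observed allele contrast (47.14 ± 0.42 vs 90.56 ± 3.8 percent of
  control, n = 3).

What the generators do not emulate: linkage disequilibrium, pedigree
structure and relatedness (the real cohorts are large families, so their
effective sample sizes are smaller than the counts suggest), sex
stratification, genotyping error, non-uniform UTR composition, wobble
pairing, and RNA structure/accessibility.  Passing tests on these fixtures
therefore validates the algorithms and their contracts, not the biological
claims on real cohorts.

## Problem sizes and numerical choices

The exact test enumerates (n1+1)·(n2+1) tables — at most 60×60 here — and
evaluates ~10⁴ grid points per test; a single test runs in milliseconds,
and the type-I-error study (10,000 null tables at n1 = 45, n2 = 33,
π = 0.23) reuses p-values across duplicate observed tables, reducing it to
a few hundred distinct evaluations.  Simulation studies in the test suite
use 500 replicates at 5,000 per arm (odds-ratio recovery) and 2,000
replicates of 10⁵ genotypes (HWE calibration).  Tie tolerances: 1e-12 on
|W| comparisons; refinement terminates at 1e-10 in π.

## Known limitations

- Printed prediction-server p-values are not reproducible (undisclosed
  background model); only the filtering semantics are implemented.
- Control-population genotype counts are reconstructed from rounded
  percentages, so the HWE p-value is asserted only as non-rejecting
  (p > 0.05), and the reconstructed value (0.77) differs from the printed
  one (0.81) within that band.
- Two published UTR coordinate numbering schemes (absolute 3′UTR position
  vs an offset convention) are not reconcilable from the printed material;
  all coordinates here are UTR-local inputs and no lift-over is guessed.
- The mature sequence of the motivating miRNA is not part of the printed
  material, so the real SNP/miRNA pair is exercised through synthetic
  fixtures with the same positional structure (SNP pairing seed
  nucleotide 2).
- Confidence intervals for the unconditional test and Boschloo/Fisher
  ordering variants are out of scope; the one-sided Wald-ordered variant
  is the only alternative provided.
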