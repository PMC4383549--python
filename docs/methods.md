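# Methods

This note documents the statistical models behind chromadelta, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical conventions. It states no empirical
result beyond what the test suite and example scripts themselves compute.

## Coordinates and conventions

All intervals are 0-based half-open (BED semantics); width = end − start.
SNP positions are 1-based in input/output TSVs (VCF convention) and
converted at the I/O boundary. Reads are reduced to fragment midpoints at
load time; fragment length is not modelled, since midpoint counting is
the simplest well-defined window assignment for ~200 bp fragments.
Nearest-gene annotation measures the distance from a site's midpoint to
the gene's TSS (not to the gene body), with ties broken toward the
lexicographically smaller gene id for determinism.

Two promoter conventions coexist in the field and both are supported:
`flank1kb` (±1 kb of the TSS; the default, matching how promoter signal
is typically quantified) and `upstream1kb` (strand-aware, ≤ 1 kb 5' of
the TSS). Reported percentages use round-half-away-from-zero to integer;
ratios such as the concordance percentage are returned at full precision
and any presentation rounding is left to the caller.

## Differential sites

Windows of `w` bp every `s` bp (`chromatin` 200/20, `enhancer` 500/50,
`tf` 200/20 with a 50-read minimum; otherwise minimum 20 pooled reads)
receive pooled per-condition midpoint counts. Normalization is by total
library size (replicates pooled) — the simplest defensible choice, and
the one the G-test expectation encodes; no replicate-variance model is
fitted (a negative-binomial replicate-aware test is out of scope).

The G statistic uses the convention 0·ln 0 = 0 and is referred to
χ²(1 df). The signed fold is `log2((b+½)/N2) − log2((a+½)/N1)` with a
half-count pseudocount per condition; direction is the sign of the
library-normalized difference. Windows below the minimum count are
excluded from every multiple-testing denominator.

**Site calling and the FDR level.** Candidate windows (unadjusted
p < 1e-3, a candidate-forming screen an order looser than any final
threshold) merge by direction when overlapping or book-ended. Each
candidate site is then **re-tested on its pooled counts**, summed over a
maximal non-overlapping subset of its member windows so no read is
counted twice, and BH adjustment is applied **across candidate sites**
using the total number of tested windows as the (conservative)
multiplicity denominator; sites with adjusted q below the threshold
(default 2.5 %) are reported. The window-level BH q is still computed
and reported per window for diagnostics. Rationale: with a 10×
overlapping grid one true site spans tens of windows, so window-level BH
inflates the discovery count and licenses spurious single-window sites
(site-level false discovery far above the nominal q); the regional
retest also pools the evidence that individual windows of a wide,
modest-fold site only see in part. The hotspot scan is a Poisson
upper-tail test of site-midpoint counts in 1 Mb tiles at the genome-wide
mean rate — the named "hotspot" routine of the underlying differential
tool is unpublished, so this scan is a declared substitute.

The plumbing peak caller thresholds step coverage, merges runs within
140 bp and keeps widths in [50 bp, 5 kb] (bounds inclusive: widths
*below* 50 or *above* 5000 are removed).

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the pipeline assumes,
at desk scale:

- genome: 2 chromosomes × 2 Mb (large enough for ±10 kb shift nulls,
  small enough for seconds-scale runs);
- background: homogeneous 0.05 read midpoints/bp/replicate, 3
  replicates/condition — a 200 bp window pools ~30 reads per condition,
  mirroring the per-window occupancy of a deeply sequenced experiment
  while keeping total reads ~1.2 M per mark;
- 20 planted non-overlapping 1 kb sites; condition-2 rate multiplied by
  2^effect inside each, |effect| ~ N(2, 0) with alternating random signs;
- replicate noise: Poisson by default; finite `nb_dispersion` switches to
  a Gamma-Poisson (negative binomial) mixture. The default is Poisson
  because the pooled-count G-test assumes Poisson-like sampling; the NB
  option exists to study robustness, not as the null of the test suite;
- expression: per-donor paired design (6 donors), gene baseline N(8, 1),
  donor random effect N(0, 0.5); a gene nearest to a planted site is
  "coupled" and its per-donor condition difference is
  `slope·effect + N(0, 0.5)` with slope 0.5 — strong enough that coupled
  genes are detectable by the paired t-test at BH q < 0.05;
- locus catalogs: 45 target and 2000 background loci, k = 1 + Poisson(9)
  SNPs per locus scattered over 50 kb, overlap planted as a per-locus
  Bernoulli (π_target = 0.4 vs π_background = 0.1 by default: a 4-fold
  enrichment). The background size matches the scale of a full
  trait-agnostic GWAS catalog; see the calibration caveat below.

Deliberate unrealisms: no sequence-level reads, GC/mappability bias,
copy number, fragment-length distribution, or basal condition-1 peaks
(condition 1 is flat background, so enhancer peaks and super-enhancers
arise only in condition 2 and every condition-2 super-enhancer is
condition-specific). Passing tests therefore demonstrate correctness of
the statistical machinery under its own assumptions, not robustness to
real-data artefacts.

## Locus permutation enrichment

Loci are matched on size (index + proxies) with geometric bins {1}, {2},
{3–4}, …, {≥65}; any bin with fewer than 10 background loci — including
empty bins — merges into its lower neighbour (upward at the bottom), so
after merging every target size maps to an occupied bin. Each
permutation draws, per target locus, one background locus uniformly from
the matching bin without replacement within the permutation; since draws
are uniform within bins, the per-bin overlap count is exactly
hypergeometric and is sampled as such (binomial for the with-replacement
fallback when a bin is smaller than its target count, with a logged
warning). The final stage is an upper-tail binomial test with n = number
of target loci and success probability expected/n, the most direct
reading of comparing observed, total and permutation-expected counts.

Two permutation p-values are reported. The **conservative** p,
(1 + #{perm ≥ obs})/(R + 1), is the inferential one: it is never exactly
zero and never anticonservative, but because the overlap count is an
integer it is sub-uniform under the null wherever permutation counts tie
the observation — a property of the estimator, not of the
implementation. The **tie-randomized** p splits tie mass uniformly and
is exactly Uniform(0,1) under exchangeability; it exists for calibration
diagnostics (the test suite verifies its uniformity by KS across
null catalogs, and separately verifies the conservative p's one-sided
validity). A further finite-background caveat: with a small background
catalog (hundreds of loci) all permutation draws share the background's
sampling noise and the empirical p acquires mild extra dispersion; the
effect shrinks as the background grows, which is one reason the default
catalog is 2000 loci.

The peak-shift null displaces each site by an integer offset uniform in
[−10 kb, +10 kb], redrawing out-of-bounds offsets rather than clamping
(clamping would pile density at chromosome ends), and compares observed
annotation overlap to the shifted background over 100 permutations.

## Super-enhancers

Peaks within 12.5 kb are stitched (TSS exclusion — dropping peaks fully
inside ±2.5 kb of a TSS — is available but off by default, following the
original formulation of the method, which predates that option); domain
signal is the sum of member peak signal. Input-control subtraction is
omitted because the synthetic data has no control track; signal is used
as supplied. The cutoff scales ranked signals to the unit square and
takes i\* = argmin(y − x) with ties toward the larger index (fewer
supers — conservative); an enhancer is super iff its signal strictly
exceeds s\_{i\*}. The flags are invariant to multiplying all signals by a
positive constant, and on strictly convex curves i\* coincides with the
last point whose discrete slope to its successor is below 1.

## Allelic motif affinity

PWMs carry a pseudocount (default 0.5) so all probabilities are
positive; the background defaults to uniform. Scanning and the null
distribution share one discretisation: per-position log2-odds are
rounded to an ε grid (default 0.01 bits) and convolved across positions
under the i.i.d. background, giving the exact distribution of the
discretised single-window score. The best-match p over a sequence is
Šidák-corrected for the number of scannable windows times strands,
`1 − (1 − p_win)^(2·offsets)`. Windows containing ambiguous bases are
skipped. The published per-allele affinity p-values for rs72664324 come
from an unprinted TRANSFAC-based tool, so those columns are not
reproduced; the package's own p-value definition above is oracle-tested
against exhaustive enumeration, and the published table is used to
validate the combination rule `diff_logp = log10(p_risk) −
log10(p_protective)` and the |diff|-descending ranking. The packaged
motif file is synthetic (hand-written CEBP-like, CCAAT-box-like and
uniform-control matrices); the packaged FASTA carries the published
25 bp allele probe sequences.

## Pipeline and problem sizes

The orchestrated run derives per-stage seeds from the master seed by
fixed offsets, so stages are individually reproducible. Default problem
sizes (2 × 2 Mb genome, 3 + 3 read sets per mark, 10,000 locus
permutations, 100 shift permutations) complete in a few seconds on one
CPU; the calibration-heavy tests (200 null catalogs at R = 1,000; the
exhaustive G-test oracle) keep the whole suite under a minute. The
pipeline's enhancer peak threshold is expressed as a fold (default 2×)
over the genome-average reads-per-million, since absolute RPM thresholds
do not transfer across library sizes.

## Known limitations

- Pooled-count testing ignores replicate-level overdispersion; with
  strongly overdispersed real data the G-test p-values would be
  anticonservative (use the NB generator option to study this).
- The hotspot scan and the site-level FDR construction are declared
  substitutes for unpublished internals of the tool they emulate.
- The shift null preserves neither GC nor gene-density structure — as in
  the original procedure, it controls only for local placement.
- Exact reproduction of genome-scale published counts requires the
  primary sequencing data and is out of scope.
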