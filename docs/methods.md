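# Methods

## Coordinate and counting conventions

All internal coordinates are 0-based half-open; GTF and RepeatMasker `.out`
(1-based closed) are converted at the I/O boundary and nowhere else. A gene is
identified by (symbol, chromosome, strand); the same symbol on two strands is
two genes. Single-exon transcripts carry no intron information and are
dropped; a gene is excluded only when every transcript is single-exon, and
exclusions are reported so that input totals always reconstruct.

An Alu counts toward a transcript when it overlaps the span by at least one
nucleotide. The exon/intron assignment is exon-first: any exon overlap of
≥ 1 nt makes it an exon Alu, and intron Alus are the remainder (Ni = Nt − Ne),
which matches the subtraction-based bookkeeping of the density definitions.
When adjusting lengths, only the Alu nucleotides lying inside the assigned
region (and the transcript span) are subtracted, so Si and Se cannot go
negative; a transcript whose adjusted lengths are non-positive is skipped and
a gene with no usable transcript is rejected with a diagnostic.

Motif occurrences are exact, case-insensitive, forward-strand matches,
overlapping matches allowed. Occurrences overlapping an assigned Alu interval
are excluded from the numerator by default, mirroring the exclusion of Alu
nucleotides from the denominator; `--count-motifs-in-alus` restores inclusive
counting. This choice is ours — the density definitions are explicit only
about the denominator — and it is the self-consistent reading: a density
whose numerator can live in sequence its denominator excludes is not a rate.

Alu pairs use the inter-interval gap (next start − previous end) strictly
less than 300 nt between *consecutive* intron Alus. Alu-exon-Alu triplets are
counted per exon (an exon contributes at most one triplet; one Alu may serve
two exons). Both thresholds are configurable (`--gap`). Fractional
transcript-averaged triplet counts are kept unrounded, since the gene value
is defined as a mean over transcripts.

Chromosome-level densities are pooled — total counts over total adjusted
lengths — never means of gene-level densities. Intergenic regions are the
complement of the merged transcript spans within the chromosome; an Alu is
intergenic when it overlaps no transcript span.

## Zero-inflated Gamma mixture

Gene-level intron Alu density within a chromosome is modelled as a point mass
at zero (probability r) plus a Gamma density on the positives. "Zero" means
exactly zero: Ni is an integer count, so no epsilon threshold is involved,
and r is estimated as the exact observed zero fraction rather than by EM —
the zero class is perfectly observed.

The Gamma ML fit profiles the scale out (θ = mean/κ) and solves the score
equation log κ − ψ(κ) = log mean − mean log by Newton iteration with the
trigamma derivative, started at the moment estimator mean²/var, halving the
step when it would leave the parameter space. Convergence is a relative
change below 1e-10 (at most 200 iterations; in practice < 10). Inputs are
sorted before accumulation so estimates are exactly invariant under input
permutation. Degenerate inputs (constant samples, non-positive values) are
rejected. The fit is cross-checked in the test suite against
`scipy.stats.gamma.fit(floc=0)`.

Q-Q plots use midpoint plotting positions (i − 0.5)/n against the fitted
inverse CDF. Field names are shape/scale throughout; the Greek-letter
conventions in the surrounding literature are inconsistent, and the values
themselves (shape ≈ 0.6, scale ≈ 1.3 for a chromosome-1-like gene set) fix
the meaning.

## Regression layer

Model-1 is a logistic regression of Alu presence on intron motif density and
log10 adjusted gene size; Model-2 an OLS regression of raw Di (not
log-transformed — the model is linear in the density as written; a
`--log-response` reading would require excluding zeros twice) on the same
covariates over the Alu-containing genes. Per-term p-values are Wald tests.
Fits go through statsmodels (GLM-Binomial IRLS, OLS); the test suite checks
them against an independently hand-rolled IRLS oracle to 1e-8. Perfect
separation is detected (fitted probabilities collapsing to 0/1 or coefficient
magnitudes beyond 15) and flagged with a warning; estimates stay finite via
the iteration cap.

Benjamini-Hochberg adjustment is applied across chromosomes separately per
model. The motif contribution is the increase in Nagelkerke R² (Model-1,
against the size-only reduced model, with the intercept-only fit as the
normalizing null) or in plain R² (Model-2), clipped at zero.

Fisher's exact test is two-sided by the point-probability method (sum of
hypergeometric probabilities not exceeding the observed table's), with the
sample odds ratio ad/(bc). On the published 48-vs-302 cluster table this
gives p = 3.995e-5 (R's `fisher.test` agrees to machine precision), which we
take as the computation behind the reported ~3.8e-5.

## Clustering

Complete linkage on Euclidean distances over the unscaled 5-feature vectors
(Di, De, pair density, triplet count, adjusted GC). Unscaled is a deliberate
default: an absolute cut height (default 4.5) and the isolation of single
genes by extreme raw triplet counts are only meaningful on raw feature units;
`--scale zscore` is available. Merge order on ties follows the (deterministic)
nearest-neighbor chain order of scipy's linkage given the input row order.
Enrichment pools the focus clusters against the remaining non-singleton
clusters; singletons are excluded from both pools, since a gene isolated by
one extreme feature is evidence about neither.

## Synthetic genomes

The generator emulates: per-chromosome gene counts with zero-inflated Gamma
target densities (defaults: the first four published chromosome parameter
rows at 200 genes each); log10-normal gene lengths (mean 4.4, sd 0.35 —
median ~25 Knt, the scale of human multi-exon genes); exon counts
2 + Geometric(0.15) with log-normal exon lengths (median 150 nt); 300 nt Alu
elements; a Poisson 5'-TTAAAA planting rate of 1.0 per adjusted intron Knt
multiplied by exp(β₁·presence + β₂·target density), both couplings zero by
default; intergenic gaps (exponential, mean 3 Knt) with intergenic Alus at
0.3 per Knt; and Bernoulli class labels with logit linear in Di and log10
size. Sequence is i.i.d. uniform ACGT with motifs overwritten in non-Alu
intron segments and a fixed synthetic 300 nt tag (55% GC) at Alu coordinates
— the tag is *not* an Alu consensus; features depend only on coordinates.

Given a target density d and total intron length I, the Alu count is
c = round(d·I/(1000 + 300·d)), which solves c = d·Si for the adjusted length
*after* insertion, so realized density matches the target up to rounding; a
positive target always places at least one element. Placement within introns
is exact uniform non-overlapping sampling (sorted-uniform gap method), with
infeasibly dense targets resampled and counted. Truth tables record both
target and realized density; realized values are exactly recomputable from
the emitted files, and the test suite asserts that round trip to 1e-12.

**What passing tests do and do not show.** The generator realizes continuous
target densities through integer Alu counts, exactly as real annotation data
does. This left-censors the density distribution below one element per
adjusted intron length (~0.04 per Knt at the default gene scale): a fit to
*realized* densities therefore shows inflated shape and shrunken scale
relative to the generating Gamma whenever the generating shape is well below
1, because such Gammas put substantial mass below the censoring point. The
recovery tests are decomposed accordingly — the zero fraction and the exact
realized values survive the loop, and the generating shape/scale are
recovered from the recorded continuous targets (within 3 Monte-Carlo SEs
from the Gamma information matrix). Passing says the estimators and the
extraction geometry are correct; it does not say that count-valued data can
identify a sub-unit-shape continuous Gamma at the low-density end — neither
here nor in real genomes. The generator also omits: Alu subfamily structure
and real consensus sequence, GC-correlated insertion preference, multiple
isoforms per gene (isoform averaging is exercised with hand-built models in
unit tests), and exonized Alus (all generated Alus are intronic, so De = 0
in synthetic runs; exon-Alu logic is unit-tested directly).

## Problem sizes and numerical choices

The acceptance script simulates at the published chromosome-1 size
(N = 1928, 20 replicates, < 10 s). The suite's null-calibration test runs
1000 replicates of both regression models at n = 300 genes; the full-loop
test uses two chromosomes of 60 genes — sizes chosen to make binomial/MC
tolerance bands tight enough to be meaningful while keeping the default test
run fast. Integration of the adjusted density curve uses adaptive quadrature
(tolerance 1e-6). Ties in nearest-site distances resolve to the common
minimum; BH preserves input order; feature tables serialize at 12
significant digits and round-trip losslessly.

## Known limitations

- Symbol reconciliation across annotation sources is out of scope: input
  gene symbols are authoritative.
- Repeat strand is read but ignored downstream; no subfamily stratification.
- The intergenic complement treats assembly gaps as sequence; on real
  genomes, supply N-masked FASTA and interpret intergenic densities
  accordingly (N bases are excluded from GC but not from region lengths).
- Model-2 is OLS on a non-negative response; inference is asymptotic and the
  heavy right tail of Di makes small-n per-chromosome p-values approximate.
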