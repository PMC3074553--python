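# aludist

Gene-centric analysis of Alu retrotransposon distribution and its association
with cancer-gene mutation classes.

Alu elements (~300 nt primate SINEs, ~11% of the human genome) contribute to
genetic instability through insertional mutagenesis and Alu/Alu non-allelic
homologous recombination. `aludist` quantifies where Alus sit relative to
genes and asks whether Alu load differs between classes of cancer genes
(dominant vs recessive, somatic vs germline, translocation vs not). It is
aimed at computational genomicists working from standard annotation files
(BED12/GTF gene models, BED6/RepeatMasker repeat coordinates, FASTA).

## What it computes

**Densities on genes, not windows.** For each multi-exon gene, Alus
overlapping the transcript are split into exon Alus (≥ 1 nt exon overlap) and
intron Alus (Ni = Nt − Ne). Densities divide counts by *Alu-adjusted* lengths
in kilo-nucleotides:

    Di = Ni / Si,   Si = (span − exons − intron-Alu nt) / 1000
    De = Ne / Se,   Se = (exons − exon-Alu nt) / 1000

plus 5'-TTAAAA motif densities (Mi, Me) over the same denominators, adjacent
Alu-pair density (gap < 300 nt), Alu-exon-Alu triplet counts, and Alu-masked
GC content. Multi-transcript genes average over their transcripts;
chromosome-level densities pool counts over pooled adjusted lengths.

**Zero-inflated Gamma mixture.** A substantial fraction of multi-exon genes
carry no intron Alu, so gene-level Di within a chromosome is modelled as

    f(x) = r·1{x = 0} + (1 − r)·Gamma(x; κ, θ)

with r the observed zero fraction and (κ, θ) fitted by maximum likelihood
(profile Newton on the shape) on the Alu-containing genes. Q-Q tables and
adjusted density curves are emitted for model checking.

**Two-step motif regression.** Per chromosome, Model-1 (logistic) regresses
Alu presence on motif density and log10 gene size; Model-2 (OLS, Alu-containing
genes only) regresses Di on the same covariates. Motif-term p-values are
Benjamini-Hochberg adjusted across chromosomes per model, and the motif's
contribution is the increase in Nagelkerke pseudo-R² (Model-1) or R²
(Model-2) over a size-only reduced model.

**Class associations and clustering.** Binary mutation-class labels are
regressed on (Di, log10 size) by logistic regression; cancer genes are
clustered (complete linkage, Euclidean, unscaled 5-feature vectors), the tree
is cut at an absolute height (default 4.5), and class enrichment of the
Alu-dense clusters is tested with Fisher's exact test.

**Synthetic genomes.** `aludist.synthetic_data` generates FASTA + BED12 +
BED6 fixtures with known per-gene target densities, motif couplings, and
class-label models so the entire pipeline is testable offline.

## Worked example

```
aludist simulate --outdir sim --seed 1 --n-chromosomes 2 --n-genes 150
aludist run-all --genes sim/genes.bed12 --repeats sim/alus.bed6 \
    --fasta sim/genome.fa --outdir results
```

The run writes `results/report.md`, which for this seed contains:

```
## Zero-inflated Gamma mixture fits

| chrom | n | r | shape | scale |
|---|---|---|---|---|
| chr1 | 150 | 0.3133 | 0.7727 | 1.044 |
| chr2 | 150 | 0.22 | 0.6562 | 0.9134 |
```

chr1 was simulated with r = 0.281, shape 0.615, scale 1.303: at 150 genes the
zero fraction 0.313 sits within binomial noise of 0.281, and the Gamma
parameters reflect both sampling noise and the granularity of integer Alu
counts (see `docs/methods.md`). The two-step table in the same report shows
no significant motif effect — the generator's default couplings are zero, so
this is the expected null behaviour:

```
| chrom | model | beta | p | BH-adjusted p | contribution |
|---|---|---|---|---|---|
| chr1 | model1 | 0.5996 | 0.381 | 0.597 | 0.007124 |
| chr1 | model2 | -0.6683 | 0.0451 | 0.0903 | 0.03755 |
```

Each stage is also available as its own subcommand (`extract`,
`chrom-densities`, `fit-mixture`, `motif-regression`, `class-assoc`,
`cluster`, `report`) operating on the persisted intermediates.

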