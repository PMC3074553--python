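"""Synthetic genomes with known ground truth.

Emulates the structure the real analysis runs on — per-chromosome gene
counts, log-normal gene lengths, a zero-inflated Gamma target for the
gene-level intron Alu density, a 5'-TTAAAA motif background with optional
Alu-motif coupling, and binary class labels whose log-odds depend on intron
Alu density and log10 gene size — so every pipeline stage is testable with
exact expectations and no external annotation resources.

Construction per gene: draw a log-normal gene length and a multi-exon
structure; draw a target density d from the chromosome's mixture; place
``c = round(d * I / (1000 + 300 d))`` non-overlapping 300-nt Alu intervals
uniformly inside the introns, where I is the total intron length — the count
solves ``c = d * Si`` with Si the Alu-adjusted intron length *after*
insertion, so the realized density matches the target up to rounding; plant
motif occurrences in the non-Alu intron sequence at a Poisson rate that is
multiplied by ``exp(beta_presence * z + beta_intensity * d)`` (z = Alu
presence), both couplings zero by default.

The Alu sequence content is a fixed synthetic 300-nt tag with configurable
GC (not a real Alu consensus): downstream features depend on coordinates
only, and the tag exercises the GC-masking logic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotations_io import (
    GeneModel,
    RepeatInterval,
    TranscriptModel,
    write_gene_models,
    write_repeat_intervals,
)

__all__ = [
    "ChromosomeSpec",
    "SyntheticGenomeSpec",
    "SyntheticTruth",
    "SimulatedGenome",
    "CHROM_MIXTURE_PARAMS",
    "simulate_density_sample",
    "simulate_genome",
    "simulate_class_labels",
    "SimulationError",
]


class SimulationError(ValueError):
    pass


# Published per-chromosome mixture parameters (N, r, scale theta, shape kappa)
# for the human genome; the chromosome entries below default to the first four.
CHROM_MIXTURE_PARAMS: dict[str, tuple[int, float, float, float]] = {
    "chr1": (1928, 0.281, 1.303, 0.615),
    "chr2": (1212, 0.271, 1.498, 0.441),
    "chr3": (1036, 0.248, 1.398, 0.459),
    "chr4": (728, 0.26, 1.573, 0.31),
    "chr5": (837, 0.238, 1.406, 0.42),
    "chr6": (952, 0.279, 1.369, 0.47),
    "chr7": (893, 0.308, 1.157, 0.735),
    "chr8": (667, 0.315, 1.553, 0.403),
    "chr9": (734, 0.342, 1.656, 0.411),
    "chr10": (749, 0.288, 1.509, 0.457),
    "chr11": (1072, 0.328, 1.349, 0.528),
    "chr12": (984, 0.269, 1.262, 0.71),
    "chr13": (325, 0.295, 1.881, 0.246),
    "chr14": (562, 0.285, 1.667, 0.475),
    "chr15": (580, 0.284, 1.367, 0.59),
    "chr16": (811, 0.337, 1.74, 0.617),
    "chr17": (1106, 0.344, 1.782, 0.617),
    "chr18": (262, 0.214, 1.694, 0.329),
    "chr19": (1342, 0.286, 1.586, 1.002),
    "chr20": (537, 0.307, 1.363, 0.582),
    "chr21": (203, 0.241, 1.758, 0.355),
    "chr22": (452, 0.352, 1.762, 0.595),
    "chrX": (778, 0.356, 1.241, 0.471),
    "chrY": (93, 0.688, 2.098, 0.217),
}


@dataclass(frozen=True)
class ChromosomeSpec:
    """One synthetic chromosome: gene count and target density mixture."""

    name: str
    n_genes: int
    r: float
    shape: float
    scale: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.r <= 1.0):
            raise SimulationError(f"{self.name}: r must lie in [0, 1]")
        if self.shape <= 0 or self.scale <= 0:
            raise SimulationError(f"{self.name}: shape and scale must be positive")
        if self.n_genes < 1:
            raise SimulationError(f"{self.name}: need at least 1 gene")


def _default_chromosomes() -> tuple[ChromosomeSpec, ...]:
    # first four published chromosome parameter rows, gene counts scaled to
    # a desk-sized genome (~200 genes each)
    return tuple(
        ChromosomeSpec(name, 200, r, shape=kappa, scale=theta)
        for name, (_, r, theta, kappa) in list(CHROM_MIXTURE_PARAMS.items())[:4]
    )


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Generation parameters; defaults emulate the human multi-exon gene set.

    Gene lengths are log10-normal (median ~25 Knt); exon counts are
    2 + Geometric; the 300-nt ``alu_length`` matches the full-length element.
    ``motif_rate`` is the background 5'-TTAAAA planting rate per adjusted
    intron Knt; couplings are on the log-rate scale.
    """

    chromosomes: tuple[ChromosomeSpec, ...] = field(default_factory=_default_chromosomes)
    gene_len_log10_mean: float = 4.4
    gene_len_log10_sd: float = 0.35
    exon_geometric_p: float = 0.15
    exon_len_log_mean: float = math.log(150.0)
    exon_len_log_sd: float = 0.4
    alu_length: int = 300
    alu_gc: float = 0.55
    motif: str = "TTAAAA"
    motif_rate: float = 1.0  # per adjusted intron Knt
    beta_presence: float = 0.0  # motif log-rate bump for Alu-containing genes
    beta_intensity: float = 0.0  # motif log-rate slope on target density
    intergenic_gap_mean: float = 3000.0
    intergenic_alu_rate: float = 0.3  # per Knt of intergenic sequence
    class_intercept: float = 0.0
    class_beta_di: float = 0.0
    class_beta_size: float = 0.0

    def __post_init__(self) -> None:
        if self.alu_length <= 0 or self.motif_rate < 0 or self.intergenic_alu_rate < 0:
            raise SimulationError("rates and lengths must be nonnegative")
        if not (0.0 <= self.alu_gc <= 1.0):
            raise SimulationError("alu_gc must lie in [0, 1]")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth: per-gene target vs realized densities, per-chromosome params."""

    genes: pd.DataFrame  # gene, chrom, target_density, realized_density, n_intron_alu, si_knt, motif_count
    chromosome_params: dict[str, tuple[float, float, float]]  # chrom -> (r, shape, scale)
    infeasible_resamples: int


@dataclass(frozen=True)
class SimulatedGenome:
    fasta_path: Path
    genes_path: Path
    repeats_path: Path
    truth: SyntheticTruth
    gene_models: tuple[GeneModel, ...]
    repeats: tuple[RepeatInterval, ...]
    chrom_lengths: dict[str, int]


def simulate_density_sample(
    r: float, shape: float, scale: float, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw n densities from the zero-inflated Gamma: 0 w.p. r, else Gamma."""
    if not (0.0 <= r <= 1.0) or shape <= 0 or scale <= 0 or n < 1:
        raise SimulationError("invalid mixture parameters")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    zero = rng.random(n) < r
    values = rng.gamma(shape, scale, n)
    values[zero] = 0.0
    return values


def _place_nonoverlapping(rng, region_len: int, count: int, item_len: int) -> list[int]:
    """Uniform non-overlapping placement of *count* items in [0, region_len).

    Gap method: draw sorted uniforms in the slack, then stack items — exact
    uniform sampling over non-overlapping configurations, no rejection.
    """
    slack = region_len - count * item_len
    if slack < 0:
        raise SimulationError("items do not fit in region")
    offsets = np.sort(rng.random(count) * slack)
    return [int(offsets[j] + j * item_len) for j in range(count)]


def _distribute_counts(rng, capacities: list[int], total: int) -> list[int]:
    """Split *total* items across regions, respecting per-region capacities."""
    if total > sum(capacities):
        raise SimulationError("total exceeds capacity")
    weights = np.asarray(capacities, dtype=float)
    counts = rng.multinomial(total, weights / weights.sum())
    # repair overflow deterministically by spilling to regions with room
    counts = counts.astype(int).tolist()
    for i in range(len(counts)):
        while counts[i] > capacities[i]:
            j = max(range(len(counts)), key=lambda k: capacities[k] - counts[k])
            counts[i] -= 1
            counts[j] += 1
    return counts


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _alu_tag(rng: np.random.Generator, length: int, gc: float) -> bytes:
    """A fixed synthetic repeat tag with the requested GC fraction."""
    n_gc = int(round(gc * length))
    bases = [b"G", b"C"] * (n_gc // 2 + 1) + [b"A", b"T"] * ((length - n_gc) // 2 + 1)
    arr = np.array([b[0] for b in bases[:length]], dtype=np.uint8)
    rng.shuffle(arr)
    return arr.tobytes()


def simulate_genome(
    spec: SyntheticGenomeSpec, seed: int, outdir: str | Path
) -> SimulatedGenome:
    """Generate a full synthetic genome and write FASTA/BED12/BED6 + truth.

    Deterministic given ``(spec, seed)``.  Gene densities whose Alu demand
    exceeds the intron capacity are resampled (counted in the truth record).
    """
    rng = np.random.default_rng(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    alu_len = spec.alu_length
    tag = _alu_tag(rng, alu_len, spec.alu_gc)
    motif_bytes = spec.motif.encode()
    mlen = len(motif_bytes)

    gene_models: list[GeneModel] = []
    repeats: list[RepeatInterval] = []
    truth_rows: list[dict] = []
    chrom_seqs: dict[str, bytes] = {}
    chrom_lengths: dict[str, int] = {}
    infeasible = 0

    for chrom in spec.chromosomes:
        gene_layouts = []  # (symbol, strand, exons, alus, motif_positions) in gene-local coords
        for gi in range(chrom.n_genes):
            symbol = f"G{chrom.name[3:]}_{gi:04d}"
            # gene structure
            for _attempt in range(100):
                length = int(round(10 ** rng.normal(spec.gene_len_log10_mean, spec.gene_len_log10_sd)))
                length = max(length, 2500)
                n_exons = 2 + int(rng.geometric(spec.exon_geometric_p)) - 1
                exon_lens = np.maximum(
                    20, np.round(rng.lognormal(spec.exon_len_log_mean, spec.exon_len_log_sd, n_exons))
                ).astype(int)
                if exon_lens.sum() < 0.4 * length:
                    break
            else:
                exon_lens = np.full(2, 100, dtype=int)
                n_exons = 2
            intron_total = length - int(exon_lens.sum())
            props = rng.dirichlet(np.ones(n_exons - 1))
            intron_lens = np.maximum(400, np.round(props * intron_total)).astype(int)
            # target density, resampled while infeasible
            capacity = [int(il // alu_len) for il in intron_lens]
            for _attempt in range(200):
                d = float(simulate_density_sample(chrom.r, chrom.shape, chrom.scale, 1, rng)[0])
                total_intron = int(intron_lens.sum())
                c = int(round(d * total_intron / (1000.0 + alu_len * d)))
                if d > 0:
                    c = max(1, c)
                if c <= int(0.8 * sum(capacity)):
                    break
                infeasible += 1
            else:
                d, c = 0.0, 0

            counts = _distribute_counts(rng, capacity, c) if c else [0] * len(capacity)
            # local coordinates: exon/intron alternation starting with exon 0
            exons_local: list[tuple[int, int]] = []
            alus_local: list[tuple[int, int]] = []
            cursor = 0
            for i, el in enumerate(exon_lens):
                exons_local.append((cursor, cursor + int(el)))
                cursor += int(el)
                if i < len(intron_lens):
                    il = int(intron_lens[i])
                    for off in _place_nonoverlapping(rng, il, counts[i], alu_len):
                        alus_local.append((cursor + off, cursor + off + alu_len))
                    cursor += il
            gene_len = cursor
            si_knt = (int(intron_lens.sum()) - c * alu_len) / 1000.0
            realized = c / si_knt if si_knt > 0 else float("nan")

            # motif planting in non-Alu intron segments
            z = 1.0 if d > 0 else 0.0
            rate = spec.motif_rate * math.exp(spec.beta_presence * z + spec.beta_intensity * d)
            m = int(rng.poisson(rate * si_knt))
            segments: list[tuple[int, int]] = []
            pos = 0
            blocked = sorted(exons_local + alus_local)
            for bs, be in blocked:
                if bs > pos:
                    segments.append((pos, bs))
                pos = max(pos, be)
            if pos < gene_len:
                segments.append((pos, gene_len))
            seg_caps = [max(0, (e - s) // mlen) for s, e in segments]
            m = min(m, sum(seg_caps))
            motif_local: list[int] = []
            if m:
                per_seg = _distribute_counts(rng, seg_caps, m)
                for (s, e), cnt in zip(segments, per_seg):
                    for off in _place_nonoverlapping(rng, e - s, cnt, mlen):
                        motif_local.append(s + off)

            strand = "+" if rng.random() < 0.5 else "-"
            gene_layouts.append((symbol, strand, exons_local, alus_local, motif_local, gene_len))
            truth_rows.append(
                {
                    "gene": symbol,
                    "chrom": chrom.name,
                    "target_density": d,
                    "realized_density": realized,
                    "n_intron_alu": c,
                    "si_knt": si_knt,
                    "motif_count": len(motif_local),
                }
            )

        # chromosome layout: intergenic gap, gene, gap, gene, ...
        placements = []  # (gene_start, layout)
        intergenic_alus: list[tuple[int, int]] = []
        cursor = 0
        for layout in gene_layouts:
            gap = int(round(rng.exponential(spec.intergenic_gap_mean))) + 500
            n_ig = int(rng.poisson(spec.intergenic_alu_rate * gap / 1000.0))
            n_ig = min(n_ig, gap // alu_len)
            for off in _place_nonoverlapping(rng, gap, n_ig, alu_len):
                intergenic_alus.append((cursor + off, cursor + off + alu_len))
            cursor += gap
            placements.append((cursor, layout))
            cursor += layout[5]
        cursor += 500
        chrom_len = cursor

        seq = _BASES[rng.integers(0, 4, chrom_len)].copy()
        all_alus: list[tuple[int, int]] = list(intergenic_alus)
        for start, (symbol, strand, exons_l, alus_l, motifs_l, glen) in placements:
            exons = tuple((start + s, start + e) for s, e in exons_l)
            t = TranscriptModel(
                transcript_id=f"{symbol}.t1",
                gene_symbol=symbol,
                chrom=chrom.name,
                strand=strand,
                start=start,
                end=start + glen,
                exons=exons,
            )
            gene_models.append(GeneModel(symbol, chrom.name, strand, (t,)))
            for s, e in alus_l:
                all_alus.append((start + s, start + e))
            for p in motifs_l:
                seq[start + p : start + p + mlen] = np.frombuffer(motif_bytes, dtype=np.uint8)
        tag_arr = np.frombuffer(tag, dtype=np.uint8)
        for s, e in all_alus:
            seq[s:e] = tag_arr[: e - s]
            repeats.append(RepeatInterval(chrom.name, s, e, "AluYsim", "+"))
        chrom_seqs[chrom.name] = seq.tobytes()
        chrom_lengths[chrom.name] = chrom_len

    # emit files
    fasta_path = outdir / "genome.fa"
    with open(fasta_path, "w") as fh:
        for name, seq in chrom_seqs.items():
            fh.write(f">{name}\n")
            text = seq.decode("ascii")
            for i in range(0, len(text), 60):
                fh.write(text[i : i + 60] + "\n")
    genes_path = outdir / "genes.bed12"
    write_gene_models(gene_models, genes_path, format="bed12")
    repeats_sorted = sorted(repeats, key=lambda r: (r.chrom, r.start))
    repeats_path = outdir / "alus.bed6"
    write_repeat_intervals(repeats_sorted, repeats_path)

    truth = SyntheticTruth(
        genes=pd.DataFrame(truth_rows),
        chromosome_params={c.name: (c.r, c.shape, c.scale) for c in spec.chromosomes},
        infeasible_resamples=infeasible,
    )
    truth.genes.to_csv(outdir / "truth.tsv", sep="\t", index=False, float_format="%.12g")
    return SimulatedGenome(
        fasta_path=fasta_path,
        genes_path=genes_path,
        repeats_path=repeats_path,
        truth=truth,
        gene_models=tuple(gene_models),
        repeats=tuple(repeats_sorted),
        chrom_lengths=chrom_lengths,
    )


def simulate_class_labels(
    features: pd.DataFrame,
    intercept: float,
    beta_di: float,
    beta_size: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Bernoulli class labels with logit = intercept + beta_di*Di + beta_size*log10_size."""
    if len(features) == 0:
        raise SimulationError("empty feature table")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eta = (
        intercept
        + beta_di * features["Di"].to_numpy(dtype=float)
        + beta_size * features["log10_size"].to_numpy(dtype=float)
    )
    prob = 1.0 / (1.0 + np.exp(-eta))
    return (rng.random(len(prob)) < prob).astype(int)
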