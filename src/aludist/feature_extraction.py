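"""Gene-level and chromosome-level Alu/motif densities.

All densities are counts per adjusted kilo-nucleotide (Knt): the nucleotides
covered by Alu elements are removed from the denominator before dividing, so
a density measures occurrences per Knt of *non-Alu* sequence.  Per-gene values
are arithmetic means over the gene's multi-exon transcripts.

Assignment rule: an Alu overlapping a transcript span by >= 1 nt counts toward
the transcript total Nt; it is an exon Alu if it overlaps any exon by >= 1 nt
(exonized and exonic Alus are not distinguished), otherwise an intron Alu,
and Ni = Nt - Ne.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .annotations_io import (
    GeneModel,
    GenomicSite,
    RepeatInterval,
    SequenceStore,
    TranscriptModel,
)

__all__ = [
    "TranscriptAluPartition",
    "GeneAluFeatures",
    "ChromosomeDensities",
    "FeatureExtractionError",
    "partition_repeats",
    "gene_alu_densities",
    "scan_motif",
    "gene_motif_densities",
    "alu_pair_density",
    "alu_exon_alu_triplets",
    "adjusted_gc_content",
    "compute_gene_features",
    "chromosome_region_densities",
    "nearest_site_distance",
    "DEFAULT_MOTIF",
    "DEFAULT_GAP",
]

DEFAULT_MOTIF = "TTAAAA"  # preferred L1-endonuclease cleavage hexamer
DEFAULT_GAP = 300  # nt; Alu-pair and Alu-exon-Alu adjacency threshold


class FeatureExtractionError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Interval helpers
# ---------------------------------------------------------------------------


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Length of the intersection of two half-open intervals (0 if disjoint)."""
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def _clip_total(interval: tuple[int, int], regions: Sequence[tuple[int, int]]) -> int:
    """Total nt of *interval* lying inside the (disjoint) *regions*."""
    s, e = interval
    return sum(_overlap(s, e, rs, re) for rs, re in regions)


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals as a sorted disjoint list."""
    ivs = sorted(intervals)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


# ---------------------------------------------------------------------------
# Alu partitioning and Eq.-style densities
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TranscriptAluPartition:
    """Alus of one transcript split into exon and intron assignments.

    ``*_alu_len`` totals are clipped to the assigned region and the transcript
    span, so they can be subtracted from region lengths without going negative.
    """

    n_total: int
    n_exon: int
    n_intron: int
    exon_alu_intervals: tuple[tuple[int, int], ...]
    intron_alu_intervals: tuple[tuple[int, int], ...]
    exon_alu_len: int
    intron_alu_len: int

    def __post_init__(self) -> None:
        assert self.n_intron == self.n_total - self.n_exon


def partition_repeats(
    transcript: TranscriptModel, repeats: Iterable[RepeatInterval]
) -> TranscriptAluPartition:
    """Assign each span-overlapping repeat to exon or intron (exon wins ties)."""
    exon_ivs: list[tuple[int, int]] = []
    intron_ivs: list[tuple[int, int]] = []
    exon_len = 0
    intron_len = 0
    exons = transcript.exons
    introns = transcript.introns
    for r in repeats:
        if r.chrom != transcript.chrom:
            continue
        if _overlap(r.start, r.end, transcript.start, transcript.end) == 0:
            continue
        if any(_overlap(r.start, r.end, s, e) for s, e in exons):
            exon_ivs.append((r.start, r.end))
            exon_len += _clip_total((r.start, r.end), exons)
        else:
            intron_ivs.append((r.start, r.end))
            intron_len += _clip_total((r.start, r.end), introns)
    return TranscriptAluPartition(
        n_total=len(exon_ivs) + len(intron_ivs),
        n_exon=len(exon_ivs),
        n_intron=len(intron_ivs),
        exon_alu_intervals=tuple(sorted(exon_ivs)),
        intron_alu_intervals=tuple(sorted(intron_ivs)),
        exon_alu_len=exon_len,
        intron_alu_len=intron_len,
    )


def _transcript_adjusted_lengths(
    transcript: TranscriptModel, part: TranscriptAluPartition
) -> tuple[float, float]:
    """(Si, Se) in Knt: intron/exon lengths with assigned Alu nt removed."""
    si = (transcript.span_length - transcript.exon_length - part.intron_alu_len) / 1000.0
    se = (transcript.exon_length - part.exon_alu_len) / 1000.0
    return si, se


def gene_alu_densities(
    gene: GeneModel, repeats: Iterable[RepeatInterval]
) -> tuple[float, float, float, float]:
    """Per-gene (Di, De, Si, Se): intron/exon Alu densities and adjusted lengths.

    Each is the mean over the gene's multi-exon transcripts of the per-transcript
    value Di = Ni/Si, De = Ne/Se with Si, Se in Knt.
    """
    repeats = [r for r in repeats if r.chrom == gene.chrom]
    di_vals, de_vals, si_vals, se_vals = [], [], [], []
    for t in gene.multi_exon_transcripts:
        part = partition_repeats(t, repeats)
        si, se = _transcript_adjusted_lengths(t, part)
        if si <= 0 or se <= 0:
            continue
        di_vals.append(part.n_intron / si)
        de_vals.append(part.n_exon / se)
        si_vals.append(si)
        se_vals.append(se)
    if not di_vals:
        raise FeatureExtractionError(
            f"gene {gene.gene_symbol}: no transcript with positive adjusted lengths"
        )
    n = len(di_vals)
    return (sum(di_vals) / n, sum(de_vals) / n, sum(si_vals) / n, sum(se_vals) / n)


# ---------------------------------------------------------------------------
# Motif scanning and densities
# ---------------------------------------------------------------------------


def scan_motif(
    sequence: str, motif: str, region: tuple[int, int] | None = None
) -> list[int]:
    """All (possibly overlapping) exact forward-strand matches of *motif*.

    Positions are 0-based starts relative to *sequence*; only matches whose
    full extent lies inside the half-open *region* are returned.  Matching is
    case-insensitive; the motif must be over {A, C, G, T}.
    """
    motif = motif.upper()
    if not motif or any(b not in "ACGT" for b in motif):
        raise ValueError(f"motif must be a nonempty string over ACGT, got {motif!r}")
    seq = sequence.upper()
    lo, hi = region if region is not None else (0, len(seq))
    positions: list[int] = []
    i = seq.find(motif, max(lo, 0))
    while i != -1 and i + len(motif) <= hi:
        positions.append(i)
        i = seq.find(motif, i + 1)
    return positions


def gene_motif_densities(
    gene: GeneModel,
    repeats: Iterable[RepeatInterval],
    sequences: SequenceStore,
    motif: str = DEFAULT_MOTIF,
    count_motifs_in_alus: bool = False,
) -> tuple[float, float]:
    """Per-gene (Mi, Me): intron and exon motif densities per adjusted Knt.

    A motif occurrence is assigned exon/intron by the same rule as Alus
    (>= 1 nt exon overlap wins); occurrences overlapping any assigned Alu
    interval by >= 1 nt are skipped unless *count_motifs_in_alus* — mirroring
    the removal of Alu nucleotides from the denominator.
    """
    repeats = [r for r in repeats if r.chrom == gene.chrom]
    mi_vals, me_vals = [], []
    for t in gene.multi_exon_transcripts:
        part = partition_repeats(t, repeats)
        si, se = _transcript_adjusted_lengths(t, part)
        if si <= 0 or se <= 0:
            continue
        seq = sequences.fetch(t.chrom, t.start, t.end)
        hits = scan_motif(seq, motif)
        alu_ivs = part.exon_alu_intervals + part.intron_alu_intervals
        m = len(motif)
        n_intron = n_exon = 0
        for pos in hits:
            s = t.start + pos
            e = s + m
            if not count_motifs_in_alus and any(
                _overlap(s, e, a, b) for a, b in alu_ivs
            ):
                continue
            if any(_overlap(s, e, a, b) for a, b in t.exons):
                n_exon += 1
            else:
                n_intron += 1
        mi_vals.append(n_intron / si)
        me_vals.append(n_exon / se)
    if not mi_vals:
        raise FeatureExtractionError(
            f"gene {gene.gene_symbol}: no transcript with positive adjusted lengths"
        )
    return sum(mi_vals) / len(mi_vals), sum(me_vals) / len(me_vals)


# ---------------------------------------------------------------------------
# Alu pairs and Alu-exon-Alu triplets
# ---------------------------------------------------------------------------


def alu_pair_count(
    intron_alu_intervals: Sequence[tuple[int, int]], gap: int = DEFAULT_GAP
) -> int:
    """Pairs of consecutive intron Alus separated by strictly less than *gap* nt."""
    ivs = sorted(intron_alu_intervals)
    return sum(1 for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]) if s2 - e1 < gap)


def alu_pair_density(
    transcript: TranscriptModel,
    part: TranscriptAluPartition,
    gap: int = DEFAULT_GAP,
) -> float:
    """Adjacent intron Alu pairs per adjusted intron Knt for one transcript."""
    si, _ = _transcript_adjusted_lengths(transcript, part)
    if si <= 0:
        raise FeatureExtractionError("non-positive adjusted intron length")
    return alu_pair_count(part.intron_alu_intervals, gap) / si


def alu_exon_alu_triplets(
    transcript: TranscriptModel,
    repeats: Iterable[RepeatInterval],
    gap: int = DEFAULT_GAP,
) -> int:
    """Exons flanked by an Alu on each side with both gaps strictly < *gap* nt.

    Counted per exon: one Alu may flank two consecutive exons, contributing to
    both; each exon contributes at most 1.
    """
    ivs = sorted(
        (r.start, r.end)
        for r in repeats
        if r.chrom == transcript.chrom
    )
    count = 0
    for es, ee in transcript.exons:
        left = any(e <= es and es - e < gap for s, e in ivs)
        right = any(s >= ee and s - ee < gap for s, e in ivs)
        if left and right:
            count += 1
    return count


# ---------------------------------------------------------------------------
# GC content
# ---------------------------------------------------------------------------


def adjusted_gc_content(
    gene: GeneModel,
    repeats: Iterable[RepeatInterval],
    sequences: SequenceStore,
) -> float:
    """GC fraction of the gene hull with Alu-covered nucleotides masked out.

    Ambiguous bases (anything outside ACGT) are dropped from numerator and
    denominator.  Raises if the whole span is Alu-covered (GC undefined).
    """
    start, end = gene.span
    seq = sequences.fetch(gene.chrom, start, end)
    masked = bytearray(seq, "ascii")
    for r in repeats:
        if r.chrom != gene.chrom:
            continue
        s = max(r.start, start) - start
        e = min(r.end, end) - start
        for i in range(s, max(s, e)):
            masked[i] = 0
    gc = total = 0
    for b in masked:
        if b == 0:
            continue
        c = chr(b)
        if c in "GC":
            gc += 1
            total += 1
        elif c in "AT":
            total += 1
    if total == 0:
        raise FeatureExtractionError(
            f"gene {gene.gene_symbol}: span entirely Alu-covered or ambiguous; GC undefined"
        )
    return gc / total


# ---------------------------------------------------------------------------
# Full per-gene feature vector
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneAluFeatures:
    """The per-gene feature vector used throughout the downstream statistics."""

    gene_symbol: str
    chrom: str
    strand: str
    Di: float
    De: float
    Mi: float
    Me: float
    pair_density: float
    triplet_count: float
    gc_adjusted: float
    Si: float
    Se: float
    log10_size: float


def compute_gene_features(
    gene: GeneModel,
    repeats: Iterable[RepeatInterval],
    sequences: SequenceStore | None = None,
    motif: str = DEFAULT_MOTIF,
    gap: int = DEFAULT_GAP,
    count_motifs_in_alus: bool = False,
) -> GeneAluFeatures:
    """Assemble the full feature vector for one gene.

    ``log10_size`` is the log10 of the mean adjusted transcript length in nt
    (span minus assigned Alu nucleotides, i.e. (Si + Se) * 1000).  Without a
    sequence store the motif and GC features are NaN.
    """
    repeats = [r for r in repeats if r.chrom == gene.chrom]
    di_vals, de_vals, si_vals, se_vals, pair_vals, trip_vals = [], [], [], [], [], []
    for t in gene.multi_exon_transcripts:
        part = partition_repeats(t, repeats)
        si, se = _transcript_adjusted_lengths(t, part)
        if si <= 0 or se <= 0:
            continue
        di_vals.append(part.n_intron / si)
        de_vals.append(part.n_exon / se)
        si_vals.append(si)
        se_vals.append(se)
        pair_vals.append(alu_pair_count(part.intron_alu_intervals, gap) / si)
        trip_vals.append(alu_exon_alu_triplets(t, repeats, gap))
    if not di_vals:
        raise FeatureExtractionError(
            f"gene {gene.gene_symbol}: no transcript with positive adjusted lengths"
        )
    n = len(di_vals)
    mean = lambda xs: sum(xs) / len(xs)  # noqa: E731
    if sequences is not None:
        mi, me = gene_motif_densities(gene, repeats, sequences, motif, count_motifs_in_alus)
        gc = adjusted_gc_content(gene, repeats, sequences)
    else:
        mi = me = gc = float("nan")
    si_mean, se_mean = mean(si_vals), mean(se_vals)
    return GeneAluFeatures(
        gene_symbol=gene.gene_symbol,
        chrom=gene.chrom,
        strand=gene.strand,
        Di=mean(di_vals),
        De=mean(de_vals),
        Mi=mi,
        Me=me,
        pair_density=mean(pair_vals),
        triplet_count=mean(trip_vals),
        gc_adjusted=gc,
        Si=si_mean,
        Se=se_mean,
        log10_size=math.log10((si_mean + se_mean) * 1000.0),
    )


# ---------------------------------------------------------------------------
# Chromosome-level pooled densities
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChromosomeDensities:
    """Pooled (not gene-averaged) densities for one chromosome, per adjusted Knt."""

    chrom: str
    intron_alu: float
    exon_alu: float
    intergenic_alu: float
    intron_motif: float
    chrom_motif: float


def chromosome_region_densities(
    genes: Sequence[GeneModel],
    repeats: Sequence[RepeatInterval],
    motif_positions: Sequence[int],
    chrom_length: int,
    motif_length: int = len(DEFAULT_MOTIF),
) -> ChromosomeDensities:
    """Chromosome-level intron/exon/intergenic Alu and motif densities.

    Every density is a pooled count over a pooled Alu-adjusted length — NOT the
    mean of per-gene densities.  Intron/exon pools run over all multi-exon
    transcripts of the given genes; intergenic regions are the complement of
    the merged transcript spans within ``[0, chrom_length)``.  *motif_positions*
    are 0-based chromosome coordinates of motif starts.
    """
    if not genes and not repeats:
        chroms = set()
    else:
        chroms = {g.chrom for g in genes} | {r.chrom for r in repeats}
    if len(chroms) > 1:
        raise FeatureExtractionError(f"inputs span multiple chromosomes: {sorted(chroms)}")
    chrom = next(iter(chroms)) if chroms else ""
    max_coord = max(
        [t.end for g in genes for t in g.transcripts] + [r.end for r in repeats] + [0]
    )
    if chrom_length < max_coord:
        raise FeatureExtractionError(
            f"chromosome length {chrom_length} < max annotated coordinate {max_coord}"
        )

    import numpy as np

    sum_ni = sum_ne = 0
    sum_si = sum_se = 0.0
    sum_mi = 0
    spans: list[tuple[int, int]] = []
    motif_starts = np.sort(np.asarray(list(motif_positions), dtype=int))
    repeats_by_start = sorted(repeats, key=lambda r: r.start)
    rep_starts = np.array([r.start for r in repeats_by_start], dtype=int)
    max_rep_len = max((r.length for r in repeats_by_start), default=0)
    for g in genes:
        for t in g.transcripts:
            spans.append((t.start, t.end))
        for t in g.multi_exon_transcripts:
            # repeats overlapping the span: start positions in a window widened
            # by the longest repeat length on the left
            lo = int(np.searchsorted(rep_starts, t.start - max_rep_len, side="left"))
            hi = int(np.searchsorted(rep_starts, t.end, side="left"))
            near = [r for r in repeats_by_start[lo:hi] if r.end > t.start]
            part = partition_repeats(t, near)
            si, se = _transcript_adjusted_lengths(t, part)
            if si <= 0 or se <= 0:
                continue
            sum_ni += part.n_intron
            sum_ne += part.n_exon
            sum_si += si
            sum_se += se
            alu_ivs = part.exon_alu_intervals + part.intron_alu_intervals
            lo_m = int(np.searchsorted(motif_starts, t.start, side="left"))
            hi_m = int(np.searchsorted(motif_starts, t.end - motif_length, side="right"))
            for pos in motif_starts[lo_m:hi_m]:
                s, e = int(pos), int(pos) + motif_length
                if any(_overlap(s, e, a, b) for a, b in alu_ivs):
                    continue
                if not any(_overlap(s, e, a, b) for a, b in t.exons):
                    sum_mi += 1

    merged = merge_intervals(spans)
    intergenic: list[tuple[int, int]] = []
    cursor = 0
    for s, e in merged:
        if s > cursor:
            intergenic.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < chrom_length:
        intergenic.append((cursor, chrom_length))

    def _overlaps_any(starts: np.ndarray, ends: np.ndarray, s: int, e: int) -> bool:
        """Does [s, e) intersect any of the sorted disjoint intervals?"""
        i = int(np.searchsorted(ends, s, side="right"))
        return i < len(starts) and starts[i] < e

    m_starts = np.array([s for s, _ in merged], dtype=int)
    m_ends = np.array([e for _, e in merged], dtype=int)
    n_intergenic_alu = 0
    intergenic_alu_nt = 0
    for r in repeats:
        if not _overlaps_any(m_starts, m_ends, r.start, r.end):
            n_intergenic_alu += 1
        intergenic_alu_nt += _clip_total((r.start, r.end), intergenic)
    intergenic_len = sum(e - s for s, e in intergenic)
    adj_intergenic = (intergenic_len - intergenic_alu_nt) / 1000.0

    alu_merged = merge_intervals((r.start, r.end) for r in repeats)
    a_starts = np.array([s for s, _ in alu_merged], dtype=int)
    a_ends = np.array([e for _, e in alu_merged], dtype=int)
    total_alu_nt = sum(min(e, chrom_length) - s for s, e in alu_merged)
    adj_chrom = (chrom_length - total_alu_nt) / 1000.0
    n_chrom_motif = sum(
        1
        for pos in motif_starts
        if pos + motif_length <= chrom_length
        and not _overlaps_any(a_starts, a_ends, int(pos), int(pos) + motif_length)
    )

    def _ratio(num: float, den: float) -> float:
        return num / den if den > 0 else float("nan")

    return ChromosomeDensities(
        chrom=chrom,
        intron_alu=_ratio(sum_ni, sum_si),
        exon_alu=_ratio(sum_ne, sum_se),
        intergenic_alu=_ratio(n_intergenic_alu, adj_intergenic),
        intron_motif=_ratio(sum_mi, sum_si),
        chrom_motif=_ratio(n_chrom_motif, adj_chrom),
    )


# ---------------------------------------------------------------------------
# Nearest genomic site
# ---------------------------------------------------------------------------


def nearest_site_distance(gene: GeneModel, sites: Iterable[GenomicSite]) -> int:
    """Distance (nt) from the gene hull midpoint to the nearest same-chromosome site."""
    same = [s for s in sites if s.chrom == gene.chrom]
    if not same:
        raise FeatureExtractionError(f"no site on chromosome {gene.chrom}")
    start, end = gene.span
    mid = (start + end) // 2
    return min(abs(mid - s.position) for s in same)
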