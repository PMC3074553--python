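"""Density arithmetic, motif scanning, and brute-force oracle agreement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aludist import (
    FeatureExtractionError,
    GeneModel,
    GenomicSite,
    RepeatInterval,
    TranscriptModel,
    adjusted_gc_content,
    alu_exon_alu_triplets,
    alu_pair_count,
    alu_pair_density,
    chromosome_region_densities,
    compute_gene_features,
    gene_alu_densities,
    gene_motif_densities,
    nearest_site_distance,
    partition_repeats,
    scan_motif,
)

from conftest import make_repeat, make_transcript


class FakeStore:
    """In-memory sequence accessor for unit tests."""

    def __init__(self, seqs):
        self.seqs = {k: v.upper() for k, v in seqs.items()}

    def __contains__(self, chrom):
        return chrom in self.seqs

    def length(self, chrom):
        return len(self.seqs[chrom])

    def fetch(self, chrom, start, end):
        if chrom not in self.seqs:
            raise KeyError(chrom)
        if start < 0 or end > len(self.seqs[chrom]):
            raise IndexError((start, end))
        return self.seqs[chrom][start:end]


# -- partition_repeats -----------------------------------------------------


def test_fully_intronic_alu(toy_transcript):
    part = partition_repeats(toy_transcript, [make_repeat(400, 700)])
    assert (part.n_total, part.n_exon, part.n_intron) == (1, 0, 1)
    assert part.intron_alu_len == 300


def test_boundary_straddling_alu_is_exonic(toy_transcript):
    part = partition_repeats(toy_transcript, [make_repeat(850, 950)])
    assert (part.n_exon, part.n_intron) == (1, 0)
    assert part.exon_alu_len == 50  # only the in-exon half counts toward exon length


def test_alu_outside_span_ignored(toy_transcript):
    part = partition_repeats(toy_transcript, [make_repeat(2000, 2300)])
    assert part.n_total == 0


def test_counts_conserve(toy_transcript):
    reps = [make_repeat(400, 700), make_repeat(850, 950), make_repeat(50, 80)]
    part = partition_repeats(toy_transcript, reps)
    assert part.n_intron + part.n_exon == part.n_total == 3


@settings(max_examples=500, deadline=None, derandomize=True)
@given(st.data())
def test_partition_agrees_with_brute_force(data):
    """Randomized toys: assignment matches an O(n*m) per-base overlap scan."""
    n_exons = data.draw(st.integers(1, 5))
    bounds = sorted(data.draw(
        st.lists(st.integers(0, 500), min_size=2 * n_exons, max_size=2 * n_exons,
                 unique=True)
    ))
    exons = tuple((bounds[2 * i], bounds[2 * i + 1]) for i in range(n_exons))
    t = make_transcript(exons[0][0], exons[-1][1], exons)
    reps = []
    for _ in range(data.draw(st.integers(0, 8))):
        s = data.draw(st.integers(-50, 550))
        ln = data.draw(st.integers(1, 120))
        reps.append(make_repeat(s, s + ln))
    part = partition_repeats(t, reps)
    # oracle: per-base membership sets
    exon_bases = {b for s, e in exons for b in range(s, e)}
    span_bases = set(range(t.start, t.end))
    ne = ni = 0
    for r in reps:
        bases = set(range(r.start, r.end))
        if not bases & span_bases:
            continue
        if bases & exon_bases:
            ne += 1
        else:
            ni += 1
    assert (part.n_exon, part.n_intron) == (ne, ni)


# -- gene_alu_densities ----------------------------------------------------


def test_worked_density_example():
    """10 Knt transcript, 2 Knt exons, three 300 nt intronic + one exonic Alu."""
    t = make_transcript(0, 10_000, [(0, 1000), (9000, 10_000)])
    gene = GeneModel("G", "chr1", "+", (t,))
    reps = [make_repeat(2000, 2300), make_repeat(3000, 3300), make_repeat(4000, 4300),
            make_repeat(9100, 9400)]  # last one fully inside exon 2
    di, de, si, se = gene_alu_densities(gene, reps)
    assert si == pytest.approx(7.1)
    assert di == pytest.approx(3 / 7.1)
    assert se == pytest.approx(1.7)
    assert de == pytest.approx(1 / 1.7)


def test_no_alus_zero_density(toy_transcript):
    gene = GeneModel("GENE1", "chr1", "+", (toy_transcript,))
    di, de, si, se = gene_alu_densities(gene, [])
    assert di == 0 and de == 0
    assert si == pytest.approx((1000 - 200) / 1000)


def test_gene_density_is_mean_over_transcripts():
    t1 = make_transcript(0, 10_000, [(0, 1000), (9000, 10_000)], tid="t1")
    t2 = make_transcript(0, 20_000, [(0, 1000), (19_000, 20_000)], tid="t2")
    gene = GeneModel("G", "chr1", "+", (t1, t2))
    reps = [make_repeat(2000, 2300)]
    di, _, _, _ = gene_alu_densities(gene, reps)
    d1 = 1 / ((10_000 - 2000 - 300) / 1000)
    d2 = 1 / ((20_000 - 2000 - 300) / 1000)
    assert di == pytest.approx((d1 + d2) / 2)


def test_adjustment_only_increases_density(toy_transcript):
    """Removing Alu nt from the denominator can only raise a density."""
    gene = GeneModel("GENE1", "chr1", "+", (toy_transcript,))
    reps = [make_repeat(300, 600)]
    di, _, si, _ = gene_alu_densities(gene, reps)
    raw = 1 / ((1000 - 200) / 1000)
    assert di >= raw


# -- scan_motif ------------------------------------------------------------


def test_motif_scan_examples():
    assert scan_motif("GGTTAAAAGG", "TTAAAA") == [2]
    assert scan_motif("TTAAAATTAAAA", "TTAAAA") == [0, 6]
    assert scan_motif("TTA", "TTAAAA") == []
    assert scan_motif("ggttaaaagg", "ttaaaa") == [2]


def test_motif_region_restriction():
    assert scan_motif("GGTTAAAAGG", "TTAAAA", region=(3, 10)) == []
    assert scan_motif("GGTTAAAAGG", "TTAAAA", region=(2, 8)) == [2]


def test_motif_overlapping_matches():
    assert scan_motif("AAAAAA", "AA") == [0, 1, 2, 3, 4]


def test_bad_motif_rejected():
    with pytest.raises(ValueError):
        scan_motif("ACGT", "TTN")


@settings(max_examples=500, deadline=None, derandomize=True)
@given(
    seq=st.text(alphabet="ACGT", min_size=0, max_size=80),
    motif=st.text(alphabet="ACGT", min_size=1, max_size=5),
)
def test_scan_agrees_with_naive_substring_oracle(seq, motif):
    expected = [i for i in range(len(seq) - len(motif) + 1) if seq[i : i + len(motif)] == motif]
    assert scan_motif(seq, motif) == expected


# -- gene_motif_densities --------------------------------------------------


def test_motif_density_counts_and_denominator():
    """One 5000 nt intron, two motifs, no Alus: Mi = 2 / 5.0."""
    t = make_transcript(0, 5200, [(0, 100), (5100, 5200)])
    gene = GeneModel("G", "chr1", "+", (t,))
    seq = ["A"] * 5200
    seq[1000:1006] = list("TTAAAA")
    seq[3000:3006] = list("TTAAAA")
    store = FakeStore({"chr1": "".join(seq)})
    mi, me = gene_motif_densities(gene, [], store)
    assert mi == pytest.approx(2 / 5.0)
    assert me == 0.0


def test_motif_inside_alu_not_counted():
    t = make_transcript(0, 5200, [(0, 100), (5100, 5200)])
    gene = GeneModel("G", "chr1", "+", (t,))
    seq = ["A"] * 5200
    seq[1000:1006] = list("TTAAAA")
    store = FakeStore({"chr1": "".join(seq)})
    alu = make_repeat(900, 1200)
    mi_excl, _ = gene_motif_densities(gene, [alu], store)
    assert mi_excl == 0.0
    mi_incl, _ = gene_motif_densities(gene, [alu], store, count_motifs_in_alus=True)
    assert mi_incl == pytest.approx(1 / ((5000 - 300) / 1000))


# -- Alu pairs and triplets ------------------------------------------------


def test_pair_gap_rule():
    assert alu_pair_count([(1000, 1300), (1500, 1800)]) == 1  # gap 200
    assert alu_pair_count([(1000, 1300), (1600, 1900)]) == 0  # gap exactly 300
    assert alu_pair_count([(0, 300), (400, 700), (950, 1250)]) == 2  # gaps 100, 250
    assert alu_pair_count([(0, 300)]) == 0


def test_pair_count_bounded_by_ni_minus_one():
    ivs = [(i * 1000, i * 1000 + 300) for i in range(5)]
    assert alu_pair_count(ivs) <= len(ivs) - 1


def test_pair_density_uses_si(toy_transcript):
    part = partition_repeats(toy_transcript, [make_repeat(200, 500), make_repeat(550, 850)])
    si = (1000 - 200 - 600) / 1000
    assert alu_pair_density(toy_transcript, part) == pytest.approx(1 / si)


def test_triplet_rule():
    t = make_transcript(1000, 3000, [(2000, 2100)], symbol="G")
    # single-exon transcript is fine for the triplet primitive itself
    reps = [make_repeat(1700, 1950), make_repeat(2150, 2450)]
    assert alu_exon_alu_triplets(t, reps) == 1
    assert alu_exon_alu_triplets(t, reps[:1]) == 0  # one side only


def test_shared_alu_serves_two_exons():
    t = make_transcript(0, 2000, [(400, 500), (700, 800)])
    reps = [make_repeat(100, 350), make_repeat(550, 650), make_repeat(900, 1150)]
    assert alu_exon_alu_triplets(t, reps) == 2


def test_triplet_gap_boundary():
    t = make_transcript(0, 2000, [(500, 600)])
    # left gap exactly 300 -> no triplet
    reps = [make_repeat(0, 200), make_repeat(650, 900)]
    assert alu_exon_alu_triplets(t, reps) == 0
    # left gap 299 -> triplet
    reps = [make_repeat(0, 201), make_repeat(650, 900)]
    assert alu_exon_alu_triplets(t, reps) == 1


# -- GC content ------------------------------------------------------------


def test_gc_after_alu_masking():
    t = make_transcript(0, 8, [(0, 2), (6, 8)])
    gene = GeneModel("G", "chr1", "+", (t,))
    store = FakeStore({"chr1": "GGCCAAAA"})
    assert adjusted_gc_content(gene, [make_repeat(4, 8)], store) == 1.0


def test_gc_all_at_is_zero():
    t = make_transcript(0, 8, [(0, 2), (6, 8)])
    gene = GeneModel("G", "chr1", "+", (t,))
    store = FakeStore({"chr1": "ATATATAT"})
    assert adjusted_gc_content(gene, [], store) == 0.0


def test_gc_excludes_ambiguous_bases():
    t = make_transcript(0, 8, [(0, 2), (6, 8)])
    gene = GeneModel("G", "chr1", "+", (t,))
    store = FakeStore({"chr1": "GCGCNNAT"})
    assert adjusted_gc_content(gene, [], store) == pytest.approx(4 / 6)


def test_gc_undefined_when_fully_masked():
    t = make_transcript(0, 8, [(0, 2), (6, 8)])
    gene = GeneModel("G", "chr1", "+", (t,))
    store = FakeStore({"chr1": "GGCCAAAA"})
    with pytest.raises(FeatureExtractionError):
        adjusted_gc_content(gene, [make_repeat(0, 8)], store)


# -- chromosome-level densities -------------------------------------------


def test_intergenic_density_toy():
    t = make_transcript(100, 900, [(100, 200), (800, 900)])
    gene = GeneModel("G", "chr1", "+", (t,))
    alu = make_repeat(0, 100)
    dens = chromosome_region_densities([gene], [alu], [], 1000)
    # intergenic [0,100)+[900,1000) = 0.2 Knt; one fully intergenic 100 nt Alu
    assert dens.intergenic_alu == pytest.approx(1 / 0.1)


def test_no_genes_whole_chromosome_intergenic():
    dens = chromosome_region_densities([], [make_repeat(100, 400)], [], 10_000)
    assert dens.intergenic_alu == pytest.approx(1 / ((10_000 - 300) / 1000))


def test_pooled_not_mean_of_gene_densities():
    t1 = make_transcript(0, 2000, [(0, 100), (1900, 2000)], tid="t1", symbol="A")
    t2 = make_transcript(3000, 13_000, [(3000, 3100), (12_900, 13_000)], tid="t2", symbol="B")
    g1 = GeneModel("A", "chr1", "+", (t1,))
    g2 = GeneModel("B", "chr1", "+", (t2,))
    reps = [make_repeat(500, 800), make_repeat(5000, 5300)]
    dens = chromosome_region_densities([g1, g2], reps, [], 20_000)
    si1 = (2000 - 200 - 300) / 1000
    si2 = (10_000 - 200 - 300) / 1000
    assert dens.intron_alu == pytest.approx(2 / (si1 + si2))
    assert dens.intron_alu != pytest.approx((1 / si1 + 1 / si2) / 2)


def test_chrom_length_too_small_rejected():
    t = make_transcript(100, 900, [(100, 200), (800, 900)])
    gene = GeneModel("G", "chr1", "+", (t,))
    with pytest.raises(FeatureExtractionError):
        chromosome_region_densities([gene], [], [], 500)


# -- nearest site ----------------------------------------------------------


def test_nearest_site_distance(toy_gene):
    sites = [GenomicSite("chr1", 100), GenomicSite("chr1", 900)]
    assert nearest_site_distance(toy_gene, sites) == 400
    assert nearest_site_distance(toy_gene, [GenomicSite("chr1", 500)]) == 0
    tie = [GenomicSite("chr1", 300), GenomicSite("chr1", 700)]
    assert nearest_site_distance(toy_gene, tie) == 200
    with pytest.raises(FeatureExtractionError):
        nearest_site_distance(toy_gene, [GenomicSite("chr9", 0)])


# -- translation invariance ------------------------------------------------


@pytest.mark.parametrize("shift", [0, 1, 12345])
def test_features_invariant_under_translation(shift):
    t = make_transcript(0 + shift, 10_000 + shift,
                        [(0 + shift, 1000 + shift), (9000 + shift, 10_000 + shift)])
    gene = GeneModel("G", "chr1", "+", (t,))
    reps = [make_repeat(2000 + shift, 2300 + shift), make_repeat(2500 + shift, 2800 + shift)]
    f = compute_gene_features(gene, reps)
    t0 = make_transcript(0, 10_000, [(0, 1000), (9000, 10_000)])
    f0 = compute_gene_features(GeneModel("G", "chr1", "+", (t0,)),
                               [make_repeat(2000, 2300), make_repeat(2500, 2800)])
    for attr in ("Di", "De", "pair_density", "triplet_count", "Si", "Se", "log10_size"):
        assert getattr(f, attr) == pytest.approx(getattr(f0, attr))
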