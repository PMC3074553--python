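import numpy as np
import pytest

from aludist import (
    GeneModel,
    RepeatInterval,
    SyntheticGenomeSpec,
    TranscriptModel,
    read_sequences,
    simulate_genome,
)


@pytest.fixture
def toy_transcript():
    """[0, 1000) with exons [0,100) and [900,1000): one 800 nt intron."""
    return TranscriptModel("t1", "GENE1", "chr1", "+", 0, 1000, ((0, 100), (900, 1000)))


@pytest.fixture
def toy_gene(toy_transcript):
    return GeneModel("GENE1", "chr1", "+", (toy_transcript,))


def make_transcript(start, end, exons, chrom="chr1", strand="+", tid="t", symbol="G"):
    return TranscriptModel(tid, symbol, chrom, strand, start, end, tuple(exons))


def make_repeat(start, end, chrom="chr1", family="AluY"):
    return RepeatInterval(chrom, start, end, family)


@pytest.fixture(scope="session")
def small_genome(tmp_path_factory):
    """A seeded 2-chromosome synthetic genome shared across I/O-heavy tests."""
    from aludist.synthetic_data import ChromosomeSpec

    outdir = tmp_path_factory.mktemp("small_genome")
    spec = SyntheticGenomeSpec(
        chromosomes=(
            ChromosomeSpec("chr1", 60, r=0.281, shape=0.615, scale=1.303),
            ChromosomeSpec("chr2", 60, r=0.271, shape=0.441, scale=1.498),
        )
    )
    return simulate_genome(spec, seed=42, outdir=outdir)


@pytest.fixture(scope="session")
def small_genome_sequences(small_genome):
    return read_sequences(small_genome.fasta_path)
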