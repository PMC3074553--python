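"""Readers and writers for the genomic file formats the pipeline touches.

Every coordinate inside the package is 0-based, half-open ``[start, end)``.
Conversion to and from 1-based closed conventions (GTF, RepeatMasker .out)
happens here and nowhere else.

A gene's identity is the triple ``(symbol, chrom, strand)``: the same symbol
annotated on two strands or chromosomes yields two independent
:class:`GeneModel` objects.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from pyfaidx import Fasta

__all__ = [
    "TranscriptModel",
    "GeneModel",
    "RepeatInterval",
    "CancerGeneRecord",
    "GenomicSite",
    "SequenceStore",
    "AnnotationError",
    "read_gene_models",
    "write_gene_models",
    "read_repeat_intervals",
    "write_repeat_intervals",
    "read_cancer_gene_table",
    "read_genomic_sites",
    "read_sequences",
    "write_feature_table",
    "read_feature_table",
    "FEATURE_COLUMNS",
]


class AnnotationError(ValueError):
    """Malformed annotation input (carries the offending line number when known)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TranscriptModel:
    """One reference transcript: a chromosome span plus its ordered exons.

    ``exons`` are half-open intervals, sorted, pairwise disjoint and contained
    in ``[start, end)``.  Introns are the gaps between consecutive exons; a
    single-exon transcript therefore has none.
    """

    transcript_id: str
    gene_symbol: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise AnnotationError(
                f"transcript {self.transcript_id}: empty span [{self.start},{self.end})"
            )
        prev_end = None
        for s, e in self.exons:
            if e <= s:
                raise AnnotationError(f"transcript {self.transcript_id}: empty exon [{s},{e})")
            if s < self.start or e > self.end:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: exon [{s},{e}) outside span"
                )
            if prev_end is not None and s < prev_end:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: exons overlap or are unsorted at [{s},{e})"
                )
            prev_end = e

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
            if self.exons[i + 1][0] > self.exons[i][1]
        )

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def is_multi_exon(self) -> bool:
        return len(self.exons) >= 2

    @property
    def exon_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def span_length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """All transcripts sharing (symbol, chrom, strand); densities average over them."""

    gene_symbol: str
    chrom: str
    strand: str
    transcripts: tuple[TranscriptModel, ...]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise AnnotationError(f"gene {self.gene_symbol}: no transcripts")
        for t in self.transcripts:
            if (t.chrom, t.strand) != (self.chrom, self.strand):
                raise AnnotationError(
                    f"gene {self.gene_symbol}: transcript {t.transcript_id} on "
                    f"{t.chrom}{t.strand}, expected {self.chrom}{self.strand}"
                )

    @property
    def span(self) -> tuple[int, int]:
        """Union hull of the transcript spans."""
        return (min(t.start for t in self.transcripts), max(t.end for t in self.transcripts))

    @property
    def multi_exon_transcripts(self) -> tuple[TranscriptModel, ...]:
        return tuple(t for t in self.transcripts if t.is_multi_exon)


@dataclass(frozen=True)
class RepeatInterval:
    """One repeat occurrence (an Alu, by default filtering)."""

    chrom: str
    start: int
    end: int
    family: str
    strand: str = "unknown"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise AnnotationError(f"repeat {self.family}: empty interval [{self.start},{self.end})")
        if not self.family:
            raise AnnotationError("repeat with empty family name")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CancerGeneRecord:
    """A cancer gene with its mutation-class labels.

    ``dominance`` is ``ambiguous`` for database entries flagged "Rec?"; such
    records are excluded from the dominant/recessive comparison only.
    ``cell_type`` is ``both`` for genes mutated in somatic and germline cells;
    such records are excluded from the somatic/germline comparison only.
    """

    gene_symbol: str
    dominance: str  # dominant | recessive | ambiguous
    cell_type: str  # somatic | germline | both
    translocation: str  # yes | no


@dataclass(frozen=True)
class GenomicSite:
    """A point annotation, e.g. a fragile-site midpoint."""

    chrom: str
    position: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.position < 0:
            raise AnnotationError(f"site {self.label}: negative position")


# ---------------------------------------------------------------------------
# Gene models (BED12 / GTF)
# ---------------------------------------------------------------------------


def _split_bed12_name(name: str) -> tuple[str, str]:
    """BED12 has one name field; ``symbol|transcript`` carries both identities."""
    if "|" in name:
        symbol, tid = name.split("|", 1)
        return symbol, tid
    return name, name


def _parse_bed12_line(line: str, lineno: int) -> TranscriptModel:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 12:
        raise AnnotationError(f"line {lineno}: BED12 needs 12 fields, got {len(fields)}")
    try:
        chrom = fields[0]
        start = int(fields[1])
        end = int(fields[2])
        symbol, tid = _split_bed12_name(fields[3])
        strand = fields[5]
        block_count = int(fields[9])
        sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
        starts = [int(x) for x in fields[11].rstrip(",").split(",")]
    except ValueError as exc:
        raise AnnotationError(f"line {lineno}: unparseable BED12 field ({exc})") from exc
    if strand not in "+-":
        raise AnnotationError(f"line {lineno}: strand must be + or -, got {strand!r}")
    if not (len(sizes) == len(starts) == block_count):
        raise AnnotationError(f"line {lineno}: blockCount disagrees with block lists")
    exons = tuple((start + o, start + o + s) for o, s in zip(starts, sizes))
    try:
        return TranscriptModel(tid, symbol, chrom, strand, start, end, exons)
    except AnnotationError as exc:
        raise AnnotationError(f"line {lineno}: {exc}") from exc


def _parse_gtf(path: Path) -> list[TranscriptModel]:
    # exon features only; transcript span is the exon hull
    exons: dict[tuple[str, str, str, str], list[tuple[int, int]]] = {}
    order: list[tuple[str, str, str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise AnnotationError(f"line {lineno}: GTF needs 9 fields, got {len(fields)}")
            if fields[2] != "exon":
                continue
            chrom, strand = fields[0], fields[6]
            try:
                start1, end1 = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise AnnotationError(f"line {lineno}: unparseable coordinates") from exc
            attrs = {}
            for item in fields[8].strip().rstrip(";").split(";"):
                item = item.strip()
                if not item:
                    continue
                key, _, value = item.partition(" ")
                attrs[key] = value.strip().strip('"')
            if "gene_id" not in attrs or "transcript_id" not in attrs:
                raise AnnotationError(f"line {lineno}: missing gene_id/transcript_id attribute")
            key = (attrs["gene_id"], attrs["transcript_id"], chrom, strand)
            if key not in exons:
                exons[key] = []
                order.append(key)
            exons[key].append((start1 - 1, end1))  # 1-based closed -> 0-based half-open
    models = []
    for symbol, tid, chrom, strand in order:
        ivs = sorted(exons[(symbol, tid, chrom, strand)])
        for (s1, e1), (s2, _) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise AnnotationError(f"transcript {tid}: overlapping exons in GTF input")
        models.append(TranscriptModel(tid, symbol, chrom, strand, ivs[0][0], ivs[-1][1], tuple(ivs)))
    return models


def read_gene_models(
    path: str | Path, format: str = "bed12"
) -> tuple[list[GeneModel], list[str]]:
    """Read transcript annotations and group them into genes.

    Single-exon transcripts carry no intron information and are dropped; a
    gene whose transcripts are ALL single-exon is reported in the returned
    exclusion list and omitted from the gene models.

    Returns ``(gene_models, excluded_single_exon_gene_symbols)``.
    """
    path = Path(path)
    if format == "bed12":
        transcripts = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                transcripts.append(_parse_bed12_line(line, lineno))
    elif format == "gtf":
        transcripts = _parse_gtf(path)
    else:
        raise ValueError(f"unknown gene model format: {format!r}")

    grouped: dict[tuple[str, str, str], list[TranscriptModel]] = {}
    order: list[tuple[str, str, str]] = []
    for t in transcripts:
        key = (t.gene_symbol, t.chrom, t.strand)
        if key not in grouped:
            grouped[key] = []
            order.append(key)
        grouped[key].append(t)

    genes: list[GeneModel] = []
    excluded: list[str] = []
    for key in order:
        members = grouped[key]
        multi = [t for t in members if t.is_multi_exon]
        if not multi:
            excluded.append(key[0])
            continue
        genes.append(GeneModel(key[0], key[1], key[2], tuple(multi)))
    return genes, excluded


def write_gene_models(genes: Iterable[GeneModel], path: str | Path, format: str = "bed12") -> None:
    """Serialize gene models; inverse of :func:`read_gene_models` coordinate-wise."""
    path = Path(path)
    lines: list[str] = []
    if format == "bed12":
        for gene in genes:
            for t in gene.transcripts:
                sizes = ",".join(str(e - s) for s, e in t.exons)
                starts = ",".join(str(s - t.start) for s, e in t.exons)
                name = t.transcript_id if t.transcript_id == t.gene_symbol else (
                    f"{t.gene_symbol}|{t.transcript_id}"
                )
                lines.append(
                    "\t".join(
                        [
                            t.chrom,
                            str(t.start),
                            str(t.end),
                            name,
                            "0",
                            t.strand,
                            str(t.start),
                            str(t.end),
                            "0",
                            str(len(t.exons)),
                            sizes,
                            starts,
                        ]
                    )
                )
    elif format == "gtf":
        for gene in genes:
            for t in gene.transcripts:
                for s, e in t.exons:
                    attrs = f'gene_id "{t.gene_symbol}"; transcript_id "{t.transcript_id}";'
                    lines.append(
                        "\t".join(
                            [t.chrom, "aludist", "exon", str(s + 1), str(e), ".", t.strand, ".", attrs]
                        )
                    )
    else:
        raise ValueError(f"unknown gene model format: {format!r}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Repeats (BED6 / RepeatMasker .out)
# ---------------------------------------------------------------------------


def read_repeat_intervals(
    path: str | Path, format: str = "bed6", family_filter: str = "Alu"
) -> list[RepeatInterval]:
    """Read repeat coordinates, keeping families whose name starts with *family_filter*.

    RepeatMasker ``.out`` rows are 1-based closed and converted; BED6 rows are
    kept as-is (already 0-based half-open).  Pass ``family_filter=""`` to keep
    every record.
    """
    path = Path(path)
    repeats: list[RepeatInterval] = []
    if format == "bed6":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 4:
                    raise AnnotationError(f"line {lineno}: BED needs >=4 fields")
                try:
                    start, end = int(fields[1]), int(fields[2])
                except ValueError as exc:
                    raise AnnotationError(f"line {lineno}: unparseable coordinates") from exc
                family = fields[3]
                strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "unknown"
                if not family.startswith(family_filter):
                    continue
                repeats.append(RepeatInterval(fields[0], start, end, family, strand))
    elif format == "rmsk_out":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                stripped = line.strip()
                if not stripped or stripped.startswith(("SW", "score", "*")):
                    continue
                fields = stripped.split()
                if len(fields) < 11:
                    raise AnnotationError(f"line {lineno}: RepeatMasker row needs >=11 fields")
                try:
                    begin1, end1 = int(fields[5]), int(fields[6])
                except ValueError as exc:
                    raise AnnotationError(f"line {lineno}: unparseable coordinates") from exc
                chrom = fields[4]
                strand = "+" if fields[8] == "+" else "-"  # RM uses C for complement
                family = fields[9]
                if not family.startswith(family_filter):
                    continue
                repeats.append(RepeatInterval(chrom, begin1 - 1, end1, family, strand))
    else:
        raise ValueError(f"unknown repeat format: {format!r}")
    return repeats


def write_repeat_intervals(repeats: Iterable[RepeatInterval], path: str | Path) -> None:
    """Write repeats as BED6."""
    lines = [
        "\t".join(
            [r.chrom, str(r.start), str(r.end), r.family, "0", r.strand if r.strand in "+-" else "."]
        )
        for r in repeats
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Cancer gene table / genomic sites
# ---------------------------------------------------------------------------

_REQUIRED_CLASS_COLUMNS = ("symbol", "dominance", "cell_type", "translocation")


def read_cancer_gene_table(path: str | Path) -> tuple[list[CancerGeneRecord], dict[str, int]]:
    """Read the cancer-gene classification TSV.

    Required columns: ``symbol``, ``dominance``, ``cell_type``,
    ``translocation``.  "Rec?" parses as ambiguous dominance; a cell type
    naming both compartments (e.g. "somatic/germline") parses as ``both``.

    Returns the records plus per-comparison exclusion counts with keys
    ``ambiguous_dominance`` and ``both_cell_types``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in _REQUIRED_CLASS_COLUMNS:
        if col not in df.columns:
            raise AnnotationError(f"cancer gene table missing required column: {col!r}")
    records: list[CancerGeneRecord] = []
    exclusions = {"ambiguous_dominance": 0, "both_cell_types": 0}
    for _, row in df.iterrows():
        raw_dom = str(row["dominance"]).strip().lower()
        if raw_dom in ("rec?", "dom?", "ambiguous", "?"):
            dominance = "ambiguous"
        elif raw_dom.startswith("dom"):
            dominance = "dominant"
        elif raw_dom.startswith("rec"):
            dominance = "recessive"
        else:
            raise AnnotationError(f"gene {row['symbol']}: unrecognized dominance {row['dominance']!r}")
        raw_cell = str(row["cell_type"]).strip().lower()
        if raw_cell == "both" or ("somatic" in raw_cell and "germline" in raw_cell):
            cell_type = "both"
        elif raw_cell.startswith("som"):
            cell_type = "somatic"
        elif raw_cell.startswith("germ"):
            cell_type = "germline"
        else:
            raise AnnotationError(f"gene {row['symbol']}: unrecognized cell type {row['cell_type']!r}")
        raw_tr = str(row["translocation"]).strip().lower()
        if raw_tr in ("yes", "y", "1", "true"):
            translocation = "yes"
        elif raw_tr in ("no", "n", "0", "false"):
            translocation = "no"
        else:
            raise AnnotationError(
                f"gene {row['symbol']}: unrecognized translocation flag {row['translocation']!r}"
            )
        if dominance == "ambiguous":
            exclusions["ambiguous_dominance"] += 1
        if cell_type == "both":
            exclusions["both_cell_types"] += 1
        records.append(CancerGeneRecord(str(row["symbol"]), dominance, cell_type, translocation))
    return records, exclusions


def read_genomic_sites(path: str | Path) -> list[GenomicSite]:
    """Read point sites (e.g. fragile-site midpoints) from a TSV: chrom, position[, label]."""
    sites: list[GenomicSite] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if fields[0] in ("chrom", "chr"):  # header
                continue
            if len(fields) < 2:
                raise AnnotationError(f"line {lineno}: site row needs chrom and position")
            try:
                pos = int(fields[1])
            except ValueError as exc:
                raise AnnotationError(f"line {lineno}: unparseable position") from exc
            sites.append(GenomicSite(fields[0], pos, fields[2] if len(fields) > 2 else ""))
    return sites


# ---------------------------------------------------------------------------
# Sequence access
# ---------------------------------------------------------------------------


class SequenceStore:
    """Case-normalized random access into a FASTA of chromosome records."""

    def __init__(self, path: str | Path):
        self._fasta = Fasta(str(path), sequence_always_upper=True, as_raw=True)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._fasta

    def length(self, chrom: str) -> int:
        if chrom not in self._fasta:
            raise KeyError(f"chromosome {chrom!r} absent from FASTA")
        return len(self._fasta[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return the uppercase sequence for half-open [start, end)."""
        if chrom not in self._fasta:
            raise KeyError(f"chromosome {chrom!r} absent from FASTA")
        n = len(self._fasta[chrom])
        if start < 0 or end > n or end < start:
            raise IndexError(f"interval [{start},{end}) out of bounds for {chrom} (length {n})")
        return str(self._fasta[chrom][start:end])


def read_sequences(path: str | Path) -> SequenceStore:
    """Open a FASTA for random access keyed by chromosome name."""
    return SequenceStore(path)


# ---------------------------------------------------------------------------
# Feature table round trip
# ---------------------------------------------------------------------------

FEATURE_COLUMNS = [
    "gene",
    "chrom",
    "strand",
    "Di",
    "De",
    "Mi",
    "Me",
    "pair_density",
    "triplet_count",
    "gc_adjusted",
    "Si",
    "Se",
    "log10_size",
]


def write_feature_table(features: Sequence, path: str | Path) -> None:
    """Write per-gene features as TSV with a fixed column order.

    Accepts a sequence of ``GeneAluFeatures`` (any object exposing the feature
    attributes) or an equivalent DataFrame; densities keep >= 10 significant
    digits so the table round-trips losslessly through :func:`read_feature_table`.
    """
    if isinstance(features, pd.DataFrame):
        df = features[FEATURE_COLUMNS]
    else:
        if not features:
            raise ValueError("empty feature collection")
        df = pd.DataFrame(
            [
                {
                    "gene": f.gene_symbol,
                    "chrom": f.chrom,
                    "strand": f.strand,
                    "Di": f.Di,
                    "De": f.De,
                    "Mi": f.Mi,
                    "Me": f.Me,
                    "pair_density": f.pair_density,
                    "triplet_count": f.triplet_count,
                    "gc_adjusted": f.gc_adjusted,
                    "Si": f.Si,
                    "Se": f.Se,
                    "log10_size": f.log10_size,
                }
                for f in features
            ],
            columns=FEATURE_COLUMNS,
        )
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature table written by :func:`write_feature_table`."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise AnnotationError(f"feature table missing columns: {missing}")
    return df[FEATURE_COLUMNS]
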