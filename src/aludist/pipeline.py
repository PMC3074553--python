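"""End-to-end orchestration: extract -> densities -> mixture -> regression ->
class associations -> clustering, with every intermediate persisted as
TSV/JSON and a markdown report at the end.

Results go to stdout/files; logging (stage timers, filter counts) goes to
stderr so the pipeline stays composable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import sys
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotations_io import (
    read_cancer_gene_table,
    read_gene_models,
    read_genomic_sites,
    read_repeat_intervals,
    read_sequences,
    write_feature_table,
)
from .association_stats import class_association, two_step_motif_analysis
from .clustering import (
    CLUSTER_FEATURES,
    DEFAULT_CUT_HEIGHT,
    cluster_class_enrichment,
    cluster_genes,
    cut_dendrogram,
    to_newick,
)
from .feature_extraction import (
    DEFAULT_GAP,
    DEFAULT_MOTIF,
    FeatureExtractionError,
    chromosome_region_densities,
    compute_gene_features,
    nearest_site_distance,
    scan_motif,
)
from .mixture_model import fit_mixture, mixture_density, qq_points

__all__ = ["PipelineConfig", "run_pipeline", "render_report", "config_from_file", "PipelineError"]

logger = logging.getLogger("aludist")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Everything a full run needs; mirrors the CLI flags one-to-one."""

    genes: str = ""
    genes_format: str = "bed12"
    repeats: str = ""
    repeats_format: str = "bed6"
    fasta: str = ""
    classes: str = ""  # optional cancer-gene class TSV
    sites: str = ""  # optional fragile-site midpoints TSV
    motif: str = DEFAULT_MOTIF
    gap: int = DEFAULT_GAP
    cut_height: float = DEFAULT_CUT_HEIGHT
    count_motifs_in_alus: bool = False
    scale: str = "none"
    min_genes: int = 10
    seed: int = 0
    outdir: str = "aludist_out"

    def validate(self) -> None:
        if self.gap <= 0 or self.cut_height < 0:
            raise ValueError("thresholds must be positive")
        if any(b not in "ACGT" for b in self.motif.upper()):
            raise ValueError("motif must be over ACGT")

    def content_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def config_from_file(path: str | Path) -> PipelineConfig:
    """Flat ``key = value`` text config; keys match the dataclass fields."""
    cfg = PipelineConfig()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"config line {lineno}: expected key = value")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if not hasattr(cfg, key):
            raise ValueError(f"config line {lineno}: unknown key {key!r}")
        current = getattr(cfg, key)
        if isinstance(current, bool):
            setattr(cfg, key, value.lower() in ("1", "true", "yes"))
        elif isinstance(current, int):
            setattr(cfg, key, int(value))
        elif isinstance(current, float):
            setattr(cfg, key, float(value))
        else:
            setattr(cfg, key, value)
    return cfg


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # annotate with the stage name
                raise PipelineError(name, str(exc)) from exc
            logger.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
            return out

        return inner

    return wrap


@_stage("extract")
def _extract(config: PipelineConfig, outdir: Path):
    genes, excluded = read_gene_models(config.genes, format=config.genes_format)
    repeats = read_repeat_intervals(config.repeats, format=config.repeats_format)
    sequences = read_sequences(config.fasta) if config.fasta else None
    logger.info(
        "extract: %d genes kept, %d single-exon gene symbols excluded, %d repeats",
        len(genes), len(excluded), len(repeats),
    )
    by_chrom: dict[str, list] = {}
    for r in repeats:
        by_chrom.setdefault(r.chrom, []).append(r)
    rows = []
    rejected = []
    for gene in genes:
        try:
            rows.append(
                compute_gene_features(
                    gene,
                    by_chrom.get(gene.chrom, []),
                    sequences,
                    motif=config.motif,
                    gap=config.gap,
                    count_motifs_in_alus=config.count_motifs_in_alus,
                )
            )
        except FeatureExtractionError as exc:
            rejected.append(gene.gene_symbol)
            logger.warning("extract: rejected %s (%s)", gene.gene_symbol, exc)
    write_feature_table(rows, outdir / "features.tsv")
    (outdir / "excluded_single_exon.txt").write_text("\n".join(excluded) + ("\n" if excluded else ""))
    features = pd.DataFrame(
        [dataclasses.asdict(f) for f in rows]
    ).rename(columns={"gene_symbol": "gene"})
    return features, genes, repeats, sequences, excluded, rejected


@_stage("chromosome_densities")
def _chrom_densities(config, genes, repeats, sequences, chrom_lengths, outdir: Path):
    by_chrom_g: dict[str, list] = {}
    for g in genes:
        by_chrom_g.setdefault(g.chrom, []).append(g)
    by_chrom_r: dict[str, list] = {}
    for r in repeats:
        by_chrom_r.setdefault(r.chrom, []).append(r)
    rows = []
    for chrom in sorted(by_chrom_g):
        length = chrom_lengths[chrom]
        motif_positions = (
            scan_motif(sequences.fetch(chrom, 0, length), config.motif)
            if sequences is not None
            else []
        )
        dens = chromosome_region_densities(
            by_chrom_g[chrom], by_chrom_r.get(chrom, []), motif_positions, length,
            motif_length=len(config.motif),
        )
        rows.append(dataclasses.asdict(dens))
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "chrom_densities.tsv", sep="\t", index=False, float_format="%.12g")
    return df


@_stage("fit_mixture")
def _mixtures(features: pd.DataFrame, outdir: Path):
    fits = {}
    qq_dir = outdir / "qq"
    qq_dir.mkdir(exist_ok=True)
    curve_dir = outdir / "density_curves"
    curve_dir.mkdir(exist_ok=True)
    for chrom, sub in features.groupby("chrom", sort=True):
        fit = fit_mixture(sub["Di"].values)
        fits[chrom] = {
            "group": chrom,
            "n": fit.n,
            "r": fit.r,
            "shape": fit.shape,
            "scale": fit.scale,
            "loglik": fit.loglik,
        }
        positive = sub.loc[sub["Di"] > 0, "Di"].values
        if fit.has_gamma and positive.size >= 2:
            pairs = qq_points(positive, fit)
            pd.DataFrame(pairs, columns=["theoretical", "empirical"]).to_csv(
                qq_dir / f"{chrom}.tsv", sep="\t", index=False, float_format="%.12g"
            )
            grid = np.linspace(1e-3, max(positive.max(), 1.0) * 1.2, 200)
            pd.DataFrame(
                {"density": grid, "adjusted_pdf": mixture_density(fit, grid)}
            ).to_csv(curve_dir / f"{chrom}.tsv", sep="\t", index=False, float_format="%.12g")
    with open(outdir / "mixture_fits.json", "w") as fh:
        json.dump(fits, fh, indent=2, sort_keys=True, allow_nan=True)
    return fits


@_stage("motif_regression")
def _two_step(features: pd.DataFrame, min_genes: int, outdir: Path):
    results = two_step_motif_analysis(features, min_genes=min_genes)
    rows = []
    for res in results:
        for model_name, fit, p, padj, contrib in (
            ("model1", res.model1, res.p1, res.padj1, res.contribution1),
            ("model2", res.model2, res.p2, res.padj2, res.contribution2),
        ):
            if fit is None:
                continue
            rows.append(
                {
                    "chrom": res.group,
                    "model": model_name,
                    "beta": fit.params["Mi"],
                    "p": p,
                    "padj": padj,
                    "neg_log10_padj": -math.log10(padj) if padj and padj > 0 else float("inf"),
                    "contribution": contrib,
                    "n": fit.n,
                    "note": res.note,
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "two_step.tsv", sep="\t", index=False, float_format="%.12g")
    return results, df


@_stage("class_association")
def _class_assoc(features, records, exclusions, genes_by_symbol, sites, outdir: Path):
    feat = features.set_index("gene")
    if sites:
        dist = {}
        for sym in feat.index:
            gene = genes_by_symbol.get(sym)
            if gene is not None:
                try:
                    dist[sym] = nearest_site_distance(gene, sites)
                except FeatureExtractionError:
                    dist[sym] = np.nan
        feat = feat.assign(fs_distance=pd.Series(dist))
    comparisons = {
        "dominant_vs_recessive": [
            (r.gene_symbol, 1 if r.dominance == "recessive" else 0)
            for r in records
            if r.dominance != "ambiguous"
        ],
        "somatic_vs_germline": [
            (r.gene_symbol, 1 if r.cell_type == "germline" else 0)
            for r in records
            if r.cell_type != "both"
        ],
        "translocation_vs_non": [
            (r.gene_symbol, 1 if r.translocation == "no" else 0) for r in records
        ],
    }
    rows = []
    results = {}
    for name, pairs in comparisons.items():
        pairs = [(s, z) for s, z in pairs if s in feat.index]
        if not pairs:
            logger.warning("class_association: no usable genes for %s", name)
            continue
        sub = feat.loc[[s for s, _ in pairs]]
        labels = [z for _, z in pairs]
        covs = ("Di", "log10_size")
        if sites and not sub["fs_distance"].isna().any():
            covs = ("Di", "log10_size", "fs_distance")
        if len(set(labels)) < 2:
            logger.warning("class_association: single-class labels for %s", name)
            continue
        res = class_association(sub, labels, classification=name, covariates=covs)
        results[name] = res
        for term in covs:
            rows.append(
                {
                    "classification": name,
                    "term": term,
                    "coef": res.fit.params[term],
                    "se": res.fit.bse[term],
                    "p": res.fit.pvalues[term],
                    "verdict": res.verdicts[term],
                    "n": res.fit.n,
                }
            )
    logger.info(
        "class_association: exclusions ambiguous_dominance=%d both_cell_types=%d",
        exclusions.get("ambiguous_dominance", 0),
        exclusions.get("both_cell_types", 0),
    )
    pd.DataFrame(rows).to_csv(outdir / "class_assoc.tsv", sep="\t", index=False, float_format="%.12g")
    return results


@_stage("clustering")
def _clustering(features, records, config, outdir: Path):
    feat = features.set_index("gene")
    cancer_symbols = [r.gene_symbol for r in records if r.gene_symbol in feat.index]
    if len(cancer_symbols) < 3:
        logger.warning("clustering: fewer than 3 cancer genes with features; skipped")
        return None
    matrix = feat.loc[cancer_symbols, CLUSTER_FEATURES]
    matrix = matrix.dropna()
    tree = cluster_genes(matrix, scale=config.scale)
    (outdir / "dendrogram.newick").write_text(to_newick(tree) + "\n")
    assignment = cut_dendrogram(tree, config.cut_height)
    pd.DataFrame(
        {"gene": list(assignment.assignment), "cluster": list(assignment.assignment.values())}
    ).to_csv(outdir / "cluster_assignments.tsv", sep="\t", index=False)
    sizes = assignment.cluster_sizes
    non_singleton = {cid: n for cid, n in sizes.items() if n > 1}
    enrichment = None
    if len(non_singleton) >= 2:
        largest = max(non_singleton, key=lambda c: non_singleton[c])
        focus = set(non_singleton) - {largest}
        labels = {
            r.gene_symbol: 1 if r.dominance == "recessive" else 0
            for r in records
            if r.gene_symbol in assignment.assignment
        }
        table, p, odds = cluster_class_enrichment(assignment, labels, focus)
        enrichment = {
            "focus_clusters": sorted(focus),
            "table": table.tolist(),
            "p": p,
            "odds_ratio": odds,
            "focus_positive_fraction": table[0, 0] / table[0].sum(),
            "rest_positive_fraction": table[1, 0] / table[1].sum(),
        }
        with open(outdir / "enrichment.json", "w") as fh:
            json.dump(enrichment, fh, indent=2, sort_keys=True)
    return {"sizes": {str(k): v for k, v in sizes.items()}, "enrichment": enrichment}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order and return the report dictionary.

    All intermediates are written under ``config.outdir``; the report itself
    is persisted as ``report.json`` and rendered to ``report.md``.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    features, genes, repeats, sequences, excluded, rejected = _extract(config, outdir)
    genes_by_symbol = {g.gene_symbol: g for g in genes}
    chrom_lengths = {}
    for chrom in {g.chrom for g in genes} | {r.chrom for r in repeats}:
        if sequences is not None and chrom in sequences:
            chrom_lengths[chrom] = sequences.length(chrom)
        else:
            ends = [t.end for g in genes if g.chrom == chrom for t in g.transcripts] + [
                r.end for r in repeats if r.chrom == chrom
            ]
            chrom_lengths[chrom] = max(ends)
    chrom_dens = _chrom_densities(config, genes, repeats, sequences, chrom_lengths, outdir)
    fits = _mixtures(features, outdir)
    two_step_results, two_step_df = _two_step(features, config.min_genes, outdir)

    assoc = {}
    clustering_summary = None
    exclusions: dict[str, int] = {}
    if config.classes:
        records, exclusions = read_cancer_gene_table(config.classes)
        sites = read_genomic_sites(config.sites) if config.sites else []
        assoc_results = _class_assoc(features, records, exclusions, genes_by_symbol, sites, outdir)
        assoc = {
            name: {
                "coefficients": res.fit.params,
                "pvalues": res.fit.pvalues,
                "verdicts": res.verdicts,
                "n": res.fit.n,
            }
            for name, res in assoc_results.items()
        }
        clustering_summary = _clustering(features, records, config, outdir)

    report = {
        "provenance": {
            "version": __version__,
            "config": dataclasses.asdict(config),
            "config_hash": config.content_hash(),
            "seed": config.seed,
        },
        "counts": {
            "genes_analyzed": int(len(features)),
            "single_exon_excluded": len(excluded),
            "rejected_degenerate": len(rejected),
            "repeats": len(repeats),
            **{f"class_excluded_{k}": v for k, v in exclusions.items()},
        },
        "chromosome_densities": chrom_dens.to_dict(orient="records"),
        "mixture_fits": fits,
        "two_step": two_step_df.to_dict(orient="records"),
        "class_associations": assoc,
        "clustering": clustering_summary,
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    render_report(report, outdir / "report.md")
    return report


def render_report(report: dict, path: str | Path) -> None:
    """Render the report dictionary to a human-readable markdown summary."""
    required = ["provenance", "counts", "chromosome_densities", "mixture_fits", "two_step"]
    missing = [k for k in required if k not in report]
    if missing:
        raise ValueError(f"incomplete report, missing sections: {missing}")
    lines = ["# Alu distribution analysis report", ""]
    prov = report["provenance"]
    lines += [
        f"version {prov['version']}, config hash `{prov['config_hash']}`, seed {prov['seed']}",
        "",
        "## Input counts",
        "",
    ]
    for k, v in report["counts"].items():
        lines.append(f"- {k}: {v}")
    lines += ["", "## Chromosome-level densities (per adjusted Knt)", ""]
    lines.append("| chrom | intron Alu | exon Alu | intergenic Alu | intron motif | chrom motif |")
    lines.append("|---|---|---|---|---|---|")
    for row in report["chromosome_densities"]:
        lines.append(
            "| {chrom} | {intron_alu:.4g} | {exon_alu:.4g} | {intergenic_alu:.4g} "
            "| {intron_motif:.4g} | {chrom_motif:.4g} |".format(**row)
        )
    lines += ["", "## Zero-inflated Gamma mixture fits", ""]
    lines.append("| chrom | n | r | shape | scale |")
    lines.append("|---|---|---|---|---|")
    for chrom, fit in sorted(report["mixture_fits"].items()):
        lines.append(
            f"| {chrom} | {fit['n']} | {fit['r']:.4g} | {fit['shape']:.4g} | {fit['scale']:.4g} |"
        )
    lines += ["", "## Two-step motif regression", ""]
    lines.append("| chrom | model | beta | p | BH-adjusted p | contribution |")
    lines.append("|---|---|---|---|---|---|")
    for row in report["two_step"]:
        lines.append(
            "| {chrom} | {model} | {beta:.4g} | {p:.3g} | {padj:.3g} | {contribution:.4g} |".format(**row)
        )
    if report.get("class_associations"):
        lines += ["", "## Mutation-class associations", ""]
        for name, res in report["class_associations"].items():
            lines.append(f"### {name} (n = {res['n']})")
            for term, p in res["pvalues"].items():
                if term == "const":
                    continue
                lines.append(
                    f"- {term}: coef {res['coefficients'][term]:.4g}, p = {p:.3g} "
                    f"({res['verdicts'].get(term, '')})"
                )
            lines.append("")
    if report.get("clustering"):
        cl = report["clustering"]
        lines += ["", "## Clustering", ""]
        lines.append(f"- cluster sizes: {cl['sizes']}")
        if cl.get("enrichment"):
            e = cl["enrichment"]
            lines.append(
                f"- enrichment in focus clusters {e['focus_clusters']}: "
                f"table {e['table']}, Fisher p = {e['p']:.3g}, OR = {e['odds_ratio']:.3g}"
            )
    Path(path).write_text("\n".join(lines) + "\n")
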