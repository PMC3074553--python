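"""Hierarchical clustering of cancer genes on Alu-related features.

Genes are described by five features — intron Alu density, exon Alu density,
intron Alu-pair density, Alu-exon-Alu triplet count, and Alu-adjusted GC
content — and clustered agglomeratively with complete linkage and Euclidean
distance.  Features enter unscaled by default: the analysis cuts the tree at
an absolute height (4.5 by default), which is only meaningful on raw feature
units; z-scoring is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .association_stats import fisher_exact_2x2

__all__ = [
    "Dendrogram",
    "ClusterAssignment",
    "ClusteringError",
    "CLUSTER_FEATURES",
    "DEFAULT_CUT_HEIGHT",
    "cluster_genes",
    "cut_dendrogram",
    "cluster_class_enrichment",
    "to_newick",
]

CLUSTER_FEATURES = ["Di", "De", "pair_density", "triplet_count", "gc_adjusted"]
DEFAULT_CUT_HEIGHT = 4.5


class ClusteringError(ValueError):
    pass


@dataclass(frozen=True)
class Dendrogram:
    """Agglomeration history: a scipy linkage matrix plus leaf labels.

    Complete linkage guarantees merge heights are non-decreasing along the
    agglomeration sequence; n leaves produce n - 1 merges.
    """

    linkage: np.ndarray  # (n-1, 4) scipy linkage matrix
    labels: tuple[str, ...]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


@dataclass(frozen=True)
class ClusterAssignment:
    """Flat clustering obtained by cutting a dendrogram at a height."""

    assignment: dict[str, int]
    cut_height: float

    @property
    def cluster_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for cid in self.assignment.values():
            sizes[cid] = sizes.get(cid, 0) + 1
        return sizes

    def members(self, cluster_id: int) -> list[str]:
        return [g for g, c in self.assignment.items() if c == cluster_id]


def cluster_genes(features: pd.DataFrame, scale: str = "none") -> Dendrogram:
    """Complete-linkage Euclidean clustering of the gene feature matrix.

    *features* is indexed by gene symbol with the five clustering feature
    columns (any numeric columns are accepted).  ``scale="zscore"``
    standardizes each column first.  Deterministic given input order.
    """
    if len(features) < 2:
        raise ClusteringError("need at least 2 genes to cluster")
    X = features.astype(float)
    bad = X.index[X.isna().any(axis=1)]
    if len(bad):
        raise ClusteringError(f"NaN feature values for genes: {list(bad)}")
    if scale == "zscore":
        sd = X.std(ddof=0).replace(0.0, 1.0)
        X = (X - X.mean()) / sd
    elif scale != "none":
        raise ClusteringError(f"unknown scaling: {scale!r}")
    Z = hierarchy.linkage(X.values, method="complete", metric="euclidean")
    return Dendrogram(linkage=Z, labels=tuple(str(i) for i in features.index))


def cut_dendrogram(tree: Dendrogram, height: float) -> ClusterAssignment:
    """Clusters = connected components after removing merges above *height*."""
    if height < 0:
        raise ClusteringError("cut height must be >= 0")
    flat = hierarchy.fcluster(tree.linkage, t=height, criterion="distance")
    return ClusterAssignment(
        assignment={label: int(c) for label, c in zip(tree.labels, flat)},
        cut_height=float(height),
    )


def cluster_class_enrichment(
    assignment: ClusterAssignment,
    labels: dict[str, int],
    focus: set[int] | frozenset[int],
) -> tuple[np.ndarray, float, float]:
    """Fisher enrichment of a binary gene class in the *focus* clusters.

    Builds the 2x2 table with rows {focus clusters pooled, remaining
    non-singleton clusters pooled} and columns {label 1, label 0}.  Singleton
    clusters are excluded from both pools (a gene isolated by an extreme
    feature value is not evidence about either pool).  Returns
    ``(table, p, odds_ratio)``.
    """
    sizes = assignment.cluster_sizes
    singletons = {cid for cid, n in sizes.items() if n == 1}
    table = np.zeros((2, 2), dtype=int)
    n_focus = n_rest = 0
    for gene, cid in assignment.assignment.items():
        if cid in singletons:
            continue
        if gene not in labels:
            raise ClusteringError(f"no class label for gene {gene}")
        row = 0 if cid in focus else 1
        col = 0 if labels[gene] else 1
        table[row, col] += 1
        if row == 0:
            n_focus += 1
        else:
            n_rest += 1
    if n_focus == 0 or n_rest == 0:
        raise ClusteringError("focus or complement pool is empty after singleton removal")
    p, odds = fisher_exact_2x2(table)
    return table, p, odds


def to_newick(tree: Dendrogram) -> str:
    """Newick serialization of the dendrogram with branch lengths."""
    root = hierarchy.to_tree(tree.linkage)
    labels = tree.labels

    def walk(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(root, root.dist) + ";"
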