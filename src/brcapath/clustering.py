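"""Unsupervised hierarchical clustering of samples and genes.

Samples are clustered over a chosen gene subset (and genes over samples)
by agglomerative clustering, default average linkage on correlation
distance ``1 - r`` — the standard choice for expression heat maps.  The
quantitative stand-in for a visual dendrogram assessment is *purity*: the
largest fraction of one subtype's samples captured by a single cluster at
a given cut ``k``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .exceptions import InputError, ParameterError
from .io import SUBTYPES, ExpressionMatrix

logger = logging.getLogger(__name__)


def _distance_matrix(data: np.ndarray, metric: str) -> tuple[np.ndarray, list[int]]:
    """Condensed distance over rows of ``data``; returns flagged degenerate rows.

    With the correlation metric a zero-variance row has no defined
    correlation; it is assigned the maximal distance 2 to every other item.
    """
    flagged: list[int] = []
    if metric == "euclidean":
        return pdist(data, metric="euclidean"), flagged
    if metric != "correlation":
        raise ParameterError(f"unknown distance {metric!r}")
    sd = data.std(axis=1)
    flagged = list(np.flatnonzero(sd == 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(data)
    r = np.atleast_2d(np.nan_to_num(r, nan=-1.0))
    d = 1.0 - r
    for i in flagged:
        d[i, :] = 2.0
        d[:, i] = 2.0
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 2.0)
    return squareform(d, checks=False), flagged


@dataclass
class ClusteringResult:
    """Dendrograms for samples and genes plus label-aware evaluation."""

    samples: list[str]
    genes: list[str]
    sample_tree: np.ndarray  # scipy linkage matrix
    gene_tree: np.ndarray
    labels: dict[str, str]
    flagged_samples: list[str]
    flagged_genes: list[str]

    def sample_assignments(self, k: int) -> dict[str, int]:
        """Flat clusters at cut ``k`` (scipy maxclust criterion)."""
        flat = hierarchy.fcluster(self.sample_tree, t=k, criterion="maxclust")
        return dict(zip(self.samples, (int(c) for c in flat)))

    def purity(self, k: int) -> dict[str, float]:
        """Per subtype: max fraction of its samples inside one cluster."""
        assign = self.sample_assignments(k)
        out: dict[str, float] = {}
        for subtype in SUBTYPES:
            members = [s for s in self.samples if self.labels[s] == subtype]
            if not members:
                continue
            clusters = [assign[s] for s in members]
            best = max(clusters.count(c) for c in set(clusters))
            out[subtype] = best / len(members)
        return out


def hierarchical_cluster(
    expr: ExpressionMatrix,
    genes,
    linkage: str = "average",
    distance: str = "correlation",
) -> ClusteringResult:
    """Agglomerate samples (over the gene subset) and genes (over samples).

    Deterministic for a given input: scipy's linkage breaks ties by
    candidate order, which is fixed by the input ordering.
    """
    genes = sorted(genes, key=expr.gene_index)
    if len(genes) < 2 or expr.n_samples < 2:
        raise InputError("need at least 2 genes and 2 samples")
    if linkage not in ("average", "complete", "ward"):
        raise ParameterError(f"unknown linkage {linkage!r}")
    sub = expr.values[[expr.gene_index(g) for g in genes], :]
    d_samples, flag_s = _distance_matrix(sub.T, distance)
    d_genes, flag_g = _distance_matrix(sub, distance)
    if flag_s or flag_g:
        logger.warning(
            "%d samples / %d genes with zero variance assigned maximal distance",
            len(flag_s), len(flag_g),
        )
    return ClusteringResult(
        samples=list(expr.samples),
        genes=genes,
        sample_tree=hierarchy.linkage(d_samples, method=linkage),
        gene_tree=hierarchy.linkage(d_genes, method=linkage),
        labels=dict(expr.labels),
        flagged_samples=[expr.samples[i] for i in flag_s],
        flagged_genes=[genes[i] for i in flag_g],
    )


def compare_gene_sets(
    expr: ExpressionMatrix,
    core,
    union_set,
    k: int = 4,
    linkage: str = "average",
    distance: str = "correlation",
) -> dict[str, dict[str, float]]:
    """Cluster on the core set and on the full associated-gene union.

    Returns per-subtype purity at cut ``k`` for both gene sets, to test
    whether the small core set clusters samples as well as the union.
    """
    core, union_set = set(core), set(union_set)
    if not core <= union_set:
        raise InputError("core must be a subset of union_set")
    res_core = hierarchical_cluster(expr, core, linkage, distance)
    res_union = hierarchical_cluster(expr, union_set, linkage, distance)
    return {
        "purity_core": res_core.purity(k),
        "purity_union": res_union.purity(k),
    }
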