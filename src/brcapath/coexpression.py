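"""Per-subtype Pearson co-expression networks and their topology.

For one subtype stratum, pairwise Pearson correlations over a chosen gene
set yield a correlation matrix; thresholding |r| produces an undirected
network whose edges keep the signed correlation as weight.  The edge rule
follows the strict convention ``|r| > threshold`` while tabulated pair
counts use the inclusive ``|r| >= threshold``; both are exposed via the
``inclusive`` flag so each printed usage can be matched.

Four per-node topology statistics are reported: degree, average shortest
path length (within the node's connected component), closeness centrality
(reachable count divided by the sum of geodesics, the Cytoscape-compatible
within-component form), and the topological coefficient

    TC(n) = mean over nodes m sharing >=1 neighbor with n of J(n, m) / k_n

with ``J(n, m)`` the number of shared neighbors, plus one if n and m are
adjacent, and ``k_n`` the degree of n.  Nodes with no neighbor-sharing
partner get TC 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import InputError, ParameterError
from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (0.5, 0.6, 0.7, 0.8, 0.9)


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson correlation matrix for one subtype stratum."""

    genes: list[str]
    R: np.ndarray
    subtype: str
    degenerate_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        n = len(self.genes)
        if self.R.shape != (n, n):
            raise InputError("correlation matrix shape mismatch")
        if not np.allclose(self.R, self.R.T, atol=1e-12):
            raise InputError("correlation matrix is not symmetric")
        if np.any(np.abs(self.R) > 1 + 1e-12):
            raise InputError("|r| exceeds 1")


@dataclass
class CoexpressionNetwork:
    """Thresholded co-expression graph; nodes include isolated genes."""

    nodes: list[str]
    edges: dict[tuple[str, str], float]  # key sorted lexicographically
    subtype: str
    threshold: float

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_weighted_edges_from((a, b, r) for (a, b), r in self.edges.items())
        return g

    def to_edge_frame(self) -> pd.DataFrame:
        rows = [
            {"gene_a": a, "gene_b": b, "r": r, "subtype": self.subtype}
            for (a, b), r in sorted(self.edges.items())
        ]
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "r", "subtype"])


@dataclass
class TopologySummary:
    """Per-node topology statistics of one network."""

    degree: dict[str, int]
    avg_shortest_path: dict[str, float]
    closeness: dict[str, float]
    topological_coefficient: dict[str, float]
    isolated_nodes: list[str]

    def to_frame(self) -> pd.DataFrame:
        nodes = list(self.degree)
        return pd.DataFrame(
            {
                "node": nodes,
                "degree": [self.degree[n] for n in nodes],
                "avg_shortest_path": [self.avg_shortest_path[n] for n in nodes],
                "closeness": [self.closeness[n] for n in nodes],
                "topological_coefficient": [
                    self.topological_coefficient[n] for n in nodes
                ],
            }
        )

    def histograms(self, bins: int = 10) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        out = {}
        for name in ("degree", "avg_shortest_path", "closeness", "topological_coefficient"):
            vals = np.array(list(getattr(self, name).values()), dtype=float)
            counts, edges = np.histogram(vals, bins=bins)
            out[name] = (edges, counts)
        return out


def pearson_matrix(
    expr: ExpressionMatrix, genes, subtype: str
) -> CorrelationMatrix:
    """Pairwise Pearson r over one subtype's samples for the given genes.

    Zero-variance genes within the stratum get r = 0 against everything
    (including themselves) and are flagged.
    """
    genes = sorted(genes, key=expr.gene_index)
    cols = expr.subtype_columns(subtype)
    if len(cols) < 3:
        raise InputError(f"subtype {subtype} has <3 samples")
    sub = expr.values[np.ix_([expr.gene_index(g) for g in genes], cols)]
    sd = sub.std(axis=1)
    degenerate = sd == 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(sub)
    R = np.atleast_2d(R)
    R[degenerate, :] = 0.0
    R[:, degenerate] = 0.0
    np.fill_diagonal(R, np.where(degenerate, 0.0, 1.0))
    R = np.clip(R, -1.0, 1.0)
    flagged = [g for g, d in zip(genes, degenerate) if d]
    if flagged:
        logger.warning("%d zero-variance genes in %s stratum", len(flagged), subtype)
    return CorrelationMatrix(genes=genes, R=R, subtype=subtype, degenerate_genes=flagged)


def threshold_network(
    corr: CorrelationMatrix, threshold: float = 0.5, inclusive: bool = False
) -> CoexpressionNetwork:
    """Build the co-expression graph: edge iff |r| > threshold (>= if inclusive)."""
    if not 0.0 <= threshold < 1.0:
        raise ParameterError("threshold must lie in [0, 1)")
    n = len(corr.genes)
    edges: dict[tuple[str, str], float] = {}
    absr = np.abs(corr.R)
    mask = absr >= threshold if inclusive else absr > threshold
    iu, ju = np.triu_indices(n, k=1)
    for i, j in zip(iu[mask[iu, ju]], ju[mask[iu, ju]]):
        a, b = corr.genes[i], corr.genes[j]
        key = (a, b) if a <= b else (b, a)
        edges[key] = float(corr.R[i, j])
    return CoexpressionNetwork(
        nodes=list(corr.genes), edges=edges, subtype=corr.subtype, threshold=threshold
    )


def pair_counts(
    corr: CorrelationMatrix, thresholds=DEFAULT_THRESHOLDS
) -> dict[float, int]:
    """Number of unordered gene pairs with |r| >= t for each threshold t."""
    n = len(corr.genes)
    iu, ju = np.triu_indices(n, k=1)
    absr = np.abs(corr.R[iu, ju])
    return {float(t): int(np.sum(absr >= t)) for t in thresholds}


def log10_pair_counts(counts: dict[float, int]) -> dict[float, float]:
    """log10 of each pair count; zero counts map to -inf -> reported as nan."""
    return {
        t: (math.log10(c) if c > 0 else float("nan")) for t, c in counts.items()
    }


def topology_summary(net: CoexpressionNetwork) -> TopologySummary:
    """Compute the four per-node topology statistics (see module docstring)."""
    g = net.to_networkx()
    degree = {n: int(g.degree[n]) for n in net.nodes}
    aspl: dict[str, float] = {}
    closeness: dict[str, float] = {}
    tc: dict[str, float] = {}
    isolated = [n for n in net.nodes if degree[n] == 0]
    neighbors = {n: set(g.neighbors(n)) for n in net.nodes}
    for n in net.nodes:
        lengths = nx.single_source_shortest_path_length(g, n)
        lengths.pop(n)
        if lengths:
            total = sum(lengths.values())
            aspl[n] = total / len(lengths)
            closeness[n] = len(lengths) / total
        else:
            aspl[n] = 0.0
            closeness[n] = 0.0
        k = degree[n]
        partners = set()
        for nb in neighbors[n]:
            partners |= neighbors[nb]
        partners.discard(n)
        ratios = []
        for m in partners:
            shared = len(neighbors[n] & neighbors[m])
            if shared == 0:
                continue
            j = shared + (1 if m in neighbors[n] else 0)
            ratios.append(j / k)
        tc[n] = float(np.mean(ratios)) if ratios else 0.0
    return TopologySummary(
        degree=degree,
        avg_shortest_path=aspl,
        closeness=closeness,
        topological_coefficient=tc,
        isolated_nodes=isolated,
    )


@dataclass
class CentralityComparison:
    """log10-degree summary of core genes vs all connected nodes."""

    core_mean_log10_degree: float | None
    all_mean_log10_degree: float | None
    all_sd_log10_degree: float | None
    n_excluded_isolated: int


def centrality_comparison(
    summary: TopologySummary, core_genes: set[str]
) -> CentralityComparison:
    """Mean/SD of log10(degree), core genes vs all nodes with degree >= 1.

    Isolated nodes are excluded (log10 of 0 is undefined); if no core gene
    is connected the core mean is reported as missing, not an error.
    """
    connected = {n: d for n, d in summary.degree.items() if d >= 1}
    if not connected:
        raise InputError("network has no edges")
    logs = {n: math.log10(d) for n, d in connected.items()}
    all_vals = np.array(list(logs.values()))
    core_vals = np.array([v for n, v in logs.items() if n in core_genes])
    return CentralityComparison(
        core_mean_log10_degree=float(core_vals.mean()) if core_vals.size else None,
        all_mean_log10_degree=float(all_vals.mean()),
        all_sd_log10_degree=float(all_vals.std(ddof=1)) if all_vals.size > 1 else 0.0,
        n_excluded_isolated=len(summary.degree) - len(connected),
    )
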