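"""Per-sample pathway alteration scores against the luminal-A reference.

For a pathway P and one sample, pathway genes are partitioned by comparing
each gene's expression G to mu, the gene's mean over the luminal-A (LA)
samples — the least-malignant subtype serves as the control.  With
upregulated genes i = 1..m (G > mu) and downregulated genes j = 1..n
(G < mu; ties excluded), the alteration score is

    score(P) = ln( sum_i (G_i / mu_i)^2  /  sum_j (G_j / mu_j)^2 )

A higher score means more positive variation of the pathway relative to
the LA state; LA samples themselves fluctuate around zero.

Numerical guards (all counts logged/flagged):

* reference means with |mu| < epsilon are clamped to sign(mu) * epsilon
  (sign of exact zero treated as +) so ratios stay finite;
* each |G/mu| ratio is capped at 1/epsilon so a near-zero reference cannot
  dominate a sum;
* an empty up or down group contributes epsilon, keeping the score finite
  and signed toward the non-empty side;
* a pathway with no scoreable gene (all ties) scores 0.

Because the pipeline z-scores expression upstream, mu can legitimately sit
near zero for uninformative genes; the guards make those genes inert while
genes whose LA mean is displaced (the informative ones) contribute real
ratios.  ``score_matrix`` can also be run on pre-normalization values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InputError
from .io import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)

DEFAULT_EPSILON = 1e-6


def reference_means(
    expr: ExpressionMatrix, epsilon: float = DEFAULT_EPSILON
) -> tuple[dict[str, float], list[str]]:
    """Per-gene mean over LA samples, clamped away from zero.

    Returns the mean map and the list of genes whose mean was clamped.
    """
    cols = expr.subtype_columns("LA")
    if len(cols) == 0:
        raise InputError("no LA samples to serve as reference")
    mu = expr.values[:, cols].mean(axis=1)
    clamped = [g for g, m in zip(expr.genes, mu) if abs(m) < epsilon]
    if clamped:
        logger.info("%d reference means clamped to +/-epsilon", len(clamped))
    mu = np.where(np.abs(mu) < epsilon, np.where(mu < 0, -epsilon, epsilon), mu)
    return dict(zip(expr.genes, mu.astype(float))), clamped


def alteration_score(
    sample_values: dict[str, float],
    pathway,
    mu: dict[str, float],
    epsilon: float = DEFAULT_EPSILON,
) -> float:
    """Scalar, per-gene-loop evaluation of the alteration score.

    This is the reference implementation; :func:`score_matrix` is the
    vectorized equivalent used by the pipeline.
    """
    # sorted iteration fixes the accumulation order, making the
    # swap-the-groups antisymmetry exact in floating point
    genes = sorted(g for g in pathway if g in mu and g in sample_values)
    if not genes:
        raise InputError("pathway shares no genes with the reference means")
    up_sum = 0.0
    down_sum = 0.0
    scoreable = 0
    for g in genes:
        m = mu[g]
        if abs(m) < epsilon:
            m = -epsilon if m < 0 else epsilon
        g_val = sample_values[g]
        if g_val == m:
            continue  # ties are neither up nor down
        ratio = g_val / m
        ratio = max(min(ratio, 1.0 / epsilon), -1.0 / epsilon)
        if g_val > m:
            up_sum += ratio * ratio
        else:
            down_sum += ratio * ratio
        scoreable += 1
    if scoreable == 0:
        logger.warning("pathway with no scoreable genes scores 0")
        return 0.0
    if up_sum == 0.0:
        up_sum = epsilon
    if down_sum == 0.0:
        down_sum = epsilon
    # log(up) - log(down) rather than log(up/down): negates exactly under
    # an up/down swap
    return math.log(up_sum) - math.log(down_sum)


@dataclass
class PathwayScoreMatrix:
    """Sample x pathway matrix of alteration scores."""

    samples: list[str]
    pathways: list[str]
    scores: np.ndarray
    reference_means: dict[str, float]
    epsilon: float
    zscored: bool = False

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.samples), len(self.pathways)):
            raise InputError("score matrix shape mismatch")
        if not np.all(np.isfinite(self.scores)):
            raise InputError("scores must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.samples, columns=self.pathways)

    def subset_samples(self, samples: list[str]) -> "PathwayScoreMatrix":
        idx = {s: i for i, s in enumerate(self.samples)}
        rows = [idx[s] for s in samples]
        return PathwayScoreMatrix(
            list(samples), list(self.pathways), self.scores[rows, :],
            self.reference_means, self.epsilon, self.zscored,
        )

    def zscore_columns(self) -> "PathwayScoreMatrix":
        """Standardize each pathway column (ddof=1) for classifier use."""
        mean = self.scores.mean(axis=0, keepdims=True)
        sd = self.scores.std(axis=0, ddof=1, keepdims=True)
        sd[sd == 0.0] = 1.0
        return PathwayScoreMatrix(
            list(self.samples), list(self.pathways),
            (self.scores - mean) / sd,
            self.reference_means, self.epsilon, zscored=True,
        )


def score_matrix(
    expr: ExpressionMatrix,
    collection: GeneSetCollection,
    pathways=None,
    epsilon: float = DEFAULT_EPSILON,
    zscore_columns: bool = False,
    mu: dict[str, float] | None = None,
) -> PathwayScoreMatrix:
    """Vectorized alteration scores for every sample x pathway.

    ``mu`` defaults to the LA reference means of ``expr`` itself; pass a
    precomputed map to score a sample subset against the full-cohort
    reference.
    """
    if pathways is None:
        pathways = collection.names()
    missing = [p for p in pathways if p not in collection]
    if missing:
        raise InputError(f"unknown pathways: {missing}")
    if mu is None:
        mu, _ = reference_means(expr, epsilon)

    cap = 1.0 / epsilon
    scores = np.zeros((expr.n_samples, len(pathways)))
    for col, name in enumerate(pathways):
        genes = [g for g in collection.sets[name] if g in mu]
        genes.sort(key=expr.gene_index)
        if not genes:
            raise InputError(f"pathway {name!r} shares no genes with the matrix")
        sub = expr.values[[expr.gene_index(g) for g in genes], :]
        mu_vec = np.array([mu[g] for g in genes])[:, None]
        mu_vec = np.where(np.abs(mu_vec) < epsilon,
                          np.where(mu_vec < 0, -epsilon, epsilon), mu_vec)
        ratio = np.clip(sub / mu_vec, -cap, cap)
        sq = ratio * ratio
        up = sub > mu_vec
        down = sub < mu_vec
        up_sum = np.where(up, sq, 0.0).sum(axis=0)
        down_sum = np.where(down, sq, 0.0).sum(axis=0)
        scoreable = (up | down).sum(axis=0)
        up_sum = np.where(up_sum == 0.0, epsilon, up_sum)
        down_sum = np.where(down_sum == 0.0, epsilon, down_sum)
        col_scores = np.log(up_sum) - np.log(down_sum)
        col_scores[scoreable == 0] = 0.0
        scores[:, col] = col_scores
    out = PathwayScoreMatrix(
        samples=list(expr.samples), pathways=list(pathways), scores=scores,
        reference_means=dict(mu), epsilon=epsilon,
    )
    return out.zscore_columns() if zscore_columns else out
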