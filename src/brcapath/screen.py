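"""Two-stage screen for subtype-associated, subtype-specific and core genes.

Stage 1: one-way fixed-effects ANOVA per gene across the four subtype
groups keeps genes with ``P < alpha_anova`` (default 0.05, raw — no
multiple-testing correction, matching the classical screen this module
implements; Benjamini-Hochberg is available as an option).

Stage 2: for every surviving gene and every subtype M, classical
pooled-variance Student's t-tests of M's samples against each of the other
three subtypes.  A gene is *associated* with M when all three p-values are
below ``alpha_t`` (default 0.01, strict inequality).  A gene associated
with exactly one subtype is *specific* to it; a gene associated with all
four simultaneously is a *core* gene.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import InputError
from .io import SUBTYPES, ExpressionMatrix
from .multitest import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class GeneScreenResult:
    """Full output of the two-stage screen."""

    anova_p: dict[str, float]
    subtype_sets: dict[str, set[str]]
    specific_sets: dict[str, set[str]]
    core_genes: set[str]
    pairwise_p: dict[tuple[str, str, str], float]
    alpha_anova: float
    alpha_t: float

    def to_dict(self) -> dict:
        return {
            "alpha_anova": self.alpha_anova,
            "alpha_t": self.alpha_t,
            "subtype_sets": {k: sorted(v) for k, v in self.subtype_sets.items()},
            "specific_sets": {k: sorted(v) for k, v in self.specific_sets.items()},
            "core_genes": sorted(self.core_genes),
            "n_anova_significant": int(
                sum(p < self.alpha_anova for p in self.anova_p.values())
            ),
        }


def _group_columns(expr: ExpressionMatrix) -> dict[str, np.ndarray]:
    cols = {s: expr.subtype_columns(s) for s in SUBTYPES}
    small = [s for s, c in cols.items() if len(c) < 2]
    if small:
        raise InputError(f"subtypes with <2 samples: {small}")
    return cols


def anova_screen(expr: ExpressionMatrix, alpha: float = 0.05) -> dict[str, float]:
    """One-way ANOVA F-test p-value per gene across the four subtypes.

    All p-values are returned; thresholding at ``alpha`` is the caller's
    job.  Genes that are constant everywhere (F undefined) get p = 1 so the
    downstream set algebra stays total.
    """
    cols = _group_columns(expr)
    groups = [expr.values[:, cols[s]] for s in SUBTYPES]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant-input and 0/0 warnings
        _, p = stats.f_oneway(*groups, axis=1)
    p = np.where(np.isfinite(p), p, 1.0)
    return dict(zip(expr.genes, p.astype(float)))


def _pooled_t_p(
    m1: np.ndarray, v1: np.ndarray, n1: int, m2: np.ndarray, v2: np.ndarray, n2: int
) -> np.ndarray:
    """Two-sided pooled-variance Student's t p-values, vectorized.

    Zero pooled variance is degenerate: p = 1 when the means are equal
    (no evidence), p = 0 when they differ (infinite t, by convention).
    """
    df = n1 + n2 - 2
    pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    degenerate = pooled == 0.0
    p = np.where(degenerate & (diff == 0.0), 1.0, p)
    p = np.where(degenerate & (diff != 0.0), 0.0, p)
    return p


def pairwise_subtype_test(
    expr: ExpressionMatrix, gene: str, subtype: str
) -> dict[str, float]:
    """Student's t of ``subtype`` vs each other subtype for one gene."""
    cols = _group_columns(expr)
    row = expr.values[expr.gene_index(gene), :]
    x = row[cols[subtype]]
    out: dict[str, float] = {}
    for other in SUBTYPES:
        if other == subtype:
            continue
        y = row[cols[other]]
        p = _pooled_t_p(
            np.array([x.mean()]), np.array([x.var(ddof=1)]), len(x),
            np.array([y.mean()]), np.array([y.var(ddof=1)]), len(y),
        )
        out[other] = float(p[0])
    return out


def screen(
    expr: ExpressionMatrix,
    alpha_anova: float = 0.05,
    alpha_t: float = 0.01,
    adjust: bool = False,
) -> GeneScreenResult:
    """Run the full two-stage screen.

    Pairwise tests are computed only for genes that pass the ANOVA stage.
    A gene may be associated with several subtypes (overlap semantics);
    ``adjust=True`` applies Benjamini-Hochberg within each stage before
    thresholding (off by default).
    """
    cols = _group_columns(expr)
    anova_p = anova_screen(expr, alpha_anova)
    p_arr = np.array([anova_p[g] for g in expr.genes])
    thresh_p = bh_adjust(p_arr) if adjust else p_arr
    passing = np.flatnonzero(thresh_p < alpha_anova)
    logger.info("ANOVA stage: %d / %d genes pass", len(passing), expr.n_genes)

    means = {s: expr.values[:, cols[s]].mean(axis=1) for s in SUBTYPES}
    variances = {s: expr.values[:, cols[s]].var(axis=1, ddof=1) for s in SUBTYPES}
    sizes = {s: len(cols[s]) for s in SUBTYPES}

    pairwise_p: dict[tuple[str, str, str], float] = {}
    subtype_sets: dict[str, set[str]] = {}
    for subtype in SUBTYPES:
        ok = np.ones(len(passing), dtype=bool)
        for other in SUBTYPES:
            if other == subtype:
                continue
            p = _pooled_t_p(
                means[subtype][passing], variances[subtype][passing], sizes[subtype],
                means[other][passing], variances[other][passing], sizes[other],
            )
            if adjust:
                p = bh_adjust(p)
            for idx, pv in zip(passing, p):
                pairwise_p[(expr.genes[idx], subtype, other)] = float(pv)
            ok &= p < alpha_t
        subtype_sets[subtype] = {expr.genes[i] for i in passing[ok]}

    specific_sets = {
        s: subtype_sets[s]
        - set().union(*(subtype_sets[o] for o in SUBTYPES if o != s))
        for s in SUBTYPES
    }
    core_genes = set.intersection(*(subtype_sets[s] for s in SUBTYPES))
    logger.info(
        "associated per subtype: %s; core: %d",
        {s: len(v) for s, v in subtype_sets.items()},
        len(core_genes),
    )
    return GeneScreenResult(
        anova_p=anova_p,
        subtype_sets=subtype_sets,
        specific_sets=specific_sets,
        core_genes=core_genes,
        pairwise_p=pairwise_p,
        alpha_anova=alpha_anova,
        alpha_t=alpha_t,
    )


def venn_counts(sets: dict[str, set[str]]) -> dict[str, int]:
    """Counts for the 15 non-empty membership regions of four sets.

    Keys are 0/1 signatures in the order of ``sets`` (e.g. ``"1111"`` is
    the intersection of all four, the core region).
    """
    if len(sets) != 4:
        raise InputError("venn_counts expects exactly four sets")
    names = list(sets)
    union = set().union(*sets.values())
    counts = {
        "".join("1" if k & (1 << (3 - i)) else "0" for i in range(4)): 0
        for k in range(1, 16)
    }
    for g in union:
        sig = "".join("1" if g in sets[n] else "0" for n in names)
        counts[sig] += 1
    return counts
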