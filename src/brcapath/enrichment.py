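"""Gene-set over-representation by the one-sided Fisher exact test.

For a query gene set (e.g. the core genes) and each pathway in a
collection, the p-value is the hypergeometric upper tail

    P(X >= count),  X ~ Hypergeom(universe_size, set_size, query_size)

i.e. the one-sided Fisher exact test for over-representation — the
standard convention for enrichment.  The universe is the measured gene
background attached to the collection; p-values are reported raw by
default (an optional Benjamini-Hochberg column is available).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .io import GeneSetCollection
from .multitest import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentRow:
    pathway: str
    count: int
    p_value: float
    query_size: int
    set_size: int
    universe_size: int
    significant: bool


def fisher_enrichment(
    query, collection: GeneSetCollection, alpha: float = 0.05, adjust: bool = False
) -> list[EnrichmentRow]:
    """Over-representation p-value for every pathway, sorted ascending.

    Query genes outside the universe are dropped with a warning; an empty
    query yields an empty result.
    """
    query = set(query)
    outside = query - collection.universe
    if outside:
        logger.warning("%d query genes outside the universe dropped", len(outside))
        query -= outside
    if not query:
        logger.warning("empty query after universe restriction")
        return []
    m = len(collection.universe)
    q = len(query)
    rows = []
    for name, members in collection.sets.items():
        count = len(query & members)
        # hypergeometric upper tail P(X >= count)
        p = float(stats.hypergeom.sf(count - 1, m, len(members), q))
        rows.append(
            EnrichmentRow(
                pathway=name,
                count=count,
                p_value=min(p, 1.0),
                query_size=q,
                set_size=len(members),
                universe_size=m,
                significant=False,
            )
        )
    rows.sort(key=lambda r: (r.p_value, r.pathway))
    pvals = [r.p_value for r in rows]
    flags = bh_adjust(pvals) < alpha if adjust else [p < alpha for p in pvals]
    for r, f in zip(rows, flags):
        r.significant = bool(f)
    return rows


def enrichment_frame(rows: list[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pathway": r.pathway,
                "count": r.count,
                "p_value": r.p_value,
                "query_size": r.query_size,
                "set_size": r.set_size,
                "universe_size": r.universe_size,
                "significant": r.significant,
            }
            for r in rows
        ],
        columns=[
            "pathway", "count", "p_value",
            "query_size", "set_size", "universe_size", "significant",
        ],
    )
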