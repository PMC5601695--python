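"""Sliding-window integration of pathway scores and LOESS smoothing.

Samples are ordered by subtype rank along the malignancy order
LA -> LB -> HER2+ -> TN (stable within subtype).  Per-sample pathway
scores are integrated over windows of ``window_size`` samples advancing by
``step`` (defaults 20/10, i.e. adjacent windows overlap by 10 samples); the
per-window median is then smoothed with LOESS (locally weighted linear
regression with tricube weights) over the window index.

A final short window is appended whenever samples remain beyond the last
full window, so no sample is silently dropped; it is flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .exceptions import InputError, ParameterError
from .io import SUBTYPE_RANK
from .pathway_score import PathwayScoreMatrix

logger = logging.getLogger(__name__)


def order_samples(
    scores: PathwayScoreMatrix, labels: dict[str, str]
) -> list[str]:
    """Samples sorted by subtype rank, stable within subtype."""
    missing = [s for s in scores.samples if s not in labels]
    if missing:
        raise InputError(f"unlabeled samples: {missing[:5]}")
    return sorted(scores.samples, key=lambda s: SUBTYPE_RANK[labels[s]])


def sliding_windows(
    n_samples: int, window_size: int = 20, step: int = 10
) -> tuple[list[tuple[int, int]], bool]:
    """Half-open index windows [0,w), [step,step+w), ...

    Returns the window list and a flag telling whether a final short
    window was appended to cover leftover samples.  When ``n_samples`` is
    below ``window_size`` a single all-sample window is returned with a
    warning.
    """
    if window_size < 1 or step < 1 or step > window_size:
        raise ParameterError("need 1 <= step <= window_size")
    if n_samples < window_size:
        logger.warning(
            "n_samples %d < window_size %d: single window", n_samples, window_size
        )
        return [(0, n_samples)], False
    windows = []
    start = 0
    while start + window_size <= n_samples:
        windows.append((start, start + window_size))
        start += step
    partial = windows[-1][1] < n_samples
    if partial:
        logger.info("appending short window [%d, %d)", start, n_samples)
        windows.append((start, n_samples))
    return windows, partial


def window_medians(values, windows: list[tuple[int, int]]) -> list[float]:
    """Median of each window slice (even counts: mean of the central pair)."""
    values = np.asarray(values, dtype=float)
    for start, end in windows:
        if not (0 <= start < end <= len(values)):
            raise InputError(f"window [{start},{end}) out of bounds")
    return [float(np.median(values[s:e])) for s, e in windows]


def loess_fit(
    x, y, span: float = 0.75, degree: int = 1
) -> list[float]:
    """LOESS-smoothed values at each x (tricube weights, local linear fit).

    Only degree-1 local fits are supported.  The fit is deterministic and,
    because points are sorted internally, invariant to input ordering.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if degree != 1:
        raise ParameterError("only locally linear (degree=1) LOESS is supported")
    if x.shape != y.shape or x.size < 3:
        raise InputError("need matching x/y with at least 3 points")
    if np.all(x == x[0]):
        raise InputError("degenerate design: all x identical")
    if span * x.size < degree + 1:
        raise ParameterError("span too small for the local fit")
    fitted_sorted = lowess(
        y, x, frac=span, it=0, return_sorted=False, is_sorted=False
    )
    return [float(v) for v in fitted_sorted]


@dataclass
class WindowSeries:
    """Per-pathway window medians and LOESS fits along the subtype order."""

    ordered_samples: list[str]
    windows: list[tuple[int, int]]
    has_partial_window: bool
    medians: dict[str, list[float]]
    fitted: dict[str, list[float]]
    window_subtype: list[str]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pathway in self.medians:
            for w, ((start, end), med, fit) in enumerate(
                zip(self.windows, self.medians[pathway], self.fitted[pathway])
            ):
                rows.append(
                    {
                        "window_index": w,
                        "start": start,
                        "end": end,
                        "dominant_subtype": self.window_subtype[w],
                        "pathway": pathway,
                        "median": med,
                        "fitted": fit,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "window_index", "start", "end", "dominant_subtype",
                "pathway", "median", "fitted",
            ],
        )


def pathway_trends(
    scores: PathwayScoreMatrix,
    labels: dict[str, str],
    window_size: int = 20,
    step: int = 10,
    span: float = 0.75,
) -> WindowSeries:
    """Order samples, window each pathway's scores, smooth the medians."""
    ordered = order_samples(scores, labels)
    sub = scores.subset_samples(ordered)
    windows, partial = sliding_windows(len(ordered), window_size, step)
    x = np.arange(len(windows), dtype=float)
    medians: dict[str, list[float]] = {}
    fitted: dict[str, list[float]] = {}
    for col, pathway in enumerate(sub.pathways):
        med = window_medians(sub.scores[:, col], windows)
        medians[pathway] = med
        fitted[pathway] = loess_fit(x, med, span=span)
    window_subtype = []
    for start, end in windows:
        labs = [labels[s] for s in ordered[start:end]]
        window_subtype.append(max(set(labs), key=labs.count))
    return WindowSeries(
        ordered_samples=ordered,
        windows=windows,
        has_partial_window=partial,
        medians=medians,
        fitted=fitted,
        window_subtype=window_subtype,
    )
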