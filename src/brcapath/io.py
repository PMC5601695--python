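"""Core data model and file I/O.

The pipeline's substrate is a gene x sample expression matrix with one
clinical subtype label per sample.  Breast cancer samples carry one of four
receptor-status subtypes ordered by reported malignancy::

    LA (luminal A) < LB (luminal B) < HER2+ < TN (triple negative)

Expression values are arbitrary but consistent units; every analysis stage
assumes the matrix has been row z-scored (:func:`zscore_rows`) unless stated
otherwise.  Gene sets ("pathways") are read from standard GMT files and are
restricted at load time to the measured gene universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import EmptyInputError, FormatError, InputError

logger = logging.getLogger(__name__)

#: Canonical subtype order, least to most malignant.
SUBTYPES: tuple[str, ...] = ("LA", "LB", "HER2+", "TN")

#: Rank of each subtype along the malignancy order (LA=0 ... TN=3).
SUBTYPE_RANK: dict[str, int] = {s: i for i, s in enumerate(SUBTYPES)}


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values with per-sample subtype labels.

    Parameters
    ----------
    genes
        Ordered, unique gene identifiers (rows).
    samples
        Ordered, unique sample identifiers (columns).
    values
        Real matrix of shape ``(len(genes), len(samples))``; must be finite.
    labels
        Mapping sample id -> subtype, one of :data:`SUBTYPES`.
    """

    genes: list[str]
    samples: list[str]
    values: np.ndarray
    labels: dict[str, str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.genes)) != len(self.genes):
            raise FormatError("duplicate gene identifiers")
        if len(set(self.samples)) != len(self.samples):
            raise FormatError("duplicate sample identifiers")
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise InputError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise InputError("expression values must be finite (no NaN/inf)")
        missing = [s for s in self.samples if s not in self.labels]
        if missing:
            raise InputError(f"samples without subtype label: {missing[:5]}")
        bad = {v for v in self.labels.values()} - set(SUBTYPES)
        if bad:
            raise InputError(f"unknown subtype labels: {sorted(bad)}")
        self._gene_index = {g: i for i, g in enumerate(self.genes)}
        self._sample_index = {s: j for j, s in enumerate(self.samples)}

    # -- convenience accessors -------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def gene_index(self, gene: str) -> int:
        return self._gene_index[gene]

    def subtype_samples(self, subtype: str) -> list[str]:
        """Samples carrying ``subtype``, in matrix column order."""
        return [s for s in self.samples if self.labels[s] == subtype]

    def subtype_columns(self, subtype: str) -> np.ndarray:
        """Column indices of the samples carrying ``subtype``."""
        return np.array(
            [j for j, s in enumerate(self.samples) if self.labels[s] == subtype],
            dtype=int,
        )

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        rows = [self._gene_index[g] for g in genes]
        return ExpressionMatrix(
            list(genes), list(self.samples), self.values[rows, :], dict(self.labels)
        )

    def subset_samples(self, samples: list[str]) -> "ExpressionMatrix":
        cols = [self._sample_index[s] for s in samples]
        return ExpressionMatrix(
            list(self.genes),
            list(samples),
            self.values[:, cols],
            {s: self.labels[s] for s in samples},
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)


@dataclass
class GeneSetCollection:
    """Named gene sets with an attached background universe."""

    sets: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise InputError(f"gene set {name!r} is empty")
            extra = members - self.universe
            if extra:
                raise InputError(
                    f"gene set {name!r} has members outside the universe: "
                    f"{sorted(extra)[:5]}"
                )

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_expression(path, labels_path) -> ExpressionMatrix:
    """Load a genes x samples TSV plus a two-column sample/subtype table.

    Samples present in the matrix but missing from the label table are
    dropped with a logged warning (samples with incomplete clinical
    annotation cannot be placed in a subtype).
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"cannot parse expression TSV {path}: {exc}") from exc
    if df.index.has_duplicates:
        raise FormatError("duplicate gene identifiers in expression TSV")
    if df.columns.has_duplicates:
        raise FormatError("duplicate sample identifiers in expression TSV")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric expression cell: {exc}") from exc

    labels_df = pd.read_csv(labels_path, sep="\t", dtype=str)
    if labels_df.shape[1] < 2:
        raise FormatError("labels TSV needs columns sample_id, subtype")
    labels = dict(zip(labels_df.iloc[:, 0], labels_df.iloc[:, 1]))

    keep = [s for s in df.columns if s in labels]
    dropped = [s for s in df.columns if s not in labels]
    if dropped:
        logger.warning(
            "dropping %d unlabeled samples (e.g. %s)", len(dropped), dropped[:3]
        )
    if not keep:
        raise EmptyInputError("no overlap between matrix samples and labels")
    cols = [df.columns.get_loc(s) for s in keep]
    return ExpressionMatrix(
        genes=[str(g) for g in df.index],
        samples=keep,
        values=values[:, cols],
        labels={s: labels[s] for s in keep},
    )


def write_expression(expr: ExpressionMatrix, path, labels_path=None) -> None:
    """Write the matrix (and optionally the labels) back to TSV."""
    expr.to_frame().to_csv(path, sep="\t", index_label="gene")
    if labels_path is not None:
        write_labels(expr.labels, labels_path, order=expr.samples)


def write_labels(labels: dict[str, str], path, order=None) -> None:
    order = list(labels) if order is None else order
    pd.DataFrame(
        {"sample_id": order, "subtype": [labels[s] for s in order]}
    ).to_csv(path, sep="\t", index=False)


def zscore_rows(expr: ExpressionMatrix) -> tuple[ExpressionMatrix, list[str]]:
    """Standardize each gene row to mean 0, sample SD 1 (ddof=1).

    Zero-variance rows cannot be scaled; they are set to all zeros and
    returned in the flag list so downstream universes stay stable.
    """
    if expr.n_samples < 2:
        raise InputError("z-scoring needs at least 2 samples")
    mean = expr.values.mean(axis=1, keepdims=True)
    sd = expr.values.std(axis=1, ddof=1, keepdims=True)
    flat = sd[:, 0] == 0.0
    sd[flat] = 1.0
    z = (expr.values - mean) / sd
    z[flat, :] = 0.0
    flagged = [g for g, f in zip(expr.genes, flat) if f]
    if flagged:
        logger.warning("%d zero-variance genes zeroed during z-scoring", len(flagged))
    out = ExpressionMatrix(
        list(expr.genes), list(expr.samples), z, dict(expr.labels)
    )
    return out, flagged


def read_gene_sets(path, universe: set[str]) -> GeneSetCollection:
    """Read a GMT file and restrict each set to the measured gene universe.

    Sets emptied by the restriction are dropped with a warning; the number
    of unmeasured member genes is logged.
    """
    sets: dict[str, set[str]] = {}
    n_dropped_genes = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields"
                )
            name, _desc, *members = fields
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = [m for m in members if m]
            kept = set(members) & universe
            n_dropped_genes += len(set(members)) - len(kept)
            if not kept:
                logger.warning("gene set %r empty after universe restriction", name)
                continue
            sets[name] = kept
    if n_dropped_genes:
        logger.info("dropped %d unmeasured gene-set members", n_dropped_genes)
    return GeneSetCollection(sets=sets, universe=set(universe))


def write_gene_sets(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, "na", *sorted(members)]) + "\n")
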