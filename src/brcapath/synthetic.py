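"""Synthetic four-subtype cohorts with known ground truth.

Real cohorts of this design (a few hundred tumors, ~20k genes, four
receptor-status subtypes with very unbalanced group sizes) cannot be
shipped, so every pipeline stage is exercised on generated cohorts in which
the answers are planted and therefore checkable:

* background genes are i.i.d. Gaussian noise around a common positive
  baseline (log-expression-like units), identical across subtypes;
* each *subtype-specific* gene has its mean shifted by ``effect_size``
  standard deviations in exactly one subtype;
* each *core* gene follows a monotone linear mean gradient along the
  malignancy order LA -> LB -> HER2+ -> TN (step ``effect_size`` SD per
  rank, sign alternating per gene), so it separates every pair of subtypes;
* core-gene residuals (block 1) and one background gene block (block 0)
  are drawn with a subtype-dependent equicorrelation, the target
  correlation decreasing along the malignancy order, emulating the
  progressive loss of co-expression toward the triple-negative subtype —
  cross-gene correlation leaves every per-gene statistic untouched;
* gene sets are generated so that designated pathways are enriched for the
  planted core genes (and, per subtype, for that subtype's specific genes),
  giving enrichment, scoring and classification stages known answers.

Expression is generated directly on a Gaussian scale: the pipeline consumes
normalized values, so no count model is used.  Everything derives from a
single integer seed and is bitwise reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ParameterError
from .io import SUBTYPES, SUBTYPE_RANK, ExpressionMatrix, GeneSetCollection

#: Scaled-down analogue of the published cohort design (363/184/37/114).
DEFAULT_N_PER_SUBTYPE: dict[str, int] = {"LA": 60, "LB": 40, "HER2+": 20, "TN": 40}

#: Target within-block pairwise correlation per subtype, decreasing along
#: the malignancy order to emulate correlation loss toward TN.
DEFAULT_CORRELATIONS: dict[str, float] = {"LA": 0.8, "LB": 0.65, "HER2+": 0.5, "TN": 0.3}


@dataclass
class PathwayTruth:
    """Planted role of one generated pathway."""

    enriched_for_core: bool
    enriched_for_subtype: str | None
    #: +1 / -1 / 0 net direction of the planted member shifts per subtype.
    direction_by_subtype: dict[str, int]


@dataclass
class CohortTruth:
    """Ground truth planted into a generated cohort."""

    specific_genes: dict[str, set[str]]
    core_genes: set[str]
    block_assignments: dict[str, int]
    block_correlation: dict[tuple[int, str], float]
    pathway_truth: dict[str, PathwayTruth] = field(default_factory=dict)
    all_genes: tuple[str, ...] = ()
    core_direction: dict[str, int] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "specific_genes": {k: sorted(v) for k, v in self.specific_genes.items()},
            "core_genes": sorted(self.core_genes),
            "block_assignments": self.block_assignments,
            "block_correlation": {
                f"{b}|{s}": r for (b, s), r in self.block_correlation.items()
            },
            "core_direction": self.core_direction,
            "pathway_truth": {
                name: {
                    "enriched_for_core": t.enriched_for_core,
                    "enriched_for_subtype": t.enriched_for_subtype,
                    "direction_by_subtype": t.direction_by_subtype,
                }
                for name, t in self.pathway_truth.items()
            },
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def generate_cohort(
    n_per_subtype: dict[str, int] | None = None,
    n_genes: int = 2000,
    n_specific_per_subtype: int = 50,
    n_core: int = 30,
    effect_size: float = 2.5,
    block_size: int = 30,
    correlations_by_subtype: dict[str, float] | None = None,
    noise_sd: float = 1.0,
    baseline: float = 10.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, CohortTruth]:
    """Draw one cohort; see the module docstring for the generative model.

    ``effect_size`` is the mean shift in units of ``noise_sd``; for core
    genes it is the per-rank step of the linear gradient, so the LA-to-TN
    contrast is ``3 * effect_size`` SD.  ``baseline`` is the common mean
    of every gene (log-expression-like scale); it cancels in the z-scored
    analyses but anchors the reference ratios of the alteration score.
    """
    n_per_subtype = dict(DEFAULT_N_PER_SUBTYPE if n_per_subtype is None else n_per_subtype)
    correlations = dict(
        DEFAULT_CORRELATIONS if correlations_by_subtype is None else correlations_by_subtype
    )
    if set(n_per_subtype) != set(SUBTYPES) or set(correlations) != set(SUBTYPES):
        raise ParameterError("n_per_subtype / correlations must cover all four subtypes")
    if any(n < 3 for n in n_per_subtype.values()):
        raise ParameterError("every subtype needs at least 3 samples")
    if n_genes < 4 * n_specific_per_subtype + n_core + block_size:
        raise ParameterError("n_genes too small for the planted structure")
    for subtype, r in correlations.items():
        if abs(r) >= 1:
            raise ParameterError(f"infeasible correlation {r} for {subtype}")

    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    samples: list[str] = []
    labels: dict[str, str] = {}
    for subtype in SUBTYPES:
        for k in range(n_per_subtype[subtype]):
            sid = f"s{len(samples):04d}"
            samples.append(sid)
            labels[sid] = subtype
    n_samples = len(samples)

    values = rng.normal(baseline, noise_sd, size=(n_genes, n_samples))

    # planted layout: [specific LA|LB|HER2+|TN][core][block][background]
    cursor = 0
    specific: dict[str, set[str]] = {}
    for subtype in SUBTYPES:
        rows = range(cursor, cursor + n_specific_per_subtype)
        specific[subtype] = {genes[i] for i in rows}
        cols = [j for j, s in enumerate(samples) if labels[s] == subtype]
        values[np.ix_(list(rows), cols)] += effect_size * noise_sd
        cursor += n_specific_per_subtype

    def _equicorr_chol(k: int, r: float) -> np.ndarray:
        cov = np.full((k, k), r)
        np.fill_diagonal(cov, 1.0)
        try:
            return np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise ParameterError(
                f"correlation {r} infeasible for a block of {k} genes"
            ) from exc

    core_rows = list(range(cursor, cursor + n_core))
    core_genes = {genes[i] for i in core_rows}
    core_direction = {genes[i]: (1 if (i - cursor) % 2 == 0 else -1) for i in core_rows}
    block_assignments: dict[str, int] = {}
    block_correlation: dict[tuple[int, str], float] = {}
    # core genes: monotone mean gradient + equicorrelated residuals whose
    # strength degrades along the malignancy order (block 1)
    dirs = np.array([core_direction[genes[i]] for i in core_rows])[:, None]
    for subtype in SUBTYPES:
        r = correlations[subtype]
        block_correlation[(1, subtype)] = r
        cols = [j for j, s in enumerate(samples) if labels[s] == subtype]
        chol = _equicorr_chol(n_core, r)
        resid = chol @ rng.standard_normal(size=(n_core, len(cols)))
        shift = dirs * effect_size * noise_sd * SUBTYPE_RANK[subtype]
        values[np.ix_(core_rows, cols)] = baseline + shift + noise_sd * resid
    for i in core_rows:
        block_assignments[genes[i]] = 1
    cursor += n_core

    block_rows = list(range(cursor, cursor + block_size))
    for i in block_rows:
        block_assignments[genes[i]] = 0
    for subtype in SUBTYPES:
        r = correlations[subtype]
        block_correlation[(0, subtype)] = r
        cols = [j for j, s in enumerate(samples) if labels[s] == subtype]
        chol = _equicorr_chol(block_size, r)
        z = rng.standard_normal(size=(block_size, len(cols)))
        values[np.ix_(block_rows, cols)] = baseline + noise_sd * (chol @ z)

    truth = CohortTruth(
        specific_genes=specific,
        core_genes=core_genes,
        block_assignments=block_assignments,
        block_correlation=block_correlation,
        all_genes=tuple(genes),
        core_direction=core_direction,
    )
    expr = ExpressionMatrix(genes=genes, samples=samples, values=values, labels=labels)
    return expr, truth


def generate_gene_sets(
    truth: CohortTruth,
    n_pathways: int = 20,
    set_size: int = 20,
    core_fraction_in_enriched: float = 0.8,
    seed: int = 0,
    n_core_enriched: int = 6,
    n_specific_enriched_per_subtype: int = 2,
) -> GeneSetCollection:
    """Generate pathways with planted enrichment structure.

    ``n_core_enriched`` pathways draw ``core_fraction_in_enriched`` of their
    members from the planted core genes; per subtype,
    ``n_specific_enriched_per_subtype`` pathways draw the same fraction from
    that subtype's specific genes.  Remaining pathways are null draws from
    the whole universe.  The planted truth is recorded in
    ``truth.pathway_truth``.
    """
    if not truth.all_genes:
        raise ParameterError("truth carries no gene universe")
    universe = list(truth.all_genes)
    if set_size > len(universe):
        raise ParameterError("set_size exceeds the gene universe")
    n_from_target = int(round(core_fraction_in_enriched * set_size))
    if n_core_enriched > 0 and n_from_target > len(truth.core_genes):
        raise ParameterError(
            "core_fraction_in_enriched * set_size exceeds the planted core set"
        )
    n_planted = n_core_enriched + n_specific_enriched_per_subtype * len(SUBTYPES)
    if n_planted > n_pathways:
        raise ParameterError("more planted pathways than n_pathways")

    rng = np.random.default_rng(seed)
    planted = set().union(truth.core_genes, *truth.specific_genes.values())
    background = sorted(set(universe) - planted)
    sets: dict[str, set[str]] = {}
    truth.pathway_truth = {}

    def _draw(pool: list[str], k: int) -> set[str]:
        k = min(k, len(pool))
        return set(rng.choice(pool, size=k, replace=False)) if k else set()

    def _core_direction(members: set[str]) -> dict[str, int]:
        net = sum(truth.core_direction.get(g, 0) for g in members)
        sign = int(np.sign(net))
        return {s: (0 if SUBTYPE_RANK[s] == 0 else sign) for s in SUBTYPES}

    # core pathways alternate target direction and draw from the matching
    # single-direction core pool first, so each pathway's planted gradient
    # is coherent rather than self-cancelling
    core_up = sorted(g for g in truth.core_genes if truth.core_direction.get(g) == 1)
    core_down = sorted(g for g in truth.core_genes if truth.core_direction.get(g) == -1)
    for k in range(n_core_enriched):
        name = f"CORE_PW_{k + 1:02d}"
        pool, spare = (core_up, core_down) if k % 2 == 0 else (core_down, core_up)
        members = _draw(pool, n_from_target)
        if len(members) < n_from_target:
            members |= _draw(spare, n_from_target - len(members))
        members |= _draw(background, set_size - len(members))
        sets[name] = members
        truth.pathway_truth[name] = PathwayTruth(
            enriched_for_core=True,
            enriched_for_subtype=None,
            direction_by_subtype=_core_direction(members),
        )
    for subtype in SUBTYPES:
        tag = subtype.replace("+", "P")
        for k in range(n_specific_enriched_per_subtype):
            name = f"{tag}_PW_{k + 1:02d}"
            members = _draw(sorted(truth.specific_genes[subtype]), n_from_target)
            members |= _draw(background, set_size - len(members))
            sets[name] = members
            truth.pathway_truth[name] = PathwayTruth(
                enriched_for_core=False,
                enriched_for_subtype=subtype,
                direction_by_subtype={s: (1 if s == subtype else 0) for s in SUBTYPES},
            )
    for k in range(n_pathways - n_planted):
        name = f"NULL_PW_{k + 1:02d}"
        sets[name] = _draw(universe, set_size)
        truth.pathway_truth[name] = PathwayTruth(
            enriched_for_core=False,
            enriched_for_subtype=None,
            direction_by_subtype={s: 0 for s in SUBTYPES},
        )
    return GeneSetCollection(sets=sets, universe=set(universe))
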