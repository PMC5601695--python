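import numpy as np
import pytest

from brcapath.io import ExpressionMatrix, zscore_rows
from brcapath.synthetic import generate_cohort, generate_gene_sets


@pytest.fixture
def tiny_expr() -> ExpressionMatrix:
    """3 genes x 12 samples, 3 per subtype, hand-checkable values."""
    rng = np.random.default_rng(5)
    genes = ["g1", "g2", "g3"]
    samples = [f"s{i}" for i in range(12)]
    labels = dict(zip(samples, ["LA"] * 3 + ["LB"] * 3 + ["HER2+"] * 3 + ["TN"] * 3))
    values = rng.normal(10, 1, size=(3, 12))
    return ExpressionMatrix(genes, samples, values, labels)


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort plus its gene sets, shared per session."""
    expr, truth = generate_cohort(seed=11)
    collection = generate_gene_sets(truth, seed=12)
    return expr, truth, collection


@pytest.fixture(scope="session")
def default_screen(default_cohort):
    from brcapath.screen import screen

    expr, truth, _ = default_cohort
    z, _flags = zscore_rows(expr)
    return z, screen(z)
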