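import numpy as np
import pandas as pd
import pytest

from ovuln.matrix import ExpressionMatrix
from ovuln.simulate import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small well-separated two-class cohort shared across tests."""
    return generate_cohort(
        CohortSpec(n_samples=60, n_genes=100, n_informative=10, effect_size=3.0, seed=11)
    )


@pytest.fixture(scope="session")
def trained_model(small_cohort):
    from ovuln.classifier import train_model

    genes = [g for g in small_cohort.expr.gene_ids if g.startswith("DEG")]
    return train_model(
        small_cohort.expr, small_cohort.labels, genes, n_folds=5, seed=11, n_estimators=100
    )


@pytest.fixture()
def random_log_expr():
    rng = np.random.default_rng(7)
    genes = [f"G{i:03d}" for i in range(30)] + ["GZMB", "PRF1", "C1QA"]
    data = pd.DataFrame(
        rng.uniform(0.1, 8.0, (len(genes), 12)),
        index=genes,
        columns=[f"S{i:02d}" for i in range(12)],
    )
    return ExpressionMatrix(data, "log2tpm1")
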