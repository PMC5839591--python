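import numpy as np
import pytest

from randbias.cohort import SyntheticCohortSpec, generate_cohort
from randbias.containers import ExpressionMatrix, SurvivalTable


@pytest.fixture
def tiny_expr() -> ExpressionMatrix:
    values = np.array(
        [
            [1.0, 2.0, 3.0, 4.0],
            [3.0, 2.0, 1.0, 0.0],
            [0.5, 0.5, 0.5, 0.5],
        ]
    )
    return ExpressionMatrix(
        values, ["gA", "gB", "gC"], ["s1", "s2", "s3", "s4"], log_transformed=True
    )


@pytest.fixture
def tiny_surv() -> SurvivalTable:
    return SurvivalTable(
        ["s1", "s2", "s3", "s4"], [1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1]
    )


@pytest.fixture(scope="session")
def null_cohort():
    """Expression independent of survival; mid-sized for module tests."""
    return generate_cohort(
        SyntheticCohortSpec(n_samples=150, n_genes=400, structure="null", seed=42)
    )


@pytest.fixture(scope="session")
def signature_cohort():
    """Latent meta-gene loading 30% of genes and driving the hazard."""
    return generate_cohort(
        SyntheticCohortSpec(
            n_samples=250,
            n_genes=800,
            structure="global_signature",
            signature_fraction=0.3,
            log_hazard_ratio=1.0,
            seed=7,
        )
    )


@pytest.fixture(scope="session")
def subclass_cohort():
    """Two survival-distinct subclasses with diffuse differential expression."""
    return generate_cohort(
        SyntheticCohortSpec(
            n_samples=240,
            n_genes=800,
            structure="subclasses",
            n_subclasses=2,
            mixing=(0.5, 0.5),
            de_fraction=0.3,
            de_effect=2.0,
            per_class_log_hazard=(0.0, 1.0),
            seed=13,
        )
    )
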