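import numpy as np
import pandas as pd
import pytest

from lncssn.containers import ExpressionMatrix, LNCRNA, MRNA, REFERENCE, TUMOR
from lncssn.preprocess import filter_low_expression, normalize_counts
from lncssn.synthetic import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but realistic cohort: 2 planted drivers, 30 lncRNAs, 100 mRNAs."""
    config = SimulationConfig(
        n_ref_samples=30,
        n_tumor_samples=40,
        n_lnc=30,
        n_mrna=100,
        n_perturbed_lnc=2,
        hazard_coefficients=(0.7, 0.7),
        seed=7,
    )
    return simulate_cohort(config)


@pytest.fixture(scope="session")
def small_normalized(small_cohort):
    expr, _, _ = small_cohort
    return normalize_counts(filter_low_expression(expr))


def toy_expression(values: np.ndarray, n_lnc: int, groups=None) -> ExpressionMatrix:
    """Build an ExpressionMatrix from an array; first ``n_lnc`` genes are lncRNAs."""
    n_genes, n_samples = values.shape
    gene_ids = [f"L{i}" for i in range(n_lnc)] + [
        f"M{i}" for i in range(n_genes - n_lnc)
    ]
    gene_info = pd.DataFrame(
        {
            "symbol": [f"sym_{g}" for g in gene_ids],
            "biotype": [LNCRNA] * n_lnc + [MRNA] * (n_genes - n_lnc),
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    sample_ids = [f"S{j}" for j in range(n_samples)]
    if groups is None:
        groups = [REFERENCE] * n_samples
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=gene_info.index, columns=sample_ids),
        gene_info=gene_info,
        sample_group=pd.Series(list(groups), index=pd.Index(sample_ids)),
    )
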