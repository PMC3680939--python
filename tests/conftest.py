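from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from coexland import (
    Cohort,
    ExpressionDataset,
    SyntheticCohortConfig,
    generate_cohort,
    loo_min_correlation,
)


def make_dataset(values, gene_ids=None, sample_ids=None, dataset_id="D1", annotations=None):
    values = np.asarray(values, dtype=float)
    genes = gene_ids or [f"g{i + 1}" for i in range(values.shape[0])]
    samples = sample_ids or [f"s{j + 1}" for j in range(values.shape[1])]
    return ExpressionDataset(
        dataset_id, pd.DataFrame(values, index=genes, columns=samples), annotations
    )


@pytest.fixture(scope="session")
def bench_cohort():
    """The default benchmark scenario: 4x150 samples, 500 genes, 8 modules."""
    return generate_cohort(SyntheticCohortConfig(seed=11))


@pytest.fixture(scope="session")
def bench_corr(bench_cohort):
    cohort, _ = bench_cohort
    return loo_min_correlation(cohort)


@pytest.fixture()
def two_dataset_cohort():
    """Tiny two-study cohort with one strongly correlated pair (g1, g2)."""
    rng = np.random.default_rng(5)
    datasets = []
    for d in range(2):
        base = rng.standard_normal(60)
        x = np.vstack(
            [
                base + 0.1 * rng.standard_normal(60),
                base + 0.1 * rng.standard_normal(60),
                rng.standard_normal(60),
                rng.standard_normal(60),
            ]
        )
        datasets.append(make_dataset(x, dataset_id=f"D{d + 1}"))
    return Cohort(datasets)
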