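import numpy as np
import pandas as pd
import pytest

from centfinder.containers import ExpressionMatrix, SampleRecord


@pytest.fixture
def two_batch_shift():
    """Same underlying data with +2 added to batch 2; 50 samples/batch,
    noise sd 1. A symmetric design where exact per-gene location
    adjustment is the closed-form oracle."""
    rng = np.random.default_rng(42)
    n_genes, n = 200, 100
    base = rng.normal(8, 1, size=(n_genes, n))
    shift = np.zeros(n)
    shift[50:] = 2.0
    x = base + shift[None, :]
    samples = [
        SampleRecord(sample_id=f"s{j}", platform_id="B1" if j < 50 else "B2")
        for j in range(n)
    ]
    em = ExpressionMatrix(
        pd.DataFrame(x, index=[f"g{i}" for i in range(n_genes)],
                     columns=[f"s{j}" for j in range(n)]),
        log2_scale=True,
        samples=samples,
    )
    return em, base


@pytest.fixture(scope="session")
def planted_study():
    """Full multi-modal synthetic study (expensive; shared per session)."""
    from centfinder.synthdata import simulate_study

    return simulate_study(seed=13)


@pytest.fixture(scope="session")
def pipeline_result(planted_study):
    from centfinder.pipeline import run_pipeline

    counts, groups = planted_study.counts_by_celltype["CT1"]
    return run_pipeline(
        planted_study.expression, planted_study.ranking_db, counts, groups, "CT1"
    )
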