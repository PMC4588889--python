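import numpy as np
import pandas as pd
import pytest

from wuescreen import ExpressionTable, SampleMeta, SimConfig, TraitTable, simulate


@pytest.fixture(scope="session")
def small_sim():
    """A small two-site dataset with causal structure (30 genes, 8+8)."""
    return simulate(SimConfig(n_genes=30, n_per_site=8, n_causal=3, seed=11))


@pytest.fixture()
def tiny_expr():
    """Hand-built 4-gene x 6-sample table (3 JH + 3 QG)."""
    samples = [
        SampleMeta("JH_1", "JH", "p1"),
        SampleMeta("JH_2", "JH", "p1"),
        SampleMeta("JH_3", "JH", "p2"),
        SampleMeta("QG_1", "QG", "p1"),
        SampleMeta("QG_2", "QG", "p2"),
        SampleMeta("QG_3", "QG", "p2"),
    ]
    values = pd.DataFrame(
        [
            [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            [0.0, 0.0, 0.0, 5.0, 0.0, 0.0],
            [2.0, 2.0, 2.0, 8.0, 8.0, 8.0],
            [4.0, 5.0, 6.0, 1.0, 1.5, 0.5],
        ],
        index=["gA", "gZeroMedian", "gUp", "gDown"],
        columns=[s.sample_id for s in samples],
    )
    return ExpressionTable(values, samples)


@pytest.fixture()
def tiny_trait(tiny_expr):
    ids = tiny_expr.sample_ids()
    wue = np.array([3.0, 3.2, 3.4, 3.9, 4.1, 4.3])
    return TraitTable(pd.DataFrame({"wue": wue}, index=pd.Index(ids, name="sample_id")))
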