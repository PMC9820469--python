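import numpy as np
import pandas as pd
import pytest

from rdhist.matrix import CountMatrix, NormalizedMatrix


def brute_force_bh(p):
    """Direct step-up definition: padj_i = min over p_j >= p_i of
    m * p_j / rank(p_j), with max-rank for ties, clipped at 1."""
    p = np.asarray(p, dtype=float)
    m = p.size
    out = np.empty(m)
    for i in range(m):
        candidates = [
            m * p[j] / np.sum(p <= p[j]) for j in range(m) if p[j] >= p[i]
        ]
        out[i] = min(1.0, min(candidates))
    return out


@pytest.fixture
def toy_matrix() -> CountMatrix:
    """3 genes x 4 samples, two conditions, two batches."""
    counts = pd.DataFrame(
        {
            "s1": [10, 100, 40],
            "s2": [12, 90, 44],
            "s3": [50, 200, 10],
            "s4": [55, 210, 12],
        },
        index=["gA", "gB", "gC"],
        dtype=np.int64,
    )
    meta = pd.DataFrame(
        {
            "condition": ["normal", "normal", "tumor", "tumor"],
            "subtype": ["normal", "normal", "basal", "basal"],
            "batch": ["b1", "b1", "b2", "b2"],
        },
        index=counts.columns,
    )
    return CountMatrix(counts=counts, sample_meta=meta)


def make_norm(values: np.ndarray, gene_ids, subtype="basal", condition="tumor",
              batch=None) -> NormalizedMatrix:
    """NormalizedMatrix straight from a value array (bypasses counts)."""
    n = values.shape[1]
    samples = [f"s{i}" for i in range(n)]
    meta = pd.DataFrame(
        {
            "condition": [condition] * n,
            "subtype": [subtype] * n,
            "batch": batch if batch is not None else ["b1"] * n,
        },
        index=samples,
    )
    return NormalizedMatrix(
        values=pd.DataFrame(values, index=gene_ids, columns=samples),
        size_factors=pd.Series(1.0, index=samples),
        sample_meta=meta,
    )
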