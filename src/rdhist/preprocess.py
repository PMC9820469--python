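"""Normalization, variance stabilization and NB Wald differential expression.

Size factors follow the median-of-ratios convention: each sample is
compared gene-wise to the geometric-mean reference sample and summarized
by the median ratio, then factors are rescaled to geometric mean 1.

The variance-stabilizing transform is a shifted log2 of normalized
counts, ``log2(count / size_factor + pseudocount)``. Downstream the values
feed Pearson correlations and ECDFs, which need variance stabilization
only approximately, so the closed-form shifted log is preferred over a
fitted mean-dispersion transform.

Differential expression is a per-gene negative-binomial Wald test:
method-of-moments dispersion pooled across the two conditions, a
delta-method standard error for the log2 fold-change, a normal reference
for the Wald statistic, and Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DesignError, NormalizationError, ValidationError
from .matrix import CountMatrix, NormalizedMatrix

logger = logging.getLogger(__name__)

#: continuity constant, on the normalized-count scale, added to group means
#: before taking the fold-change ratio so zero-count groups stay finite
LFC_CONTINUITY = 0.5

_MIN_DISPERSION = 1e-8


def size_factors(matrix: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Genes with a zero count in any sample are excluded from the reference;
    if no gene is positive in all samples the matrix cannot be normalized
    and filtering low-count genes is suggested.
    """
    counts = matrix.counts.to_numpy(dtype=float)
    all_positive = (counts > 0).all(axis=1)
    if not all_positive.any():
        raise NormalizationError(
            "no gene has nonzero counts in every sample; "
            "filter low-count genes before normalizing"
        )
    ref = counts[all_positive]
    log_geomean = np.log(ref).mean(axis=1)
    ratios = np.log(ref) - log_geomean[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=matrix.counts.columns, name="size_factor")


def vst(
    matrix: CountMatrix,
    pseudocount: float = 4.0,
    min_total_count: int = 10,
    factors: pd.Series | None = None,
) -> NormalizedMatrix:
    """Shifted-log variance-stabilizing transform.

    Genes whose total raw count across samples is below ``min_total_count``
    are removed before transforming; size factors are computed on the full
    matrix unless supplied.
    """
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be positive")
    if factors is None:
        factors = size_factors(matrix)
    keep = matrix.counts.sum(axis=1) >= min_total_count
    counts = matrix.counts.loc[keep].to_numpy(dtype=float)
    values = np.log2(counts / factors.to_numpy()[None, :] + pseudocount)
    return NormalizedMatrix(
        values=pd.DataFrame(
            values, index=matrix.counts.index[keep], columns=matrix.counts.columns
        ),
        size_factors=factors,
        sample_meta=matrix.sample_meta,
        pseudocount=pseudocount,
        min_total_count=min_total_count,
    )


@dataclass
class DETable:
    """Per-gene differential-expression results (tumor vs normal)."""

    table: pd.DataFrame  # columns: log2fc, se, wald_stat, p, padj, is_deg

    def __post_init__(self):
        required = {"log2fc", "se", "wald_stat", "p", "padj"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"DE table lacks columns {sorted(missing)}")

    @property
    def degs(self) -> list[str]:
        return list(self.table.index[self.table["is_deg"]])

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t", float_format="%.10g")


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Classic construction: sort ascending, multiply p_(i) by m/i, take the
    cumulative minimum from the largest rank down, clip at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValidationError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def nb_wald_de(
    matrix: CountMatrix,
    condition_labels=None,
    tumor_label: str = "tumor",
    normal_label: str = "normal",
    factors: pd.Series | None = None,
    lfc_cut: float = 1.0,
    padj_cut: float = 0.05,
) -> DETable:
    """Negative-binomial Wald test of tumor vs normal, gene by gene.

    Works on size-factor-normalized counts. For each gene the two group
    means are compared via ``log2fc = log2((mean_t + c) / (mean_n + c))``
    with continuity constant ``c = 0.5`` normalized counts; the pooled
    method-of-moments dispersion ``alpha = max(0, (s^2 - mean)/mean^2)``
    feeds a delta-method SE from the NB variance ``mu + alpha*mu^2``.
    """
    if condition_labels is None:
        condition_labels = matrix.sample_meta["condition"]
    labels = pd.Series(np.asarray(condition_labels), index=matrix.counts.columns)
    for lvl in (tumor_label, normal_label):
        if (labels == lvl).sum() < 2:
            raise DesignError(f"need >= 2 samples with condition {lvl!r}")
    if factors is None:
        factors = size_factors(matrix)

    norm = matrix.counts.to_numpy(dtype=float) / factors.to_numpy()[None, :]
    t_cols = (labels == tumor_label).to_numpy()
    n_cols = (labels == normal_label).to_numpy()
    xt, xn = norm[:, t_cols], norm[:, n_cols]
    nt, nn = xt.shape[1], xn.shape[1]

    mt, mn = xt.mean(axis=1), xn.mean(axis=1)
    vt, vn = xt.var(axis=1, ddof=1), xn.var(axis=1, ddof=1)
    pooled_var = ((nt - 1) * vt + (nn - 1) * vn) / (nt + nn - 2)
    pooled_mean = (nt * mt + nn * mn) / (nt + nn)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled_var - pooled_mean) / pooled_mean**2
    alpha = np.where(np.isfinite(alpha), alpha, 0.0)
    alpha = np.maximum(alpha, _MIN_DISPERSION)

    c = LFC_CONTINUITY
    log2fc = np.log2((mt + c) / (mn + c))
    ln2sq = np.log(2.0) ** 2
    var_mt = (mt + alpha * mt**2) / nt
    var_mn = (mn + alpha * mn**2) / nn
    se = np.sqrt((var_mt / (mt + c) ** 2 + var_mn / (mn + c) ** 2) / ln2sq)
    se = np.maximum(se, 1e-12)
    wald = log2fc / se
    p = 2.0 * stats.norm.sf(np.abs(wald))
    p = np.clip(p, 0.0, 1.0)
    padj = bh_adjust(p)

    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "se": se,
            "wald_stat": wald,
            "p": p,
            "padj": padj,
        },
        index=matrix.counts.index,
    )
    result = DETable(table=table)
    return select_degs(result, lfc_cut=lfc_cut, padj_cut=padj_cut)


def select_degs(table: DETable, lfc_cut: float = 1.0, padj_cut: float = 0.05) -> DETable:
    """Flag differentially expressed genes: |log2fc| > cut and padj < cut."""
    df = table.table
    df["is_deg"] = (df["log2fc"].abs() > lfc_cut) & (df["padj"] < padj_cut)
    return table


def batch_confounded(sample_meta: pd.DataFrame) -> bool:
    """True when batch is completely determined by condition.

    In that design (e.g. a two-source tumor/normal merge) a batch effect
    is indistinguishable from the biological contrast, so count-based DE
    should only run with an explicit opt-in.
    """
    ct = pd.crosstab(sample_meta["condition"], sample_meta["batch"])
    per_condition_batches = (ct > 0).sum(axis=1)
    return bool(
        (per_condition_batches == 1).all() and sample_meta["batch"].nunique() > 1
    )


def center_batches(values: pd.DataFrame, batch_labels) -> pd.DataFrame:
    """Subtract the per-batch mean from each gene (row) of a value matrix.

    Used before correlation when batch varies within the selected samples;
    removes additive batch offsets without touching count-based statistics.
    """
    batches = pd.Series(np.asarray(batch_labels), index=values.columns)
    out = values.copy()
    for batch in batches.unique():
        cols = batches.index[batches == batch]
        out[cols] = out[cols].sub(out[cols].mean(axis=1), axis=0)
    return out
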