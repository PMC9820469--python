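"""Driver-vs-gene-set correlation enrichment with a random-set empirical null.

The question this module answers: does a gene set (e.g. the
replication-dependent histones) correlate with a driver gene (e.g. HMGA1)
more strongly than random gene-sets of the same size do? The procedure:

1. correlate the driver with every set gene across the selected samples
   (per tumor subtype, or all tumors), on variance-stabilized values;
2. draw many random gene-sets of matched size, excluding the set under
   test and the driver, and pool their gene-level correlations into an
   empirical null;
3. compare the two samples of correlation coefficients via their ECDFs
   with a two-sample Kolmogorov-Smirnov test.

Samples labelled ``normal-like`` or ``unclassified`` are always excluded
from correlation analyses.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import catalog as _catalog
from .errors import InsufficientSamplesError, ValidationError
from .matrix import NormalizedMatrix
from .preprocess import bh_adjust, center_batches

logger = logging.getLogger(__name__)

#: subtype labels that are always dropped before correlating
EXCLUDED_SUBTYPES = ("normal-like", "unclassified")

DEFAULT_N_SETS = 1000


# ---------------------------------------------------------------------------
# result types
# ---------------------------------------------------------------------------

@dataclass
class Ecdf:
    """Empirical CDF with the right-continuous step convention.

    ``support`` holds the sorted unique observations; ``probs[i]`` is
    F(support[i]) = (# observations <= support[i]) / n. Ties collapse onto
    one support point; the final probability is exactly 1.
    """

    support: np.ndarray
    probs: np.ndarray
    n: int

    def __call__(self, x) -> np.ndarray:
        idx = np.searchsorted(self.support, np.asarray(x, dtype=float), side="right")
        padded = np.concatenate([[0.0], self.probs])
        return padded[idx]


@dataclass
class KSResult:
    """Two-sample Kolmogorov-Smirnov statistic and asymptotic p-value."""

    D: float
    p: float
    n1: int
    n2: int


@dataclass
class EnrichmentResult:
    """Everything computed for one subtype (or the pooled 'all' analysis)."""

    subtype: str
    set_correlations: pd.DataFrame  # columns: gene_id, r, p, padj, n_samples
    null_correlations: np.ndarray
    ecdf_set: Ecdf
    ecdf_null: Ecdf
    ks: KSResult
    summary: dict = field(default_factory=dict)

    def records_frame(self) -> pd.DataFrame:
        out = self.set_correlations.copy()
        if "subtype" not in out.columns:
            out.insert(0, "subtype", self.subtype)
        return out[["subtype"] + [c for c in out.columns if c != "subtype"]]

    def summary_dict(self) -> dict:
        return {
            "subtype": self.subtype,
            "ks_D": self.ks.D,
            "ks_p": self.ks.p,
            "n_set": self.ks.n1,
            "n_null": self.ks.n2,
            **self.summary,
        }


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def ecdf(values) -> Ecdf:
    """Empirical CDF of a non-empty sample: F(x) = (# values <= x) / n."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValidationError("cannot build an ECDF from an empty sample")
    support, counts = np.unique(arr, return_counts=True)
    probs = np.cumsum(counts) / arr.size
    probs[-1] = 1.0
    return Ecdf(support=support, probs=probs, n=int(arr.size))


def _ks_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """sup |F_x - F_y| over the pooled support (right-continuous steps)."""
    pooled = np.concatenate([x, y])
    pooled.sort(kind="mergesort")
    fx = np.searchsorted(np.sort(x), pooled, side="right") / x.size
    fy = np.searchsorted(np.sort(y), pooled, side="right") / y.size
    return float(np.abs(fx - fy).max())


def _ks_asymptotic_p(d: float, n1: int, n2: int) -> float:
    """Kolmogorov asymptotic tail with the small-sample correction factor.

    Q(lambda) = 2 * sum_{k>=1} (-1)^(k-1) exp(-2 k^2 lambda^2) with
    lambda = (sqrt(n_e) + 0.12 + 0.11/sqrt(n_e)) * D, n_e = n1*n2/(n1+n2).
    The series is truncated once a term drops below 1e-10; if it has not
    converged by then lambda is so small that Q is 1.
    """
    if d <= 0:
        return 1.0
    ne = n1 * n2 / (n1 + n2)
    lam = (math.sqrt(ne) + 0.12 + 0.11 / math.sqrt(ne)) * d
    total = 0.0
    for k in range(1, 101):
        term = 2.0 * (-1.0) ** (k - 1) * math.exp(-2.0 * k * k * lam * lam)
        total += term
        if abs(term) < 1e-10:
            return float(min(max(total, 0.0), 1.0))
    return 1.0


#: use the exact null distribution when n1*n2 is at most this large
_KS_EXACT_LIMIT = 10_000


def _ks_exact_p(d: float, n1: int, n2: int) -> float:
    """Exact P(D >= d) under the permutation null (no ties assumed).

    Counts monotone lattice paths from (0,0) to (n1,n2) on which
    |i/n1 - j/n2| stays strictly below d at every visited point; the
    complement of their fraction among all binom(n1+n2, n1) paths is the
    exact tail probability. Integer arithmetic throughout, so the result
    is exact to float rounding.
    """
    if d <= 0:
        return 1.0
    # |i*n2 - j*n1| >= c  <=>  |i/n1 - j/n2| >= d  (all quantities integer)
    c = int(round(d * n1 * n2))
    if abs(c - d * n1 * n2) > 1e-6:
        c = math.ceil(d * n1 * n2 - 1e-9)
    prev = [0] * (n2 + 1)
    prev[0] = 1
    for j in range(1, n2 + 1):
        prev[j] = prev[j - 1] if abs(j * n1) < c else 0
    for i in range(1, n1 + 1):
        cur = [0] * (n2 + 1)
        cur[0] = prev[0] if abs(i * n2) < c else 0
        for j in range(1, n2 + 1):
            if abs(i * n2 - j * n1) < c:
                cur[j] = cur[j - 1] + prev[j]
        prev = cur
    total = math.comb(n1 + n2, n1)
    return float(min(max(1.0 - prev[n2] / total, 0.0), 1.0))


def ks_two_sample(x, y, method: str = "auto") -> KSResult:
    """Two-sided two-sample KS test.

    ``method`` selects the p-value computation: ``"asymp"`` is the
    Kolmogorov series with Stephens' small-sample correction factor,
    ``"exact"`` the exact permutation-null tail (valid without ties), and
    ``"auto"`` (default) uses the exact tail for small tie-free samples
    (n1*n2 <= 10_000) and the asymptotic series otherwise — at the sizes
    the enrichment pipeline produces (a gene set vs thousands of pooled
    null correlations) the asymptotic form is the one exercised.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("each sample needs at least 2 observations")
    d = _ks_statistic(x, y)
    n1, n2 = int(x.size), int(y.size)
    if method not in ("auto", "exact", "asymp"):
        raise ValidationError(f"unknown method {method!r}")
    use_exact = method == "exact"
    if method == "auto" and n1 * n2 <= _KS_EXACT_LIMIT:
        pooled = np.concatenate([x, y])
        use_exact = np.unique(pooled).size == pooled.size
    p = _ks_exact_p(d, n1, n2) if use_exact else _ks_asymptotic_p(d, n1, n2)
    return KSResult(D=d, p=p, n1=n1, n2=n2)


def ks_permutation_p(x, y, n_shuffles: int = 2000, seed: int = 0) -> float:
    """Permutation p-value for the KS statistic (label reshuffling)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d_obs = _ks_statistic(x, y)
    pooled = np.concatenate([x, y])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_shuffles):
        perm = rng.permutation(pooled)
        if _ks_statistic(perm[: x.size], perm[x.size:]) >= d_obs - 1e-15:
            hits += 1
    return (hits + 1) / (n_shuffles + 1)


# ---------------------------------------------------------------------------
# sample selection and vectorized driver correlation
# ---------------------------------------------------------------------------

def select_samples(
    sample_meta: pd.DataFrame,
    subtype: str = "all",
    tumor_only: bool = True,
) -> pd.Index:
    """Samples entering a correlation analysis for one subtype.

    ``"all"`` keeps every subtype (tumors only unless ``tumor_only`` is
    off); a named subtype keeps its tumor samples. ``normal-like`` and
    ``unclassified`` samples are always dropped.
    """
    meta = sample_meta[~sample_meta["subtype"].isin(EXCLUDED_SUBTYPES)]
    if subtype != "all":
        meta = meta[meta["subtype"] == subtype]
    if tumor_only:
        meta = meta[meta["condition"] == "tumor"]
    return meta.index


def _prepare_values(
    norm: NormalizedMatrix,
    sample_ids: pd.Index,
    center_batch: bool = True,
    spearman: bool = False,
) -> np.ndarray:
    values = norm.values[list(sample_ids)]
    batches = norm.sample_meta.loc[sample_ids, "batch"]
    if center_batch and batches.nunique() > 1:
        values = center_batches(values, batches)
    arr = values.to_numpy(dtype=float)
    if spearman:
        arr = stats.rankdata(arr, axis=1)
    return arr


def _pearson_vs_driver(arr: np.ndarray, driver_row: int, gene_rows: np.ndarray):
    """Pearson r of one row against many, plus two-sided t-transform p."""
    n = arr.shape[1]
    centered = arr - arr.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    d = centered[driver_row]
    dn = norms[driver_row]
    with np.errstate(divide="ignore", invalid="ignore"):
        r = centered[gene_rows] @ d / (norms[gene_rows] * dn)
    degenerate = ~np.isfinite(r)
    if degenerate.any():
        logger.warning("%d zero-variance genes: r recorded as 0, p as 1",
                       int(degenerate.sum()))
    r = np.where(degenerate, 0.0, np.clip(r, -1.0, 1.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = np.where(
        np.isfinite(t), 2.0 * stats.t.sf(np.abs(np.where(np.isfinite(t), t, 0.0)),
                                         df=n - 2), 0.0
    )
    p = np.where(degenerate, 1.0, np.clip(p, 0.0, 1.0))
    return r, p


def correlate_driver(
    norm: NormalizedMatrix,
    driver: str,
    genes,
    subtype: str = "all",
    tumor_only: bool = True,
    center_batch: bool = True,
    spearman: bool = False,
) -> pd.DataFrame:
    """Correlate the driver with each listed gene across selected samples.

    Returns one record per gene: ``gene_id, subtype, r, p, padj,
    n_samples``, with p from the t transform ``r * sqrt((n-2)/(1-r^2))``
    and BH adjustment across the gene list.
    """
    genes = list(genes)
    if not genes:
        raise ValidationError("gene list must not be empty")
    index = pd.Index(norm.gene_ids)
    missing = [g for g in [driver, *genes] if g not in index]
    if missing:
        raise ValidationError(f"genes absent from the matrix: {missing[:5]}")
    sample_ids = select_samples(norm.sample_meta, subtype, tumor_only=tumor_only)
    if len(sample_ids) < 3:
        raise InsufficientSamplesError(
            f"subtype {subtype!r}: only {len(sample_ids)} samples after filtering"
        )
    arr = _prepare_values(norm, sample_ids, center_batch=center_batch,
                          spearman=spearman)
    driver_row = index.get_loc(driver)
    gene_rows = index.get_indexer(genes)
    r, p = _pearson_vs_driver(arr, driver_row, gene_rows)
    return pd.DataFrame(
        {
            "gene_id": genes,
            "subtype": subtype,
            "r": r,
            "p": p,
            "padj": bh_adjust(p),
            "n_samples": len(sample_ids),
        }
    )


def build_null(
    norm: NormalizedMatrix,
    driver: str,
    random_sets: list[list[str]],
    subtype: str = "all",
    tumor_only: bool = True,
    center_batch: bool = True,
    spearman: bool = False,
    per_set_summary: bool = False,
) -> np.ndarray:
    """Pool driver correlations over every gene of every random set.

    Order is deterministic: set order, then gene order within each set.
    With ``per_set_summary`` the null is the per-set median correlation
    instead of the pooled gene-level values.
    """
    if not random_sets:
        raise ValidationError("need at least one random set")
    index = pd.Index(norm.gene_ids)
    sample_ids = select_samples(norm.sample_meta, subtype, tumor_only=tumor_only)
    if len(sample_ids) < 3:
        raise InsufficientSamplesError(
            f"subtype {subtype!r}: only {len(sample_ids)} samples after filtering"
        )
    arr = _prepare_values(norm, sample_ids, center_batch=center_batch,
                          spearman=spearman)
    unique_genes = sorted({g for s in random_sets for g in s})
    rows = index.get_indexer(unique_genes)
    if (rows < 0).any():
        bad = [g for g, row in zip(unique_genes, rows) if row < 0]
        raise ValidationError(f"random-set genes absent from matrix: {bad[:5]}")
    r, _ = _pearson_vs_driver(arr, index.get_loc(driver), rows)
    r_by_gene = dict(zip(unique_genes, r))
    per_set = [np.array([r_by_gene[g] for g in s]) for s in random_sets]
    if per_set_summary:
        return np.array([np.median(s) for s in per_set])
    return np.concatenate(per_set)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_enrichment(
    norm: NormalizedMatrix,
    driver: str,
    gene_set,
    subtypes=None,
    n_sets: int = DEFAULT_N_SETS,
    seed: int = 0,
    tumor_only_all: bool = True,
    center_batch: bool = True,
    spearman: bool = False,
    per_set_summary: bool = False,
) -> list[EnrichmentResult]:
    """Full enrichment for 'all' samples plus each requested subtype.

    ``gene_set`` may be a :class:`GeneSetCatalog` or an iterable of
    symbols; it is mapped onto the matrix first and random control sets of
    matched size are drawn per subtype (subtype-offset seeds) from the
    matrix genes minus the mapped set and the driver. A subtype failing
    its preconditions is skipped with a warning rather than aborting the
    whole run.
    """
    if n_sets < 1:
        raise ValidationError("n_sets must be >= 1")
    if n_sets < 50:
        logger.warning("n_sets=%d gives an underpowered empirical null", n_sets)
    mapped = _catalog.map_set(gene_set, norm, set_name="set")
    set_ids = [g for g in mapped.mapped_ids if g != driver]
    if len(set_ids) < 2:
        raise ValidationError("gene set must map to >= 2 genes besides the driver")
    if mapped.unmapped_symbols:
        logger.info("%d set symbols not present in matrix",
                    len(mapped.unmapped_symbols))

    subtypes = list(subtypes) if subtypes is not None else []
    analyses = ["all", *subtypes]
    results: list[EnrichmentResult] = []
    seed_seq = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                   seed_seq.spawn(len(analyses))]

    for analysis, sub_seed in zip(analyses, child_seeds):
        tumor_only = tumor_only_all if analysis == "all" else True
        try:
            records = correlate_driver(
                norm, driver, set_ids, subtype=analysis, tumor_only=tumor_only,
                center_batch=center_batch, spearman=spearman,
            )
            random_sets = _catalog.sample_random_sets(
                norm, exclude=set(mapped.mapped_ids), set_size=len(set_ids),
                n_sets=n_sets, seed=sub_seed, driver=driver,
            )
            null = build_null(
                norm, driver, random_sets, subtype=analysis,
                tumor_only=tumor_only, center_batch=center_batch,
                spearman=spearman, per_set_summary=per_set_summary,
            )
        except InsufficientSamplesError as exc:
            logger.warning("skipping subtype %r: %s", analysis, exc)
            continue
        set_r = records["r"].to_numpy()
        ks = ks_two_sample(set_r, null)
        results.append(
            EnrichmentResult(
                subtype=analysis,
                set_correlations=records,
                null_correlations=null,
                ecdf_set=ecdf(set_r),
                ecdf_null=ecdf(null),
                ks=ks,
                summary={
                    "set_median_r": float(np.median(set_r)),
                    "set_mean_r": float(np.mean(set_r)),
                    "null_median_r": float(np.median(null)),
                    "null_mean_r": float(np.mean(null)),
                },
            )
        )
    return results


def write_results(results: list[EnrichmentResult], outdir) -> tuple[Path, Path]:
    """Write per-gene records as TSV and per-subtype summaries as JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = pd.concat([r.records_frame() for r in results], ignore_index=True)
    records_path = outdir / "enrichment_correlations.tsv"
    records.to_csv(records_path, sep="\t", index=False, float_format="%.10g")
    summary_path = outdir / "enrichment_summary.json"
    summary = [r.summary_dict() for r in results]
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return records_path, summary_path


def plot_ecdfs(result: EnrichmentResult, path) -> Path:
    """Step plot of the set vs null correlation ECDFs for one subtype."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for e, label, color in (
        (result.ecdf_set, "gene set", "#c0392b"),
        (result.ecdf_null, "random sets", "#7f8c8d"),
    ):
        ax.step(e.support, e.probs, where="post", label=label, color=color)
    ax.set_xlabel("Pearson r with driver")
    ax.set_ylabel("ECDF")
    ax.set_title(
        f"{result.subtype}: D={result.ks.D:.3f}, p={result.ks.p:.2e}"
    )
    ax.legend()
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
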