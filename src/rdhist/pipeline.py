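"""High-level pipeline stages shared by the CLI and library users.

Each stage reads/writes plain TSV/JSON so runs are auditable and
byte-reproducible for a fixed seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

from . import __version__
from .catalog import GeneSetCatalog, load_rd_hist_catalog
from .enrichment import run_enrichment, write_results, plot_ecdfs
from .errors import DesignError, ValidationError
from .matrix import CountMatrix, read_matrix, write_matrix
from .preprocess import batch_confounded, nb_wald_de, vst
from .synthetic import SynthConfig, SynthTruth, generate_dataset

logger = logging.getLogger(__name__)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def log_run_header(config: dict, seed: int | None = None) -> None:
    import numpy, pandas, scipy

    logger.info("rdhist %s (numpy %s, scipy %s, pandas %s)", __version__,
                numpy.__version__, scipy.__version__, pandas.__version__)
    if seed is not None:
        logger.info("seed: %d", seed)
    logger.info("config: %s",
                json.dumps(_jsonable(config), default=str, sort_keys=True))


def run_simulate(config: SynthConfig, outdir) -> dict[str, Path]:
    """Simulate a dataset and write counts, metadata and the truth record."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix, truth = generate_dataset(config)
    counts_path, meta_path = write_matrix(matrix, outdir / "counts.tsv")
    truth_path = truth.to_json(outdir / "truth.json")
    logger.info("simulated %d genes x %d samples (driver %s, module of %d)",
                matrix.n_genes, matrix.n_samples, truth.driver_id,
                len(truth.module_ids))
    return {"counts": counts_path, "meta": meta_path, "truth": truth_path}


def run_de(
    matrix: CountMatrix,
    outdir,
    lfc_cut: float = 1.0,
    padj_cut: float = 0.05,
    allow_confounded: bool = False,
) -> Path:
    """Tumor-vs-normal DE with the batch-confounding guard.

    When batch is completely determined by condition a batch effect cannot
    be separated from the biological contrast; the run is refused unless
    the caller opts in explicitly.
    """
    if batch_confounded(matrix.sample_meta):
        if not allow_confounded:
            raise DesignError(
                "batch is confounded with condition; rerun with "
                "allow_confounded to accept fold-changes that absorb any "
                "batch effect"
            )
        logger.warning(
            "batch confounded with condition: fold-changes include any "
            "batch effect (allow_confounded set)"
        )
    table = nb_wald_de(matrix, lfc_cut=lfc_cut, padj_cut=padj_cut)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    de_path = outdir / "de_results.tsv"
    table.to_tsv(de_path)
    logger.info("DE: %d / %d genes flagged (|log2FC| > %g, padj < %g)",
                len(table.degs), len(table.table), lfc_cut, padj_cut)
    return de_path


def run_enrich(
    matrix: CountMatrix,
    driver: str,
    gene_set,
    outdir,
    subtypes=None,
    n_sets: int = 1000,
    pseudocount: float = 4.0,
    seed: int = 0,
    spearman: bool = False,
    per_set_summary: bool = False,
    plot: bool = False,
) -> dict[str, Path]:
    """VST-normalize and run the correlation-enrichment analysis."""
    if driver not in matrix.gene_ids:
        raise ValidationError(f"driver gene {driver!r} absent from the matrix")
    norm = vst(matrix, pseudocount=pseudocount)
    if subtypes is None:
        meta = matrix.sample_meta
        tumor = meta[meta["condition"] == "tumor"]
        subtypes = sorted(
            s for s in tumor["subtype"].unique()
            if s not in ("normal-like", "unclassified")
        )
    results = run_enrichment(
        norm, driver, gene_set, subtypes=subtypes, n_sets=n_sets, seed=seed,
        spearman=spearman, per_set_summary=per_set_summary,
    )
    records_path, summary_path = write_results(results, outdir)
    paths = {"records": records_path, "summary": summary_path}
    if plot:
        for res in results:
            paths[f"plot_{res.subtype}"] = plot_ecdfs(
                res, Path(outdir) / f"ecdf_{res.subtype}.png"
            )
    for res in results:
        logger.info("subtype %-8s KS D=%.3f p=%.3g (set median r=%.3f, "
                    "null median r=%.3f)", res.subtype, res.ks.D, res.ks.p,
                    res.summary["set_median_r"], res.summary["null_median_r"])
    return paths


def run_demo(
    outdir,
    seed: int = 0,
    config: SynthConfig | None = None,
    n_sets: int = 1000,
    plot: bool = False,
) -> dict[str, Path]:
    """End-to-end demonstration on simulated data.

    Simulates the default dataset (driver + correlated module, tumor
    fold-change, condition-linked batches), runs DE (opting into the
    confounded design, as the simulated two-source merge requires), then
    runs the enrichment with the injected module as the gene set.
    """
    outdir = Path(outdir)
    config = config if config is not None else SynthConfig(seed=seed)
    log_run_header(asdict(config), seed=seed)
    paths = run_simulate(config, outdir)
    matrix = read_matrix(paths["counts"], paths["meta"])
    truth = SynthTruth.from_json(paths["truth"])
    paths["de"] = run_de(matrix, outdir, allow_confounded=True)
    enrich_paths = run_enrich(
        matrix,
        driver=truth.driver_id,
        gene_set=[truth.driver_id, *truth.module_ids],
        outdir=outdir,
        n_sets=n_sets,
        seed=seed,
        plot=plot,
    )
    paths.update(enrich_paths)
    return paths


def resolve_gene_set(catalog_path=None) -> GeneSetCatalog | list[str]:
    """User catalog TSV (gene_symbol column) or the packaged RD-HIST list."""
    if catalog_path is None:
        return load_rd_hist_catalog()
    import pandas as pd

    df = pd.read_csv(catalog_path, sep="\t", comment="#", dtype=str)
    if "gene_symbol" not in df.columns:
        raise ValidationError("catalog file needs a 'gene_symbol' column")
    return list(df["gene_symbol"])
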