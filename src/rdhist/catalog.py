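"""Gene-set catalog: the packaged RD-HIST list, set mapping, random control sets.

The replication-dependent histone (RD-HIST) genes are the S-phase
co-regulated core and linker histone genes, organized in three genomic
clusters (HIST1 on chromosome 6, HIST2 and HIST3 on chromosome 1) plus a
few non-clustered members. The packaged catalog carries 72 genes with
family (H1/H2A/H2B/H3/H4) and cluster annotations and is integrity-checked
on load against the canonical per-cluster family counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .errors import IntegrityError, SamplingError, ValidationError
from .matrix import CountMatrix

logger = logging.getLogger(__name__)

FAMILIES = ("H1", "H2A", "H2B", "H3", "H4")
CLUSTERS = ("HIST1", "HIST2", "HIST3", "other")

# Canonical composition of the three clusters: family -> count.
_EXPECTED_CLUSTER_COUNTS = {
    "HIST1": {"H1": 6, "H2A": 12, "H2B": 15, "H3": 10, "H4": 12},
    "HIST2": {"H2A": 3, "H2B": 1, "H3": 1, "H4": 1},
    "HIST3": {"H2A": 1, "H2B": 1, "H3": 1},
}
_EXPECTED_TOTAL = 72


@dataclass
class GeneSetCatalog:
    """An annotated gene list: one row per gene with family and cluster."""

    entries: pd.DataFrame  # columns: gene_symbol, family, cluster

    def __post_init__(self):
        required = {"gene_symbol", "family", "cluster"}
        if not required.issubset(self.entries.columns):
            raise ValidationError(f"catalog needs columns {sorted(required)}")
        if self.entries["gene_symbol"].duplicated().any():
            dup = self.entries.loc[
                self.entries["gene_symbol"].duplicated(), "gene_symbol"
            ].iloc[0]
            raise ValidationError(f"duplicated gene symbol in catalog: {dup!r}")

    @property
    def symbols(self) -> list[str]:
        return list(self.entries["gene_symbol"])

    def __len__(self) -> int:
        return len(self.entries)

    def count(self, cluster: str | None = None, family: str | None = None) -> int:
        sel = pd.Series(True, index=self.entries.index)
        if cluster is not None:
            sel &= self.entries["cluster"] == cluster
        if family is not None:
            sel &= self.entries["family"] == family
        return int(sel.sum())


@dataclass
class MappedSet:
    """Result of mapping catalog symbols onto a matrix's gene ids."""

    set_name: str
    mapped_ids: list[str]
    unmapped_symbols: list[str]

    @property
    def n_mapped(self) -> int:
        return len(self.mapped_ids)


def load_rd_hist_catalog() -> GeneSetCatalog:
    """Load the packaged 72-gene RD-HIST catalog and verify its composition.

    Raises :class:`IntegrityError` listing every failed count check if the
    fixture was corrupted or replaced with a non-conforming file.
    """
    with resources.files("rdhist.data").joinpath("rd_hist_catalog.tsv").open() as fh:
        entries = pd.read_csv(fh, sep="\t", comment="#", dtype=str)
    catalog = GeneSetCatalog(entries=entries)

    failures = []
    if len(catalog) != _EXPECTED_TOTAL:
        failures.append(f"total entries {len(catalog)} != {_EXPECTED_TOTAL}")
    for cluster, fam_counts in _EXPECTED_CLUSTER_COUNTS.items():
        for family, expected in fam_counts.items():
            got = catalog.count(cluster=cluster, family=family)
            if got != expected:
                failures.append(f"{cluster}/{family}: {got} != {expected}")
        cluster_total = catalog.count(cluster=cluster)
        expected_total = sum(fam_counts.values())
        if cluster_total != expected_total:
            failures.append(f"{cluster} total: {cluster_total} != {expected_total}")
    bad_family = set(entries["family"]) - set(FAMILIES)
    if bad_family:
        failures.append(f"unknown families: {sorted(bad_family)}")
    bad_cluster = set(entries["cluster"]) - set(CLUSTERS)
    if bad_cluster:
        failures.append(f"unknown clusters: {sorted(bad_cluster)}")
    if failures:
        raise IntegrityError("catalog fixture failed checks: " + "; ".join(failures))
    return catalog


def map_set(catalog_or_symbols, matrix: CountMatrix, set_name: str = "set") -> MappedSet:
    """Partition symbols into those present/absent among the matrix genes.

    Matching is exact and case-sensitive; alias resolution (e.g. HIST1H4H
    vs H4C8) is deliberately left to the caller, and unmapped symbols are
    reported rather than silently dropped.
    """
    if isinstance(catalog_or_symbols, GeneSetCatalog):
        symbols = catalog_or_symbols.symbols
    else:
        symbols = list(catalog_or_symbols)
    if not symbols:
        raise ValidationError("cannot map an empty symbol list")
    present = set(matrix.gene_ids)
    mapped = [s for s in symbols if s in present]
    unmapped = [s for s in symbols if s not in present]
    if not mapped:
        logger.warning("no symbols of set %r mapped to the matrix", set_name)
    return MappedSet(set_name=set_name, mapped_ids=mapped, unmapped_symbols=unmapped)


def sample_random_sets(
    matrix: CountMatrix,
    exclude,
    set_size: int,
    n_sets: int,
    seed: int,
    driver: str | None = None,
) -> list[list[str]]:
    """Draw ``n_sets`` random control gene-sets of exactly ``set_size`` genes.

    Genes are drawn uniformly without replacement (within each set) from
    the matrix genes minus ``exclude`` and minus the driver; distinct sets
    may overlap. Deterministic for a fixed seed.
    """
    if set_size < 1 or n_sets < 1:
        raise ValidationError("set_size and n_sets must be positive")
    excluded = set(exclude)
    if driver is not None:
        excluded.add(driver)
    universe = np.array([g for g in matrix.gene_ids if g not in excluded])
    if len(universe) < set_size:
        raise SamplingError(
            f"only {len(universe)} eligible genes but set_size={set_size}"
        )
    rng = np.random.default_rng(seed)
    return [
        list(rng.choice(universe, size=set_size, replace=False))
        for _ in range(n_sets)
    ]
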