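"""Count-matrix container and tab-delimited I/O.

A :class:`CountMatrix` holds an integer gene x sample matrix plus a
per-sample metadata table with three required columns: ``condition``
(tumor/normal), ``subtype`` (free-form label) and ``batch``. On disk the
matrix is a TSV whose first column is the gene id and whose remaining
columns are samples; the metadata travels in a companion TSV with columns
``sample_id``, ``condition``, ``subtype``, ``batch``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

META_COLUMNS = ("condition", "subtype", "batch")


@dataclass
class CountMatrix:
    """Integer expression counts with per-sample metadata.

    counts : DataFrame, genes in rows (index = gene ids), samples in columns.
    sample_meta : DataFrame indexed by sample id with columns
        ``condition``, ``subtype``, ``batch``.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self):
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValidationError(f"duplicated gene id: {dup!r}")
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise ValidationError(f"duplicated sample id: {dup!r}")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            raise ValidationError("counts must be integers")
        if (values < 0).any():
            raise ValidationError("counts must be non-negative")
        missing = [c for c in META_COLUMNS if c not in self.sample_meta.columns]
        if missing:
            raise ValidationError(f"sample metadata lacks columns: {missing}")
        if list(self.sample_meta.index) != list(self.counts.columns):
            raise ValidationError(
                "sample metadata rows must match matrix columns (same ids, same order)"
            )
        if self.sample_meta[list(META_COLUMNS)].isna().any().any():
            raise ValidationError("sample metadata contains missing values")

    # -- convenience ------------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def equals(self, other: "CountMatrix") -> bool:
        return self.counts.equals(other.counts) and self.sample_meta[
            list(META_COLUMNS)
        ].equals(other.sample_meta[list(META_COLUMNS)])


@dataclass
class NormalizedMatrix:
    """Variance-stabilized expression values on the log2 scale.

    Carries the size factors used for normalization and the sample
    metadata of the source :class:`CountMatrix` (genes may have been
    filtered, so the gene index can be a subset of the source's).
    """

    values: pd.DataFrame
    size_factors: pd.Series
    sample_meta: pd.DataFrame
    pseudocount: float = 4.0
    min_total_count: int = 10

    def __post_init__(self):
        if (self.size_factors <= 0).any():
            raise ValidationError("size factors must be positive")
        if list(self.values.columns) != list(self.size_factors.index):
            raise ValidationError("size factor index must match sample columns")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def _meta_path_for(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.tsv") if path.suffix != ".tsv" else (
        path.with_name(path.stem + ".meta.tsv")
    )


def write_matrix(matrix: CountMatrix, path, meta_path=None) -> tuple[Path, Path]:
    """Write counts and metadata as two UTF-8 TSV files.

    Returns the (counts_path, meta_path) actually written. The default
    metadata path replaces ``.tsv`` with ``.meta.tsv``.
    """
    path = Path(path)
    meta_path = Path(meta_path) if meta_path is not None else _meta_path_for(path)
    counts = matrix.counts.copy()
    counts.index.name = "gene_id"
    counts.to_csv(path, sep="\t", encoding="utf-8")
    meta = matrix.sample_meta[list(META_COLUMNS)].copy()
    meta.index.name = "sample_id"
    meta.to_csv(meta_path, sep="\t", encoding="utf-8")
    return path, meta_path


def read_matrix(path, meta_path=None) -> CountMatrix:
    """Read a counts TSV plus its companion metadata TSV.

    Raises :class:`ParseError` with a 1-based line number for non-integer
    or negative counts, duplicated ids and missing metadata columns.
    """
    path = Path(path)
    meta_path = Path(meta_path) if meta_path is not None else _meta_path_for(path)
    try:
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"cannot read counts file {path}: {exc}") from exc
    if raw.index.duplicated().any():
        pos = int(np.flatnonzero(raw.index.duplicated())[0])
        raise ParseError(f"duplicated gene id {raw.index[pos]!r}", line=pos + 2)
    columns = {}
    for col in raw.columns:
        numeric = pd.to_numeric(raw[col], errors="coerce")
        bad = numeric.isna() | (numeric != numeric.round()) | (numeric < 0)
        if bad.any():
            pos = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"non-integer or negative count {raw[col].iloc[pos]!r} "
                f"in sample {col!r}",
                line=pos + 2,
            )
        columns[col] = numeric.astype(np.int64)
    counts = pd.DataFrame(columns, index=raw.index)

    try:
        meta = pd.read_csv(meta_path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover
        raise ParseError(f"cannot read metadata file {meta_path}: {exc}") from exc
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ParseError(f"metadata lacks columns {missing}", line=1)
    try:
        meta = meta.loc[counts.columns]
    except KeyError as exc:
        raise ParseError(f"metadata is missing samples: {exc}") from exc
    return CountMatrix(counts=counts, sample_meta=meta)
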