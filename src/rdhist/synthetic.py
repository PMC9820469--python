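"""Negative-binomial count simulator with a driver-correlated gene module.

The generator emulates the statistical structure of a tumor/normal bulk
RNA-seq compendium in which one driver gene co-varies with a module of
genes (a latent-factor Gaussian copula with tunable correlation ``rho``),
the module is differentially expressed in tumors, and samples from the
two conditions may come from different batches.

Mechanism, per sample:

* a latent factor ``z ~ N(0, 1)``;
* driver log-mean     ``b_d + s * z``;
* module gene log-mean ``b_g + s * (rho * z + sqrt(1 - rho^2) * e_g)``;
* other gene log-mean  ``b_g + s * e_g`` (independent of ``z``);
* tumor samples add ``log2fc_module * ln 2`` to driver+module log-means;
* one batch adds ``batch_shift`` to all log-means;
* a per-sample library-size factor multiplies every mean;
* counts ~ NB(mean = mu, Var = mu + dispersion * mu^2).

``rho`` is the latent correlation; the correlation realized on the count
scale is attenuated by NB sampling noise, so downstream tests compare
realized correlations against calibration, not ``rho`` itself.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .matrix import CountMatrix

_LN2 = math.log(2.0)


@dataclass
class SynthConfig:
    """Parameters of one simulated dataset.

    ``n_samples_per_group`` maps a ``(condition, subtype)`` pair to a
    group size; conditions must be ``"tumor"`` or ``"normal"``. Effect
    sizes (``rho``, ``log2fc_module``) are stand-ins chosen to produce a
    clearly detectable module at the default sizes; no field is calibrated
    to a published dataset.
    """

    n_genes: int = 2000
    n_samples_per_group: dict[tuple[str, str], int] = field(
        default_factory=lambda: {
            ("tumor", "basal"): 200,
            ("tumor", "lumA"): 200,
            ("tumor", "lumB"): 200,
            ("tumor", "HER2"): 200,
            ("normal", "normal"): 200,
        }
    )
    module_size: int = 58
    rho: float = 0.5
    log2fc_module: float = 2.0
    dispersion: float = 0.1
    batch_shift: float = 0.3
    baseline_log_mean_range: tuple[float, float] = (math.log(50.0), math.log(2000.0))
    latent_sd: float = 0.5
    library_sd: float = 0.15
    batch_by_condition: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be a positive integer")
        if self.module_size < 1:
            raise ConfigurationError("module_size must be a positive integer")
        if self.module_size + 1 > self.n_genes:
            raise ConfigurationError("module_size + 1 must not exceed n_genes")
        if not 0.0 <= self.rho <= 1.0:
            raise ConfigurationError("rho must lie in [0, 1]")
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be positive")
        if self.latent_sd < 0:
            raise ConfigurationError("latent_sd must be non-negative")
        if self.library_sd < 0:
            raise ConfigurationError("library_sd must be non-negative")
        lo, hi = self.baseline_log_mean_range
        if not lo < hi:
            raise ConfigurationError("baseline_log_mean_range must be (low, high)")
        if not self.n_samples_per_group:
            raise ConfigurationError("n_samples_per_group must not be empty")
        for key, n in self.n_samples_per_group.items():
            cond = key[0]
            if cond not in ("tumor", "normal"):
                raise ConfigurationError(
                    f"n_samples_per_group condition must be tumor/normal, got {cond!r}"
                )
            if n < 2:
                raise ConfigurationError(
                    f"n_samples_per_group[{key!r}] must be >= 2, got {n}"
                )


@dataclass
class SynthTruth:
    """Ground truth of a simulated dataset (for verification, not inference)."""

    driver_id: str
    module_ids: list[str]
    rho: float
    log2fc_module: float
    batch_shift: float
    seed: int

    def to_json(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")
        return path

    @classmethod
    def from_json(cls, path) -> "SynthTruth":
        return cls(**json.loads(Path(path).read_text()))


def _sample_table(config: SynthConfig) -> pd.DataFrame:
    """Build the sample metadata in group insertion order."""
    rows = []
    for (condition, subtype), n in config.n_samples_per_group.items():
        for _ in range(n):
            rows.append((condition, subtype))
    ids = [f"S{i + 1:05d}" for i in range(len(rows))]
    meta = pd.DataFrame(rows, columns=["condition", "subtype"], index=ids)
    if config.batch_by_condition:
        # Mirrors a two-source merge: all tumors from one study,
        # all normals from another.
        meta["batch"] = np.where(meta["condition"] == "tumor", "batch1", "batch2")
    else:
        meta["batch"] = [
            "batch1" if i % 2 == 0 else "batch2" for i in range(len(meta))
        ]
    return meta


def generate_dataset(config: SynthConfig) -> tuple[CountMatrix, SynthTruth]:
    """Simulate one count matrix; deterministic for a fixed seed.

    Draw order (fixed so outputs are reproducible): baseline log-means,
    library factors, latent factor z, per-gene noise, NB counts.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    gene_ids = [f"G{i + 1:06d}" for i in range(config.n_genes)]
    driver_idx = 0
    module_idx = np.arange(1, config.module_size + 1)
    meta = _sample_table(config)
    n_samples = len(meta)

    lo, hi = config.baseline_log_mean_range
    baseline = rng.uniform(lo, hi, size=config.n_genes)
    lib = np.exp(rng.normal(0.0, config.library_sd, size=n_samples))
    z = rng.standard_normal(n_samples)
    eps = rng.standard_normal((config.n_genes, n_samples))

    s = config.latent_sd
    rho = config.rho
    latent = s * eps
    latent[driver_idx, :] = s * z
    latent[module_idx, :] = s * (
        rho * z[None, :] + math.sqrt(1.0 - rho**2) * eps[module_idx, :]
    )

    log_mean = baseline[:, None] + latent
    tumor_cols = (meta["condition"] == "tumor").to_numpy()
    affected = np.zeros(config.n_genes, dtype=bool)
    affected[driver_idx] = True
    affected[module_idx] = True
    log_mean[np.ix_(affected, tumor_cols)] += config.log2fc_module * _LN2
    shifted_cols = (meta["batch"] == "batch2").to_numpy()
    log_mean[:, shifted_cols] += config.batch_shift

    mu = np.exp(log_mean) * lib[None, :]
    alpha = config.dispersion
    # NB(n, p) with n = 1/alpha, p = 1/(1 + alpha*mu) has the target
    # mean mu and variance mu + alpha*mu^2.
    counts = rng.negative_binomial(1.0 / alpha, 1.0 / (1.0 + alpha * mu))

    matrix = CountMatrix(
        counts=pd.DataFrame(counts.astype(np.int64), index=gene_ids,
                            columns=list(meta.index)),
        sample_meta=meta,
    )
    truth = SynthTruth(
        driver_id=gene_ids[driver_idx],
        module_ids=[gene_ids[i] for i in module_idx],
        rho=config.rho,
        log2fc_module=config.log2fc_module,
        batch_shift=config.batch_shift,
        seed=config.seed,
    )
    return matrix, truth
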