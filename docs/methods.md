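# Methods

## The statistical question

The pipeline asks two linked questions about a gene set S (canonically
the replication-dependent histone genes) and a driver gene d (canonically
HMGA1) in a tumor/normal RNA-seq compendium with intrinsic-subtype
labels:

1. are the genes of S differentially expressed between tumor and normal
   tissue, and
2. is the profile of correlations {r(d, g) : g ∈ S} across tumor samples
   shifted relative to what equally sized sets of random genes produce?

The second question is deliberately framed as a two-sample comparison of
correlation coefficients rather than a parametric test on any single r:
the set-level signal of a co-regulated module is a *distributional* shift
of many modest correlations, and the random-set null absorbs whatever
generic inter-gene correlation the dataset carries (depth, batch,
proliferation signatures) without modelling it.

## Enrichment procedure

For each analysis stratum (each tumor subtype, plus all tumors pooled;
samples labelled `normal-like` or `unclassified` are always excluded, and
strata with fewer than 3 samples are skipped with a warning):

- Pearson r between driver and every mapped set gene on
  variance-stabilized values; two-sided p from t = r√((n−2)/(1−r²)) on
  n−2 degrees of freedom; BH adjustment within the gene list. Spearman
  (rank-transformed Pearson) is available as an option for heavy-tailed
  data. A zero-variance gene yields r = 0, p = 1 and a warning rather
  than an error.
- `n_sets` (default 1000) random gene-sets of exactly matched size, drawn
  uniformly without replacement within each set from the matrix genes
  minus the set under test and minus the driver. The driver exclusion
  avoids a degenerate r = 1 member; the set exclusion keeps the null
  clean of the alternative. Sets are drawn per stratum with child seeds
  spawned from the master seed, so the whole analysis is reproducible.
- The null is the pooled list of gene-level correlations over all random
  sets (the distribution plotted against the set's own correlations). A
  per-set-median summary null is available behind a flag; it answers a
  different, stricter question (is the set's *typical* correlation
  extreme among sets) and is not the default.
- The two samples are compared by their ECDFs with a two-sided two-sample
  Kolmogorov–Smirnov test.

### KS p-values

D is the supremum of |F₁ − F₂| over the pooled support with
right-continuous ECDFs. The p-value uses the asymptotic Kolmogorov tail
Q(λ) = 2·Σ (−1)^(k−1) e^(−2k²λ²) at
λ = (√n_e + 0.12 + 0.11/√n_e)·D, n_e = n₁n₂/(n₁+n₂), truncating the
series when a term falls below 1e-10. At the sizes the pipeline produces
(a set of ~58 r's against a pooled null of tens of thousands) this
approximation is accurate. For small tie-free samples (n₁·n₂ ≤ 10⁴) the
implementation switches to the exact permutation-null tail computed by
the classic lattice-path recursion in integer arithmetic, because at
e.g. n₁ = n₂ = 50 the discrete null makes the continuous approximation
off by up to ~0.03 in the middle of the p range — the same small-sample
practice as R's `ks.test` and scipy. Tied data fall back to the
asymptotic form.

## Differential expression

The DE stage is a deliberately minimal negative-binomial Wald test, fully
specified and testable:

- size factors by median-of-ratios (genes with any zero excluded from the
  geometric-mean reference; factors rescaled to geometric mean 1);
- per-gene pooled method-of-moments dispersion
  α̂ = max((s² − m̄)/m̄², 10⁻⁸) from within-group variances of normalized
  counts — no shrinkage across genes, which is adequate at the sample
  sizes simulated here (n ≥ 50 per group) though noisy for very small
  designs;
- log₂FC = log₂((m_t + c)/(m_n + c)) with continuity constant c = 0.5
  normalized counts, keeping zero-count groups finite;
- delta-method SE from Var(m̂) = (m + αm²)/n per group, normal reference
  for the Wald statistic, BH adjustment, and DEG rule |log₂FC| > 1 and
  padj < 0.05 (both thresholds configurable).

No independent filtering or outlier handling is attempted. Because
median-of-ratios normalization equalizes the median gene ratio, a
condition in which a large fraction of genes shifts one way is partially
absorbed into the size factors; with the set sizes this pipeline targets
(tens of genes among thousands) the effect on fold-change estimates is
negligible, and the validation simulations use a DE fraction of ≤ 3%.

### Batch handling

No factor-analysis batch correction is attempted. Instead: when batch is
completely determined by condition — the design produced by merging a
tumor-only study with a normal-only study — count-based DE is refused
unless the caller passes `allow_confounded`, because a batch effect is
then formally indistinguishable from the biological contrast. For
correlation analyses, which are computed within strata, per-gene
batch-mean-centering is applied whenever more than one batch is present
among the selected samples; an additive batch offset cancels exactly and
correlations are unaffected by it.

## The simulator

Counts are negative binomial, NB(μ, α) with Var = μ + αμ², over a
log-scale mean built from independent pieces (per sample j, gene g):

log μ_gj = b_g + s·u_gj + [tumor] ln2·log₂FC·1{g ∈ module}
           + [batch] shift + ln(ℓ_j)

where b_g ~ U(ln 50, ln 2000) spans realistic expression depth,
ℓ_j ~ logNormal(0, 0.15) is a library-size factor, and u_gj is the
copula: u = z_j for the driver, u = ρ·z_j + √(1−ρ²)·ε_gj for module
genes, u = ε_gj otherwise, with z, ε independent standard normal. ρ is
therefore the *latent* correlation; the realized count-scale correlation
is attenuated by NB noise (at the defaults, ρ = 0.5 realizes r ≈ 0.35,
i.e. "moderate"), so tests compare realized correlations against
calibration rather than against ρ itself.

Defaults: 2000 genes, a 58-gene module (the size of a typical mapped
histone set), four tumor subtypes of 200 samples plus 200 normals,
α = 0.1, latent SD s = 0.5 (a ~50% coefficient of biological variation),
log₂FC = 2, batch tied to condition (batch shift 0.3) to mirror a
two-source merge. None of the effect sizes is calibrated to a published
dataset; they are documented stand-ins chosen to be clearly detectable
at these sample sizes. All draws come from a single seeded generator in a
fixed order (baselines, library factors, latent factor, gene noise,
counts), making outputs bit-reproducible.

What the simulator does *not* emulate: transcriptome-wide correlation
structure beyond one module (real data have many co-expression blocks),
gene-length and GC effects, count outliers, and any nonlinear
driver–module relationship. Passing tests therefore certify the
machinery (calibration, power, determinism, selection rules) under the
stated generative model, not performance on real tumor compendia.

## Validation performed by the test suite

- KS statistic identical to a brute-force pooled-support oracle; exact
  small-sample p identical to an independent implementation; returned p
  within 0.03 of a 2000-shuffle permutation p at n₁ = n₂ = 50.
- Null calibration: with ρ = 0 the enrichment KS test at α = 0.05
  rejects in 2–9% of 200 replicate datasets (200 samples, 200 random
  sets each); independently piloted at 5.5% over 600 replicates.
- Power: rejection frequency non-decreasing in ρ over {0, 0.25, 0.5} and
  ≥ 0.9 at ρ = 0.5 with 200 samples.
- NB Wald test: type-I fraction within [0.03, 0.08] at nominal 0.05 over
  2000 null genes (n = 50/group); mean estimated log₂FC within ±0.2 of
  an injected 2.0 (n = 100/group, 100 module genes among 4000).
- BH step-up equal to the direct definition on all hypothesis-generated
  vectors of length ≤ 12, including ties.
- End-to-end byte-reproducibility of the demo for a fixed seed.

## Numerical and design notes

- VST pseudocount 4 (configurable): large enough to damp the variance of
  low-count genes on the log scale, small enough not to flatten the
  mid-range. Genes with total count < 10 are dropped before VST.
- Pearson r is clipped to [−1, 1] against rounding; |r| = 1 maps to
  p = 0 through the t transform.
- BH uses a stable mergesort so tied p-values adjust identically.
- The `all` stratum is tumor-only by default (the tumor/normal contrast
  already lives in the DE stage); pooling normals in is available via
  `tumor_only_all=False`.
- Random sets are drawn per stratum (subtype-offset child seeds) rather
  than shared across strata; sharing would correlate the strata's null
  noise without changing any single stratum's validity.

## Known limitations

- The catalog ships in classic HIST* nomenclature; current HGNC symbols
  (H4C8 etc.) must be mapped by the user — matching is exact and
  case-sensitive by design, and unmapped symbols are reported.
- Method-of-moments dispersion without shrinkage is not recommended for
  designs below ~20 samples per group.
- The confounded tumor/normal merge fundamentally limits causal
  interpretation of DE fold-changes even with `allow_confounded`; the
  enrichment statistic, computed within tumor strata, does not inherit
  that confounding.
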