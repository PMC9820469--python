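# rdhist

Correlation enrichment of a gene set against a driver gene in bulk
RNA-seq, with a random-gene-set empirical null — built around the question
of whether the replication-dependent histone (RD-HIST) genes, the
S-phase-coupled core and linker histone genes organized in the HIST1,
HIST2 and HIST3 genomic clusters, are coordinately overexpressed in
tumors and co-expressed with an oncogenic driver such as HMGA1 in breast
cancer. The package is aimed at computational biologists who want that
analysis as a tested, reusable pipeline that can also be validated end to
end on simulated data with known ground truth.

## What it computes

Given an integer gene × sample count matrix with per-sample metadata
(condition tumor/normal, intrinsic subtype, batch):

1. **Normalization and VST.** Median-of-ratios size factors
   *s<sub>j</sub>* (each sample's median count ratio to the
   geometric-mean reference, rescaled to geometric mean 1), then a
   variance-stabilizing shifted log,
   *v<sub>gj</sub>* = log₂(*c<sub>gj</sub>*/*s<sub>j</sub>* + 4).
2. **Differential expression.** A per-gene negative-binomial Wald test of
   tumor vs normal: method-of-moments dispersion α̂ pooled across groups
   (Var = μ + αμ²), delta-method SE for the log₂ fold-change,
   Benjamini–Hochberg FDR, and the selection rule |log₂FC| > 1 with
   adjusted p < 0.05. Designs in which batch is confounded with condition
   are refused unless explicitly allowed.
3. **Correlation enrichment.** Pearson *r* between the driver and every
   set gene on VST values, per subtype and for all tumors pooled
   (samples labelled `normal-like` or `unclassified` are excluded);
   1000 random gene-sets of matched size (excluding the set under test
   and the driver) supply the pooled empirical null; the two samples of
   correlation coefficients are compared through their ECDFs with a
   two-sided two-sample Kolmogorov–Smirnov test
   (D = sup|F₁ − F₂|; asymptotic p with Stephens' small-sample
   correction, or the exact permutation-null tail for small samples).
4. **ΔΔCt.** The comparative-Ct RT-qPCR utility:
   ΔΔCt = ΔCt<sub>treated</sub> − ΔCt<sub>control</sub>,
   fold = 2<sup>−ΔΔCt</sup>.

A negative-binomial simulator with a latent-factor copula (one shared
factor with tunable correlation ρ between the driver and a gene module,
an injected tumor fold-change, per-condition batches and library-size
variation) provides ground-truth data for every stage; the packaged
72-gene RD-HIST catalog (families H1/H2A/H2B/H3/H4, clusters
HIST1/HIST2/HIST3/other) ships as an auditable TSV.

## Worked example

```sh
rdhist demo --outdir demo_out --seed 7
```

simulates 2000 genes × 1000 samples (four tumor subtypes of 200 samples
plus 200 normals; a 58-gene module correlated with the driver at latent
ρ = 0.5 and overexpressed in tumors at log₂FC = 2), then runs DE and
enrichment. It prints:

```
DE: 59 / 2000 genes flagged (|log2FC| > 1, padj < 0.05)
subtype all      KS D=1.000 p=1.51e-52 (set median r=0.346, null median r=-0.009)
subtype HER2     KS D=1.000 p=1.51e-52 (set median r=0.374, null median r=-0.010)
subtype basal    KS D=0.983 p=9.15e-51 (set median r=0.350, null median r=-0.008)
subtype lumA     KS D=0.991 p=1.39e-51 (set median r=0.304, null median r=-0.006)
subtype lumB     KS D=0.998 p=2.51e-52 (set median r=0.322, null median r=-0.011)
```

The 59 flagged genes are exactly the injected module plus the driver; the
set's median correlation (~0.35 — "moderate", as the latent ρ = 0.5 is
attenuated by counting noise) separates completely from the random-set
null centered at 0, hence D ≈ 1 and vanishing KS p in every subtype.
Outputs land in `demo_out/`: `counts.tsv` + `counts.meta.tsv` +
`truth.json` (the simulated dataset and its ground truth),
`de_results.tsv`, `enrichment_correlations.tsv`,
`enrichment_summary.json`, and `run.log`. The same stages are available
separately as `rdhist simulate`, `rdhist de`, `rdhist enrich` (with
`--catalog` defaulting to the packaged RD-HIST list) and `rdhist ddct`,
or as library functions (`rdhist.generate_dataset`, `rdhist.nb_wald_de`,
`rdhist.run_enrichment`, ...).

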