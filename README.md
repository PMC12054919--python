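# lactovar

Variance partitioning and class-informed genomic prediction for milk
production traits, built around mammary multi-omics functional classes.

Dairy genetics works with millions of imputed sequence variants but only a
small fraction of them tag causal variation for traits like milk yield or
protein percentage.  `lactovar` implements the quantitative machinery for
asking *which* functionally annotated variant classes — tissue-specific
genes, differentially expressed genes, miRNA targets, RNA-editing regions,
regulatory elements, e/sQTLs — carry disproportionate genetic variance, and
for converting that knowledge into better genomic predictions.  It is aimed
at quantitative geneticists working with deregressed PTA phenotypes and
sequence-level genotype panels.

## What it computes

**Variance partitioning (GREML).**  With a VanRaden genomic relationship
matrix per variant class, the model

    y = 1μ + Σ_f g_f + ε,   g_f ~ N(0, G_f σ²_f)

is fit by AI-REML (EM fallback, bounded quasi-Newton polish).  Per-class
proportions h²_f = σ²_f/σ²_P are summarized as per-variant enrichment odds
ratios

    enrichment = (h²_f / h²_all) / (n_f / n),

and a circular genome-shift permutation — all sites advanced by one random
offset on the concatenated autosomes, preserving every inter-site distance —
provides the positional null for site-defined classes.

**Functional-class statistics.**  Tissue-specificity t-statistics from a
+1/−1 indicator OLS on standardized log2 expression (top 10% = specific
genes); miRNA prioritization by one-sided Fisher enrichment of negatively
correlated predicted targets combined with the variance captured by the
target regions (candidate ⇔ Fisher p < 0.05 and h²_t > 0.1); hyper-editing
A→G site detection with 100-bp cluster calling, the combined editing level
(mapped G + unmapped G)/(mapped depth + unmapped G), and lactation-stage
comparison.

**Genomic prediction.**  GBLUP and two-component MultiBLUP through the
mixed-model equations; BayesR and BayesRC by single-site Gibbs sampling of
a four-component effect mixture N(0, γ_k σ²_β), γ = (0, 0.01, 0.1, 1), where
BayesRC learns separate mixing proportions inside and outside a functional
annotation.  Accuracy is reported as validation reliability: the squared
correlation between genomic values and validation deregressed PTAs, in
percent.

**Synthetic cohorts.**  `lactovar.syndata` generates every input with known
ground truth — genotypes, class maps, mixture effects at a target h²,
expression panels with planted specific genes, miRNA systems with planted
regulators, and reads with planted editing — so the whole pipeline is
testable without external data.

## Worked example

```python
import numpy as np
from lactovar import syndata, grm, varcomp
from lactovar.syndata import SimConfig, ClassSpec

cfg = SimConfig(
    n_individuals=2000, n_variants=5000, seed=77, h2_target=0.6,
    class_specs=[ClassSpec("hot", 0.2, (0.0, 0.0, 0.0, 1.0)),
                 ClassSpec("other", 0.0, (1.0, 0.0, 0.0, 0.0))],
)
geno = syndata.sim_genotypes(cfg)
classes = syndata.sim_class_map(geno, cfg)
truth, pheno = syndata.sim_effects_and_phenotypes(geno, classes, cfg)

fit = varcomp.partition_two(pheno, geno, classes, "hot")
print(f"h2_hot  = {fit.proportions['hot']:.3f}")
print(f"h2_all  = {fit.h2_all:.3f}")
enr = varcomp.enrichment(fit, classes.counts(), n_total=geno.n_variants)
print(f"enrichment(hot) = {enr[0].enrichment:.2f}")
```

Every causal variant here sits in the "hot" class (20% of the panel), and
the two-GRM fit recovers that:

```
h2_hot  = 0.579
h2_all  = 0.604
enrichment(hot) = 4.79
```

i.e. the class captures essentially all genetic variance (h²_hot ≈ the 0.6
simulated heritability, h²_other ≈ 0), and its per-variant enrichment sits
near the theoretical maximum for a class holding 1/5 of the variants,
(h²_hot/h²_all)/(0.2) ≈ 5.

A thin CLI mirrors the library (`lactovar simulate`, `grm`, `prune`,
`reml`, `permute`, `tspec`, `mirna`, `edit`, `predict`); run any subcommand
with `--help`.

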