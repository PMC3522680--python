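# mtglasso

Joint marker selection for genome-wide association studies with **multiple
correlated quantitative traits**, via the group Lasso on stacked data, with
EBIC tuning and multi-split adjusted p-values.

## The problem

GWAS cohorts often measure several related traits on the same genotyped
subjects — e.g. the CD4/CD8 ratio and CD4:CD3 in heterogeneous stock mice,
two highly correlated immunological indices expected to share susceptible
SNPs.  One-SNP-at-a-time scans miss SNPs with weak marginal but strong
joint effects, and running a separate Lasso per trait ignores the
correlation between traits.  `mtglasso` analyses the traits jointly: with
`n` subjects, `q` traits and `p` SNPs (additive 0/1/2 coding) the data are
stacked into a single regression with `N = n·q` observations in which SNP
`j` contributes one **group** of `q` coefficients `β_j = (β_j1, …, β_jq)`.
The estimate minimises the group-Lasso criterion

```
(1/(2n)) ‖y − Σ_j X_j β_j‖²  +  λ Σ_j √q · ‖β_j‖₂
```

so a SNP is selected for all traits at once while its per-trait effects may
differ.  Covariate blocks are orthonormalized via Cholesky factors, the
criterion is minimised by **group cyclical coordinate descent** (closed-form
multivariate soft-threshold updates, warm-started along a 100-point λ
path), λ is chosen by the **extended BIC** with the group-Lasso
degrees-of-freedom approximation, and significance of the selected SNPs is
assessed by **multi-sample splitting** (select on one half, F-test on the
other, Bonferroni-adjust by the selected-set size, aggregate B splits by
adaptive quantiles).  See `docs/methods.md` for the full model description.

Intended users: statistical geneticists and methodologists who need a
transparent, testable reference implementation of grouped multi-trait
penalized selection — not a replacement for large-scale GWAS toolchains.

## Worked example

```python
from mtglasso import (SimulationDesign, simulate_dataset,
                      MultiTraitGroupLasso, score_selection)

design = SimulationDesign(n=500, p=1000, q=2, rho=0.5, seed=7)
ds = simulate_dataset(design)                 # 12 causal SNPs, 24 causal pairs
res = MultiTraitGroupLasso(ds.data, None).fit()
print(res.summary(max_rows=14))
print(score_selection(res.params, ds.true_beta))
```

prints

```
Joint multi-trait group Lasso
================================================================
subjects: 500    SNPs: 1000    traits: 2    stacked N: 1000
whitening: identity    EBIC gamma: 1
selected lambda: 0.0531267    df: 18.49    EBIC: -1260.08
selected SNPs (groups): 12
----------------------------------------------------------------
SNP                   trait1      trait2
snp25                 0.3605      0.3861
snp26                 0.4398      0.4266
...
snp60                 0.4499      0.4418
================================================================
SelectionMetrics(true_positive=24, model_size=24, fdr=0.0, fnr=0.0,
                 sse=0.1993920562817942)
```

The EBIC-selected model recovers exactly the twelve simulated causal SNPs
(24 of 24 causal SNP-trait pairs, no false positives); the coefficients are
the penalized estimates per standardized genotype, shrunk from the true
value 0.5.  Multi-split p-values for the selected SNPs follow from
`res.multisplit(B=20, seed=7).pvalues` (here ~0 for all twelve).

The same pipeline is available from the shell:

```bash
mtglasso simulate --n 500 --p 1000 --seed 7 --out-dir sim/
mtglasso fit --genotypes sim/genotypes.csv --phenotypes sim/phenotypes.csv --out fit.tsv
mtglasso pvalues --genotypes sim/genotypes.csv --phenotypes sim/phenotypes.csv -B 50 --seed 7 --out pvals.tsv
mtglasso evaluate --n 500 --p 500 --replicates 20 --seed 1 --out metrics.tsv
```

PLINK `.raw` genotype tables are read with `--dialect plink_raw`; SNPs can
be screened with `--maf-threshold 0.05`, and missing genotypes are either a
hard error (joint modelling cannot include SNPs with missingness) or
mean-imputed with `--impute-mean`.

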