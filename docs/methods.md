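# Methods

## Model

`mtglasso` addresses marker selection in genome-wide association studies
where several correlated quantitative traits are measured on the same
genotyped subjects (the motivating setting is a pair of immunological
indices such as the CD4/CD8 ratio and CD4:CD3 in heterogeneous stock mice).
When traits share a genetic basis, analysing them jointly is more powerful
than running one penalized regression per trait and intersecting the
results.

With `n` subjects, `q` traits and `p` SNPs (additive 0/1/2 coding), each
trait follows a linear model on the same covariates,
`y_k = X β_k + ε_k`.  The data are *stacked* into a single regression with
`N = n·q` observations: rows are ordered subject-major / trait-minor, and
SNP `j` contributes a block of `q` covariate columns whose coefficients
`β_j = (β_j1, …, β_jq)` form a group.  The group Lasso criterion

    (1/(2c)) ‖y − Σ_j X_j β_j‖² + λ Σ_j w_j ‖β_j‖₂ ,    w_j = √q,

selects SNPs all-in/all-out across traits while letting per-trait effect
sizes differ.  Genotype columns are centered and scaled to unit variance
(so λ is comparable across SNPs); traits are centered (the grand mean of
the stacked response is zero, no intercept is fitted) and by default scaled
to unit variance.  Reported coefficients are mapped back to
standardized-genotype / original-trait units (`Results.params`), with a
raw-genotype version available (`params_raw`).

### Residual covariance

The stacked least-squares loss is in principle weighted by the inverse
residual covariance Σ of the traits.  The default is `whitening='identity'`
after per-trait variance scaling, which keeps the criterion an ordinary
least-squares group Lasso — the form the coordinate-descent algorithm and
the degrees-of-freedom approximation assume.  Two alternatives are
provided: `'plugin'` (estimate Σ from the residuals of an identity-whitened
fit, then refit once with the whitener `W = chol(Σ)⁻¹` applied to each
subject's q-vector of responses and, implicitly, to each covariate block —
this preserves the group structure), and `'user_supplied'`.  Iterating the
Σ estimate further is not supported; one refit is the documented behaviour.

### Orthonormalization and the solver

Each block is orthonormalized through the Cholesky factor `R_j` of
`(1/c)·X_j'X_j` with the scale convention `X̃_j'X̃_j = c·I`, `c = n`.  Under
identity whitening the Kronecker block structure makes `R_j` a positive
multiple of `I_q` (exactly `I_q` after standardization).  On the
orthonormalized scale the single-group subproblem has the closed form
`b_j = S(z_j, λ w_j)` where `z_j = b_j + X̃_j'r/c` and
`S(z, t) = (1 − t/‖z‖)₊ z` is the multivariate soft-threshold (the zero
vector when `z = 0`).  Group cyclical coordinate descent (GCD) iterates
these exact minimizations; the objective is non-increasing after every
update and converges to a global minimizer of the convex criterion.

Numerical choices:

* convergence when the largest coefficient change in a sweep falls below
  `tol` (default `1e-4`); sweep cap `max_iter = 10,000`;
* λ path: 100 points, log-spaced from `λ_max = max_j ‖X̃_j'y‖/(c w_j)` down
  to `0.001·λ_max`, warm-started;
* the default strategy cycles the active set until stable and then scans
  the full gradient (one GEMM) for violating groups; this is
  tolerance-identical to plain cyclic sweeps (tested) but much faster when
  most groups are inactive.  The inner sweep has a numba-compiled kernel
  with a pure-numpy fallback;
* `z_j = 0` maps to the zero block without division; constant SNPs are a
  hard error at orthonormalization (their Gram blocks are singular);
* KKT residuals are recorded along the path; solutions satisfy the
  stationarity conditions within `10·tol`.

### Tuning: degrees of freedom and EBIC

λ is chosen by minimising the extended BIC over the path,

    EBIC(λ) = N log(RSS/N) + df·log N + 2γ·df·log G,

with `G = p` groups (selection is at the group level) and the group-Lasso
DF approximation `df = Σ_{j active} [1 + (q−1)·‖b_j‖/‖b_j^LS‖]` with the
per-group ratio clipped to [0, 1]; `b_j^LS = X̃_j'y/c` is the single-group
least-squares estimate, cheap under block orthonormality.  With `q = 1`
the DF is the nonzero count and the pipeline is exactly Lasso + EBIC.
γ defaults to 1.0 — the conservative end of the family, appropriate when
`p ≫ n`; it is configurable, and ties in the criterion resolve toward the
larger λ (the sparser model).  An exactly interpolating fit (RSS = 0) is
floored at the smallest positive float so the criterion stays finite.

### Multi-split p-values

Significance for selected SNPs uses multi-sample splitting: `B` times
(default 50), the subjects are split in half; the full pipeline selects a
set `S` on one half, and on the other half each group in `S` receives the
p-value of the F-test in the regular linear regression where that group is
the only group, Bonferroni-adjusted by `|S|` and capped at 1 (groups
outside `S` get 1).  The F-test stacks the half's traits with per-trait
intercepts, so the residual degrees of freedom are `n₂·q − 2q` and the
stacked rows are treated as independent — consistent with identity-Σ
whitening; for `q = 1` it is the squared-t test of simple regression.
Across splits the adjusted p-values are aggregated by empirical quantiles
(inverse-ECDF type) over the grid γ ∈ {0.05, 0.10, …, 1.00}:

    P_j = min{1, (1 − log γ_min) · inf_γ Q_j(γ)},   γ_min = 0.05,

so the adaptive correction factor is 1 − log 0.05 ≈ 3.996.  The final
p-values are valid for family-wise error control and are monotone in the
split-level values; a fixed seed reproduces the splits bit-for-bit.

## Synthetic data

The generator reproduces the benchmark design: `n = 500` subjects,
`p = 5000` (or 10,000) SNPs, `q = 2` traits; residual trait correlation ρ ∈
{0.1, 0.5, 0.9}; twelve causal SNPs in three clusters (indices 25–28,
41–44, 57–60), shared by both traits.  Genotypes come from latent normals —
exchangeable correlation 0.2 within each causal cluster, 0.2 among all
noise SNPs, causal and noise independent — generated with one shared factor
per block so no p×p covariance is materialised, and discretised at
Φ⁻¹(0.25)/Φ⁻¹(0.75), i.e. Hardy–Weinberg genotype frequencies
(¼, ½, ¼) at allele frequency ½.  Responses are `Y = Xs·β + E` with
standardized genotypes and bivariate-normal residual rows (unit variances,
correlation ρ).  All nonzero effects default to magnitude 0.5 (the original
per-SNP effect values are not available; 0.5 gives per-SNP standardized
effects around 0.25, a realistic moderate-signal GWAS regime, so headline
operating characteristics should be read as qualitative, not point
reproductions).  With unmatched fraction `f`, the same ⌈12f⌉ shared causal
indices are dropped and each trait receives its own replacements adjacent
to the clusters, leaving exactly a fraction `f` of each trait's 12 causal
SNPs trait-specific.

What the generator does *not* emulate: realistic linkage-disequilibrium
decay from a reference panel, minor-allele-frequency spectra (every SNP has
MAF ½; the method is explicitly not intended for rare variants), population
structure or relatedness, and non-Gaussian trait distributions.  Passing
tests therefore demonstrate correctness of the algorithmics and the
claimed operating characteristics under this idealised design, not
performance on real cohorts.

## Evaluation conventions

Metrics count (SNP, trait) pairs: the fully matched design has 24 true
pairs; a SNP selected by the joint method contributes `q` pairs.  FDR uses
the 0/0 = 0 convention; SSE is `Σ (β̂ − β)²` over all `p·q` entries on the
standardized-genotype scale.  The combined-individual baseline runs the
identical path/EBIC machinery per trait (`q = 1`), pools selected pairs,
and reports the cross-trait overlap separately.  The single-SNP scan is
simple regression per (SNP, trait) with Bonferroni correction over tested
(non-constant) SNPs.  Prediction is k-fold (default 5): fit on k−1 parts,
predict all traits on the held-out part, pool squared errors.

## Problem sizes used by the checks

The package's own verification experiments run at desk scale: the recovery
and ordering experiment uses n=500, p=500, q=2, ρ=0.5, effect 0.5, 20
replicates; multi-split error control uses the global null with n=200,
p=50, B=20, 200 replicates (ρ=0.5 for the full-procedure check, ρ=0 for
the F-test calibration, matching that test's own sampling assumptions);
the five-fold prediction comparison uses n=300, p=200, 20 replicates.
Generator calibration uses n=50,000 draws.  These sizes preserve the
n/p/signal regime of the full-scale design while keeping the whole
verification run in minutes.

## Known limitations

* The identity-Σ default ignores residual correlation during estimation;
  it still selects well in the simulated regimes, and the plugin whitener
  is available, but no claim of efficiency-optimal weighting is made.
* The EBIC γ is a genuine tuning choice; smaller γ trades false positives
  for power.
* The stacked F-test is mildly anti-conservative when residual trait
  correlation is high; in the multi-split procedure the |S|-adjustment,
  quantile aggregation and the 3.996 multiplier absorb this in practice
  (verified under the global null at ρ=0.5).
* With partially matched supports the group structure forces a selected
  SNP onto every trait, inflating model size and FDR by construction.
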