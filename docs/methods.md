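# Methods

## The two-stage model

`pathlancaster` tests whether a pathway (a named set of genes) is
associated with a continuous trait in a sequencing association study.

**Stage I — gene level.** For gene *i* with dosage matrix `G_i`
(n subjects × J_i variants, values 0/1/2) the trait is modelled as
`y = Xα + G_i β_i + ε`, with the variant effects `β_ij` treated as random
with mean 0 and variance `w_ij τ_i`. The gene-level null `H0: τ_i = 0` is
tested with the variance-component score statistic

    Q_i = (y − μ̂)ᵀ G_i W_i G_iᵀ (y − μ̂),

where `μ̂` is the null least-squares fit of `y` on `X` and
`W_i = diag(w_i1, …)`. Under the null `Q_i` follows a mixture of 1-df
chi-squares whose weights are the eigenvalues of
`σ² W^{1/2} Gᵀ(I − H) G W^{1/2}` (`H` the hat matrix of `X`). This is the
locally most powerful score test for this random-effects alternative
(SKAT); common variants, principal components and other covariates enter
as columns of `X`.

**Stage II — pathway level.** The m gene-level p-values inside a pathway
are combined by the Lancaster statistic

    T = Σ_i F_i^{-1}(1 − P_i),   F_i = CDF of χ²_{w_i},  w_i > 0,

which generalizes Fisher's method (w_i ≡ 2, where the transform is
−2 ln p exactly). Gene-level p-values are correlated through linkage
disequilibrium, so T does not follow χ²_{Σw}. The corrected null matches
the first two moments of T to a scaled chi-square `c·χ²_v`
(Satterthwaite):

    E(T) = Σ w_i,   var(T) = 2Σ w_i + 2Σ_{i<j} ρ_ij,
    c = var/(2E),   v = 2E²/var,

with `ρ_ij = cov(F_i^{-1}(1−P_i), F_j^{-1}(1−P_j))` under the null.
Zero covariance recovers the exact independent χ²_{Σw} null.

**Why Lancaster.** Among weighted combined p-value statistics the
Lancaster procedure attains the optimal Bahadur slope `Σ λ_i c_i(θ)`
(λ_i = sample-size fractions, c_i = per-test slopes); the weighted Z-test
attains only `(Σ w_i √(λ_i c_i))²/Σw_i²` (≤ by Cauchy–Schwarz) and Good's
weighted product test `Σ w_i λ_i c_i / max_i w_i` (≤ termwise). The ratio
of two slopes is the limiting inverse ratio of the sample sizes the tests
need to reach an equally small significance level, which is the relevant
comparison when signals are sparse. `bahadur.empirical_slope` verifies
these limits by regressing −2 ln P_n on n through the origin over the top
half of an increasing n-grid (pre-asymptotic bias is concentrated at
small n).

**Competitive test.** The Satterthwaite-corrected Lancaster test is
self-contained (`H0`: this pathway has no effect). The competitive
variant asks whether the pathway outperforms a random gene set of the same
size: L permuted gene sets are drawn without replacement from the gene
universe (exact size matching; a gene carries its own weight wherever it
is shuffled), and the competitive p-value is the fraction of permuted
sets whose Lancaster p-value is at most the real pathway's. The plain
fraction (which can be 0) is the default; an add-one variant
`(1+count)/(1+L)` is available for downstream FDR.

## Estimating the covariance ρ_ij

The theory defines ρ_ij but not an estimator. The default is null
resampling: permute the phenotype (which preserves the genotype LD
architecture generating the correlation), rerun the gene-level tests,
transform each resampled p-vector by `F_i^{-1}(1−·)`, and take the sample
covariance across B resamples (default B = 1000 in the pipeline). An
analytic-zero and a user-supplied matrix are accepted alternatives. If a
noisy estimate implies a non-positive total variance, off-diagonals are
shrunk toward zero by the minimal factor restoring positivity (with a
warning). In the simulation engine the null resamples are fresh null
phenotypes, which are exchangeable with permutations under the global
null used there.

## Evaluating the mixture-of-chi-squares survival function

No closed form exists for `Pr(Σ λ_k χ²_1 > q)` with general weights. The
evaluation chain, in order:

1. trailing eigenvalues whose cumulative squared sum is below
   `(3e-3·λ_max)²` are absorbed as a mean shift of q (first-order exact;
   the residual error is of order the dropped standard deviation squared,
   ~1e-5);
2. one distinct eigenvalue (or all tied): exact scaled chi-square;
3. Ruben's series — the mixture survival expands with β = min λ as
   `Σ_k a_k Pr(χ²_{K+2k} > q/β)` with non-negative a_k summing to one, so
   truncation error is bounded by the untouched coefficient mass
   (tolerance 1e-9, at most 10⁴ terms, geometric convergence at rate
   `1 − min/max`);
4. Imhof's characteristic-function inversion (adaptive quadrature over a
   truncation point set by the integrand's envelope bound) when the
   series would converge too slowly;
5. the Liu three-moment (non-central chi-square) approximation as a last
   resort, logged, and flagged in outputs.

Chi-square quantile transforms, survival functions and combined p-values
are computed in log space where available; combined p-values below the
double-precision floor are reported through `log10_p`. For the
normal-quantile (Z) combiners, p-values at the boundaries are clamped to
[1e-300, 1 − 1e-15] to avoid infinite quantiles; the chi-square combiners
accept p = 1 exactly (the transform contributes 0).

## Synthetic data

The generator emulates an exome-sequencing pathway study:

- **MAF spectrum**: 80% of variants rare, Uniform(0.001, 0.03); the rest
  Uniform(0.03, 0.5). A rare-heavy stand-in for an exome spectrum; both
  the fractions and ranges are configuration.
- **LD**: haplotypes from a Gaussian-threshold copula — within blocks of
  10 adjacent variants the latent normals share an exchangeable
  correlation 0.5; dosage = sum of two independent haplotypes. Blocks are
  laid down independently of gene boundaries, so neighbouring genes share
  LD and their p-values correlate (the regime the Satterthwaite
  correction exists for).
- **Pathways**: by default each pathway draws its genes from a shared
  pool (sizes uniform on 10–100), reproducing the heavy gene sharing of
  real pathway databases; a partition mode and an explicit
  overlap-fraction mode exist for controlled experiments. Variant counts
  per gene are 1 + Poisson (mean ≈ 12.4 variants per gene overall).
- **Effects**: the hierarchical model β_pgv = C_p · C_g d_g · C_gv d_gv ·
  e_pgv. One central causal pathway; 50% of its genes causal; 70% of the
  variants in causal genes causal; signs detrimental/protective 80/20 at
  both gene and variant level; |β| = |log10 MAF| (rare variants stronger)
  or 1/√(MAF(1−MAF)). The "1/MAF(1−MAF)" law is read as the standard
  inverse-SD convention 1/√(MAF(1−MAF)); the literal reciprocal-variance
  form is available as `effect_law="inv_var_maf_literal"`.
- **Noise**: σ² = Var(Xβ)(1−h²)/h² targets heritability h² = 0.2.
- **Defaults** mirror the reference design: 822 subjects, 353 pathways,
  3304 genes, α = 0.05 with Bonferroni correction across pathways.

What the generator does **not** emulate: real haplotype structure
(recombination hotspots, population-specific LD decay), population
stratification (single homogeneous population by default; genotype PCs
can be passed into X but are off), genotyping/calling error, and
non-normal trait distributions. Calibration and power results on this
generator therefore demonstrate the statistical machinery, not
performance on any particular cohort.

## Gene-level Lancaster weights

Four weight functions for the pathway stage:

- **uniform**: w = 2 (Fisher).
- **gene size**: w = 2·median(n_i)/n_i with n_i the SNP count of gene i —
  deflates large genes.
- **AIC / BIC**: w = 2·Δ_i/median(Δ), floored at 0.1, where Δ_i is the
  criterion difference of the gene's null-vs-full multi-SNP linear
  regression. The originating description ("degrees of variation
  summarized by the gene-level multi-SNP regression") does not pin down a
  formula; this normalized criterion-difference form keeps weights
  strictly positive and comparable across genes, and is recorded as a
  package choice. Under a global null the median Δ is negative (ΔAIC ≈
  −J_i), so the ratio is positive but genes with strong chance
  association receive *smaller* weights; empirically this makes the
  AIC/BIC-weighted tests conservative (inflation factor well below 1),
  consistent in direction with their being the most conservative weights
  in the reference results.
- **case-study MAF weights**: w2 = 4·MAF(1−MAF) (up-weights common
  variants) and w3 = 1/(MAF(1−MAF)) (up-weights rare), at the gene's mean
  MAF.

Because the AIC/BIC weights depend on the observed phenotype, the
simulation engine recomputes them per replicate and re-transforms the
permutation p-value matrix accordingly; the size-based and uniform
weights are fixed per genotype batch.

## Scenario evaluation

`run_scenario` fixes genotypes and pathway structure per batch (default 5
batches), redraws phenotypes per replicate, and estimates the null
covariance once per batch from B = 400 null-phenotype resamples. Gene
p-values inside the engine use the fast moment-matched mixture evaluation
(the same route for real and resampled phenotypes, so the moment matching
is self-consistent); the public `skat_pvalue` API uses the exact chain
above. Pathway p-values are thresholded at α/n_pathways (Bonferroni).
Reported quantities: pathway type I error (null scenarios), stringent
power (the central causal pathway is detected), lenient power (any
pathway sharing a causal gene with it is detected), and the Q-Q inflation
factor λ of the pooled pathway p-values.

The inflation factor is the ratio of the trapezoid area under the curve
of sorted observed −log10 p against −log10 expected uniform quantiles
((i−0.5)/m, rank-matched) to the area under the identity line, both
anchored at the origin and ending at −log10(0.5/m). The extreme order
statistics dominate this area, so single-draw λ values scatter with
standard deviation ≈ 0.05 at m = 10⁴ even for perfectly uniform inputs.

Problem sizes used by the shipped acceptance computations: the
heritability check runs 100 replicates at n = 1000 over ~300 genes; the
null-calibration check runs 500 replicates at n = 500 with 40 pathways
over 300 genes — a scaled-down version of the full design chosen to keep
the runs desk-sized while leaving Monte-Carlo error well inside the
asserted bands.

## Numerical and design notes

- Lancaster with w = 2 uses −2 ln p exactly, making Fisher a bit-for-bit
  special case.
- Good's combiner: with pairwise-distinct weights the closed-form null
  CDF `Σ Λ_i q^{1/w_i}`, `Λ_i = w_i^{m−1}/Π_{j≠i}(w_i−w_j)` is used; with
  all weights equal the statistic is a rescaled Fisher statistic and the
  null is the exact χ²_{2m}; partial ties (where the Λ_i are undefined
  and no rescale exists) use a seeded Monte-Carlo null (10⁶ draws by
  default).
- Good's correlated Bahadur slope uses Σw² in its denominator as stated
  in its source; note it does not reduce to the independent max-weight
  form at zero correlation. Both forms are reported as-is rather than
  reconciled.
- The displayed weighted-Z slope formula lost radical signs in its
  source's typesetting; the implementation follows the underlying
  derivation: slope = (Σ w_i √(λ_i c_i))² / Σ w_i².
- Competitive rankings under a common-weight rescale are preserved only
  up to near-ties: the chi-square quantile transform is nonlinear in w,
  so orderings of set sums can swap when two sets are nearly tied.
- Degenerate inputs: p = 0 is rejected (the transform diverges); an
  all-zero genotype matrix yields Q = 0 and p = 1 with a warning; a
  rank-deficient covariate matrix is an error; competitive pathways
  larger than the gene universe are an error.

## Known limitations

- Continuous traits only; binary-trait SKAT, burden/C-alpha tests and
  SKAT-O are out of scope, as are mixed-model (kinship) adjustments.
- The Satterthwaite null matches two moments; its extreme tail deviates
  slightly from the exact correlated null, so astronomically small
  pathway p-values should be read as orders of magnitude, not exact
  values.
- The competitive permutation null shuffles genes, not subjects; it does
  not condition on gene-gene correlation within the permuted sets.
- Gene identifiers are matched by exact case-sensitive string equality;
  no symbol aliasing.
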