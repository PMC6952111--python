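# Methods

## Generative model and posterior

For a locus of m variants with marginal z-scores S and LD matrix Σ, the
model is the standard summary-statistic multivariate normal: given true
(z-scale) effects Λ, `S | Λ ~ N(ΣΛ, Σ)`; given a binary causal
configuration C, `Λ | C ~ N(0, σ² diag(C))`. Integrating Λ out gives

    S | C ~ N(0, Σ + σ² Σ diag(C) Σ).

σ defaults to 5.2, the conventional prior scale for the effect of a causal
variant that reaches genome-wide-scale significance with ~50% power. The
prior over configurations is independent Bernoulli(π = 0.01) per variant,
truncated to `1 ≤ |C| ≤ k_max`. Two choices deserve comment:

- **At least one causal variant.** The framework is applied only to genes
  pre-selected for a significant eQTL, so the model space excludes the
  all-zero configuration by default (`CausalPrior.include_null=False`).
  This is not cosmetic: the meta-analysis produces two statistic forms, and
  when the signs of the eQTL and AIM statistics agree one of the two forms
  is essentially signal-free. If the null configuration were allowed, the
  signal-free form would concentrate its posterior on "no causal variant"
  and return a near-empty causal set, the smaller-set rule would select it,
  and the recall of the meta approach would collapse (~0.80 in our
  simulations instead of ≥ 0.95). With the null excluded, a signal-free
  statistic spreads its posterior over all single-variant configurations
  and yields a near-full set, which the smaller-set rule correctly rejects.
  `include_null=True` remains available for single-statistic diagnostics.
- **k_max.** The model bound is 6 causal variants per locus; desk-scale
  analyses and the shipped experiments use `k_max = 3` (≈ 2.1 × 10⁴
  configurations at m = 50), which enumerates in milliseconds. A budget
  guard refuses > 10⁷ configurations.

The posterior is enumerated exactly and normalized by log-sum-exp; the
ρ-causal set is grown greedily, at each step adding the variant that most
increases the covered mass f(K) = Σ {P(C|S) : support(C) ⊆ K}, stopping at
f(K) ≥ ρ. Ties go to the lowest variant index. f is monotone with
f(full set) = 1, so termination is guaranteed; on random m = 8 posteriors
the greedy set matches the exhaustive minimal set in well over 90% of
cases and never fails the coverage bound. The greedy objective is the
covered configuration mass, not the sum of per-variant inclusion
probabilities; the two coincide for single-causal posteriors but the
former is the one with the coverage-interval semantics.

### Numerics

Writing E for the identity columns at the causal indices,
`Σ diag(C) Σ = (ΣE)(ΣE)ᵀ`, and the Woodbury identity reduces each
configuration's density to a k×k solve against `M = I + σ² Σ[idx, idx]`:
`log|Cov| = log|Σ| + log|M|` and
`SᵀCov⁻¹S = SᵀΣ⁻¹S − σ² S[idx]ᵀ M⁻¹ S[idx]`. All configurations of one
size are evaluated with batched (stacked) linear algebra. A dense-Cholesky
evaluation of the same density ships alongside and the two agree to 1e-8
on random m = 50 instances; the enumerated posterior is additionally
checked against a brute-force scipy-MVN oracle at m ≤ 8.

Empirical correlation matrices are rank-deficient whenever m exceeds the
sample count, so every matrix passes through
`regularize: Σ → (Σ + ridge·I)/(1 + ridge)` with ridge = 1e-3 before any
factorization. This keeps the unit diagonal exactly, changes no entry by
more than the ridge, and makes the smallest eigenvalue strictly positive.

## Association statistics

- **eQTL z-scores**: per-variant OLS with standardized dosages,
  `z_i = (β̂_i/σ̂_i)√n`, `σ̂² = RSS/(n−2)`. Covariates are residualized out
  of the phenotype once per gene before the per-variant fits — equivalent
  for the z-score up to degrees of freedom, which follow the printed n−2
  regardless. Constant dosage columns are dropped with a warning; a perfect
  fit (σ̂ = 0) raises. Precomputed z-score TSVs are accepted in place of
  expression data.
- **AIM z-scores**: the pooled two-proportion (case/control) z comparing
  heterozygote fractions between AIM and balanced individuals. Genes with
  zero AIM individuals are skipped — the statistic does not exist. Variants
  whose pooled heterozygote fraction is 0 or 1 among the status-called
  individuals carry no AIM information and are excluded from the analysis
  (and from the eQTL side, to keep the vectors aligned).
- **Correlation matrices**: Σ_E is the Pearson correlation of dosages,
  Σ_A of 0/1 heterozygosity indicators, Σ_M their entrywise average.
  Σ_A is computed over the individuals with a non-missing AIM call for the
  gene (the set actually informing the AIM statistic); computing it over
  all genotyped individuals is a one-line change in the pipeline and makes
  little difference in practice.

## AIM calling

Per sample-gene: the aiSNP is the heterozygous coding SNP with the most
reads (ties: lexicographically smallest SNP id), a ≥ 20-read total filter
is applied, and the allelic ratio is binarized either by the empirical rule
(AIM iff AR < 0.35 or AR > 0.65, strict inequalities — boundary ratios are
balanced) or by an exact two-sided binomial test at α = 0.05 (minlike
two-sided rule: sum of all outcome probabilities ≤ the observed one; this
gives p = 0.1153 for counts 6/14). The 0.35/0.65 defaults correspond to
two standard deviations of an empirical allelic-ratio distribution around
0.5 with SD 0.075; `empirical_thresholds` re-derives thresholds from any
supplied AR sample. Exhaustive enumeration over all count pairs with ≤ 40
total reads confirms the empirical rule calls a superset of the binomial
rule's AIM labels — the binomial rule is the stringent one, and on data
with typical read depths it leaves many genes with zero AIM individuals,
which is why the empirical rule is the default.

## Synthetic data

The generator produces every input the pipeline consumes, at three levels:

- **Haplotypes.** A latent-Gaussian threshold copula: each haplotype's
  allele vector thresholds a latent MVN draw at Φ⁻¹(MAF). Within an LD
  block the pairwise latent correlations are calibrated through the
  bivariate-normal orthant probability (Owen's T) so that the *binary*
  allele correlation — hence the genotype correlation — matches the
  block's target in expectation; blocks are independent; haplotypes are
  i.i.d., so genotypes are Hardy–Weinberg. Because two binary variables
  with very different frequencies cannot be highly correlated, MAFs are
  drawn per block (base frequency plus a jitter that narrows as the target
  correlation grows), which is also how real LD blocks look. Default MAF
  range (0.1, 0.5); 325 diploid samples, matching a typical single-tissue
  eQTL panel.
- **Summary statistics.** Direct draws from the sampling distribution
  `S ~ N(λ Σ C, Σ)` given an LD matrix, causal configuration and
  non-centrality λ. `ncp_for_power`/`power_for_ncp` map two-sided power to
  λ; the default significance threshold is the one whose critical value is
  5.2, anchoring 50% power at λ = 5.2 (so 80% power ↦ λ ≈ 6.04).
- **Reads.** Allelic counts at an aiSNP: Binomial(depth, 0.5 + effect) for
  heterozygous carriers of the causal variant, Binomial(depth, 0.5)
  otherwise, with constant or Poisson depth.

The default simulated locus is a *single* LD block of all 50 variants at
target correlation 0.8. This mirrors how loci reach the fine-mapper in
practice: the m = 50 input variants are the top eQTL hits of a gene,
selected for association and therefore mutually correlated with the causal
variant. Scattering the variants over many small independent blocks would
surround the signal with pure nulls — a geometry the selection step never
produces — and dilutes the reduction rate accordingly.

What the generator does **not** emulate: real LD spectra (block-constant
targets only), reference/mapping bias in allele-specific reads, phasing
errors, multi-SNP read overlap, or covariate structure in expression.
Passing simulations therefore demonstrate the statistical machinery —
calibration of the coverage contract, the benefit of a second orthogonal
statistic, correctness of the posterior — not robustness to those
real-data artifacts; absolute reduction rates depend strongly on the LD
distribution and transfer only qualitatively.

All randomness flows through one scenario seed; per-locus streams derive
deterministically from (seed, locus index), so scenarios are reproducible
and embarrassingly parallel.

## Experiment sizes

The shipped studies use 500 loci for the matched-effect recall/reduction
study and 200 paired loci per point for the AIM effect-size sweep
(λ_A ∈ {2.0, 3.0, 4.0, 5.2} at λ_E = 5.2), with m = 50, ρ = 0.95,
σ = 5.2, k_max = 3; the sweep shares loci and eQTL draws across points so
the comparison is paired. At 500 loci the two-sided binomial Monte-Carlo
error on a 0.95 recall is about ±0.02, which is the slack the recall check
allows; the sweep's monotonicity check allows 0.02 of median noise.

## Meta-analysis details

Equal 1/√2 weights are the default (the two "studies" are treated as
equally sized); an inverse-variance-style weighted combination is available
but off by default. The exact joint model — two conditionally independent
MVN likelihoods, one per statistic — is implemented as
`joint_log_likelihood` and serves as the oracle for the approximation: the
acceptance region of thresholding both meta forms is the square inscribed
in the joint model's circular region, and configuration rankings under the
two models agree (Spearman > 0.8 in simulation). The exact covariance of
the combined statistic given a configuration,
`½(Σ_E+Σ_A) + ½(σ_a²Σ_A Σ_c Σ_A + σ_e²Σ_E Σ_c Σ_E)`, is exposed as
`meta_config_covariance` and verified against Monte-Carlo draws; the
fine-mapping step itself uses the simpler Σ_M-based CAVIAR-form covariance,
with σ_a = σ_e = σ = 5.2 throughout.

## Degenerate inputs and tie-breaks

Zero total reads → undefined allelic ratio (error; callers filter first).
aiSNP ties → smallest SNP id. Boundary allelic ratios (exactly 0.35/0.65)
→ balanced. Constant genotype columns → dropped from the eQTL scan.
All-het / no-het columns among AIM-called individuals → variant excluded
from the gene's analysis. Greedy ties → lowest variant index. Meta set
ties (equal sizes) → the S_M1 set. Gene-level failures in the pipeline are
logged with a reason and skipped, never fatal.

## Limitations

Exact enumeration bounds m (top-50 selection) and k_max; no stochastic
posterior approximation is provided. No functional-annotation priors. The
AIM statistic binarizes per-individual imbalance and uses only the deepest
aiSNP, trading sensitivity for robustness to noisy allele-specific counts.
The pipeline assumes expression is pre-normalized and genotypes pre-phased;
no covariate inference, normalization, imputation or read realignment is
performed.
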